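"""Synthetic circadian methylome generator: ground truth and closure."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import nnls

from rhythmage import (
    MixtureSchedule,
    SimulationConfig,
    compute_clock,
    deviation_proportion_correlation,
    estimate_proportions,
    extend_clock_with_sites,
    fit_cosinor,
    generate_reference_profiles,
    generate_toy_clock,
    proportions_at_time,
    screen_sites,
    select_reference_sites,
    simulate_study,
)
from tests.conftest import TOY_TARGETS


class TestReferenceProfiles:
    def test_same_seed_identical(self):
        a = generate_reference_profiles(100, 3, seed=5)
        b = generate_reference_profiles(100, 3, seed=5)
        pd.testing.assert_frame_equal(a.betas, b.betas)
        assert a.discriminating == b.discriminating

    def test_values_in_unit_interval_and_markers_planted(self):
        panel = generate_reference_profiles(100, 2, seed=5, n_discriminating=10)
        arr = panel.betas.to_numpy()
        assert arr.min() >= 0 and arr.max() <= 1
        diff = np.abs(arr[:, 0] - arr[:, 1]) > 0.5
        assert diff.sum() >= 20  # both types' marker sites separate the columns

    def test_mixtures_uniquely_recoverable_noiseless(self):
        panel = generate_reference_profiles(1000, 6, seed=5)
        R = panel.betas.loc[panel.discriminating_sites].to_numpy()
        assert np.isfinite(np.linalg.cond(R))
        truth = np.array([0.1, 0.15, 0.2, 0.25, 0.2, 0.1])
        w, _ = nnls(R, R @ truth)
        assert np.abs(w - truth).max() < 1e-8

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            generate_reference_profiles(0, 3, seed=1)
        with pytest.raises(ValueError):
            generate_reference_profiles(100, 1, seed=1)


class TestProportionsAtTime:
    def test_zero_amplitude_returns_base(self):
        sched = MixtureSchedule.constant(("a", "b"), (0.25, 0.75))
        assert proportions_at_time(sched, 7.3) == pytest.approx([0.25, 0.75])

    def test_two_type_antiphasic_closed_form(self):
        sched = MixtureSchedule(
            ("a", "b"), (0.5, 0.5), (0.1, 0.1), (0.0, 12.0)
        )
        # at t=0: raw = (0.6, 0.4), already sums to 1
        assert proportions_at_time(sched, 0.0) == pytest.approx([0.6, 0.4])

    def test_periodicity(self):
        sched = MixtureSchedule(
            ("a", "b", "c"), (0.2, 0.3, 0.5), (0.1, 0.2, 0.0), (3.0, 15.0, 0.0)
        )
        for t in (0.0, 5.5, 13.25):
            assert proportions_at_time(sched, t) == pytest.approx(
                proportions_at_time(sched, t + sched.period), abs=1e-12
            )

    def test_simplex_always(self):
        sched = MixtureSchedule(
            ("a", "b"), (0.5, 0.5), (0.5, 0.0), (0.0, 0.0)
        )
        out = proportions_at_time(sched, np.linspace(0, 24, 49))
        assert np.all(out >= 0)
        assert np.allclose(out.sum(axis=1), 1.0)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            MixtureSchedule(("a", "b"), (0.6, 0.6), (0, 0), (0, 0))  # sum != 1
        with pytest.raises(ValueError):
            MixtureSchedule(("a", "b"), (0.5, 0.5), (0.6, 0.0), (0, 0))  # amp > base


class TestSimulateStudy:
    def test_noiseless_samples_are_exact_mixtures(self, noiseless_study):
        st = noiseless_study
        profiles = st.panel.betas.to_numpy()
        for j, sid in enumerate(st.betas.columns):
            p = st.true_proportions.loc[sid].to_numpy()
            assert np.abs(st.betas[sid].to_numpy() - profiles @ p).max() < 1e-12

    def test_seed_determinism_bit_identical(self):
        cfg = SimulationConfig(n_cpgs=200, seed=42)
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        pd.testing.assert_frame_equal(a.betas, b.betas)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        assert a.oscillating_cpgs == b.oscillating_cpgs

    def test_invariants(self):
        st = simulate_study(SimulationConfig(n_cpgs=200, seed=8))
        arr = st.betas.to_numpy()
        assert arr.min() >= 0 and arr.max() <= 1
        assert np.allclose(st.true_proportions.sum(axis=1), 1.0, atol=1e-12)
        assert list(st.samples["sample_id"]) == list(st.betas.columns)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(noise_sd=-0.1)

    def test_intracellular_oscillators_recovered_by_screen(self):
        # 100 planted oscillating CpGs, amplitude 0.05, logit noise 0.01,
        # constant composition, 24 samples over 72 h
        types = ("Neu", "NK", "B", "CD4T", "CD8T", "Mono")
        sched = MixtureSchedule.constant(
            types, (0.2, 0.15, 0.15, 0.2, 0.15, 0.15)
        )
        cfg = SimulationConfig(
            n_cpgs=1000,
            frac_oscillating=0.1,
            oscillation_amplitude=0.05,
            frac_age_trend=0.0,
            noise_sd=0.01,
            seed=21,
        )
        st = simulate_study(cfg, schedule=sched)
        res = screen_sites(st.betas, st.samples["time_hours"].to_numpy())
        planted = set(st.oscillating_cpgs)
        detected = planted & set(res.significant)
        assert len(detected) >= 0.8 * len(planted)


class TestToyClocks:
    def test_linear_mixture_midpoint(self, panel6):
        clock = generate_toy_clock(
            panel6, dict.fromkeys(panel6.cell_types, 50.0) | {"NK": 60.0, "B": 40.0}
        )
        mix = pd.DataFrame(
            {"m": 0.5 * panel6.betas["NK"] + 0.5 * panel6.betas["B"]}
        )
        est = compute_clock(mix, clock)["value"].iloc[0]
        assert est == pytest.approx(50.0, abs=1e-8)

    def test_rate_clock_exact_on_pure_profiles(self, panel6):
        targets = {c: 20.0 * TOY_TARGETS[c] for c in panel6.cell_types}
        clock = generate_toy_clock(panel6, targets, "rate")
        est = compute_clock(panel6.betas, clock, missing_policy="drop")
        for ct, value in zip(panel6.cell_types, est["value"]):
            assert value == pytest.approx(targets[ct], rel=1e-6)

    def test_rank_deficient_profiles_rejected(self):
        frame = pd.DataFrame(
            {"a": [0.5, 0.5], "b": [0.5, 0.5]}, index=["cg1", "cg2"]
        )
        with pytest.raises(ValueError, match="rank"):
            generate_toy_clock(frame, {"a": 40.0, "b": 60.0})

    def test_missing_target_rejected(self, panel6):
        with pytest.raises(ValueError):
            generate_toy_clock(panel6, {"NK": 50.0})

    def test_extended_clock_preserves_pure_predictions(self, panel6, toy_linear_clock):
        marker = set(panel6.discriminating_sites)
        extra = [c for c in panel6.betas.index if c not in marker][:20]
        extended = extend_clock_with_sites(
            toy_linear_clock, panel6.betas, extra, weight=0.5
        )
        base = compute_clock(panel6.betas, toy_linear_clock)["value"]
        ext = compute_clock(panel6.betas, extended)["value"]
        assert np.abs(base.to_numpy() - ext.to_numpy()).max() < 0.2

    def test_subtype_age_sign_pattern_in_deconvolved_blood(self, panel6):
        # NK-older / B-younger / CD4T-younger targets reproduce the
        # deviation-proportion correlation sign pattern (+, -, -)
        clock = generate_toy_clock(panel6, TOY_TARGETS)
        rng = np.random.default_rng(31)
        n = 200
        props = rng.dirichlet(np.full(6, 20.0), size=n)
        betas = pd.DataFrame(
            panel6.betas.to_numpy() @ props.T,
            index=panel6.betas.index,
            columns=[f"P{i}" for i in range(n)],
        )
        ages = compute_clock(betas, clock)["value"].to_numpy()
        est = estimate_proportions(
            betas, panel6.betas, select_reference_sites(panel6.betas, 10)
        )
        deviations = ages - 50.0  # common chronological age
        r_nk, _ = deviation_proportion_correlation(deviations, est, "NK")
        r_b, _ = deviation_proportion_correlation(deviations, est, "B")
        r_cd4, _ = deviation_proportion_correlation(deviations, est, "CD4T")
        assert r_nk > 0 and r_b < 0 and r_cd4 < 0


class TestNoiselessClosure:
    def test_simulate_deconvolve_recovers_truth(self, noiseless_study):
        st = noiseless_study
        sites = select_reference_sites(st.panel.betas, 10)
        est = estimate_proportions(st.betas, st.panel.betas, sites)
        err = np.abs(
            est[st.panel.cell_types].to_numpy() - st.true_proportions.to_numpy()
        )
        assert err.max() < 1e-6

    def test_mixture_induced_age_oscillation_acrophase(self, noiseless_study):
        st = noiseless_study
        clock = generate_toy_clock(st.panel, TOY_TARGETS)
        values = (
            compute_clock(st.betas, clock)
            .set_index("sample_id")
            .loc[st.betas.columns, "value"]
            .to_numpy()
        )
        times = st.samples["time_hours"].to_numpy()
        fit = fit_cosinor(times, values)
        # oracle: cosinor of the schedule-induced age curve on a dense grid
        dense_t = np.linspace(0, 24, 241)[:-1]
        p = np.stack([proportions_at_time(st.schedule, t) for t in dense_t])
        targets = np.array([TOY_TARGETS[c] for c in st.panel.cell_types])
        oracle = fit_cosinor(dense_t, p @ targets)
        gap = abs(fit.acrophase - oracle.acrophase) % 24
        assert min(gap, 24 - gap) < 0.5
        assert fit.p_value < 0.05
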