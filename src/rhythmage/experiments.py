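"""Seeded generative experiments over the full pipeline.

Each experiment simulates studies with the synthetic generator, runs the
corresponding estimators, and reports recovery/calibration statistics.
They are deliberately scaled down (hundreds of CpGs, tens of samples) so
a full battery runs in minutes on one CPU; the methods note documents the
problem sizes.  All randomness derives from one integer seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .adjustment import intrinsic_age_residuals, paired_timepoint_contrast
from .clocks import compute_clock
from .cosinor import fit_cosinor, fit_cosinor_combined, screen_sites
from .deconvolution import estimate_proportions, select_reference_sites
from .synthetic import (
    MixtureSchedule,
    SimulationConfig,
    default_wbc_schedule,
    extend_clock_with_sites,
    generate_reference_profiles,
    generate_toy_clock,
    simulate_study,
)

# the 72-h single-subject collection design: every 3 h for 72 h
WBC_NEU_TIMES = tuple(float(t) for t in range(0, 72, 3))
# the multi-subject neutrophil design: every 3 h for 24 h
NEUTROPHIL_TIMES = tuple(float(t) for t in range(0, 25, 3))

TOY_TARGETS = {
    "Neu": 50.0, "NK": 56.0, "B": 44.0, "CD4T": 46.0, "CD8T": 50.0, "Mono": 50.0,
}


def _circular_error(est: float, true: float, period: float = 24.0) -> float:
    d = (est - true) % period
    return min(d, period - d)


def cosinor_noise_recovery(
    n_reps: int = 200,
    seed: int = 0,
    mesor: float = 50.0,
    amplitude: float = 3.0,
    acrophase: float = 12.0,
) -> dict:
    """Acrophase recovery of a noisy cosine on the 72-h design.

    Noise sd is amplitude/3.  Returns the fraction of replicates with
    acrophase error below 1 h and the error distribution.
    """
    rng = np.random.default_rng([seed, 11])
    t = np.array(WBC_NEU_TIMES)
    sd = amplitude / 3.0
    errors = np.empty(n_reps)
    for r in range(n_reps):
        y = (
            mesor
            + amplitude * np.cos(2 * np.pi * (t - acrophase) / 24.0)
            + rng.normal(0.0, sd, size=t.size)
        )
        fit = fit_cosinor(t, y)
        errors[r] = _circular_error(fit.acrophase, acrophase)
    return {
        "errors_h": errors,
        "fraction_within_1h": float(np.mean(errors < 1.0)),
        "n_reps": n_reps,
    }


def null_pvalue_calibration(n_reps: int = 2000, seed: int = 0, n: int = 24) -> dict:
    """Zero-amplitude test calibration under the null (i.i.d. Gaussian).

    Returns the replicate p-values (vectorised via the site screen) and
    the empirical type-I error at alpha = 0.05.
    """
    rng = np.random.default_rng([seed, 12])
    t = np.array(WBC_NEU_TIMES[:n])
    y = rng.normal(size=(n_reps, n))
    frame = pd.DataFrame(y, index=[f"rep{i}" for i in range(n_reps)])
    res = screen_sites(frame, t, alpha=0.05)
    p = res.p_values.to_numpy()
    return {
        "p_values": p,
        "type_i_error": float(np.mean(p < 0.05)),
        "n_reps": n_reps,
    }


def combined_cosinor_recovery(
    n_reps: int = 40, seed: int = 0, snr: float = 3.0
) -> dict:
    """Per-subject acrophase recovery of the combined multi-subject fit.

    Three subjects sampled every 3 h over 24 h (9 points each) with
    distinct MESOR/amplitude/acrophase; noise sd = amplitude/snr per
    subject.  Reports per-replicate maximal acrophase error, the
    all-three-within-1-h rate and the joint zero-amplitude p-values.
    """
    rng = np.random.default_rng([seed, 13])
    t = np.array(NEUTROPHIL_TIMES)
    params = [
        ("subj01", 50.0, 2.0, 4.0),
        ("subj02", 55.0, 2.5, 10.0),
        ("subj03", 60.0, 3.0, 18.0),
    ]
    max_errors = np.empty(n_reps)
    p_values = np.empty(n_reps)
    for r in range(n_reps):
        times, values, ids = [], [], []
        for sid, mesor, amp, acro in params:
            y = (
                mesor
                + amp * np.cos(2 * np.pi * (t - acro) / 24.0)
                + rng.normal(0.0, amp / snr, size=t.size)
            )
            times.append(t)
            values.append(y)
            ids.extend([sid] * t.size)
        fit = fit_cosinor_combined(
            np.concatenate(times), np.concatenate(values), np.array(ids)
        )
        errs = [
            _circular_error(fit.subjects[sid].acrophase, acro)
            for sid, _, _, acro in params
        ]
        max_errors[r] = max(errs)
        p_values[r] = fit.p_value
    return {
        "max_acrophase_errors_h": max_errors,
        "all_within_1h_rate": float(np.mean(max_errors < 1.0)),
        "median_max_error_h": float(np.median(max_errors)),
        "joint_significant_rate": float(np.mean(p_values < 0.05)),
        "n_reps": n_reps,
    }


def deconvolution_noise_error(
    n_samples: int = 50, seed: int = 0, noise_sd: float = 0.05
) -> dict:
    """Mean absolute proportion error under logit-normal noise.

    Random simplex mixtures of a 3-type panel, logit-scale noise of the
    given sd on the mixed betas, Houseman-style recovery on the selected
    marker sites.
    """
    from scipy.special import expit, logit

    rng = np.random.default_rng([seed, 14])
    panel = generate_reference_profiles(200, 3, seed=seed, n_discriminating=10)
    ref = panel.betas
    true = rng.dirichlet(np.ones(3), size=n_samples)
    mixed = ref.to_numpy() @ true.T
    z = logit(np.clip(mixed, 1e-6, 1 - 1e-6))
    noisy = expit(z + rng.normal(0.0, noise_sd, size=z.shape))
    betas = pd.DataFrame(
        noisy, index=ref.index, columns=[f"S{i:03d}" for i in range(n_samples)]
    )
    sites = select_reference_sites(ref, 10)
    est = estimate_proportions(betas, ref, sites)
    err = np.abs(est[ref.columns].to_numpy() - true)
    return {
        "mean_abs_error": float(err.mean()),
        "n_samples": n_samples,
    }


def _clock_series(study, clock) -> np.ndarray:
    est = compute_clock(study.betas, clock)
    return est.set_index("sample_id").loc[study.betas.columns, "value"].to_numpy()


def composition_mechanism(n_reps: int = 200, seed: int = 0, n_cpgs: int = 300) -> dict:
    """Composition-only oscillation: raw clock estimates oscillate, the
    cell-count-adjusted residuals do not.

    Single subject, 24 samples over 72 h, oscillating NK/B/CD4T mixture
    proportions, no intracellular oscillators.  Returns the replicate
    rates of raw cosinor p < 0.05 and adjusted cosinor p > 0.05.
    """
    raw_sig = np.zeros(n_reps, dtype=bool)
    adj_nonsig = np.zeros(n_reps, dtype=bool)
    schedule = default_wbc_schedule()
    for r in range(n_reps):
        cfg = SimulationConfig(
            n_cpgs=n_cpgs,
            times=WBC_NEU_TIMES,
            frac_oscillating=0.0,
            frac_age_trend=0.0,
            noise_sd=0.05,
            seed=(seed * 100003 + r) % (2**31),
        )
        study = simulate_study(cfg, schedule=schedule)
        clock = generate_toy_clock(study.panel, TOY_TARGETS, "linear")
        times = study.samples["time_hours"].to_numpy()
        values = _clock_series(study, clock)
        raw = fit_cosinor(times, values)
        raw_sig[r] = raw.p_value < 0.05

        sites = select_reference_sites(study.panel.betas, 10)
        props = estimate_proportions(study.betas, study.panel.betas, sites)
        resid = intrinsic_age_residuals(
            values, study.samples["age_years"].to_numpy(), props
        )
        adj = fit_cosinor(times, resid)
        adj_nonsig[r] = adj.p_value > 0.05
    return {
        "raw_significant_rate": float(raw_sig.mean()),
        "adjusted_nonsignificant_rate": float(adj_nonsig.mean()),
        "n_reps": n_reps,
    }


def intracellular_mechanism(
    n_reps: int = 200, seed: int = 0, n_cpgs: int = 300
) -> dict:
    """Intracellular oscillation on clock CpGs survives cell-count
    adjustment.

    A mostly-pure neutrophil fraction with near-constant composition; 20
    clock CpGs (disjoint from the deconvolution marker sites) oscillate
    within neutrophils with beta amplitude 0.05.  Returns the replicate
    rates of raw and adjusted cosinor significance.
    """
    types = ("Neu", "NK", "B", "CD4T", "CD8T", "Mono")
    schedule = MixtureSchedule(
        cell_types=types,
        base=(0.85, 0.03, 0.03, 0.04, 0.03, 0.02),
        amplitude=(0.02, 0.0, 0.0, 0.0, 0.0, 0.0),
        acrophase=(0.0,) * 6,
    )
    raw_sig = np.zeros(n_reps, dtype=bool)
    adj_sig = np.zeros(n_reps, dtype=bool)
    for r in range(n_reps):
        rep_seed = (seed * 100003 + 50000 + r) % (2**31)
        panel = generate_reference_profiles(
            n_cpgs, 6, seed=rep_seed, n_discriminating=10, cell_types=list(types)
        )
        marker = set(panel.discriminating_sites)
        extra = [c for c in panel.betas.index if c not in marker][:20]
        base_clock = generate_toy_clock(panel, TOY_TARGETS, "linear")
        clock = extend_clock_with_sites(base_clock, panel.betas, extra, weight=0.5)
        cfg = SimulationConfig(
            n_cpgs=n_cpgs,
            times=WBC_NEU_TIMES,
            oscillating_cpgs=tuple(extra),
            oscillation_amplitude=0.05,
            oscillation_acrophase=8.0,
            oscillating_cell_types=("Neu",),
            frac_age_trend=0.0,
            noise_sd=0.05,
            seed=rep_seed,
        )
        study = simulate_study(cfg, schedule=schedule, panel=panel)
        times = study.samples["time_hours"].to_numpy()
        values = _clock_series(study, clock)
        raw_sig[r] = fit_cosinor(times, values).p_value < 0.05

        sites = select_reference_sites(panel.betas, 10)
        props = estimate_proportions(study.betas, panel.betas, sites)
        resid = intrinsic_age_residuals(
            values, study.samples["age_years"].to_numpy(), props
        )
        adj_sig[r] = fit_cosinor(times, resid).p_value < 0.05
    return {
        "raw_significant_rate": float(raw_sig.mean()),
        "adjusted_significant_rate": float(adj_sig.mean()),
        "n_reps": n_reps,
    }


def timepoint_contrast_experiment(
    n_reps: int = 200,
    seed: int = 0,
    n_pairs: int = 32,
    t1: float = 12.75,
    t2: float = 16.25,
    amplitude: float = 1.5,
    acrophase: float = 12.0,
    noise_sd: float = 1.0,
) -> dict:
    """Direction of the afternoon-vs-noon paired contrast.

    Per replicate, ``n_pairs`` donors carry a common 24-h oscillation of
    epigenetic age (acrophase near noon) on top of donor-specific MESORs;
    estimates at 12:45 and 16:15 are compared by paired t-test.  Returns
    the rate of negative mean (t2 - t1) differences and the mean
    difference distribution.
    """
    rng = np.random.default_rng([seed, 15])
    negative = np.zeros(n_reps, dtype=bool)
    mean_diffs = np.empty(n_reps)
    w = 2 * np.pi / 24.0
    for r in range(n_reps):
        mesor = rng.normal(55.0, 2.0, size=n_pairs)
        y1 = (
            mesor
            + amplitude * np.cos(w * (t1 - acrophase))
            + rng.normal(0.0, noise_sd, size=n_pairs)
        )
        y2 = (
            mesor
            + amplitude * np.cos(w * (t2 - acrophase))
            + rng.normal(0.0, noise_sd, size=n_pairs)
        )
        ids = np.array([f"donor{i:02d}" for i in range(n_pairs)])
        contrast = paired_timepoint_contrast(y1, y2, ids)
        negative[r] = contrast.mean_difference < 0
        mean_diffs[r] = contrast.mean_difference
    return {
        "negative_rate": float(negative.mean()),
        "mean_differences": mean_diffs,
        "n_reps": n_reps,
    }


def site_screen_power(
    seed: int = 0,
    n_planted: int = 100,
    n_null: int = 900,
    amplitude: float = 0.05,
    noise_sd: float = 0.01,
) -> dict:
    """Sensitivity of the per-CpG screen for planted oscillators.

    Planted sites oscillate on the beta scale with the given amplitude
    (>= 3x the beta-scale noise) among null sites, 24 samples over 72 h.
    """
    rng = np.random.default_rng([seed, 16])
    t = np.array(WBC_NEU_TIMES)
    n_sites = n_planted + n_null
    base = rng.uniform(0.2, 0.8, size=n_sites)
    y = np.tile(base[:, None], (1, t.size))
    phases = rng.uniform(0, 24, size=n_planted)
    y[:n_planted] += amplitude * np.cos(
        2 * np.pi * (t[None, :] - phases[:, None]) / 24.0
    )
    y += rng.normal(0.0, noise_sd, size=y.shape)
    y = np.clip(y, 0.0, 1.0)
    ids = [f"osc{i}" for i in range(n_planted)] + [f"null{i}" for i in range(n_null)]
    frame = pd.DataFrame(y, index=ids, columns=[f"S{i}" for i in range(t.size)])
    res = screen_sites(frame, t, alpha=0.05)
    detected = sum(1 for s in res.significant if s.startswith("osc"))
    false_pos = sum(1 for s in res.significant if s.startswith("null"))
    return {
        "sensitivity": detected / n_planted,
        "false_positive_rate": false_pos / n_null,
        "n_planted": n_planted,
        "n_null": n_null,
    }
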