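"""Synthetic circadian methylome studies with known ground truth.

Whole-blood (or neutrophil-depleted) methylation profiles are modelled as
convex mixtures of cell-type reference methylomes whose mixing proportions
oscillate with a 24-h period — the mechanism by which cycling leukocyte
counts create apparent beta-value rhythms even when each cell type's
epigenome is static.  On top of the inter-cellular mixture the generator
can plant

* intracellular oscillators: a minority of CpGs whose beta oscillates
  within designated cell types (added to the cell-type profile *before*
  mixing),
* age-trend CpGs with a linear slope per year of chronological age,
* array-like measurement noise, additive Gaussian on the logit scale and
  back-transformed (heteroscedastic near 0/1, support-respecting).

Every study records its full ground truth (true proportions per sample,
the oscillating-site set, per-subject ages) so downstream estimators can
be verified end to end.  A fixed seed makes outputs bit-identical; all
sub-generators derive from the one study seed by fixed offsets.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .clocks import ClockDefinition

_BETA_EPS = 1e-6  # clipping bound after noise, keeps logit finite

DEFAULT_CELL_TYPES = ("Neu", "NK", "B", "CD4T", "CD8T", "Mono")


@dataclasses.dataclass(frozen=True)
class ReferencePanel:
    """Cell-type reference methylomes plus the planted discriminating sites.

    ``betas`` is CpG x cell-type with all values in [0, 1];
    ``discriminating`` maps each cell type to its planted marker CpGs
    (half hyper-, half hypo-methylated in that type relative to the rest).
    """

    betas: pd.DataFrame
    discriminating: dict[str, list[str]]

    @property
    def cell_types(self) -> list[str]:
        return list(self.betas.columns)

    @property
    def discriminating_sites(self) -> list[str]:
        out: list[str] = []
        for sites in self.discriminating.values():
            out.extend(sites)
        return out


@dataclasses.dataclass(frozen=True)
class MixtureSchedule:
    """24-h oscillation schedule of cell-type proportions.

    Each type's pre-normalisation proportion follows
    ``base_k + amplitude_k * cos(2*pi*(t - acrophase_k)/period)``; the
    vector is clipped at zero and renormalised, so the realised
    proportions lie on the simplex at every time point.
    """

    cell_types: tuple[str, ...]
    base: tuple[float, ...]
    amplitude: tuple[float, ...]
    acrophase: tuple[float, ...]
    period: float = 24.0

    def __post_init__(self) -> None:
        k = len(self.cell_types)
        if not (len(self.base) == len(self.amplitude) == len(self.acrophase) == k):
            raise ValueError("schedule fields must have one entry per cell type")
        base = np.asarray(self.base, float)
        amp = np.asarray(self.amplitude, float)
        if np.any(base < 0) or abs(base.sum() - 1.0) > 1e-8:
            raise ValueError("base proportions must be >=0 and sum to 1")
        if np.any(amp < 0):
            raise ValueError("amplitudes must be >= 0")
        if np.any(amp > base + 1e-12):
            raise ValueError(
                "amplitude must not exceed the base proportion "
                "(pre-normalisation proportions must stay >= 0)"
            )
        if self.period <= 0:
            raise ValueError("period must be positive")

    @staticmethod
    def constant(cell_types, base) -> "MixtureSchedule":
        k = len(cell_types)
        return MixtureSchedule(
            tuple(cell_types), tuple(base), (0.0,) * k, (0.0,) * k
        )


def default_wbc_schedule(residual_neutrophils: float = 0.15) -> MixtureSchedule:
    """Neutrophil-depleted WBC fraction schedule.

    Lymphocyte-dominated composition with a configurable residual
    neutrophil fraction left over from the depletion (realistically
    ~10-20% of cells).  NK cells peak around noon while B and CD4+ T
    cells peak around midnight, i.e. NK is antiphasic to B/CD4T — the
    pattern seen in circadian leukocyte counts.
    """
    if not 0.0 <= residual_neutrophils < 0.5:
        raise ValueError("residual_neutrophils must lie in [0, 0.5)")
    rest = 1.0 - residual_neutrophils
    base = {
        "Neu": residual_neutrophils,
        "NK": 0.15 * rest / 0.85,
        "B": 0.15 * rest / 0.85,
        "CD4T": 0.30 * rest / 0.85,
        "CD8T": 0.15 * rest / 0.85,
        "Mono": 0.10 * rest / 0.85,
    }
    amp = {"Neu": 0.0, "NK": 0.05, "B": 0.04, "CD4T": 0.05, "CD8T": 0.0, "Mono": 0.0}
    acro = {"Neu": 0.0, "NK": 12.0, "B": 0.0, "CD4T": 0.0, "CD8T": 0.0, "Mono": 0.0}
    types = tuple(DEFAULT_CELL_TYPES)
    amp = {k: min(v, base[k]) for k, v in amp.items()}
    return MixtureSchedule(
        cell_types=types,
        base=tuple(base[t] for t in types),
        amplitude=tuple(amp[t] for t in types),
        acrophase=tuple(acro[t] for t in types),
    )


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Design of one synthetic circadian methylome study.

    The defaults mirror a 72-h single-subject collection sampled every
    3 h (24 samples), the densest circadian design the generator targets;
    the multi-subject neutrophil-style design is three subjects sampled
    every 3 h for 24 h.

    Parameters of scientific note (all beta-scale unless stated):

    * ``frac_oscillating`` / ``oscillation_amplitude`` — fraction of CpGs
      with an intracellular 24-h oscillation and its amplitude;
      acrophases are site-specific uniform on [0, 24) unless
      ``oscillation_acrophase`` pins them.
    * ``oscillating_cell_types`` — cell types carrying the intracellular
      oscillators (default: all types).
    * ``frac_age_trend`` / ``age_slope_per_year`` — fraction of CpGs with
      a linear age trend and the absolute slope per year (random sign).
    * ``noise_sd`` — measurement-noise standard deviation on the logit
      scale (0 disables noise entirely, making samples exact mixtures).
    """

    n_cpgs: int = 2000
    n_cell_types: int = 6
    n_subjects: int = 1
    times: tuple[float, ...] = tuple(float(t) for t in range(0, 72, 3))
    ages: tuple[float, ...] = (52.0,)
    frac_oscillating: float = 0.05
    oscillation_amplitude: float = 0.05
    oscillation_acrophase: float | None = None
    oscillating_cpgs: tuple[str, ...] | None = None
    oscillating_cell_types: tuple[str, ...] | None = None
    frac_age_trend: float = 0.05
    age_slope_per_year: float = 0.002
    noise_sd: float = 0.05
    n_discriminating: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cpgs < 1 or self.n_cell_types < 2 or self.n_subjects < 1:
            raise ValueError("non-positive study dimensions")
        if len(self.ages) != self.n_subjects:
            raise ValueError("ages must list one age per subject")
        for frac in (self.frac_oscillating, self.frac_age_trend):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if any(t < 0 for t in self.times):
            raise ValueError("sampling times must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise dispersion must be >= 0")


@dataclasses.dataclass(frozen=True)
class SimulatedStudy:
    """A synthetic study: betas + sample sheet + full ground truth."""

    betas: pd.DataFrame
    samples: pd.DataFrame
    true_proportions: pd.DataFrame
    oscillating_cpgs: tuple[str, ...]
    panel: ReferencePanel
    schedule: MixtureSchedule
    config: SimulationConfig


def generate_reference_profiles(
    n_cpgs: int,
    n_cell_types: int,
    seed: int,
    n_discriminating: int = 10,
    cell_types=None,
) -> ReferencePanel:
    """Generate cell-type reference methylomes with planted marker sites.

    Each cell type gets ``n_discriminating`` marker CpGs, half near 1 in
    that type and near 0 in the others (hyper-specific) and half the
    reverse (hypo-specific), making mixtures identifiable by constrained
    projection.  The remaining CpGs are drawn from a bimodal distribution
    on [0, 1] (methylation arrays are strongly bimodal) with a small
    independent per-type jitter.
    """
    if n_cpgs < 1 or n_cell_types < 2:
        raise ValueError("need n_cpgs >= 1 and n_cell_types >= 2")
    if cell_types is None:
        if n_cell_types <= len(DEFAULT_CELL_TYPES):
            cell_types = list(DEFAULT_CELL_TYPES[:n_cell_types])
        else:
            cell_types = [f"CT{i + 1}" for i in range(n_cell_types)]
    if n_discriminating * n_cell_types > n_cpgs:
        raise ValueError("not enough CpGs for the requested marker sites")
    rng = np.random.default_rng(seed)
    cpg_ids = [f"cg{i:06d}" for i in range(n_cpgs)]

    # bimodal background shared across types, plus small per-type jitter
    low = rng.beta(2.0, 10.0, size=n_cpgs)
    high = rng.beta(10.0, 2.0, size=n_cpgs)
    background = np.where(rng.random(n_cpgs) < 0.5, low, high)
    betas = background[:, None] + rng.normal(0.0, 0.01, size=(n_cpgs, n_cell_types))
    betas = np.clip(betas, 0.0, 1.0)

    discriminating: dict[str, list[str]] = {}
    pos = 0
    n_hyper = n_discriminating - n_discriminating // 2
    for j, ct in enumerate(cell_types):
        sites = list(range(pos, pos + n_discriminating))
        pos += n_discriminating
        for s_idx, site in enumerate(sites):
            target_high = s_idx < n_hyper
            for jj in range(n_cell_types):
                own = jj == j
                hi = (own and target_high) or (not own and not target_high)
                if hi:
                    betas[site, jj] = rng.uniform(0.85, 0.98)
                else:
                    betas[site, jj] = rng.uniform(0.02, 0.10)
        discriminating[ct] = [cpg_ids[s] for s in sites]

    frame = pd.DataFrame(
        betas, index=pd.Index(cpg_ids, name="cpg_id"), columns=list(cell_types)
    )
    return ReferencePanel(betas=frame, discriminating=discriminating)


def proportions_at_time(schedule: MixtureSchedule, t) -> np.ndarray:
    """Realised simplex proportions at time(s) ``t`` (hours).

    Raw per-type values ``base + amp*cos(2*pi*(t - acro)/period)`` are
    clipped at zero (with a warning if clipping occurs) and divided by
    their sum.  Scalar ``t`` returns a vector; array ``t`` returns a
    (len(t), n_types) matrix.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    base = np.asarray(schedule.base)
    amp = np.asarray(schedule.amplitude)
    acro = np.asarray(schedule.acrophase)
    w = 2.0 * np.pi / schedule.period
    raw = base[None, :] + amp[None, :] * np.cos(w * (t_arr[:, None] - acro[None, :]))
    if np.any(raw < 0):
        warnings.warn("negative pre-normalisation proportions clipped to 0")
        raw = np.maximum(raw, 0.0)
    out = raw / raw.sum(axis=1, keepdims=True)
    return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out


def simulate_study(
    config: SimulationConfig,
    schedule: MixtureSchedule | None = None,
    panel: ReferencePanel | None = None,
) -> SimulatedStudy:
    """Simulate one circadian methylome study.

    Per sample at time ``t`` of subject ``s`` with age ``a``:

    1. intracellular oscillators perturb the designated cell types'
       profiles: ``beta_ik(t) = clip(beta_ik + A*cos(2*pi*(t - phi_i)/24))``;
    2. age-trend sites shift by ``slope_i * (a - 45)`` in every type;
    3. the sample beta is the exact convex mixture
       ``sum_k p_k(t) * profile_k(t)`` with ``p(t)`` from the schedule;
    4. logit-normal measurement noise is added and the result clipped to
       ``[1e-6, 1 - 1e-6]`` (skipped entirely when ``noise_sd == 0``).
    """
    if schedule is None:
        if config.n_cell_types != len(DEFAULT_CELL_TYPES):
            raise ValueError("default schedule requires 6 cell types")
        schedule = default_wbc_schedule()
    if panel is None:
        panel = generate_reference_profiles(
            config.n_cpgs,
            config.n_cell_types,
            seed=config.seed,
            n_discriminating=config.n_discriminating,
            cell_types=list(schedule.cell_types),
        )
    if list(panel.cell_types) != list(schedule.cell_types):
        raise ValueError("panel and schedule cell types must match")

    profiles = panel.betas.to_numpy(dtype=float)
    n_cpgs = profiles.shape[0]
    cpg_ids = list(panel.betas.index)
    cell_types = list(panel.cell_types)
    k = len(cell_types)

    # sub-generators derived from the study seed by fixed offsets
    rng_sites = np.random.default_rng([config.seed, 1])
    rng_noise = np.random.default_rng([config.seed, 2])

    # intracellular oscillators
    if config.oscillating_cpgs is not None:
        osc_idx = np.array(
            [cpg_ids.index(c) for c in config.oscillating_cpgs], dtype=int
        )
    else:
        n_osc = int(round(config.frac_oscillating * n_cpgs))
        osc_idx = rng_sites.choice(n_cpgs, size=n_osc, replace=False)
    if config.oscillation_acrophase is None:
        osc_phase = rng_sites.uniform(0.0, 24.0, size=osc_idx.size)
    else:
        osc_phase = np.full(osc_idx.size, float(config.oscillation_acrophase))
    if config.oscillating_cell_types is None:
        osc_types = np.arange(k)
    else:
        osc_types = np.array(
            [cell_types.index(ct) for ct in config.oscillating_cell_types], int
        )

    # age-trend sites, random sign
    n_trend = int(round(config.frac_age_trend * n_cpgs))
    trend_idx = rng_sites.choice(n_cpgs, size=n_trend, replace=False)
    trend_slope = config.age_slope_per_year * rng_sites.choice(
        [-1.0, 1.0], size=n_trend
    )

    sample_rows = []
    beta_cols = []
    prop_rows = []
    idx = 0
    for s in range(config.n_subjects):
        subject = f"subj{s + 1:02d}"
        age = float(config.ages[s])
        for t in config.times:
            p = proportions_at_time(schedule, float(t))
            prof_t = profiles.copy()
            if osc_idx.size:
                wobble = config.oscillation_amplitude * np.cos(
                    2.0 * np.pi * (t - osc_phase) / 24.0
                )
                for jj in osc_types:
                    prof_t[osc_idx, jj] = np.clip(
                        prof_t[osc_idx, jj] + wobble, 0.0, 1.0
                    )
            if trend_idx.size:
                shift = trend_slope * (age - 45.0)
                prof_t[trend_idx, :] = np.clip(
                    prof_t[trend_idx, :] + shift[:, None], 0.0, 1.0
                )
            beta = prof_t @ p
            if config.noise_sd > 0:
                z = logit(np.clip(beta, _BETA_EPS, 1.0 - _BETA_EPS))
                z = z + rng_noise.normal(0.0, config.noise_sd, size=n_cpgs)
                beta = np.clip(expit(z), _BETA_EPS, 1.0 - _BETA_EPS)
            idx += 1
            sid = f"S{idx:03d}"
            sample_rows.append(
                {
                    "sample_id": sid,
                    "subject_id": subject,
                    "time_hours": float(t) % 24.0,
                    "age_years": age,
                }
            )
            beta_cols.append(beta)
            prop_rows.append(p)

    samples = pd.DataFrame(sample_rows)
    betas = pd.DataFrame(
        np.column_stack(beta_cols),
        index=pd.Index(cpg_ids, name="cpg_id"),
        columns=samples["sample_id"].tolist(),
    )
    true_props = pd.DataFrame(
        np.vstack(prop_rows),
        index=pd.Index(samples["sample_id"], name="sample_id"),
        columns=cell_types,
    )
    return SimulatedStudy(
        betas=betas,
        samples=samples,
        true_proportions=true_props,
        oscillating_cpgs=tuple(cpg_ids[i] for i in osc_idx),
        panel=panel,
        schedule=schedule,
        config=config,
    )


def generate_toy_clock(
    panel: ReferencePanel | pd.DataFrame,
    target_ages_by_type: dict[str, float],
    clock_type: str = "linear",
    name: str = "toy",
    cpgs=None,
) -> ClockDefinition:
    """Build a demo clock hitting a target age on each pure cell type.

    ``linear`` solves the (under-determined) system exactly by minimum-
    norm least squares on the profile matrix, so the clock applied to a
    pure profile returns its target age to machine precision whenever the
    profiles are linearly independent.  ``rate`` builds an epiTOC2-style
    estimator via NNLS (ground state 0, per-site rates from the fitted
    non-negative coefficients), exact when the NNLS residual vanishes.
    ``average`` greedily selects a site set whose per-type mean beta
    approaches the targets — approximate by nature, since an average of
    betas is confined to [0, 1].
    """
    profiles = panel.betas if isinstance(panel, ReferencePanel) else panel
    if cpgs is None:
        if isinstance(panel, ReferencePanel):
            cpgs = panel.discriminating_sites
        else:
            cpgs = list(profiles.index)
    missing = [ct for ct in profiles.columns if ct not in target_ages_by_type]
    if missing:
        raise ValueError(f"no target age for cell types {missing}")
    targets = np.array([float(target_ages_by_type[c]) for c in profiles.columns])
    P = profiles.loc[cpgs].to_numpy(dtype=float)  # sites x types
    k = P.shape[1]

    if clock_type == "linear":
        A = np.column_stack([P.T, np.ones(k)])  # types x (sites + 1)
        if np.linalg.matrix_rank(A) < k:
            raise ValueError(
                "profile matrix is rank-deficient: pure-type targets are "
                "not simultaneously attainable"
            )
        theta, _, _, _ = np.linalg.lstsq(A, targets, rcond=None)
        if np.max(np.abs(A @ theta - targets)) > 1e-8:
            raise ValueError("linear toy clock could not match targets exactly")
        weights = dict(zip(cpgs, theta[:-1]))
        return ClockDefinition(
            name=name, family="linear", cpg_weights=weights,
            intercept=float(theta[-1]),
        )

    if clock_type == "rate":
        from scipy.optimize import nnls

        if np.any(targets <= 0):
            raise ValueError("rate-clock targets must be positive")
        a, resid = nnls(P.T, targets)
        if resid > 1e-6 * max(1.0, float(np.linalg.norm(targets))):
            raise ValueError(
                "rate toy clock could not match targets with non-negative "
                "site rates"
            )
        support = np.flatnonzero(a > 1e-12)
        if support.size == 0:
            raise ValueError("rate toy clock degenerate: empty support")
        n_sites = support.size
        weights = {}
        rate_params = {}
        for i in support:
            weights[cpgs[i]] = 1.0
            rate_params[cpgs[i]] = (1.0 / (n_sites * a[i]), 0.0)
        return ClockDefinition(
            name=name, family="rate", cpg_weights=weights,
            rate_params=rate_params,
        )

    if clock_type == "average":
        if np.any((targets <= 0) | (targets >= 1)):
            raise ValueError("average-clock targets must lie in (0, 1)")
        chosen: list[int] = []
        best_err = np.inf
        for _ in range(min(200, P.shape[0])):
            sums = P[chosen].sum(axis=0) if chosen else np.zeros(k)
            cand_means = (sums[None, :] + P) / (len(chosen) + 1)
            errs = np.sum((cand_means - targets[None, :]) ** 2, axis=1)
            errs[chosen] = np.inf
            best = int(np.argmin(errs))
            if errs[best] >= best_err:
                break
            best_err = errs[best]
            chosen.append(best)
        weights = {cpgs[i]: 1.0 for i in chosen}
        return ClockDefinition(name=name, family="average", cpg_weights=weights)

    raise ValueError(f"unknown clock_type {clock_type!r}")


def extend_clock_with_sites(
    clock: ClockDefinition,
    profiles: pd.DataFrame,
    sites,
    weight: float,
) -> ClockDefinition:
    """Add equally-weighted CpGs to a linear clock, preserving pure-type
    predictions.

    The intercept is lowered by ``weight * sum(mean profile beta at the
    new sites)``; when the new sites have (near-)identical betas across
    cell types — e.g. background sites of the synthetic panel — pure-type
    targets are preserved (near-)exactly.  Used to plant clock CpGs that
    do not overlap the deconvolution marker sites.
    """
    if clock.family != "linear":
        raise ValueError("only linear clocks can be extended")
    overlap = [s for s in sites if s in clock.cpg_weights]
    if overlap:
        raise ValueError(f"sites already in the clock: {overlap[:5]}")
    mean_beta = profiles.loc[list(sites)].mean(axis=1)
    weights = dict(clock.cpg_weights)
    for s in sites:
        weights[s] = weight
    return ClockDefinition(
        name=clock.name + "+sites",
        family="linear",
        cpg_weights=weights,
        intercept=clock.intercept - weight * float(mean_beta.sum()),
        transform=clock.transform,
        adult_age=clock.adult_age,
    )


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Write a study to disk (beta TSV, sample CSV, ground-truth CSVs,
    reference TSV); returns the path map."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "betas": str(out / "betas.tsv"),
        "samples": str(out / "samples.csv"),
        "true_proportions": str(out / "true_proportions.csv"),
        "true_oscillating_cpgs": str(out / "true_oscillating_cpgs.csv"),
        "reference": str(out / "reference.tsv"),
    }
    study.betas.to_csv(paths["betas"], sep="\t", float_format="%.10g")
    study.samples.to_csv(paths["samples"], index=False)
    study.true_proportions.to_csv(paths["true_proportions"])
    pd.Series(
        list(study.oscillating_cpgs), name="cpg_id"
    ).to_csv(paths["true_oscillating_cpgs"], index=False)
    study.panel.betas.to_csv(paths["reference"], sep="\t", float_format="%.10g")
    return paths
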