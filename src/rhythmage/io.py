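"""File formats, configuration and the pipeline driver.

Conventions: CSV is comma-separated UTF-8 with ``.`` decimals and ``NA``
for missing; beta and reference matrices may also be TSV (common for
methylation exports) with ``cpg_id`` as the first column.  Collection
times are decimal hours on the 24-h clock; ``HH:MM`` tokens are accepted
and converted, and hours >= 24 (multi-day collections) wrap modulo 24 —
a 24-h cosinor only ever sees time of day.  Sample alignment is always a
``sample_id`` join, never column order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adjustment import intrinsic_age_residuals, paired_timepoint_contrast
from .clocks import ClockDefinition, compute_clock, save_clock_definition
from .cosinor import bonferroni_adjust, fit_cosinor, fit_cosinor_combined, screen_sites
from .deconvolution import (
    estimate_proportions,
    proportion_rhythm_report,
    select_reference_sites,
)
from .synthetic import (
    MixtureSchedule,
    SimulationConfig,
    generate_toy_clock,
    simulate_study,
    write_study,
)

log = logging.getLogger(__name__)

_BETA_TOL = 1e-9


def parse_time(token) -> float:
    """Parse a collection time to decimal hours in [0, 24).

    Accepts 24-h ``HH:MM`` tokens (``"12:45"`` -> 12.75) or decimal
    hours; values outside [0, 24) are wrapped modulo 24 with a warning.
    """
    if isinstance(token, str) and ":" in token:
        parts = token.split(":")
        if len(parts) != 2:
            raise ValueError(f"cannot parse time token {token!r}")
        try:
            hours, minutes = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ValueError(f"cannot parse time token {token!r}") from exc
        if not 0 <= minutes < 60:
            raise ValueError(f"minutes out of range in {token!r}")
        value = hours + minutes / 60.0
    else:
        try:
            value = float(token)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"cannot parse time token {token!r}") from exc
    if not np.isfinite(value):
        raise ValueError(f"cannot parse time token {token!r}")
    if value >= 24.0 or value < 0.0:
        warnings.warn(f"time {token!r} wrapped into [0, 24)")
        value = value % 24.0
    return value


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a CpG x sample beta matrix (TSV/CSV, first column ``cpg_id``).

    Values are validated to [0, 1] with 1e-9 tolerance for float dust;
    ``NA`` marks missing.  Duplicate CpG ids and out-of-range or
    non-numeric cells are format errors naming the offender.
    """
    frame = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, na_values=["NA"], comment=None
    )
    dupes = frame.index[frame.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate CpG ids in {path}: {dupes[:5]}")
    for col in frame.columns:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.isna() & frame[col].notna()
        if bad.any():
            row = frame.index[bad.to_numpy()][0]
            raise ValueError(f"non-numeric beta at ({row}, {col}) in {path}")
        frame[col] = values
    arr = frame.to_numpy(dtype=float)
    finite = np.isfinite(arr)
    if finite.any():
        lo, hi = arr[finite].min(), arr[finite].max()
        if lo < -_BETA_TOL or hi > 1.0 + _BETA_TOL:
            pos = np.argwhere(finite & ((arr < -_BETA_TOL) | (arr > 1 + _BETA_TOL)))[0]
            raise ValueError(
                f"beta outside [0, 1] at ({frame.index[pos[0]]}, "
                f"{frame.columns[pos[1]]}) in {path}"
            )
    frame = frame.clip(0.0, 1.0)
    frame.index.name = "cpg_id"
    return frame


def write_beta_matrix(betas: pd.DataFrame, path) -> None:
    betas.to_csv(path, sep=_sep_for(path), float_format="%.10f", na_rep="NA")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet CSV.

    Requires columns ``sample_id`` (unique), ``subject_id``,
    ``time_hours`` (``HH:MM`` or decimal, wrapped into [0, 24)) and
    ``age_years`` (>= 0); extra covariate columns pass through.
    """
    sheet = pd.read_csv(path)
    required = ["sample_id", "subject_id", "time_hours", "age_years"]
    missing = [c for c in required if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns {missing}")
    if sheet["sample_id"].duplicated().any():
        dupes = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_ids in {path}: {dupes[:5]}")
    sheet["time_hours"] = [parse_time(t) for t in sheet["time_hours"]]
    ages = pd.to_numeric(sheet["age_years"], errors="raise")
    if (ages < 0).any():
        raise ValueError(f"negative age in {path}")
    sheet["age_years"] = ages.astype(float)
    return sheet


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Either simulate inputs (``simulate`` holds :class:`SimulationConfig`
    overrides) or point ``betas``/``samples``/``reference``/``clocks`` at
    files on disk.
    """

    outdir: str
    seed: int = 0
    simulate: dict | None = None
    betas: str | None = None
    samples: str | None = None
    reference: str | None = None
    clock_files: tuple[str, ...] = ()
    alpha: float = 0.05
    period: float = 24.0
    missing_policy: str = "error"
    sites_per_type: int = 10
    include_types: tuple[str, ...] | None = None
    contrast_times: tuple[float, float] = (12.75, 16.25)
    contrast_pairs: int = 32

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @staticmethod
    def from_json(path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        if "clock_files" in raw:
            raw["clock_files"] = tuple(raw["clock_files"])
        if raw.get("include_types") is not None:
            raw["include_types"] = tuple(raw["include_types"])
        if "contrast_times" in raw:
            raw["contrast_times"] = tuple(raw["contrast_times"])
        return PipelineConfig(**raw)


def demo_config(outdir, seed: int = 0) -> PipelineConfig:
    """Bundled demo configuration: simulated neutrophil-depleted study
    with composition-driven oscillation, a toy linear clock and a toy
    mitotic-rate clock."""
    return PipelineConfig(
        outdir=str(outdir),
        seed=seed,
        simulate={"n_cpgs": 800, "noise_sd": 0.05, "frac_oscillating": 0.0},
    )


def _fit_series(times, values, subject_ids, period):
    subjects = pd.unique(np.asarray(subject_ids))
    if subjects.size > 1:
        return fit_cosinor_combined(times, values, subject_ids, period=period)
    return fit_cosinor(times, values, period=period)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis and write per-stage CSVs plus a JSON
    summary and a reproducibility manifest.

    Stages: simulate (optional) -> clock estimation -> cosinor per clock
    -> genome-wide site screen + clock-CpG overlap -> deconvolution ->
    proportion rhythms -> cell-count adjustment -> adjusted cosinor ->
    two-timepoint paired contrast (simulation mode).  Any stage error
    aborts with a stage-tagged message; partial outputs are retained.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        clock_defs: list[ClockDefinition] = []
        stage = "simulate"
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            sim_cfg = SimulationConfig(**sim_kwargs)
            study = simulate_study(sim_cfg)
            write_study(study, out / "inputs")
            betas = study.betas
            samples = study.samples
            reference = study.panel.betas
            targets = {
                "Neu": 50.0, "NK": 56.0, "B": 44.0,
                "CD4T": 46.0, "CD8T": 50.0, "Mono": 50.0,
            }
            targets = {c: targets.get(c, 50.0) for c in reference.columns}
            toy_linear = generate_toy_clock(study.panel, targets, "linear", name="toy_linear")
            rate_targets = {c: max(v, 1.0) * 20.0 for c, v in targets.items()}
            toy_rate = generate_toy_clock(study.panel, rate_targets, "rate", name="toy_rate")
            clock_defs = [toy_linear, toy_rate]
            for cd in clock_defs:
                save_clock_definition(cd, out / "inputs" / f"clock_{cd.name}.csv")
        else:
            from .clocks import load_clock_definition

            if not (config.betas and config.samples):
                raise ValueError("need betas and samples paths when not simulating")
            betas = read_beta_matrix(config.betas)
            samples = read_sample_sheet(config.samples)
            reference = (
                read_beta_matrix(config.reference) if config.reference else None
            )
            clock_defs = [load_clock_definition(p) for p in config.clock_files]
            study = None

        samples = samples.set_index("sample_id").loc[betas.columns].reset_index()
        times = samples["time_hours"].to_numpy(dtype=float)
        subject_ids = samples["subject_id"].to_numpy()

        stage = "clocks"
        estimates = pd.concat(
            [compute_clock(betas, cd, config.missing_policy) for cd in clock_defs],
            ignore_index=True,
        )
        estimates.to_csv(out / "clock_estimates.csv", index=False)

        stage = "cosinor"
        fit_rows = []
        fits = {}
        for cd in clock_defs:
            vals = (
                estimates.loc[estimates["clock"] == cd.name]
                .set_index("sample_id")
                .loc[betas.columns, "value"]
                .to_numpy(dtype=float)
            )
            fit = _fit_series(times, vals, subject_ids, config.period)
            fits[cd.name] = fit
            fit_rows.append(
                {
                    "series": cd.name,
                    "mesor": fit.mesor,
                    "amplitude": fit.amplitude,
                    "acrophase_h": fit.acrophase,
                    "p": fit.p_value,
                    "n": fit.n,
                }
            )
        fits_frame = pd.DataFrame(fit_rows)
        fits_frame["p_bonferroni"] = bonferroni_adjust(
            fits_frame["p"].to_numpy(), m=len(clock_defs)
        )
        fits_frame.to_csv(out / "clock_cosinor_fits.csv", index=False)

        stage = "screen"
        screen = screen_sites(betas, times, alpha=config.alpha, period=config.period)
        screen.p_values.to_csv(out / "site_screen_pvalues.csv")
        overlap_rows = []
        for cd in clock_defs:
            from .clocks import clock_cpg_overlap

            count, pct = clock_cpg_overlap(screen.significant, cd)
            overlap_rows.append(
                {
                    "clock": cd.name,
                    "n_clock_cpgs": len(cd.cpgs),
                    "n_overlapping": count,
                    "percent": round(pct, 1),
                }
            )
        pd.DataFrame(overlap_rows).to_csv(out / "clock_cpg_overlap.csv", index=False)

        proportions = None
        if reference is not None:
            stage = "deconvolve"
            sites = select_reference_sites(reference, config.sites_per_type)
            proportions = estimate_proportions(betas, reference, sites)
            proportions.to_csv(out / "proportions.csv")
            rhythms = proportion_rhythm_report(
                proportions, times, period=config.period
            )
            rhythms.to_csv(out / "proportion_cosinor_fits.csv")

        adjusted = {}
        if proportions is not None:
            stage = "adjust"
            adj_rows = []
            for cd in clock_defs:
                vals = (
                    estimates.loc[estimates["clock"] == cd.name]
                    .set_index("sample_id")
                    .loc[betas.columns, "value"]
                    .to_numpy(dtype=float)
                )
                resid = intrinsic_age_residuals(
                    vals,
                    samples["age_years"].to_numpy(dtype=float),
                    proportions,
                    included_types=config.include_types,
                )
                fit = _fit_series(times, resid, subject_ids, config.period)
                adjusted[cd.name] = fit
                adj_rows.append(
                    {
                        "series": cd.name + "_adjusted",
                        "mesor": fit.mesor,
                        "amplitude": fit.amplitude,
                        "acrophase_h": fit.acrophase,
                        "p": fit.p_value,
                        "n": fit.n,
                    }
                )
                pd.DataFrame(
                    {"sample_id": betas.columns, "residual": resid}
                ).to_csv(out / f"residuals_{cd.name}.csv", index=False)
            adj_frame = pd.DataFrame(adj_rows)
            adj_frame["p_bonferroni"] = bonferroni_adjust(
                adj_frame["p"].to_numpy(), m=len(clock_defs)
            )
            adj_frame.to_csv(out / "adjusted_cosinor_fits.csv", index=False)

        contrast_summary = None
        if config.simulate is not None and clock_defs:
            stage = "compare"
            t1, t2 = config.contrast_times
            cohort_cfg = SimulationConfig(
                n_cpgs=sim_cfg.n_cpgs,
                n_cell_types=sim_cfg.n_cell_types,
                n_subjects=config.contrast_pairs,
                times=(t1, t2),
                ages=tuple(
                    40.0 + (i % 25) for i in range(config.contrast_pairs)
                ),
                noise_sd=sim_cfg.noise_sd,
                seed=(config.seed + 7919) % (2**31),
            )
            cohort = simulate_study(cohort_cfg, panel=study.panel)
            rows = []
            for cd in clock_defs:
                est = compute_clock(cohort.betas, cd, config.missing_policy)
                est = est.merge(
                    cohort.samples, on="sample_id", validate="one_to_one"
                )
                first = est[np.isclose(est["time_hours"], t1 % 24.0)]
                second = est[np.isclose(est["time_hours"], t2 % 24.0)]
                first = first.set_index("subject_id")["value"]
                second = second.set_index("subject_id")["value"]
                contrast = paired_timepoint_contrast(
                    first.to_numpy(), second.loc[first.index].to_numpy(),
                    first.index.to_numpy(),
                )
                rows.append(
                    {
                        "clock": cd.name,
                        "mean_difference": contrast.mean_difference,
                        "t": contrast.t_statistic,
                        "p": contrast.p_value,
                        "n_pairs": contrast.n_pairs,
                    }
                )
            contrast_summary = pd.DataFrame(rows)
            contrast_summary.to_csv(out / "timepoint_contrast.csv", index=False)

        stage = "summary"
        summary = {
            "clocks": [
                {
                    "clock": name,
                    "mesor": fit.mesor,
                    "amplitude": fit.amplitude,
                    "acrophase_h": fit.acrophase,
                    "p": fit.p_value,
                    "p_bonferroni": min(1.0, fit.p_value * len(clock_defs)),
                    "bonferroni_significant": fit.p_value * len(clock_defs)
                    < config.alpha,
                    "adjusted_p": (
                        adjusted[name].p_value if name in adjusted else None
                    ),
                }
                for name, fit in fits.items()
            ],
            "n_oscillating_sites": screen.count,
            "n_sites_screened": int(len(screen.p_values)),
            "alpha": config.alpha,
            "period": config.period,
        }
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2)

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
            },
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:  # noqa: BLE001 - re-tag with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
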