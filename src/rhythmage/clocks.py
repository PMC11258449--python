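"""Epigenetic clock arithmetic.

A clock is a named predictor over CpG beta values.  Three families cover
the predictors commonly applied to blood methylation:

``linear``
    Age-style clocks: ``value = g^-1(intercept + sum_i w_i * beta_i)``
    where ``g`` is either the identity or the piecewise log "antilog"
    transform of the Horvath pan-tissue calculator.
``average``
    Mitotic-score clocks that report the mean beta over a fixed CpG set
    (epiTOC-style), a value in [0, 1].
``rate``
    Mitotic division estimators (epiTOC2-style) that convert each site's
    beta into an estimated cumulative number of stem-cell divisions via a
    per-site de-novo methylation rate ``delta_i`` and ground state
    ``beta0_i``:  ``(1/N) * sum_i max(0, (beta_i - beta0_i) /
    (delta_i * (1 - beta0_i)))``.

Coefficient files are plain CSV with ``#key=value`` comment headers (see
:func:`load_clock_definition`); only toy/demo coefficient sets ship with
the package, but any user-supplied file in this format loads.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

FAMILIES = ("linear", "average", "rate")
TRANSFORMS = ("identity", "horvath_antilog")
MISSING_POLICIES = ("error", "drop", "impute")

_BETA_TOL = 1e-9  # float dust allowed outside [0, 1]
INTERCEPT_KEY = "(Intercept)"


class ClockFormatError(ValueError):
    """Malformed clock coefficient file."""


@dataclasses.dataclass(frozen=True)
class ClockDefinition:
    """A named epigenetic clock.

    ``rate_params`` maps CpG id -> (delta, beta0) and is required for the
    rate family only.  ``adult_age`` is used only by the
    ``horvath_antilog`` transform.
    """

    name: str
    family: str
    cpg_weights: dict[str, float]
    intercept: float = 0.0
    transform: str = "identity"
    adult_age: float = 20.0
    rate_params: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ClockFormatError(f"unknown clock family {self.family!r}")
        if self.transform not in TRANSFORMS:
            raise ClockFormatError(f"unknown transform {self.transform!r}")
        if not self.cpg_weights:
            raise ClockFormatError("clock must reference at least one CpG")
        if self.family in ("average", "rate") and self.transform != "identity":
            raise ClockFormatError(
                f"{self.family} family requires the identity transform"
            )
        if self.family == "rate":
            rp = self.rate_params or {}
            for cpg in self.cpg_weights:
                if cpg not in rp:
                    raise ClockFormatError(f"rate clock missing params for {cpg}")
                delta, beta0 = rp[cpg]
                if not delta > 0:
                    raise ClockFormatError(f"{cpg}: delta must be > 0")
                if not (0.0 <= beta0 < 1.0):
                    raise ClockFormatError(f"{cpg}: beta0 must lie in [0, 1)")

    @property
    def cpgs(self) -> list[str]:
        return list(self.cpg_weights)


@dataclasses.dataclass(frozen=True)
class ClockEstimate:
    """One clock prediction for one sample."""

    sample_id: str
    clock: str
    value: float
    n_missing_cpgs: int


def horvath_transform(age: float, adult_age: float = 20.0) -> float:
    """Forward age transform of the Horvath pan-tissue calculator.

    ``F(x) = log(x + 1) - log(a + 1)`` for ``x <= a`` and
    ``(x - a)/(a + 1)`` otherwise; continuous, strictly increasing and
    zero at ``x = a``.
    """
    if age <= -1:
        raise ValueError("age must be > -1")
    if age <= adult_age:
        return math.log(age + 1.0) - math.log(adult_age + 1.0)
    return (age - adult_age) / (adult_age + 1.0)


def inverse_horvath_transform(score: float, adult_age: float = 20.0) -> float:
    """Exact inverse of :func:`horvath_transform`."""
    if score <= 0.0:
        return math.exp(score) * (adult_age + 1.0) - 1.0
    return score * (adult_age + 1.0) + adult_age


def _validate_betas(values: np.ndarray, clock_name: str) -> np.ndarray:
    finite = values[np.isfinite(values)]
    if finite.size and (finite.min() < -_BETA_TOL or finite.max() > 1.0 + _BETA_TOL):
        raise ValueError(
            f"beta values outside [0, 1] passed to clock {clock_name!r}"
        )
    return np.clip(values, 0.0, 1.0)


def compute_clock(
    betas: pd.DataFrame,
    clock: ClockDefinition,
    missing_policy: str = "error",
) -> pd.DataFrame:
    """Apply one clock to a beta matrix (CpG x sample).

    Parameters
    ----------
    betas : DataFrame
        CpG x sample matrix of beta values in [0, 1]; NaN marks missing.
    missing_policy : {"error", "drop", "impute"}
        ``error`` rejects any missing clock CpG; ``drop`` omits missing
        sites (average/rate families renormalise over the present sites;
        the linear family omits the corresponding terms); ``impute``
        substitutes 0.5.

    Returns
    -------
    DataFrame with columns ``sample_id``, ``clock``, ``value``,
    ``n_missing_cpgs``.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    cpgs = clock.cpgs
    present = [c for c in cpgs if c in betas.index]
    missing = [c for c in cpgs if c not in betas.index]
    if not present and missing_policy != "impute":
        raise ValueError(f"no CpGs of clock {clock.name!r} found in the matrix")

    sub = betas.reindex(cpgs)  # cpg order of the clock; absent rows are NaN
    values = sub.to_numpy(dtype=float)
    n_missing = np.isnan(values).sum(axis=0)  # per sample, incl. absent rows

    if np.isnan(values).any():
        if missing_policy == "error":
            bad = sub.index[np.isnan(values).any(axis=1)].tolist()
            raise ValueError(
                f"clock {clock.name!r}: missing betas for {bad[:5]}"
                f"{'...' if len(bad) > 5 else ''} (policy=error)"
            )
        if missing_policy == "impute":
            values = np.where(np.isnan(values), 0.5, values)
    values = _validate_betas(values, clock.name)

    mask = ~np.isnan(values)  # per (cpg, sample) availability under "drop"
    if not mask.any(axis=0).all():
        raise ValueError(
            f"clock {clock.name!r}: some samples have no clock CpGs at all"
        )

    if clock.family == "linear":
        w = np.array([clock.cpg_weights[c] for c in cpgs])
        contrib = np.where(mask, values, 0.0) * w[:, None]
        score = clock.intercept + contrib.sum(axis=0)
        if clock.transform == "horvath_antilog":
            out = np.array(
                [inverse_horvath_transform(s, clock.adult_age) for s in score]
            )
        else:
            out = score
    elif clock.family == "average":
        out = np.where(mask, values, 0.0).sum(axis=0) / mask.sum(axis=0)
    else:  # rate
        delta = np.array([clock.rate_params[c][0] for c in cpgs])
        beta0 = np.array([clock.rate_params[c][1] for c in cpgs])
        per_site = (values - beta0[:, None]) / (delta * (1.0 - beta0))[:, None]
        per_site = np.maximum(per_site, 0.0)
        out = np.where(mask, per_site, 0.0).sum(axis=0) / mask.sum(axis=0)

    return pd.DataFrame(
        {
            "sample_id": betas.columns,
            "clock": clock.name,
            "value": out,
            "n_missing_cpgs": n_missing.astype(int),
        }
    )


def clock_cpg_overlap(oscillating_cpgs, clock: ClockDefinition) -> tuple[int, float]:
    """Count and percentage of clock CpGs in an oscillating-site set.

    Returns ``(count, percent)`` with the percentage at full precision
    (round to one decimal for reporting).
    """
    cpgs = set(clock.cpgs)
    if not cpgs:
        raise ValueError("empty clock")
    count = len(cpgs & set(oscillating_cpgs))
    return count, 100.0 * count / len(cpgs)


def save_clock_definition(clock: ClockDefinition, path) -> None:
    """Write a clock coefficient file (CSV with ``#key=value`` header)."""
    lines = [
        f"#name={clock.name}",
        f"#family={clock.family}",
        f"#transform={clock.transform}",
        f"#adult_age={float(clock.adult_age)!r}",
    ]
    if clock.family == "linear":
        lines.append(f"{INTERCEPT_KEY},{float(clock.intercept)!r}")
    for cpg, w in clock.cpg_weights.items():
        if clock.family == "rate":
            delta, beta0 = clock.rate_params[cpg]
            lines.append(f"{cpg},{float(w)!r},{float(delta)!r},{float(beta0)!r}")
        else:
            lines.append(f"{cpg},{float(w)!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def load_clock_definition(path) -> ClockDefinition:
    """Load a clock coefficient file written by :func:`save_clock_definition`.

    Format: ``#name=``, ``#family=``, ``#transform=``, ``#adult_age=``
    comment lines, then one ``cpg_id,weight[,delta,beta0]`` row per CpG;
    the linear-family intercept is the reserved ``(Intercept),<value>``
    row.  Duplicate CpG ids, unknown families/transforms, non-positive
    deltas and a missing intercept are rejected with the offending line.
    """
    meta: dict[str, str] = {}
    weights: dict[str, float] = {}
    rate_params: dict[str, tuple[float, float]] = {}
    intercept: float | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise ClockFormatError(f"line {lineno}: malformed header")
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
                continue
            parts = [p.strip() for p in line.split(",")]
            if parts[0] == INTERCEPT_KEY:
                intercept = float(parts[1])
                continue
            cpg = parts[0]
            if cpg in weights:
                raise ClockFormatError(f"line {lineno}: duplicate CpG {cpg!r}")
            try:
                weights[cpg] = float(parts[1])
            except (IndexError, ValueError) as exc:
                raise ClockFormatError(f"line {lineno}: bad weight") from exc
            if len(parts) >= 4:
                delta, beta0 = float(parts[2]), float(parts[3])
                if delta <= 0:
                    raise ClockFormatError(f"line {lineno}: delta must be > 0")
                rate_params[cpg] = (delta, beta0)

    family = meta.get("family", "")
    if family not in FAMILIES:
        raise ClockFormatError(f"unknown family {family!r} in {path}")
    transform = meta.get("transform", "identity")
    if transform not in TRANSFORMS:
        raise ClockFormatError(f"unknown transform {transform!r} in {path}")
    if family == "linear" and intercept is None:
        raise ClockFormatError(f"linear clock {path} lacks an {INTERCEPT_KEY} row")
    return ClockDefinition(
        name=meta.get("name", "unnamed"),
        family=family,
        cpg_weights=weights,
        intercept=intercept if intercept is not None else 0.0,
        transform=transform,
        adult_age=float(meta.get("adult_age", 20.0)),
        rate_params=rate_params or None,
    )
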