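"""Cell-count adjustment and paired contrasts of epigenetic age.

Implements the intrinsic-age strategy: regress epigenetic age on
chronological age and a subset of estimated leukocyte proportions, and
analyse the residuals — any oscillation driven purely by circadian cell
composition is absorbed by the covariates, while cell-intrinsic rhythms
survive.  Also provides paired Student's t contrasts: two time-of-day
points matched by donor, and each sorted subtype against matched whole
blood.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

_CONST_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class PairedContrast:
    """Paired Student's t-test summary."""

    mean_difference: float
    t_statistic: float
    p_value: float
    n_pairs: int


def intrinsic_age_residuals(
    epigenetic_ages,
    chronological_ages,
    proportions: pd.DataFrame,
    included_types=None,
) -> np.ndarray:
    """Residuals of epigenetic age on chronological age + cell proportions.

    OLS of epigenetic age on ``[1, chronological age, selected
    proportions]``; residuals have mean zero and are orthogonal to every
    included covariate.

    ``included_types`` defaults to all proportion columns except the one
    with the largest mean (compositions are simplex-constrained, so the
    full set is collinear with the intercept); passing the full set
    raises.  A constant chronological age (single-subject series) or a
    constant proportion column is dropped from the design automatically
    with a log notice.
    """
    y = np.asarray(epigenetic_ages, dtype=float)
    chrono = np.asarray(chronological_ages, dtype=float)
    if y.shape != chrono.shape or y.ndim != 1:
        raise ValueError("ages must be aligned 1-D arrays")
    if len(proportions) != y.size:
        raise ValueError("proportions must align with the age series")
    prop_cols = [c for c in proportions.columns if c != "residual"]
    if included_types is None:
        means = proportions[prop_cols].mean()
        included_types = [c for c in prop_cols if c != means.idxmax()]
    else:
        included_types = list(included_types)
        unknown = [c for c in included_types if c not in prop_cols]
        if unknown:
            raise ValueError(f"unknown cell types {unknown}")
        if set(included_types) == set(prop_cols):
            raise ValueError(
                "including the full simplex of proportions is collinear "
                "with the intercept; drop one cell type"
            )

    cols = [np.ones_like(y)]
    if np.ptp(chrono) > _CONST_TOL:
        cols.append(chrono)
    else:
        log.info("chronological age constant across samples; dropped from design")
    for c in included_types:
        v = proportions[c].to_numpy(dtype=float)
        if np.ptp(v) > _CONST_TOL:
            cols.append(v)
        else:
            log.info("proportion column %r constant; dropped from design", c)
    X = np.column_stack(cols)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            "adjustment design is rank-deficient (collinear covariates); "
            "residuals use the minimum-norm fit"
        )
    return y - X @ beta


def deviation_proportion_correlation(
    deviations, proportions: pd.DataFrame, cell_type: str
) -> tuple[float, float]:
    """Pearson correlation between age deviation and one subtype proportion.

    Returns ``(r, p)`` with the two-sided t-based p-value.  Zero variance
    in either variable is undefined and raises.
    """
    d = np.asarray(deviations, dtype=float)
    if cell_type not in proportions.columns:
        raise ValueError(f"unknown cell type {cell_type!r}")
    x = proportions[cell_type].to_numpy(dtype=float)
    if d.size != x.size or d.size < 3:
        raise ValueError("need >=3 aligned observations")
    if np.ptp(d) <= _CONST_TOL or np.ptp(x) <= _CONST_TOL:
        raise ValueError("correlation undefined: zero variance input")
    r, p = stats.pearsonr(d, x)
    return float(r), float(p)


def paired_timepoint_contrast(
    values_t1, values_t2, subject_ids
) -> PairedContrast:
    """Paired Student's t-test of matched per-subject values at two times.

    ``values_t1`` and ``values_t2`` are aligned with ``subject_ids``
    (one pair per subject).  Reports the mean difference (t2 - t1), the
    t statistic and the two-sided p-value.  All-zero differences give
    t = 0, p = 1; zero within-pair variance with a non-zero mean is
    reported as p ~ 0 (infinite t).
    """
    v1 = np.asarray(values_t1, dtype=float)
    v2 = np.asarray(values_t2, dtype=float)
    ids = np.asarray(subject_ids)
    if not (v1.shape == v2.shape == ids.shape) or v1.ndim != 1:
        raise ValueError("values and subject_ids must be aligned 1-D arrays")
    if v1.size < 2:
        raise ValueError("need >=2 matched pairs")
    if len(set(ids.tolist())) != ids.size:
        dupes = sorted({s for s in ids.tolist() if list(ids).count(s) > 1})
        raise ValueError(f"subjects not uniquely matched: {dupes}")
    bad = ~(np.isfinite(v1) & np.isfinite(v2))
    if bad.any():
        raise ValueError(f"unmatched subjects (missing values): {ids[bad].tolist()}")

    diff = v2 - v1
    mean = float(diff.mean())
    n = diff.size
    sd = float(diff.std(ddof=1))
    if sd <= _CONST_TOL * max(1.0, abs(mean)):
        if abs(mean) <= _CONST_TOL:
            return PairedContrast(0.0, 0.0, 1.0, n)
        t_stat = np.inf if mean > 0 else -np.inf
        return PairedContrast(mean, float(t_stat), 0.0, n)
    t_stat = mean / (sd / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t_stat), n - 1))
    return PairedContrast(mean, float(t_stat), p, n)


def subtype_vs_wholeblood_contrast(
    subtype_ages: pd.DataFrame,
    wholeblood_ages,
    subject_ids=None,
) -> dict[str, PairedContrast]:
    """Paired contrast of each sorted subtype against matched whole blood.

    ``subtype_ages`` is subject x subtype (epigenetic ages of the sorted
    fractions); ``wholeblood_ages`` the matched whole-blood ages.  Returns
    one :class:`PairedContrast` per subtype, mean difference = subtype
    minus whole blood.
    """
    wb = np.asarray(wholeblood_ages, dtype=float)
    if subject_ids is None:
        subject_ids = np.asarray(subtype_ages.index)
    out = {}
    for ct in subtype_ages.columns:
        out[ct] = paired_timepoint_contrast(
            wb, subtype_ages[ct].to_numpy(dtype=float), subject_ids
        )
    return out
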