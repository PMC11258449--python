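"""Reference-based white-blood-cell deconvolution.

Estimates per-sample cell-type proportions from methylation beta values by
constrained projection onto sorted-cell reference profiles (the Houseman
approach): at a set of discriminating CpGs the sample's betas are modelled
as a convex mixture of the reference methylomes, and the mixture weights
are found by least squares on the simplex,

    min_w || R w - beta ||_2   s.t.  w >= 0,  sum(w) = 1.

The equality constraint reflects samples fully explained by the reference
panel; ``sum_to_one=False`` relaxes it to ``sum(w) <= 1`` for panels known
to be incomplete.  The solver is deterministic: an NNLS warm start refined
by SLSQP, which agrees with the exact quadratic-program solution to well
below 1e-6 on well-conditioned panels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize

from .cosinor import DEFAULT_PERIOD, bonferroni_adjust, fit_cosinor


def select_reference_sites(
    reference: pd.DataFrame, n_per_type: int
) -> list[str]:
    """Pick discriminating CpGs from a reference matrix (CpG x cell type).

    For each cell type the ``n_per_type`` sites maximising the gap between
    that type's beta and the mean of the other types are chosen, split
    evenly between hyper-methylated (positive gap) and hypo-methylated
    (negative gap) sites; the union over types is returned in reference
    order.  If fewer candidates exist than requested, all CpGs are
    returned with a warning.
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    k = reference.shape[1]
    if k < 2:
        raise ValueError("reference needs >=2 cell types")
    if n_per_type * k >= reference.shape[0]:
        warnings.warn(
            "requested more discriminating sites than available; "
            "returning all CpGs"
        )
        return list(reference.index)

    n_hyper = n_per_type - n_per_type // 2
    n_hypo = n_per_type // 2
    chosen: dict[str, None] = {}
    values = reference.to_numpy(dtype=float)
    total = values.sum(axis=1)
    for j in range(k):
        others_mean = (total - values[:, j]) / (k - 1)
        gap = values[:, j] - others_mean
        order = np.argsort(gap)
        for idx in order[::-1][:n_hyper]:
            chosen[reference.index[idx]] = None
        for idx in order[:n_hypo]:
            chosen[reference.index[idx]] = None
    return [c for c in reference.index if c in chosen]


def _simplex_lsq(A: np.ndarray, b: np.ndarray, sum_to_one: bool) -> np.ndarray:
    """Least squares on the (sub-)simplex. Deterministic given inputs."""
    k = A.shape[1]

    # warm start: NNLS with a strong sum-constraint row, then polish
    lam = 100.0 * max(1.0, np.abs(A).max())
    A_aug = np.vstack([A, lam * np.ones((1, k))])
    b_aug = np.concatenate([b, [lam]])
    w0, _ = optimize.nnls(A_aug, b_aug)
    s = w0.sum()
    w0 = w0 / s if s > 0 else np.full(k, 1.0 / k)

    def fun(w):
        r = A @ w - b
        return 0.5 * float(r @ r)

    def jac(w):
        return A.T @ (A @ w - b)

    if sum_to_one:
        constraints = [
            {
                "type": "eq",
                "fun": lambda w: w.sum() - 1.0,
                "jac": lambda w: np.ones_like(w),
            }
        ]
    else:
        constraints = [
            {
                "type": "ineq",
                "fun": lambda w: 1.0 - w.sum(),
                "jac": lambda w: -np.ones_like(w),
            }
        ]
    res = optimize.minimize(
        fun,
        w0,
        jac=jac,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=constraints,
        options={"ftol": 1e-16, "maxiter": 500},
    )
    w = np.clip(res.x, 0.0, 1.0)
    if sum_to_one:
        w = w / w.sum()
    return w


def estimate_proportions(
    betas: pd.DataFrame,
    reference: pd.DataFrame,
    sites=None,
    sum_to_one: bool = True,
) -> pd.DataFrame:
    """Estimate cell-type proportions for every sample.

    Parameters
    ----------
    betas : DataFrame
        CpG x sample beta matrix.
    reference : DataFrame
        CpG x cell-type reference betas.
    sites : list of CpG ids, optional
        Discriminating sites to project on (default: all shared CpGs).
    sum_to_one : bool
        Equality constraint ``sum(w) = 1`` (default) or ``<= 1``.

    Returns
    -------
    DataFrame indexed by sample id with one column per cell type plus a
    ``residual`` column holding the Euclidean norm of the projection
    residual.  Proportions are non-negative and (by construction, not by
    post-hoc normalisation) sum to one per sample.
    """
    if sites is None:
        sites = [c for c in reference.index if c in betas.index]
    missing = [s for s in sites if s not in betas.index or s not in reference.index]
    if missing:
        raise ValueError(f"sites absent from betas or reference: {missing[:5]}")
    R = reference.loc[sites].to_numpy(dtype=float)
    if np.isnan(R).any():
        raise ValueError("reference has missing values on the selected sites")
    k = reference.shape[1]
    if np.linalg.matrix_rank(R) < k:
        raise ValueError(
            "reference is rank-deficient on the selected sites; "
            "select more or better discriminating sites"
        )
    B = betas.loc[sites].to_numpy(dtype=float)

    rows = []
    for j in range(B.shape[1]):
        w = _simplex_lsq(R, B[:, j], sum_to_one)
        resid = float(np.linalg.norm(R @ w - B[:, j]))
        rows.append(np.concatenate([w, [resid]]))
    out = pd.DataFrame(
        rows,
        index=pd.Index(betas.columns, name="sample_id"),
        columns=list(reference.columns) + ["residual"],
    )
    return out


def proportion_rhythm_report(
    proportions: pd.DataFrame,
    times,
    period: float = DEFAULT_PERIOD,
) -> pd.DataFrame:
    """Cosinor fit per cell type over the estimated proportions.

    ``proportions`` is sample x cell-type (a ``residual`` column, if
    present, is ignored).  P-values are Bonferroni-adjusted across the
    number of cell types.
    """
    cols = [c for c in proportions.columns if c != "residual"]
    t = np.asarray(times, dtype=float)
    if t.size != proportions.shape[0]:
        raise ValueError("times must align with proportion rows")
    rows = []
    for c in cols:
        fit = fit_cosinor(t, proportions[c].to_numpy(dtype=float), period=period)
        rows.append(
            {
                "cell_type": c,
                "mesor": fit.mesor,
                "amplitude": fit.amplitude,
                "acrophase_h": fit.acrophase,
                "p_value": fit.p_value,
                "n": fit.n,
            }
        )
    report = pd.DataFrame(rows).set_index("cell_type")
    report["p_bonferroni"] = bonferroni_adjust(
        report["p_value"].to_numpy(), m=len(cols)
    )
    return report
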