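"""Cosinor rhythmometry.

Single-component cosinor regression fits a cosine with known period
(24 h by default) to a time series by ordinary least squares on the
linearised design ``[1, cos(2*pi*t/tau), sin(2*pi*t/tau)]``:

    y(t) = M + A*cos(2*pi*(t - phi)/tau) + e
         = M + b_c*cos(w*t) + b_s*sin(w*t) + e

with MESOR ``M`` (rhythm-adjusted mean), amplitude ``A = hypot(b_c, b_s)``
(half the peak-to-trough range) and acrophase ``phi`` (hour of the fitted
peak).  Rhythm detection is the classical zero-amplitude test: a partial
F-test that the cosine and sine coefficients are jointly zero.

The module provides the single-series fit, a fixed-effects multi-subject
("combined") fit with individual-specific MESOR, amplitude and acrophase,
and a vectorised genome-wide per-CpG screen.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PERIOD = 24.0

# amplitudes below this (on the scale of the data) are treated as zero when
# deciding the degenerate perfect-fit convention
_ZERO_AMP = 1e-12


@dataclasses.dataclass(frozen=True)
class SubjectRhythm:
    """Per-subject rhythm parameters from a combined cosinor fit."""

    mesor: float
    amplitude: float
    acrophase: float


@dataclasses.dataclass(frozen=True)
class CosinorFit:
    """Result of a cosinor regression.

    Attributes
    ----------
    mesor : float
        Midline Estimating Statistic Of Rhythm — the rhythm-adjusted mean.
    amplitude : float
        Half the peak-to-trough range of the fitted cosine (>= 0).
    acrophase : float
        Hour of day of the fitted peak, wrapped into ``[0, period)``.
    period : float
        Fixed oscillation period in hours.
    p_value : float
        Zero-amplitude F-test p-value.
    n : int
        Number of observations used.
    subjects : dict or None
        Per-subject :class:`SubjectRhythm` sets for combined fits.
    """

    mesor: float
    amplitude: float
    acrophase: float
    period: float
    p_value: float
    n: int
    subjects: dict[str, SubjectRhythm] | None = None

    @property
    def nadir(self) -> float:
        """Hour of day of the fitted trough (acrophase + half period)."""
        return float((self.acrophase + self.period / 2.0) % self.period)

    @property
    def peak_to_trough(self) -> float:
        return 2.0 * self.amplitude


@dataclasses.dataclass(frozen=True)
class ScreenResult:
    """Genome-wide per-CpG oscillation screen."""

    p_values: pd.Series
    alpha: float
    significant: pd.Index

    @property
    def count(self) -> int:
        return int(len(self.significant))


def _design(t: np.ndarray, period: float) -> np.ndarray:
    w = 2.0 * np.pi / period
    return np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])


def _acrophase(b_cos: float, b_sin: float, period: float) -> float:
    # y = b_c cos(wt) + b_s sin(wt) = A cos(w (t - phi)) with
    # b_c = A cos(w phi), b_s = A sin(w phi)
    return float((period / (2.0 * np.pi)) * np.arctan2(b_sin, b_cos) % period)


def _check_series(times, values) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("times and values must be finite")
    return t, y


def fit_cosinor(times, values, period: float = DEFAULT_PERIOD) -> CosinorFit:
    """Fit a single-component cosinor to one series.

    Parameters
    ----------
    times : array-like
        Sampling times in hours; need not fall within one cycle.
    values : array-like
        Observed series (clock estimates, proportions, betas, ...).
    period : float
        Fixed period in hours (default 24).

    Raises
    ------
    ValueError
        Fewer than 4 observations, or all times coincide modulo the
        period (rank-deficient design).

    Notes
    -----
    A constant series is reported with amplitude 0 and p = 1.  A perfect
    (zero-residual) fit with non-zero amplitude is reported with p = 0.
    """
    t, y = _check_series(times, values)
    n = t.size
    if n < 4:
        raise ValueError(f"cosinor needs >=4 observations, got {n}")
    X = _design(t, period)
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError(
            "degenerate sampling design: times coincide modulo the period"
        )
    if np.ptp(y) == 0.0:
        return CosinorFit(float(y[0]), 0.0, 0.0, period, 1.0, n)

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss1 = float(resid @ resid)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    amp = float(np.hypot(beta[1], beta[2]))
    acro = _acrophase(beta[1], beta[2], period)
    df2 = n - 3
    if rss1 <= 1e-12 * max(rss0, 1.0) / n:
        p = 0.0 if amp > _ZERO_AMP else 1.0
    else:
        f_stat = ((rss0 - rss1) / 2.0) / (rss1 / df2)
        p = float(stats.f.sf(f_stat, 2, df2))
    return CosinorFit(float(beta[0]), amp, acro, period, p, n)


def fit_cosinor_combined(
    times, values, subject_ids, period: float = DEFAULT_PERIOD
) -> CosinorFit:
    """Combined multi-subject cosinor with individual-specific parameters.

    The full model has one intercept and one cosine/sine coefficient pair
    per subject (3m fixed-effect parameters for m subjects); the null model
    keeps only the per-subject intercepts.  The joint zero-amplitude test
    is the partial F-test with (2m, n - 3m) degrees of freedom.

    With a single subject the fit is identical to :func:`fit_cosinor`.

    The top-level ``mesor`` and ``amplitude`` are the means of the
    per-subject values and ``acrophase`` is their circular mean, so that
    the m = 1 case reduces exactly.
    """
    t, y = _check_series(times, values)
    ids = np.asarray(subject_ids)
    if ids.shape != t.shape:
        raise ValueError("subject_ids must align with times")
    subjects = list(dict.fromkeys(ids.tolist()))
    m = len(subjects)
    n = t.size

    cols_full = []
    cols_null = []
    w = 2.0 * np.pi / period
    for s in subjects:
        mask = (ids == s).astype(float)
        t_s = t[ids == s]
        if t_s.size < 4 or np.unique(np.round(t_s % period, 9)).size < 3:
            raise ValueError(
                f"subject {s!r}: needs >=4 observations at >=3 distinct "
                "times modulo the period"
            )
        cols_null.append(mask)
        cols_full.extend([mask, mask * np.cos(w * t), mask * np.sin(w * t)])
    X1 = np.column_stack(cols_full)
    X0 = np.column_stack(cols_null)
    df2 = n - 3 * m
    if df2 < 1:
        raise ValueError("not enough observations for the combined model")
    if np.linalg.matrix_rank(X1) < 3 * m:
        raise ValueError("rank-deficient combined design")

    beta1, _, _, _ = np.linalg.lstsq(X1, y, rcond=None)
    beta0, _, _, _ = np.linalg.lstsq(X0, y, rcond=None)
    r1 = y - X1 @ beta1
    r0 = y - X0 @ beta0
    rss1 = float(r1 @ r1)
    rss0 = float(r0 @ r0)

    per_subject: dict = {}
    for j, s in enumerate(subjects):
        ms, bc, bs = beta1[3 * j : 3 * j + 3]
        per_subject[s] = SubjectRhythm(
            float(ms), float(np.hypot(bc, bs)), _acrophase(bc, bs, period)
        )

    amps = np.array([r.amplitude for r in per_subject.values()])
    mesors = np.array([r.mesor for r in per_subject.values()])
    acros = np.array([r.acrophase for r in per_subject.values()])
    ang = 2.0 * np.pi * acros / period
    acro_mean = float(
        (period / (2.0 * np.pi))
        * np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
        % period
    )

    if np.ptp(y) == 0.0:
        p = 1.0
    elif rss1 <= 1e-12 * max(rss0, 1.0) / n:
        p = 0.0 if amps.max(initial=0.0) > _ZERO_AMP else 1.0
    else:
        f_stat = ((rss0 - rss1) / (2.0 * m)) / (rss1 / df2)
        p = float(stats.f.sf(f_stat, 2 * m, df2))

    return CosinorFit(
        float(mesors.mean()),
        float(amps.mean()),
        acro_mean,
        period,
        p,
        n,
        subjects=per_subject,
    )


def screen_sites(
    betas: pd.DataFrame,
    times,
    alpha: float = 0.05,
    period: float = DEFAULT_PERIOD,
) -> ScreenResult:
    """Per-CpG cosinor screen over a beta matrix (CpG x sample).

    Each row is fit independently; the significant set is taken at the
    unadjusted ``p < alpha`` threshold, matching the convention of
    genome-wide oscillating-site counts.  Zero-variance rows are reported
    with p = 1 and excluded from the significant set.
    """
    t = np.asarray(times, dtype=float)
    if betas.shape[1] != t.size:
        raise ValueError(
            f"betas has {betas.shape[1]} columns but {t.size} times given"
        )
    n = t.size
    if n < 4:
        raise ValueError("screen needs >=4 samples")
    X = _design(t, period)
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("degenerate sampling design")

    Y = betas.to_numpy(dtype=float).T  # samples x cpgs
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    rss1 = np.einsum("ij,ij->j", resid, resid)
    centered = Y - Y.mean(axis=0)
    rss0 = np.einsum("ij,ij->j", centered, centered)
    df2 = n - 3

    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ((rss0 - rss1) / 2.0) / (rss1 / df2)
    p = stats.f.sf(f_stat, 2, df2)

    amp = np.hypot(coef[1], coef[2])
    perfect = rss1 <= 1e-12 * np.maximum(rss0, 1.0) / n
    p = np.where(perfect, np.where(amp > _ZERO_AMP, 0.0, 1.0), p)
    p = np.where(rss0 == 0.0, 1.0, p)  # constant rows

    p_ser = pd.Series(p, index=betas.index, name="p_value")
    sig = p_ser.index[p_ser.to_numpy() < alpha]
    return ScreenResult(p_values=p_ser, alpha=alpha, significant=sig)


def bonferroni_adjust(p_values, m: int | None = None):
    """Bonferroni-adjust p-values: ``p_adj = min(1, m * p)``.

    ``m`` defaults to the number of tests supplied.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size if p.ndim else 1
    if m < 1:
        raise ValueError("m must be >= 1")
    adj = np.minimum(1.0, m * p)
    if np.isscalar(p_values) or np.ndim(p_values) == 0:
        return float(adj)
    if isinstance(p_values, pd.Series):
        return pd.Series(adj, index=p_values.index, name=p_values.name)
    return adj


def oscillation_summary(fit: CosinorFit) -> dict:
    """Report-row summary of one cosinor fit.

    Includes the amplitude expressed as a percentage of the MESOR
    (``100*A/M``) and the peak-to-nadir swing (``100*2A/M``); both are
    NaN when the MESOR is zero (flagged via ``percent_defined``).
    """
    defined = fit.mesor != 0.0
    if defined:
        amp_pct = 100.0 * fit.amplitude / fit.mesor
        p2n_pct = 200.0 * fit.amplitude / fit.mesor
    else:
        warnings.warn("MESOR is zero: percent-of-MESOR metrics undefined")
        amp_pct = float("nan")
        p2n_pct = float("nan")
    return {
        "mesor": fit.mesor,
        "amplitude": fit.amplitude,
        "acrophase_h": fit.acrophase,
        "nadir_h": fit.nadir,
        "amplitude_pct_of_mesor": amp_pct,
        "peak_to_nadir_pct": p2n_pct,
        "p_value": fit.p_value,
        "n": fit.n,
        "percent_defined": defined,
    }
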