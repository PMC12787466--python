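"""Full pairwise partial correlations with t-based p-values.

Edge weights of the health network are partial correlations Rp: the
correlation between each pair of variables after linearly removing the
effect of all remaining variables. For a positive-definite sample
covariance S with precision matrix Omega = S^-1,

    Rp_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj),

which coincides with correlating the residuals of i and j after ordinary
least-squares regression on the other p-2 columns.

Significance uses the classical t transform for a partial correlation with
conditioning-set size k = p - 2:

    t = r * sqrt((n - k - 2) / (1 - r^2)),   df = n - k - 2,

two-sided. At the study's size (n = 188, p = 17) this gives df = 171.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PcorResult:
    """Partial-correlation matrix with matched two-sided p-values.

    ``rp`` and ``pvals`` are symmetric p x p matrices; by convention the
    diagonal of ``rp`` is 1 and of ``pvals`` is 0. ``k`` is the size of
    the conditioning set (p - 2).
    """

    rp: np.ndarray
    pvals: np.ndarray
    n: int
    k: int
    labels: list[str]

    @property
    def p(self) -> int:
        return len(self.labels)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        rp = pd.DataFrame(self.rp, index=self.labels, columns=self.labels)
        pv = pd.DataFrame(self.pvals, index=self.labels, columns=self.labels)
        return rp, pv

    def to_csv(self, rp_path: str | Path, pvals_path: str | Path) -> None:
        rp, pv = self.to_frames()
        rp.to_csv(rp_path, float_format="%.10g")
        pv.to_csv(pvals_path, float_format="%.10g")


def pcor_pvalue(r, n: int, k: int):
    """Two-sided p-value for a partial correlation.

    Parameters
    ----------
    r : float or ndarray
        Partial correlation(s), |r| <= 1.
    n : int
        Sample size.
    k : int
        Number of conditioning variables.
    """
    df = n - k - 2
    if df < 1:
        raise ValueError(f"degrees of freedom n - k - 2 = {df} < 1")
    r = np.asarray(r, dtype=float)
    r_clipped = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_clipped * np.sqrt(df / (1.0 - r_clipped**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r_clipped) >= 1.0, 0.0, p)
    return float(p) if p.ndim == 0 else p


def _check_columns(x: np.ndarray, labels: list[str]) -> None:
    variances = x.var(axis=0, ddof=1)
    constant = [labels[j] for j in np.flatnonzero(variances == 0)]
    if constant:
        raise ValueError(f"constant column(s): {constant}")


def _collinear_columns(x: np.ndarray, labels: list[str]) -> list[str]:
    """Columns exactly explained by the others (for error reporting)."""
    bad = []
    for j in range(x.shape[1]):
        others = np.delete(x, j, axis=1)
        design = np.column_stack([np.ones(len(x)), others])
        resid = x[:, j] - design @ np.linalg.lstsq(design, x[:, j], rcond=None)[0]
        if np.sum(resid**2) <= 1e-10 * max(np.sum(x[:, j] ** 2), 1.0):
            bad.append(labels[j])
    return bad


def partial_correlations(data, labels: list[str] | None = None) -> PcorResult:
    """Estimate the full pairwise partial-correlation matrix.

    ``data`` may be a :class:`~pcornet.cohort.CohortTable`, a pandas
    DataFrame or an (n, p) array. Categorical variables enter as their
    numeric codes (a single Pearson-type mixed matrix). Requires
    ``n > p + 2`` so every pairwise test has at least one degree of
    freedom.
    """
    frame = getattr(data, "frame", data)
    if isinstance(frame, pd.DataFrame):
        labels = list(frame.columns)
        x = frame.to_numpy(dtype=float)
    else:
        x = np.asarray(frame, dtype=float)
        if labels is None:
            labels = [f"V{j}" for j in range(x.shape[1])]
    n, p = x.shape
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 observations (n={n}, p={p})")
    _check_columns(x, labels)

    cov = np.cov(x, rowvar=False, ddof=1)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 1e-10 * eigvals[-1]:
        raise ValueError(
            f"singular covariance; collinear column(s): "
            f"{_collinear_columns(x, labels) or 'unidentified'}"
        )
    omega = np.linalg.inv(cov)
    d = np.sqrt(np.diag(omega))
    rp = -omega / np.outer(d, d)
    rp = (rp + rp.T) / 2.0
    np.fill_diagonal(rp, 1.0)

    k = p - 2
    pvals = pcor_pvalue(rp, n, k)
    pvals = (pvals + pvals.T) / 2.0
    np.fill_diagonal(pvals, 0.0)
    return PcorResult(rp=rp, pvals=pvals, n=n, k=k, labels=labels)
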