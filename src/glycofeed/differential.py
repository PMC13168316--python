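"""Per-glycoform linear-model contrasts with empirical-Bayes moderation.

Each glycoform's clr abundance is modeled with a cell-means design over the
(strategy, phase) cells; named contrasts test stationary-vs-exponential
within a strategy, or strategy-vs-strategy within a phase. With few
biological replicates per cell, per-glycoform variance estimates are noisy;
empirical-Bayes moderation shrinks them toward a pooled inverse-gamma prior
(fitted by matching moments of the log residual variances) and augments the
residual degrees of freedom accordingly, the standard moderated-t approach
for small-n omics designs. Effects on the clr (natural-log-ratio) scale are
reported divided by ln 2 as log2 fold changes; p-values are BH-adjusted
within each comparison and labelled with significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .compositional import ClrMatrix

__all__ = [
    "CellMeansFit",
    "ContrastResult",
    "fit_cell_means",
    "test_contrast",
    "assign_stars",
    "pairwise_cell_contrast",
]

_LN2 = np.log(2.0)


def assign_stars(adjusted_p: float) -> str:
    """Significance label for an adjusted p-value.

    ``***`` below 0.001, ``**`` below 0.01, ``*`` below 0.05, else ``ns``.
    """
    p = float(adjusted_p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class CellMeansFit:
    """OLS cell-means fit of every glycoform on (strategy, phase) cells."""

    cells: list[str]                # cell labels "strategy|phase"
    coef: pd.DataFrame              # cells x glycoforms cell means
    sigma2: pd.Series               # residual variance per glycoform
    df_resid: int
    xtx_inv: np.ndarray             # (X'X)^-1, shared across glycoforms
    n_samples: int


def _cell_labels(metadata: pd.DataFrame) -> pd.Series:
    return metadata["strategy"].astype(str) + "|" + metadata["phase"].astype(str)


def fit_cell_means(clr: ClrMatrix, min_replicates: int = 2) -> CellMeansFit:
    """Fit per-glycoform OLS with one mean per (strategy, phase) cell.

    All glycoforms share the design, so a single least-squares solve covers
    the whole matrix. Residual df is n_samples - n_cells. Cells with fewer
    than ``min_replicates`` samples make variances unidentifiable and raise.
    """
    labels = _cell_labels(clr.metadata)
    cells = sorted(labels.unique())
    counts = labels.value_counts()
    under = [c for c in cells if counts[c] < min_replicates]
    if under:
        raise ValueError(f"cells with fewer than {min_replicates} replicates: {under}")
    X = (labels.to_numpy()[:, None] == np.asarray(cells)[None, :]).astype(float)
    Y = clr.to_numpy()
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    df = Y.shape[0] - len(cells)
    if df < 1:
        raise ValueError("no residual degrees of freedom (one replicate per cell?)")
    sigma2 = (resid ** 2).sum(axis=0) / df
    return CellMeansFit(
        cells=cells,
        coef=pd.DataFrame(coef, index=cells, columns=clr.values.columns),
        sigma2=pd.Series(sigma2, index=clr.values.columns),
        df_resid=df,
        xtx_inv=np.linalg.inv(X.T @ X),
        n_samples=Y.shape[0],
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/x scale)."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x - dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_variances(sigma2: np.ndarray, df: int) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of residual variances toward a pooled prior.

    Fits a scaled inverse-chi-square prior (scale ``s0^2``, df ``d0``) to the
    observed variances by matching the mean and variance of ``log(s^2)``
    against their theoretical values under the model, then returns the
    posterior variances ``(d0*s0^2 + df*s^2) / (d0 + df)`` together with
    ``(d0, s0^2)``. When the observed spread of log-variances is no larger
    than expected from chi-square sampling alone, the prior df is infinite
    and all variances collapse to the common value.
    """
    s2 = np.asarray(sigma2, dtype=float)
    ok = s2 > 0
    z = np.log(np.where(ok, s2, 1.0))[ok]
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_var = float(np.var(e, ddof=1)) if len(e) > 1 else 0.0
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(np.mean(e)))
        post = np.full_like(s2, s0_2)
        return post, d0, s0_2
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_2 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, d0, s0_2


@dataclass
class ContrastResult:
    """Per-glycoform effects for one named comparison."""

    comparison: str
    table: pd.DataFrame  # columns: log2FC, t, p, adj_p, stars
    moderated: bool
    prior_df: float | None = None


def test_contrast(
    fit: CellMeansFit,
    contrast: dict[str, float] | pd.Series,
    comparison: str,
    moderate: bool = True,
) -> ContrastResult:
    """Test a zero-sum contrast of cell means for every glycoform.

    ``contrast`` maps cell labels ("strategy|phase") to weights summing to
    zero. The effect is the weighted combination of cell means on the clr
    scale divided by ln 2 (log2FC); the t statistic uses moderated variances
    by default, with df augmented by the prior df. BH adjustment is applied
    across glycoforms within this one comparison.
    """
    w = pd.Series(0.0, index=fit.cells)
    for cell, weight in dict(contrast).items():
        if cell not in w.index:
            raise ValueError(f"unknown cell {cell!r}; available: {fit.cells}")
        w[cell] = weight
    if abs(w.sum()) > 1e-9:
        raise ValueError(f"contrast weights must sum to 0, got {w.sum():g}")
    L = w.to_numpy()
    effect = L @ fit.coef.to_numpy()
    unit_var = float(L @ fit.xtx_inv @ L)
    if moderate:
        s2, d0, _ = squeeze_variances(fit.sigma2.to_numpy(), fit.df_resid)
        df_t = fit.df_resid + (d0 if np.isfinite(d0) else 1e6)
        prior_df = d0
    else:
        s2 = fit.sigma2.to_numpy()
        df_t = fit.df_resid
        prior_df = None
    se = np.sqrt(s2 * unit_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_t)
    adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({
        "log2FC": effect / _LN2,
        "t": t,
        "p": p,
        "adj_p": adj,
        "stars": [assign_stars(a) for a in adj],
    }, index=fit.coef.columns)
    table.index.name = "glycoform"
    return ContrastResult(comparison=comparison, table=table,
                          moderated=moderate, prior_df=prior_df)


def pairwise_cell_contrast(
    fit: CellMeansFit, cell_a: str, cell_b: str, moderate: bool = True
) -> ContrastResult:
    """Convenience wrapper: mean(cell_a) - mean(cell_b)."""
    name = f"{cell_a}_vs_{cell_b}"
    return test_contrast(fit, {cell_a: 1.0, cell_b: -1.0}, name, moderate=moderate)
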