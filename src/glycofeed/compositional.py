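"""Compositional statistics for glycoform abundance profiles.

Fractional abundances summing to a constant live on a simplex, where naive
Euclidean statistics are distorted. The centered log-ratio (clr) transform
maps each sample to log(part / geometric mean of parts), an unconstrained
space with zero row sums in which linear models, PCA, correlations and
Euclidean-distance PERMANOVA are meaningful.

The PERMANOVA here partitions the Gower-centered squared Euclidean distance
matrix by sequential (Type-I) model terms, including interactions, with
pseudo-F statistics assessed by free permutation of samples; the companion
dispersion test checks multivariate homogeneity of within-group spread
(distance to group centroid) so that location effects are not confounded
with unequal dispersion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .glycoforms import GlycoformTable

logger = logging.getLogger(__name__)


@dataclass
class ClrMatrix:
    """Samples x glycoforms matrix in centered log-ratio space.

    Rows sum to zero; ``metadata`` carries strategy/phase/replicate.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.metadata.index):
            raise ValueError("clr matrix and metadata sample ids differ")

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def clr_transform(
    table: GlycoformTable,
    zero_policy: Literal["strict", "replace"] = "strict",
    replace_delta: float = 0.01,
) -> ClrMatrix:
    """Centered log-ratio transform of a fractional-abundance table.

    ``clr_jk = ln(x_jk / g_k(x))`` with ``g_k`` the row geometric mean.
    Scale-invariant (clr(c·x) = clr(x)) and zero-row-sum by construction.

    Zeros cannot be log-transformed: under ``zero_policy="strict"`` (the
    default — appropriate when every glycoform was detected in every sample)
    a zero raises naming the offending sample and glycoform; ``"replace"``
    substitutes ``replace_delta`` percent and renormalizes, with a warning.
    """
    X = table.values().copy()
    if (X < 0).any():
        raise ValueError("negative abundances cannot be clr-transformed")
    zeros = X <= 0
    if zeros.any():
        if zero_policy == "strict":
            i, j = np.argwhere(zeros)[0]
            raise ValueError(
                "zero abundance at sample "
                f"{table.abundances.index[i]!r}, glycoform "
                f"{table.abundances.columns[j]!r}; use zero_policy='replace' "
                "to impute"
            )
        logger.warning(
            "replacing %d zero abundance(s) with %.4g%% before clr",
            int(zeros.sum()), replace_delta,
        )
        X[zeros] = replace_delta
        X = 100.0 * X / X.sum(axis=1, keepdims=True)
    logX = np.log(X)
    clr = logX - logX.mean(axis=1, keepdims=True)
    values = pd.DataFrame(clr, index=table.abundances.index, columns=table.abundances.columns)
    return ClrMatrix(values, table.metadata.copy())


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca(clr: ClrMatrix) -> PcaResult:
    """PCA of the (always column-centered) clr matrix.

    Explained-variance fractions sum to 1 over the retained components
    (min(n_samples - 1, n_features)); component signs are fixed by making
    each component's largest-magnitude loading positive.
    """
    X = clr.to_numpy()
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if np.allclose(X, X.mean(axis=0), atol=1e-14):
        raise ValueError("constant matrix: total variance is zero")
    n_comp = min(X.shape[0] - 1, X.shape[1])
    model = _SkPCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(n_comp):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1.0
            scores[:, k] *= -1.0
    names = [f"PC{k + 1}" for k in range(n_comp)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=clr.values.index, columns=names),
        loadings=pd.DataFrame(loadings, index=names, columns=clr.values.columns),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


def spearman_sample_correlation(clr: ClrMatrix) -> pd.DataFrame:
    """Sample-by-sample Spearman correlation of clr glycan profiles.

    Profiles are compared across glycoforms (glycoforms as observations,
    samples as variables), so each entry reflects how similarly two samples
    rank their glycoforms. Samples with a constant profile have undefined
    rank correlations and are returned as NaN.
    """
    X = clr.to_numpy()
    if X.shape[1] < 2:
        raise ValueError("need at least 2 glycoforms per sample")
    corr = pd.DataFrame(X.T).corr(method="spearman")
    rho = corr.to_numpy()
    const = np.ptp(X, axis=1) == 0
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    ids = clr.values.index
    return pd.DataFrame(rho, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# PERMANOVA with sequential terms


@dataclass
class PermanovaResult:
    """Distance-based ANOVA table: one row per model term plus residual/total."""

    table: pd.DataFrame
    n_permutations: int
    seed: int | None

    def r_squared(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])


def _design_matrix(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Dummy-coded (full-rank, drop-first) columns for a main effect or
    an interaction written ``a:b`` / ``a×b``."""
    factors = [f.strip() for f in term.replace("×", ":").split(":")]
    parts = []
    for f in factors:
        if f not in metadata.columns:
            raise ValueError(f"unknown metadata column {f!r} in term {term!r}")
        codes, levels = pd.factorize(metadata[f], sort=True)
        if len(levels) < 2:
            raise ValueError(f"term {f!r} has fewer than 2 levels")
        D = np.eye(len(levels))[codes][:, 1:]  # drop first level
        parts.append(D)
    out = parts[0]
    for D in parts[1:]:
        out = np.einsum("ij,ik->ijk", out, D).reshape(len(out), -1)
    return out


def _hat(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return Q @ Q.T


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ (-0.5 * d2) @ J


def _sequential_ss(G: np.ndarray, hats: list[np.ndarray]) -> np.ndarray:
    """Sequential (Type-I) sums of squares: SS_k = tr((H_k - H_{k-1}) G)."""
    prev = np.zeros_like(G)
    out = []
    for H in hats:
        out.append(np.einsum("ij,ji->", H - prev, G))
        prev = H
    return np.asarray(out)


def permanova(
    clr: ClrMatrix,
    formula_terms: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
    *,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on Euclidean distances of clr values.

    Terms are fitted sequentially (Type-I) in the order given; interactions
    (``"phase:strategy"``) must come after their main effects. For each term,
    pseudo-F = (SS_term / df_term) / (SS_residual / df_residual) with the
    residual taken from the full model, and the p-value is the add-one
    permutation tail probability under free permutation of samples,
    ``p = (#{F* >= F} + 1) / (n_perm + 1)``. With ``exhaustive=True`` all n!
    distinct orderings are enumerated instead (tiny n only) and
    ``p = #{F* >= F} / n!`` counts the identity among the orderings.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = clr.to_numpy()
    n = X.shape[0]
    meta = clr.metadata
    # squared Euclidean distances; Gower-centered inner-product matrix
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    G = _gower_center(sq)
    ss_total = np.trace(G)

    designs = [_design_matrix(meta, t) for t in formula_terms]
    dfs = [D.shape[1] for D in designs]
    if n <= sum(dfs):
        raise ValueError("more model df than samples")
    cum: list[np.ndarray] = []
    hats = []
    acc = np.ones((n, 1))
    for D in designs:
        acc = np.hstack([acc, D])
        if np.linalg.matrix_rank(acc) < acc.shape[1]:
            raise ValueError("rank-deficient sequential design (empty cells?)")
        hats.append(_hat(acc) - np.ones((n, n)) / n)
    H_full = hats[-1]
    df_res = n - 1 - sum(dfs)

    def term_F(Gp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ss = _sequential_ss(Gp, hats)
        ss_res = np.trace(Gp) - np.einsum("ij,ji->", H_full, Gp)
        # residual SS below float noise is treated as exactly zero so that
        # degenerate (perfectly separated) configurations tie reproducibly
        if ss_res <= 1e-12 * ss_total:
            F = np.where(ss > 1e-12 * ss_total, np.inf, 0.0)
        else:
            F = (ss / np.asarray(dfs)) / (ss_res / df_res)
        return ss, F

    ss_obs, F_obs = term_F(G)
    ss_res = ss_total - ss_obs.sum()
    # tie tolerance: permuted statistics equal to the observed one (up to
    # float noise, which can be relatively large for near-degenerate F) count
    # as >= per the permutation-test convention
    tie = np.maximum(1e-12, 1e-9 * np.abs(F_obs))
    tie = np.where(np.isfinite(F_obs), tie, 0.0)

    if exhaustive:
        count = np.zeros(len(dfs))
        total = 0
        for perm in _iter_permutations(range(n)):
            idx = np.asarray(perm)
            _, Fp = term_F(G[np.ix_(idx, idx)])
            count += Fp >= F_obs - tie
            total += 1
        pvals = count / total
        n_done = total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(dfs))
        for _ in range(n_perm):
            idx = rng.permutation(n)
            _, Fp = term_F(G[np.ix_(idx, idx)])
            count += Fp >= F_obs - tie
        pvals = (count + 1) / (n_perm + 1)
        n_done = n_perm

    rows = []
    for t, df, ss, F, p in zip(formula_terms, dfs, ss_obs, F_obs, pvals):
        rows.append({"term": t, "df": df, "SS": ss, "F": F,
                     "R2": ss / ss_total, "p": p})
    rows.append({"term": "Residual", "df": df_res, "SS": ss_res, "F": np.nan,
                 "R2": ss_res / ss_total, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total, "F": np.nan,
                 "R2": 1.0, "p": np.nan})
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table=table, n_permutations=n_done, seed=seed)


@dataclass
class DispersionResult:
    """Multivariate homogeneity-of-dispersion test (betadisper-style)."""

    distances: pd.Series
    group_means: pd.Series
    F: float
    p: float
    n_permutations: int
    seed: int | None


def dispersion_test(
    clr: ClrMatrix,
    grouping: str | Sequence,
    n_perm: int = 999,
    seed: int | None = None,
    *,
    exhaustive: bool = False,
) -> DispersionResult:
    """Test homogeneity of multivariate dispersion across groups.

    Each sample's Euclidean distance to its group centroid in clr space is
    the dispersion score; homogeneity is assessed with a one-way F ratio on
    those scores, with the null distribution obtained by permuting group
    labels of the distances. ``p`` uses the add-one convention (or exact
    enumeration with ``exhaustive=True``).
    """
    X = clr.to_numpy()
    if isinstance(grouping, str):
        groups = clr.metadata[grouping].to_numpy()
    else:
        groups = np.asarray(list(grouping))
        if len(groups) != X.shape[0]:
            raise ValueError("grouping length mismatch")
    labels, counts = np.unique(groups, return_counts=True)
    if (counts < 2).any():
        small = labels[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    dist = np.empty(X.shape[0])
    for lab in labels:
        m = groups == lab
        centroid = X[m].mean(axis=0)
        dist[m] = np.sqrt(((X[m] - centroid) ** 2).sum(axis=1))

    def f_ratio(d: np.ndarray, g: np.ndarray) -> float:
        grand = d.mean()
        ss_b = sum(((d[g == lab].mean() - grand) ** 2) * (g == lab).sum() for lab in labels)
        ss_w = sum(((d[g == lab] - d[g == lab].mean()) ** 2).sum() for lab in labels)
        df_b = len(labels) - 1
        df_w = len(d) - len(labels)
        if ss_w <= 1e-12 * (ss_b + ss_w):
            return np.inf if ss_b > 1e-12 * (ss_b + ss_w) else 0.0
        return (ss_b / df_b) / (ss_w / df_w)

    F_obs = f_ratio(dist, groups)
    tie = max(1e-12, 1e-9 * abs(F_obs)) if np.isfinite(F_obs) else 0.0
    if exhaustive:
        count = total = 0
        for perm in _iter_permutations(range(len(dist))):
            count += f_ratio(dist, groups[np.asarray(perm)]) >= F_obs - tie
            total += 1
        p = count / total
        n_done = total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            count += f_ratio(dist, groups[rng.permutation(len(dist))]) >= F_obs - tie
        p = (count + 1) / (n_perm + 1)
        n_done = n_perm
    return DispersionResult(
        distances=pd.Series(dist, index=clr.values.index, name="dist_to_centroid"),
        group_means=pd.Series({lab: dist[groups == lab].mean() for lab in labels}),
        F=float(F_obs), p=float(p), n_permutations=n_done, seed=seed,
    )
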