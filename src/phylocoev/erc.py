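"""Evolutionary rate covariation (ERC).

Genes that work together tend to speed up and slow down together across
a phylogeny.  ERC quantifies this as the correlation coefficient of two
genes' branch-specific relative evolutionary rates: each gene's branch
length on the fixed species topology divided by a genome-wide reference
expectation for that branch, then standardized per gene.  A pathway's
association with a focal gene is summarized by the mean ERC between the
focal gene and the pathway members, and assessed against a permutation
null in which the focal gene is replaced by random genes from the
profiled background.

Pearson correlation on ratio-standardized rates is the default; a
Spearman option is available for robustness (``method="spearman"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from phylocoev.phylo_io import BranchLengthTable

__all__ = [
    "RateProfileSet",
    "ERCMatrix",
    "PermutationResult",
    "relative_rates",
    "erc_pair",
    "erc_matrix",
    "group_mean_erc",
    "permutation_pvalue",
]

MIN_SHARED_BRANCHES = 3


@dataclass
class RateProfileSet:
    """Per-gene standardized branch-rate profiles over a shared branch index.

    ``profiles`` is branches x genes; entries are mean-centered,
    unit-scaled relative rates with NaN where a gene lacks data for a
    branch.  Standardization is per gene over its own non-missing
    branches, so ERC is invariant to per-gene positive rescaling of the
    raw rates.
    """

    profiles: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def branch_ids(self) -> list[str]:
        return list(self.profiles.index)

    def profile(self, gene: str) -> np.ndarray:
        return self.profiles[gene].to_numpy(dtype=float)


def relative_rates(table: BranchLengthTable, min_branches: int = 10) -> RateProfileSet:
    """Branch-specific relative rates: gene length / reference length,
    then per-gene centering and unit scaling.

    Genes with fewer than ``min_branches`` non-missing branches are
    dropped with a warning (default 10: below that a correlation over
    branches is too noisy to interpret).
    """
    ref = table.reference
    raw = table.gene_lengths.to_numpy(dtype=float) / ref[:, None]
    out = {}
    dropped = []
    for j, gene in enumerate(table.genes):
        col = raw[:, j]
        obs = ~np.isnan(col)
        if obs.sum() < min_branches:
            dropped.append(gene)
            continue
        mu = col[obs].mean()
        sd = col[obs].std(ddof=0)
        # constant-rate gene: centered profile is all zeros (its ERC to
        # anything is undefined and surfaces as NaN downstream)
        out[gene] = (col - mu) / sd if sd > 0 else col - mu
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} gene(s) with < {min_branches} usable "
            f"branches: {dropped[:10]}",
            UserWarning,
            stacklevel=2,
        )
    return RateProfileSet(
        pd.DataFrame(out, index=[str(b) for b in table.branch_ids])
    )


def _pairwise(a: np.ndarray, b: np.ndarray, method: str) -> tuple[float, int]:
    shared = ~np.isnan(a) & ~np.isnan(b)
    n = int(shared.sum())
    if n < MIN_SHARED_BRANCHES:
        warnings.warn(
            f"only {n} shared branches (< {MIN_SHARED_BRANCHES}); ERC undefined",
            UserWarning,
            stacklevel=3,
        )
        return np.nan, n
    x, y = a[shared], b[shared]
    if method == "spearman":
        x, y = rankdata(x), rankdata(y)
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero rate variance on shared branches; ERC undefined",
                      UserWarning, stacklevel=3)
        return np.nan, n
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0)), n


def erc_pair(a: np.ndarray, b: np.ndarray, method: str = "pearson") -> tuple[float, int]:
    """ERC between two rate profiles: correlation over shared branches.

    Returns ``(erc, n_shared)``; the value is NaN (with a warning) when
    fewer than 3 branches are shared or a profile has no variance there.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must share the branch index")
    return _pairwise(a, b, method)


@dataclass
class ERCMatrix:
    """Symmetric gene x gene ERC matrix with per-cell shared-branch counts."""

    values: pd.DataFrame
    n_shared: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    def erc(self, a: str, b: str) -> float:
        return float(self.values.at[a, b])


def erc_matrix(profiles: RateProfileSet, method: str = "pearson") -> ERCMatrix:
    """All pairwise ERC values; symmetric with unit diagonal."""
    genes = profiles.genes
    m = len(genes)
    vals = np.eye(m)
    counts = np.zeros((m, m), dtype=int)
    cols = [profiles.profile(g) for g in genes]
    obs = [~np.isnan(c) for c in cols]
    for i in range(m):
        counts[i, i] = int(obs[i].sum())
        for j in range(i + 1, m):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r, n = _pairwise(cols[i], cols[j], method)
            vals[i, j] = vals[j, i] = r
            counts[i, j] = counts[j, i] = n
    return ERCMatrix(
        values=pd.DataFrame(vals, index=genes, columns=genes),
        n_shared=pd.DataFrame(counts, index=genes, columns=genes),
    )


def group_mean_erc(focal: str, geneset, m: ERCMatrix) -> tuple[float, int]:
    """Mean ERC between a focal gene and a gene set (pathway score).

    Returns ``(mean, n_contributing)`` over genes with a defined ERC to
    the focal gene; genes absent from the matrix are ignored.
    """
    geneset = [g for g in geneset if g != focal]
    if not geneset:
        raise ValueError("gene set is empty (after removing the focal gene)")
    vals = [m.values.at[focal, g] for g in geneset if g in m.values.columns]
    vals = [v for v in vals if not np.isnan(v)]
    if not vals:
        raise ValueError(
            f"no defined ERC values between {focal!r} and the gene set"
        )
    return float(np.mean(vals)), len(vals)


@dataclass
class PermutationResult:
    focal: str
    observed_mean_erc: float
    n_contributing: int
    null_means: np.ndarray
    p_value: float  # primary definition: k/N
    p_value_corrected: float  # (k+1)/(N+1)
    seed: int
    pool_size: int
    n_permutations: int


def permutation_pvalue(
    focal: str,
    geneset,
    profiles: RateProfileSet,
    n_permutations: int = 10_000,
    seed: int = 0,
    method: str = "pearson",
    matrix: ERCMatrix | None = None,
) -> PermutationResult:
    """Permutation p-value for a pathway-mean ERC.

    The observed statistic is the mean ERC between ``focal`` and the
    gene set.  Each null draw replaces the focal gene with a random
    gene from the background pool (all profiled genes excluding the
    focal gene and the set itself, so the tested entities cannot
    inflate their own null) and recomputes the set-mean ERC.  Draws are
    with replacement.  The primary p-value is the fraction of null
    means at least as large as the observed one (ties count); the
    bias-corrected (k+1)/(N+1) form is reported alongside.
    """
    geneset = list(dict.fromkeys(g for g in geneset if g != focal))
    if not geneset:
        raise ValueError("gene set is empty")
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} is small; p-value resolution is coarse",
            UserWarning, stacklevel=2,
        )
    if matrix is None and not profiles.profiles.isna().any().any():
        # fast path (no missing data): all needed correlations in one
        # matrix product instead of the full gene x gene ERC matrix
        genes = profiles.genes
        if focal not in genes:
            raise ValueError(f"focal gene {focal!r} not profiled")
        set_cols = [g for g in geneset if g in genes]
        if not set_cols:
            raise ValueError(f"no gene-set member is profiled")
        pool = [g for g in genes if g != focal and g not in set(geneset)]
        if not pool:
            raise ValueError("background pool is empty")
        X = profiles.profiles.to_numpy(dtype=float)
        if method == "spearman":
            X = rankdata(X, axis=0)
        Z = X - X.mean(axis=0)
        sd = Z.std(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            Z = np.where(sd > 0, Z / sd, np.nan)
        col = {g: i for i, g in enumerate(genes)}
        S = Z[:, [col[g] for g in set_cols]]
        n_b = X.shape[0]
        focal_ercs = np.clip(Z[:, col[focal]] @ S / n_b, -1, 1)
        observed = float(np.nanmean(focal_ercs))
        if np.isnan(observed):
            raise ValueError(
                f"no defined ERC values between {focal!r} and the gene set"
            )
        n_contrib = int(np.sum(~np.isnan(focal_ercs)))
        P = Z[:, [col[g] for g in pool]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pool_means = np.nanmean(np.clip(P.T @ S / n_b, -1, 1), axis=1)
    else:
        if matrix is None:
            matrix = erc_matrix(profiles, method=method)
        observed, n_contrib = group_mean_erc(focal, geneset, matrix)
        pool = [g for g in matrix.genes if g != focal and g not in set(geneset)]
        if not pool:
            raise ValueError("background pool is empty")
        # group_mean_erc depends only on the drawn focal gene, so compute
        # the pool's set-means once and sample rows.
        set_cols = [g for g in geneset if g in matrix.values.columns]
        sub = matrix.values.loc[pool, set_cols].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pool_means = np.nanmean(sub, axis=1)
    ok = ~np.isnan(pool_means)
    pool_means = pool_means[ok]
    if pool_means.size == 0:
        raise ValueError("no pool gene has a defined ERC to the gene set")

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, pool_means.size, size=n_permutations)
    null_means = pool_means[draws]
    k = int(np.sum(null_means >= observed))
    return PermutationResult(
        focal=focal,
        observed_mean_erc=observed,
        n_contributing=n_contrib,
        null_means=null_means,
        p_value=k / n_permutations,
        p_value_corrected=(k + 1) / (n_permutations + 1),
        seed=seed,
        pool_size=len(pool),
        n_permutations=n_permutations,
    )
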