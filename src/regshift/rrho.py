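"""Rank-rank hypergeometric overlap (RRHO) between two differential-
expression signatures, plus the flat Fisher gene-set overlap test.

Genes are ranked by the signed significance ``sign(logFC) * (-log10 p)`` in
descending order, so strongly up-regulated genes sit at the top and
strongly down-regulated genes at the bottom of each list.  The RRHO map
slides a threshold down both lists and tests the overlap of the two top
segments with a one-sided hypergeometric test at each threshold pair; the
grid of -log10 B-H-adjusted p-values visualizes where the signatures agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class RankedGeneList:
    """Gene ids ordered by descending signed significance."""

    gene_ids: list[str]
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def rank(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


def rank_genes(de_table: pd.DataFrame) -> RankedGeneList:
    """Rank a DE table (columns gene/gene_id, logFC, p) by
    ``sign(logFC) * (-log10 p)``, descending; ties broken by gene_id."""
    df = de_table.rename(columns={"gene": "gene_id"}).copy()
    for col in ("gene_id", "logFC", "p"):
        if col not in df.columns:
            raise ValueError(f"DE table missing column {col!r}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene in DE table: {dup!r}")
    p = df["p"].to_numpy(dtype=float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]; floor p=0 upstream")
    df["score"] = np.sign(df["logFC"].to_numpy(dtype=float)) * (-np.log10(p))
    df = df.sort_values(["score", "gene_id"], ascending=[False, True])
    return RankedGeneList(df["gene_id"].tolist(),
                          df["score"].to_numpy(dtype=float))


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"invalid hypergeometric arguments N={N} K={K} n={n} k={k}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class RRHOMap:
    """Grid of overlap significances between two ranked lists.

    ``matrix[i, j]`` is the -log10 B-H-adjusted one-sided hypergeometric p
    for the overlap of the top ``thresholds[i]`` genes of list A with the
    top ``thresholds[j]`` genes of list B.  Cell (0, 0) is the concordant
    top-of-both-lists (up-up) corner.
    """

    matrix: np.ndarray
    thresholds: np.ndarray
    step: int

    def to_dataframe(self) -> pd.DataFrame:
        labels = [f"top{t}" for t in self.thresholds]
        return pd.DataFrame(self.matrix, index=labels, columns=labels)


def default_step(n_genes: int) -> int:
    """Step size giving at most a 100 x 100 map."""
    return max(1, n_genes // 100)


def rrho_map(list_a: RankedGeneList, list_b: RankedGeneList,
             step: int | None = None) -> RRHOMap:
    """Compute the RRHO significance grid for two rankings of the same
    gene universe."""
    if set(list_a.gene_ids) != set(list_b.gene_ids):
        missing = sorted(set(list_a.gene_ids) ^ set(list_b.gene_ids))
        raise ValueError(f"gene universes differ; e.g. {missing[:5]}")
    n = len(list_a)
    if step is None:
        step = default_step(n)
    if step < 1:
        raise ValueError("step must be >= 1")

    rank_b = list_b.rank
    ra = np.arange(n)                                   # rank in A by A order
    rb = np.array([rank_b[g] for g in list_a.gene_ids])

    m = int(np.ceil(n / step))
    thresholds = np.minimum((np.arange(1, m + 1)) * step, n)
    # cumulative joint rank counts: counts[i, j] = #genes with
    # rank_a < thresholds[i] and rank_b < thresholds[j]
    edges = np.concatenate(([-0.5], thresholds - 0.5))
    hist, _, _ = np.histogram2d(ra, rb, bins=[edges, edges])
    counts = hist.cumsum(axis=0).cumsum(axis=1).astype(int)

    # vectorized upper tails over the whole grid
    pvals = stats.hypergeom.sf(
        counts - 1, n, thresholds[:, None], thresholds[None, :]
    )
    adjusted = multipletests(pvals.ravel(), method="fdr_bh")[1].reshape(m, m)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(np.clip(adjusted, 1e-300, 1.0))
    return RRHOMap(neglog, thresholds, step)


def fisher_overlap(set_a: set[str], set_b: set[str],
                   universe: set[str]) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test on the overlap of two gene
    sets within a universe; returns (sample odds ratio, p)."""
    if not universe:
        raise ValueError("empty universe")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - len(set_a | set_b)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)
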