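"""GWAS variant prioritization through dynamic TF binding sites.

The chain mirrors standard post-GWAS practice: keep genome-wide-significant
common variants (p < 5e-8, MAF > 1%), LD-prune them to independent index
variants (pairwise r^2 <= 0.1, greedy by ascending p), pool each index with
its high-LD proxies (r^2 > 0.8), intersect the pooled candidate set with
dynamic binding sites extended by 500 bp each side, annotate by gene-body
containment, and test allelic imbalance of accessibility at heterozygous
sites with an exact binomial test.

LD is computed from a user-supplied haplotype panel (binary haplotype x
variant matrix); positions in variant tables are 1-based and converted to
0-based points for interval arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel, GenomicInterval, build_tree, extend_intervals

REQUIRED_COLUMNS = ["rsid", "chrom", "pos", "ref", "alt", "p", "beta"]


@dataclass
class HaplotypePanel:
    """Binary haplotypes (rows) over variants (columns)."""

    matrix: np.ndarray
    rsids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 2:
            raise ValueError("panel must be a 2-D matrix with >= 2 haplotypes")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("panel entries must be 0/1")
        if self.matrix.shape[1] != len(self.rsids):
            raise ValueError("rsid list does not match panel columns")
        self._index = {r: i for i, r in enumerate(self.rsids)}

    def column(self, rsid: str) -> int:
        return self._index[rsid]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "HaplotypePanel":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(dtype=np.int8), list(df.columns))


def read_variants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns {missing}")
    return df


def compute_r2(panel: HaplotypePanel, i: int | str, j: int | str) -> float:
    """Squared LD correlation between two panel columns from haplotype
    frequencies: r^2 = (p_AB - p_A p_B)^2 / (p_A(1-p_A) p_B(1-p_B))."""
    ci = panel.column(i) if isinstance(i, str) else i
    cj = panel.column(j) if isinstance(j, str) else j
    x = panel.matrix[:, ci].astype(float)
    y = panel.matrix[:, cj].astype(float)
    pa, pb = x.mean(), y.mean()
    if pa in (0.0, 1.0):
        raise ValueError(f"column {i} is monomorphic")
    if pb in (0.0, 1.0):
        raise ValueError(f"column {j} is monomorphic")
    pab = (x * y).mean()
    return float((pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb)))


def filter_variants(variants: pd.DataFrame, p_max: float = 5e-8,
                    maf_min: float = 0.01) -> pd.DataFrame:
    """Genome-wide significance and common-variant filters, both strict."""
    out = variants[(variants["p"] < p_max)]
    if "maf" in variants.columns:
        out = out[out["maf"] > maf_min]
    return out.reset_index(drop=True)


def ld_prune(variants: pd.DataFrame, panel: HaplotypePanel,
             r2_max: float = 0.1) -> pd.DataFrame:
    """Greedy LD pruning by ascending p (ties by rsid): a variant is kept
    iff its r^2 with every already-kept variant on the same chromosome is
    <= ``r2_max``.  The retained set is pairwise r^2 <= r2_max."""
    ordered = variants.sort_values(["p", "rsid"])
    kept_rows = []
    kept_by_chrom: dict[str, list[str]] = {}
    for row in ordered.itertuples(index=False):
        prior = kept_by_chrom.get(row.chrom, [])
        if all(compute_r2(panel, row.rsid, other) <= r2_max for other in prior):
            kept_rows.append(row)
            kept_by_chrom.setdefault(row.chrom, []).append(row.rsid)
    return pd.DataFrame(kept_rows, columns=list(ordered.columns))


def ld_pool(index_variants: pd.DataFrame, all_variants: pd.DataFrame,
            panel: HaplotypePanel, r2_min: float = 0.8) -> dict[str, pd.DataFrame]:
    """Expand each index variant into its locus pool: the index plus every
    same-chromosome variant with r^2 strictly greater than ``r2_min``.
    A variant contested by several indexes goes to the lower-p index."""
    claimed: dict[str, str] = {}
    ordered = index_variants.sort_values(["p", "rsid"])
    for idx in ordered.itertuples(index=False):
        claimed[idx.rsid] = idx.rsid
        same_chrom = all_variants[all_variants["chrom"] == idx.chrom]
        for row in same_chrom.itertuples(index=False):
            if row.rsid in claimed:
                continue
            try:
                r2 = compute_r2(panel, idx.rsid, row.rsid)
            except ValueError:
                continue
            if r2 > r2_min:
                claimed[row.rsid] = idx.rsid
    pools = {}
    for idx in ordered.itertuples(index=False):
        members = [r for r, owner in claimed.items() if owner == idx.rsid]
        pools[idx.rsid] = (
            all_variants[all_variants["rsid"].isin(members)]
            .sort_values(["chrom", "pos"]).reset_index(drop=True)
        )
    return pools


def annotate_variant(chrom: str, pos_1based: int,
                     genes: list[GeneModel]) -> str:
    """Gene-body containment annotation: "<gene> intron" when the variant
    lies inside a gene body (a proxy: exon structure is not modelled),
    else "Intergenic region"."""
    point = pos_1based - 1
    for g in genes:
        if g.chrom == chrom and g.body.contains_point(point):
            return f"{g.gene_id} intron"
    return "Intergenic region"


def overlap_dbs_variants(pooled: dict[str, pd.DataFrame],
                         dbs_intervals: list[GenomicInterval],
                         genes: list[GeneModel] | None = None,
                         pad: int = 500,
                         chrom_sizes: dict[str, int] | None = None,
                         ) -> pd.DataFrame:
    """Intersect pooled candidate variants with extended dynamic binding
    sites, producing a prioritized-variant report.

    DBS intervals are the un-extended site intervals; each is grown by
    ``pad`` bp per side here.  A variant is retained iff its (0-based)
    position falls inside an extended DBS; ``locus_id`` groups rows by the
    DBS that contains them.
    """
    extended = extend_intervals(dbs_intervals, pad, chrom_sizes)
    named = [
        GenomicInterval(iv.chrom, iv.start, iv.end,
                        name=f"{iv.chrom}-{iv.start}-{iv.end}")
        for iv in extended
    ]
    tree = build_tree(named)
    rows = []
    for index_rsid, pool in pooled.items():
        for row in pool.itertuples(index=False):
            point = int(row.pos) - 1
            chrom_tree = tree.get(row.chrom)
            if chrom_tree is None:
                continue
            hits = sorted(h.data for h in chrom_tree.overlap(point, point + 1))
            for hit in hits:
                rows.append({
                    "rsid": row.rsid, "chrom": row.chrom, "pos": int(row.pos),
                    "ref": row.ref, "alt": row.alt,
                    "dbs": hit.name, "locus_id": hit.name,
                    "index_rsid": index_rsid,
                    "annotation": (annotate_variant(row.chrom, int(row.pos), genes)
                                   if genes is not None else ""),
                })
    out = pd.DataFrame(
        rows, columns=["rsid", "chrom", "pos", "ref", "alt", "dbs",
                       "annotation", "locus_id", "index_rsid"],
    )
    return out.sort_values(["chrom", "pos", "rsid"]).reset_index(drop=True)


def allelic_imbalance(ref_count: int, alt_count: int) -> float:
    """Exact two-sided binomial test of allele-count balance (prop. 0.5)."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be >= 0")
    n = ref_count + alt_count
    if n == 0:
        raise ValueError("total count must be >= 1")
    return float(stats.binomtest(ref_count, n, 0.5, alternative="two-sided").pvalue)


def group_loci(table: pd.DataFrame) -> pd.DataFrame:
    """Group a prioritized-variant table by its DBS interval, returning one
    row per locus with the member rsids."""
    if table.empty:
        return pd.DataFrame(columns=["locus_id", "n_variants", "rsids"])
    grouped = (
        table.groupby("locus_id", sort=True)["rsid"]
        .agg(["size", lambda s: ",".join(sorted(s))])
        .reset_index()
    )
    grouped.columns = ["locus_id", "n_variants", "rsids"]
    return grouped
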