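"""Seeded synthetic multi-omics dataset generator.

Emulates the statistical structure of an ATAC-seq + RNA-seq + GWAS study of
a lipid-stimulated endothelial cell model at desk scale: Poisson cut-count
tracks with peak enrichment, Tn5-like dinucleotide insertion bias and
footprint depletion at bound motifs; a planted regulator whose altered
binding sites drive expression changes in designated target genes; a
haplotype panel with block LD structure and causal GWAS variants planted
inside the altered (dynamic) binding sites.

Everything is deterministic given the seed: each stage draws from its own
stream derived from the seed with a fixed stage key, so adding a stage never
perturbs earlier stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    GeneModel,
    GenomicInterval,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
    write_genes,
)

# Fixed Tn5-like dinucleotide insertion-bias multipliers, indexed by
# 4*code(first base) + code(second base) with A,C,G,T -> 0..3.  Values are a
# stylized preference for GC-containing steps; the mean is close to 1 so the
# genome-wide rate is approximately preserved.
DINUC_BIAS = np.array([
    0.70, 1.05, 1.10, 0.75,   # AA AC AG AT
    1.05, 1.45, 1.30, 1.05,   # CA CC CG CT
    1.10, 1.30, 1.40, 1.00,   # GA GC GG GT
    0.75, 1.00, 1.05, 0.65,   # TA TC TG TT
])

BASES = np.array(list("ACGT"))

# stage keys for per-stage random streams
_STAGE_SEQ = 0
_STAGE_ANNOT = 1
_STAGE_TRACKS = 2
_STAGE_EXPR = 3
_STAGE_GWAS = 4


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset.

    Rates are in cuts per base; ``regulator_effect`` is the log2 fold change
    added to target-gene expression; ``footprint_depth`` is the fractional
    cut-rate depletion inside a bound motif.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 200
    n_tfs: int = 5
    sites_per_tf: int = 200
    site_width: int = 15
    peak_halfwidth: int = 200
    frac_altered_sites: float = 0.3
    footprint_depth: float = 0.8
    peak_height: float = 2.0
    background_rate: float = 0.2
    regulator_effect: float = 2.0
    regulator_direction: str = "activated"   # or "repressed"
    n_targets: int = 20
    n_replicates: int = 4
    expression_sigma: float = 0.5            # replicate noise, log2 units
    plaque_concordance: float = 0.7          # rank concordance of 2nd signature
    n_haplotypes: int = 500
    n_variants: int = 2000
    ld_block_size: int = 10                  # variants per LD block
    n_causal_loci: int = 3
    causal_in_dbs: bool = True
    mutation_rate: float = 0.02              # haplotype copy error per allele

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "n_genes", "n_tfs",
                     "sites_per_tf", "site_width", "n_replicates",
                     "n_haplotypes", "n_variants", "ld_block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_altered_sites", "footprint_depth"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("peak_height", "background_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.regulator_direction not in ("activated", "repressed"):
            raise ValueError("regulator_direction must be activated|repressed")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}

    @property
    def tf_names(self) -> list[str]:
        return [f"TF{i + 1}" for i in range(self.n_tfs)]

    @property
    def planted_regulator(self) -> str:
        return self.tf_names[0]


@dataclass
class Annotation:
    genes: list[GeneModel]
    sites: dict[str, list[GenomicInterval]]
    altered_sites: list[GenomicInterval]
    target_genes: list[str]


# ---------------------------------------------------------------------------
# genome sequence
# ---------------------------------------------------------------------------

def simulate_sequences(cfg: SimulationConfig) -> dict[str, np.ndarray]:
    """Uniform-random base codes (0..3 = A,C,G,T) per chromosome."""
    rng = _rng(cfg.seed, _STAGE_SEQ)
    return {c: rng.integers(0, 4, cfg.chrom_length).astype(np.uint8)
            for c in cfg.chrom_names}


def dinuc_bias_per_base(seq_codes: np.ndarray,
                        bias_table: np.ndarray = DINUC_BIAS) -> np.ndarray:
    """Bias multiplier at each position from the dinucleotide starting there.

    The final base has no complete dinucleotide and gets multiplier 1.
    """
    out = np.ones(len(seq_codes), dtype=float)
    if len(seq_codes) >= 2:
        idx = 4 * seq_codes[:-1].astype(int) + seq_codes[1:].astype(int)
        out[:-1] = bias_table[idx]
    return out


def write_fasta(sequences: dict[str, np.ndarray], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, codes in sequences.items():
            fh.write(f">{chrom}\n")
            s = "".join(BASES[codes])
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# annotation: genes + binding sites
# ---------------------------------------------------------------------------

def _place_nonoverlapping(rng: np.random.Generator, n: int, width: int,
                          chrom_sizes: dict[str, int],
                          existing: dict[str, list[tuple[int, int]]],
                          max_tries: int = 200) -> list[GenomicInterval]:
    """Uniformly place ``n`` width-bp intervals avoiding overlap with
    ``existing`` spans (per chromosome) and with each other."""
    chroms = list(chrom_sizes)
    placed: list[GenomicInterval] = []
    spans = {c: sorted(existing.get(c, [])) for c in chroms}
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries * n:
            raise ValueError(
                "genome too small to place binding sites without overlap"
            )
        chrom = chroms[int(rng.integers(len(chroms)))]
        # keep sites clear of chromosome ends so flank windows and pads fit
        margin = min(600, max(0, (chrom_sizes[chrom] - width) // 10))
        if chrom_sizes[chrom] - width - margin <= margin:
            margin = 0
        start = int(rng.integers(margin, chrom_sizes[chrom] - width - margin))
        end = start + width
        if any(s < end and start < e for s, e in spans[chrom]):
            continue
        spans[chrom].append((start, end))
        placed.append(GenomicInterval(chrom, start, end))
    return placed


def simulate_annotation(cfg: SimulationConfig) -> Annotation:
    """Place genes and per-TF binding-site sets.

    The first TF is the planted regulator: a fraction ``frac_altered_sites``
    of its sites are "altered" (condition-specific binding) and clustered
    within a few kb of designated target genes (always within 50 kb).
    """
    rng = _rng(cfg.seed, _STAGE_ANNOT)
    sizes = cfg.chrom_sizes

    # genes: uniform bodies of 5-30 kb
    genes: list[GeneModel] = []
    for i in range(cfg.n_genes):
        chrom = cfg.chrom_names[int(rng.integers(cfg.n_chroms))]
        max_len = max(2, min(30_000, sizes[chrom] // 4))
        min_len = min(5_000, max(1, max_len - 1))
        length = int(rng.integers(min_len, max_len))
        margin = min(60_000, max(0, (sizes[chrom] - length) // 4))
        start = int(rng.integers(margin, sizes[chrom] - length - margin))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i + 1:04d}", chrom, start, start + length, strand))

    target_ids = sorted(
        rng.choice([g.gene_id for g in genes], size=cfg.n_targets, replace=False)
    )
    targets = {g.gene_id: g for g in genes if g.gene_id in set(target_ids)}

    sites: dict[str, list[GenomicInterval]] = {}
    altered: list[GenomicInterval] = []
    for ti, tf in enumerate(cfg.tf_names):
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.chrom_names}
        tf_sites: list[GenomicInterval] = []
        if ti == 0 and cfg.frac_altered_sites > 0:
            n_alt = int(round(cfg.frac_altered_sites * cfg.sites_per_tf))
            for j in range(n_alt):
                tgt = targets[target_ids[j % len(target_ids)]]
                for _ in range(200):
                    offset = int(rng.integers(500, 3_000))
                    sign = -1 if rng.random() < 0.5 else 1
                    start = tgt.tss + sign * offset
                    end = start + cfg.site_width
                    if start < 0 or end > sizes[tgt.chrom]:
                        continue
                    if any(s < end and start < e for s, e in occupied[tgt.chrom]):
                        continue
                    break
                else:
                    raise ValueError("could not place altered site near target")
                occupied[tgt.chrom].append((start, end))
                iv = GenomicInterval(tgt.chrom, start, end,
                                     name=f"{tf}_alt{j + 1:03d}")
                tf_sites.append(iv)
                altered.append(iv)
        n_rest = cfg.sites_per_tf - len(tf_sites)
        rest = _place_nonoverlapping(rng, n_rest, cfg.site_width, sizes, occupied)
        tf_sites.extend(
            GenomicInterval(iv.chrom, iv.start, iv.end,
                            name=f"{tf}_s{k + 1:03d}")
            for k, iv in enumerate(rest)
        )
        sites[tf] = sorted(tf_sites)
    altered = sorted(altered)
    return Annotation(genes, sites, altered, list(target_ids))


# ---------------------------------------------------------------------------
# cut-count tracks
# ---------------------------------------------------------------------------

def simulate_cut_tracks(
    cfg: SimulationConfig,
    annotation: Annotation,
    sequences: dict[str, np.ndarray] | None = None,
) -> dict[tuple[str, int], SignalTrack]:
    """Poisson per-base cut counts for each (condition, replicate).

    Rates: ``background_rate`` genome-wide, raised to ``peak_height`` within
    +/- ``peak_halfwidth`` of every site center; multiplied by
    ``1 - footprint_depth`` inside every bound motif span; altered sites of
    the planted regulator are bound in one condition only ("treated" when
    the regulator is activated, "control" when repressed).  A fixed
    dinucleotide bias multiplier modulates every base.
    """
    if sequences is None:
        sequences = simulate_sequences(cfg)
    rng = _rng(cfg.seed, _STAGE_TRACKS)
    sizes = cfg.chrom_sizes
    altered = {(iv.chrom, iv.start, iv.end) for iv in annotation.altered_sites}

    bias = {c: dinuc_bias_per_base(sequences[c]) for c in cfg.chrom_names}

    base = {c: np.full(sizes[c], cfg.background_rate, dtype=float)
            for c in cfg.chrom_names}
    for tf_sites in annotation.sites.values():
        for iv in tf_sites:
            center = (iv.start + iv.end) // 2
            lo = max(0, center - cfg.peak_halfwidth)
            hi = min(sizes[iv.chrom], center + cfg.peak_halfwidth)
            base[iv.chrom][lo:hi] = cfg.peak_height

    rates: dict[str, dict[str, np.ndarray]] = {}
    for cond in ("treated", "control"):
        r = {c: base[c].copy() for c in cfg.chrom_names}
        bound_cond = "treated" if cfg.regulator_direction == "activated" else "control"
        for tf_sites in annotation.sites.values():
            for iv in tf_sites:
                is_alt = (iv.chrom, iv.start, iv.end) in altered
                if is_alt and cond != bound_cond:
                    continue  # unbound in this condition: no footprint
                r[iv.chrom][iv.start:iv.end] *= (1.0 - cfg.footprint_depth)
        for c in cfg.chrom_names:
            r[c] *= bias[c]
        rates[cond] = r

    tracks: dict[tuple[str, int], SignalTrack] = {}
    for cond in ("treated", "control"):
        for rep in range(1, cfg.n_replicates + 1):
            data = {c: rng.poisson(rates[cond][c]).astype(float)
                    for c in cfg.chrom_names}
            tracks[(cond, rep)] = SignalTrack(data, condition=cond)
    return tracks


def pool_tracks(tracks: dict[tuple[str, int], SignalTrack],
                condition: str) -> SignalTrack:
    """Sum replicate tracks of one condition into a consensus track."""
    reps = [t for (cond, _), t in sorted(tracks.items()) if cond == condition]
    if not reps:
        raise ValueError(f"no tracks for condition {condition!r}")
    out = reps[0].copy()
    for t in reps[1:]:
        out = out + t
    out.condition = condition
    return out


# ---------------------------------------------------------------------------
# expression + differential expression
# ---------------------------------------------------------------------------

def simulate_expression_de(
    cfg: SimulationConfig, annotation: Annotation
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate expression and two DE tables.

    Returns ``(expression, de_treated, de_plaque)``: a gene-level mean
    expression table, the stimulated-vs-control DE table (gene, logFC, p,
    fdr from a per-gene two-sample t-test on ``n_replicates`` simulated
    log2 replicate values per condition), and a second "plaque-like" DE
    table whose signed-significance scores correlate with the first at
    ``plaque_concordance``.
    """
    if cfg.n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = _rng(cfg.seed, _STAGE_EXPR)
    gene_ids = [g.gene_id for g in annotation.genes]
    n = len(gene_ids)
    targets = set(annotation.target_genes)

    mu = rng.normal(5.0, 2.0, n)                       # baseline log2 mean
    effect = np.array([
        cfg.regulator_effect if g in targets else 0.0 for g in gene_ids
    ])
    if cfg.regulator_direction == "repressed":
        effect = -effect

    reps_c = rng.normal(mu[:, None], cfg.expression_sigma, (n, cfg.n_replicates))
    reps_t = rng.normal((mu + effect)[:, None], cfg.expression_sigma,
                        (n, cfg.n_replicates))
    logfc = reps_t.mean(axis=1) - reps_c.mean(axis=1)
    tres = stats.ttest_ind(reps_t, reps_c, axis=1)
    p = np.clip(tres.pvalue, 1e-300, 1.0)

    from statsmodels.stats.multitest import multipletests
    fdr = multipletests(p, method="fdr_bh")[1]

    expression = pd.DataFrame({
        "gene_id": gene_ids,
        "expression": np.power(2.0, mu),
    })
    de_treated = pd.DataFrame({
        "gene_id": gene_ids, "logFC": logfc, "p": p, "fdr": fdr,
    })

    # plaque-like signature: signed score correlated with the first at rho
    rho = cfg.plaque_concordance
    score_a = np.sign(logfc) * (-np.log10(p))
    noise = rng.normal(0.0, score_a.std() if score_a.std() > 0 else 1.0, n)
    score_b = rho * score_a + np.sqrt(max(0.0, 1.0 - rho ** 2)) * noise
    p_b = np.clip(np.power(10.0, -np.abs(score_b)), 1e-300, 1.0)
    de_plaque = pd.DataFrame({
        "gene_id": gene_ids,
        "logFC": np.sign(score_b),
        "p": p_b,
    })
    return expression, de_treated, de_plaque


def genes_with_expression(annotation: Annotation,
                          expression: pd.DataFrame) -> list[GeneModel]:
    expr = dict(zip(expression["gene_id"], expression["expression"]))
    return [
        GeneModel(g.gene_id, g.chrom, g.start, g.end, g.strand,
                  expression=float(expr[g.gene_id]))
        for g in annotation.genes
    ]


# ---------------------------------------------------------------------------
# haplotypes + GWAS summary statistics
# ---------------------------------------------------------------------------

@dataclass
class GwasSimulation:
    panel: np.ndarray            # (n_haplotypes, n_variants) int8
    variants: pd.DataFrame       # rsid, chrom, pos (1-based), ref, alt, p, beta, maf
    causal: pd.DataFrame         # rsid, chrom, pos, dbs_chrom, dbs_start, dbs_end


def simulate_haplotypes_gwas(
    cfg: SimulationConfig, dbs: list[GenomicInterval]
) -> GwasSimulation:
    """Binary haplotype panel with block LD plus a GWAS summary table.

    Haplotypes are built per LD block by copying one of two complementary
    founder patterns with a small per-allele mutation rate, giving high
    within-block r^2, near-zero cross-block r^2 and MAF near 0.5 for every
    variant.  One causal variant per locus is moved into a distinct dynamic
    binding site (when ``causal_in_dbs``), given genome-wide-significant p,
    and its block-mates receive r^2-graded p-values.  An exact-copy proxy
    (r^2 = 1) is planted next to each causal variant.
    """
    if cfg.causal_in_dbs and not dbs:
        raise ValueError("causal_in_dbs=True but no dynamic binding sites given")
    rng = _rng(cfg.seed, _STAGE_GWAS)
    sizes = cfg.chrom_sizes

    # variant positions, sorted within chromosome
    chrom_of = rng.integers(0, cfg.n_chroms, cfg.n_variants)
    positions = np.empty(cfg.n_variants, dtype=int)
    chroms = np.empty(cfg.n_variants, dtype=object)
    idx0 = 0
    order: list[int] = []
    for ci, chrom in enumerate(cfg.chrom_names):
        k = int((chrom_of == ci).sum())
        pos = np.sort(rng.choice(sizes[chrom], size=k, replace=False))
        positions[idx0:idx0 + k] = pos
        chroms[idx0:idx0 + k] = chrom
        order.extend(range(idx0, idx0 + k))
        idx0 += k

    # LD blocks: consecutive runs of ld_block_size variants within a chromosome
    block_id = np.empty(cfg.n_variants, dtype=int)
    b = 0
    start = 0
    for chrom in cfg.chrom_names:
        members = np.flatnonzero(chroms == chrom)
        for j in range(0, len(members), cfg.ld_block_size):
            block_id[members[j:j + cfg.ld_block_size]] = b
            b += 1
    n_blocks = b

    panel = np.empty((cfg.n_haplotypes, cfg.n_variants), dtype=np.int8)
    for blk in range(n_blocks):
        cols = np.flatnonzero(block_id == blk)
        founder = rng.integers(0, 2, len(cols))
        choice = rng.integers(0, 2, (cfg.n_haplotypes, 1))
        flips = (rng.random((cfg.n_haplotypes, len(cols))) < cfg.mutation_rate)
        panel[:, cols] = (founder[None, :] ^ (1 - choice) ^ flips).astype(np.int8)

    # causal loci: one block per locus, causal variant repositioned into a DBS
    causal_rows = []
    neglog_p = rng.uniform(0.0, 4.0, cfg.n_variants)     # null: p in [1e-4, 1]
    beta = rng.normal(0.0, 0.01, cfg.n_variants)
    if cfg.n_causal_loci > 0:
        if cfg.n_causal_loci > len(dbs):
            raise ValueError("not enough dynamic binding sites for causal loci")
        chosen_dbs = [dbs[i] for i in
                      rng.choice(len(dbs), cfg.n_causal_loci, replace=False)]
        used_blocks: set[int] = set()
        for site in chosen_dbs:
            candidates = np.flatnonzero(
                (chroms == site.chrom)
                & ~np.isin(block_id, list(used_blocks))
            )
            if len(candidates) == 0:
                raise ValueError(f"no variants available on {site.chrom}")
            blk = int(block_id[candidates[int(rng.integers(len(candidates)))]])
            used_blocks.add(blk)
            cols = np.flatnonzero(block_id == blk)
            causal = int(cols[len(cols) // 2])
            positions[causal] = (site.start + site.end) // 2
            # exact-copy proxy in the same block
            proxy = int(cols[0]) if cols[0] != causal else int(cols[-1])
            panel[:, proxy] = panel[:, causal]
            e0 = float(rng.uniform(9.0, 14.0))
            neglog_p[causal] = e0
            b_causal = float(rng.normal(0.0402, 0.005)) * (1 if rng.random() < 0.5 else -1)
            beta[causal] = b_causal
            for j in cols:
                if j == causal:
                    continue
                r2 = _column_r2(panel, causal, int(j))
                neglog_p[j] = max(0.0, r2 * e0 + float(rng.normal(0.0, 0.5)))
                beta[j] = r2 * b_causal + float(rng.normal(0.0, 0.005))
            causal_rows.append({
                "rsid": f"rs{causal + 1}", "chrom": site.chrom,
                "pos": int(positions[causal]) + 1,
                "dbs_chrom": site.chrom, "dbs_start": site.start,
                "dbs_end": site.end,
            })

    freq = panel.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    if (maf <= 0.01).any():
        raise AssertionError("construction should guarantee MAF > 1%")

    ref_idx = rng.integers(0, 4, cfg.n_variants)
    alt_idx = (ref_idx + rng.integers(1, 4, cfg.n_variants)) % 4
    variants = pd.DataFrame({
        "rsid": [f"rs{i + 1}" for i in range(cfg.n_variants)],
        "chrom": chroms,
        "pos": positions + 1,                            # 1-based for tables
        "ref": BASES[ref_idx],
        "alt": BASES[alt_idx],
        "p": np.clip(np.power(10.0, -neglog_p), 1e-300, 1.0),
        "beta": beta,
        "maf": maf,
    })
    causal_df = pd.DataFrame(
        causal_rows,
        columns=["rsid", "chrom", "pos", "dbs_chrom", "dbs_start", "dbs_end"],
    )
    return GwasSimulation(panel, variants, causal_df)


def _column_r2(panel: np.ndarray, i: int, j: int) -> float:
    x, y = panel[:, i].astype(float), panel[:, j].astype(float)
    pa, pb = x.mean(), y.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return 0.0
    pab = (x * y).mean()
    return float((pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb)))


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """A complete simulated study, ready for every downstream stage."""

    config: SimulationConfig
    annotation: Annotation
    sequences: dict[str, np.ndarray]
    tracks: dict[tuple[str, int], SignalTrack]
    expression: pd.DataFrame
    de_treated: pd.DataFrame
    de_plaque: pd.DataFrame
    gwas: GwasSimulation

    @property
    def genes(self) -> list[GeneModel]:
        return genes_with_expression(self.annotation, self.expression)


def simulate_dataset(cfg: SimulationConfig) -> Dataset:
    """Run every generator stage in order and bundle the results."""
    annotation = simulate_annotation(cfg)
    sequences = simulate_sequences(cfg)
    tracks = simulate_cut_tracks(cfg, annotation, sequences)
    expression, de_treated, de_plaque = simulate_expression_de(cfg, annotation)
    gwas = simulate_haplotypes_gwas(cfg, annotation.altered_sites)
    return Dataset(cfg, annotation, sequences, tracks,
                   expression, de_treated, de_plaque, gwas)


def write_dataset(ds: Dataset, outdir: str | Path) -> None:
    """Write the dataset in the pipeline's interchange formats, including
    planted-truth sidecar files for recovery tests."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = ds.config

    write_chrom_sizes(cfg.chrom_sizes, out / "chrom.sizes")
    write_fasta(ds.sequences, out / "genome.fa")
    pd.DataFrame({
        "kmer": ["".join(p) for p in
                 (BASES[i // 4] + BASES[i % 4] for i in range(16))],
        "rate": DINUC_BIAS,
    }).to_csv(out / "bias_kmer.tsv", sep="\t", index=False)

    write_genes(ds.genes, out / "genes.tsv")
    ds.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    ds.de_treated.to_csv(out / "de_treated.tsv", sep="\t", index=False)
    ds.de_plaque.to_csv(out / "de_plaque.tsv", sep="\t", index=False)
    for tf, sites in ds.annotation.sites.items():
        write_bed(sites, out / f"sites_{tf}.bed")
    for (cond, rep), track in ds.tracks.items():
        write_bedgraph(track, out / f"cuts_{cond}_{rep}.bedgraph")

    pd.DataFrame(ds.gwas.panel).to_csv(
        out / "haplotypes.tsv", sep="\t", index=False,
        header=list(ds.gwas.variants["rsid"]),
    )
    ds.gwas.variants.to_csv(out / "gwas.tsv", sep="\t", index=False)

    write_bed(ds.annotation.altered_sites, out / "truth_altered_sites.bed")
    pd.DataFrame({"gene_id": ds.annotation.target_genes}).to_csv(
        out / "truth_target_genes.tsv", sep="\t", index=False)
    ds.gwas.causal.to_csv(out / "truth_causal_variants.tsv", sep="\t", index=False)
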