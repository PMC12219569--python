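"""End-to-end drivers tying the stages together on a simulated study.

These are the same call sequences a user would run on real data exported as
bedGraph/BED/TSV; on a synthetic dataset they additionally score recovery
of the planted truth (altered sites, target genes, causal variants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import footprint as fp
from . import regpot as rp
from . import rrho as rr
from . import variants as vr
from .io import GenomicInterval, SignalTrack
from .simulate import BASES, DINUC_BIAS, Dataset, pool_tracks


def dinuc_rates() -> dict[str, float]:
    """The generator's true dinucleotide cut-rate table as a k-mer mapping."""
    return {BASES[i] + BASES[j]: float(DINUC_BIAS[4 * i + j])
            for i in range(4) for j in range(4)}


def de_gene_set(de_table: pd.DataFrame, fdr: float = 0.05) -> set[str]:
    """Differentially expressed genes at a B-H FDR threshold."""
    col = "fdr" if "fdr" in de_table.columns else "p"
    return set(de_table.loc[de_table[col] < fdr, "gene_id"])


def corrected_condition_tracks(ds: Dataset) -> tuple[SignalTrack, SignalTrack]:
    """Replicate-pooled, depth-normalized, bias-corrected tracks."""
    rates = dinuc_rates()
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        treated = fp.correct_bias(
            pool_tracks(ds.tracks, "treated").to_cpm(), ds.sequences, rates)
        control = fp.correct_bias(
            pool_tracks(ds.tracks, "control").to_cpm(), ds.sequences, rates)
    return treated, control


def consensus_track(ds: Dataset) -> SignalTrack:
    """All replicates of both conditions pooled and depth-normalized, the
    open-chromatin profile used for regulatory potentials."""
    merged = pool_tracks(ds.tracks, "treated") + pool_tracks(ds.tracks, "control")
    merged.condition = "consensus"
    return merged.to_cpm()


@dataclass
class StudyResults:
    ranking: pd.DataFrame                 # TF ISD ranking
    targeted: rp.EmpiricalNullResult      # targeted ISD of altered sites
    dbs: list[fp.DBSRecord]               # called dynamic binding sites
    dbs_sensitivity: float
    dbs_fdr: float
    tf_diff: pd.DataFrame
    variant_table: pd.DataFrame           # prioritized variants (called DBSs)
    causal_recovered: float               # fraction of planted causal loci
    rrho_max: float                       # peak -log10 FDR of the RRHO map
    fisher: tuple[float, float]           # (odds ratio, p) of DE-set overlap


def run_study(ds: Dataset, n_null: int = 1000, n_perm: int = 500,
              n_background: int = 150, seed: int = 0) -> StudyResults:
    """Run every analysis stage on a simulated dataset and score recovery."""
    genes = ds.genes
    gene_ids = [g.gene_id for g in genes]
    de_genes = de_gene_set(ds.de_treated)
    expression = pd.Series({g.gene_id: g.expression for g in genes})

    consensus = consensus_track(ds)
    delta = {tf: rp.isd_delta_rp(consensus, sites, genes)
             for tf, sites in ds.annotation.sites.items()}
    ranking = rp.rank_regulators(delta, de_genes, gene_ids,
                                 n_background=n_background, seed=seed)
    targeted = rp.targeted_isd(consensus, ds.annotation.altered_sites, genes,
                               de_genes, expression, n_null=n_null, seed=seed)

    treated, control = corrected_condition_tracks(ds)
    dbs: list[fp.DBSRecord] = []
    for tf, sites in ds.annotation.sites.items():
        dbs.extend(fp.call_dbs(sites, treated, control, tf=tf))
    truth = {(iv.chrom, iv.start, iv.end) for iv in ds.annotation.altered_sites}
    called = {(r.interval.chrom, r.interval.start, r.interval.end) for r in dbs}
    tp = len(called & truth)
    sensitivity = tp / len(truth) if truth else float("nan")
    fdr = (len(called) - tp) / len(called) if called else 0.0
    tf_diff = fp.tf_differential(ds.annotation.sites, treated, control,
                                 n_perm=n_perm, seed=seed)

    panel = vr.HaplotypePanel(ds.gwas.panel, list(ds.gwas.variants["rsid"]))
    significant = vr.filter_variants(ds.gwas.variants)
    index = vr.ld_prune(significant, panel)
    pools = vr.ld_pool(index, ds.gwas.variants, panel)
    table = vr.overlap_dbs_variants(
        pools, [r.interval for r in dbs], genes,
        chrom_sizes=ds.config.chrom_sizes,
    )
    causal = ds.gwas.causal
    recovered = (
        float(causal["rsid"].isin(set(table["rsid"])).mean())
        if len(causal) else float("nan")
    )

    list_a = rr.rank_genes(ds.de_treated[["gene_id", "logFC", "p"]])
    list_b = rr.rank_genes(ds.de_plaque)
    rrho_max = float(rr.rrho_map(list_a, list_b).matrix.max())
    plaque_de = de_gene_set(ds.de_plaque, fdr=0.05)
    fisher = rr.fisher_overlap(de_genes, plaque_de, set(gene_ids))

    return StudyResults(ranking, targeted, dbs, sensitivity, fdr, tf_diff,
                        table, recovered, rrho_max, fisher)
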