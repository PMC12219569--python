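"""Bias-corrected TF footprint scoring, dynamic-binding-site calling and
per-TF global differential binding.

A footprint score is the depletion of (bias-corrected, depth-normalized)
transposase cut signal inside a motif relative to its flanks: bound motifs
are protected, so a deep center with tall flanks scores high.  A dynamic
binding site (DBS) is a site whose score changes at least two-fold between
conditions (|log2 ratio| >= 1 on pseudocount-stabilized scores).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import GenomicInterval, SignalTrack


@dataclass(frozen=True)
class FootprintParams:
    flank_width: int = 30          # bp each side of the motif
    epsilon: float = 0.01          # pseudocount for fold changes
    kmer_k: int = 2                # bias-model order
    fold_threshold: float = 1.0    # |log2 ratio| for a DBS ("two-fold")
    tf_delta_threshold: float = 0.1   # |Δscore| for per-TF significance
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.flank_width <= 0:
            raise ValueError("flank_width must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.fold_threshold <= 0:
            raise ValueError("fold_threshold must be > 0")


def correct_bias(track: SignalTrack, sequences: dict[str, np.ndarray],
                 kmer_rates: dict[str, float],
                 params: FootprintParams = FootprintParams()) -> SignalTrack:
    """Divide the signal by the expected relative cut rate of the k-mer at
    each position, then renormalize to the original library size.

    ``sequences`` holds per-chromosome base codes (0..3 = A,C,G,T);
    ``kmer_rates`` maps k-mer strings to relative rates (the synthetic
    generator records its true bias table).  K-mers absent from the table
    (or truncated at the chromosome end) get rate 1.0; their occurrences
    are counted and reported in a single warning.
    """
    k = params.kmer_k
    bases = np.array(list("ACGT"))
    # dense lookup over all 4^k k-mers
    lut = np.ones(4 ** k, dtype=float)
    seen = np.zeros(4 ** k, dtype=bool)
    for idx in range(4 ** k):
        digits = [(idx // 4 ** (k - 1 - j)) % 4 for j in range(k)]
        kmer = "".join(bases[digits])
        if kmer in kmer_rates:
            lut[idx] = float(kmer_rates[kmer])
            seen[idx] = True

    original = track.library_size
    out = {}
    n_unseen = 0
    for chrom, arr in track.data.items():
        codes = sequences[chrom].astype(np.int64)
        if len(codes) != len(arr):
            raise ValueError(f"sequence length mismatch on {chrom}")
        idx = np.zeros(max(0, len(codes) - k + 1), dtype=np.int64)
        for j in range(k):
            idx = idx * 4 + codes[j: len(codes) - k + 1 + j]
        rates = np.ones(len(arr), dtype=float)
        rates[: len(idx)] = lut[idx]
        n_unseen += int((~seen[idx]).sum()) + (len(arr) - len(idx))
        out[chrom] = arr / rates
    if n_unseen:
        warnings.warn(
            f"{n_unseen} positions with k-mers absent from the bias table "
            "were left uncorrected (rate 1.0)",
            stacklevel=2,
        )
    corrected = SignalTrack(out, track.condition)
    if corrected.library_size > 0:
        corrected = corrected.scaled_to(original)
    return corrected


def footprint_score(track: SignalTrack, site: GenomicInterval,
                    params: FootprintParams = FootprintParams()) -> float:
    """Flank-minus-center depletion score for one site, clipped at 0."""
    arr = track.data.get(site.chrom)
    if arr is None:
        raise ValueError(f"chromosome {site.chrom} not in track")
    fw = params.flank_width
    if site.start - fw < 0 or site.end + fw > len(arr):
        raise ValueError(
            f"site {site.chrom}:{site.start}-{site.end} with {fw} bp flanks "
            "extends off the chromosome"
        )
    center = arr[site.start:site.end].mean()
    flank = np.concatenate(
        (arr[site.start - fw:site.start], arr[site.end:site.end + fw])
    ).mean()
    return max(0.0, float(flank - center))


def score_sites(track: SignalTrack, sites: list[GenomicInterval],
                params: FootprintParams = FootprintParams()) -> np.ndarray:
    return np.array([footprint_score(track, s, params) for s in sites])


@dataclass(frozen=True)
class DBSRecord:
    """A dynamic binding site: a motif occurrence whose footprint score
    changed at least two-fold between conditions."""

    interval: GenomicInterval
    tf: str
    log2_change: float
    direction: str   # "activated" (treated > control) or "repressed"


def call_dbs(sites: list[GenomicInterval], treated: SignalTrack,
             control: SignalTrack, tf: str = "",
             params: FootprintParams = FootprintParams()) -> list[DBSRecord]:
    """Call dynamic binding sites from two depth-normalized, bias-corrected
    tracks.  Per site, ``Δ = log2((score_t + ε) / (score_c + ε))``; the
    site is a DBS iff ``|Δ| >= fold_threshold``, activated when Δ > 0.
    """
    eps = params.epsilon
    st = score_sites(treated, sites, params)
    sc = score_sites(control, sites, params)
    delta = np.log2((st + eps) / (sc + eps))
    records = []
    for site, d in zip(sites, delta):
        if abs(d) >= params.fold_threshold:
            records.append(DBSRecord(
                interval=site, tf=tf or (site.name or ""),
                log2_change=float(d),
                direction="activated" if d > 0 else "repressed",
            ))
    return records


def dbs_to_dataframe(records: list[DBSRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.interval.chrom, r.interval.start, r.interval.end,
          r.interval.name or "", r.tf, r.log2_change, r.direction)
         for r in records],
        columns=["chrom", "start", "end", "site", "tf", "log2_change",
                 "direction"],
    )


def tf_differential(per_tf_sites: dict[str, list[GenomicInterval]],
                    treated: SignalTrack, control: SignalTrack,
                    params: FootprintParams = FootprintParams(),
                    n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-TF global differential binding between two conditions.

    Footprint scores of all sites of all TFs are min-max scaled to [0, 1]
    per condition; ``Δscore`` for a TF is the mean scaled-score change over
    its sites.  Significance comes from ``n_perm`` size-matched random site
    draws from the pooled site universe (two-sided), with B-H FDR across
    TFs; a TF is flagged significant when FDR and |Δscore| pass the
    thresholds.
    """
    tfs = [tf for tf, s in per_tf_sites.items() if s]
    for tf, s in per_tf_sites.items():
        if not s:
            warnings.warn(f"TF {tf} has no sites and is excluded", stacklevel=2)
    if len(tfs) < 2:
        raise ValueError("need >= 2 TFs with sites for a pooled background")

    all_sites: list[GenomicInterval] = []
    owner: list[str] = []
    for tf in tfs:
        all_sites.extend(per_tf_sites[tf])
        owner.extend([tf] * len(per_tf_sites[tf]))

    st = score_sites(treated, all_sites, params)
    sc = score_sites(control, all_sites, params)

    # One [0, 1] scale shared by both conditions: scaling each condition by
    # its own extremes would let differential sites shift that condition's
    # min/max and leak a spurious global offset into every unchanged site.
    lo = min(st.min(), sc.min())
    hi = max(st.max(), sc.max())
    if hi == lo:
        diff = np.zeros_like(st)
    else:
        diff = (st - sc) / (hi - lo)
    owner_arr = np.array(owner)
    rng = np.random.default_rng(seed)

    rows = []
    for tf in tfs:
        mask = owner_arr == tf
        n_sites = int(mask.sum())
        d_obs = float(diff[mask].mean())
        perm = np.empty(n_perm)
        for i in range(n_perm):
            draw = rng.choice(len(diff), size=n_sites, replace=False)
            perm[i] = diff[draw].mean()
        p = (1 + int((np.abs(perm) >= abs(d_obs)).sum())) / (n_perm + 1)
        rows.append({"tf": tf, "delta_score": d_obs, "p": p,
                     "n_sites": n_sites})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = (
        (out["fdr"] < params.fdr_threshold)
        & (out["delta_score"].abs() > params.tf_delta_threshold)
    )
    return out.sort_values(["p", "tf"]).reset_index(drop=True)
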