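"""Readers, writers and interval algebra for the genomic formats the pipeline touches.

All coordinates are 0-based half-open internally.  Variant tables print
1-based positions (the convention of GWAS summary statistics); they are
converted on ingest and converted back for reports.  Chromosome names are
matched by exact string equality — no "chr" aliasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains_point(self, pos: int) -> bool:
        """True if 0-based position ``pos`` lies inside [start, end)."""
        return self.start <= pos < self.end


@dataclass
class SignalTrack:
    """Per-base cut-count signal over a genome, one array per chromosome.

    ``data`` maps chromosome name to a float array of non-negative per-base
    values; ``condition`` is a free-form label (e.g. "treated").
    """

    data: dict[str, np.ndarray]
    condition: str = ""

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"negative signal on {chrom}")
            self.data[chrom] = arr

    @property
    def library_size(self) -> float:
        """Total cut count summed over all chromosomes."""
        return float(sum(arr.sum() for arr in self.data.values()))

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.data.items()}

    def copy(self) -> "SignalTrack":
        return SignalTrack({c: a.copy() for c, a in self.data.items()}, self.condition)

    def to_cpm(self) -> "SignalTrack":
        """Depth-normalize to counts per million cut sites."""
        total = self.library_size
        if total == 0:
            return self.copy()
        factor = 1e6 / total
        return SignalTrack(
            {c: a * factor for c, a in self.data.items()}, self.condition
        )

    def scaled_to(self, target_library_size: float) -> "SignalTrack":
        total = self.library_size
        if total == 0:
            return self.copy()
        f = target_library_size / total
        return SignalTrack({c: a * f for c, a in self.data.items()}, self.condition)

    def __add__(self, other: "SignalTrack") -> "SignalTrack":
        if set(self.data) != set(other.data):
            raise ValueError("chromosome sets differ")
        return SignalTrack(
            {c: self.data[c] + other.data[c] for c in self.data}, self.condition
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with its body span, TSS anchor and mean normalized expression."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    expression: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene span for {self.gene_id}")
        if self.expression < 0:
            raise ValueError("expression must be >= 0")

    @property
    def tss(self) -> int:
        """0-based transcription start site (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.gene_id)


# ---------------------------------------------------------------------------
# BED / bedGraph / chrom.sizes
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into a list of intervals, order preserved.

    Raises ValueError naming the offending line for malformed records or
    start >= end.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, score))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED3 or BED6 (6 columns whenever a name or score is present)."""
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.name is None and iv.score is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = iv.name if iv.name is not None else "."
                score = f"{iv.score:g}" if iv.score is not None else "0"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bedgraph(path: str | Path, chrom_sizes: Mapping[str, int],
                  condition: str = "") -> SignalTrack:
    """Expand a 4-column bedGraph into per-base arrays.

    Unspecified bases are 0.  Overlapping records, negative values and
    records extending beyond the chromosome size are errors.
    """
    arrays = {c: np.zeros(int(n), dtype=float) for c, n in chrom_sizes.items()}
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    if (df["value"] < 0).any():
        bad = df[df["value"] < 0].iloc[0]
        raise ValueError(
            f"negative value {bad.value} at {bad.chrom}:{bad.start}-{bad.end}"
        )
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in arrays:
            raise ValueError(f"chromosome {chrom!r} not in chrom_sizes")
        size = len(arrays[chrom])
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if ((starts < 0) | (starts >= ends) | (ends > size)).any():
            raise ValueError(
                f"record outside chromosome {chrom} of size {size} "
                "(or start >= end)"
            )
        order = np.argsort(starts, kind="stable")
        if (starts[order][1:] < ends[order][:-1]).any():
            raise ValueError(f"overlapping bedGraph records on {chrom}")
        # piecewise-constant expansion via a difference array
        diff = np.zeros(size + 1)
        np.add.at(diff, starts, sub["value"].to_numpy())
        np.add.at(diff, ends, -sub["value"].to_numpy())
        arrays[chrom] = diff[:-1].cumsum()
    return SignalTrack(arrays, condition)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write a track as run-length-compressed bedGraph (zero runs omitted)."""
    frames = []
    for chrom in track.data:
        arr = track.data[chrom]
        if arr.size == 0:
            continue
        # run boundaries where the value changes
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [arr.size]))
        values = arr[starts]
        keep = values != 0
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts[keep], "end": ends[keep],
            "value": values[keep],
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=["chrom", "start", "end", "value"]))
    df.to_csv(path, sep="\t", header=False, index=False,
              float_format="%g")


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------

def read_genes(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    genes = [
        GeneModel(
            gene_id=str(r.gene_id), chrom=str(r.chrom), start=int(r.start),
            end=int(r.end), strand=str(r.strand),
            expression=float(getattr(r, "expression", 0.0)),
        )
        for r in df.itertuples(index=False)
    ]
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in gene table")
    return genes


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end, g.strand, g.tss, g.expression)
         for g in genes],
        columns=["gene_id", "chrom", "start", "end", "strand", "tss", "expression"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def build_tree(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    """Index intervals per chromosome for overlap queries."""
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def overlap(query: GenomicInterval,
            subjects: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Subjects sharing >= 1 base with ``query`` (half-open semantics)."""
    trees = subjects if isinstance(subjects, dict) else build_tree(subjects)
    tree = trees.get(query.chrom)
    if tree is None:
        return []
    return sorted((hit.data for hit in tree.overlap(query.start, query.end)))


def extend_intervals(sites: Sequence[GenomicInterval], pad: int,
                     chrom_sizes: Mapping[str, int] | None = None,
                     ) -> list[GenomicInterval]:
    """Grow each interval by ``pad`` bp on both sides, clipping at 0 and at
    the chromosome end when sizes are supplied.  Names and scores carry over.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    out = []
    for iv in sites:
        start = max(0, iv.start - pad)
        end = iv.end + pad
        if chrom_sizes is not None and iv.chrom in chrom_sizes:
            end = min(end, chrom_sizes[iv.chrom])
        out.append(replace(iv, start=start, end=end))
    return out


def mask_track(track: SignalTrack,
               sites: Iterable[GenomicInterval]) -> SignalTrack:
    """Zero the signal at every base covered by any site; other bases unchanged."""
    out = track.copy()
    for iv in sites:
        arr = out.data.get(iv.chrom)
        if arr is None:
            continue
        arr[max(0, iv.start):min(len(arr), iv.end)] = 0.0
    return out
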