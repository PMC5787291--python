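"""Readers and writers for the genomic formats the pipeline touches.

All internal coordinates are 0-based half-open.  GFF3 (1-based closed) is
converted at the boundary; BED/bedGraph are native.  Strand-aware anchors:
the TSS of a plus-strand gene is ``start``, of a minus-strand gene ``end - 1``.
All readers are gzip-transparent (a ``.gz`` suffix is enough).
"""
from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

log = logging.getLogger("nucdyn")

GENE_CATEGORIES = ("PCG", "TE", "TEG", "PSG")

__all__ = [
    "GeneModel",
    "OccupancyTrack",
    "GenomeSequence",
    "Gff3ParseError",
    "read_gff3",
    "write_gff3",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
    "read_bed6",
    "write_bed6",
]


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: strand-aware TSS/TTS and exon structure.

    ``exons`` are 0-based half-open intervals, sorted, non-overlapping and
    contained in ``[start, end)``.  Introns are the gaps between exons.
    """

    gene_id: str
    seq_id: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    category: str = "PCG"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        prev = self.start
        for s, e in self.exons:
            if s < prev or e > self.end or s >= e:
                raise ValueError(
                    f"{self.gene_id}: exon ({s},{e}) outside gene or out of order"
                )
            prev = e
        if self.category not in GENE_CATEGORIES:
            log.warning("%s: unknown category %r, defaulting to PCG",
                        self.gene_id, self.category)
            object.__setattr__(self, "category", "PCG")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return tuple(out)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def oriented_offset(self, pos: int) -> int:
        """Transcript-oriented offset of a genomic position from the TSS
        (negative = upstream, positive = downstream)."""
        return pos - self.tss if self.strand == "+" else self.tss - pos


@dataclass
class OccupancyTrack:
    """Per-base non-negative occupancy signal over named sequences.

    ``library_scale`` is the factor by which raw per-base read counts were
    multiplied to reach the stored values (1.0 = raw count scale; an RPM
    track has scale 1e6 / mapped reads).
    """

    values: dict[str, np.ndarray]
    library_scale: float = 1.0

    def __post_init__(self):
        for name, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"{name}: track values must be 1-D")
            if np.any(arr < 0):
                raise ValueError(f"{name}: negative occupancy values")
            self.values[name] = arr
        if not np.isfinite(self.mean()):
            raise ValueError("track mean is not finite")

    def lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.values.items()}

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def mean(self) -> float:
        n = sum(len(v) for v in self.values.values())
        return self.total() / n if n else 0.0

    def to_rpm(self) -> "OccupancyTrack":
        """Return a copy normalised to reads-per-million (library scale folded in)."""
        raw_total = self.total() / self.library_scale
        if raw_total <= 0:
            raise ValueError("cannot normalise an empty track")
        scale = 1e6 / raw_total
        return OccupancyTrack(
            {k: v / self.library_scale * scale for k, v in self.values.items()},
            library_scale=scale,
        )


@dataclass
class GenomeSequence:
    """Uppercase nucleotide strings over {A,C,G,T,N} keyed by seq_id."""

    seqs: dict[str, str] = field(default_factory=dict)

    def lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.seqs.items()}

    def __getitem__(self, seq_id: str) -> str:
        return self.seqs[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.seqs


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

class Gff3ParseError(ValueError):
    """Malformed GFF3 input; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"GFF3 line {lineno}: {message}")
        self.lineno = lineno


def _gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff3(path, category_attribute: str = "category",
              default_category: str = "PCG") -> list[GeneModel]:
    """Parse gene/mRNA/exon features into one representative model per gene.

    The representative transcript is the longest mRNA (by span).  Coordinates
    are converted from 1-based closed to 0-based half-open.  A gene's category
    is read from ``category_attribute`` on the gene feature (default PCG).
    """
    genes: dict[str, dict] = {}
    mrnas: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise Gff3ParseError(lineno, f"expected 9 columns, got {len(fields)}")
            seq_id, _src, ftype, start_s, end_s, _score, strand, _phase, attrs_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise Gff3ParseError(lineno, f"non-integer coordinates {start_s!r}/{end_s!r}")
            if start1 < 1 or end1 < start1:
                raise Gff3ParseError(lineno, f"bad interval [{start1},{end1}]")
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _gff3_attributes(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise Gff3ParseError(lineno, "gene feature without ID")
                genes[gid] = dict(seq_id=seq_id, strand=strand, start=start, end=end,
                                  category=attrs.get(category_attribute, default_category))
                order.append(gid)
            elif ftype == "mRNA":
                mid = attrs.get("ID")
                parent = attrs.get("Parent")
                if mid is None or parent is None:
                    raise Gff3ParseError(lineno, "mRNA feature without ID/Parent")
                mrnas[mid] = dict(parent=parent, start=start, end=end, lineno=lineno)
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise Gff3ParseError(lineno, "exon feature without Parent")
                for p in parent.split(","):
                    exons.setdefault(p, []).append((start, end))

    out: list[GeneModel] = []
    for gid in order:
        g = genes[gid]
        children = [(mid, m) for mid, m in mrnas.items() if m["parent"] == gid]
        if children:
            # representative = longest mRNA; ties broken by ID for determinism
            mid, m = max(children, key=lambda km: (km[1]["end"] - km[1]["start"], km[0]))
            exon_list = sorted(exons.get(mid, [(m["start"], m["end"])]))
        else:
            exon_list = sorted(exons.get(gid, [(g["start"], g["end"])]))
        for s, e in exon_list:
            if s < g["start"] or e > g["end"]:
                raise ValueError(
                    f"{gid}: exon [{s},{e}) outside gene span "
                    f"[{g['start']},{g['end']})")
        out.append(GeneModel(gene_id=gid, seq_id=g["seq_id"], strand=g["strand"],
                             start=g["start"], end=g["end"], exons=tuple(exon_list),
                             category=g["category"]))
    return out


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Emit gene/mRNA/exon features (one mRNA per gene), 1-based closed."""
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            a = f"ID={g.gene_id};category={g.category}"
            fh.write(f"{g.seq_id}\t-\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{a}\n")
            mid = f"{g.gene_id}.1"
            fh.write(f"{g.seq_id}\t-\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={mid};Parent={g.gene_id}\n")
            for s, e in g.exons:
                fh.write(f"{g.seq_id}\t-\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                         f"Parent={mid}\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path, genome_lengths: Mapping[str, int]) -> OccupancyTrack:
    """Dense per-base track from a bedGraph file; uncovered bases are 0.

    Overlapping intervals and intervals beyond the sequence length are errors.
    """
    values = {name: np.zeros(length, dtype=float)
              for name, length in genome_lengths.items()}
    last_end: dict[str, list] = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"bedGraph line {lineno}: expected 4 columns")
            name, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if name not in values:
                raise ValueError(f"bedGraph line {lineno}: unknown sequence {name!r}")
            if e > len(values[name]) or s < 0 or s >= e:
                raise ValueError(
                    f"bedGraph line {lineno}: interval [{s},{e}) out of bounds "
                    f"for {name} (length {len(values[name])})")
            intervals = last_end.setdefault(name, [])
            intervals.append((s, e, lineno))
            values[name][s:e] = v
    # overlap check (after collection so unsorted input is allowed)
    for name, intervals in last_end.items():
        intervals.sort()
        for (s1, e1, _), (s2, _e2, ln2) in zip(intervals, intervals[1:]):
            if s2 < e1:
                raise ValueError(
                    f"bedGraph line {ln2}: interval overlaps a previous one on {name}")
    return OccupancyTrack(values)


def _format_value(v: float) -> str:
    if v == int(v):
        return str(int(v))
    return repr(float(v))


def write_bedgraph(track: OccupancyTrack, path) -> None:
    """Run-length-merged bedGraph; zero runs omitted; sorted, deterministic."""
    with _open(path, "wt") as fh:
        for name in sorted(track.values):
            arr = track.values[name]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                fh.write(f"{name}\t{s}\t{e}\t{_format_value(v)}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_VALID = set("ACGTN")


def read_fasta(path) -> GenomeSequence:
    """Uppercased sequences; letters outside {A,C,G,T,N} become N (warned)."""
    seqs: dict[str, str] = {}
    n_mapped = 0
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            s = str(rec.seq).upper()
            if not set(s) <= _VALID:
                cleaned = "".join(c if c in _VALID else "N" for c in s)
                n_mapped += sum(1 for a, b in zip(s, cleaned) if a != b)
                s = cleaned
            if not s:
                log.warning("FASTA record %s has an empty body", rec.id)
            seqs[rec.id] = s
    if n_mapped:
        log.warning("read_fasta: %d non-ACGTN letters mapped to N", n_mapped)
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path, width: int = 60) -> None:
    with _open(path, "wt") as fh:
        for name in genome.seqs:
            fh.write(f">{name}\n")
            s = genome.seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def read_bed6(path) -> list[tuple[str, int, int, str, float, str]]:
    out = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line {lineno}: expected >=3 columns")
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            out.append((parts[0], int(parts[1]), int(parts[2]), name, score, strand))
    return out


def write_bed6(records: Iterable[tuple], path) -> None:
    with _open(path, "wt") as fh:
        for seq_id, start, end, name, score, strand, *extra in records:
            cols = [seq_id, str(start), str(end), str(name),
                    _format_value(float(score)), strand, *map(str, extra)]
            fh.write("\t".join(cols) + "\n")
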