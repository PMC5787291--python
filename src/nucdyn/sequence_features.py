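"""GC-content profiling and IUPAC consensus scanning for promoter elements.

Built-in motifs: TATA box (CTATAWAWA), P1BS (GNATATNC, the PHR-family
binding site of phosphate-starvation-responsive promoters), G-box (CACGTG)
and Y-patch (CYTCYYCCYC).  Scans cover both strands by default (logged);
overlapping matches are all reported, and for self-reverse-complementary
consensi the duplicate hit on the opposite strand at the same center is
deduplicated to one.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .genomic_io import GeneModel, GenomeSequence

log = logging.getLogger("nucdyn")

__all__ = [
    "MotifDefinition",
    "MotifHit",
    "MOTIFS",
    "revcomp",
    "scan_motif",
    "gc_profile",
    "gc_window_content",
    "hits_near_anchor",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    consensus: str

    def __post_init__(self):
        if not self.consensus:
            raise ValueError("empty consensus")
        bad = set(self.consensus) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def is_self_revcomp(self) -> bool:
        return revcomp(self.consensus) == self.consensus

    def regex(self) -> str:
        return "".join(c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]"
                       for c in self.consensus)


MOTIFS = {
    "TATA": MotifDefinition("TATA", "CTATAWAWA"),
    "P1BS": MotifDefinition("P1BS", "GNATATNC"),
    "G-box": MotifDefinition("G-box", "CACGTG"),
    "Y-patch": MotifDefinition("Y-patch", "CYTCYYCCYC"),
}


@dataclass(frozen=True)
class MotifHit:
    motif: str
    seq_id: str
    start: int          # 0-based, forward-strand coordinates of the match span
    strand: str

    length: int = 0

    @property
    def center(self) -> int:
        # left-of-center base for even-length motifs
        return self.start + (self.length - 1) // 2

    @property
    def end(self) -> int:
        return self.start + self.length


def scan_motif(genome: GenomeSequence, motif: MotifDefinition,
               both_strands: bool = True) -> list[MotifHit]:
    """All (overlapping) consensus matches; positions in forward coordinates.

    A minus-strand hit means the reverse complement of the forward substring
    matches the consensus.  For self-reverse-complementary consensi the two
    strands produce identical spans; those duplicates are collapsed to the
    plus-strand hit.
    """
    if both_strands:
        log.debug("scan_motif %s: scanning both strands", motif.name)
    fwd = re.compile(f"(?=({motif.regex()}))")
    rev = re.compile(f"(?=({MotifDefinition(motif.name, revcomp(motif.consensus)).regex()}))")
    hits: list[MotifHit] = []
    m = len(motif)
    for seq_id in genome.seqs:
        s = genome.seqs[seq_id]
        plus_starts = set()
        for match in fwd.finditer(s):
            hits.append(MotifHit(motif.name, seq_id, match.start(), "+", m))
            plus_starts.add(match.start())
        if both_strands:
            for match in rev.finditer(s):
                if motif.is_self_revcomp and match.start() in plus_starts:
                    continue  # same span, same center: dedup
                hits.append(MotifHit(motif.name, seq_id, match.start(), "-", m))
    hits.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return hits


def _gc_arrays(genome: GenomeSequence, seq_id: str):
    s = np.frombuffer(genome.seqs[seq_id].encode(), dtype=np.uint8)
    gc = (s == ord("G")) | (s == ord("C"))
    valid = s != ord("N")
    return gc.astype(float), valid.astype(float)


def gc_profile(genome: GenomeSequence, anchors,
               window: tuple[int, int] = (1000, 1000), bin_size: int = 10):
    """Per-bin GC fraction among non-N bases, averaged over strand-oriented
    anchors.  Returns ``(bin_centers, fractions)``; all-N bins are excluded
    from the average.
    """
    from .metagene import _oriented_window  # shared windowing logic
    up, down = window
    if (up + down) % bin_size:
        raise ValueError("bin_size must divide the window length")
    n_bins = (up + down) // bin_size
    gc_sum = np.zeros(n_bins)
    n_sum = np.zeros(n_bins)
    cache = {}
    for anchor in anchors:
        if len(anchor) == 4:
            _, seq_id, pos, strand = anchor
        else:
            seq_id, pos, strand = anchor
        if seq_id not in genome.seqs:
            continue
        if seq_id not in cache:
            cache[seq_id] = _gc_arrays(genome, seq_id)
        gc, valid = cache[seq_id]
        w_gc = _oriented_window(gc * valid, int(pos), strand, window)
        w_valid = _oriented_window(valid, int(pos), strand, window)
        w_gc = np.nan_to_num(w_gc)
        w_valid = np.nan_to_num(w_valid)
        gc_sum += w_gc.reshape(n_bins, bin_size).sum(axis=1)
        n_sum += w_valid.reshape(n_bins, bin_size).sum(axis=1)
    centers = -up + bin_size * (np.arange(n_bins) + 0.5)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_sum > 0, gc_sum / n_sum, np.nan)
    return centers, frac


def gc_window_content(genome: GenomeSequence, gene: GeneModel,
                      region: str = "around", span: int = 1000) -> float:
    """Single GC fraction over a strand-oriented span at the TSS.

    ``region``: 'around' (+-span), 'upstream' ([-span, 0)) or 'downstream'
    ([0, span)), in transcript orientation.  A span truncated by the contig
    edge is computed on the available bases and flagged with a warning.
    """
    if region not in ("around", "upstream", "downstream"):
        raise ValueError(f"unknown region {region!r}")
    gc, valid = _gc_arrays(genome, gene.seq_id)
    sign = 1 if gene.strand == "+" else -1
    if region == "around":
        off_lo, off_hi = -span, span
    elif region == "upstream":
        off_lo, off_hi = -span, 0
    else:
        off_lo, off_hi = 0, span
    a = gene.tss + sign * off_lo
    b = gene.tss + sign * off_hi
    lo, hi = (a, b) if a <= b else (b + 1, a + 1)
    L = len(gc)
    if lo < 0 or hi > L:
        log.warning("gc_window_content: %s window truncated by contig edge",
                    gene.gene_id)
    lo, hi = max(0, lo), min(L, hi)
    n = valid[lo:hi].sum()
    return float(gc[lo:hi].sum() / n) if n else float("nan")


def hits_near_anchor(hits, genes, side: str = "upstream",
                     span: int = 500) -> dict[str, list]:
    """Assign motif hits to genes whose strand-oriented span contains the hit
    center.  'upstream': center offset in [-span, -1]; 'downstream': [0, span].
    A hit may map to multiple genes.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError("side must be 'upstream' or 'downstream'")
    if span <= 0:
        raise ValueError("span must be positive")
    out: dict[str, list] = {}
    by_seq: dict[str, list] = {}
    for h in hits:
        by_seq.setdefault(h.seq_id, []).append(h)
    for g in genes:
        for h in by_seq.get(g.seq_id, ()):
            o = g.oriented_offset(h.center)
            ok = (-span <= o <= -1) if side == "upstream" else (0 <= o <= span)
            if ok:
                out.setdefault(g.gene_id, []).append(h)
    return out
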