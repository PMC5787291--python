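"""Strand-oriented, anchor-aligned occupancy matrices and averaged profiles.

A profile row is the binned signal over a window around an anchor (TSS, TTS,
exon 5' boundary, motif center, ...), coordinate-reversed for minus-strand
anchors so that positive offsets always mean transcriptional downstream.
Window bases falling off the sequence are flagged missing (NaN) and excluded
from averages rather than zero-padded.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .genomic_io import GeneModel, OccupancyTrack

log = logging.getLogger("nucdyn")

__all__ = [
    "ProfileMatrix",
    "QuintileGrouping",
    "build_profile_matrix",
    "average_profile",
    "scaled_gene_body_profile",
    "exon_boundary_profiles",
    "make_quintiles",
    "DEFAULT_EXON_CLASSES",
]

# exon-length classes holding one to four nucleosomes
DEFAULT_EXON_CLASSES = ((170, 240), (315, 350), (480, 550), (645, 715))


@dataclass
class ProfileMatrix:
    """Rows = genes/sites, columns = bins of oriented offset from the anchor."""

    row_ids: list[str]
    anchor: str
    window: tuple[int, int]      # (upstream bp, downstream bp)
    bin_size: int
    values: np.ndarray           # rows x bins, NaN = missing
    oriented: bool = True

    @property
    def n_bins(self) -> int:
        return (self.window[0] + self.window[1]) // self.bin_size

    @property
    def bin_centers(self) -> np.ndarray:
        up = self.window[0]
        return (-up + self.bin_size * (np.arange(self.n_bins) + 0.5))

    def row(self, row_id: str) -> np.ndarray:
        return self.values[self.row_ids.index(row_id)]

    def subset(self, row_ids) -> "ProfileMatrix":
        wanted = set(row_ids)
        idx = [i for i, r in enumerate(self.row_ids) if r in wanted]
        return ProfileMatrix([self.row_ids[i] for i in idx], self.anchor,
                             self.window, self.bin_size, self.values[idx],
                             self.oriented)


@dataclass
class QuintileGrouping:
    """gene_id -> quintile 1..5 under an explicit ordering direction."""

    assignment: dict[str, int]
    ordering_variable: str
    direction: str  # 'ascending': quintile 1 holds the lowest values

    def members(self, q: int) -> list[str]:
        return [g for g, v in self.assignment.items() if v == q]


def _oriented_window(arr: np.ndarray, pos: int, strand: str,
                     window: tuple[int, int]) -> np.ndarray:
    """Per-base signal over oriented offsets [-up, +down); NaN off-sequence.

    Oriented offset o maps to genomic position pos + o (plus strand) or
    pos - o (minus strand).
    """
    up, down = window
    n = up + down
    out = np.full(n, np.nan)
    L = len(arr)
    if strand == "+":
        lo, hi = pos - up, pos + down
        src_lo, src_hi = max(0, lo), min(L, hi)
        if src_hi > src_lo:
            out[src_lo - lo:src_hi - lo] = arr[src_lo:src_hi]
    else:
        # offset o -> genomic pos - o for o in [-up, down)
        lo, hi = pos - down + 1, pos + up + 1
        src_lo, src_hi = max(0, lo), min(L, hi)
        if src_hi > src_lo:
            rev = arr[src_lo:src_hi][::-1]
            dst_lo = (pos + up) - (src_hi - 1)
            out[dst_lo:dst_lo + len(rev)] = rev
    return out


def build_profile_matrix(track: OccupancyTrack, anchors,
                         window: tuple[int, int] = (1000, 1000),
                         bin_size: int = 10,
                         anchor_name: str = "custom") -> ProfileMatrix:
    """Binned, strand-oriented signal matrix around a list of anchors.

    ``anchors`` is an iterable of ``(row_id, seq_id, pos, strand)`` (a 3-tuple
    ``(seq_id, pos, strand)`` also works; the row id is then synthesised).
    Row r, bin b holds the mean signal over that bin's bases.  Anchors whose
    position lies off-sequence are dropped with a warning.
    """
    up, down = window
    if (up + down) % bin_size:
        raise ValueError("bin_size must divide the window length")
    n_bins = (up + down) // bin_size
    rows, ids, dropped = [], [], 0
    for i, anchor in enumerate(anchors):
        if len(anchor) == 4:
            row_id, seq_id, pos, strand = anchor
        else:
            seq_id, pos, strand = anchor
            row_id = f"site{i:06d}"
        if seq_id not in track.values or not 0 <= pos < len(track.values[seq_id]):
            dropped += 1
            continue
        base = _oriented_window(track.values[seq_id], int(pos), strand, window)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            binned = np.nanmean(base.reshape(n_bins, bin_size), axis=1)
        rows.append(binned)
        ids.append(row_id)
    if dropped:
        log.warning("build_profile_matrix: dropped %d off-sequence anchors", dropped)
    values = np.array(rows) if rows else np.empty((0, n_bins))
    return ProfileMatrix(ids, anchor_name, window, bin_size, values)


def tss_anchors(genes) -> list[tuple]:
    return [(g.gene_id, g.seq_id, g.tss, g.strand) for g in genes]


def tts_anchors(genes) -> list[tuple]:
    return [(g.gene_id, g.seq_id, g.tts, g.strand) for g in genes]


def average_profile(matrix: ProfileMatrix, row_subset=None):
    """Column-wise mean over non-missing entries.

    Returns ``(bin_centers, means)``.  Raises on an empty subset.
    """
    m = matrix if row_subset is None else matrix.subset(row_subset)
    if m.values.shape[0] == 0:
        raise ValueError("average_profile: empty row subset")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(m.values, axis=0)
    return m.bin_centers, means


def scaled_gene_body_profile(track: OccupancyTrack, genes, n_bins: int = 100,
                             flank: int = 1000, bin_size: int = 10) -> np.ndarray:
    """Averaged profile with each gene body rescaled to ``n_bins`` segments
    and flanks kept in native bp (binned at ``bin_size``).

    Layout of the returned vector: ``flank//bin_size`` upstream bins, then
    ``n_bins`` body bins, then ``flank//bin_size`` downstream bins.  Genes
    shorter than ``n_bins`` bases are skipped (count logged).
    """
    n_flank = flank // bin_size
    rows, skipped = [], 0
    for g in genes:
        arr = track.values.get(g.seq_id)
        if arr is None:
            skipped += 1
            continue
        L = g.length
        if L < n_bins:
            skipped += 1
            continue
        body = arr[g.start:g.end]
        if g.strand == "-":
            body = body[::-1]
        csum = np.concatenate(([0.0], np.cumsum(body)))
        edges = np.linspace(0, L, n_bins + 1)
        seg_sums = np.diff(np.interp(edges, np.arange(L + 1), csum))
        seg_means = seg_sums / np.diff(edges)
        upstream = _oriented_window(arr, g.tss, g.strand, (flank, 0))
        downstream = _oriented_window(arr, g.tts, g.strand, (0, flank))
        with np.errstate(invalid="ignore"):
            up_b = np.nanmean(upstream.reshape(n_flank, bin_size), axis=1)
            dn_b = np.nanmean(downstream.reshape(n_flank, bin_size), axis=1)
        rows.append(np.concatenate([up_b, seg_means, dn_b]))
    if skipped:
        log.info("scaled_gene_body_profile: skipped %d genes", skipped)
    if not rows:
        raise ValueError("no usable genes for a scaled gene-body profile")
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.array(rows), axis=0)


def exon_boundary_profiles(track: OccupancyTrack, genes,
                           length_classes=DEFAULT_EXON_CLASSES,
                           window: tuple[int, int] = (200, 400),
                           bin_size: int = 10) -> dict:
    """One averaged profile per exon-length class, anchored at the exon 5'
    boundary (strand-oriented).  Classes are inclusive bp intervals; empty
    classes are omitted with a warning.  Returns class -> (centers, means).
    """
    for (a1, b1), (a2, b2) in zip(sorted(length_classes), sorted(length_classes)[1:]):
        if a2 <= b1:
            raise ValueError("length classes must be non-overlapping")
    out = {}
    for lo, hi in length_classes:
        anchors = []
        for g in genes:
            for j, (s, e) in enumerate(g.exons):
                if lo <= e - s <= hi:
                    five_prime = s if g.strand == "+" else e - 1
                    anchors.append((f"{g.gene_id}.exon{j}", g.seq_id,
                                    five_prime, g.strand))
        if not anchors:
            log.warning("exon class %d-%d bp: no exons, omitted", lo, hi)
            continue
        m = build_profile_matrix(track, anchors, window, bin_size,
                                 anchor_name="exon5p")
        out[(lo, hi)] = average_profile(m)
    return out


def array_amplitude(centers: np.ndarray, values: np.ndarray,
                    window: tuple[int, int]) -> float:
    """Peak-to-trough amplitude of a phased nucleosome oscillation.

    The amplitude of an array is the largest difference between a local
    maximum and an adjacent *internal* local minimum (a trough lying between
    two peaks).  The profile's monotone fall-off at the window edges — e.g.
    into the NDR — is not an array trough and is ignored; without this the
    measure would be dominated by the NDR depth rather than by phasing.
    """
    from scipy.signal import find_peaks
    lo, hi = window
    mask = (centers >= lo) & (centers <= hi)
    v = values[mask].astype(float)
    v = np.where(np.isfinite(v), v, np.nanmin(v))
    if v.size < 5:
        return 0.0
    span = float(v.max() - v.min())
    if span == 0:
        return 0.0
    prom = 0.05 * span
    peaks, _ = find_peaks(v, prominence=prom)
    troughs, _ = find_peaks(-v, prominence=prom)
    internal = [t for t in troughs if peaks.size and peaks[0] < t < peaks[-1]]
    best = 0.0
    for t in internal:
        left = peaks[peaks < t].max()
        right = peaks[peaks > t].min()
        best = max(best, min(v[left], v[right]) - v[t])
    return float(best)


def make_quintiles(values: dict[str, float],
                   direction: str = "ascending",
                   ordering_variable: str = "custom") -> QuintileGrouping:
    """Rank-based split into 5 near-equal groups (sizes differ by <= 1).

    ``direction='ascending'``: quintile 1 holds the lowest values (the GC
    convention); ``'descending'``: quintile 1 holds the highest (the
    expression convention).  Ties are broken by stable input order.
    """
    if direction not in ("ascending", "descending"):
        raise ValueError("direction must be 'ascending' or 'descending'")
    items = [(g, v) for g, v in values.items() if np.isfinite(v)]
    if len(items) < 5:
        raise ValueError("need at least 5 genes with finite values")
    keys = np.array([v for _, v in items])
    if direction == "descending":
        keys = -keys
    order = np.argsort(keys, kind="stable")
    assignment = {}
    for q, chunk in enumerate(np.array_split(order, 5), start=1):
        for i in chunk:
            assignment[items[i][0]] = q
    return QuintileGrouping(assignment, ordering_variable, direction)
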