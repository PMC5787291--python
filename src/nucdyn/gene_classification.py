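"""Gene classification by TSS nucleosome architecture.

Three complementary views:

* -1-nucleosome position subsets: the offset of the first well-defined
  nucleosome upstream of the TSS, binned around the two antiphase promoter
  architectures (-140 and -250 bp);
* k-means clusters of row-mean-normalised TSS profiles (k = 6 by default);
* a two-way typing of the clusters from centroid geometry — type I
  ("housekeeping-like": nucleosome-depleted upstream of the TSS) versus
  type II ("stress-responsive-like": an evident -1 nucleosome) — plus the
  Fisher's-exact association of typing with TATA-box presence.

Cluster labels from k-means are arbitrary under reseeding, so the I/II
grouping is re-derived from centroid shape rather than from label identity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import argrelextrema
from sklearn.cluster import KMeans

from .metagene import ProfileMatrix
from .stats_core import fisher_exact_2x2

log = logging.getLogger("nucdyn")

__all__ = [
    "PromoterClassification",
    "ClusterAssignment",
    "find_minus1",
    "classify_promoters",
    "cluster_tss_profiles",
    "assign_types",
    "tata_association",
    "DEFAULT_PROMOTER_BINS",
]

DEFAULT_PROMOTER_BINS = {"minus140": (-165, -115), "minus250": (-275, -225)}


@dataclass
class PromoterClassification:
    """gene_id -> {'minus140','minus250','unclassified'} plus the detected
    -1 dyad offset (bp, None when no qualifying upstream peak exists)."""

    labels: dict[str, str]
    offsets: dict[str, Optional[float]]

    def members(self, label: str) -> list[str]:
        return [g for g, l in self.labels.items() if l == label]


@dataclass
class ClusterAssignment:
    labels: dict[str, str]            # gene_id -> cluster letter
    centroids: np.ndarray             # k x bins, ordered by decreasing size
    bin_centers: np.ndarray
    cluster_names: tuple[str, ...]
    types: dict[str, str] = field(default_factory=dict)  # cluster -> I/II

    def gene_types(self) -> dict[str, str]:
        return {g: self.types[c] for g, c in self.labels.items() if c in self.types}


def find_minus1(row: np.ndarray, bin_centers: np.ndarray,
                search_window: tuple[int, int] = (-400, -50),
                prominence_frac: float = 0.1) -> Optional[float]:
    """Offset of the highest local maximum within the upstream search window
    exceeding ``prominence_frac`` x row maximum; None when absent."""
    finite = np.isfinite(row)
    if not finite.any():
        return None
    threshold = prominence_frac * np.nanmax(row)
    filled = np.where(finite, row, -np.inf)
    is_max = np.zeros(len(row), dtype=bool)
    if len(row) >= 3:
        is_max[argrelextrema(filled, np.greater_equal, order=1)[0]] = True
        # plateau-proof: require strictly greater than at least one neighbour
        interior = np.arange(1, len(row) - 1)
        strict = (filled[interior] > filled[interior - 1]) | \
                 (filled[interior] > filled[interior + 1])
        is_max[interior] &= strict
    lo, hi = search_window
    in_window = (bin_centers >= lo) & (bin_centers <= hi)
    candidates = np.flatnonzero(is_max & in_window & (filled > threshold))
    if candidates.size == 0:
        return None
    best = candidates[np.argmax(filled[candidates])]
    return float(bin_centers[best])


def classify_promoters(matrix: ProfileMatrix,
                       bins: dict = DEFAULT_PROMOTER_BINS,
                       search_window: tuple[int, int] = (-400, -50),
                       prominence_frac: float = 0.1) -> PromoterClassification:
    """Assign each gene to the promoter-architecture bin containing its
    detected -1 offset; offsets outside every bin give 'unclassified'."""
    labels, offsets = {}, {}
    centers = matrix.bin_centers
    for i, gid in enumerate(matrix.row_ids):
        off = find_minus1(matrix.values[i], centers, search_window,
                          prominence_frac)
        offsets[gid] = off
        label = "unclassified"
        if off is not None:
            for name, (lo, hi) in bins.items():
                if lo <= off <= hi:
                    label = name
                    break
        labels[gid] = label
    return PromoterClassification(labels, offsets)


def cluster_tss_profiles(matrix: ProfileMatrix, k: int = 6,
                         seed: int = 0, n_init: int = 10) -> ClusterAssignment:
    """k-means on row-mean-normalised TSS profiles.

    Rows with zero/NaN mean are dropped (logged).  Clusters are renamed
    A, B, ... in decreasing size so that identical input and seed give
    identical labels.
    """
    keep, X, ids = [], [], []
    for i, gid in enumerate(matrix.row_ids):
        row = matrix.values[i]
        if not np.all(np.isfinite(row)):
            continue
        mu = row.mean()
        if mu <= 0:
            continue
        ids.append(gid)
        X.append(row / mu)
    if len(X) < k:
        raise ValueError(f"k={k} exceeds the {len(X)} usable rows")
    dropped = matrix.values.shape[0] - len(X)
    if dropped:
        log.warning("cluster_tss_profiles: dropped %d unusable rows", dropped)
    X = np.array(X)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                random_state=seed)
    raw_labels = km.fit_predict(X)
    sizes = np.bincount(raw_labels, minlength=k)
    if (sizes == 0).any():
        log.warning("cluster_tss_profiles: %d empty clusters", int((sizes == 0).sum()))
    order = np.argsort(-sizes, kind="stable")
    names = tuple(chr(ord("A") + i) for i in range(k))
    rename = {int(old): names[new] for new, old in enumerate(order)}
    labels = {gid: rename[int(l)] for gid, l in zip(ids, raw_labels)}
    centroids = km.cluster_centers_[order]
    return ClusterAssignment(labels, centroids, matrix.bin_centers, names)


def assign_types(assignment: ClusterAssignment,
                 upstream_window: tuple[int, int] = (-200, -50),
                 downstream_window: tuple[int, int] = (50, 300),
                 theta: float = 0.8) -> dict[str, str]:
    """Type I iff the centroid's upstream mean is below ``theta`` x its
    downstream mean (an NDR in place of a -1 nucleosome); else type II.

    Invariant to uniform rescaling of the input rows (the rule is a ratio).
    """
    centers = assignment.bin_centers
    up = (centers >= upstream_window[0]) & (centers <= upstream_window[1])
    down = (centers >= downstream_window[0]) & (centers <= downstream_window[1])
    types = {}
    for name, centroid in zip(assignment.cluster_names, assignment.centroids):
        u = float(np.nanmean(centroid[up]))
        d = float(np.nanmean(centroid[down]))
        types[name] = "I" if u < theta * d else "II"
    assignment.types = types
    return types


def tata_association(typing: dict[str, str], tata_genes) -> tuple[float, float]:
    """Fold enrichment of TATA-box presence in type II over type I genes and
    the two-sided Fisher's exact p-value.

    fold = (TATA rate among type II) / (TATA rate among type I); infinity
    when no type I gene has a TATA box (p is still computed).
    """
    tata_genes = set(tata_genes)
    n_II = sum(1 for t in typing.values() if t == "II")
    n_I = sum(1 for t in typing.values() if t == "I")
    if n_I == 0 or n_II == 0:
        raise ValueError("typing must contain both type I and type II genes")
    t_II = sum(1 for g, t in typing.items() if t == "II" and g in tata_genes)
    t_I = sum(1 for g, t in typing.items() if t == "I" and g in tata_genes)
    table = [[t_II, n_II - t_II], [t_I, n_I - t_I]]
    _, p = fisher_exact_2x2(table)
    rate_II = t_II / n_II
    rate_I = t_I / n_I
    fold = rate_II / rate_I if rate_I > 0 else float("inf")
    return fold, p
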