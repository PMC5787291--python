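"""Statistical battery: BH adjustment, Fisher's exact, rank tests, track
correlations, and the resampling test for enrichment of dynamic nucleosomes
at differentially expressed genes.

The resampling enrichment draws ``n_iter`` gene sets of the same size as the
DEG set uniformly without replacement from the universe and reports, per
dynamic class, the observed carrier proportion, the null mean and SD, an
empirical p-value and a two-sided exact binomial p-value against the class
prevalence (the paper-style "binomial test with 10,000 iterations" is
ambiguous, so both readings are reported).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .genomic_io import OccupancyTrack

log = logging.getLogger("nucdyn")

__all__ = [
    "EnrichmentResult",
    "bh_adjust",
    "fisher_exact_2x2",
    "rank_tests",
    "track_correlation",
    "resample_enrichment",
]

EXACT_N_MAX = 25  # rank tests enumerate exactly at or below this sample size


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    NaN entries are propagated as NaN and excluded from the family size m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    q = p[mask]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q, kind="stable")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj, 1.0)
    out[mask] = adjusted
    return out


def fisher_exact_2x2(table) -> tuple[float, float]:
    """(odds ratio, two-sided p) for a 2x2 count table.

    Two-sided p is the conditional hypergeometric sum of tables at least as
    improbable as the observed one.  A zero margin gives p = 1 and an
    undefined (NaN) odds ratio.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("table must be 2x2 non-negative integers")
        t = t.astype(int)
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        log.debug("fisher_exact_2x2: zero margin, odds ratio undefined")
        return float("nan"), 1.0
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def rank_tests(x, y, kind: str = "mannwhitney") -> float:
    """Two-sided p-value for a Mann-Whitney U test (independent samples) or a
    Wilcoxon signed-rank test (paired samples).

    Exact enumeration for samples of size <= 25 without ties; the tie-corrected
    normal approximation above that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if kind == "mannwhitney":
        method = "exact" if max(len(x), len(y)) <= EXACT_N_MAX else "asymptotic"
        try:
            return float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                          method=method).pvalue)
        except ValueError:  # ties prevent the exact method
            return float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                          method="asymptotic").pvalue)
    if kind == "wilcoxon_signed":
        if len(x) != len(y):
            raise ValueError("wilcoxon_signed needs equal-length paired samples")
        d = x - y
        if np.all(d == 0):
            return 1.0
        method = "exact" if len(x) <= EXACT_N_MAX else "approx"
        try:
            return float(sps.wilcoxon(x, y, alternative="two-sided",
                                      method=method, correction=False).pvalue)
        except ValueError:
            return float(sps.wilcoxon(x, y, alternative="two-sided",
                                      method="approx", correction=False).pvalue)
    raise ValueError(f"unknown test kind {kind!r}")


def track_correlation(a: OccupancyTrack, b: OccupancyTrack,
                      kind: str = "spearman", bin: int = 100) -> float:
    """Correlation coefficient between two tracks over binned values."""
    if bin <= 0:
        raise ValueError("bin must be positive")
    if set(a.values) != set(b.values):
        raise ValueError("tracks cover different sequences")
    xs, ys = [], []
    for seq_id in sorted(a.values):
        va, vb = a.values[seq_id], b.values[seq_id]
        if len(va) != len(vb):
            raise ValueError(f"length mismatch on {seq_id}")
        n = (len(va) // bin) * bin
        if n == 0:
            continue
        xs.append(va[:n].reshape(-1, bin).mean(axis=1))
        ys.append(vb[:n].reshape(-1, bin).mean(axis=1))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if np.std(x) == 0 or np.std(y) == 0:
        log.warning("track_correlation: zero-variance input, undefined")
        return float("nan")
    if kind == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if kind == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation kind {kind!r}")


@dataclass
class EnrichmentResult:
    category: str
    observed_prop: float
    null_mean: float
    null_sd: float
    empirical_p: float
    binomial_p: float
    n_iterations: int
    n_deg: int
    universe_size: int


def resample_enrichment(deg_ids, gene_to_classes: dict, universe,
                        n_iter: int = 10000, seed: int = 0,
                        classes=None) -> dict[str, EnrichmentResult]:
    """Per-class enrichment of dynamic-nucleosome carriers among DEGs.

    ``gene_to_classes`` maps gene_id -> set of dynamic classes the gene
    carries (a gene "has" a class when at least one qualifying dynamic
    nucleosome lies in its gene-related region).  The null draws ``n_iter``
    same-size gene sets uniformly without replacement from ``universe``;
    the same draws are shared across classes.  Deterministic under ``seed``.
    """
    universe = sorted(set(universe))
    deg_ids = sorted(set(deg_ids))
    n = len(universe)
    m = len(deg_ids)
    if m > n:
        raise ValueError("DEG set larger than the universe")
    if not set(deg_ids) <= set(universe):
        raise ValueError("deg_ids must be a subset of the universe")
    if n_iter < 1000:
        raise ValueError("n_iter must be >= 1000")
    if classes is None:
        classes = sorted({c for g in universe
                          for c in gene_to_classes.get(g, ())})
    idx = {g: i for i, g in enumerate(universe)}
    carrier = np.zeros((len(classes), n), dtype=bool)
    for ci, cls in enumerate(classes):
        for g in universe:
            if cls in gene_to_classes.get(g, ()):
                carrier[ci, idx[g]] = True
    deg_idx = np.array([idx[g] for g in deg_ids], dtype=int)
    obs_counts = carrier[:, deg_idx].sum(axis=1) if m else np.zeros(len(classes), int)

    rng = np.random.default_rng(seed)
    null_counts = np.empty((n_iter, len(classes)), dtype=np.int32)
    for it in range(n_iter):
        draw = rng.choice(n, size=m, replace=False)
        null_counts[it] = carrier[:, draw].sum(axis=1)

    out = {}
    for ci, cls in enumerate(classes):
        nulls = null_counts[:, ci]
        obs = int(obs_counts[ci])
        prevalence = carrier[ci].mean()
        emp_p = (1.0 + int((nulls >= obs).sum())) / (n_iter + 1.0)
        binom_p = sps.binomtest(obs, m, max(min(prevalence, 1.0), 0.0)
                                ).pvalue if m else 1.0
        out[cls] = EnrichmentResult(
            category=cls,
            observed_prop=obs / m if m else float("nan"),
            null_mean=float(nulls.mean() / m) if m else float("nan"),
            null_sd=float(nulls.std(ddof=1) / m) if m else float("nan"),
            empirical_p=float(emp_p),
            binomial_p=float(binom_p),
            n_iterations=n_iter,
            n_deg=m,
            universe_size=n,
        )
    return out
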