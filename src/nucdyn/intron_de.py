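"""Intron-read-based differential transcription and FPKM computation.

Changes in intronic read abundance track nascent transcription more closely
than steady-state exonic abundance, so differential transcription is tested
on intron counts.  The engine is a self-contained negative-binomial Wald
test: median-of-ratios size factors, method-of-moments dispersion shrunk
toward a trended mean-dispersion fit, a Wald z on the intron log2 fold
change, and Benjamini-Hochberg adjustment over the testable genes.  Genes
with all-zero intron counts are not testable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genomic_io import GeneModel
from .stats_core import bh_adjust

log = logging.getLogger("nucdyn")

__all__ = ["CountTable", "DEResult", "count_reads", "fpkm", "de_test",
           "size_factors"]

DISPERSION_FLOOR = 1e-8
SHRINKAGE_WEIGHT = 0.25  # weight of the per-gene moment estimate vs the trend


@dataclass
class CountTable:
    """Intron- and exon-assigned counts (genes x samples) plus the design."""

    intron: pd.DataFrame
    exon: pd.DataFrame
    design: pd.DataFrame  # index = sample, columns: condition, replicate

    def __post_init__(self):
        for name, df in (("intron", self.intron), ("exon", self.exon)):
            arr = df.to_numpy()
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise ValueError(f"{name} counts must be non-negative integers")
        if list(self.intron.columns) != list(self.design.index):
            raise ValueError("design index must match count columns")

    def samples(self, condition: str) -> list[str]:
        return list(self.design.index[self.design["condition"] == condition])


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    base_mean: float
    log2fc: float
    p: float
    padj: float
    call: str  # up / down / ns


# ---------------------------------------------------------------------------
# read counting
# ---------------------------------------------------------------------------

def count_reads(reads, genes: list[GeneModel], samples=None,
                stranded: bool = False) -> pd.DataFrame:
    """Assign BED6-style read intervals to intronic or exonic gene features.

    A read is intron-assigned iff it overlaps intronic bases of exactly one
    gene and no exonic bases; exon-assigned iff it overlaps exonic bases of
    exactly one gene.  Reads touching two genes are dropped (counted in the
    log).  Returns a DataFrame indexed by gene_id with columns
    ``intron`` and ``exon``.
    """
    by_seq: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_seq.setdefault(g.seq_id, []).append(g)
    intron_counts = {g.gene_id: 0 for g in genes}
    exon_counts = {g.gene_id: 0 for g in genes}
    ambiguous = unassigned = 0
    for seq_id, start, end, _name, _score, strand in reads:
        hit_genes = []
        for g in by_seq.get(seq_id, ()):
            if start < g.end and end > g.start:
                if stranded and strand in "+-" and strand != g.strand:
                    continue
                hit_genes.append(g)
        if len(hit_genes) == 0:
            unassigned += 1
            continue
        if len(hit_genes) > 1:
            ambiguous += 1
            continue
        g = hit_genes[0]
        exonic = any(start < e and end > s for s, e in g.exons)
        if exonic:
            exon_counts[g.gene_id] += 1
        elif any(start < e and end > s for s, e in g.introns):
            intron_counts[g.gene_id] += 1
        else:
            unassigned += 1  # overlaps the span edge only
    if ambiguous:
        log.info("count_reads: dropped %d multi-gene reads", ambiguous)
    if unassigned:
        log.debug("count_reads: %d reads outside gene features", unassigned)
    return pd.DataFrame({"intron": intron_counts, "exon": exon_counts})


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------

def fpkm(table: CountTable, genes: list[GeneModel],
         condition: str = "control") -> dict[str, float]:
    """Fragments per kilobase of exon per million assigned reads, averaged
    over the replicates of one condition."""
    samples = table.samples(condition)
    if not samples:
        raise ValueError(f"no samples for condition {condition!r}")
    lib = (table.exon[samples].sum(axis=0) + table.intron[samples].sum(axis=0))
    if (lib <= 0).any():
        raise ValueError("zero library size")
    lengths_kb = {g.gene_id: g.exonic_length / 1000.0 for g in genes}
    out = {}
    for g in genes:
        vals = [table.exon.at[g.gene_id, s] / (lengths_kb[g.gene_id] * lib[s] / 1e6)
                for s in samples]
        out[g.gene_id] = float(np.mean(vals))
    return out


# ---------------------------------------------------------------------------
# differential transcription
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors (geometric-mean reference)."""
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.sum() < 10:
        log.warning("size_factors: <10 all-positive genes, "
                    "falling back to total-count ratios")
        totals = arr.sum(axis=0)
        return pd.Series(totals / np.exp(np.mean(np.log(totals))),
                         index=counts.columns)
    logs = np.log(arr[positive])
    ref = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(sf, index=counts.columns)


def _dispersion_trend(mu: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu by non-negative least squares."""
    from scipy.optimize import nnls
    mask = (mu > 0) & np.isfinite(disp)
    if mask.sum() < 5:
        level = float(np.nanmedian(disp[mask])) if mask.any() else 0.1
        return np.full_like(mu, max(level, DISPERSION_FLOOR))
    A = np.column_stack([np.ones(mask.sum()), 1.0 / mu[mask]])
    coef, _ = nnls(A, np.maximum(disp[mask], 0.0))
    trend = coef[0] + coef[1] / np.maximum(mu, 1e-8)
    return np.maximum(trend, DISPERSION_FLOOR)


def de_test(table: CountTable, alpha: float = 0.05,
            pseudocount: float = 0.5) -> pd.DataFrame:
    """Negative-binomial Wald test on intron counts, treated vs control.

    Returns a DataFrame (index gene_id) with columns base_mean, log2fc, p,
    padj and call; non-testable genes (all-zero intron counts) carry NaN p.
    A gene is 'up' iff padj < alpha and log2fc > 0, 'down' iff padj < alpha
    and log2fc < 0.
    """
    ctrl = table.samples("control")
    trt = table.samples("treated")
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("need >= 2 replicates per condition for dispersion")
    sf = size_factors(table.intron)
    norm = table.intron / sf
    yc = norm[ctrl].to_numpy(dtype=float)
    yt = norm[trt].to_numpy(dtype=float)
    nc, nt = yc.shape[1], yt.shape[1]
    mu_c = yc.mean(axis=1)
    mu_t = yt.mean(axis=1)
    base_mean = np.concatenate([yc, yt], axis=1).mean(axis=1)
    testable = (yc.sum(axis=1) + yt.sum(axis=1)) > 0

    # method-of-moments dispersion pooled across conditions
    var_within = (yc.var(axis=1, ddof=1) * (nc - 1)
                  + yt.var(axis=1, ddof=1) * (nt - 1)) / (nc + nt - 2)
    mu_bar = np.maximum((mu_c * nc + mu_t * nt) / (nc + nt), 1e-8)
    disp_mom = np.maximum((var_within - mu_bar) / mu_bar ** 2, DISPERSION_FLOOR)
    trend = _dispersion_trend(mu_bar[testable], disp_mom[testable]) \
        if testable.any() else np.array([])
    disp = np.full(len(mu_bar), np.nan)
    disp[testable] = np.maximum(
        SHRINKAGE_WEIGHT * disp_mom[testable] + (1 - SHRINKAGE_WEIGHT) * trend,
        DISPERSION_FLOOR)

    log2fc = np.log2((mu_t + pseudocount) / (mu_c + pseudocount))
    se2 = ((1.0 / np.maximum(mu_c + pseudocount, 1e-8) + disp) / nc
           + (1.0 / np.maximum(mu_t + pseudocount, 1e-8) + disp) / nt)
    se_log2 = np.sqrt(se2) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se_log2
    p = np.where(testable, 2.0 * sps.norm.sf(np.abs(z)), np.nan)
    padj = bh_adjust(p)
    call = np.where(np.isfinite(padj) & (padj < alpha),
                    np.where(log2fc > 0, "up", "down"), "ns")
    call = np.where(testable, call, "ns")
    return pd.DataFrame({
        "base_mean": base_mean, "log2fc": log2fc, "p": p, "padj": padj,
        "call": call, "dispersion": disp,
    }, index=table.intron.index)


def de_results(df: pd.DataFrame) -> list[DEResult]:
    """DataFrame rows as DEResult records."""
    return [DEResult(g, float(r.base_mean), float(r.log2fc), float(r.p),
                     float(r.padj), str(r.call))
            for g, r in df.iterrows()]
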