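"""Synthetic study generator with planted, manifest-recorded ground truth.

Emulates the statistical structure of a paired-condition MNase-seq /
RNA-seq experiment on a compact genome:

* phased nucleosome arrays downstream of each TSS (repeat length ``nrl``,
  Gaussian dyad kernels of SD ``kernel_sd``), decaying away from the TSS;
* two antiphase promoter architectures, with the -1 nucleosome dyad at
  either -140 or -250 bp from the TSS and further phased nucleosomes
  upstream of it;
* two TSS archetypes: "open" promoters with a nucleosome-depleted region
  (NDR) immediately upstream of the TSS and an attenuated -1 (type I,
  housekeeping-like), versus "occupied" promoters with a full-height -1
  and partially delocalised nucleosome signal over the proximal promoter
  (type II, stress-responsive-like);
* GC composition correlated with the occupancy landscape (trough just
  upstream of the TSS, elevated GC over the first 500 bp downstream, a
  local GC bump under the -1 dyad);
* promoter cis-elements (TATA box, P1BS, G-box, Y-patch) planted at
  manifest-recorded offsets, with TATA preferentially in type II genes;
* a treated condition differing from control only by planted dynamics:
  dyad shifts (uniform in ``shift_range``), occupancy scalings and
  fuzziness (kernel SD) scalings on manifest-selected nucleosomes;
* intron/exon count tables (2 replicates x 2 conditions) from a
  negative-binomial model, with differential transcription planted on
  intron counts and DE genes preferentially drawn from genes carrying
  planted nucleosome dynamics (odds multiplier ``de_dynamic_odds``).

One seed fixes every random choice; identical configs give byte-identical
emitted files.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .genomic_io import GeneModel, GenomeSequence, OccupancyTrack

log = logging.getLogger("nucdyn")

__all__ = [
    "SimulationConfig",
    "TruthManifest",
    "simulate_genome",
    "simulate_tracks",
    "simulate_counts",
    "simulate_study",
]

# offset ranges (bp upstream of the TSS) reserved for each planted element,
# kept disjoint so plantings never overwrite each other
_MOTIF_SLOTS = {
    "TATA": (12, 50),
    "Y-patch": (60, 95),
    "G-box": (110, 300),
    "P1BS": (320, 490),
}
_MOTIF_CONSENSUS = {
    "TATA": "CTATAWAWA",
    "Y-patch": "CYTCYYCCYC",
    "G-box": "CACGTG",
    "P1BS": "GNATATNC",
}
_IUPAC_CHOICES = {"W": "AT", "Y": "CT", "N": "ACGT", "R": "AG", "S": "GC",
                  "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
                  "V": "ACG"}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.  Defaults are the study conditions."""

    n_genes: int = 200
    genome_length: Optional[int] = None  # auto-sized when None
    seed: int = 0

    # chromatin geometry
    nrl: int = 180                 # nucleosome repeat length, bp
    kernel_sd: float = 25.0        # dyad kernel SD (fuzziness), bp
    ndr_width: int = 150           # NDR span upstream of TSS for type I genes
    plus1_pos: int = 90            # +1 dyad offset downstream of the TSS
    n_down_nucs: int = 5
    n_up_nucs: int = 3
    downstream_decay: float = 0.85  # occupancy decay per array position
    upstream_decay: float = 0.75
    upstream_fuzz: float = 1.3     # upstream kernels are intrinsically fuzzier
    nuc_mass: float = 600.0        # expected reads per nucleosome footprint
    background: float = 0.2        # uniform per-base background read rate
    promoter_fill: float = 0.45    # delocalised promoter signal, type II genes
    ndr_attenuation: float = 0.05  # residual signal inside the NDR
    typeI_minus1_scale: float = 0.3

    # gene architecture
    frac_minus140: float = 0.5
    frac_minus250: float = 0.5
    frac_typeI: float = 0.5
    gene_length_range: tuple[int, int] = (1800, 3600)
    flank: int = 1700              # intergenic flank on each side of a gene
    exon_range: tuple[int, int] = (2, 5)

    # planted nucleosome dynamics
    n_shift: int = 0
    n_occ: int = 0
    n_fuzz: int = 0
    shift_range: tuple[int, int] = (50, 95)
    occ_factor: float = 2.0
    fuzz_factor: float = 2.0

    # noise model
    poisson: bool = True           # Poisson-sample per-base counts
    noise_sd: float = 0.0          # additional Gaussian noise on the signal

    # cis-elements
    tata_rate_typeI: float = 0.08
    tata_odds_typeII: float = 3.0
    p1bs_fraction: float = 0.25
    gbox_fraction: float = 0.2
    ypatch_fraction: float = 0.3

    # expression / differential transcription
    de_fraction: float = 0.0
    de_log2fc: float = 2.0
    de_dynamic_odds: float = 1.0   # odds multiplier: DE among dynamics carriers
    nb_dispersion: float = 0.05
    intron_mean: float = 200.0
    expr_sigma: float = 0.6
    exon_to_intron: float = 5.0
    n_replicates: int = 2
    size_factors: tuple[float, ...] = (1.0, 1.1, 0.9, 1.05)

    def __post_init__(self):
        for name in ("frac_minus140", "frac_minus250", "frac_typeI",
                     "de_fraction", "p1bs_fraction", "gbox_fraction",
                     "ypatch_fraction", "tata_rate_typeI"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.frac_minus140 + self.frac_minus250 > 1.0 + 1e-9:
            raise ValueError("frac_minus140 + frac_minus250 exceeds 1")
        lo, hi = self.shift_range
        if not (1 <= lo <= hi < self.nrl):
            raise ValueError("shift_range must lie within [1, nrl)")
        if self.nrl < 2 * self.kernel_sd:
            raise ValueError("nrl < 2 x kernel_sd: phasing unresolvable")

    @property
    def slot(self) -> int:
        """Genomic span reserved per gene (gene body plus both flanks)."""
        return self.gene_length_range[1] + 2 * self.flank

    def required_length(self) -> int:
        return self.n_genes * self.slot + self.flank


@dataclass
class TruthManifest:
    """Planted ground truth: serialisable and reloadable losslessly."""

    genes: dict[str, dict] = field(default_factory=dict)
    nucleosomes: list[dict] = field(default_factory=list)
    motifs: list[dict] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "wt") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "TruthManifest":
        try:
            data = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path) as fh:
                data = json.load(fh)
        return cls(**data)

    def genes_with_dynamics(self, classes=None) -> set[str]:
        out = set()
        for nuc in self.nucleosomes:
            dyn = nuc.get("dynamic")
            if dyn and (classes is None or dyn["kind"] in classes):
                out.add(nuc["gene_id"])
        return out


# ---------------------------------------------------------------------------
# deterministic per-stage RNG streams
# ---------------------------------------------------------------------------

def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stage)))


# ---------------------------------------------------------------------------
# gene layout and per-gene attributes
# ---------------------------------------------------------------------------

def _assign_gene_attributes(config: SimulationConfig):
    """Deterministic per-gene attributes (promoter class, type, strand,
    lengths, exon structure, planted dynamics) from the config seed."""
    rng = _rng(config, 1)
    n = config.n_genes
    # promoter class
    classes = np.full(n, "minus140", dtype=object)
    u = rng.random(n)
    classes[u >= config.frac_minus140] = "minus250"
    classes[u >= config.frac_minus140 + config.frac_minus250] = "unclassified"
    # type I (NDR) vs type II (occupied promoter)
    types = np.where(rng.random(n) < config.frac_typeI, "I", "II")
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    lengths = rng.integers(config.gene_length_range[0],
                           config.gene_length_range[1] + 1, size=n)
    n_exons = rng.integers(config.exon_range[0], config.exon_range[1] + 1, size=n)

    # planted dynamics: a shared pool of "dynamic" genes so that events of
    # different kinds can co-occur on the same genes (needed for the
    # DE <-> dynamics coupling); each kind uses its own array position.
    n_dyn = max(config.n_shift, config.n_occ, config.n_fuzz)
    dyn_order = rng.permutation(n)
    dynamics = {}  # gene index -> {kind: payload}
    # planted events sit mid-array (+3 for shifts, +2/+4 for the others):
    # a dyad shifted off the +1 lands on the promoter taper, whose slope
    # biases its called position by up to ~10 bp
    for kind, count, down_idx in (("shift", config.n_shift, 3),
                                  ("occupancy", config.n_occ, 2),
                                  ("fuzziness", config.n_fuzz, 4)):
        for j in range(min(count, n)):
            # same leading genes for every kind -> kinds co-occur when counts match
            gi = int(dyn_order[j])
            dynamics.setdefault(gi, {})[kind] = {"down_index": down_idx}
    # magnitudes / directions
    for gi, kinds in dynamics.items():
        if "shift" in kinds:
            lo, hi = config.shift_range
            mag = int(rng.integers(lo, hi + 1))
            sign = 1 if rng.random() < 0.5 else -1
            kinds["shift"].update(magnitude=mag * sign)  # transcript-oriented
        if "occupancy" in kinds:
            up = rng.random() < 0.5
            kinds["occupancy"].update(
                factor=config.occ_factor if up else 1.0 / config.occ_factor)
        if "fuzziness" in kinds:
            up = rng.random() < 0.5
            kinds["fuzziness"].update(
                factor=config.fuzz_factor if up else 1.0 / config.fuzz_factor)
    return {
        "classes": classes, "types": types, "strands": strands,
        "lengths": lengths, "n_exons": n_exons, "dynamics": dynamics,
    }


def _build_gene_models(config: SimulationConfig, attrs) -> list[GeneModel]:
    rng = _rng(config, 2)
    genes = []
    for i in range(config.n_genes):
        start = config.flank + i * config.slot
        length = int(attrs["lengths"][i])
        end = start + length
        k = int(attrs["n_exons"][i])
        # partition the gene into k exons separated by k-1 introns (>=150 bp)
        min_exon, min_intron = 150, 150
        free = length - k * min_exon - (k - 1) * min_intron
        if free < 0:
            k, free = 1, length - min_exon
        cuts = np.sort(rng.integers(0, free + 1, size=2 * k - 2)) if k > 1 else []
        sizes = np.diff(np.concatenate(([0], cuts, [free])))
        exons, pos = [], start
        for j in range(k):
            e_len = min_exon + int(sizes[2 * j])
            exons.append((pos, pos + e_len))
            pos += e_len
            if j < k - 1:
                pos += min_intron + int(sizes[2 * j + 1])
        exons[-1] = (exons[-1][0], end)  # absorb rounding into the last exon
        genes.append(GeneModel(
            gene_id=f"gene{i:05d}", seq_id="chrS", strand=str(attrs["strands"][i]),
            start=start, end=end, exons=tuple(exons), category="PCG"))
    return genes


# ---------------------------------------------------------------------------
# nucleosome layout per gene
# ---------------------------------------------------------------------------

def _nucleosome_plan(config: SimulationConfig, attrs, genes) -> list[dict]:
    """Per-nucleosome plan: transcript offsets, masses, kernel SDs and planted
    dynamics, resolved to genomic dyad coordinates."""
    plan = []
    for i, gene in enumerate(genes):
        cls = attrs["classes"][i]
        gtype = attrs["types"][i]
        dyn = attrs["dynamics"].get(i, {})
        sign = 1 if gene.strand == "+" else -1
        # downstream array: +1, +2, ... ; slightly taller +1
        for k in range(config.n_down_nucs):
            offset = config.plus1_pos + k * config.nrl
            mass = config.nuc_mass * 1.1 * config.downstream_decay ** k
            entry = {
                "gene_id": gene.gene_id, "role": "down", "index": k + 1,
                "offset": offset, "mass": mass, "sd": config.kernel_sd,
                "dyad": gene.tss + sign * offset, "dynamic": None,
            }
            for kind, payload in dyn.items():
                if payload["down_index"] == k + 1:
                    entry["dynamic"] = {"kind": kind, **{
                        kk: vv for kk, vv in payload.items() if kk != "down_index"}}
            plan.append(entry)
        # upstream array anchored on the -1 dyad at the promoter-class position
        if cls != "unclassified":
            minus1 = 140 if cls == "minus140" else 250
            for k in range(config.n_up_nucs):
                offset = -(minus1 + k * config.nrl)
                mass = config.nuc_mass * config.upstream_decay ** k
                if gtype == "I":
                    mass *= config.typeI_minus1_scale
                plan.append({
                    "gene_id": gene.gene_id, "role": "up", "index": k + 1,
                    "offset": offset, "mass": mass,
                    "sd": config.kernel_sd * config.upstream_fuzz,
                    "dyad": gene.tss + sign * offset, "dynamic": None,
                })
    return plan


def _add_kernel(arr: np.ndarray, center: float, sd: float, mass: float) -> None:
    lo = max(0, int(center - 4 * sd))
    hi = min(len(arr), int(center + 4 * sd) + 1)
    if hi <= lo:
        return
    x = np.arange(lo, hi)
    arr[lo:hi] += mass * np.exp(-0.5 * ((x - center) / sd) ** 2) / (
        sd * np.sqrt(2 * np.pi))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def simulate_gene_models(config: SimulationConfig) -> list[GeneModel]:
    """Annotation only (no sequence/track synthesis) — cheap path for
    count-level simulations."""
    return _build_gene_models(config, _assign_gene_attributes(config))


def simulate_genome(config: SimulationConfig):
    """Genome sequence, annotation and manifest with planted promoter classes,
    gene types and cis-elements."""
    if config.genome_length is not None and config.genome_length < config.required_length():
        raise ValueError(
            f"genome_length={config.genome_length} cannot hold {config.n_genes} "
            f"genes (need >= {config.required_length()})")
    length = config.genome_length or config.required_length()
    attrs = _assign_gene_attributes(config)
    genes = _build_gene_models(config, attrs)
    manifest = TruthManifest()

    rng = _rng(config, 3)
    # position-wise GC probability correlated with the occupancy landscape
    gc = np.full(length, 0.42)
    for i, gene in enumerate(genes):
        sign = 1 if gene.strand == "+" else -1
        tss = gene.tss

        def paint(off_lo, off_hi, value):
            a = tss + sign * off_lo
            b = tss + sign * off_hi
            lo, hi = (a, b) if a <= b else (b, a)
            gc[max(0, lo):min(length, hi)] = value

        paint(-500, 0, 0.36)
        paint(-config.ndr_width, 0, 0.30)   # trough just upstream of the TSS
        paint(0, 500, 0.54)                 # wide downstream GC peak
        cls = attrs["classes"][i]
        if cls != "unclassified":
            minus1 = 140 if cls == "minus140" else 250
            center = tss - sign * minus1
            lo = max(0, center - 60)
            hi = min(length, center + 61)
            x = np.arange(lo, hi)
            gc[lo:hi] += 0.10 * np.exp(-0.5 * ((x - center) / 40.0) ** 2)
    gc = np.clip(gc, 0.05, 0.95)

    is_sc = rng.random(length) < gc
    pick = rng.integers(0, 2, size=length)
    letters = np.where(is_sc, np.where(pick == 0, "G", "C"),
                       np.where(pick == 0, "A", "T"))

    # plant cis-elements at disjoint upstream slots, manifest-recorded
    def plant(gene, motif_name, rng):
        lo, hi = _MOTIF_SLOTS[motif_name]
        consensus = _MOTIF_CONSENSUS[motif_name]
        m = len(consensus)
        u = int(rng.integers(lo + m, hi + 1))  # motif occupies [-u, -u+m)
        inst = "".join(c if c in "ACGT" else rng.choice(list(_IUPAC_CHOICES[c]))
                       for c in consensus)
        sign = 1 if gene.strand == "+" else -1
        if gene.strand == "+":
            gstart = gene.tss - u
            letters[gstart:gstart + m] = list(inst)
        else:
            gstart = gene.tss + u - m + 1
            rc = inst.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            letters[gstart:gstart + m] = list(rc)
        center_off = -(u - (m - 1) // 2)
        manifest.motifs.append({
            "gene_id": gene.gene_id, "motif": motif_name, "instance": inst,
            "genomic_start": int(gstart), "strand": gene.strand,
            "tss_offset": int(center_off),
            "genomic_center": int(gene.tss + sign * center_off),
        })
        return True

    rng_m = _rng(config, 4)
    for i, gene in enumerate(genes):
        gtype = attrs["types"][i]
        odds_I = config.tata_rate_typeI / max(1e-12, 1 - config.tata_rate_typeI)
        odds = odds_I * (config.tata_odds_typeII if gtype == "II" else 1.0)
        p_tata = odds / (1 + odds)
        has_tata = bool(rng_m.random() < p_tata)
        has = {"TATA": has_tata,
               "P1BS": bool(rng_m.random() < config.p1bs_fraction),
               "G-box": bool(rng_m.random() < config.gbox_fraction),
               "Y-patch": bool(rng_m.random() < config.ypatch_fraction)}
        for name, flag in has.items():
            if flag:
                plant(gene, name, rng_m)
        manifest.genes[gene.gene_id] = {
            "promoter_class": str(attrs["classes"][i]),
            "gene_type": str(gtype),
            "strand": gene.strand,
            "tata": has_tata,
            "motifs": [k for k, v in has.items() if v],
            "de": None,
        }

    genome = GenomeSequence({"chrS": "".join(letters)})
    return genome, genes, manifest


def simulate_tracks(genes: list[GeneModel], config: SimulationConfig,
                    manifest: Optional[TruthManifest] = None,
                    replicate: int = 0):
    """Paired-condition occupancy tracks; treated differs from control only by
    the planted dynamics (plus independent sampling noise).

    ``replicate`` selects an independent noise stream over the same expected
    signal: biological replicates share the architecture and differ only in
    sampling.
    """
    attrs = _assign_gene_attributes(config)
    plan = _nucleosome_plan(config, attrs, genes)
    length = (config.genome_length or config.required_length())
    by_gene = {g.gene_id: g for g in genes}

    # non-nucleosomal landscape: uniform background, attenuated inside the
    # NDR of type I genes; type II genes get delocalised promoter signal
    # that rises from -500 to the -1 dyad, holds level to -30 and tapers to
    # zero at the TSS.  The profile is monotone into the -1 peak flank on
    # purpose: box fills or truncated ramps put step edges near planted
    # dyads and bias their called positions.
    landscape = np.full(length, config.background)
    h0 = config.nuc_mass / (config.kernel_sd * np.sqrt(2 * np.pi))
    for i, gene in enumerate(genes):
        sign = 1 if gene.strand == "+" else -1
        tss = gene.tss
        if attrs["types"][i] == "I":
            # the NDR is the depleted zone between the -1 and +1 nucleosomes;
            # its upstream edge stops 30 bp short of the -1 dyad so the
            # attenuation step never sits under a planted kernel
            cls = attrs["classes"][i]
            minus1 = {"minus140": 140, "minus250": 250}.get(cls)
            ndr_span = (minus1 - 30) if minus1 else config.ndr_width
            a, b = tss + sign * -ndr_span, tss
            lo, hi = (a, b) if a <= b else (b + 1, a + 1)
            landscape[max(0, lo):min(length, hi)] *= config.ndr_attenuation
        else:
            # class-independent shape: rise over [-740,-660] (clear of every
            # planted upstream dyad), flat plateau to -30, taper to the TSS.
            # A slope under a dyad kernel biases its called position, and a
            # class-dependent baseline would break the antiphase-subset
            # pooling geometry, so both are avoided by construction.
            offs = np.arange(-740, 0)
            fill = np.empty(offs.shape)
            level = config.promoter_fill * h0
            rise = offs <= -660
            fill[rise] = level * (offs[rise] + 740) / 80.0
            fill[(offs > -660) & (offs <= -30)] = level
            tail = offs > -30
            fill[tail] = level * (-offs[tail]) / 30.0
            pos = tss + sign * offs
            ok = (pos >= 0) & (pos < length)
            landscape[pos[ok]] += fill[ok]

    control = landscape.copy()
    treated = landscape.copy()
    for entry in plan:
        gene = by_gene[entry["gene_id"]]
        sign = 1 if gene.strand == "+" else -1
        _add_kernel(control, entry["dyad"], entry["sd"], entry["mass"])
        dyad_t, sd_t, mass_t = entry["dyad"], entry["sd"], entry["mass"]
        dyn = entry["dynamic"]
        if dyn:
            if dyn["kind"] == "shift":
                dyad_t = entry["dyad"] + sign * dyn["magnitude"]
            elif dyn["kind"] == "occupancy":
                mass_t = entry["mass"] * dyn["factor"]
            elif dyn["kind"] == "fuzziness":
                sd_t = entry["sd"] * dyn["factor"]
        _add_kernel(treated, dyad_t, sd_t, mass_t)
        entry = dict(entry)
        entry["treated_dyad"] = int(round(dyad_t))
        entry["treated_sd"] = float(sd_t)
        entry["treated_mass"] = float(mass_t)
        if manifest is not None:
            manifest.nucleosomes.append(_manifest_nucleosome(entry))

    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, 5, replicate)))
    if config.noise_sd > 0:
        control = np.clip(control + rng.normal(0, config.noise_sd, length), 0, None)
        treated = np.clip(treated + rng.normal(0, config.noise_sd, length), 0, None)
    if config.poisson:
        control = rng.poisson(control).astype(float)
        treated = rng.poisson(treated).astype(float)

    if manifest is None:
        manifest = TruthManifest()
        for entry in plan:
            manifest.nucleosomes.append(_manifest_nucleosome(entry))
    return (OccupancyTrack({"chrS": control}),
            OccupancyTrack({"chrS": treated}),
            manifest)


def _manifest_nucleosome(entry: dict) -> dict:
    out = {
        "gene_id": entry["gene_id"], "role": entry["role"],
        "index": int(entry["index"]), "dyad": int(entry["dyad"]),
        "mass": float(entry["mass"]), "sd": float(entry["sd"]),
        "dynamic": entry["dynamic"],
    }
    for k in ("treated_dyad", "treated_sd", "treated_mass"):
        if k in entry:
            out[k] = entry[k]
    return out


def simulate_counts(genes: list[GeneModel], config: SimulationConfig,
                    manifest: Optional[TruthManifest] = None):
    """Intron/exon count tables (2 conditions x ``n_replicates``) with planted
    intron-count DE, preferentially at genes carrying planted dynamics."""
    from .intron_de import CountTable  # local import to avoid a cycle

    attrs = _assign_gene_attributes(config)
    rng = _rng(config, 6)
    n = len(genes)
    gene_ids = [g.gene_id for g in genes]
    mu_intron = rng.lognormal(np.log(config.intron_mean), config.expr_sigma, n)
    mu_exon = mu_intron * config.exon_to_intron

    dyn_genes = {genes[i].gene_id for i in attrs["dynamics"]}
    n_de = int(round(config.de_fraction * n))
    weights = np.array([config.de_dynamic_odds if g in dyn_genes else 1.0
                        for g in gene_ids])
    de_idx = (rng.choice(n, size=n_de, replace=False, p=weights / weights.sum())
              if n_de else np.array([], dtype=int))
    lfc = np.zeros(n)
    signs = np.where(rng.random(n_de) < 0.5, 1.0, -1.0)
    lfc[de_idx] = signs * config.de_log2fc

    no_intron = np.array([len(g.introns) == 0 for g in genes])
    de_on_exons = no_intron & (lfc != 0)
    if de_on_exons.any():
        log.warning("%d DE genes lack introns; DE planted on exon counts",
                    int(de_on_exons.sum()))

    reps = config.n_replicates
    samples = ([f"control_{r + 1}" for r in range(reps)]
               + [f"treated_{r + 1}" for r in range(reps)])
    sf = np.asarray(config.size_factors[:2 * reps], dtype=float)
    if len(sf) < 2 * reps:
        sf = np.concatenate([sf, np.ones(2 * reps - len(sf))])

    def draw(mean):
        mean = np.maximum(mean, 1e-12)
        if config.nb_dispersion < 1e-8:
            return rng.poisson(mean)
        r = 1.0 / config.nb_dispersion
        p = r / (r + mean)
        return rng.negative_binomial(r, p)

    intron = np.zeros((n, 2 * reps), dtype=int)
    exon = np.zeros((n, 2 * reps), dtype=int)
    for j, name in enumerate(samples):
        treated = name.startswith("treated")
        fold = 2.0 ** lfc if treated else np.ones(n)
        mi = mu_intron * fold * sf[j]
        me = mu_exon * np.where(de_on_exons, fold, 1.0) * sf[j]
        mi = np.where(no_intron, 0.0, mi)
        intron[:, j] = draw(mi)
        exon[:, j] = draw(me)

    table = CountTable(
        intron=pd.DataFrame(intron, index=gene_ids, columns=samples),
        exon=pd.DataFrame(exon, index=gene_ids, columns=samples),
        design=pd.DataFrame({
            "condition": ["control"] * reps + ["treated"] * reps,
            "replicate": list(range(1, reps + 1)) * 2,
        }, index=samples),
    )

    if manifest is None:
        manifest = TruthManifest()
    for i, gid in enumerate(gene_ids):
        info = manifest.genes.setdefault(gid, {})
        if lfc[i] != 0:
            info["de"] = {"direction": "up" if lfc[i] > 0 else "down",
                          "log2fc": float(lfc[i]),
                          "on_exons": bool(de_on_exons[i])}
        else:
            info.setdefault("de", None)
    return table, manifest


def simulate_study(config: SimulationConfig):
    """Convenience: genome + annotation + tracks + counts + one manifest."""
    genome, genes, manifest = simulate_genome(config)
    control, treated, manifest = simulate_tracks(genes, config, manifest)
    counts, manifest = simulate_counts(genes, config, manifest)
    return genome, genes, control, treated, counts, manifest
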