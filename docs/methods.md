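# Methods

`nucdyn` analyses paired-condition nucleosome-occupancy tracks (MNase-seq
style per-base coverage) together with gene annotation, genome sequence and
intron/exon read-count tables. This note describes the models and
procedures, the synthetic data they are validated against, the parameters
that matter, and the numerical choices made where the design was open.

## Occupancy model and coordinate conventions

All coordinates are 0-based half-open internally; GFF3 (1-based closed) is
converted at the I/O boundary. The TSS of a plus-strand gene is `start`, of
a minus-strand gene `end − 1`; "upstream/downstream" always means
transcript orientation. Occupancy tracks are per-base non-negative signals;
`library_scale` records the factor between stored values and raw read
counts (1.0 for the synthetic tracks, whose conditions share expected
depth by construction).

## Metagene profiling

Profile matrices are built by slicing a window around each anchor (TSS,
TTS, exon 5′ boundary, motif center), coordinate-reversing minus-strand
rows, and averaging the per-base signal within fixed-width bins (default
10 bp — fine enough to resolve 50-bp dyad shifts). Window bases off the
contig are flagged missing and excluded from averages; zero-padding would
bias flank means downward. Gene bodies are rescaled to a fixed number of
segments by exact cumulative-sum interpolation, with flanks kept in native
bp. Quintile stratification is rank-based with stable tie-breaking; the
direction is an explicit parameter because GC quintiles are conventionally
numbered lowest-first while expression quintiles are numbered
highest-first.

**Array amplitude.** The "peak-to-trough amplitude" of a phased array is
measured as the largest difference between a local maximum and an adjacent
*internal* trough (a minimum flanked by peaks on both sides), with 5%
prominence filtering. The global max−min over a window is *not* a phasing
measure: any profile that falls to a common floor inside the window (e.g.
between the −1 position and the NDR) pins the pooled/subset ratio of two
antiphase cohorts at exactly ½ regardless of how completely their
oscillations cancel.

## Nucleosome calling

The caller Gaussian-smooths the track and accepts local maxima above a
height threshold greedily in height order, subject to a minimum dyad
spacing. Per call: occupancy = smoothed summit height; fuzziness =
signal-weighted SD of position within the footprint (dyad ± 75 bp); mass =
raw signal sum over the footprint.

Defaults are set by the resolution the shift classification requires:

* `smooth_sd = 12 bp`. The effective peak SD is
  √(kernel² + smooth²); at 20-bp smoothing the overlapping-tail pull
  between peaks ~85 bp apart biases measured displacements of 93–95 bp
  shifts past the upper class bound. At 12 bp the bias stays below
  ~0.5 bp.
* `min_distance = 75 bp`. A dyad shifted by s bp within a 180-bp array
  lands 180−s ≥ 85 bp from its unshifted neighbour (less a few bp of
  mutual pull); calls that close must coexist or large shifts merge into
  single calls and become unrecoverable.
* `min_height = 0.5 ×` genome-wide mean signal; `half_width = 75 bp`.

**Fuzziness truncation bias.** The ±75-bp footprint truncates wide
kernels: a 25-bp kernel is measured at ≈24.7 bp but a 50-bp kernel at
≈37 bp (ratio 1.5, not 2). Fuzziness *comparisons* between conditions are
unaffected (both sides truncate identically); absolute fuzziness values
saturate above ~40 bp.

## Dynamic-nucleosome classification

Calls from the two conditions are paired per sequence by mutual-nearest-
neighbour matching within 100 bp, iterated on the leftovers (equivalently:
candidate pairs accepted greedily by distance). Iteration matters because
a dyad shifted by more than half the spacing sits closer to its
neighbour's twin than to its own. Unpaired calls are gain/loss candidates.

A pair can carry any of three classes (multiple allowed):

* **Position shift** — 50 ≤ |Δdyad| ≤ 95 bp (closed bounds). The sign is
  reported 5′→3′ using the strand of the gene whose related region
  (TSS−1000 … TTS+200) contains the dyad; intergenic dyads use genomic
  orientation and are flagged.
* **Occupancy change** — conditional binomial test: given the summed
  footprint masses m_c + m_t (rounded to the read-count scale), the
  treated share is Binomial(m_c+m_t, ½) under no change; two-sided p,
  BH-adjusted across pairs, class at FDR < 0.05. Masses are divided by
  `library_scale` first: the binomial split is calibrated for Poisson
  counts, and applying it to values scaled above the count scale would be
  anti-conservative.
* **Fuzziness change** — two-sided F test on the squared weighted-SD
  ratio with effective degrees of freedom equal to the footprint masses,
  BH-adjusted separately from the occupancy family (the two families are
  reported at separate FDRs).

Region rates assign each dyad to exactly one class by precedence
exon > intron > promoter bins (0–200, 200–500, 500–1000 bp upstream) >
TTS+200 > intergenic, and report dynamics per kb per 100 nucleosomes.
UTRs are not split out: the gene model carries exon structure but no CDS,
so UTR boundaries are not derivable.

## Gene classification by TSS architecture

* **−1 subsets.** The −1 nucleosome is the highest local maximum in
  [−400, −50] exceeding 10% of the row maximum; genes are binned at
  −140 ± 25 and −250 ± 25 bp (the point positions carry ±25-bp bins
  because profile rows are binned).
* **k-means.** Rows are divided by their mean before clustering (shape,
  not depth, should drive clusters); k-means++ with 10 restarts and a
  fixed seed; clusters renamed A, B, … by decreasing size so labels are
  reproducible.
* **Type I/II.** Because cluster labels are arbitrary under reseeding,
  the housekeeping-like/stress-responsive-like split is re-derived from
  centroid geometry: type I iff mean over [−200, −50] < 0.8 × mean over
  [+50, +300] (an NDR in place of a −1 nucleosome). The rule is scale-
  invariant.
* **TATA association** is the rate ratio of TATA presence (type II over
  type I) with a two-sided Fisher's exact p.

## Intron-count differential transcription

Intronic read abundance tracks nascent transcription; the test operates on
intron counts with exon counts kept for FPKM. The engine is self-contained:
median-of-ratios size factors; per-gene method-of-moments NB dispersion
(floored at 1e−8) shrunk 75% toward a trended fit α(μ) = a₀ + a₁/μ
(non-negative least squares) — with 2+2 replicates the per-gene moment
estimate is essentially noise, so heavy shrinkage is what keeps the Wald
test calibrated; Wald z on log2 fold change with delta-method SE
(1/μ + α)/n per condition and a 0.5 pseudocount; BH across testable genes
(genes with any nonzero intron count). Calls: up/down iff padj < 0.05 with
the matching sign. Read-to-feature assignment: a read is intron-assigned
iff it overlaps intronic bases of exactly one gene and no exonic bases;
junction reads are exon-assigned; multi-gene reads are dropped and
counted.

## Resampling enrichment (dynamics at DEGs)

A gene "carries" a dynamic class when ≥1 qualifying dynamic dyad lies in
its gene-related region (TSS−1000 … TTS+200). For the DEG set, the null
is n_iter (default 10,000) equal-size uniform draws without replacement
from the testable-gene universe; the same draws serve all classes.
Reported per class: observed carrier proportion, null mean ± SD, the
empirical p (1 + #{null ≥ observed})/(n_iter + 1), and a two-sided exact
binomial p of the observed count against the class prevalence — the
phrase "binomial test with N iterations" admits either reading, so both
are computed. Directional classes are also collapsed to their kinds
(shift/occupancy/fuzziness) for carrier sets, since a gene-level coupling
hypothesis is direction-free. Drawing from the testable universe rather
than all annotated genes avoids trivial enrichment through expression
status.

## Synthetic data: what it emulates, and what it does not

The generator plants, per gene: phased downstream arrays (+1 at +90 bp,
repeat length 180 bp, Gaussian dyad kernels of SD 25 bp, occupancy
decaying 0.85×/position), an antiphase promoter architecture (−1 at −140
or −250 bp with upstream arrays at 0.75×/position decay and intrinsically
fuzzier kernels, 1.3×SD — upstream phasing is weaker than genic phasing,
and this is also what lets pooled antiphase cohorts cancel), and one of
two TSS archetypes: type I with an NDR (the depleted zone between −1 and
+1; background attenuated to 5%, −1 mass reduced to 30%) or type II with
a full −1 plus delocalised promoter signal (a ramp/plateau shape common to
both promoter classes; slopes are kept clear of every planted dyad because
a gradient under a kernel biases its called position). Planted dynamics
modify single mid-array nucleosomes (+3 for shifts — uniform 50–95 bp,
either direction; +2 for occupancy ×2 or ×½; +4 for fuzziness ×2 or ×½);
mid-array placement keeps shifted dyads off the promoter slopes. Sequence
is drawn base-wise with GC probability tracking the occupancy landscape
(trough upstream of the TSS, elevated first 500 bp downstream, a bump
under the −1) and cis-elements (TATA, Y-patch, G-box, P1BS) are planted in
disjoint upstream slots, TATA with 3× odds in type II genes. Counts are
negative-binomial (dispersion 0.05, lognormal expression with median
intron mean 200) with DE planted on intron counts (log2FC ±2) and DE genes
drawn with a configurable odds multiplier toward dynamics-carrying genes.
Noise is per-base Poisson sampling (optionally plus Gaussian); replicates
share the architecture and differ only in the sampling stream. One seed
fixes everything; emitted files are byte-identical across reruns.

Not emulated: MNase sequence bias, fragment-length structure, chromatin
heterogeneity between cells, batch effects between replicates, overlapping
genes, alternative isoforms. Passing tests therefore demonstrate that the
pipeline recovers planted structure under a clean generative model — not
that it is robust to every artefact of real chromatin data. One deliberate
consequence of the clean model: delocalised promoter signal plus Poisson
noise yields extra low-occupancy "fuzzy" calls on type II promoters, which
behave as calibrated stable pairs downstream.

## Problem sizes

Validation runs use 60–300 genes (~0.4–1.9 Mb genomes, 8–16 planted
nucleosomes per gene), 2000-gene count tables over 50 seeds for null
calibration, and 400 replicate simulations for the resampling-p
calibration; these sizes give stable estimates for every reported
quantity while keeping a full validation run in minutes on one CPU.

## Known limitations

* Fuzziness saturates above ~40 bp (footprint truncation, above).
* Shifts of exactly 95 bp sit on the closed class bound; the few-bp
  measurement pull near a neighbour can push them just outside, so
  recovery is quoted over the full 50–95 bp range rather than per
  magnitude.
* The caller's binomial occupancy test assumes count-scale masses; tracks
  normalised far above the count scale should be rescaled first.
* `de_test` requires ≥2 replicates per condition; with exactly 2 the test
  leans on the trended dispersion fit.
* The synthetic genome is gene-sparse (long empty flanks); genome-wide
  correlation summaries are computed over gene-related regions for this
  reason.
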