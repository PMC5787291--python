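# nucdyn

Nucleosome-pattern analysis of paired-condition occupancy tracks, for
chromatin biologists studying how nucleosome organisation around genes
changes under a perturbation (e.g. nutrient starvation) and whether those
changes track transcriptional changes.

Given per-base MNase-seq-style occupancy tracks for two conditions, gene
annotation, genome sequence and intron/exon read-count tables, the package

* builds strand-oriented metagene profiles (TSS, TTS, scaled gene body,
  exon boundaries, motif centers) with GC/expression quintile
  stratification;
* classifies genes by TSS nucleosome architecture: −1-nucleosome position
  subsets (−140/−250 bp antiphase classes), k-means profile clusters, and
  a type I (NDR, housekeeping-like) vs type II (−1-occupied,
  stress-responsive-like) split, plus TATA-box association;
* calls nucleosomes (dyad, occupancy, fuzziness) and classifies dynamic
  nucleosomes between conditions into position shift (50–95 bp),
  occupancy change (FDR < 0.05) and fuzziness change (FDR < 0.05), with
  per-region rates;
* scans IUPAC cis-elements (TATA `CTATAWAWA`, P1BS `GNATATNC`, G-box
  `CACGTG`, Y-patch `CYTCYYCCYC`) and compares occupancy at their sites;
* tests differential transcription on intron counts with a
  negative-binomial Wald test (BH-adjusted);
* measures enrichment of dynamic nucleosomes at differentially expressed
  genes against a resampled null of equal-size random gene sets.

A synthetic-data generator plants all of this structure with a recorded
truth manifest, so every stage is validated end-to-end against known
ground truth. See `docs/methods.md` for models, statistics and parameter
rationale.

## The statistics at the core

For a nucleosome pair with footprint signal masses m_c (control) and m_t
(treated), the occupancy test is the conditional binomial

> p = two-sided tail of Binomial(m_c + m_t, ½) at m_t,

BH-adjusted across pairs. Fuzziness (signal-weighted SD of position within
the dyad ± 75 bp footprint) is compared by a two-sided F test on the
variance ratio with effective df equal to the masses. For DEG enrichment,
with D the DEG set and c(g) the indicator that gene g carries a dynamic
nucleosome of a class in its gene-related region (TSS−1000 … TTS+200),

> observed = mean c(g) over D, null = the same over 10,000 uniform
> same-size draws from the testable universe; empirical
> p = (1 + #{null ≥ observed}) / (n_iter + 1),

alongside an exact binomial p against the class prevalence.

## Worked example

Run the one-command synthetic demo (300 genes, planted shifts, occupancy
and fuzziness changes on 90 genes, 20% of genes differentially
transcribed with 5× odds toward dynamics carriers):

```sh
nucdyn run --outdir demo --seed 7
```

This writes the study (`genome.fa`, `genes.gff3`, four bedGraphs, count
tables, `truth_manifest.json`) and all analysis artifacts to `demo/`,
ending with a summary (abridged):

```
callnucs:  control_calls 2745, treated_calls 2752
dynamics:  2574 pairs, 688 dynamic, 178 gain, 171 loss
cluster:   minus140 137, minus250 150; types A,B -> II, C..F -> I
de:        34 up, 27 down of 300 testable
motifs:    tata_fold_typeII 2.00 (Fisher p 0.0100), 711 P1BS hits
enrich shift:     obs 0.525  null 0.313 +- 0.053  empirical_p 1e-4
enrich occupancy: obs 0.689  null 0.440 +- 0.057  empirical_p 1e-4
enrich fuzziness: obs 0.607  null 0.353 +- 0.055  empirical_p 1e-4
```

Reading this: the caller recovers ~9 nucleosomes per gene; 688 of 2574
matched pairs change significantly between conditions; genes split into
the two antiphase promoter classes and the two architecture types, with
TATA boxes twice as frequent upstream of type II genes; 61 genes change
intronic transcription; and differentially expressed genes carry dynamic
nucleosomes of each kind far more often than equally sized random gene
sets (4–4.6 null SDs above the null mean), reproducing the planted
DE↔dynamics coupling.

Individual stages are available as subcommands (`nucdyn simulate`,
`profile`, `callnucs`, `dynamics`, `cluster`, `motifs`, `de`, `enrich`)
and as library functions (`nucdyn.call_nucleosomes`,
`nucdyn.classify_dynamics`, `nucdyn.de_test`,
`nucdyn.resample_enrichment`, …).

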