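# Methods

`plasmatrace` implements a tumor-informed strategy for monitoring minimal
residual disease from blood plasma: a patient's own tumor/germline exome
comparison nominates somatic single-nucleotide variants (SNVs), a small
personalized amplicon panel tracks those SNVs in cell-free DNA (cfDNA) with
unique-molecular-identifier (UMI) error correction, and the resulting
mutated-tumor-molecule (MTM) counts are turned into a longitudinal ctDNA
readout per patient. This note records the model, the defaults, and the
design choices, in the package's own terms.

## Quantification model

A plasma sample's ctDNA level is

```
MTM/mL = (Σ_assays mutant consensus reads) / plasma volume [mL]
```

where a *consensus read* is the collapsed sequence of a UMI family with at
least `min_family_size = 3` members, and a *mutant* consensus read carries
the targeted alternate base. Statuses partition every sample:

* `excluded` — fewer than `qc_min_consensus = 400` consensus reads summed
  over all assays (QC failure; takes precedence over everything else);
* `positive` — MTM/mL ≥ `positivity_mtm_per_ml = 1.0`;
* `trace` — 0 < MTM/mL < threshold (the "trace" band is a convention of
  this package: figures in the literature mark such samples distinctly
  without defining a numeric band);
* `negative` — zero MTM.

Positivity is thresholded on the concentration (MTM/mL) rather than on a
raw read count so that plasma volumes other than 4 mL behave consistently;
at the standard 4 mL input the two rules coincide (4 mutant reads ⇔
1 MTM/mL). MTM counts are integers; MTM/mL is never rounded before
thresholding.

Because library preparation attaches on average two barcodes to each input
molecule, the number of *original* mutated molecules is estimated as MTM/2
and reported alongside (never instead of) MTM.

The limit of detection is the minimum mutant-read requirement over the
typical per-sample consensus depth, `LOD% = 100 · 4 / median_depth`,
reported to two significant figures (e.g. 0.026% at a median of 15,463
consensus reads per sample).

## Panel design

Candidates pass iff tumor VAF > 0.10 (strict), tumor alternate depth ≥ 10,
germline alternate reads ≤ 1, and germline depth ≥ 30. The depth floor is
this package's safeguard: retrospectively identified germline contaminants
tend to have under-sequenced germline compartments, so a floor blocks the
low-depth escape class while the ≤ 1-alt-read rule (with an optional strict
0-read mode via `max_germline_alt=0`) addresses the rest. Ranking is
oncogenic-first, then tumor VAF descending, then (chrom, pos) ascending — a
declared total order, so selection is permutation-invariant; the top ten
become the panel. Manual IGV-style review is replaced by the deterministic
rules plus a per-candidate selection log. Amplicon windows default to 91 bp
centered on the target and must lie in [75, 105] bp (cfDNA fragments are
short).

## UMI consensus

Reads are `UMI (12 nt) + fixed 8 nt anchor + amplicon payload`, assigned to
assays alignment-free by a 16-base payload prefix (exact, then unique
1-mismatch). Families group by (target, exact UMI); then small families are
absorbed directionally into a family whose UMI is within Hamming distance 1
when the small/large size ratio is ≤ 0.1 — processing order is (size
descending, UMI lexicographic), the parent is the largest candidate (ties:
lexicographically smallest UMI), and ratios use the original exact-UMI
sizes, so the partition is deterministic and order-independent. The merge
threshold is exposed as configuration since published pipelines delegate
this step to their correction tool without stating parameters.

Consensus calls the most frequent base per position when its fraction is
≥ 0.75, otherwise `N`; ties give `N`. The 0.75 threshold is chosen so that
a single dissenting read in a family of 3–4 cannot flip a base. Members
whose length differs from the modal family length are dropped before
calling (chimera guard), and the size floor applies after that drop.
Counting is by fixed offset within the payload (no indels are modelled; a
BAM-based path is out of scope).

## Germline flagging

An inherited heterozygous variant sits near 50% allele fraction in plasma
regardless of tumor burden. A panel SNV is retrospectively flagged germline
when, over all non-excluded samples: the series has ≥ 4 points, every
consensus VAF is ≥ 0.20, and the coefficient of variation (sample SD /
mean) is ≤ 0.25. These thresholds are declared conventions — the
qualitative criterion in the literature is "consistent levels" — and are
exposed as parameters. Flagged SNVs are removed from every sample's counts
and the course is re-classified from the remaining assays, so corrected
MTM/mL can only decrease; QC re-uses the remaining assays' depth. Series
shorter than 4 passing samples are reported indeterminate, never flagged.
A true somatic variant under primary-resistant disease with tumor fraction
high enough that VAF stays ≥ 0.20 throughout would satisfy the same
criterion; this is an intrinsic ambiguity of the "consistent levels" idea,
not an implementation artifact.

## Tumor volume and correlations

Volume uses the ellipsoid approximation V = (π/6)·d1·d2·d3 in the input
diameter unit cubed. One missing diameter is imputed as the mean of the two
known; two missing assume a sphere. Spearman correlations use mid-ranks for
ties; p-values are exact permutation enumerations for n ≤ 9 and the t
approximation above that, reported descriptively without multiple-testing
correction.

## Synthetic cohort generator

The generator exists so every downstream operation can be validated against
known truth without restricted clinical data. Its defaults are the study
conditions the package models: 12 patients, 16–145 candidate SNVs per
patient, panels of ten, ~1,537 consensus reads per assay, 4 mL plasma,
2 metastatic patients, 3 disguised germline variants cohort-wide.

* **Mutant-fraction model.** Heterozygous diploid tumor without copy-number
  change: a sample at tumor fraction `f` carries each somatic variant on a
  fraction `f/2` of its cfDNA molecules; germline variants sit at 0.5
  independent of `f`. This closed form is what recovery tests score
  against.
* **Candidate tables.** Each candidate is independently "intended to pass"
  the panel filters with probability `pass_probability = 0.65`;
  intended-fail candidates violate exactly one randomly chosen rule. If a
  draw leaves fewer passing candidates than the panel size, the shortfall
  is converted to passes so every simulated patient is assay-designable
  (every study patient yielded a full panel). Somatic VAFs are drawn under
  tumor purity 0.8 (≤ 0.42), while disguised germline variants sit at ~0.5
  with one stray alternate germline read at depth ~120 — they pass the
  filters and deterministically out-rank somatic candidates, mirroring how
  purity dilutes somatic but not germline allele fractions.
* **Reads.** Per assay, enough molecules are drawn that surviving UMI
  families match the target consensus depth; each molecule founds exactly
  two UMI families (mean two barcodes per molecule, taken literally);
  family sizes are 1 + Poisson(mean − 1) with `family_size_mean = 5` (the
  distribution is not stated anywhere; this is a placeholder exposed in
  config, as is the 12 nt UMI length). Molecule-level errors
  (`e_molecule = 1e-5`, e.g. first-cycle polymerase or DNA damage) are
  applied once per molecule and survive consensus; read-level errors
  (`e_read = 0.002`, sequencer scale) are applied per read and are removed
  by consensus. Qualities are constant Q30 and unused.
* **Trajectories.** Three shapes over 180 days: responder (decline to 0),
  relapse (decline, nadir, re-rise), resistant (plateau ~0.3; doubled for
  metastatic patients). cfDNA concentration (6 + 2500·f ng/mL) and tumor
  diameters (sphere of volume 400·f cm³) are monotone in `f` with optional
  multiplicative lognormal noise (defaults 0.15 and 0.05), so at zero noise
  their ranks recover `f`'s exactly.
* **Counts shortcut.** `simulate_consensus_counts` draws surviving-family
  and mutant-family counts directly from the binomial laws the read
  simulator follows, without error channels — used for cohort-scale checks
  where read-level error behavior is exercised elsewhere.

What the generator does *not* emulate: cfDNA fragment-size profiles, GC
bias, indels/CNVs/fusions, paired-end structure, base-quality variation,
position-specific error hotspots, or the real hairpin read structure.
Passing tests therefore demonstrate correctness of the pipeline's logic and
its statistical behavior under the declared error model, not robustness to
every artifact of real sequencing.

## Problem sizes and numerics

Tests run the read-level pipeline at consensus depths of 120–1,500 per
assay and the cohort-scale germline-recovery check at depth 600 via the
counts shortcut; these sizes give the binomial standard errors the
assertions use while keeping the suite quick. Recovery assertions use
3-standard-error bands; the error-suppression check compares against the
closed-form binomial tail P(Binom(5, e) ≥ 4) for a wrong majority.
Degenerate inputs are defined explicitly: empty candidate lists warn and
return empty; constant series make Spearman's r undefined (reported, not
raised); zero-depth targets have undefined consensus VAF and contribute
nothing to germline evidence; ties in consensus calling resolve to `N`;
modal-length ties resolve to the shorter length.
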