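# plasmatrace

Tumor-informed monitoring of circulating tumor DNA (ctDNA) from
ultra-deep UMI amplicon sequencing.

## What it does, and for whom

In solid tumors — the motivating setting is pediatric rhabdomyosarcoma —
treatment response and relapse can be tracked from blood plasma: a small
fraction of cell-free DNA (cfDNA) originates from tumor cells and carries
the tumor's somatic mutations. `plasmatrace` implements the
*tumor-informed* version of this analysis for bioinformaticians building or
validating such pipelines:

1. **Panel design** — from paired tumor/germline exome variant evidence,
   select up to ten patient-specific single-nucleotide variants (SNVs):
   tumor VAF > 10%, alternate depth ≥ 10, ≤ 1 alternate germline read, and a
   germline depth floor guarding against inherited variants in disguise.
2. **UMI consensus** — collapse reads sharing a unique molecular identifier
   (UMI) into error-corrected consensus reads (family size ≥ 3, 75%
   majority per base), so sequencer errors scattered across reads vanish
   while true molecule variants remain.
3. **Quantification** — a mutated tumor molecule (MTM) is a consensus read
   carrying a targeted SNV. The ctDNA level is

   `MTM/mL = Σ mutant consensus reads / plasma volume`,

   with samples classified excluded (< 400 consensus reads across assays),
   positive (≥ 1 MTM/mL), trace, or negative; original molecule count
   ≈ MTM/2 (two barcodes per input molecule); limit of detection
   = 100 · 4 / median consensus depth (0.026% at a median of 15,463).
4. **Longitudinal reporting** — retrospective flagging of germline SNVs
   (high, flat VAF series), ellipsoid tumor volume V = (π/6)·d1·d2·d3 with
   standard imputation, Spearman correlations with exact small-n permutation
   p-values, cohort summaries and per-patient trajectories.
5. **Synthetic cohorts** — a ground-truth generator (variant tables,
   sample sheets, tumor measurements, UMI-tagged FASTQ) with the
   statistical structure the analysis assumes, so everything above is
   testable without restricted clinical data.

See `docs/methods.md` for the model, defaults and design decisions.

## Worked example

```python
import numpy as np
from plasmatrace import (
    SimConfig, design_panel, build_assays, simulate_sample_reads,
    process_sample, classify_sample, compute_lod, simulate_wes_variant_table,
)
from plasmatrace.panel_design import candidates_from_frame
from plasmatrace.synthetic_cohort import write_fastq

config = SimConfig(seed=7, target_consensus_depth=400)
rng = np.random.default_rng(7)

# 1. tumor/germline exome comparison -> candidate SNVs -> ten-target panel
table, truth = simulate_wes_variant_table(config, "P01", rng=rng)
panel = design_panel(candidates_from_frame(table), patient_id="P01")
print(f"{len(table)} candidates -> panel of {len(panel.targets)} SNVs")

# 2. one plasma sample at tumor fraction 0.04, sequenced and consensus-called
assays = build_assays(panel, config, rng)
reads = simulate_sample_reads(assays, f=0.04, config=config, rng=rng)
write_fastq(reads, "P01_d0.fastq")
counts, diag = process_sample(
    "P01_d0.fastq", panel, {t: a.sequence for t, a in assays.items()}
)
print(f"{diag['n_reads']} reads -> {diag['n_consensus']} consensus reads")

# 3. quantify
quant = classify_sample(counts, plasma_volume_ml=4.0, patient_id="P01")
print(f"MTM={quant.mtm_total}  MTM/mL={quant.mtm_per_ml:.2f}  "
      f"est. molecules={quant.est_molecules:.0f}  status={quant.status}")
print(f"assay LOD at this depth: {compute_lod(4, quant.total_consensus_all_assays)}%")
```

Output:

```
138 candidates -> panel of 10 SNVs
21833 reads -> 3973 consensus reads
MTM=64  MTM/mL=16.00  est. molecules=32  status=positive
assay LOD at this depth: 0.1%
```

Reading it: of 138 candidate SNVs from the simulated exome comparison, ten
passed the filters and were selected. The sample's ~21.8k raw reads
collapsed to ~4k error-corrected consensus reads across the ten assays
(~400 per assay, as configured). At a true tumor fraction of 4%, each
somatic target is mutated on ~2% of molecules, yielding 64 MTM in 4 mL of
plasma — 16 MTM/mL, well above the 1 MTM/mL positivity threshold — and an
estimated 32 original mutated molecules. At this (deliberately shallow)
depth the detection limit is 0.1%; at production depth (~15,000 consensus
reads/sample) it is 0.026%.

The same workflow is available from the shell:

```bash
plasmatrace simulate --seed 7 --n-patients 2 --consensus-depth 120 --out fx/
plasmatrace design-panel --candidates fx/P01_variants.tsv --patient-id P01 --out panel.tsv
plasmatrace consensus --fastq fx/P01_d000.fastq --panel fx/P01_panel.tsv \
    --assays fx/P01_assays.tsv --out counts.tsv
plasmatrace quantify --counts counts.tsv --plasma-volume 4.0 --out quant.json
plasmatrace report --fixture fx/ --out report/
```

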