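"""Sample-level ctDNA quantification: MTM/mL, positivity and limit of detection.

The ctDNA level of a plasma sample is the total number of mutated tumor
molecules (MTM — consensus reads carrying a targeted somatic variant) across
all assays, divided by the plasma volume in mL.  A sample is:

* ``excluded``  — total consensus depth across all assays below the QC floor
  (default 400), regardless of its MTM count;
* ``positive``  — MTM/mL at or above the positivity threshold (default 1.0;
  with 4 mL plasma this is the familiar 4-mutant-read rule);
* ``trace``     — some MTM observed but below the positivity threshold;
* ``negative``  — no MTM at all.

Because the library preparation tags each original molecule with on average
two barcodes, the number of original mutated molecules is roughly half the
MTM value; that estimate is reported alongside, never instead of, MTM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .umi_consensus import ConsensusCounts

QC_MIN_CONSENSUS = 400
POSITIVITY_MTM_PER_ML = 1.0

STATUSES = ("excluded", "negative", "trace", "positive")


@dataclass
class SampleQuantification:
    """The per-sample readout: counts, concentration, QC status, call."""

    patient_id: str
    day: float
    plasma_volume_ml: float
    total_consensus_all_assays: int
    mtm_total: int
    mtm_per_ml: float
    est_molecules: float
    status: str
    per_target: dict[str, ConsensusCounts] = field(default_factory=dict)

    @property
    def excluded(self) -> bool:
        return self.status == "excluded"

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "day": self.day,
            "plasma_volume_ml": self.plasma_volume_ml,
            "total_consensus_all_assays": self.total_consensus_all_assays,
            "mtm_total": self.mtm_total,
            "mtm_per_ml": self.mtm_per_ml,
            "est_molecules": self.est_molecules,
            "status": self.status,
        }


@dataclass
class AssayPerformance:
    """Detection floor of the assay given its typical consensus depth."""

    median_consensus_per_sample: float
    min_mutant_reads: int = 4

    @property
    def lod_fraction(self) -> float:
        """Limit of detection as a percentage, to 2 significant figures."""
        return compute_lod(self.min_mutant_reads, self.median_consensus_per_sample)


def mtm_per_ml(mtm_total: int, plasma_volume_ml: float) -> float:
    """MTM per mL plasma: the exact ratio, no rounding."""
    if plasma_volume_ml <= 0:
        raise ValueError("plasma volume must be positive")
    if mtm_total < 0:
        raise ValueError("mtm_total must be non-negative")
    return mtm_total / plasma_volume_ml


def estimate_molecules(mtm_total: int) -> float:
    """Estimated original mutated molecules: half the MTM count.

    The assay attaches on average two barcodes per input molecule, so each
    original molecule yields on average two UMI families.
    """
    if mtm_total < 0:
        raise ValueError("mtm_total must be non-negative")
    return mtm_total / 2


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def compute_lod(min_mutant_reads: int, median_consensus_per_sample: float) -> float:
    """Limit of detection as a percentage of consensus reads.

    The smallest reportable mutant fraction is the minimum mutant-read
    requirement over the typical total consensus depth per sample; reported
    to 2 significant figures.
    """
    if median_consensus_per_sample <= 0:
        raise ValueError("median consensus depth must be positive")
    return round_sig(100.0 * min_mutant_reads / median_consensus_per_sample, 2)


def classify_sample(
    counts: dict[str, ConsensusCounts],
    plasma_volume_ml: float,
    qc_min_consensus: int = QC_MIN_CONSENSUS,
    positivity_mtm_per_ml: float = POSITIVITY_MTM_PER_ML,
    patient_id: str = "",
    day: float = 0.0,
) -> SampleQuantification:
    """Combine per-target consensus counts into the sample-level call.

    QC exclusion (total consensus across all assays below ``qc_min_consensus``)
    takes precedence over every other status.  MTM/mL is computed as an exact
    ratio and compared unrounded against the positivity threshold.
    """
    total = sum(c.total_consensus for c in counts.values())
    mtm = sum(c.mutant_consensus for c in counts.values())
    conc = mtm_per_ml(mtm, plasma_volume_ml)
    if total < qc_min_consensus:
        status = "excluded"
    elif conc >= positivity_mtm_per_ml:
        status = "positive"
    elif mtm > 0:
        status = "trace"
    else:
        status = "negative"
    return SampleQuantification(
        patient_id=patient_id,
        day=day,
        plasma_volume_ml=plasma_volume_ml,
        total_consensus_all_assays=total,
        mtm_total=mtm,
        mtm_per_ml=conc,
        est_molecules=estimate_molecules(mtm),
        status=status,
        per_target=dict(counts),
    )
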