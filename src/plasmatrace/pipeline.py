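"""End-to-end drivers: FASTQ fixtures in, quantified patient courses out."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import panel_design
from .ctdna_quant import (
    POSITIVITY_MTM_PER_ML,
    QC_MIN_CONSENSUS,
    SampleQuantification,
    classify_sample,
)
from .longitudinal_report import (
    PatientCourse,
    TumorMeasurement,
    flag_and_requantify,
    summarize_cohort,
)
from .umi_consensus import ReadStructure, process_sample


def run_sample(
    fastq_path,
    panel,
    assay_sequences: dict[str, str],
    plasma_volume_ml: float,
    structure: ReadStructure | None = None,
    patient_id: str = "",
    day: float = 0.0,
    min_family_size: int = 3,
    qc_min_consensus: int = QC_MIN_CONSENSUS,
    positivity_mtm_per_ml: float = POSITIVITY_MTM_PER_ML,
) -> SampleQuantification:
    """Consensus-call one FASTQ and classify the sample."""
    counts, _diag = process_sample(
        fastq_path, panel, assay_sequences, structure=structure,
        min_family_size=min_family_size,
    )
    return classify_sample(
        counts,
        plasma_volume_ml=plasma_volume_ml,
        qc_min_consensus=qc_min_consensus,
        positivity_mtm_per_ml=positivity_mtm_per_ml,
        patient_id=patient_id,
        day=day,
    )


def _read_assays(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["target_id"], df["sequence"]))


def run_fixture(
    fixture_dir,
    structure: ReadStructure | None = None,
    min_family_size: int = 3,
    qc_min_consensus: int = QC_MIN_CONSENSUS,
    positivity_mtm_per_ml: float = POSITIVITY_MTM_PER_ML,
    flag_germline: bool = True,
) -> list[PatientCourse]:
    """Run the full analysis over a fixture directory written by the simulator.

    Reads the sample sheet, per-patient panels and assay tables, processes
    every FASTQ into a ``SampleQuantification``, applies retrospective
    germline flagging per patient, and returns the quantified courses.
    """
    fixture = Path(fixture_dir)
    sheet = pd.read_csv(fixture / "sample_sheet.tsv", sep="\t")
    measurements = pd.read_csv(fixture / "measurements.tsv", sep="\t")
    courses = []
    for pid, rows in sheet.groupby("patient_id", sort=True):
        panel = panel_design.read_panel_tsv(fixture / f"{pid}_panel.tsv")
        assay_seqs = _read_assays(fixture / f"{pid}_assays.tsv")
        quants = []
        for row in rows.itertuples(index=False):
            quants.append(
                run_sample(
                    fixture / row.fastq,
                    panel,
                    assay_seqs,
                    plasma_volume_ml=float(row.plasma_volume_ml),
                    structure=structure,
                    patient_id=pid,
                    day=float(row.day),
                    min_family_size=min_family_size,
                    qc_min_consensus=qc_min_consensus,
                    positivity_mtm_per_ml=positivity_mtm_per_ml,
                )
            )
        course = PatientCourse(
            patient_id=str(pid),
            sample_sheet=rows.reset_index(drop=True),
            measurements=[
                TumorMeasurement(
                    day=float(m.day),
                    d1=None if pd.isna(m.d1) else float(m.d1),
                    d2=None if pd.isna(m.d2) else float(m.d2),
                    d3=None if pd.isna(m.d3) else float(m.d3),
                )
                for m in measurements[measurements["patient_id"] == pid].itertuples()
            ],
            metastatic=bool(rows["metastatic"].iloc[0])
            if "metastatic" in rows
            else False,
        )
        course.attach_quantifications(quants)
        if flag_germline:
            flags, corrected = flag_and_requantify(
                course.quantifications,
                qc_min_consensus=qc_min_consensus,
                positivity_mtm_per_ml=positivity_mtm_per_ml,
            )
            course.germline_flags = flags
            course.attach_quantifications(corrected)
        courses.append(course)
    return courses


def quantifications_frame(courses: list[PatientCourse]) -> pd.DataFrame:
    rows = []
    for c in courses:
        for q in c.quantifications:
            rows.append(q.to_dict())
    return pd.DataFrame(rows)


def cohort_report(courses: list[PatientCourse]) -> dict:
    return summarize_cohort(courses)
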