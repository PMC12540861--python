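"""Synthetic ctDNA-monitoring cohorts with known ground truth.

Generates everything the analysis consumes — paired tumor/germline candidate
variant tables, patient courses (sample sheets, tumor diameter measurements,
treatment phases), and UMI-tagged amplicon FASTQ reads — from a compact
configuration, with the hidden simulation state returned as ``SimTruth`` so
recovery can be scored.

Statistical structure emulated:

* heterozygous-diploid tumor variants under tumor purity, so a cfDNA sample
  with tumor fraction ``f`` carries each somatic variant on a fraction
  ``f/2`` of its molecules; inherited (germline) variants sit at 0.5
  regardless of ``f``;
* two error channels: molecule-level errors applied once per original
  molecule (these survive UMI consensus) and read-level errors applied
  independently per read (these are removed by consensus when families are
  large enough);
* UMI family sizes ~ 1 + Poisson(mean - 1), and two barcodes per original
  molecule, so the expected number of original molecules is half the number
  of consensus reads;
* longitudinal tumor-fraction trajectories shaped like treatment response
  (decline to zero), relapse (decline then re-rise) or primary resistance
  (plateau), with cfDNA concentration and tumor diameters monotonically
  linked to tumor fraction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import panel_design
from .longitudinal_report import PatientCourse, TumorMeasurement
from .panel_design import PanelDesign
from .umi_consensus import ConsensusCounts, ReadStructure

TRAJECTORY_SHAPES = ("responder", "relapse", "resistant")

#: default tumor-fraction schedules (day, f) per trajectory shape
DEFAULT_SCHEDULES = {
    "responder": [(0, 0.30), (21, 0.08), (42, 0.01), (84, 0.0), (126, 0.0), (180, 0.0)],
    "relapse": [(0, 0.25), (21, 0.05), (42, 0.004), (84, 0.0), (126, 0.06), (180, 0.30)],
    "resistant": [(0, 0.30), (21, 0.26), (42, 0.30), (84, 0.27), (126, 0.30), (180, 0.29)],
}

_ONCOGENES = ["MYOD1", "NRAS", "FGFR4", "CTNNB1", "TP53"]

_B2C = {"A": 0, "C": 1, "G": 2, "T": 3}
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Depth/assay defaults follow the monitoring setting this package models:
    ten assays per patient, ~1,537 consensus reads per assay, 4 mL plasma,
    16-145 candidate SNVs per patient.
    """

    n_patients: int = 12
    snvs_per_patient_range: tuple[int, int] = (16, 145)
    trajectory_shape: str = "relapse"
    tumor_fraction_schedule: list[tuple[float, float]] | None = None
    target_consensus_depth: int = 1537
    family_size_mean: float = 5.0
    e_molecule: float = 1e-5
    e_read: float = 0.002
    umi_length: int = 12
    plasma_volume_ml: float = 4.0
    seed: int = 0
    # candidate-table model
    pass_probability: float = 0.65
    oncogenic_probability: float = 0.02
    tumor_purity: float = 0.8
    panel_size: int = 10
    planted_germline_total: int = 3
    n_metastatic: int = 2
    # monotone links from tumor fraction to the clinical covariates
    cfdna_base_ng_ml: float = 6.0
    cfdna_per_f_ng_ml: float = 2500.0
    cfdna_noise_sd: float = 0.15
    volume_per_f_cm3: float = 400.0
    diameter_noise_sd: float = 0.05
    anchor: str = "ACGTACGT"

    def __post_init__(self) -> None:
        lo, hi = self.snvs_per_patient_range
        if lo > hi:
            raise ValueError("snvs_per_patient_range is inverted")
        if lo < 1:
            raise ValueError("at least one candidate SNV per patient required")
        for name in ("e_molecule", "e_read", "pass_probability", "tumor_purity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.family_size_mean < 1:
            raise ValueError("family_size_mean must be >= 1")
        if self.umi_length < 8:
            raise ValueError("umi_length must be >= 8")
        if self.tumor_fraction_schedule is not None:
            days = [d for d, _ in self.tumor_fraction_schedule]
            if any(b <= a for a, b in zip(days, days[1:])):
                raise ValueError("schedule days must be strictly increasing")
            if any(not (0.0 <= f <= 1.0) for _, f in self.tumor_fraction_schedule):
                raise ValueError("tumor fractions must be in [0, 1]")
        if self.trajectory_shape not in TRAJECTORY_SHAPES:
            raise ValueError(f"unknown trajectory shape {self.trajectory_shape!r}")
        if self.plasma_volume_ml <= 0:
            raise ValueError("plasma_volume_ml must be positive")

    @property
    def read_structure(self) -> ReadStructure:
        return ReadStructure(umi_length=self.umi_length, anchor=self.anchor)

    def schedule(self, metastatic: bool = False) -> list[tuple[float, float]]:
        sched = self.tumor_fraction_schedule or DEFAULT_SCHEDULES[self.trajectory_shape]
        if metastatic:
            sched = [(d, min(1.0, 2.0 * f)) for d, f in sched]
        return list(sched)

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        d["snvs_per_patient_range"] = list(d["snvs_per_patient_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["snvs_per_patient_range"] = tuple(d["snvs_per_patient_range"])
        if d.get("tumor_fraction_schedule") is not None:
            d["tumor_fraction_schedule"] = [
                (float(a), float(b)) for a, b in d["tumor_fraction_schedule"]
            ]
        return cls(**d)


@dataclass
class PatientTruth:
    """Hidden state for one simulated patient."""

    patient_id: str
    candidate_ids: list[str] = field(default_factory=list)
    intended_pass_ids: list[str] = field(default_factory=list)
    germline_ids: list[str] = field(default_factory=list)
    panel_ids: list[str] = field(default_factory=list)
    sample_f: dict[float, float] = field(default_factory=dict)
    expected_mutant_fraction: dict[float, dict[str, float]] = field(default_factory=dict)


@dataclass
class SimTruth:
    patients: dict[str, PatientTruth] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            pid: {
                "candidate_ids": t.candidate_ids,
                "intended_pass_ids": t.intended_pass_ids,
                "germline_ids": t.germline_ids,
                "panel_ids": t.panel_ids,
                "sample_f": {str(k): v for k, v in t.sample_f.items()},
                "expected_mutant_fraction": {
                    str(day): frac for day, frac in t.expected_mutant_fraction.items()
                },
            }
            for pid, t in self.patients.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        truth = cls()
        for pid, d in payload.items():
            truth.patients[pid] = PatientTruth(
                patient_id=pid,
                candidate_ids=d["candidate_ids"],
                intended_pass_ids=d["intended_pass_ids"],
                germline_ids=d["germline_ids"],
                panel_ids=d["panel_ids"],
                sample_f={float(k): v for k, v in d["sample_f"].items()},
                expected_mutant_fraction={
                    float(k): v for k, v in d["expected_mutant_fraction"].items()
                },
            )
        return truth


@dataclass(frozen=True)
class Assay:
    """One amplicon assay: the payload sequence and where its target sits."""

    target_id: str
    sequence: str
    offset: int  # 0-based position of the target base in the payload
    ref: str
    alt: str


# ---------------------------------------------------------------------------
# WES candidate tables


def _draw_pass_candidate(rng, purity: float) -> dict:
    vaf = rng.uniform(0.12, purity / 2)
    depth = 60 + rng.poisson(60)
    alt = max(10, int(round(vaf * depth)))
    g_depth = 60 + rng.poisson(60)
    g_alt = 1 if rng.random() < 0.25 else 0
    return dict(
        tumor_alt=alt, tumor_depth=depth, germline_alt=g_alt, germline_depth=g_depth
    )


def _draw_fail_candidate(rng, purity: float) -> dict:
    rule = rng.integers(0, 4)
    depth = 60 + rng.poisson(60)
    g_depth = 60 + rng.poisson(60)
    g_alt = 1 if rng.random() < 0.25 else 0
    if rule == 0:  # VAF <= 10%
        vaf = rng.uniform(0.02, 0.095)
        alt = min(int(vaf * depth), int(0.10 * depth))
        alt = max(1, alt)
        return dict(
            tumor_alt=alt, tumor_depth=depth, germline_alt=g_alt, germline_depth=g_depth
        )
    if rule == 1:  # alt depth < 10 at acceptable VAF
        alt = int(rng.integers(3, 10))
        depth = int(round(alt / rng.uniform(0.15, 0.35)))
        return dict(
            tumor_alt=alt, tumor_depth=max(depth, alt), germline_alt=g_alt,
            germline_depth=g_depth,
        )
    base = _draw_pass_candidate(rng, purity)
    if rule == 2:  # germline contamination
        base["germline_alt"] = int(rng.integers(2, 8))
        return base
    # rule == 3: thin germline coverage
    base["germline_depth"] = int(rng.integers(10, 30))
    base["germline_alt"] = min(base["germline_alt"], base["germline_depth"])
    return base


def _draw_germline_candidate(rng) -> dict:
    """A disguised inherited het variant: ~50% tumor VAF, 1 stray germline read."""
    depth = 100 + rng.poisson(30)
    alt = int(rng.binomial(depth, 0.5))
    alt = int(np.clip(alt, np.ceil(0.45 * depth), np.floor(0.55 * depth)))
    g_depth = int(110 + rng.integers(0, 21))
    return dict(
        tumor_alt=alt, tumor_depth=depth, germline_alt=1, germline_depth=g_depth
    )


def simulate_wes_variant_table(
    config: SimConfig,
    patient_id: str,
    rng: np.random.Generator | None = None,
    n_candidates: int | None = None,
    n_planted_germline: int = 0,
) -> tuple[pd.DataFrame, PatientTruth]:
    """Simulate one patient's paired tumor/germline candidate SNV table.

    Each candidate is intended to pass or fail the panel filters with
    probability ``pass_probability`` (i.i.d.); intended-fail candidates break
    exactly one randomly chosen rule.  ``n_planted_germline`` candidates are
    disguised inherited variants (tumor VAF ~0.5, one alternate germline read
    at comfortable depth) that pass the filters and, because purity caps
    somatic VAF below 0.5, out-rank somatic candidates during selection.

    If fewer somatic candidates pass than needed to fill a panel, the
    shortfall is covered by converting intended-fail candidates to passes so
    every simulated patient is assay-designable.
    """
    rng = rng or np.random.default_rng(config.seed)
    if n_candidates is None:
        lo, hi = config.snvs_per_patient_range
        n = int(rng.integers(lo, hi + 1))
    else:
        n = int(n_candidates)
    if n < 1:
        raise ValueError("zero candidates requested")
    if n_planted_germline > n:
        raise ValueError("more planted germline variants than candidates")

    n_somatic = n - n_planted_germline
    intents = rng.random(n_somatic) < config.pass_probability
    needed = max(0, (config.panel_size - n_planted_germline) - int(intents.sum()))
    if needed:
        for i in np.flatnonzero(~intents)[:needed]:
            intents[i] = True

    # unique genomic positions
    positions = set()
    while len(positions) < n:
        chrom = f"chr{int(rng.integers(1, 23))}"
        pos = int(rng.integers(1_000_000, 50_000_000))
        positions.add((chrom, pos))
    positions = sorted(positions)
    order = rng.permutation(n)

    rows = []
    truth = PatientTruth(patient_id=patient_id)
    kinds = ["germline"] * n_planted_germline + [
        "pass" if p else "fail" for p in intents
    ]
    for i, kind in enumerate(kinds):
        chrom, pos = positions[order[i]]
        ref, alt = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
        if kind == "germline":
            counts = _draw_germline_candidate(rng)
        elif kind == "pass":
            counts = _draw_pass_candidate(rng, config.tumor_purity)
        else:
            counts = _draw_fail_candidate(rng, config.tumor_purity)
        oncogenic = kind == "pass" and rng.random() < config.oncogenic_probability
        consequence = rng.choice(
            ["synonymous", "non_synonymous", "other"], p=[0.12, 0.83, 0.05]
        )
        gene = rng.choice(_ONCOGENES) if oncogenic else ""
        snv_id = f"{chrom}_{pos}_{ref}_{alt}"
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene": gene,
                "consequence": consequence,
                "oncogenic": oncogenic,
                **counts,
            }
        )
        truth.candidate_ids.append(snv_id)
        if kind == "germline":
            truth.germline_ids.append(snv_id)
            truth.intended_pass_ids.append(snv_id)
        elif kind == "pass":
            truth.intended_pass_ids.append(snv_id)
    df = pd.DataFrame(rows)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    return df, truth


# ---------------------------------------------------------------------------
# patient courses


def simulate_patient_course(
    config: SimConfig,
    panel: PanelDesign,
    rng: np.random.Generator | None = None,
    metastatic: bool = False,
) -> tuple[PatientCourse, dict[float, float]]:
    """Simulate sample-sheet metadata and tumor measurements for one patient.

    Samples follow the configured tumor-fraction schedule; cfDNA
    concentration and tumor diameters are monotone functions of the tumor
    fraction (with optional multiplicative lognormal noise), so at zero
    noise their ranks reproduce the tumor-fraction ranks exactly.
    Returns the course scaffold (quantifications attach after sequencing)
    and the hidden day -> tumor-fraction map.
    """
    if not panel.targets:
        raise ValueError("panel is empty")
    rng = rng or np.random.default_rng(config.seed)
    schedule = config.schedule(metastatic=metastatic)
    if not schedule:
        raise ValueError("empty tumor-fraction schedule")
    rows = []
    measurements = []
    sample_f: dict[float, float] = {}
    for day, f in schedule:
        cfdna = config.cfdna_base_ng_ml + config.cfdna_per_f_ng_ml * f
        if config.cfdna_noise_sd > 0:
            cfdna *= float(np.exp(rng.normal(0.0, config.cfdna_noise_sd)))
        phase = "diagnosis" if day <= 0 else ("treatment" if day < 90 else "follow-up")
        rows.append(
            {
                "patient_id": panel.patient_id,
                "day": float(day),
                "plasma_volume_ml": config.plasma_volume_ml,
                "cfdna_ng_ml": cfdna,
                "phase": phase,
            }
        )
        volume = config.volume_per_f_cm3 * f
        diameter = (6.0 * volume / np.pi) ** (1.0 / 3.0)
        noise = (
            np.exp(rng.normal(0.0, config.diameter_noise_sd, size=3))
            if config.diameter_noise_sd > 0
            else np.ones(3)
        )
        measurements.append(
            TumorMeasurement(
                day=float(day),
                d1=float(diameter * noise[0]),
                d2=float(diameter * noise[1]),
                d3=float(diameter * noise[2]),
            )
        )
        sample_f[float(day)] = float(f)
    last_day = schedule[-1][0]
    relapse_days = []
    if config.trajectory_shape == "relapse" and config.tumor_fraction_schedule is None:
        relapse_days = [float(last_day)]
    course = PatientCourse(
        patient_id=panel.patient_id,
        sample_sheet=pd.DataFrame(rows),
        measurements=measurements,
        treatments=[(0.0, 90.0, "chemotherapy"), (90.0, float(last_day), "follow-up")],
        relapse_days=relapse_days,
        metastatic=metastatic,
    )
    return course, sample_f


# ---------------------------------------------------------------------------
# assays and reads


def build_assays(
    panel: PanelDesign, config: SimConfig, rng: np.random.Generator
) -> dict[str, Assay]:
    """Random amplicon payload sequences for a panel, unique demux prefixes."""
    structure = config.read_structure
    assays: dict[str, Assay] = {}
    prefixes: list[str] = []
    for t in panel.targets:
        start, end = panel.amplicons[t.snv_id]
        length = end - start + 1
        offset = t.pos - start
        while True:
            seq = "".join(rng.choice(["A", "C", "G", "T"], size=length))
            seq = seq[:offset] + t.ref + seq[offset + 1 :]
            prefix = seq[: structure.prefix_length]
            if all(
                sum(a != b for a, b in zip(prefix, p)) > 2 for p in prefixes
            ):
                break
        prefixes.append(prefix)
        assays[t.snv_id] = Assay(
            target_id=t.snv_id, sequence=seq, offset=offset, ref=t.ref, alt=t.alt
        )
    return assays


def family_survival_probability(family_size_mean: float, min_family_size: int = 3) -> float:
    """P(UMI family reaches the consensus size floor) under 1+Poisson sizes."""
    lam = family_size_mean - 1.0
    return float(stats.poisson.sf(min_family_size - 2, lam))


def expected_molecules(config: SimConfig, min_family_size: int = 3) -> int:
    """Original molecules per assay needed to hit the target consensus depth."""
    p = family_survival_probability(config.family_size_mean, min_family_size)
    return max(1, int(round(config.target_consensus_depth / (2.0 * p))))


def _apply_errors(codes: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """In-place uniform substitution errors on a base-code matrix."""
    if rate <= 0:
        return
    mask = rng.random(codes.shape) < rate
    n = int(mask.sum())
    if n:
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=n)) % 4


def simulate_sample_reads(
    assays: dict[str, Assay],
    f: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    germline_ids: frozenset | set = frozenset(),
    n_molecules: int | None = None,
) -> list[tuple[str, str, str]]:
    """Simulate one plasma sample's UMI-tagged amplicon reads.

    For each assay, ``n_molecules`` original molecules (default: enough that
    surviving UMI families match the target consensus depth) are drawn
    mutant with probability ``f/2`` (0.5 for planted germline targets).
    Molecule-level errors are applied once per molecule; every molecule then
    founds two UMI families whose reads carry independent read-level errors.
    Reads are ``UMI + anchor + payload`` with constant Q30 qualities, in a
    deterministic shuffled order.  Returns (name, sequence, quality) tuples.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError("tumor fraction must be in [0, 1]")
    if not assays:
        raise ValueError("empty assay panel")
    rng = rng or np.random.default_rng(config.seed)
    structure = config.read_structure
    anchor_codes = np.array([_B2C[b] for b in structure.anchor], dtype=np.int8)
    lam = config.family_size_mean - 1.0
    n_mol_default = n_molecules or expected_molecules(config)

    all_seqs: list[np.ndarray] = []
    for tid in sorted(assays):
        assay = assays[tid]
        n_mol = n_mol_default
        p_mut = 0.5 if tid in germline_ids else f / 2.0
        payload_codes = np.array([_B2C[b] for b in assay.sequence], dtype=np.int8)
        mols = np.tile(payload_codes, (n_mol, 1))
        mutant = rng.random(n_mol) < p_mut
        mols[mutant, assay.offset] = _B2C[assay.alt]
        _apply_errors(mols, config.e_molecule, rng)

        n_fam = 2 * n_mol
        fam_mol = np.repeat(np.arange(n_mol), 2)
        sizes = 1 + rng.poisson(lam, size=n_fam)
        umis = rng.integers(0, 4, size=(n_fam, config.umi_length), dtype=np.int8)

        read_mol = np.repeat(fam_mol, sizes)
        read_fam = np.repeat(np.arange(n_fam), sizes)
        reads = mols[read_mol]
        _apply_errors(reads, config.e_read, rng)
        full = np.concatenate(
            [
                umis[read_fam],
                np.tile(anchor_codes, (len(reads), 1)),
                reads,
            ],
            axis=1,
        )
        all_seqs.append(full)

    records: list[tuple[str, str, str]] = []
    idx = 0
    chunks = []
    for arr in all_seqs:
        ascii_ = _DECODE[arr].astype(np.uint8)
        width = arr.shape[1]
        qual = "?" * width
        for row in ascii_:
            chunks.append((row.tobytes().decode(), qual))
    order = rng.permutation(len(chunks))
    for idx, j in enumerate(order):
        seq, qual = chunks[j]
        records.append((f"read_{idx}", seq, qual))
    return records


def write_fastq(records, path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def simulate_consensus_counts(
    target_ids,
    f: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    germline_ids: frozenset | set = frozenset(),
) -> dict[str, ConsensusCounts]:
    """Molecule-level shortcut: consensus counts without read synthesis.

    Draws, per target, the number of surviving UMI families and the number
    of mutant families directly from the binomial laws the read simulator
    follows.  Sequencing-error channels are not modelled (valid as a
    zero-noise approximation); use :func:`simulate_sample_reads` plus the
    consensus pipeline when error behavior matters.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError("tumor fraction must be in [0, 1]")
    rng = rng or np.random.default_rng(config.seed)
    p_surv = family_survival_probability(config.family_size_mean)
    n_mol = expected_molecules(config)
    counts = {}
    for tid in target_ids:
        p_mut = 0.5 if tid in germline_ids else f / 2.0
        survived = int(rng.binomial(2 * n_mol, p_surv))
        mutant = int(rng.binomial(survived, p_mut))
        counts[tid] = ConsensusCounts(
            target_id=tid, total_consensus=survived, mutant_consensus=mutant
        )
    return counts


# ---------------------------------------------------------------------------
# fixture sets


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_set(config: SimConfig, out_dir) -> dict:
    """Write a complete synthetic cohort to ``out_dir``.

    Per patient: candidate variant table, designed panel, assay sequences,
    per-sample FASTQ; cohort-wide: sample sheet, tumor measurements, hidden
    truth JSON and a checksum manifest.  Byte-identical for a fixed seed.
    Trajectory shapes cycle responder/relapse/resistant; the first
    ``n_metastatic`` patients are metastatic; the first
    ``planted_germline_total`` patients each carry one disguised germline
    variant.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_patients)
    truth = SimTruth()
    sheet_rows = []
    meas_rows = []
    files: list[Path] = []

    for i in range(config.n_patients):
        rng = np.random.default_rng(children[i])
        pid = f"P{i + 1:02d}"
        shape = TRAJECTORY_SHAPES[i % len(TRAJECTORY_SHAPES)]
        pconfig = SimConfig(**{**asdict(config), "trajectory_shape": shape})
        n_germ = 1 if i < config.planted_germline_total else 0
        metastatic = i < config.n_metastatic

        table, ptruth = simulate_wes_variant_table(
            pconfig, pid, rng=rng, n_planted_germline=n_germ
        )
        table_path = out / f"{pid}_variants.tsv"
        table.to_csv(table_path, sep="\t", index=False)
        files.append(table_path)

        candidates = panel_design.candidates_from_frame(table)
        panel = panel_design.design_panel(
            candidates, panel_size=config.panel_size, patient_id=pid
        )
        ptruth.panel_ids = panel.target_ids
        panel_path = out / f"{pid}_panel.tsv"
        panel.write_tsv(panel_path)
        files.append(panel_path)

        assays = build_assays(panel, pconfig, rng)
        assay_path = out / f"{pid}_assays.tsv"
        pd.DataFrame(
            [
                {
                    "target_id": a.target_id,
                    "sequence": a.sequence,
                    "offset": a.offset,
                    "ref": a.ref,
                    "alt": a.alt,
                }
                for a in assays.values()
            ]
        ).to_csv(assay_path, sep="\t", index=False)
        files.append(assay_path)

        course, sample_f = simulate_patient_course(
            pconfig, panel, rng=rng, metastatic=metastatic
        )
        ptruth.sample_f = sample_f
        germline_in_panel = frozenset(ptruth.germline_ids) & set(panel.target_ids)
        for day, f in sample_f.items():
            ptruth.expected_mutant_fraction[day] = {
                tid: (0.5 if tid in germline_in_panel else f / 2.0)
                for tid in panel.target_ids
            }
            records = simulate_sample_reads(
                assays, f, pconfig, rng=rng, germline_ids=germline_in_panel
            )
            fq = out / f"{pid}_d{int(day):03d}.fastq"
            write_fastq(records, fq)
            files.append(fq)
        sheet = course.sample_sheet.copy()
        sheet["fastq"] = [f"{pid}_d{int(d):03d}.fastq" for d in sheet["day"]]
        sheet["metastatic"] = metastatic
        sheet_rows.append(sheet)
        for m in course.measurements:
            meas_rows.append(
                {"patient_id": pid, "day": m.day, "d1": m.d1, "d2": m.d2, "d3": m.d3}
            )
        truth.patients[pid] = ptruth

    sheet_path = out / "sample_sheet.tsv"
    pd.concat(sheet_rows, ignore_index=True).to_csv(sheet_path, sep="\t", index=False)
    files.append(sheet_path)
    meas_path = out / "measurements.tsv"
    pd.DataFrame(meas_rows).to_csv(meas_path, sep="\t", index=False)
    files.append(meas_path)
    truth_path = out / "truth.json"
    truth.to_json(truth_path)
    files.append(truth_path)
    config_path = out / "config.yaml"
    config.to_yaml(config_path)
    files.append(config_path)

    manifest = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "files": {p.name: _sha256(p) for p in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def verify_fixture(fixture_dir) -> bool:
    """Re-hash every file listed in the manifest; raise on any mismatch."""
    out = Path(fixture_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    for name, digest in manifest["files"].items():
        actual = _sha256(out / name)
        if actual != digest:
            raise ValueError(f"checksum mismatch for {name}")
    return True
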