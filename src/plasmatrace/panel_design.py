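"""Patient-specific SNV panel selection from paired tumor/germline evidence.

A tumor-informed ctDNA assay tracks a handful of somatic single-nucleotide
variants that were observed in the patient's own tumor sequencing.  Candidate
SNVs are filtered on tumor variant allele frequency (VAF), tumor alternate
read depth and germline read evidence, ranked, and the top ``panel_size``
(default ten) become the targets of a multiplex amplicon assay.

The germline safeguards matter: an inherited heterozygous variant looks like
a high-VAF somatic variant in the tumor, and if its germline evidence is thin
(low depth, or a single stray alternate read) it can slip into the panel and
contaminate every downstream ctDNA measurement with a constant ~50% signal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import pandas as pd

BASES = ("A", "C", "G", "T")

#: inclusive amplicon length bounds (bp) achievable by the assay chemistry
AMPLICON_MIN = 75
AMPLICON_MAX = 105

DEFAULT_AMPLICON_LENGTH = 91


@dataclass(frozen=True)
class TargetSNV:
    """One candidate tumor-specific SNV with its read evidence.

    Coordinates are 1-based (VCF convention).  ``tumor_vaf`` is derived from
    the alt/total tumor read counts.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    tumor_alt: int
    tumor_depth: int
    germline_alt: int
    germline_depth: int
    gene: str = ""
    consequence: str = "other"  # synonymous | non_synonymous | other
    oncogenic: bool = False

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if not (0 <= self.tumor_alt <= self.tumor_depth):
            raise ValueError("tumor_alt must be within [0, tumor_depth]")
        if not (0 <= self.germline_alt <= self.germline_depth):
            raise ValueError("germline_alt must be within [0, germline_depth]")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def tumor_vaf(self) -> float:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else 0.0

    @property
    def snv_id(self) -> str:
        return f"{self.chrom}_{self.pos}_{self.ref}_{self.alt}"


@dataclass
class PanelDesign:
    """A per-patient assay panel: ordered targets plus amplicon windows.

    ``amplicons`` maps snv_id -> (start, end), a 1-based fully closed genomic
    window that must contain the target position.  ``selection_log`` records,
    for every candidate seen, whether it passed and (if not) the first rule it
    failed.  ``underpowered`` is set when fewer candidates passed than the
    requested panel size.
    """

    patient_id: str
    targets: list[TargetSNV]
    amplicons: dict[str, tuple[int, int]] = field(default_factory=dict)
    selection_log: list[dict] = field(default_factory=list)
    underpowered: bool = False

    @property
    def target_ids(self) -> list[str]:
        return [t.snv_id for t in self.targets]

    def amplicon_offset(self, snv_id: str) -> int:
        """0-based offset of the target base within its amplicon payload."""
        start, _end = self.amplicons[snv_id]
        target = next(t for t in self.targets if t.snv_id == snv_id)
        return target.pos - start

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.targets:
            start, end = self.amplicons.get(t.snv_id, (None, None))
            rows.append(
                {
                    "patient_id": self.patient_id,
                    "snv_id": t.snv_id,
                    "chrom": t.chrom,
                    "pos": t.pos,
                    "ref": t.ref,
                    "alt": t.alt,
                    "gene": t.gene,
                    "consequence": t.consequence,
                    "oncogenic": t.oncogenic,
                    "tumor_vaf": t.tumor_vaf,
                    "tumor_alt": t.tumor_alt,
                    "tumor_depth": t.tumor_depth,
                    "germline_alt": t.germline_alt,
                    "germline_depth": t.germline_depth,
                    "amplicon_start": start,
                    "amplicon_end": end,
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_log(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.selection_log, fh, indent=1)


# rule order defines which failure is reported for a rejected candidate
_RULES = ("tumor_vaf", "tumor_alt_depth", "germline_alt", "germline_depth")


def _first_failure(
    snv: TargetSNV,
    min_vaf: float,
    min_alt_depth: int,
    max_germline_alt: int,
    min_germline_depth: int,
) -> str | None:
    if not snv.tumor_vaf > min_vaf:
        return "tumor_vaf"
    if snv.tumor_alt < min_alt_depth:
        return "tumor_alt_depth"
    if snv.germline_alt > max_germline_alt:
        return "germline_alt"
    if snv.germline_depth < min_germline_depth:
        return "germline_depth"
    return None


def filter_candidates(
    candidates: list[TargetSNV],
    min_vaf: float = 0.10,
    min_alt_depth: int = 10,
    max_germline_alt: int = 1,
    min_germline_depth: int = 30,
) -> tuple[list[TargetSNV], list[dict]]:
    """Apply the panel inclusion rules to a candidate list.

    A candidate passes iff tumor VAF is strictly above ``min_vaf`` (default
    >10%), tumor alternate depth is >= ``min_alt_depth`` (default 10), at most
    ``max_germline_alt`` alternate reads were seen in germline DNA (default 1;
    set 0 for the stricter no-evidence mode) and germline depth is at least
    ``min_germline_depth``.  The depth floor is a safeguard: germline variants
    that masquerade as somatic tend to do so because the germline compartment
    was under-sequenced.

    Returns (passing, selection_log); the log records the first failing rule
    for each rejected candidate.
    """
    if not candidates:
        warnings.warn("empty candidate list", stacklevel=2)
        return [], []
    passing: list[TargetSNV] = []
    log: list[dict] = []
    for snv in candidates:
        failure = _first_failure(
            snv, min_vaf, min_alt_depth, max_germline_alt, min_germline_depth
        )
        log.append(
            {"snv_id": snv.snv_id, "passed": failure is None, "failed_rule": failure}
        )
        if failure is None:
            passing.append(snv)
    return passing, log


def _rank_key(snv: TargetSNV):
    # oncogenic first, then VAF desc, then (chrom, pos) as a total tie-break
    return (not snv.oncogenic, -snv.tumor_vaf, snv.chrom, snv.pos)


def rank_and_select(
    passing: list[TargetSNV],
    panel_size: int = 10,
    patient_id: str = "",
    selection_log: list[dict] | None = None,
    amplicon_length: int = DEFAULT_AMPLICON_LENGTH,
) -> PanelDesign:
    """Rank filtered candidates and keep the top ``panel_size``.

    Ordering: oncogenic variants first (pathological relevance), then tumor
    VAF descending, then chromosome and position ascending so the order is
    total and permutation-invariant.  If fewer than ``panel_size`` pass, all
    are kept and the panel is flagged ``underpowered``.

    Each selected target gets a default amplicon window of
    ``amplicon_length`` bp centered on the target position (clipped at the
    chromosome start).
    """
    if not (AMPLICON_MIN <= amplicon_length <= AMPLICON_MAX):
        raise ValueError(
            f"amplicon_length must be in [{AMPLICON_MIN}, {AMPLICON_MAX}]"
        )
    ranked = sorted(passing, key=_rank_key)
    seen_pos: set[tuple[str, int]] = set()
    targets: list[TargetSNV] = []
    for snv in ranked:
        key = (snv.chrom, snv.pos)
        if key in seen_pos:
            continue
        seen_pos.add(key)
        targets.append(snv)
        if len(targets) == panel_size:
            break
    underpowered = len(targets) < panel_size
    if underpowered:
        warnings.warn(
            f"only {len(targets)} candidates passed for panel of {panel_size}",
            stacklevel=2,
        )
    amplicons = {}
    for t in targets:
        half = amplicon_length // 2
        start = max(1, t.pos - half)
        end = start + amplicon_length - 1
        amplicons[t.snv_id] = (start, end)
    return PanelDesign(
        patient_id=patient_id,
        targets=targets,
        amplicons=amplicons,
        selection_log=list(selection_log or []),
        underpowered=underpowered,
    )


def validate_amplicons(panel: PanelDesign) -> PanelDesign:
    """Check every amplicon window against the assay's size constraints.

    Windows must be 75-105 bp (achievable amplicon sizes for cfDNA, whose
    fragments are short) and must contain their target position.  Violations
    raise ``ValueError``; the panel is returned unchanged when valid.
    """
    for t in panel.targets:
        if t.snv_id not in panel.amplicons:
            raise ValueError(f"no amplicon window for {t.snv_id}")
        start, end = panel.amplicons[t.snv_id]
        length = end - start + 1
        if not (AMPLICON_MIN <= length <= AMPLICON_MAX):
            raise ValueError(
                f"amplicon for {t.snv_id} is {length} bp, outside "
                f"[{AMPLICON_MIN}, {AMPLICON_MAX}]"
            )
        if not (start <= t.pos <= end):
            raise ValueError(f"target {t.snv_id} not inside its amplicon window")
    return panel


def design_panel(
    candidates: list[TargetSNV],
    panel_size: int = 10,
    patient_id: str = "",
    **filter_kwargs,
) -> PanelDesign:
    """Filter, rank, select and validate in one call."""
    passing, log = filter_candidates(candidates, **filter_kwargs)
    panel = rank_and_select(
        passing, panel_size=panel_size, patient_id=patient_id, selection_log=log
    )
    return validate_amplicons(panel)


# ---------------------------------------------------------------------------
# I/O: TSV dialect of the simulator, and VCF with per-sample AD/DP

_TSV_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "tumor_alt",
    "tumor_depth",
    "germline_alt",
    "germline_depth",
]


def candidates_from_frame(df: pd.DataFrame) -> list[TargetSNV]:
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"candidate table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TargetSNV(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                tumor_alt=int(row.tumor_alt),
                tumor_depth=int(row.tumor_depth),
                germline_alt=int(row.germline_alt),
                germline_depth=int(row.germline_depth),
                gene=str(getattr(row, "gene", "") or ""),
                consequence=str(getattr(row, "consequence", "other")),
                oncogenic=bool(getattr(row, "oncogenic", False)),
            )
        )
    return out


def read_candidates_tsv(path) -> list[TargetSNV]:
    return candidates_from_frame(pd.read_csv(path, sep="\t"))


def read_candidates_vcf(path, tumor_sample: str, germline_sample: str) -> list[TargetSNV]:
    """Read biallelic SNV records from a VCF with per-sample AD fields."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                continue
            t_ad = rec.samples[tumor_sample]["AD"]
            g_ad = rec.samples[germline_sample]["AD"]
            out.append(
                TargetSNV(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    tumor_alt=int(t_ad[1]),
                    tumor_depth=int(t_ad[0]) + int(t_ad[1]),
                    germline_alt=int(g_ad[1]),
                    germline_depth=int(g_ad[0]) + int(g_ad[1]),
                )
            )
    return out


def read_panel_tsv(path) -> PanelDesign:
    df = pd.read_csv(path, sep="\t")
    targets = candidates_from_frame(df)
    amplicons = {
        t.snv_id: (int(s), int(e))
        for t, s, e in zip(targets, df["amplicon_start"], df["amplicon_end"])
    }
    patient = str(df["patient_id"].iloc[0]) if len(df) else ""
    return PanelDesign(patient_id=patient, targets=targets, amplicons=amplicons)
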