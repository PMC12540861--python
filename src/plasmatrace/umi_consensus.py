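"""UMI-family clustering and error-corrected consensus calling.

Each original cfDNA molecule is tagged with a random unique molecular
identifier (UMI) before amplification, so all reads sharing a UMI at one
target descend from a single molecule.  Collapsing a UMI family to its
per-position majority base removes errors introduced after tagging
(polymerase and sequencer errors scattered across individual reads), while
errors present in the original molecule survive consensus.  A family must
contain at least ``min_family_size`` reads (default 3) to yield a consensus
read; a mutated tumor molecule (MTM) is a consensus read carrying the
targeted alternate base.

Reads are amplicon-structured: ``UMI + fixed anchor + payload``.  Targets are
identified alignment-free by matching the payload prefix against the known
amplicon sequences (exact, then 1-mismatch), which is sufficient because no
indels are modelled.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .panel_design import PanelDesign

DEFAULT_ANCHOR = "ACGTACGT"
DEFAULT_PREFIX_LENGTH = 16


@dataclass(frozen=True)
class ReadStructure:
    """Layout of a single-end amplicon read: leading UMI, fixed anchor, payload."""

    umi_length: int = 12
    anchor: str = DEFAULT_ANCHOR
    prefix_length: int = DEFAULT_PREFIX_LENGTH  # payload bases used for demux

    @property
    def header_length(self) -> int:
        return self.umi_length + len(self.anchor)


@dataclass(frozen=True)
class RawRead:
    umi: str
    target_id: str
    payload: str


@dataclass
class UmiFamily:
    target_id: str
    umi: str
    members: list[str]

    @property
    def family_size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ConsensusRead:
    target_id: str
    umi: str
    sequence: str  # may contain N at unresolved positions
    family_size: int


@dataclass
class ConsensusCounts:
    """Per-target consensus tally at the target base.

    ``total_consensus`` counts consensus reads with a resolved (non-N) base at
    the target offset; ``mutant_consensus`` is the MTM count (alternate base);
    ``other_noise`` counts resolved bases that are neither ref nor alt.
    """

    target_id: str
    total_consensus: int = 0
    mutant_consensus: int = 0
    other_noise: int = 0

    @property
    def consensus_vaf(self) -> float | None:
        if self.total_consensus == 0:
            return None
        return self.mutant_consensus / self.total_consensus

    def __post_init__(self) -> None:
        if not (0 <= self.mutant_consensus <= self.total_consensus):
            raise ValueError("0 <= mutant_consensus <= total_consensus required")


@dataclass
class DiscardBin:
    """Reads rejected during demultiplexing, tallied by reason."""

    reasons: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.reasons.values())


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_umi(
    sequence: str,
    structure: ReadStructure,
    prefix_map: dict[str, str],
) -> RawRead | str:
    """Split one read into (UMI, target, payload) or return a discard reason.

    ``prefix_map`` maps each target's payload prefix (``prefix_length`` bases)
    to its target id.  Assignment is exact-match first, then unique
    1-mismatch; reads matching no target, or too short to contain the header
    plus a prefix, are discarded with a reason.
    """
    min_len = structure.header_length + structure.prefix_length
    if len(sequence) < min_len:
        return "too_short"
    umi = sequence[: structure.umi_length]
    anchor = sequence[structure.umi_length : structure.header_length]
    if _hamming(anchor, structure.anchor) > 1:
        return "anchor_mismatch"
    payload = sequence[structure.header_length :]
    prefix = payload[: structure.prefix_length]
    target = prefix_map.get(prefix)
    if target is None:
        hits = [t for p, t in prefix_map.items() if _hamming(prefix, p) <= 1]
        if len(hits) != 1:
            return "unassigned"
        target = hits[0]
    return RawRead(umi=umi, target_id=target, payload=payload)


def demultiplex(
    sequences,
    structure: ReadStructure,
    prefix_map: dict[str, str],
) -> tuple[list[RawRead], DiscardBin]:
    """Assign an iterable of read sequences to targets; tally discards."""
    reads: list[RawRead] = []
    bin_ = DiscardBin()
    for seq in sequences:
        out = extract_umi(seq, structure, prefix_map)
        if isinstance(out, RawRead):
            reads.append(out)
        else:
            bin_.reasons[out] += 1
    return reads, bin_


def read_fastq_sequences(path) -> list[str]:
    """Sequences of a (plain-text or gzipped) FASTQ file."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        return [entry.sequence for entry in fh]


def _umi_neighbors(umi: str):
    """The 3L+1 UMIs within Hamming distance 1 (including umi itself)."""
    yield umi
    for i, base in enumerate(umi):
        for b in "ACGT":
            if b != base:
                yield umi[:i] + b + umi[i + 1 :]


def cluster_families(
    reads: list[RawRead],
    merge_hamming: int = 1,
    merge_ratio: float = 0.1,
) -> list[UmiFamily]:
    """Group reads into UMI families per target, merging sequencing-error UMIs.

    Reads are first grouped by (target, exact UMI).  Small families whose UMI
    is within ``merge_hamming`` (only 0 or 1 supported) of a much larger
    family's UMI are then absorbed directionally: families are processed in
    (size descending, UMI ascending) order and a family is merged into the
    kept family with the largest original size (ties broken by lexicographic
    UMI) among those with Hamming distance <= ``merge_hamming`` and
    small/large original-size ratio <= ``merge_ratio``.  Original exact-UMI
    sizes govern the ratio test throughout, which makes the partition
    independent of merge bookkeeping.
    """
    if merge_hamming not in (0, 1):
        raise ValueError("merge_hamming must be 0 or 1")
    grouped: dict[tuple[str, str], list[str]] = defaultdict(list)
    for r in reads:
        grouped[(r.target_id, r.umi)].append(r.payload)

    by_target: dict[str, list[tuple[str, list[str]]]] = defaultdict(list)
    for (target, umi), members in grouped.items():
        by_target[target].append((umi, members))

    families: list[UmiFamily] = []
    for target in sorted(by_target):
        entries = sorted(by_target[target], key=lambda e: (-len(e[1]), e[0]))
        kept: dict[str, UmiFamily] = {}  # umi -> family
        original_size = {umi: len(members) for umi, members in entries}
        for umi, members in entries:
            parent = None
            if merge_hamming == 1:
                best = None
                for neighbor in _umi_neighbors(umi):
                    if neighbor == umi or neighbor not in kept:
                        continue
                    big = original_size[neighbor]
                    if len(members) / big <= merge_ratio:
                        key = (-big, neighbor)
                        if best is None or key < best[0]:
                            best = (key, neighbor)
                if best is not None:
                    parent = best[1]
            if parent is not None:
                kept[parent].members.extend(members)
            else:
                kept[umi] = UmiFamily(target_id=target, umi=umi, members=list(members))
        families.extend(kept[umi] for umi, _ in entries if umi in kept)
    return families


_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def call_consensus(
    family: UmiFamily,
    min_family_size: int = 3,
    majority: float = 0.75,
) -> ConsensusRead | None:
    """Collapse one UMI family into an error-corrected consensus read.

    Members whose length differs from the modal member length are dropped
    first (chimera guard; modal ties resolve to the shorter length).  If the
    remaining family is smaller than ``min_family_size`` no consensus is
    emitted.  Otherwise each position is called as the most frequent base
    when its fraction is >= ``majority``; ties between top bases, or a top
    fraction below the threshold, yield ``N``.
    """
    if not family.members:
        raise ValueError("empty family")
    lengths = Counter(len(m) for m in family.members)
    modal_len = min(
        (length for length, n in lengths.items() if n == max(lengths.values()))
    )
    members = [m for m in family.members if len(m) == modal_len]
    if len(members) < min_family_size:
        return None
    mat = (
        np.frombuffer("".join(members).encode(), dtype=np.uint8)
        .reshape(len(members), modal_len)
    )
    # per-column counts over the 4 bases (non-ACGT characters are ignored)
    counts = np.zeros((4, modal_len), dtype=np.int64)
    for code, idx in _CODE.items():
        counts[idx] = (mat == code).sum(axis=0)
    top = counts.max(axis=0)
    ties = (counts == top[None, :]).sum(axis=0) > 1
    frac_ok = top >= majority * len(members)
    best_idx = counts.argmax(axis=0)
    seq = _DECODE[best_idx].copy()
    seq[~frac_ok | ties] = ord("N")
    return ConsensusRead(
        target_id=family.target_id,
        umi=family.umi,
        sequence=seq.tobytes().decode(),
        family_size=len(members),
    )


def consensus_from_families(
    families: list[UmiFamily],
    min_family_size: int = 3,
    majority: float = 0.75,
) -> list[ConsensusRead]:
    out = []
    for fam in families:
        cons = call_consensus(fam, min_family_size=min_family_size, majority=majority)
        if cons is not None:
            out.append(cons)
    return out


def count_consensus(
    consensus_reads: list[ConsensusRead],
    panel: PanelDesign,
) -> dict[str, ConsensusCounts]:
    """Tally mutant vs wild-type consensus reads at every panel target.

    The target base is located by its fixed offset within the amplicon
    payload (panel position minus amplicon window start).  Consensus reads
    with ``N`` at the offset are excluded from the total; resolved bases that
    are neither ref nor alt are reported as ``other_noise``.
    """
    offsets = {}
    alleles = {}
    for t in panel.targets:
        off = panel.amplicon_offset(t.snv_id)
        start, end = panel.amplicons[t.snv_id]
        if not (0 <= off <= end - start):
            raise ValueError(f"target offset outside payload for {t.snv_id}")
        offsets[t.snv_id] = off
        alleles[t.snv_id] = (t.ref, t.alt)
    counts = {tid: ConsensusCounts(target_id=tid) for tid in offsets}
    for cons in consensus_reads:
        tid = cons.target_id
        if tid not in offsets:
            continue
        off = offsets[tid]
        if off >= len(cons.sequence):
            raise ValueError(f"target offset outside payload for {tid}")
        base = cons.sequence[off]
        if base == "N":
            continue
        cc = counts[tid]
        cc.total_consensus += 1
        ref, alt = alleles[tid]
        if base == alt:
            cc.mutant_consensus += 1
        elif base != ref:
            cc.other_noise += 1
    return counts


def process_sample(
    fastq_path,
    panel: PanelDesign,
    assay_sequences: dict[str, str],
    structure: ReadStructure | None = None,
    min_family_size: int = 3,
    majority: float = 0.75,
    merge_hamming: int = 1,
    merge_ratio: float = 0.1,
) -> tuple[dict[str, ConsensusCounts], dict]:
    """FASTQ -> per-target consensus counts for one plasma sample.

    ``assay_sequences`` maps target id to its amplicon payload sequence
    (used for prefix demultiplexing).  Returns the counts and a diagnostics
    dict (read/family/discard tallies).
    """
    structure = structure or ReadStructure()
    prefix_map = {
        seq[: structure.prefix_length]: tid for tid, seq in assay_sequences.items()
    }
    if len(prefix_map) != len(assay_sequences):
        raise ValueError("assay payload prefixes are not unique")
    sequences = read_fastq_sequences(fastq_path)
    reads, discards = demultiplex(sequences, structure, prefix_map)
    families = cluster_families(
        reads, merge_hamming=merge_hamming, merge_ratio=merge_ratio
    )
    consensus = consensus_from_families(
        families, min_family_size=min_family_size, majority=majority
    )
    counts = count_consensus(consensus, panel)
    diagnostics = {
        "n_reads": len(sequences),
        "n_assigned": len(reads),
        "n_discarded": discards.total,
        "discard_reasons": dict(discards.reasons),
        "n_families": len(families),
        "n_consensus": len(consensus),
    }
    return counts, diagnostics


def counts_to_frame(counts: dict[str, ConsensusCounts]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "target_id": c.target_id,
                "total_consensus": c.total_consensus,
                "mutant_consensus": c.mutant_consensus,
                "other_noise": c.other_noise,
                "consensus_vaf": c.consensus_vaf,
            }
            for c in counts.values()
        ]
    )
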