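"""UMI extraction, family clustering, consensus calling and MTM counting."""

import itertools
from collections import Counter

import numpy as np
import pytest

import helpers_naive as naive
from conftest import make_snv
from plasmatrace import (
    RawRead,
    ReadStructure,
    SimConfig,
    UmiFamily,
    build_assays,
    call_consensus,
    cluster_families,
    count_consensus,
    demultiplex,
    design_panel,
    extract_umi,
    process_sample,
    simulate_sample_reads,
)
from plasmatrace.panel_design import PanelDesign, candidates_from_frame
from plasmatrace.synthetic_cohort import simulate_wes_variant_table, write_fastq
from plasmatrace.umi_consensus import consensus_from_families

STRUCT = ReadStructure(umi_length=12, anchor="ACGTACGT")


def _read(umi, payload, anchor="ACGTACGT"):
    return umi + anchor + payload


class TestExtractUmi:
    def test_recovers_planted_structure(self):
        payload = "TTGACCATGGCATTCCAAGGTT"
        prefix_map = {payload[:16]: "T1"}
        out = extract_umi(_read("AAAACCCCGGGG", payload), STRUCT, prefix_map)
        assert isinstance(out, RawRead)
        assert out.umi == "AAAACCCCGGGG"
        assert out.target_id == "T1"
        assert out.payload == payload

    def test_one_mismatch_prefix_still_assigned(self):
        payload = "TTGACCATGGCATTCCAAGGTT"
        prefix_map = {("A" + payload[1:])[:16]: "T1"}
        out = extract_umi(_read("AAAACCCCGGGG", payload), STRUCT, prefix_map)
        assert isinstance(out, RawRead) and out.target_id == "T1"

    def test_short_read_goes_to_discard_bin(self):
        reads, bin_ = demultiplex(["ACGT"], STRUCT, {"A" * 16: "T1"})
        assert reads == [] and bin_.reasons["too_short"] == 1

    def test_unassignable_read_counted(self):
        payload = "T" * 30
        reads, bin_ = demultiplex(
            [_read("AAAACCCCGGGG", payload)], STRUCT, {"G" * 16: "T1"}
        )
        assert reads == [] and bin_.reasons["unassigned"] == 1

    def test_zero_error_simulation_has_zero_discards(self, noiseless_config, rng):
        table, _ = simulate_wes_variant_table(
            noiseless_config, "P01", rng=rng, n_candidates=30
        )
        panel = design_panel(candidates_from_frame(table), patient_id="P01")
        assays = build_assays(panel, noiseless_config, rng)
        records = simulate_sample_reads(
            assays, 0.3, noiseless_config, rng=rng, n_molecules=110
        )
        assert len(records) >= 10_000
        prefix_map = {a.sequence[:16]: tid for tid, a in assays.items()}
        reads, bin_ = demultiplex(
            [seq for _, seq, _ in records], noiseless_config.read_structure, prefix_map
        )
        assert bin_.total == 0
        assert len(reads) == len(records)


class TestClusterFamilies:
    def test_identical_umis_form_one_family(self):
        reads = [RawRead("AAAATTTTCCCC", "T1", "ACGT") for _ in range(5)]
        fams = cluster_families(reads)
        assert len(fams) == 1 and fams[0].family_size == 5

    def test_small_neighbor_family_absorbed(self):
        reads = [RawRead("A" * 12, "T1", "ACGT")] * 100 + [
            RawRead("A" * 11 + "T", "T1", "ACGT")
        ] * 2
        fams = cluster_families(reads)
        assert len(fams) == 1
        assert fams[0].umi == "A" * 12 and fams[0].family_size == 102

    def test_similar_sized_neighbors_not_merged(self):
        reads = [RawRead("A" * 12, "T1", "ACGT")] * 10 + [
            RawRead("A" * 11 + "T", "T1", "ACGT")
        ] * 9
        assert len(cluster_families(reads)) == 2

    def test_family_sizes_conserve_assigned_reads(self, rng):
        umis = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(200)]
        reads = [
            RawRead(umis[int(rng.integers(0, 200))], f"T{int(rng.integers(0, 3))}", "AC")
            for _ in range(2000)
        ]
        fams = cluster_families(reads)
        assert sum(f.family_size for f in fams) == len(reads)

    def test_matches_allpairs_directional_oracle(self, rng):
        # a UMI multiset with deliberate near-collisions and skewed sizes
        base_umis = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(30)]
        reads = []
        for u in base_umis:
            n = int(rng.integers(1, 60))
            reads += [RawRead(u, "T1", "ACGT")] * n
            if rng.random() < 0.6:  # satellite error UMI
                i = int(rng.integers(0, 8))
                sat = u[:i] + rng.choice([b for b in "ACGT" if b != u[i]]) + u[i + 1 :]
                reads += [RawRead(sat, "T1", "ACGT")] * int(rng.integers(1, 4))
        got = {
            (f.target_id, f.umi): sorted(f.members) for f in cluster_families(reads)
        }
        expected = {
            k: sorted(v)
            for k, v in naive.naive_cluster(
                [(r.target_id, r.umi, r.payload) for r in reads]
            ).items()
        }
        assert got == expected


class TestCallConsensus:
    def test_three_identical_reads_reproduce_the_read(self):
        fam = UmiFamily("T1", "A" * 12, ["ACGTAC"] * 3)
        cons = call_consensus(fam)
        assert cons.sequence == "ACGTAC" and cons.family_size == 3

    def test_family_of_two_yields_no_consensus(self):
        assert call_consensus(UmiFamily("T1", "A" * 12, ["ACGT", "ACGT"])) is None

    def test_majority_rule_at_family_of_four(self):
        # one dissenting read at 3/4 = 0.75 meets the threshold; 2/2 ties to N
        fam = UmiFamily("T1", "A" * 12, ["A", "A", "A", "C"])
        assert call_consensus(fam).sequence == "A"
        fam = UmiFamily("T1", "A" * 12, ["A", "A", "C", "C"])
        assert call_consensus(fam).sequence == "N"

    @pytest.mark.parametrize("size", [3, 4, 5, 6])
    def test_enumeration_of_all_base_multisets(self, size):
        """Every base multiset up to family size 6 matches the declared rule."""
        for combo in itertools.combinations_with_replacement("ACGT", size):
            got = call_consensus(UmiFamily("T", "A" * 12, list(combo)))
            counts = Counter(combo)
            top = max(counts.values())
            winners = [b for b, c in counts.items() if c == top]
            expected = (
                winners[0] if len(winners) == 1 and top >= 0.75 * size else "N"
            )
            assert got.sequence == expected, combo

    def test_minority_length_members_dropped_before_consensus(self):
        fam = UmiFamily("T1", "A" * 12, ["ACGT", "ACGT", "ACGT", "ACGTT"])
        cons = call_consensus(fam)
        assert cons.sequence == "ACGT" and cons.family_size == 3
        # dropping the chimera can sink the family below the size floor
        fam = UmiFamily("T1", "A" * 12, ["ACGT", "ACGT", "ACGTT"])
        assert call_consensus(fam) is None

    def test_raising_size_floor_never_increases_consensus_yield(self, rng):
        fams = [
            UmiFamily("T1", f"{i:012d}".replace("1", "A").replace("0", "C"),
                      ["ACGT"] * int(rng.integers(1, 8)))
            for i in range(50)
        ]
        yields = [
            len(consensus_from_families(fams, min_family_size=k)) for k in (1, 2, 3, 4, 5)
        ]
        assert all(a >= b for a, b in zip(yields, yields[1:]))


class TestCountConsensus:
    def _panel_one_target(self):
        snv = make_snv(pos=10**6, ref="A", alt="G")
        return snv, PanelDesign(
            patient_id="P",
            targets=[snv],
            amplicons={snv.snv_id: (10**6 - 2, 10**6 + 2)},
        )

    def test_all_reference_reads_count_zero_mtm(self):
        snv, panel = self._panel_one_target()
        from plasmatrace import ConsensusRead

        reads = [
            ConsensusRead(snv.snv_id, "A" * 12, "CCACC", 3) for _ in range(1000)
        ]
        counts = count_consensus(reads, panel)[snv.snv_id]
        assert (counts.total_consensus, counts.mutant_consensus) == (1000, 0)

    def test_alt_other_and_n_bases_routed_correctly(self):
        snv, panel = self._panel_one_target()
        from plasmatrace import ConsensusRead

        reads = [
            ConsensusRead(snv.snv_id, "A" * 12, "CCGCC", 3),  # alt -> MTM
            ConsensusRead(snv.snv_id, "A" * 12, "CCTCC", 3),  # other base
            ConsensusRead(snv.snv_id, "A" * 12, "CCNCC", 3),  # unresolved
            ConsensusRead(snv.snv_id, "A" * 12, "CCACC", 3),  # ref
        ]
        counts = count_consensus(reads, panel)[snv.snv_id]
        assert counts.total_consensus == 3
        assert counts.mutant_consensus == 1
        assert counts.other_noise == 1
        assert counts.consensus_vaf == pytest.approx(1 / 3)


class TestPipelineProperties:
    def test_mutant_fraction_independent_of_read_error(self, tmp_path, rng):
        """With no molecule-level errors, read errors do not bias the MTM rate."""
        config = SimConfig(
            seed=5, e_molecule=0.0, e_read=0.0, target_consensus_depth=10_000
        )
        snv = make_snv(pos=10**6, ref="A", alt="G")
        panel = PanelDesign(
            "P", [snv], {snv.snv_id: (10**6 - 45, 10**6 + 45)}
        )
        assays = build_assays(panel, config, rng)
        f = 0.3
        fractions = {}
        for e_read in (0.0, 0.01):
            cfg = SimConfig(
                seed=5, e_molecule=0.0, e_read=e_read, target_consensus_depth=10_000
            )
            records = simulate_sample_reads(
                assays, f, cfg, rng=np.random.default_rng(99)
            )
            fq = tmp_path / f"e{e_read}.fastq"
            write_fastq(records, fq)
            counts, _ = process_sample(
                fq, panel, {t: a.sequence for t, a in assays.items()}
            )
            cc = counts[snv.snv_id]
            fractions[e_read] = (cc.consensus_vaf, cc.total_consensus)
        p = f / 2
        for vaf, n in fractions.values():
            se = (p * (1 - p) / n) ** 0.5
            assert abs(vaf - p) < 3 * se

    def test_pipeline_equals_naive_reference_small_fixture(self, tmp_path, rng):
        config = SimConfig(seed=3, target_consensus_depth=150)
        table, _ = simulate_wes_variant_table(config, "P01", rng=rng, n_candidates=25)
        panel = design_panel(
            candidates_from_frame(table), panel_size=3, patient_id="P01"
        )
        assays = build_assays(panel, config, rng)
        records = simulate_sample_reads(assays, 0.2, config, rng=rng)
        assert len(records) <= 5000
        fq = tmp_path / "s.fastq"
        write_fastq(records, fq)
        seqs = {t: a.sequence for t, a in assays.items()}
        counts, _ = process_sample(fq, panel, seqs)
        expected = naive.naive_pipeline(
            fq, panel, seqs, config.umi_length, config.anchor
        )
        got = {
            t: (c.total_consensus, c.mutant_consensus, c.other_noise)
            for t, c in counts.items()
        }
        assert got == expected
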