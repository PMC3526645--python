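"""Three-level quality filter: demultiplexing, trimming, dereplication."""

from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from bitematch.seq_io import ReadRecord, SampleManifest, ManifestEntry
from bitematch.qc import (
    ADAPTER_A,
    ADAPTER_B,
    AmbiguousLocusError,
    LocusPrimerSet,
    PipelineConfig,
    level1_demultiplex,
    level2_trim,
    level3_dereplicate,
    filter_sample,
    reverse_complement,
    run_pipeline,
)
from bitematch.simulate import SimulationConfig, generate_study


def _primer(primer_sets, locus):
    return next(ps for ps in primer_sets if ps.locus == locus)


def fwd_read(ps, insert, read_id="r", quality=40):
    seq = ADAPTER_A + ps.forward_primer + insert + reverse_complement(
        ps.reverse_primer.replace("Y", "C").replace("R", "A")
    )
    return ReadRecord(read_id, seq, [quality] * len(seq))


class TestLevel1:
    def test_forward_16s_read_assigned(self, primer_sets):
        ps = _primer(primer_sets, "16S")
        insert = "AC" * 105
        read = ReadRecord("r1", ADAPTER_A + ps.forward_primer + insert)
        by_locus, audit = level1_demultiplex([read], primer_sets)
        assert [r.read_id for r in by_locus["16S"]] == ["r1"]
        assert by_locus["16S"][0].orientation == "forward"
        assert audit.unassigned == 0

    def test_length_219_discarded(self, primer_sets):
        ps = _primer(primer_sets, "16S")
        seq = (ADAPTER_A + ps.forward_primer + "AC" * 105)[:219]
        by_locus, audit = level1_demultiplex([ReadRecord("r1", seq)], primer_sets)
        assert audit.fail_min_length == 1
        assert not any(by_locus.values())

    def test_reverse_rpob_read_canonicalized(self, primer_sets):
        """A B-adapter read matches its locus through IUPAC codes (R ~ A)
        and comes back reverse-complemented to forward orientation."""
        ps = _primer(primer_sets, "rpoB")
        concrete_rev = "CGAGAGACAACCCCTTTATT"  # R resolved to A
        tail = "ACGT" * 54
        raw = ADAPTER_B + concrete_rev + tail
        by_locus, _ = level1_demultiplex([ReadRecord("r1", raw)], primer_sets)
        (read,) = by_locus["rpoB"]
        assert read.orientation == "reverse"
        # independent reverse-complement check
        manual = raw[::-1].translate(str.maketrans("ACGT", "TGCA"))
        assert read.sequence == manual

    def test_reverse_quality_is_reversed_with_sequence(self, primer_sets):
        raw = ADAPTER_B + "CGAGAGACAACCCCTTTATT" + "ACGT" * 54
        by_locus, _ = level1_demultiplex(
            [ReadRecord("r1", raw, [40] * (len(raw) - 1) + [12])], primer_sets
        )
        assert by_locus["rpoB"][0].quality[0] == 12

    def test_unassignable_read_counted(self, primer_sets):
        read = ReadRecord("r1", "ACGT" * 60)
        _, audit = level1_demultiplex([read], primer_sets)
        assert audit.unassigned == 1

    def test_ambiguous_primer_sets_raise(self):
        twins = [
            LocusPrimerSet("16S", "GAGGTTGATCATGGCTCAG", "ACAACGCAGGTCCATCT", (238, 248)),
            LocusPrimerSet("ITS", "GAGGTTGATCATGGCTCAG", "ACAACGCAGGTCCATCT", (238, 248)),
        ]
        read = ReadRecord("r1", ADAPTER_A + "GAGGTTGATCATGGCTCAG" + "AC" * 105)
        with pytest.raises(AmbiguousLocusError, match="r1"):
            level1_demultiplex([read], twins)


class TestLevel2:
    def test_clean_insert_unchanged(self, primer_sets):
        ps = _primer(primer_sets, "16S")
        insert = "ACGT" * 50
        trimmed = level2_trim(fwd_read(ps, insert), ps)
        assert trimmed.sequence == insert
        assert len(trimmed.quality) == 200

    def test_truncated_at_first_low_quality_base(self, primer_sets):
        ps = _primer(primer_sets, "16S")
        insert = "ACGT" * 50
        read = fwd_read(ps, insert)
        quality = list(read.quality)
        quality[len(ADAPTER_A) + len(ps.forward_primer) + 1] = 19
        read = ReadRecord(read.read_id, read.sequence, quality)
        assert level2_trim(read, ps).sequence == insert[:1]

    def test_truncated_at_ambiguous_base(self, primer_sets):
        ps = _primer(primer_sets, "16S")
        insert = "ACGT" * 50
        insert = insert[:149] + "N" + insert[150:]
        trimmed = level2_trim(fwd_read(ps, insert), ps)
        # independent scan for the first non-ACGT position
        expected_cut = next(i for i, b in enumerate(insert) if b not in "ACGT")
        assert expected_cut == 149
        assert trimmed.sequence == insert[:expected_cut]

    def test_reverse_primer_tail_removed_when_partial(self, primer_sets):
        ps = _primer(primer_sets, "16S")
        insert = "ACGT" * 50
        rc_rev = reverse_complement(ps.reverse_primer)
        seq = ADAPTER_A + ps.forward_primer + insert + rc_rev[:9]
        trimmed = level2_trim(ReadRecord("r", seq, [40] * len(seq)), ps)
        assert trimmed.sequence == insert

    def test_idempotent_on_simulated_reads(self, primer_sets):
        study = generate_study(SimulationConfig(n_participants=2, seed=5))
        ps = _primer(primer_sets, "ITS")
        by_locus, _ = level1_demultiplex(study.reads_by_sample["T1"], primer_sets)
        for read in by_locus["ITS"]:
            once = level2_trim(read, ps)
            twice = level2_trim(once, ps)
            assert twice.sequence == once.sequence
            assert twice.quality == once.quality


class TestLevel3:
    def test_identical_reads_collapse(self, loose_config):
        reads = [ReadRecord(f"r{i}", "ACGTA" * 40) for i in range(3)]
        uniques, _ = level3_dereplicate(reads, loose_config)
        assert [(u.sequence, u.frequency) for u in uniques] == [("ACGTA" * 40, 3)]

    def test_singleton_discarded(self, loose_config):
        uniques, audit = level3_dereplicate([ReadRecord("r", "ACGTA" * 40)], loose_config)
        assert uniques == []
        assert audit.singleton_reads == 1

    def test_multiset_counts_match_bruteforce(self, loose_config):
        a, b, c = "A" * 200, "C" * 200, "G" * 200
        reads = [ReadRecord(f"r{i}", s) for i, s in enumerate([a, a, b, c, c, c, c, c])]
        uniques, audit = level3_dereplicate(reads, loose_config)
        oracle = {
            seq: n
            for seq, n in Counter(r.sequence for r in reads).items()
            if n >= loose_config.min_frequency
        }
        assert {u.sequence: u.frequency for u in uniques} == oracle
        assert audit.singleton_reads == 1
        assert audit.kept_reads + audit.singleton_reads + audit.fail_min_length == len(reads)

    @given(
        st.lists(
            st.tuples(st.sampled_from(["AAA", "CCC", "GGG", "TTT", "ACG"]), st.integers(1, 5)),
            max_size=6,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_bruteforce_equivalence_on_random_multisets(self, multiset):
        config = PipelineConfig(
            min_raw_length=3, min_trimmed_length=3, min_frequency=2, min_unique_reads=1
        )
        reads = [
            ReadRecord(f"r{i}_{j}", seq * 70)
            for i, (seq, n) in enumerate(multiset)
            for j in range(n)
        ]
        uniques, audit = level3_dereplicate(reads, config)
        counts = Counter(r.sequence for r in reads)
        assert {u.sequence: u.frequency for u in uniques} == {
            s: n for s, n in counts.items() if n >= 2
        }
        assert audit.kept_reads + audit.singleton_reads == len(reads)

    def test_order_invariance(self, loose_config):
        reads = [ReadRecord(f"r{i}", s * 40) for i, s in enumerate(["ACGTA", "TTTTT", "ACGTA"])]
        forward, _ = level3_dereplicate(reads, loose_config)
        backward, _ = level3_dereplicate(reads[::-1], loose_config)
        assert forward == backward


class TestOrientationCanonicalization:
    def test_forward_and_reverse_emissions_dereplicate_identically(self, primer_sets):
        """The same templates sequenced in either direction collapse to one
        unique-read set after canonicalization."""
        ps = _primer(primer_sets, "16S")
        inserts = ["".join("ACGT"[(i * 7 + j) % 4] for j in range(205)) for i in range(5)]
        concrete_rev = ps.reverse_primer  # 16S-R has no ambiguity codes
        forward_reads, reverse_reads = [], []
        for i, insert in enumerate(inserts):
            fwd = ADAPTER_A + ps.forward_primer + insert + reverse_complement(concrete_rev)
            rev = ADAPTER_B + concrete_rev + reverse_complement(insert) + reverse_complement(ps.forward_primer)
            for j in range(2):
                forward_reads.append(ReadRecord(f"f{i}_{j}", fwd, [40] * len(fwd)))
                reverse_reads.append(ReadRecord(f"r{i}_{j}", rev, [40] * len(rev)))

        def dereplicate(reads):
            by_locus, _ = level1_demultiplex(reads, primer_sets)
            trimmed = [level2_trim(r, ps) for r in by_locus["16S"]]
            uniques, _ = level3_dereplicate(trimmed)
            return uniques

        assert dereplicate(forward_reads) == dereplicate(reverse_reads)
        assert {u.sequence for u in dereplicate(forward_reads)} == set(inserts)


class TestPipeline:
    def test_monotone_shrinkage_and_audit_conservation(self, default_study):
        for sample_id, reads in default_study.reads_by_sample.items():
            entry = next(e for e in default_study.manifest if e.sample_id == sample_id)
            per_locus = filter_sample(
                sample_id, entry.participant_id, entry.sample_type, reads
            )
            if not per_locus:
                continue
            audit0 = per_locus[0].audit
            assigned = sum(s.audit["reads_in"] for s in per_locus)
            assert (
                audit0["fail_len_raw"] + audit0["unassigned"] + assigned
                == len(reads)
            )
            for sample in per_locus:
                a = sample.audit
                assert a["fail_len_trimmed"] + a["singletons"] + a["kept_reads"] == a["reads_in"]
                assert a["reads_in"] <= a["raw_reads"]
                assert sample.total_frequency == a["kept_reads"]

    def test_under_ten_unique_reads_triggers_cross_locus_exclusion(self, primer_sets):
        import numpy as np

        ps = next(p for p in primer_sets if p.locus == "16S")
        inserts = [
            "".join("ACGT"[b] for b in np.random.default_rng(500 + i).integers(0, 4, 205))
            for i in range(9)
        ]
        reads = []
        for i, insert in enumerate(inserts):
            for j in range(2):
                read = fwd_read(ps, insert, read_id=f"r{i}_{j}")
                reads.append(read)
        manifest = SampleManifest([
            ManifestEntry("B9", 9, "bite", "pooled_four_loci", "b.fastq"),
            ManifestEntry("T9", 9, "teeth", "pooled_four_loci", "t.fastq"),
        ])
        result = run_pipeline(manifest, {"B9": reads, "T9": reads * 2})
        bite = next(s for s in result.samples if s.sample_id == "B9")
        assert len(bite.unique_reads) == 9
        assert not bite.included
        assert "B9" in result.cross_locus_exclusions

    def test_skin_sample_yields_no_assigned_reads(self, primer_sets):
        config = SimulationConfig(n_participants=2, include_skin=True, seed=3)
        study = generate_study(config)
        per_locus = filter_sample("S1", 1, "skin", study.reads_by_sample["S1"])
        assert per_locus == []

    def test_missing_reads_rejected(self):
        manifest = SampleManifest(
            [ManifestEntry("T1", 1, "teeth", "pooled_four_loci", "t.fastq")]
        )
        with pytest.raises(Exception, match="T1"):
            run_pipeline(manifest, {})
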