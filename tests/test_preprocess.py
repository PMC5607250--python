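"""Adapter trimming, junk/length filtering, tag collapse and the ledger."""

import random
from collections import Counter

import pytest

from caprimir.preprocess import (FilterLedger, ReadRecord, filter_and_collapse,
                                 is_junk, length_distribution, merge_libraries,
                                 preprocess_library, trim_adapter3)
from caprimir.synthetic import (DEFAULT_ADAPTER, SimulationConfig,
                                gen_references, simulate_library)

ADAPTER = "TGGAATTC"


class TestTrimAdapter:
    def test_exact_adapter_at_three_prime_end(self):
        read = "ACGTACGTACGTACGTACGT" + ADAPTER
        assert trim_adapter3(read, ADAPTER, min_overlap=6, max_mismatch=0) == \
            "ACGTACGTACGTACGTACGT"

    def test_no_adapter_returns_none(self):
        assert trim_adapter3("ACGT" * 8, ADAPTER, 6, 0) is None

    def test_one_mismatch_tolerated(self):
        read = "ACGTACGTACGTACGTACGT" + "TGGTATTC"  # A->T at position 3
        assert trim_adapter3(read, ADAPTER, 6, 1) == "ACGTACGTACGTACGTACGT"
        assert trim_adapter3(read, ADAPTER, 6, 0) is None

    def test_leftmost_match_wins(self):
        read = "ACGT" + ADAPTER + "CCCC" + ADAPTER
        assert trim_adapter3(read, ADAPTER, 6, 1) == "ACGT"

    def test_truncated_adapter_prefix_at_end(self):
        read = "ACGTACGTACGTACGTACGT" + ADAPTER[:6]
        assert trim_adapter3(read, ADAPTER, 6, 0) == "ACGTACGTACGTACGTACGT"
        # below min_overlap the prefix is not a match
        read = "ACGTACGTACGTACGTACGT" + ADAPTER[:5]
        assert trim_adapter3(read, ADAPTER, 6, 0) is None

    def test_min_overlap_validation(self):
        with pytest.raises(ValueError):
            trim_adapter3("ACGT", "ACG", min_overlap=4)

    def test_matches_slow_reference_scan(self):
        """Fast seeded search equals the brute-force position scan."""
        rng = random.Random(0)
        adapter = DEFAULT_ADAPTER
        for _ in range(300):
            n = rng.randint(18, 60)
            seq = "".join(rng.choice("ACGT") for _ in range(n))
            if rng.random() < 0.5:
                insert_at = rng.randint(0, n)
                seq = seq[:insert_at] + adapter[:rng.randint(6, len(adapter))]
            fast = trim_adapter3(seq, adapter, 6, 1)
            slow = _scan(seq, adapter, 6, 1)
            assert fast == slow, seq

    def test_planted_no_adapter_fraction_recovered(self):
        cfg = SimulationConfig(
            seed=11, n_reads_per_library=(1_000, 1_000), n_mirnas=5,
            n_novel_hairpins=1, no_adapter_fraction=0.05, read_error_rate=0.0)
        bundle, truth = gen_references(cfg)
        reads = simulate_library(bundle, truth, cfg, "E")
        _, ledger = preprocess_library(reads, "E", cfg.adapter)
        assert ledger.reads["no_3adt"] == truth.no_adapter_counts["E"]


def _scan(seq, adapter, min_overlap, max_mismatch):
    for p in range(0, len(seq) - min_overlap + 1):
        span = min(len(adapter), len(seq) - p)
        if span < min_overlap:
            break
        mm = sum(a != b for a, b in zip(seq[p:p + span], adapter[:span]))
        if mm <= max_mismatch:
            return seq[:p]
    return None


class TestJunk:
    @pytest.mark.parametrize("seq,expect", [
        ("A" * 17, True),            # homopolymer, under min length
        ("A" * 18, True),            # homopolymer, in length range
        ("ACGTNACGTACGTACGTACGTA", True),   # contains N
        ("ATATATATATATATATATATAT", True),   # dinucleotide repeat
        ("ACGTAGCTAGGCTTACGATCGA", False),  # complex 22-mer
        ("ACGTACGTAAAAAAAAAAGTCA", True),   # homopolymer run of 10
    ])
    def test_junk_rules(self, seq, expect):
        assert is_junk(seq) is expect


class TestFilterAndCollapse:
    def test_homopolymers_removed_regardless_of_length(self):
        tags, ledger = filter_and_collapse(["A" * 17, "A" * 18], "E")
        assert tags == {}
        assert ledger.reads["junk"] == 2

    def test_collapse_counts(self):
        inserts = ["ACGTAGCTAGGCTTACGATCGA"] * 3 + ["TGCATGCATGCATCAGTCGATA"]
        tags, ledger = filter_and_collapse(inserts, "E")
        assert tags == {"ACGTAGCTAGGCTTACGATCGA": 3, "TGCATGCATGCATCAGTCGATA": 1}
        assert ledger.reads["valid"] == 4

    def test_u_and_case_normalisation(self):
        tags, _ = filter_and_collapse(
            ["acguagcuaggcuuacgaucga", "ACGTAGCTAGGCTTACGATCGA"], "E")
        assert tags == {"ACGTAGCTAGGCTTACGATCGA": 2}

    def test_ledger_partition(self):
        inserts = ["A" * 18, None, "ACGT" * 4, "ACGTAGCTAGGCTTACGATCGA"]
        _, ledger = filter_and_collapse(inserts, "E")
        assert ledger.check_partition()
        assert ledger.raw == 4
        assert ledger.reads["junk"] == 1
        assert ledger.reads["no_3adt"] == 1
        assert ledger.reads["length"] == 1  # 16-mer below 18
        assert ledger.reads["valid"] == 1

    def test_empty_input(self):
        tags, ledger = filter_and_collapse([], "E")
        assert tags == {} and ledger.raw == 0

    def test_order_invariance(self):
        rng = random.Random(5)
        inserts = [
            "".join(rng.choice("ACGT") for _ in range(rng.randint(15, 30)))
            for _ in range(200)
        ] + [None] * 10
        tags1, led1 = filter_and_collapse(list(inserts), "E")
        rng.shuffle(inserts)
        tags2, led2 = filter_and_collapse(inserts, "E")
        assert tags1 == tags2
        assert led1.as_dict() == led2.as_dict()

    def test_collapse_round_trip(self):
        rng = random.Random(7)
        inserts = [
            "".join(rng.choice("ACGT") for _ in range(rng.randint(18, 26)))
            for _ in range(100)
        ]
        keep = [s for s in inserts if not is_junk(s)]
        tags, _ = filter_and_collapse(inserts, "E")
        expanded = Counter()
        for seq, n in tags.items():
            expanded[seq] += n
        assert expanded == Counter(keep)


class TestLengthDistribution:
    def test_single_tag(self):
        df = merge_libraries({"E": {"ACGTAGCTAGGCTTACGATCGA": 10}})
        dist = length_distribution(df)
        assert dist.loc[22, "reads_E"] == 10
        assert dist.loc[22, "frac_reads_E"] == 1.0
        assert dist.loc[22, "frac_unique_E"] == 1.0

    def test_fractions_sum_to_one(self, small_result):
        dist = length_distribution(small_result.tag_df)
        for col in dist.columns:
            if col.startswith("frac_"):
                assert abs(dist[col].sum() - 1.0) < 1e-12

    def test_mode_is_22(self):
        """With enough miRNAs for abundance averaging, the count-weighted
        length histogram peaks at 22 nt, matching the planted truth."""
        cfg = SimulationConfig(
            seed=6, n_reads_per_library=(20_000, 20_000), n_mirnas=100,
            n_novel_hairpins=5)
        bundle, truth = gen_references(cfg)
        per_lib = {}
        for lib in ("E", "L"):
            reads = simulate_library(bundle, truth, cfg, lib)
            per_lib[lib], _ = preprocess_library(reads, lib, cfg.adapter)
        dist = length_distribution(merge_libraries(per_lib))
        assert dist["reads_E"].idxmax() == 22
        assert dist["reads_L"].idxmax() == 22


def test_read_record_validation():
    with pytest.raises(ValueError):
        ReadRecord("r1", "")
    with pytest.raises(ValueError):
        ReadRecord("r1", "ACGT", "II")
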