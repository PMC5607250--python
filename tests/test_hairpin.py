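"""Folding DP vs exhaustive oracle, structure features, criteria engine,
and novel-candidate calling."""

import random
import shutil
import subprocess

import pytest

from caprimir._seq import GenomeIndex
from caprimir.hairpin import (CriteriaThresholds, HairpinStructure, arm_of,
                              call_novel, candidate_windows, enumerate_pairings,
                              evaluate_criteria, evaluate_hairpin, fold_hairpin,
                              fold_score, pairing_score, structure_features)

rng = random.Random(1)


def _rand(n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestFolding:
    def test_perfect_stem(self):
        h = fold_hairpin("G" * 10 + "AAAA" + "C" * 10 + _rand(30),
                         mature_span=(0, 10))
        assert h.dot_bracket[:24] == "((((((((((....))))))))))"

    def test_dp_equals_exhaustive_enumeration(self):
        """Optimal DP score matches brute force over all non-crossing
        pairings for short sequences."""
        for _ in range(60):
            seq = _rand(rng.randint(4, 12))
            best = max(pairing_score(seq, p) for p in enumerate_pairings(seq))
            assert abs(best - fold_score(seq)) < 1e-9, seq

    def test_poly_a_has_no_pairs(self):
        h = fold_hairpin("A" * 60)
        assert h.pairs == [] and not h.is_hairpin

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            fold_hairpin("ACGT" * 5)  # 20 nt < 50
        with pytest.raises(ValueError):
            fold_hairpin("ACGT" * 100)  # 400 nt > 300

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            fold_hairpin("ACGTN" * 12)

    def test_external_structure_used_verbatim(self):
        db = "(" * 21 + "." * 8 + ")" * 21
        h = fold_hairpin("A" * 50, structure=db, energy=-42.0)
        assert h.dot_bracket == db
        assert h.energy_kcal_mol == -42.0

    def test_u_input_accepted(self):
        mat = "GGGAUCGGGAUCGGGAUCGGGA".replace("U", "T")
        h1 = fold_hairpin("GGGAUCGGGAUCGGGAUCGGGA" + "AAAA"
                          + "UCCCGAUCCCGAUCCCGAUCCC" + "AA")
        h2 = fold_hairpin(mat + "AAAA" + "TCCCGATCCCGATCCCGATCCC" + "AA")
        assert h1.dot_bracket == h2.dot_bracket


class TestStructureFeatures:
    def test_perfect_hairpin(self):
        db = "(" * 20 + "." * 8 + ")" * 20
        h = HairpinStructure("A" * 48, db, -30.0, (0, 20))
        f = structure_features(h)
        assert f["stem_pairs"] == 20
        assert f["loop_length"] == 8
        assert f["largest_stem_bulge"] == 0
        assert f["mature_errors"] == 0
        assert f["mature_pairs"] == 20
        assert f["mature_in_stem_pct"] == 100.0

    def test_13nt_bulge_measured(self):
        db = "(" * 21 + "." * 8 + ")" * 8 + "." * 13 + ")" * 13
        h = HairpinStructure("A" * len(db), db, -30.0, (0, 20))
        assert structure_features(h)["largest_stem_bulge"] == 13

    def test_mature_overlapping_loop(self):
        # 22-nt mature with 5 nt inside the terminal loop: 17/22 in stem
        db = "(" * 20 + "." * 8 + ")" * 20
        h = HairpinStructure("A" * 48, db, -30.0, (3, 25))
        f = structure_features(h)
        assert abs(f["mature_in_stem_pct"] - 100 * 17 / 22) < 1e-9

    def test_unbalanced_structure_rejected(self):
        with pytest.raises(ValueError):
            HairpinStructure("A" * 10, "(((....)))"[:-1] + "(", -1.0, (0, 5))


class TestCriteria:
    def test_energy_boundary_inclusive(self):
        db = "(" * 21 + "." * 8 + ")" * 21
        for energy, ok in ((-15.0, True), (-14.9, False), (-17.7, True)):
            h = HairpinStructure("A" * 50, db, energy, (0, 20))
            rep = evaluate_hairpin(h)
            assert rep.flags["c3"] is ok

    def test_overall_equals_conjunction(self):
        db = "(" * 21 + "." * 8 + ")" * 21
        rep = evaluate_hairpin(HairpinStructure("A" * 50, db, -30.0, (0, 20)))
        assert rep.overall == all(rep.flags.values())
        assert rep.overall

    def test_generator_hairpins_pass(self, small_refs):
        """Planted precursors re-folded by the bundled folder satisfy all
        structural criteria (the pipeline's recall ceiling is 100%)."""
        bundle, truth = small_refs
        for row in truth.mirnas.itertuples():
            h = fold_hairpin(
                row.precursor_seq,
                mature_span=(row.mature_offset,
                             row.mature_offset + len(row.mature_seq)))
            rep = evaluate_hairpin(h)
            assert rep.overall, (row.id, rep.flags)

    def test_relaxing_thresholds_is_monotone(self):
        """Candidate sets only grow when any single threshold is relaxed."""
        windows = [_rand(100) for _ in range(30)]
        default = CriteriaThresholds()
        relaxed = [
            CriteriaThresholds(max_stem_bulge=20),
            CriteriaThresholds(min_stem_pairs=10),
            CriteriaThresholds(max_energy=-5.0),
            CriteriaThresholds(min_hairpin_length=30),
            CriteriaThresholds(max_loop_length=30),
            CriteriaThresholds(max_mature_errors=10),
            CriteriaThresholds(min_mature_pairs=6),
            CriteriaThresholds(min_mature_in_stem_pct=50.0),
        ]
        structures = [fold_hairpin(w, mature_span=(10, 32)) for w in windows]
        base_pass = {i for i, h in enumerate(structures)
                     if evaluate_hairpin(h, default).overall}
        for th in relaxed:
            loose_pass = {i for i, h in enumerate(structures)
                          if evaluate_hairpin(h, th).overall}
            assert base_pass <= loose_pass


class TestArmOf:
    def _pre(self):
        db = "(" * 35 + "." * 10 + ")" * 35
        return HairpinStructure("A" * 80, db, -30.0, (0, 22))

    def test_five_prime(self):
        assert arm_of((1, 22), self._pre()) == "5p"

    def test_three_prime(self):
        assert arm_of((55, 76), self._pre()) == "3p"

    def test_tie_goes_to_5p(self):
        pre = self._pre()
        loop_mid = (pre.loop_span[0] + pre.loop_span[1] - 1) / 2
        span = (int(loop_mid) - 10, int(loop_mid) + 12)  # centred on loop
        if (span[0] + span[1] - 1) / 2 == loop_mid:
            assert arm_of(span, pre) == "5p"


class TestCallNovel:
    def test_planted_novels_recalled(self, small_refs):
        bundle, truth = small_refs
        genome = GenomeIndex(bundle.genome)
        planted = truth.mirnas[truth.mirnas["is_novel"]]
        unmatched = {row.mature_seq: {"E": 10, "L": 10}
                     for row in planted.itertuples()}
        cands = call_novel(unmatched, genome)
        assert len(cands) == len(planted)

    def test_low_count_tags_excluded(self, small_refs):
        bundle, truth = small_refs
        genome = GenomeIndex(bundle.genome)
        row = truth.mirnas[truth.mirnas["is_novel"]].iloc[0]
        assert call_novel({row["mature_seq"]: {"E": 2, "L": 0}}, genome,
                          min_reads=3) == []
        assert call_novel({row["mature_seq"]: {"E": 2, "L": 2}}, genome,
                          min_reads=3) != []

    def test_unstructured_locus_yields_nothing(self, small_refs):
        bundle, _ = small_refs
        genome = GenomeIndex(bundle.genome)
        # a tag from a hairpin-free stretch of the toy genome
        tag = bundle.genome["chr1"][100:122]
        assert call_novel({tag: {"E": 50, "L": 50}}, genome) == []

    def test_unmapped_tag_yields_nothing(self, small_refs):
        bundle, _ = small_refs
        genome = GenomeIndex(bundle.genome)
        assert call_novel({"ACGTAGCTAGGCTTACGATCGA": {"E": 9, "L": 9}},
                          genome) == []

    def test_minus_strand_locus_folds(self, small_refs):
        """A tag matching the reverse strand is evaluated on that strand."""
        bundle, truth = small_refs
        from caprimir._seq import revcomp
        genome = GenomeIndex(bundle.genome)
        row = truth.mirnas[truth.mirnas["is_novel"]].iloc[0]
        cands = call_novel({revcomp(row["mature_seq"]): {"E": 10, "L": 10}},
                           genome)
        assert len(cands) == 1
        assert cands[0].report.overall


def test_windows_cover_both_arm_placements(small_refs):
    bundle, truth = small_refs
    genome = GenomeIndex(bundle.genome)
    row = truth.mirnas.iloc[0]
    locus = (row["contig"], row["mature_start"], row["mature_end"], "+")
    wins = candidate_windows(genome, locus, flank=80)
    assert len(wins) == 3
    for ws, we, (ms, me) in wins:
        assert genome.contigs[row["contig"]][ws + ms:ws + me] == row["mature_seq"]


def test_rnafold_structure_plugs_in(small_refs):
    """An externally predicted (thermodynamic) structure can replace the
    bundled folder and the planted hairpins still pass all criteria."""
    if shutil.which("RNAfold") is None:
        pytest.xfail("RNAfold binary not on PATH")
    bundle, truth = small_refs
    row = truth.mirnas.iloc[0]
    out = subprocess.run(
        ["RNAfold", "--noPS"], input=row["precursor_seq"] + "\n",
        capture_output=True, text=True, check=True).stdout.splitlines()
    struct, energy = out[1].rsplit(" ", 1)[0].strip(), float(
        out[1].rsplit("(", 1)[1].rstrip(")"))
    h = fold_hairpin(
        row["precursor_seq"],
        mature_span=(row["mature_offset"],
                     row["mature_offset"] + len(row["mature_seq"])),
        structure=struct, energy=energy)
    rep = evaluate_hairpin(h)
    assert rep.overall, rep.flags
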