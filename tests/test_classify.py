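"""Six-group cascade, tolerance matching, families and conservation."""

import random

import pytest

from caprimir._seq import revcomp
from caprimir.classify import (Classifier, MapTolerance, align_tag,
                               classify_tags, conservation_profile, family_of,
                               family_summary, seed_of)
from caprimir.contaminants import RefRecord, ReferenceBundle
from caprimir.preprocess import merge_libraries
from caprimir.synthetic import SimulationConfig, gen_references

rng = random.Random(9)


def _rand(n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _mut(seq, positions):
    s = list(seq)
    for p in positions:
        s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
    return "".join(s)


class TestAlignTag:
    def setup_method(self):
        self.ref = _rand(22)

    def test_exact(self):
        assert align_tag(self.ref, self.ref) == 0

    def test_two_substitutions(self):
        assert align_tag(_mut(self.ref, [5, 15]), self.ref) == 2

    def test_three_substitutions_rejected(self):
        assert align_tag(_mut(self.ref, [5, 10, 15]), self.ref) is None

    def test_end_truncation_and_extension(self):
        assert align_tag(self.ref[:-2], self.ref) == 0  # 3' truncated
        assert align_tag(self.ref[2:], self.ref) == 0   # 5' truncated
        assert align_tag(self.ref + "AC", self.ref) == 0  # 3' extended

    def test_shift_beyond_tolerance_rejected(self):
        assert align_tag(self.ref[3:] + "AAA", self.ref,
                         MapTolerance(0, 2)) is None


@pytest.fixture(scope="module")
def cascade_bundle():
    """Hand-built bundle exercising every cascade branch.

    chi-miR-1: focal mature, precursor planted in the genome     -> 1a
    bta-miR-2: other-species mature, precursor in the genome     -> 1b
    hsa-miR-3: mature match, precursor absent, tag in genome in
               hairpin-forming context                           -> 2a
    hsa-miR-4: as miR-3 but the genome context is unstructured   -> 2b
    hsa-miR-5: mature match, nothing maps to the genome          -> 3
    """
    m1, m2, m3, m4, m5 = (_rand(22) for _ in range(5))
    loop = "ACAACCAA"

    def hairpin(m):
        ext = _rand(3)
        return ext + m + loop + revcomp(m) + revcomp(ext)

    pre1, pre2 = hairpin(m1), hairpin(m2)
    genome = (
        _rand(400) + pre1 + _rand(400) + pre2 + _rand(400)
        + hairpin(m3)          # m3's own precursor is NOT in the references
        + _rand(400) + m4      # m4 sits in unstructured sequence
        + _rand(400)
    )
    return ReferenceBundle(
        genome={"chr1": genome},
        mature=[
            RefRecord("chi-miR-1", m1, "chi"),
            RefRecord("bta-miR-2", m2, "bta"),
            RefRecord("hsa-miR-3", m3, "hsa"),
            RefRecord("hsa-miR-4", m4, "hsa"),
            RefRecord("hsa-miR-5", m5, "hsa"),
        ],
        premirna=[
            RefRecord("chi-mir-1", pre1, "chi"),
            RefRecord("bta-mir-2", pre2, "bta"),
            RefRecord("hsa-mir-3", _rand(80), "hsa"),  # decoy, unmappable
        ],
        mature_to_pre={"chi-miR-1": "chi-mir-1", "bta-miR-2": "bta-mir-2",
                       "hsa-miR-3": "hsa-mir-3"},
        focal_species="chi", species=["chi", "bta", "hsa"],
    ), (m1, m2, m3, m4, m5), (pre1, pre2)


class TestCascade:
    @pytest.mark.parametrize("idx,group", [
        (0, "1a"), (1, "1b"), (2, "2a"), (3, "2b"), (4, "3")])
    def test_groups(self, cascade_bundle, idx, group):
        bundle, matures, _ = cascade_bundle
        a = Classifier(bundle).map_known(matures[idx])
        assert a.group == group
        assert a.matched_mirna_id is not None

    def test_random_tag_unassigned(self, cascade_bundle):
        bundle, *_ = cascade_bundle
        assert Classifier(bundle).map_known(_rand(22)).group == "unassigned"

    def test_tolerated_variant_still_matches(self, cascade_bundle):
        bundle, matures, _ = cascade_bundle
        a = Classifier(bundle).map_known(_mut(matures[0], [4, 12]))
        assert a.group == "1a" and a.mismatches == 2

    def test_other_arm_detected(self, cascade_bundle):
        """A tag from the opposite precursor arm is an arm-derived known."""
        bundle, matures, pres = cascade_bundle
        star_tag = revcomp(matures[0])  # the 3' arm of chi-mir-1
        a = Classifier(bundle).map_known(star_tag)
        assert a.arm_derived
        assert a.group == "1a"
        assert a.precursor_id == "chi-mir-1"
        assert a.arm == "3p"

    def test_focal_species_priority_on_ties(self, cascade_bundle):
        bundle, matures, _ = cascade_bundle
        bundle_dup = ReferenceBundle(
            genome=bundle.genome,
            mature=bundle.mature + [RefRecord("aaa-miR-9", matures[0], "aaa")],
            premirna=bundle.premirna, mature_to_pre=bundle.mature_to_pre,
            focal_species="chi", species=bundle.species + ["aaa"],
        )
        a = Classifier(bundle_dup).map_known(matures[0])
        assert a.matched_mirna_id == "chi-miR-1"
        assert a.matched_species == "chi"


class TestClassifyTable:
    def test_cascade_exclusivity_and_min_reads(self, cascade_bundle):
        bundle, matures, _ = cascade_bundle
        tag_df = merge_libraries({
            "E": {matures[0]: 5, matures[1]: 2, _rand(22): 6},
            "L": {matures[1]: 2},
        })
        out = classify_tags(tag_df, bundle, min_reads=3)
        # every classified tag gets exactly one group; 4-read rule: >3
        assert len(out) == 3
        assert out.loc[matures[0], "group"] == "1a"
        assert out.loc[matures[1], "group"] == "1b"  # 4 total reads: kept
        assert (out["group"] != "").all()

    def test_removing_focal_species_demotes_to_1b(self):
        """With every focal miRNA conserved in another species, deleting the
        focal records sends former-1a tags to 1b, never to group 4."""
        cfg = SimulationConfig(
            seed=21, n_reads_per_library=(5_000, 5_000), n_mirnas=10,
            n_novel_hairpins=1, conserved_fraction=1.0)
        bundle, truth = gen_references(cfg)
        focal = [r for r in bundle.mature if r.species == cfg.focal_species]
        stripped = ReferenceBundle(
            genome=bundle.genome,
            mature=[r for r in bundle.mature if r.species != "chi"],
            premirna=[r for r in bundle.premirna if r.species != "chi"],
            mature_to_pre={k: v for k, v in bundle.mature_to_pre.items()
                           if not k.startswith("chi-")},
            focal_species="chi", species=bundle.species,
        )
        clf_full = Classifier(bundle)
        clf_stripped = Classifier(stripped)
        for rec in focal:
            assert clf_full.map_known(rec.seq).group == "1a"
            assert clf_stripped.map_known(rec.seq).group in {"1b", "2a", "2b", "3"}


class TestFamilies:
    @pytest.mark.parametrize("name,family", [
        ("chi-miR-30a-5p", "miR-30"),
        ("bta-miR-30f", "miR-30"),
        ("hsa-miR-30e", "miR-30"),
        ("chi-let-7a", "let-7"),
        ("chi-let-7f", "let-7"),
        ("hsa-mir-2284x", "miR-2284"),
        ("lin-4", "lin-4"),
        ("unnamed-small-rna", None),  # no stem token
    ])
    def test_family_stem_rule(self, name, family):
        assert family_of(name) == family

    def test_summary_counts(self, small_result):
        fams = family_summary(small_result.assignments)
        # every planted family recovered exactly once
        truth_fams = set(
            small_result.truth.mirnas.query("~is_novel")["family"])
        assert set(fams.index) == truth_fams
        assert (fams["n_members"] >= 1).all()

    def test_planted_family_count_recovered(self):
        cfg = SimulationConfig(
            seed=13, n_reads_per_library=(8_000, 8_000), n_mirnas=12,
            n_novel_hairpins=1, n_families=4, de_fraction=0.0)
        from caprimir import run_pipeline

        res = run_pipeline(cfg)
        fams = family_summary(res.assignments)
        assert len(fams) == 4

    def test_seed_region(self):
        assert seed_of("UGAGGUAGUAGGUUGUAUAGUU") == "GAGGTAG"


class TestConservation:
    def test_profile_counts_each_species(self, small_result):
        profile, conserved_in = conservation_profile(
            small_result.assignments, small_result.bundle)
        truth = small_result.truth.mirnas
        known = truth[~truth["is_novel"]]
        # focal count >= number of detected focal-primary miRNAs
        assert profile["chi"] >= (known["species"] == "chi").sum() * 0.9
        # miRNAs planted in 2 species are reported as conserved in 2
        assert set(conserved_in.index) <= {1, 2}
        assert conserved_in.get(2, 0) > 0

    def test_empty_assignments(self, small_result):
        import pandas as pd

        empty = pd.DataFrame(columns=["mirna_id", "species"])
        profile, conserved_in = conservation_profile(
            empty, small_result.bundle)
        assert (profile == 0).all()
        assert len(conserved_in) == 0
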