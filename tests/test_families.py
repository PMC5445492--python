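"""Two-pass clustering, curation of private insertions, the 80% family
rule and orphan clade rescue."""

import numpy as np
import pytest

import copiascan as cs
from copiascan import classify as cl
from copiascan import families as fam


def _copies(element, n, rate, seed0):
    return {f"c{i}": cs.degrade(element, "mutate", {"p_sub": rate}, seed0 + i)
            for i in range(n)}


@pytest.fixture(scope="module")
def ancestors():
    a = cs.make_element(cs.galea_spec("FamA"), 1)
    b = cs.make_element(cs.funco1_spec("FamB", ltr_len=200, internal_len=5000), 1)
    return a, b


class TestClusterPass1:
    def test_ten_copies_one_cluster(self, ancestors):
        a, _ = ancestors
        copies = _copies(a, 10, 0.05, 10)
        clusters, leftovers = cs.cluster_pass1(copies)
        assert len(clusters) == 1 and len(clusters[0].members) == 10
        assert leftovers == []

    def test_divergent_families_stay_separate(self, ancestors):
        a, _ = ancestors
        far = cs.degrade(a, "mutate", {"p_sub": 0.45}, 77)  # ~55% identity
        copies = {**_copies(a, 3, 0.03, 20),
                  **{f"d{i}": cs.degrade(far, "mutate", {"p_sub": 0.03}, 30 + i)
                     for i in range(3)}}
        clusters, _ = cs.cluster_pass1(copies)
        assert len(clusters) == 2
        assert {tuple(sorted(c.members)) for c in clusters} == \
               {("c0", "c1", "c2"), ("d0", "d1", "d2")}

    def test_single_copy_is_leftover(self, ancestors):
        a, _ = ancestors
        clusters, leftovers = cs.cluster_pass1({"only": a})
        assert clusters == [] and leftovers == ["only"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cs.cluster_pass1({})

    def test_input_order_invariance(self, ancestors):
        a, b = ancestors
        copies = {**_copies(a, 3, 0.03, 40),
                  **{f"b{i}": cs.degrade(b, "mutate", {"p_sub": 0.03}, 50 + i)
                     for i in range(3)}}
        c1, _ = cs.cluster_pass1(copies)
        c2, _ = cs.cluster_pass1(dict(reversed(list(copies.items()))))
        assert [c.members for c in c1] == [c.members for c in c2]


class TestRescuePass2:
    def test_truncated_copy_rescued(self, ancestors):
        a, _ = ancestors
        copies = _copies(a, 3, 0.03, 60)
        trunc = cs.degrade(cs.degrade(a, "mutate", {"p_sub": 0.02}, 70),
                           "truncate", {"fraction": 0.7, "end": "5p"}, 71)
        copies["trunc"] = trunc
        clusters, leftovers = cs.cluster_pass1(copies)
        assert "trunc" in leftovers
        clusters, orphans = cs.rescue_pass2(clusters, leftovers, copies)
        assert "trunc" in clusters[0].members
        assert clusters[0].pass_of_origin["trunc"] == 2
        assert orphans == []

    def test_decayed_copy_becomes_orphan(self, ancestors):
        a, _ = ancestors
        copies = _copies(a, 3, 0.03, 80)
        copies["dead"] = cs.degrade(a, "mutate", {"p_sub": 0.35}, 90)
        clusters, leftovers = cs.cluster_pass1(copies)
        assert "dead" in leftovers
        clusters, orphans = cs.rescue_pass2(clusters, leftovers, copies)
        assert orphans == ["dead"]

    def test_tie_goes_to_higher_identity_cluster(self, ancestors):
        """A leftover matching two clusters above both pass-2 thresholds
        joins the one with the higher identity."""
        a, _ = ancestors
        copies = {"c0": cs.degrade(a, "mutate", {"p_sub": 0.01}, 100),
                  "c1": cs.degrade(a, "mutate", {"p_sub": 0.01}, 101),
                  "f0": cs.degrade(a, "mutate", {"p_sub": 0.04}, 110),
                  "f1": cs.degrade(a, "mutate", {"p_sub": 0.04}, 111),
                  "probe": cs.degrade(a, "mutate", {"p_sub": 0.015}, 120)}
        clusters = [fam.Cluster(["f0", "f1"]), fam.Cluster(["c0", "c1"])]
        clusters, orphans = cs.rescue_pass2(clusters, ["probe"], copies)
        assert orphans == []
        joined = next(c for c in clusters if "probe" in c.members)
        assert set(joined.members) >= {"c0", "c1"}


class TestCuration:
    def test_nested_insertion_excised(self, ancestors):
        a, b = ancestors
        copies = _copies(a, 2, 0.02, 130)
        copies["nest"] = cs.degrade(a, "nest", {"inner": b}, 140)
        aln = cs.curate_copies(copies)
        degapped = {k: v.replace("-", "") for k, v in aln.items()}
        assert len(degapped["nest"]) < len(copies["nest"]) - 4000
        for other in ("c0", "c1"):
            ident, _ = fam.dna_identity_coverage(degapped["nest"],
                                                 degapped[other])
            assert ident >= 80.0

    def test_small_private_insertion_retained(self, ancestors):
        a, _ = ancestors
        ins = a[:3000] + "ACGTACGTACGTACG" + a[3000:]  # 15 bp <= 20 bp rule
        copies = {"plain1": a, "plain2": cs.degrade(a, "mutate",
                                                    {"p_sub": 0.01}, 150),
                  "ins": ins}
        aln = cs.curate_copies(copies)
        assert len(aln["ins"].replace("-", "")) == len(ins)

    def test_identical_copies_fixed_point(self, ancestors):
        a, _ = ancestors
        aln = cs.curate_copies({"x": a, "y": a})
        assert aln["x"] == aln["y"] == a

    def test_needs_two_members(self, ancestors):
        with pytest.raises(ValueError):
            cs.curate_copies({"x": ancestors[0]})


class TestConsensus:
    def test_identical_members(self):
        aln = {"a": "ACGT", "b": "ACGT", "c": "ACGT"}
        assert cs.build_consensus(aln) == "ACGT"

    def test_majority_wins(self):
        aln = {"a": "ACGT", "b": "ACGT", "c": "AGGT"}
        assert cs.build_consensus(aln) == "ACGT"

    def test_gap_majority_column_dropped(self):
        aln = {"a": "A-GT", "b": "A-GT", "c": "ACGT"}
        assert cs.build_consensus(aln) == "AGT"

    def test_consensus_recovers_ancestor(self, ancestors):
        a, _ = ancestors
        copies = _copies(a, 5, 0.05, 160)
        aln = cs.curate_copies(copies)
        cons = cs.build_consensus(aln)
        assert cs.ltr_identity(cons, a) >= 99.0


class TestValidateFamilies:
    def test_split_clusters_of_same_family_merge(self, ancestors):
        a, _ = ancestors
        copies = _copies(a, 4, 0.03, 170)
        half1 = fam.Cluster(["c0", "c1"])
        half2 = fam.Cluster(["c2", "c3"])
        fams, orphans = cs.validate_families([half1, half2], copies,
                                             {k: "GalEa" for k in copies})
        assert len(fams) == 1
        assert sorted(fams[0].members) == ["c0", "c1", "c2", "c3"]
        assert orphans == []

    def test_valid_cluster_unchanged(self, ancestors):
        a, _ = ancestors
        copies = _copies(a, 3, 0.03, 180)
        fams, _ = cs.validate_families([fam.Cluster(sorted(copies))], copies,
                                       {k: "GalEa" for k in copies})
        assert len(fams) == 1 and sorted(fams[0].members) == sorted(copies)

    def test_singleton_galea_promoted(self, ancestors):
        a, _ = ancestors
        fams, orphans = cs.validate_families([], {"solo": a},
                                             {"solo": "GalEa"},
                                             singletons=["solo"])
        assert len(fams) == 1
        assert fams[0].is_orphan_singleton and fams[0].clade == "GalEa"

    def test_singleton_other_clade_not_promoted(self, ancestors):
        _, b = ancestors
        fams, orphans = cs.validate_families([], {"solo": b},
                                             {"solo": "FunCo1"},
                                             singletons=["solo"])
        assert fams == [] and orphans == ["solo"]

    def test_family_identity_invariant_and_partition(self, ancestors):
        a, b = ancestors
        copies = {**_copies(a, 3, 0.04, 190),
                  **{f"b{i}": cs.degrade(b, "mutate", {"p_sub": 0.04}, 200 + i)
                     for i in range(3)}}
        clusters, leftovers = cs.cluster_pass1(copies)
        clusters, orphans = cs.rescue_pass2(clusters, leftovers, copies)
        clades = {k: ("GalEa" if k.startswith("c") else "FunCo1")
                  for k in copies}
        fams, more = cs.validate_families(clusters, copies, clades)
        # partition: every non-orphan copy in exactly one family
        seen = [m for f in fams for m in f.members]
        assert sorted(seen + orphans + more) == sorted(copies)
        assert len(seen) == len(set(seen))
        # all intra-family curated identities >= 80
        for f in fams:
            degapped = {m: f.alignment[m].replace("-", "") for m in f.members}
            for i, x in enumerate(f.members):
                for y in f.members[i + 1:]:
                    ident, _ = fam.dna_identity_coverage(degapped[x],
                                                         degapped[y])
                    assert ident >= 80.0

    def test_three_families_in_three_out(self):
        """F families at <= 60% inter-identity come out as exactly F."""
        base = cs.make_element(cs.galea_spec("X"), 5)
        rng = np.random.default_rng(0)
        copies, clades = {}, {}
        for fi in range(3):
            anc = cs.degrade(base, "mutate", {"p_sub": 0.40}, 300 + fi)
            for i in range(3):
                name = f"f{fi}m{i}"
                copies[name] = cs.degrade(anc, "mutate", {"p_sub": 0.03},
                                          400 + 10 * fi + i)
                clades[name] = "GalEa"
        clusters, leftovers = cs.cluster_pass1(copies)
        clusters, orphans = cs.rescue_pass2(clusters, leftovers, copies)
        fams, more = cs.validate_families(clusters, copies, clades)
        assert len(fams) == 3
        groups = {tuple(sorted(f.members)) for f in fams}
        assert groups == {tuple(f"f{fi}m{i}" for i in range(3))
                          for fi in range(3)}


class TestAssignOrphans:
    def test_ripped_orphan_assigned_to_galea(self, panel):
        elem = cs.make_element(cs.galea_spec("FamA"), 1)
        ripped = cs.degrade(elem, "rip", {"target_at": 0.72}, 7)
        dom = cs.extract_rt_rnaseh(elem, panel)
        db = {"F001": ("GalEa", dom.protein)}
        calls = cs.assign_orphans(
            {"orp": ripped}, db,
            translator=lambda dna: cl.rip_aware_translate(dna, panel))
        assert calls["orp"] == "GalEa"

    def test_random_sequence_unassigned(self, panel):
        dom, _ = cs.synth.clade_domain_protein("GalEa")
        calls = cs.assign_orphans(
            {"rnd": cs.make_background(4000, 0.5, 9)},
            {"F001": ("GalEa", dom)},
            translator=lambda dna: cl.rip_aware_translate(dna, panel))
        assert calls["rnd"] == "unassigned"

    def test_short_alignment_unassigned(self, panel):
        """An orphan aligning over only ~200 aa fails the length rule."""
        elem = cs.make_element(cs.galea_spec("FamA"), 1)
        dom = cs.extract_rt_rnaseh(elem, panel)
        short_ref = dom.protein[:200]
        calls = cs.assign_orphans(
            {"orp": elem}, {"F001": ("GalEa", short_ref)},
            translator=lambda dna: cl.rip_aware_translate(dna, panel))
        assert calls["orp"] == "unassigned"
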