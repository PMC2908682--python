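import itertools
import math

import pytest

from conftest import mismatch11_site, perfect_site

from mimdesign.design import (
    DesignError,
    DesignParams,
    MimicStatus,
    capture_matrix,
    choose_bulge_sequence,
    design_mimic_site,
    name_mimic,
    validate_mimic,
)
from mimdesign.duplex import align_duplex, is_capturing, is_cleavable, score_duplex
from mimdesign.fixtures import FixtureSpec, generate_mirna_set
from mimdesign.seqio import Alphabet, MatureMiRNA, NucleotideSequence


def _mirna(mirna_id, seq):
    return MatureMiRNA.from_id(mirna_id, NucleotideSequence(seq, Alphabet.RNA))


class TestDesignGeometry:
    @pytest.mark.parametrize("length", [19, 20, 21, 22, 24])
    def test_site_length_is_target_minus_one_plus_bulge(self, length):
        spec = FixtureSpec(seed=13, n_families=3, members_per_family=1,
                           mirna_length=length)
        for mirna in generate_mirna_set(spec):
            mimic = design_mimic_site(mirna)
            assert len(mimic.site) == length - 1 + 3

    def test_bulge_replaces_partner_of_position_11(self, mirna21, sparams, dparams):
        mimic = design_mimic_site(mirna21, sparams, dparams)
        aln = align_duplex(mirna21, mimic.site, sparams)
        assert aln.unpaired_mirna == (11,)
        assert aln.bulge_flanks == (10, 12)
        assert aln.bulge_length == dparams.bulge_length
        # for a 21-nt miRNA the bulge occupies site positions 11-13 (1-based)
        assert mimic.bulge_interval == (10, 13)

    def test_fresh_design_is_functional_for_all_sources(self, catalogue5):
        for mirna in catalogue5:
            mimic = design_mimic_site(mirna)
            assert mimic.status is MimicStatus.MIMIC_FUNCTIONAL
            rep = validate_mimic(mimic.site, mirna)
            assert rep.capturing and not rep.cleavable


class TestChooseBulgeSequence:
    def _parts(self, mirna, dparams):
        rc = str(perfect_site(mirna))
        pos = dparams.bulge_replaces_position
        idx = len(mirna) - pos  # 0-based partner of the bulged position
        return rc[:idx], rc[idx + 1:]

    def test_first_admissible_candidate_returned(self, mirna21, sparams, dparams):
        site5, site3 = self._parts(mirna21, dparams)
        chosen, log = choose_bulge_sequence([mirna21], site5, site3, sparams, dparams)
        # recompute the admissible set by brute force over all 64 3-mers
        admissible = []
        for cand in itertools.product("ACGT", repeat=3):
            bulge = "".join(cand)
            site = site5 + bulge + site3
            max_run = max(len(list(g)) for _, g in itertools.groupby(site))
            aln = align_duplex(mirna21, site, sparams)
            score = score_duplex(aln, sparams)
            ok = (
                max_run <= dparams.homopolymer_max
                and not is_cleavable(aln, score, sparams)
                and is_capturing(aln, score, sparams)
                and aln.bulge_site_interval == (len(site5), len(site5) + 3)
            )
            if ok:
                admissible.append(bulge)
        assert chosen == admissible[0]
        assert {e["candidate"] for e in log}.isdisjoint(admissible)

    def test_pair_restoring_candidate_geometry_is_inadmissible(self, sparams, dparams):
        # a bulge starting with the Watson-Crick partner of position 11 lets
        # the centre re-pair: the minimum-score alignment collapses to a
        # 2-nt bulge next to a restored central pair, so the candidate fails
        # the intended-geometry requirement and capture is lost
        mirna = _mirna("xxx-miR600a", "CGUUAAUUACCUCCUCGGGAU")  # position 11 = C
        site5, site3 = self._parts(mirna, dparams)
        site = site5 + "G" + "AA" + site3  # G pairs the central C
        aln = align_duplex(mirna, site, sparams)
        score = score_duplex(aln, sparams)
        assert aln.bulge_length < dparams.bulge_length
        assert not is_capturing(aln, score, sparams)
        chosen, _ = choose_bulge_sequence([mirna], site5, site3, sparams, dparams)
        assert not chosen.startswith("G")

    def test_homopolymer_run_with_flanks_rejected(self, sparams, dparams):
        # positions 12-13 are U,U so the site 5' part ends in AA; an AAA bulge
        # would create a 5-nt A run although position 11 (C) mismatches A
        mirna = _mirna("xxx-miR601a", "ACGUACGUACCUUACGUACGU")
        site5, site3 = self._parts(mirna, dparams)
        assert site5.endswith("AA")
        chosen, log = choose_bulge_sequence([mirna], site5, site3, sparams, dparams)
        reasons = {e["candidate"]: e["reason"] for e in log}
        assert "homopolymer" in reasons["AAA"]
        assert chosen != "AAA"


class TestValidateMimic:
    def test_trichotomy_for_one_mirna(self, mirna21, sparams, dparams):
        mimic = design_mimic_site(mirna21, sparams, dparams)
        assert validate_mimic(mimic.site, mirna21, sparams).status is MimicStatus.MIMIC_FUNCTIONAL
        assert validate_mimic(perfect_site(mirna21), mirna21, sparams).status is MimicStatus.CLEAVABLE
        status = validate_mimic(mismatch11_site(mirna21), mirna21, sparams).status
        assert status is not MimicStatus.MIMIC_FUNCTIONAL

    def test_heavily_mismatched_site_is_inert(self, mirna21, sparams):
        site = list(str(perfect_site(mirna21)))
        for pos in (3, 5, 7, 9, 15, 18):  # scatter non-pairing bases
            base = mirna21.sequence[pos - 1]
            site[len(mirna21) - pos] = {"A": "C", "C": "A", "G": "A", "U": "C"}[base]
        rep = validate_mimic("".join(site), mirna21, sparams)
        assert rep.status is MimicStatus.INERT


class TestSubgroupDesign:
    def test_wobble_coverable_variants_share_one_mimic(self):
        a = _mirna("xxx-miR700a", "CGUUAAUUACUCCUCCGGGAU")
        b = _mirna("xxx-miR700b", "CGUUGAUUACUCCUCCGGGAU")  # A5->G, coverable by T
        mimic = design_mimic_site([a, b])
        for member in (a, b):
            assert validate_mimic(mimic.site, member).status is MimicStatus.MIMIC_FUNCTIONAL

    def test_non_coverable_column_raises(self):
        a = _mirna("xxx-miR701a", "CGUUAAUUACUCCUCCGGGAU")
        b = _mirna("xxx-miR701b", "CGUUCAUUACUCCUCCGGGAU")  # A5->C: {A,C} has no cover
        with pytest.raises(DesignError, match="position 5"):
            design_mimic_site([a, b])

    def test_shorter_member_captured_with_dangling_site_end(self):
        long = _mirna("xxx-miR702a", "CGUUAAUUACUCCUCCGGGAU")
        short = _mirna("xxx-miR702b", "CGUUAAUUACUCCUCCGGG")  # same 5' 19 nt
        mimic = design_mimic_site([long, short])
        assert len(mimic.site) == 23  # designed against the longest member
        trimmed = NucleotideSequence(mimic.site[2:], Alphabet.DNA)
        assert validate_mimic(trimmed, short).status is MimicStatus.MIMIC_FUNCTIONAL


@pytest.mark.parametrize(
    "family, variants, whole, expected",
    [
        ("172", ["a"], True, "MIM172"),
        ("169", ["g", "d", "f", "e"], False, "MIM169defg"),
        ("161", [".1"], False, "MIM161.1"),
    ],
)
def test_name_mimic(family, variants, whole, expected):
    subgroup = [
        _mirna(f"xxx-miR{family}{v}", "CGUUAAUUACUCCUCCGGGAU") for v in variants
    ]
    assert name_mimic(family, subgroup, whole_family=whole) == expected


class TestCaptureMatrix:
    def test_diagonal_all_true_for_designed_set(self, catalogue5, sparams):
        mimics = [design_mimic_site(m) for m in catalogue5]
        matrix = capture_matrix(mimics, catalogue5, sparams)
        for mimic in mimics:
            for source in mimic.sources:
                assert matrix.captures.at[mimic.name, source]

    def test_two_noncentral_substitutions_cross_capture(self, sparams):
        a = _mirna("xxx-miR800a", "CGUUAAUUACUCCUCCGGGAU")
        # positions 15 and 16 flipped to non-pairing bases: outside the core,
        # outside the seed region, total penalty 2.0 <= 3.0
        b = _mirna("xxx-miR801a", "CGUUAAUUACUCCUAGGGGAU")
        mimic_a = design_mimic_site(a)
        matrix = capture_matrix([mimic_a], [a, b], sparams)
        assert matrix.captures.at[mimic_a.name, "xxx-miR801a"]
        assert matrix.off_targets() == [(mimic_a.name, "xxx-miR801a")]

    def test_eight_substitutions_not_captured(self, sparams):
        a = _mirna("xxx-miR802a", "CGUUAAUUACUCCUCCGGGAU")
        b = _mirna("xxx-miR803a", "CGACGGAAUCUCCUCCGGGAU")  # diverged 5' half
        mimic_a = design_mimic_site(a)
        matrix = capture_matrix([mimic_a], [b], sparams)
        assert not matrix.captures.at[mimic_a.name, "xxx-miR803a"]

    def test_unalignable_pair_marked(self, mirna21, sparams):
        mimic = design_mimic_site(mirna21)  # 23-nt site
        long_mirna = _mirna("xxx-miR900a", "CGUUAAUUACUCCUCCGGGAUCGUAC")  # 26 nt
        matrix = capture_matrix([mimic], [long_mirna], sparams)
        assert not matrix.captures.at[mimic.name, "xxx-miR900a"]
        assert math.isnan(matrix.noncentral.at[mimic.name, "xxx-miR900a"])
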