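"""pegRNA construction rules: flap, PBS, HA, pair complementarity."""

import numpy as np
import pytest

from conftest import random_seq
from wtpe.design import (
    DEFAULT_SCAFFOLD,
    EditSpec,
    design_pair,
    design_single,
    validate_plan,
)
from wtpe.errors import CoordinateError, DesignError
from wtpe.locus import Locus, SpacerSite, reverse_complement
from wtpe.simulate import make_deletion_scenario, make_translocation_scenario


def plus_site_at(locus: Locus, cut: int) -> SpacerSite:
    s = cut - 17
    return SpacerSite(
        locus.name,
        locus.sequence[s : s + 20],
        locus.sequence[s + 20 : s + 23],
        "+",
        (s, s + 20),
    )


@pytest.fixture()
def toy60(rng):
    chars = list(random_seq(rng, 60))
    chars[34] = "G"  # PAM GG so the + site cuts at 30
    chars[35] = "G"
    return Locus("toy60", "".join(chars))


class TestDesignSingle:
    def test_flap_and_pbs_hand_construction(self, toy60):
        site = plus_site_at(toy60, 30)
        peg = design_single(site, toy60, EditSpec(edit_seq="T", ha_len=13, pbs_len=13))
        seq = toy60.sequence
        assert peg.flap_dna == "T" + seq[30:43]
        assert peg.pbs == reverse_complement(seq[17:30])
        assert peg.rt_template == reverse_complement(peg.flap_dna)
        assert peg.full_sequence == (
            peg.spacer + DEFAULT_SCAFFOLD + peg.rt_template + peg.pbs
        )
        assert peg.spacer == site.protospacer

    def test_no_ha_flap_is_edit_only(self, toy60):
        site = plus_site_at(toy60, 30)
        peg = design_single(site, toy60, EditSpec(edit_seq="GATATC", ha_len=0))
        assert peg.flap_dna == "GATATC"

    def test_ecorv_appended_when_absent(self, toy60):
        site = plus_site_at(toy60, 30)
        peg = design_single(
            site, toy60, EditSpec(edit_seq="AAA", ha_len=0, include_ecorv=True)
        )
        assert peg.flap_dna == "AAAGATATC"
        # palindromic site reads identically in the RT template
        assert "GATATC" in peg.rt_template

    def test_ecorv_with_ha_is_design_error(self, toy60):
        site = plus_site_at(toy60, 30)
        with pytest.raises(DesignError):
            design_single(
                site, toy60, EditSpec(edit_seq="A", ha_len=10, include_ecorv=True)
            )

    def test_minus_strand_matches_design_on_revcomp_locus(self, rng):
        """Strand symmetry: a - site design equals the + design on the mirror."""
        chars = list(random_seq(rng, 80))
        chars[40 - 6] = "C"  # CCN PAM on + so a - site cuts at 40
        chars[40 - 5] = "C"
        locus = Locus("fwd", "".join(chars))
        n = len(locus)
        s = 40 - 3
        minus = SpacerSite(
            "fwd",
            reverse_complement(locus.sequence[s : s + 20]),
            reverse_complement(locus.sequence[s - 3 : s]),
            "-",
            (s, s + 20),
        )
        mirror = Locus("rev", reverse_complement(locus.sequence))
        plus = plus_site_at(mirror, n - 40)
        spec = EditSpec(edit_seq="TT", ha_len=10, pbs_len=10)
        peg_minus = design_single(minus, locus, spec)
        peg_plus = design_single(plus, mirror, spec)
        assert peg_minus.flap_dna == peg_plus.flap_dna
        assert peg_minus.pbs == peg_plus.pbs

    def test_window_exceeding_locus_raises(self, toy60):
        site = plus_site_at(toy60, 30)
        with pytest.raises(CoordinateError):
            design_single(site, toy60, EditSpec(edit_seq="T", ha_len=40))
        with pytest.raises(CoordinateError):
            design_single(site, toy60, EditSpec(edit_seq="T", ha_len=5, pbs_len=17 + 15))


class TestDesignPair:
    def test_c2_flaps_mutually_reverse_complementary(self):
        _, plan, _ = make_deletion_scenario(seed=7, design_class="C2", edit_seq="CTGCAG")
        assert reverse_complement(plan.pegrna_a.flap_dna) == plan.pegrna_b.flap_dna
        assert plan.pegrna_a.flap_dna == "CTGCAG"

    def test_c1_ha_copies_retained_sequence_beyond_partner_cut(self):
        locus, plan, _ = make_deletion_scenario(seed=8, design_class="C1", ha_len=10)
        cut_a = plan.pegrna_a.site.cut_position
        cut_b = plan.pegrna_b.site.cut_position
        flap_a = plan.pegrna_a.flap_dna
        assert flap_a == plan.edit_seq + locus.sequence[cut_b : cut_b + 10]
        flap_b = plan.pegrna_b.flap_dna
        assert flap_b == reverse_complement(plan.edit_seq) + reverse_complement(
            locus.sequence[cut_a - 10 : cut_a]
        )

    def test_deletion_retained_segments(self):
        locus, plan, _ = make_deletion_scenario(seed=9, arm_len=100, del_len=600)
        assert plan.retained_segments == (
            "toy_locus:0-100(+)",
            f"toy_locus:700-{len(locus)}(+)",
        )

    def test_wrong_orientation_rejected(self):
        locus, plan, _ = make_deletion_scenario(seed=10)
        a, b = plan.pegrna_a.site, plan.pegrna_b.site
        with pytest.raises(DesignError):
            design_pair(b, a, locus, plan.edit_spec, "C1")  # PAMs point outward

    def test_overlapping_protospacers_rejected(self):
        locus, plan, _ = make_deletion_scenario(seed=11, arm_len=150, del_len=300)
        a = plan.pegrna_a.site
        # fabricate a - site overlapping a's protospacer
        s = a.protospacer_interval[0] + 5
        b = SpacerSite(
            locus.name,
            reverse_complement(locus.sequence[s : s + 20]),
            "AGG",
            "-",
            (s, s + 20),
        )
        with pytest.raises((DesignError, CoordinateError)):
            design_pair(a, b, locus, plan.edit_spec, "C1")

    def test_translocation_intent_detected(self):
        _, _, plan, _ = make_translocation_scenario(seed=12)
        assert plan.intent == "translocation"
        assert plan.locus_names == ("toy_chrA", "toy_chrB")


class TestValidatePlan:
    def test_well_formed_c1_plan_has_no_findings(self):
        _, plan, _ = make_deletion_scenario(seed=13)
        assert validate_plan(plan) == []

    def test_short_ha_warns(self):
        _, plan, _ = make_deletion_scenario(seed=14, ha_len=6)
        findings = validate_plan(plan)
        assert any(f.code == "HA_BELOW_8" and f.level == "warning" for f in findings)

    def test_corrupted_c2_complementarity_is_error(self):
        # non-palindromic edit so the corrupted flap is detectable
        _, plan, _ = make_deletion_scenario(seed=15, design_class="C2", edit_seq="AAACCC")
        import dataclasses

        bad_b = dataclasses.replace(
            plan.pegrna_b, rt_template=plan.pegrna_a.rt_template
        )
        bad = dataclasses.replace(plan, pegrna_b=bad_b)
        findings = validate_plan(bad)
        assert any(f.code == "C2_COMPLEMENTARITY" and f.level == "error" for f in findings)

    def test_edit_free_c2_is_error(self):
        _, plan, _ = make_deletion_scenario(seed=16, design_class="C2", edit_seq="AC")
        import dataclasses

        spec = dataclasses.replace(plan.edit_spec, edit_seq="")
        bad = dataclasses.replace(plan, edit_spec=spec)
        findings = validate_plan(bad)
        assert any(f.code == "C2_EMPTY_EDIT" for f in findings)

    def test_pbs_outside_melting_window_warns(self):
        _, plan, _ = make_deletion_scenario(seed=17, pbs_len=20)
        findings = validate_plan(plan)
        assert any(f.code == "PBS_WINDOW" for f in findings)
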