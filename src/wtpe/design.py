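"""pegRNA construction for single edits, paired deletions and translocations.

A pegRNA is spacer + invariant scaffold + 3' extension, where the extension
is the RT template followed by the primer binding site (PBS), all written
5'->3'.  The RT template is stored as DNA and is the reverse complement of
the DNA flap that reverse transcriptase appends to the broken non-target
strand:

* ``flap = edit_seq + HA`` for homology-armed (C1-style) designs, where the
  HA copies the genomic sequence immediately PAM-proximal of the cut (single
  edits) or the retained sequence beyond the partner cut (paired designs);
* ``flap = edit_seq`` for homology-independent (C2-style) designs, with the
  two flaps of a pair mutually reverse-complementary over the edit.

The PBS is the reverse complement of the ``pbs_len`` nucleotides immediately
5' of the cut on the non-target strand (the strand carrying the protospacer).

All window arithmetic is done in a "plus frame": for a - strand site the
locus is reverse-complemented so the site reads as a + strand site, windows
are taken there, and results are already strand-correct because pegRNA parts
are defined on the site's own strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .errors import CoordinateError, DesignError
from .locus import (
    Locus,
    SpacerSite,
    format_interval,
    reverse_complement,
)

#: standard SpCas9 sgRNA scaffold, stored as DNA (T for U); configurable.
DEFAULT_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
)

ECORV_SITE = "GATATC"

#: shortest homology arm with demonstrated intermolecular homology search
MIN_RECOMMENDED_HA = 8
PBS_RANGE = (8, 17)

Intent = Literal["single_edit", "deletion", "translocation"]
DesignClass = Literal["C1", "C2"]


@dataclass(frozen=True)
class EditSpec:
    """What to write at the junction and how the pegRNA should be shaped.

    ``ha_len == 0`` means a homology-independent design (the flap carries only
    the edit); ``flap_override`` replaces the computed flap entirely, which is
    how single-base conversions (flap differing from the reference by a
    substitution) are expressed.
    """

    edit_seq: str = ""
    ha_len: int = 13
    pbs_len: int = 13
    include_ecorv: bool = False
    flap_override: str | None = None

    def __post_init__(self) -> None:
        if self.pbs_len <= 0:
            raise DesignError("pbs_len must be positive")
        if self.ha_len < 0:
            raise DesignError("ha_len must be non-negative")


@dataclass(frozen=True)
class PegRNA:
    """spacer + scaffold + RT template + PBS, each stored 5'->3' as DNA."""

    site: SpacerSite
    spacer: str
    scaffold: str
    rt_template: str
    pbs: str

    @property
    def flap_dna(self) -> str:
        """The 3' ssDNA flap written onto the non-target strand."""
        return reverse_complement(self.rt_template)

    @property
    def full_sequence(self) -> str:
        return self.spacer + self.scaffold + self.rt_template + self.pbs

    def as_rna(self) -> str:
        return self.full_sequence.replace("T", "U")


@dataclass(frozen=True)
class DesignPlan:
    """A pegRNA (or pair) with its loci, class and edit bookkeeping."""

    intent: Intent
    design_class: DesignClass
    pegrna_a: PegRNA
    pegrna_b: PegRNA | None
    locus_names: tuple[str, ...]
    edit_spec: EditSpec
    retained_segments: tuple[str, ...] = ()

    @property
    def edit_seq(self) -> str:
        return self.edit_spec.edit_seq

    def to_dict(self) -> dict:
        def peg(p: PegRNA | None) -> dict | None:
            if p is None:
                return None
            return {
                "locus": p.site.locus_name,
                "protospacer_interval": list(p.site.protospacer_interval),
                "strand": p.site.strand,
                "cut_position": p.site.cut_position,
                "spacer": p.spacer,
                "scaffold": p.scaffold,
                "rt_template": p.rt_template,
                "pbs": p.pbs,
                "full_sequence": p.full_sequence,
                "flap_dna": p.flap_dna,
            }

        return {
            "intent": self.intent,
            "design_class": self.design_class,
            "edit_seq": self.edit_spec.edit_seq,
            "ha_len": self.edit_spec.ha_len,
            "pbs_len": self.edit_spec.pbs_len,
            "retained_segments": list(self.retained_segments),
            "pegrna_a": peg(self.pegrna_a),
            "pegrna_b": peg(self.pegrna_b),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def parts_table(self) -> pd.DataFrame:
        """pegRNA parts as a tidy table (for TSV export / cloning oligos)."""
        rows = []
        for label, p in (("a", self.pegrna_a), ("b", self.pegrna_b)):
            if p is None:
                continue
            rows.append(
                {
                    "pegrna": label,
                    "locus": p.site.locus_name,
                    "site": p.site.interval_str,
                    "spacer": p.spacer,
                    "scaffold": p.scaffold,
                    "rt_template": p.rt_template,
                    "pbs": p.pbs,
                    "full_sequence": p.full_sequence,
                    "extension_oligo": p.rt_template + p.pbs,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class Finding:
    level: Literal["error", "warning"]
    code: str
    message: str


def _plus_frame(site: SpacerSite, locus: Locus) -> tuple[str, int]:
    """Return (sequence, cut) in a frame where the site reads as + strand."""
    if site.locus_name != locus.name:
        raise DesignError(f"site is on {site.locus_name!r}, not {locus.name!r}")
    if site.strand == "+":
        return locus.sequence, site.cut_position
    return reverse_complement(locus.sequence), len(locus) - site.cut_position


def _build_flap(seq: str, cut: int, spec: EditSpec) -> str:
    """Flap written at a cut in plus-frame coordinates (single-site rule)."""
    if spec.flap_override is not None:
        return spec.flap_override
    if spec.include_ecorv:
        if spec.ha_len > 0:
            raise DesignError(
                "EcoRV tagging is a homology-independent design; the HA occupies "
                "the 5' proximal RT-template portion (set ha_len=0)"
            )
        if ECORV_SITE in spec.edit_seq:
            return spec.edit_seq
        return spec.edit_seq + ECORV_SITE
    if spec.ha_len == 0:
        return spec.edit_seq
    if cut + spec.ha_len > len(seq):
        raise CoordinateError("homology arm window extends past the locus end")
    return spec.edit_seq + seq[cut : cut + spec.ha_len]


def _build_pbs(seq: str, cut: int, pbs_len: int) -> str:
    if cut - pbs_len < 0:
        raise CoordinateError("PBS window extends past the locus start")
    return reverse_complement(seq[cut - pbs_len : cut])


def _make_pegrna(site: SpacerSite, flap: str, pbs: str, scaffold: str) -> PegRNA:
    return PegRNA(
        site=site,
        spacer=site.protospacer,
        scaffold=scaffold,
        rt_template=reverse_complement(flap),
        pbs=pbs,
    )


def design_single(
    site: SpacerSite,
    locus: Locus,
    spec: EditSpec,
    scaffold: str = DEFAULT_SCAFFOLD,
) -> PegRNA:
    """Design one pegRNA writing ``edit_seq`` (plus optional HA) at the cut.

    The HA copies the ``ha_len`` nucleotides of the non-target strand
    immediately PAM-proximal of the cut, so the flap can re-anneal to the
    PAM-proximal fragment for homology-mediated integration.
    """
    seq, cut = _plus_frame(site, locus)
    flap = _build_flap(seq, cut, spec)
    pbs = _build_pbs(seq, cut, spec.pbs_len)
    return _make_pegrna(site, flap, pbs, scaffold)


def design_pair(
    site_a: SpacerSite,
    site_b: SpacerSite,
    loci: Locus | Sequence[Locus],
    spec: EditSpec,
    design_class: DesignClass,
    scaffold: str = DEFAULT_SCAFFOLD,
) -> DesignPlan:
    """Design a bi-directional pegRNA pair for a deletion or translocation.

    Orientation rule: both PAMs must point into the fragment being removed or
    exchanged, i.e. site_a on + strand and site_b on - strand (in the frame
    where site_a's locus comes first).  C2 pairs carry only mutually
    reverse-complementary edits; C1 pairs add, to each flap, an HA identical
    to the first ``ha_len`` retained nucleotides beyond the *partner* cut, so
    the accurate join is ``retained_a + edit + retained_b``.
    """
    if isinstance(loci, Locus):
        locus_a = locus_b = loci
        intent: Intent = "deletion"
    else:
        locus_a, locus_b = loci
        intent = "deletion" if locus_a.name == locus_b.name else "translocation"

    if design_class not in ("C1", "C2"):
        raise DesignError(f"unknown design class {design_class!r}")
    if design_class == "C2" and spec.ha_len != 0:
        spec = EditSpec(
            edit_seq=spec.edit_seq,
            ha_len=0,
            pbs_len=spec.pbs_len,
            include_ecorv=spec.include_ecorv,
        )
    if design_class == "C1" and spec.ha_len == 0:
        raise DesignError("C1 designs require ha_len > 0")

    if site_a.strand != "+" or site_b.strand != "-":
        raise DesignError(
            "paired design requires PAMs pointing into the removed/exchanged "
            "fragment: site_a on '+' and site_b on '-' "
            f"(got {site_a.strand!r}/{site_b.strand!r})"
        )
    cut_a, cut_b = site_a.cut_position, site_b.cut_position
    if intent == "deletion":
        if cut_a >= cut_b:
            raise CoordinateError("deletion requires cut_a < cut_b on the locus")
        ia, ib = site_a.protospacer_interval, site_b.protospacer_interval
        if ia[1] > ib[0]:
            raise DesignError("protospacers overlap; junctions cannot form cleanly")

    edit = spec.edit_seq
    ha = spec.ha_len if design_class == "C1" else 0

    # pegRNA a: NTS is the + strand of locus_a; flap extends retained_a rightward.
    seq_a, seq_b = locus_a.sequence, locus_b.sequence
    if ha:
        if cut_b + ha > len(seq_b):
            raise CoordinateError("HA for pegRNA a extends past partner locus end")
        if cut_a - ha < 0:
            raise CoordinateError("HA for pegRNA b extends past partner locus start")
    flap_a = edit + (seq_b[cut_b : cut_b + ha] if ha else "")
    pbs_a = _build_pbs(seq_a, cut_a, spec.pbs_len)
    peg_a = _make_pegrna(site_a, flap_a, pbs_a, scaffold)

    # pegRNA b: NTS is the - strand of locus_b; work in its plus frame.
    frame_b, fcut_b = _plus_frame(site_b, locus_b)
    flap_b = reverse_complement(edit) + (
        reverse_complement(seq_a[cut_a - ha : cut_a]) if ha else ""
    )
    pbs_b = _build_pbs(frame_b, fcut_b, spec.pbs_len)
    peg_b = _make_pegrna(site_b, flap_b, pbs_b, scaffold)

    if intent == "deletion":
        retained = (
            format_interval(locus_a.name, 0, cut_a),
            format_interval(locus_b.name, cut_b, len(locus_b)),
        )
    else:
        retained = (
            format_interval(locus_a.name, 0, cut_a),
            format_interval(locus_b.name, cut_b, len(locus_b)),
        )

    return DesignPlan(
        intent=intent,
        design_class=design_class,
        pegrna_a=peg_a,
        pegrna_b=peg_b,
        locus_names=(locus_a.name, locus_b.name),
        edit_spec=spec,
        retained_segments=retained,
    )


def validate_plan(plan: DesignPlan) -> list[Finding]:
    """Machine-checkable findings about a plan; nothing is raised."""
    findings: list[Finding] = []
    spec = plan.edit_spec

    if plan.design_class == "C2" and plan.pegrna_b is not None:
        fa, fb = plan.pegrna_a.flap_dna, plan.pegrna_b.flap_dna
        if reverse_complement(fa) != fb:
            findings.append(
                Finding(
                    "error",
                    "C2_COMPLEMENTARITY",
                    "C2 flaps are not mutually reverse-complementary",
                )
            )
        if not spec.edit_seq:
            findings.append(
                Finding(
                    "error",
                    "C2_EMPTY_EDIT",
                    "C2 flaps carry only the edit; an empty edit leaves nothing "
                    "for the flaps to anneal over",
                )
            )
    if plan.design_class == "C1" and 0 < spec.ha_len < MIN_RECOMMENDED_HA:
        findings.append(
            Finding(
                "warning",
                "HA_BELOW_8",
                f"HA of {spec.ha_len} nt is below the {MIN_RECOMMENDED_HA}-nt "
                "microhomology shown sufficient for homology search",
            )
        )
    lo, hi = PBS_RANGE
    if not lo <= spec.pbs_len <= hi:
        findings.append(
            Finding(
                "warning",
                "PBS_WINDOW",
                f"PBS of {spec.pbs_len} nt is outside the usual melting window "
                f"[{lo}, {hi}]",
            )
        )
    return findings
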