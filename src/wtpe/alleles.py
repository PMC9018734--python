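"""Exact expected sequences for each editing-outcome structure.

For every design intent the predictor emits:

* the wild-type reference(s);
* the *accurate-edit* allele — retained fragment(s) joined through exactly one
  copy of the edit, with the homology arm (if any) collapsed to a single copy
  by successful homology-mediated joining;
* indel *archetypes*: ``ha_duplication`` (flap blunt-ligated by NHEJ without
  collapsing the HA, so the HA appears twice, flanking the join) and
  ``no_flap_join`` (direct end joining with no flap written at all);
* for translocations, the reciprocal derivative as a separately labelled
  sequence — predicted for completeness although it is typically not
  recovered experimentally.

Intervals of the inserted edit (junction) and of the retained 17-nt residue
spacers are annotated in accurate-allele coordinates (0-based, half-open).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .design import DesignPlan
from .errors import CoordinateError, ReferenceMismatchError
from .locus import RESIDUE_SPACER_LEN, Locus, reverse_complement


@dataclass(frozen=True)
class PredictedAlleles:
    """Reference set for one design: WT, accurate edit and indel archetypes."""

    wt_refs: dict[str, str]
    accurate_ref: str
    junction_interval: tuple[int, int]
    residue_spacer_intervals: tuple[tuple[int, int], ...]
    archetype_refs: dict[str, str]
    wt_cut_positions: dict[str, tuple[int, ...]]
    edit_seq: str
    reciprocal_ref: str | None = None
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "wt_refs": self.wt_refs,
            "accurate_ref": self.accurate_ref,
            "junction_interval": list(self.junction_interval),
            "residue_spacer_intervals": [list(x) for x in self.residue_spacer_intervals],
            "archetype_refs": self.archetype_refs,
            "wt_cut_positions": {k: list(v) for k, v in self.wt_cut_positions.items()},
            "edit_seq": self.edit_seq,
            "reciprocal_ref": self.reciprocal_ref,
            "notes": list(self.notes),
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PredictedAlleles":
        return cls(
            wt_refs=dict(d["wt_refs"]),
            accurate_ref=d["accurate_ref"],
            junction_interval=tuple(d["junction_interval"]),
            residue_spacer_intervals=tuple(tuple(x) for x in d["residue_spacer_intervals"]),
            archetype_refs=dict(d["archetype_refs"]),
            wt_cut_positions={k: tuple(v) for k, v in d["wt_cut_positions"].items()},
            edit_seq=d["edit_seq"],
            reciprocal_ref=d.get("reciprocal_ref"),
            notes=tuple(d.get("notes", ())),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PredictedAlleles":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _mirror(interval: tuple[int, int], length: int) -> tuple[int, int]:
    return (length - interval[1], length - interval[0])


def predict_single_edit(plan: DesignPlan, locus: Locus) -> PredictedAlleles:
    """Accurate allele and archetypes for a single-site flap integration.

    The accurate allele inserts the flap at the cut; a homology arm anneals to
    (and therefore replaces, identically) the PAM-proximal sequence it copies,
    so only one HA copy remains.  The HA-duplication archetype joins the full
    flap bluntly, leaving both the flap HA and its genomic copy.
    """
    if plan.intent != "single_edit":
        raise ValueError(f"plan intent is {plan.intent!r}, expected 'single_edit'")
    peg = plan.pegrna_a
    spec = plan.edit_spec
    site = peg.site

    # work in the frame where the site reads as + strand
    if site.strand == "+":
        seq, cut = locus.sequence, site.cut_position
    else:
        seq, cut = reverse_complement(locus.sequence), len(locus) - site.cut_position

    flap = peg.flap_dna
    consumed = spec.ha_len
    if cut + consumed > len(seq):
        raise CoordinateError("HA window extends past the locus end")
    if spec.flap_override is None and consumed > 0:
        ha = flap[len(spec.edit_seq) :]
        if ha != seq[cut : cut + consumed]:
            raise ReferenceMismatchError(
                "pegRNA homology arm does not match the reference downstream of the cut"
            )
        junction_len = len(flap) - consumed
    else:
        junction_len = len(flap)

    accurate = seq[:cut] + flap + seq[cut + consumed :]
    junction = (cut, cut + junction_len)
    residues = ((cut - RESIDUE_SPACER_LEN, cut),)

    archetypes: dict[str, str] = {"no_flap_join": seq}
    if spec.flap_override is None and consumed > 0:
        archetypes["ha_duplication"] = seq[:cut] + flap + seq[cut:]

    if site.strand == "-":
        la = len(accurate)
        junction = _mirror(junction, la)
        residues = tuple(_mirror(r, la) for r in residues)
        accurate = reverse_complement(accurate)
        archetypes = {k: reverse_complement(v) for k, v in archetypes.items()}

    return PredictedAlleles(
        wt_refs={locus.name: locus.sequence},
        accurate_ref=accurate,
        junction_interval=junction,
        residue_spacer_intervals=residues,
        archetype_refs=archetypes,
        wt_cut_positions={locus.name: (site.cut_position,)},
        edit_seq=spec.edit_seq if spec.flap_override is None else flap,
    )


def predict_deletion(plan: DesignPlan, locus: Locus) -> PredictedAlleles:
    """Accurate deletion allele: retained_a + edit + retained_b on one locus."""
    if plan.intent != "deletion":
        raise ValueError(f"plan intent is {plan.intent!r}, expected 'deletion'")
    cut_a = plan.pegrna_a.site.cut_position
    cut_b = plan.pegrna_b.site.cut_position
    if cut_a > cut_b:
        raise CoordinateError("deletion cuts out of order (cut_a > cut_b)")
    seq = locus.sequence
    edit = plan.edit_seq

    accurate = seq[:cut_a] + edit + seq[cut_b:]
    junction = (cut_a, cut_a + len(edit))
    residues = (
        (cut_a - RESIDUE_SPACER_LEN, cut_a),
        (junction[1], junction[1] + RESIDUE_SPACER_LEN),
    )
    archetypes = {"no_flap_join": seq[:cut_a] + seq[cut_b:]}
    if plan.design_class == "C1":
        flap_a = plan.pegrna_a.flap_dna
        archetypes["ha_duplication"] = seq[:cut_a] + flap_a + seq[cut_b:]

    return PredictedAlleles(
        wt_refs={locus.name: seq},
        accurate_ref=accurate,
        junction_interval=junction,
        residue_spacer_intervals=residues,
        archetype_refs=archetypes,
        wt_cut_positions={locus.name: (cut_a, cut_b)},
        edit_seq=edit,
    )


def predict_translocation(
    plan: DesignPlan, locus_a: Locus, locus_b: Locus
) -> PredictedAlleles:
    """Derivative-chromosome allele locus_a[:cut_a] + edit + locus_b[cut_b:].

    The reciprocal derivative (locus_b head + reverse-oriented edit + locus_a
    tail) is emitted separately with a note: balanced products are predicted
    by symmetry but are typically not observed.
    """
    if plan.intent != "translocation":
        raise ValueError(f"plan intent is {plan.intent!r}, expected 'translocation'")
    cut_a = plan.pegrna_a.site.cut_position
    cut_b = plan.pegrna_b.site.cut_position
    a, b = locus_a.sequence, locus_b.sequence
    edit = plan.edit_seq

    accurate = a[:cut_a] + edit + b[cut_b:]
    junction = (cut_a, cut_a + len(edit))
    residues = (
        (cut_a - RESIDUE_SPACER_LEN, cut_a),
        (junction[1], junction[1] + RESIDUE_SPACER_LEN),
    )
    reciprocal = b[:cut_b] + reverse_complement(edit) + a[cut_a:]
    archetypes = {"no_flap_join": a[:cut_a] + b[cut_b:]}
    if plan.design_class == "C1":
        archetypes["ha_duplication"] = a[:cut_a] + plan.pegrna_a.flap_dna + b[cut_b:]

    return PredictedAlleles(
        wt_refs={locus_a.name: a, locus_b.name: b},
        accurate_ref=accurate,
        junction_interval=junction,
        residue_spacer_intervals=residues,
        archetype_refs=archetypes,
        wt_cut_positions={locus_a.name: (cut_a,), locus_b.name: (cut_b,)},
        edit_seq=edit,
        reciprocal_ref=reciprocal,
        notes=(
            "reciprocal derivative predicted by symmetry; balanced products "
            "are typically not recovered",
        ),
    )


def predict(plan: DesignPlan, *loci: Locus) -> PredictedAlleles:
    """Dispatch on plan intent."""
    if plan.intent == "single_edit":
        return predict_single_edit(plan, loci[0])
    if plan.intent == "deletion":
        return predict_deletion(plan, loci[0])
    return predict_translocation(plan, loci[0], loci[1])


def write_alleles_fasta(alleles: PredictedAlleles, path: str | Path) -> None:
    """All predicted sequences as FASTA (WT, accurate, archetypes, reciprocal)."""
    with open(path, "w") as fh:
        for name, seq in alleles.wt_refs.items():
            fh.write(f">wt|{name}\n{seq}\n")
        fh.write(f">accurate\n{alleles.accurate_ref}\n")
        for name, seq in alleles.archetype_refs.items():
            fh.write(f">archetype|{name}\n{seq}\n")
        if alleles.reciprocal_ref is not None:
            fh.write(f">reciprocal\n{alleles.reciprocal_ref}\n")


def write_annotations_tsv(alleles: PredictedAlleles, path: str | Path) -> None:
    """BED-like sidecar (0-based half-open) of junction/residue intervals."""
    with open(path, "w") as fh:
        fh.write("sequence\tstart\tend\tfeature\n")
        j0, j1 = alleles.junction_interval
        fh.write(f"accurate\t{j0}\t{j1}\tedit_junction\n")
        for (s, e) in alleles.residue_spacer_intervals:
            fh.write(f"accurate\t{s}\t{e}\tresidue_spacer\n")
        for name, cuts in alleles.wt_cut_positions.items():
            for c in cuts:
                fh.write(f"wt|{name}\t{c}\t{c}\tcut_site\n")
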