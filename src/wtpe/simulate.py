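"""Synthetic inputs with known ground truth for every pipeline stage.

The read simulator is the generative counterpart of the outcome taxonomy:
per-read class labels are drawn from a stated mixture over {UNEDITED,
ACCURATE_EDIT, EDIT_WITH_INDEL, PURE_INDEL}; sequences come from the
predicted allele matching the label, with indels drawn from archetypes that
mirror the error structures seen at real junctions:

* ``ha_duplication`` — NHEJ blunt-ligates the flap without collapsing the
  homology arm, leaving the junction flanked by repeated HA copies;
* ``blunt_join`` — end resection at the junction boundary (a deletion flush
  against the edit);
* ``random_small`` — a small insertion or deletion (geometric sizes) placed
  near the junction but outside the edit itself.

Pure indels are built on the no-flap join (failed flap extension followed by
direct end joining), with a small indel at the join.  Sequencing error is a
per-base substitution rate and an optional per-base indel rate.  Everything
is deterministic under a fixed seed.

Gel and qPCR generators invert the corresponding efficiency formulas, so a
noise-free run recovers the stated true fraction exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alleles import PredictedAlleles, predict_deletion, predict_single_edit, predict_translocation
from .design import DesignPlan, EditSpec, design_pair, design_single
from .errors import ConfigError
from .locus import RESIDUE_SPACER_LEN, Locus, SpacerSite
from .quant import GelLane, QpcrSample

SIM_CLASSES = ("UNEDITED", "ACCURATE_EDIT", "EDIT_WITH_INDEL", "PURE_INDEL")

#: serial tenfold dilution series used for qPCR standard curves (copies/uL)
DILUTION_SERIES = (2e1, 1e2, 1e3, 1e4, 1e5, 1e6, 1e7, 1e8, 1e9)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class OutcomeMixture:
    """Class proportions, read count, seed and sequencing-error model."""

    proportions: dict[str, float]
    n_reads: int
    seed: int = 0
    sub_rate: float = 0.0
    indel_rate: float = 0.0
    fixed_counts: bool = False

    def __post_init__(self) -> None:
        if set(self.proportions) - set(SIM_CLASSES):
            raise ConfigError(f"unknown outcome classes: {set(self.proportions) - set(SIM_CLASSES)}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"mixture proportions sum to {total}, not 1")
        for rate in (self.sub_rate, self.indel_rate):
            if not 0.0 <= rate <= 0.05:
                raise ConfigError("error rates must lie in [0, 0.05]")
        if self.n_reads < 0:
            raise ConfigError("n_reads must be non-negative")


@dataclass(frozen=True)
class IndelModel:
    """Archetype weights and size distribution for simulated indels."""

    weights: dict[str, float] = field(
        default_factory=lambda: {"ha_duplication": 0.4, "blunt_join": 0.3, "random_small": 0.3}
    )
    geom_p: float = 0.5
    max_indel: int = 6

    def __post_init__(self) -> None:
        if abs(sum(self.weights.values()) - 1.0) > 1e-9:
            raise ConfigError("indel archetype weights must sum to 1")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _indel_size(rng: np.random.Generator, model: IndelModel) -> int:
    return int(min(rng.geometric(model.geom_p), model.max_indel))


def apply_sequencing_errors(
    seq: str, rng: np.random.Generator, sub_rate: float, indel_rate: float = 0.0
) -> str:
    """Per-base substitution (uniform over the three alternatives) + indels."""
    if sub_rate > 0:
        arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
        hits = np.flatnonzero(rng.random(arr.size) < sub_rate)
        for i in hits:
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
        seq = "".join(arr)
    if indel_rate > 0:
        out = []
        for ch in seq:
            if rng.random() < indel_rate:
                if rng.random() < 0.5:
                    continue  # deletion
                out.append(str(_BASES[rng.integers(0, 4)]))  # insertion before base
            out.append(ch)
        seq = "".join(out)
    return seq


def _delete(seq: str, start: int, size: int) -> str:
    start = max(0, start)
    return seq[:start] + seq[start + size :]


def _insert(seq: str, pos: int, ins: str) -> str:
    return seq[:pos] + ins + seq[pos:]


def _draw_class_labels(mix: OutcomeMixture, rng: np.random.Generator) -> list[str]:
    classes = [c for c in SIM_CLASSES if mix.proportions.get(c, 0) > 0]
    probs = np.array([mix.proportions[c] for c in classes], dtype=float)
    probs /= probs.sum()
    if mix.fixed_counts:
        # largest-remainder rounding to exact counts
        raw = probs * mix.n_reads
        counts = np.floor(raw).astype(int)
        remainder = mix.n_reads - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:remainder]] += 1
        labels: list[str] = []
        for c, k in zip(classes, counts):
            labels.extend([c] * int(k))
        return labels
    return [classes[i] for i in rng.choice(len(classes), size=mix.n_reads, p=probs)]


def _edit_with_indel_seq(
    alleles: PredictedAlleles, model: IndelModel, rng: np.random.Generator
) -> tuple[str, str]:
    """A read carrying the intended edit plus an indel near the junction."""
    weights = dict(model.weights)
    if "ha_duplication" not in alleles.archetype_refs:
        weights.pop("ha_duplication", None)
    names = list(weights)
    probs = np.array([weights[n] for n in names], dtype=float)
    probs /= probs.sum()
    arche = names[rng.choice(len(names), p=probs)]

    acc = alleles.accurate_ref
    j0, j1 = alleles.junction_interval
    if arche == "ha_duplication":
        return alleles.archetype_refs["ha_duplication"], arche

    # a deletion restoring a WT length turns the edit into a substitution-like
    # patch (not identifiable under substitution tolerance): reject and redraw
    wt_lengths = {len(s) for s in alleles.wt_refs.values()}
    for _ in range(20):
        size = _indel_size(rng, model)
        if arche == "blunt_join":
            # resection flush against the edit, on a random side
            if rng.random() < 0.5:
                cand = _delete(acc, j0 - size, size)
            else:
                cand = _delete(acc, j1, size)
        else:
            # random_small: ins/del a few nt from the junction, outside the edit
            offset = int(rng.integers(0, 6))
            if rng.random() < 0.5:
                side_pos = j0 - offset if rng.random() < 0.5 else j1 + offset
                cand = _insert(acc, side_pos, random_dna(rng, size))
            elif rng.random() < 0.5:
                cand = _delete(acc, j0 - offset - size, size)
            else:
                cand = _delete(acc, j1 + offset, size)
        if len(cand) not in wt_lengths and cand != acc:
            return cand, arche
    return _insert(acc, j1, random_dna(rng, 2)), arche  # deterministic fallback


def _pure_indel_seq(
    alleles: PredictedAlleles, model: IndelModel, rng: np.random.Generator
) -> str:
    """A read with an indel at the cut/join and no intended edit."""
    base = alleles.archetype_refs["no_flap_join"]
    join = alleles.junction_interval[0]
    forbidden = {alleles.accurate_ref, *alleles.wt_refs.values()}
    # At a junction-type no-flap join (base differs from WT), inserted random
    # bases score as a degraded copy of the edit under optimal alignment, so
    # insertion-bearing pure indels are not identifiable from edits with
    # indels; only resections are generated there.  At a single-site cut the
    # no-flap join is the WT sequence itself and both op types are safe.
    allow_insertions = base in alleles.wt_refs.values()
    for _ in range(20):
        size = _indel_size(rng, model)
        if allow_insertions and rng.random() < 0.5:
            cand = _insert(base, join, random_dna(rng, size))
        else:
            cand = _delete(base, join - rng.integers(0, size + 1), size)
        if (
            cand not in forbidden
            and len(cand) != len(alleles.accurate_ref)
            and not (alleles.edit_seq and alleles.edit_seq in cand)
        ):
            return cand
    return _delete(base, join, model.max_indel)  # deterministic fallback


def simulate_reads(
    alleles: PredictedAlleles,
    mix: OutcomeMixture,
    indel_model: IndelModel | None = None,
    id_prefix: str = "sim",
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw reads from an outcome mixture with ground-truth labels.

    Returns ``(reads, truth)`` where reads are (id, sequence) pairs and the
    truth table records the class label, archetype and pre-error sequence of
    every read.  Byte-identical output under a fixed seed.
    """
    indel_model = indel_model or IndelModel()
    rng = np.random.default_rng(mix.seed)
    labels = _draw_class_labels(mix, rng)

    wt_names = list(alleles.wt_refs)
    reads: list[tuple[str, str]] = []
    truth_rows = []
    for i, label in enumerate(labels):
        arche = ""
        if label == "UNEDITED":
            name = wt_names[rng.integers(0, len(wt_names))] if len(wt_names) > 1 else wt_names[0]
            seq = alleles.wt_refs[name]
        elif label == "ACCURATE_EDIT":
            seq = alleles.accurate_ref
        elif label == "EDIT_WITH_INDEL":
            seq, arche = _edit_with_indel_seq(alleles, indel_model, rng)
        else:
            seq = _pure_indel_seq(alleles, indel_model, rng)
            arche = "no_flap_join"
        final = apply_sequencing_errors(seq, rng, mix.sub_rate, mix.indel_rate)
        rid = f"{id_prefix}_{i:06d}"
        reads.append((rid, final))
        truth_rows.append(
            {"read_id": rid, "true_class": label, "archetype": arche, "pre_error_seq": seq}
        )
    truth = pd.DataFrame(truth_rows, columns=["read_id", "true_class", "archetype", "pre_error_seq"])
    return reads, truth


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Constant-Q30 FASTQ (the classifier is quality-agnostic)."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'?' * len(seq)}\n")


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def simulate_gel(
    true_fraction: float,
    lengths: tuple[int, int],
    intensity_scale: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> GelLane:
    """Greyscales whose noise-free densitometry returns 100*true_fraction.

    Band mass is molar amount times length, so greyscales are generated as
    fraction * length (times a scale); Gaussian noise is optional.
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise ConfigError("true_fraction must lie in [0, 1]")
    ld, lu = lengths
    gd = intensity_scale * true_fraction * ld
    gu = intensity_scale * (1.0 - true_fraction) * lu
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        gd = max(0.0, gd + rng.normal(0.0, noise_sd))
        gu = max(0.0, gu + rng.normal(0.0, noise_sd))
    return GelLane(
        greyscale_deleted=gd,
        greyscale_undeleted=gu,
        len_deleted_bp=ld,
        len_undeleted_bp=lu,
    )


def simulate_qpcr(
    true_fraction: float,
    curve_params: dict[str, tuple[float, float]] | None = None,
    total_copies: float = 1e5,
    replicate_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int | None = None,
    dilution_series: Sequence[float] = DILUTION_SERIES,
) -> tuple[QpcrSample, pd.DataFrame]:
    """CT tables for a sample with ``true_fraction`` of molecules deleted.

    Returns the sample CTs and a tidy dilution-series table (columns assay,
    copies, ct) from which standard curves are refit downstream; with zero
    noise the full pipeline recovers 100*true_fraction exactly.
    """
    if not 0.0 < true_fraction <= 1.0:
        raise ConfigError("true_fraction must lie in (0, 1]")
    if curve_params is None:
        curve_params = {"deleted": (-3.32, 38.0), "flanking": (-3.35, 37.5)}
    for assay, (slope, _) in curve_params.items():
        if slope >= 0:
            raise ConfigError(f"{assay} slope must be negative")
    rng = np.random.default_rng(seed)

    rows = []
    for assay, (slope, intercept) in curve_params.items():
        for c in dilution_series:
            rows.append({"assay": assay, "copies": c, "ct": slope * np.log10(c) + intercept})
    dilution = pd.DataFrame(rows, columns=["assay", "copies", "ct"])

    def cts(assay: str, copies: float) -> tuple[float, ...]:
        slope, intercept = curve_params[assay]
        base = slope * np.log10(copies) + intercept
        if replicate_sd > 0:
            return tuple(float(base + rng.normal(0.0, replicate_sd)) for _ in range(n_replicates))
        return tuple(float(base) for _ in range(n_replicates))

    sample = QpcrSample(
        ct_deleted=cts("deleted", true_fraction * total_copies),
        ct_flanking=cts("flanking", total_copies),
    )
    return sample, dilution


# ---------------------------------------------------------------------------
# toy scenario builders: random loci with planted, correctly oriented sites
# ---------------------------------------------------------------------------


def _plant_plus_site(seq: list[str], cut: int) -> None:
    """Force an NGG PAM so that a + strand site cuts exactly at ``cut``."""
    seq[cut + 4] = "G"
    seq[cut + 5] = "G"


def _plant_minus_site(seq: list[str], cut: int) -> None:
    """Force a CCN (on +) PAM so that a - strand site cuts exactly at ``cut``."""
    seq[cut - 6] = "C"
    seq[cut - 5] = "C"


def _site_at(locus: Locus, cut: int, strand: str) -> SpacerSite:
    seq = locus.sequence
    if strand == "+":
        s = cut - RESIDUE_SPACER_LEN
        proto, pam = seq[s : s + 20], seq[s + 20 : s + 23]
    else:
        s = cut - 3
        from .locus import reverse_complement

        proto = reverse_complement(seq[s : s + 20])
        pam = reverse_complement(seq[s - 3 : s])
    return SpacerSite(
        locus_name=locus.name,
        protospacer=proto,
        pam=pam,
        strand=strand,
        protospacer_interval=(s, s + 20),
    )


def _random_locus_avoiding(
    rng: np.random.Generator, length: int, name: str, plant, avoid: str
) -> Locus:
    for _ in range(100):
        chars = list(random_dna(rng, length))
        plant(chars)
        seq = "".join(chars)
        if not avoid or avoid not in seq:
            return Locus(name=name, sequence=seq)
    raise RuntimeError("could not generate a locus avoiding the edit sequence")


def make_deletion_scenario(
    seed: int = 0,
    arm_len: int = 150,
    del_len: int = 300,
    edit_seq: str = "GATATC",
    design_class: str = "C1",
    ha_len: int = 13,
    pbs_len: int = 13,
) -> tuple[Locus, DesignPlan, PredictedAlleles]:
    """Random locus with a properly oriented pegRNA pair around a deletion.

    The + strand site cuts at ``arm_len`` and the - strand site at
    ``arm_len + del_len`` (PAMs pointing into the deleted fragment); the
    edit sequence is guaranteed absent from the wild-type locus.
    """
    rng = np.random.default_rng(seed)
    cut_a, cut_b = arm_len, arm_len + del_len
    length = arm_len * 2 + del_len

    def plant(chars: list[str]) -> None:
        _plant_plus_site(chars, cut_a)
        _plant_minus_site(chars, cut_b)

    avoid = edit_seq if len(edit_seq) >= 4 else ""  # short motifs are unavoidable
    locus = _random_locus_avoiding(rng, length, "toy_locus", plant, avoid)
    site_a = _site_at(locus, cut_a, "+")
    site_b = _site_at(locus, cut_b, "-")
    spec = EditSpec(edit_seq=edit_seq, ha_len=ha_len if design_class == "C1" else 0, pbs_len=pbs_len)
    plan = design_pair(site_a, site_b, locus, spec, design_class)
    return locus, plan, predict_deletion(plan, locus)


def make_single_edit_scenario(
    seed: int = 0,
    length: int = 240,
    cut: int = 120,
    edit_seq: str = "T",
    ha_len: int = 13,
    pbs_len: int = 13,
    include_ecorv: bool = False,
) -> tuple[Locus, DesignPlan, PredictedAlleles]:
    """Random locus with one + strand site and a single-edit pegRNA."""
    rng = np.random.default_rng(seed)
    locus = _random_locus_avoiding(
        rng, length, "toy_single", lambda c: _plant_plus_site(c, cut), ""
    )
    site = _site_at(locus, cut, "+")
    spec = EditSpec(
        edit_seq=edit_seq,
        ha_len=0 if include_ecorv else ha_len,
        pbs_len=pbs_len,
        include_ecorv=include_ecorv,
    )
    peg = design_single(site, locus, spec)
    plan = DesignPlan(
        intent="single_edit",
        design_class="C1" if spec.ha_len else "C2",
        pegrna_a=peg,
        pegrna_b=None,
        locus_names=(locus.name,),
        edit_spec=spec,
    )
    return locus, plan, predict_single_edit(plan, locus)


def make_translocation_scenario(
    seed: int = 0,
    len_a: int = 300,
    len_b: int = 300,
    cut_a: int = 180,
    cut_b: int = 120,
    edit_seq: str = "CTGCAG",
    design_class: str = "C2",
    ha_len: int = 13,
    pbs_len: int = 13,
) -> tuple[Locus, Locus, DesignPlan, PredictedAlleles]:
    """Two random loci with a + site on A and a - site on B (exchange design)."""
    rng = np.random.default_rng(seed)
    locus_a = _random_locus_avoiding(
        rng, len_a, "toy_chrA", lambda c: _plant_plus_site(c, cut_a), edit_seq
    )
    locus_b = _random_locus_avoiding(
        rng, len_b, "toy_chrB", lambda c: _plant_minus_site(c, cut_b), edit_seq
    )
    site_a = _site_at(locus_a, cut_a, "+")
    site_b = _site_at(locus_b, cut_b, "-")
    spec = EditSpec(edit_seq=edit_seq, ha_len=ha_len if design_class == "C1" else 0, pbs_len=pbs_len)
    plan = design_pair(site_a, site_b, (locus_a, locus_b), spec, design_class)
    return locus_a, locus_b, plan, predict_translocation(plan, locus_a, locus_b)
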