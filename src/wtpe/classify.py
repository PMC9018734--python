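"""Classification of merged amplicon reads into editing-outcome classes.

Each read is globally aligned (affine gaps, free end gaps at the amplicon
termini) to the wild-type reference(s) and to the predicted accurate-edit
allele.  The better-scoring reference decides ``aligned_to``; indel
operations are collected inside a quantification window around the cut
(wild-type frame) or the edit junction (edited frame), and the class is
assigned by two booleans:

====================  ===========  ==================
class                 edit found   indel in window
====================  ===========  ==================
ACCURATE_EDIT         yes          no
EDIT_WITH_INDEL       yes          yes
PURE_INDEL            no           yes
UNEDITED              no           no
====================  ===========  ==================

Substitutions alone never change a read's class: they lower alignment scores
but are not indel operations, which protects classification against
sequencing substitution error.  The edit is "found" when the read carries
the intended edit sequence verbatim, or when its alignment to the accurate
allele covers the annotated edit interval without any gap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import pandas as pd
from Bio import Align, SeqIO

from .alleles import PredictedAlleles
from .errors import ConfigError, EmptyTableError

CLASSES = ("UNEDITED", "ACCURATE_EDIT", "EDIT_WITH_INDEL", "PURE_INDEL", "DISCARDED")

#: editing-activity thresholds, in percent of retained reads
ON_TARGET_THRESHOLD_PCT = 0.2
OFF_TARGET_THRESHOLD_PCT = 0.01


@dataclass(frozen=True)
class ClassifyParams:
    """Alignment scoring and windowing knobs."""

    window: int = 20
    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -12.0
    gap_extend: float = -2.0
    min_read_len: int = 20


@dataclass(frozen=True)
class ClassifiedRead:
    read_id: str
    outcome: str
    aligned_to: str  # "wt" | "edited" | "none"
    edit_distance: int
    indel_ops: tuple[tuple[int, str, int], ...]
    reason: str = ""

    def cigarish(self) -> str:
        return ";".join(f"{p}{t[0].upper()}{l}" for p, t, l in self.indel_ops) or "."


@dataclass
class OutcomeTable:
    """Per-class counts and frequencies (percent of retained reads)."""

    n_total: int
    n_discarded: int
    counts: dict[str, int]
    mode: str = "on_target"
    window: int = 20

    @property
    def n_retained(self) -> int:
        return self.n_total - self.n_discarded

    def freq(self, cls: str) -> float:
        return 100.0 * self.counts.get(cls, 0) / self.n_retained

    @property
    def frequencies(self) -> dict[str, float]:
        return {c: self.freq(c) for c in CLASSES if c != "DISCARDED"}

    @property
    def prime_edit_freq(self) -> float:
        """Accurate edits + edits containing indels, in percent."""
        return self.freq("ACCURATE_EDIT") + self.freq("EDIT_WITH_INDEL")

    @property
    def total_indel_freq(self) -> float:
        return self.freq("EDIT_WITH_INDEL") + self.freq("PURE_INDEL")

    @property
    def editing_activity(self) -> float:
        """All edited reads: prime edits plus pure indels, in percent."""
        return self.prime_edit_freq + self.freq("PURE_INDEL")

    @property
    def threshold_pct(self) -> float:
        return ON_TARGET_THRESHOLD_PCT if self.mode == "on_target" else OFF_TARGET_THRESHOLD_PCT

    @property
    def above_threshold(self) -> bool:
        return self.editing_activity > self.threshold_pct

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_discarded": self.n_discarded,
            "n_retained": self.n_retained,
            "counts": dict(self.counts),
            "frequencies_pct": self.frequencies,
            "prime_edit_freq_pct": self.prime_edit_freq,
            "total_indel_freq_pct": self.total_indel_freq,
            "editing_activity_pct": self.editing_activity,
            "mode": self.mode,
            "threshold_pct": self.threshold_pct,
            "above_threshold": self.above_threshold,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _make_aligner(params: ClassifyParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    # free end gaps: reads may start/end short of the reference termini
    try:  # Biopython >= 1.88 naming
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def _alignment_features(aln) -> tuple[tuple[tuple[int, str, int], ...], tuple, int]:
    """Internal indel ops (ref coords), aligned target blocks, edit distance."""
    t_blocks, q_blocks = aln.aligned
    ops: list[tuple[int, str, int]] = []
    for i in range(1, len(t_blocks)):
        dt = int(t_blocks[i][0] - t_blocks[i - 1][1])
        dq = int(q_blocks[i][0] - q_blocks[i - 1][1])
        if dt > 0:
            ops.append((int(t_blocks[i - 1][1]), "del", dt))
        if dq > 0:
            ops.append((int(t_blocks[i - 1][1]), "ins", dq))
    counts = aln.counts()
    edit_distance = int(counts.mismatches) + sum(l for _, _, l in ops)
    return tuple(ops), tuple(tuple(map(int, b)) for b in t_blocks), edit_distance


def _ops_in_windows(
    ops: Sequence[tuple[int, str, int]], windows: Sequence[tuple[int, int]]
) -> tuple[tuple[int, str, int], ...]:
    hit = []
    for pos, kind, length in ops:
        span = (pos, pos + length) if kind == "del" else (pos, pos)
        for w0, w1 in windows:
            if kind == "ins":
                if w0 <= pos <= w1:
                    hit.append((pos, kind, length))
                    break
            elif span[0] < w1 and span[1] > w0:
                hit.append((pos, kind, length))
                break
    return tuple(hit)


class ReadClassifier:
    """Stateful wrapper binding a reference set to alignment parameters."""

    def __init__(self, alleles: PredictedAlleles, params: ClassifyParams | None = None):
        self.alleles = alleles
        self.params = params or ClassifyParams()
        self._aligner = _make_aligner(self.params)
        w = self.params.window
        j0, j1 = alleles.junction_interval
        self._edited_windows = [(max(0, j0 - w), j1 + w)]
        self._wt_windows = {
            name: [(max(0, c - w), c + w) for c in cuts]
            for name, cuts in alleles.wt_cut_positions.items()
        }

    @staticmethod
    def _hamming(a: str, b: str) -> int:
        import numpy as np

        x = np.frombuffer(a.encode(), dtype="S1")
        y = np.frombuffer(b.encode(), dtype="S1")
        return int((x != y).sum())

    def _gapless_fast_path(self, read: str, read_id: str) -> ClassifiedRead | None:
        """Substitution-only reads match one reference at its full length.

        Fires only when the gapless mismatch score provably dominates any
        gapped alignment to a different-length reference: reaching such a
        reference costs at least one gap of the length difference, so the
        mismatch budget is bounded by that gap cost (and by a same-length
        gap pair otherwise).  Within the budget the classification is
        identical to the full affine alignment: no indel ops, edit intact.
        """
        p = self.params
        alleles = self.alleles
        refs = [("edited", alleles.accurate_ref)] + [
            ("wt", r) for r in alleles.wt_refs.values()
        ]
        best: tuple[int, str] | None = None
        min_gap_cost = 2 * abs(p.gap_open)  # same-length detour: ins + del pair
        for kind, ref in refs:
            delta = abs(len(ref) - len(read))
            if delta == 0:
                d = self._hamming(read, ref)
                if best is None or d < best[0]:
                    best = (d, kind)
            else:
                cost = abs(p.gap_open) + abs(p.gap_extend) * (delta - 1)
                min_gap_cost = min(min_gap_cost, cost)
        if best is None:
            return None
        d, kind = best
        # a mismatch costs (match - mismatch); gapless must beat the cheapest
        # gapped alternative with margin, and stay plausibly read-like
        per_mismatch = p.match - p.mismatch
        if d * per_mismatch >= min_gap_cost or d > int(0.04 * len(read)):
            return None
        if kind == "edited" and alleles.edit_seq:
            return ClassifiedRead(read_id, "ACCURATE_EDIT", "edited", d, ())
        return ClassifiedRead(read_id, "UNEDITED", kind, d, ())

    def classify(self, read: str, read_id: str = "read") -> ClassifiedRead:
        p = self.params
        if not read or len(read) < p.min_read_len:
            return ClassifiedRead(read_id, "DISCARDED", "none", 0, (), reason="too short")

        alleles = self.alleles
        edit = alleles.edit_seq
        j0, j1 = alleles.junction_interval

        # fast paths for exact/substitution-only matches (dominant in low-error data)
        if read == alleles.accurate_ref:
            return ClassifiedRead(read_id, "ACCURATE_EDIT", "edited", 0, ())
        for name, ref in alleles.wt_refs.items():
            if read == ref:
                return ClassifiedRead(read_id, "UNEDITED", "wt", 0, ())
        fast = self._gapless_fast_path(read, read_id)
        if fast is not None:
            return fast

        # score-only pass selects the reference; one full alignment follows
        wt_scored = [
            (self._aligner.score(ref, read), name, ref)
            for name, ref in self.alleles.wt_refs.items()
        ]
        wt_score, wt_name, wt_ref = max(wt_scored, key=lambda t: t[0])
        ed_score = self._aligner.score(alleles.accurate_ref, read)

        edit_in_read = bool(edit) and edit in read
        if ed_score > wt_score:
            aligned_to = "edited"
        elif ed_score < wt_score:
            aligned_to = "wt"
        else:
            # tie: decide by presence of the exact edit string
            if bool(edit):
                aligned_to = "edited" if edit_in_read else "wt"
            else:
                return ClassifiedRead(
                    read_id, "DISCARDED", "none", 0, (), reason="ambiguous alignment"
                )

        if aligned_to == "edited":
            ed_aln = self._aligner.align(alleles.accurate_ref, read)[0]
            ops, blocks, dist = _alignment_features(ed_aln)
            window_ops = _ops_in_windows(ops, self._edited_windows)
            # intact = no edit reference position deleted; insertions split
            # aligned blocks but leave target coverage contiguous
            pos = j0
            for t0, t1 in blocks:
                if t1 <= pos:
                    continue
                if t0 > pos:
                    break
                pos = t1
                if pos >= j1:
                    break
            edit_intact = j1 > j0 and pos >= j1
            edit_found = bool(edit) and (edit_intact or edit_in_read)
            if edit_found and not window_ops:
                outcome = "ACCURATE_EDIT"
            elif edit_found:
                outcome = "EDIT_WITH_INDEL"
            elif window_ops:
                outcome = "PURE_INDEL"
            else:
                outcome = "UNEDITED"
            return ClassifiedRead(read_id, outcome, "edited", dist, window_ops)

        wt_aln = self._aligner.align(wt_ref, read)[0]
        ops, _, dist = _alignment_features(wt_aln)
        window_ops = _ops_in_windows(ops, self._wt_windows[wt_name])
        outcome = "PURE_INDEL" if window_ops else "UNEDITED"
        return ClassifiedRead(read_id, outcome, "wt", dist, window_ops)


def classify_read(
    read: str,
    alleles: PredictedAlleles,
    params: ClassifyParams | None = None,
    read_id: str = "read",
) -> ClassifiedRead:
    """Classify one read (convenience wrapper around :class:`ReadClassifier`)."""
    return ReadClassifier(alleles, params).classify(read, read_id)


def classify_reads(
    reads: Iterable[tuple[str, str]],
    alleles: PredictedAlleles,
    params: ClassifyParams | None = None,
) -> list[ClassifiedRead]:
    """Classify (read_id, sequence) pairs; order-independent per read."""
    clf = ReadClassifier(alleles, params)
    return [clf.classify(seq, read_id) for read_id, seq in reads]


def tabulate(
    classified: Iterable[ClassifiedRead],
    mode: Literal["on_target", "off_target"] = "on_target",
    window: int = 20,
) -> OutcomeTable:
    """Count classes and derive frequencies as percent of retained reads."""
    if mode not in ("on_target", "off_target"):
        raise ConfigError(f"unknown mode {mode!r}")
    counts: dict[str, int] = {c: 0 for c in CLASSES}
    n = 0
    for cr in classified:
        counts[cr.outcome] += 1
        n += 1
    discarded = counts.pop("DISCARDED")
    if n - discarded == 0:
        raise EmptyTableError("no retained reads to tabulate")
    return OutcomeTable(n_total=n, n_discarded=discarded, counts=counts, mode=mode, window=window)


@dataclass(frozen=True)
class EditorComparison:
    freq_diff: dict[str, float]
    freq_ratio: dict[str, float]
    activity_a: float
    activity_b: float
    activity_ratio: float
    a_below_b: bool


def compare_editors(table_a: OutcomeTable, table_b: OutcomeTable) -> EditorComparison:
    """Per-class differences/ratios between two editors at the same site."""
    if table_a.window != table_b.window:
        raise ConfigError("outcome tables use different quantification windows")
    diff, ratio = {}, {}
    for c in table_a.frequencies:
        fa, fb = table_a.freq(c), table_b.freq(c)
        diff[c] = fa - fb
        ratio[c] = fa / fb if fb > 0 else float("inf") if fa > 0 else float("nan")
    act_a, act_b = table_a.editing_activity, table_b.editing_activity
    return EditorComparison(
        freq_diff=diff,
        freq_ratio=ratio,
        activity_a=act_a,
        activity_b=act_b,
        activity_ratio=act_a / act_b if act_b > 0 else float("inf") if act_a > 0 else float("nan"),
        a_below_b=act_a < act_b,
    )


def demultiplex_and_trim(
    reads: Iterable, barcodes: dict[str, str] | pd.DataFrame
) -> tuple[dict[str, list[tuple[str, str]]], int]:
    """Assign reads to samples by exact barcode(+primer) prefix and trim it.

    ``reads`` yields Bio.SeqRecord objects or (id, sequence) pairs.  Reads
    whose prefix matches no barcode are discarded (counted, not kept); one
    mismatch is enough to discard under the exact-prefix policy.
    """
    if isinstance(barcodes, pd.DataFrame):
        barcodes = dict(zip(barcodes["sample"], barcodes["barcode"]))
    seen: dict[str, str] = {}
    for sample, bc in barcodes.items():
        if bc in seen:
            raise ConfigError(f"duplicate barcode {bc!r} for samples {seen[bc]!r} and {sample!r}")
        seen[bc] = sample
    # longest barcode first so nested prefixes resolve deterministically
    ordered = sorted(barcodes.items(), key=lambda kv: -len(kv[1]))

    out: dict[str, list[tuple[str, str]]] = {s: [] for s in barcodes}
    unassigned = 0
    for rec in reads:
        if hasattr(rec, "seq"):
            rid, seq = rec.id, str(rec.seq).upper()
        else:
            rid, seq = rec[0], rec[1].upper()
        for sample, bc in ordered:
            if seq.startswith(bc):
                out[sample].append((rid, seq[len(bc):]))
                break
        else:
            unassigned += 1
    return out, unassigned


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """(id, sequence) pairs from a FASTQ file (gzip allowed via .gz suffix)."""
    path = str(path)
    if path.endswith(".gz"):
        import gzip

        with gzip.open(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield rec.id, str(rec.seq).upper()
    else:
        for rec in SeqIO.parse(path, "fastq"):
            yield rec.id, str(rec.seq).upper()


def write_classified_tsv(classified: Iterable[ClassifiedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tclass\taligned_to\tedit_distance\tindel_ops\treason\n")
        for cr in classified:
            fh.write(
                f"{cr.read_id}\t{cr.outcome}\t{cr.aligned_to}\t{cr.edit_distance}\t"
                f"{cr.cigarish()}\t{cr.reason}\n"
            )
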