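"""Independent affine-gap alignment oracle for classifier tests.

A from-scratch Gotoh dynamic program (match +2, mismatch -4, gap open -12,
extend -2, free end gaps on both sequences) with full traceback, written
against integer score matrices so comparisons are exact.  It shares no code
with the package's alignment path and exists to cross-check classification
decisions on small reads.
"""

from __future__ import annotations

import numpy as np

MATCH, MISMATCH, OPEN, EXTEND = 2, -4, -12, -2
NEG = -(10**9)


def _fill(ref: str, read: str):
    n, m = len(ref), len(read)
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    Ix = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # ref consumed, gap in read
    Iy = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # read consumed, gap in ref
    M[0, 0] = 0
    if m:
        Iy[0, 1:] = 0  # free leading read overhang
    ref_arr = np.frombuffer(ref.encode(), dtype="S1")
    read_arr = np.frombuffer(read.encode(), dtype="S1")
    j_idx = np.arange(1, m + 1)
    for i in range(1, n + 1):
        s = np.where(read_arr == ref_arr[i - 1], MATCH, MISMATCH).astype(np.int64)
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = s + prev_best[:-1]
        Ix[i, 0] = 0  # free leading ref overhang
        Ix[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:] + OPEN, Iy[i - 1, 1:] + OPEN),
            Ix[i - 1, 1:] + EXTEND,
        )
        A = np.maximum(M[i], Ix[i])
        if m:
            vals = A[:-1] + OPEN - EXTEND * j_idx
            Iy[i, 1:] = np.maximum.accumulate(vals) + EXTEND * j_idx
    return M, Ix, Iy


def align(ref: str, read: str):
    """Optimal score, indel ops (ref coords) and aligned ref blocks."""
    n, m = len(ref), len(read)
    M, Ix, Iy = _fill(ref, read)
    H = np.maximum(np.maximum(M, Ix), Iy)
    # free trailing gaps: end anywhere on the last row or column
    j_end = int(np.argmax(H[n, :]))
    i_end = int(np.argmax(H[:, m]))
    if H[n, j_end] >= H[i_end, m]:
        i, j = n, j_end
    else:
        i, j = i_end, m
    score = int(H[i, j])

    state = max(
        (("M", M[i, j]), ("Ix", Ix[i, j]), ("Iy", Iy[i, j])), key=lambda t: t[1]
    )[0]
    pairs: list[tuple[int, int]] = []  # aligned (ref_pos, read_pos)
    dels: list[tuple[int, int]] = []  # (ref_pos, len), interior only
    inss: list[tuple[int, int]] = []
    while i > 0 and j > 0:
        if state == "M":
            pairs.append((i - 1, j - 1))
            target = M[i, j] - (MATCH if ref[i - 1] == read[j - 1] else MISMATCH)
            i, j = i - 1, j - 1
            for cand in ("M", "Ix", "Iy"):
                if {"M": M, "Ix": Ix, "Iy": Iy}[cand][i, j] == target:
                    state = cand
                    break
        elif state == "Ix":
            if Ix[i, j] == Ix[i - 1, j] + EXTEND:
                nxt = "Ix"
            elif Ix[i, j] == M[i - 1, j] + OPEN:
                nxt = "M"
            else:
                nxt = "Iy"
            dels.append((i - 1, 1))
            i, state = i - 1, nxt
            if state == "Ix" and j == 0:
                break
        else:  # Iy
            if Iy[i, j] == Iy[i, j - 1] + EXTEND:
                nxt = "Iy"
            elif Iy[i, j] == M[i, j - 1] + OPEN:
                nxt = "M"
            else:
                nxt = "Ix"
            inss.append((i, 1))
            j, state = j - 1, nxt

    pairs.reverse()
    # merge unit gaps into runs; drop terminal gaps (free ends)
    first_ref = pairs[0][0] if pairs else 0
    last_ref = pairs[-1][0] if pairs else 0

    def merge(units, interior_lo, interior_hi):
        units = sorted(p for p, _ in units)
        runs: list[tuple[int, int]] = []
        for p in units:
            if runs and p == runs[-1][0] + runs[-1][1]:
                runs[-1] = (runs[-1][0], runs[-1][1] + 1)
            else:
                runs.append((p, 1))
        return [(p, l) for p, l in runs if interior_lo <= p <= interior_hi]

    del_runs = merge(dels, first_ref + 1, last_ref - 1)
    ins_runs = [
        (p, sum(1 for q, _ in inss if q == p))
        for p in sorted({q for q, _ in inss})
        if first_ref < p <= last_ref
    ]
    ops = sorted(
        [(p, "del", l) for p, l in del_runs] + [(p, "ins", l) for p, l in ins_runs]
    )
    # aligned ref blocks (contiguous runs of aligned ref positions)
    blocks: list[tuple[int, int]] = []
    for rp, _ in pairs:
        if blocks and rp == blocks[-1][1]:
            blocks[-1] = (blocks[-1][0], rp + 1)
        else:
            blocks.append((rp, rp + 1))
    return score, ops, blocks


def classify(read: str, alleles, window: int = 20) -> str:
    """Outcome class from oracle alignments, per the documented taxonomy."""
    edit = alleles.edit_seq
    j0, j1 = alleles.junction_interval
    wt_results = {name: align(ref, read) for name, ref in alleles.wt_refs.items()}
    wt_name = max(wt_results, key=lambda n: wt_results[n][0])
    wt_score = wt_results[wt_name][0]
    ed_score, ed_ops, ed_blocks = align(alleles.accurate_ref, read)

    def in_windows(ops, windows):
        hits = []
        for pos, kind, length in ops:
            for w0, w1 in windows:
                if kind == "ins":
                    if w0 <= pos <= w1:
                        hits.append((pos, kind, length))
                        break
                elif pos < w1 and pos + length > w0:
                    hits.append((pos, kind, length))
                    break
        return hits

    if ed_score > wt_score or (ed_score == wt_score and edit and edit in read):
        win = [(max(0, j0 - window), j1 + window)]
        wops = in_windows(ed_ops, win)
        covered = j1 > j0
        pos = j0
        for b0, b1 in ed_blocks:
            if b1 <= pos:
                continue
            if b0 > pos:
                break
            pos = b1
            if pos >= j1:
                break
        covered = covered and pos >= j1
        edit_found = bool(edit) and (covered or edit in read)
        if edit_found and not wops:
            return "ACCURATE_EDIT"
        if edit_found:
            return "EDIT_WITH_INDEL"
        return "PURE_INDEL" if wops else "UNEDITED"

    cuts = alleles.wt_cut_positions[wt_name]
    win = [(max(0, c - window), c + window) for c in cuts]
    wops = in_windows(wt_results[wt_name][1], win)
    return "PURE_INDEL" if wops else "UNEDITED"
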