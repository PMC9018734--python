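"""Outcome classification, tabulation, thresholds, demultiplexing."""

import numpy as np
import pytest

import gotoh_oracle
from conftest import random_seq
from wtpe.classify import (
    ClassifiedRead,
    ClassifyParams,
    ReadClassifier,
    classify_read,
    classify_reads,
    compare_editors,
    demultiplex_and_trim,
    tabulate,
)
from wtpe.errors import ConfigError, EmptyTableError


def mutate_reads(al, rng, n):
    """Hand-mutated reads from the allele set with known constructions."""
    acc = al.accurate_ref
    wt = next(iter(al.wt_refs.values()))
    j0, j1 = al.junction_interval
    cut = al.wt_cut_positions[next(iter(al.wt_cut_positions))][0]
    reads = []
    for i in range(n):
        kind = i % 5
        if kind == 0:
            reads.append(acc)
        elif kind == 1:
            reads.append(wt)
        elif kind == 2:  # deletion inside the window, edit kept
            size = int(rng.integers(1, 4))
            off = int(rng.integers(2, 8))
            reads.append(acc[: j1 + off] + acc[j1 + off + size :])
        elif kind == 3:  # insertion at the WT cut (pure indel)
            ins = random_seq(rng, int(rng.integers(2, 5)))
            reads.append(wt[:cut] + ins + wt[cut:])
        else:  # substitutions only, away from the junction
            pos = int(rng.integers(5, j0 - 25))
            base = {"A": "C", "C": "G", "G": "T", "T": "A"}[acc[pos]]
            reads.append(acc[:pos] + base + acc[pos + 1 :])
    return reads


class TestClassifyRead:
    def test_exact_accurate_and_wt(self, deletion_scenario):
        _, _, al = deletion_scenario
        assert classify_read(al.accurate_ref, al).outcome == "ACCURATE_EDIT"
        wt = next(iter(al.wt_refs.values()))
        assert classify_read(wt, al).outcome == "UNEDITED"

    def test_deletion_in_window_on_edited_allele(self, deletion_scenario):
        _, _, al = deletion_scenario
        j0, j1 = al.junction_interval
        read = al.accurate_ref[: j1 + 3] + al.accurate_ref[j1 + 5 :]
        out = classify_read(read, al)
        assert out.outcome == "EDIT_WITH_INDEL"
        assert any(k == "del" and l == 2 for _, k, l in out.indel_ops)

    def test_insertion_at_wt_cut_is_pure_indel(self, deletion_scenario):
        _, _, al = deletion_scenario
        wt = next(iter(al.wt_refs.values()))
        cut = al.wt_cut_positions[next(iter(al.wt_cut_positions))][0]
        read = wt[:cut] + "TTAG" + wt[cut:]
        out = classify_read(read, al)
        assert out.outcome == "PURE_INDEL"
        assert any(k == "ins" and l == 4 for _, k, l in out.indel_ops)

    def test_substitutions_never_create_pure_indel(self, deletion_scenario, rng):
        _, _, al = deletion_scenario
        wt = next(iter(al.wt_refs.values()))
        arr = list(wt)
        for pos in rng.choice(len(wt), size=6, replace=False):
            arr[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[pos]]
        assert classify_read("".join(arr), al).outcome == "UNEDITED"

    def test_indel_outside_window_ignored(self, deletion_scenario):
        _, _, al = deletion_scenario
        j1 = al.junction_interval[1]
        pos = j1 + 60  # well outside the +/-20 window
        read = al.accurate_ref[:pos] + al.accurate_ref[pos + 3 :]
        assert classify_read(read, al).outcome == "ACCURATE_EDIT"

    def test_empty_read_discarded(self, deletion_scenario):
        _, _, al = deletion_scenario
        assert classify_read("", al).outcome == "DISCARDED"

    def test_matches_exhaustive_alignment_oracle(self, rng):
        """Class assignments equal an independent Gotoh oracle's on toy reads."""
        from wtpe.simulate import make_deletion_scenario

        _, _, al = make_deletion_scenario(seed=31, arm_len=60, del_len=80)
        reads = mutate_reads(al, rng, 50)
        clf = ReadClassifier(al)
        for read in reads:
            assert clf.classify(read).outcome == gotoh_oracle.classify(read, al)

    def test_permutation_invariance(self, deletion_scenario, rng):
        _, _, al = deletion_scenario
        reads = [(f"r{i}", s) for i, s in enumerate(mutate_reads(al, rng, 30))]
        fwd = {c.read_id: c.outcome for c in classify_reads(reads, al)}
        shuffled = list(reads)
        rng.shuffle(shuffled)
        rev = {c.read_id: c.outcome for c in classify_reads(shuffled, al)}
        assert fwd == rev


def _table(counts, mode="on_target"):
    made = []
    for cls, k in counts.items():
        made += [ClassifiedRead(f"{cls}{i}", cls, "wt", 0, ()) for i in range(k)]
    return tabulate(made, mode=mode)


class TestTabulate:
    def test_arithmetic(self):
        t = _table(
            {"ACCURATE_EDIT": 400, "EDIT_WITH_INDEL": 300, "PURE_INDEL": 100, "UNEDITED": 200}
        )
        assert t.prime_edit_freq == pytest.approx(70.0)
        assert t.total_indel_freq == pytest.approx(40.0)
        assert t.freq("UNEDITED") == pytest.approx(20.0)
        assert sum(t.frequencies.values()) == pytest.approx(100.0)

    def test_on_target_threshold(self):
        # 0.15% activity with the 0.2% on-target threshold
        t = _table({"ACCURATE_EDIT": 15, "UNEDITED": 9985})
        assert t.editing_activity == pytest.approx(0.15)
        assert not t.above_threshold

    def test_off_target_threshold(self):
        # 0.015% activity crosses the lowered 0.01% off-target threshold
        t = _table({"PURE_INDEL": 15, "UNEDITED": 99985}, mode="off_target")
        assert t.editing_activity == pytest.approx(0.015)
        assert t.above_threshold

    def test_zero_retained_reads_raises(self):
        discarded = [ClassifiedRead("d", "DISCARDED", "none", 0, ())]
        with pytest.raises(EmptyTableError):
            tabulate(discarded)


class TestCompareEditors:
    def test_identical_tables_all_zero(self):
        t = _table({"ACCURATE_EDIT": 10, "UNEDITED": 90})
        cmp = compare_editors(t, t)
        assert all(v == 0 for v in cmp.freq_diff.values())
        assert not cmp.a_below_b

    def test_activity_ratio(self):
        a = _table({"ACCURATE_EDIT": 10, "UNEDITED": 90})
        b = _table({"ACCURATE_EDIT": 5, "UNEDITED": 95})
        assert compare_editors(a, b).activity_ratio == pytest.approx(2.0)

    def test_ratios_match_division_oracle(self, rng):
        for _ in range(10):
            ka = {c: int(rng.integers(1, 50)) for c in ("ACCURATE_EDIT", "PURE_INDEL", "UNEDITED")}
            kb = {c: int(rng.integers(1, 50)) for c in ("ACCURATE_EDIT", "PURE_INDEL", "UNEDITED")}
            a, b = _table(ka), _table(kb)
            cmp = compare_editors(a, b)
            for cls in ka:
                assert cmp.freq_ratio[cls] == pytest.approx(a.freq(cls) / b.freq(cls))

    def test_mismatched_windows_raise(self):
        a = _table({"UNEDITED": 10})
        b = _table({"UNEDITED": 10})
        b.window = 30
        with pytest.raises(ConfigError):
            compare_editors(a, b)


class TestDemultiplex:
    def test_exact_split(self):
        barcodes = {"s1": "AAAA", "s2": "CCCC"}
        reads = [(f"a{i}", "AAAA" + "GGGG") for i in range(10)]
        reads += [(f"b{i}", "CCCC" + "TTTT") for i in range(10)]
        out, unassigned = demultiplex_and_trim(reads, barcodes)
        assert len(out["s1"]) == len(out["s2"]) == 10
        assert unassigned == 0
        assert out["s1"][0][1] == "GGGG"  # barcode trimmed

    def test_one_mismatch_is_discarded(self):
        out, unassigned = demultiplex_and_trim(
            [("r", "AATAGGGG")], {"s1": "AAAA", "s2": "CCCC"}
        )
        assert unassigned == 1
        assert not out["s1"] and not out["s2"]

    def test_duplicate_barcode_raises(self):
        with pytest.raises(ConfigError):
            demultiplex_and_trim([], {"s1": "AAAA", "s2": "AAAA"})
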