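"""Grubbs thresholding, RT correction and the stage-2 pairwise matcher."""

import math

import numpy as np
import pytest

from gcalign.model import AlignedGroup, PeakList
from gcalign.full_alignment import LandmarkSet
from gcalign.partial_alignment import (
    GrubbsConfig,
    Thresholds,
    align_all,
    align_pair,
    correct_rt,
    derive_thresholds,
    grubbs_critical,
    grubbs_remove,
    prune_landmarks,
)
from gcalign.similarity import MixtureParams, mixture_similarity, rt_distance, spectrum_similarity_or

from helpers import make_peak, random_spectrum, spec_of, zpeak

# published one-sided Grubbs critical values at the 5% level
GRUBBS_TABLE_5PCT = {
    3: 1.1531, 4: 1.4625, 5: 1.6714, 6: 1.8221, 7: 1.9381, 8: 2.0317,
    9: 2.1096, 10: 2.1761, 11: 2.2339, 12: 2.2850, 13: 2.3305, 14: 2.3717,
    15: 2.4090, 16: 2.4433, 17: 2.4748, 18: 2.5040, 19: 2.5312, 20: 2.5566,
    21: 2.5804, 22: 2.6028, 23: 2.6239, 24: 2.6439, 25: 2.6629, 26: 2.6809,
    27: 2.6981, 28: 2.7145, 29: 2.7301, 30: 2.7451,
}


class TestGrubbs:
    def test_critical_values_match_published_table(self):
        for n, expected in GRUBBS_TABLE_5PCT.items():
            assert grubbs_critical(n, 0.05) == pytest.approx(expected, abs=2e-4)

    def test_single_high_outlier_removed(self):
        out = grubbs_remove([8, 9, 10, 10, 10, 50], "high")
        assert out == [8, 9, 10, 10, 10]

    def test_low_tail_direction(self):
        out = grubbs_remove([-40, 10, 10, 10, 11, 12], "low")
        assert out == [10, 10, 10, 11, 12]

    def test_identical_values_unchanged(self):
        assert grubbs_remove([5.0] * 6, "high") == [5.0] * 6

    def test_too_few_values_unchanged(self):
        assert grubbs_remove([1.0, 100.0], "high") == [1.0, 100.0]

    def test_decisions_match_table_lookup_oracle(self):
        """One removal step agrees with a critical-value-table lookup for n=3..30."""
        rng = np.random.default_rng(2024)
        for n in range(3, 31):
            for _ in range(20):
                values = list(rng.normal(0.0, 1.0, n))
                mean = np.mean(values)
                sd = np.std(values, ddof=1)
                g = (max(values) - mean) / sd
                oracle_removes = g > GRUBBS_TABLE_5PCT[n]
                out = grubbs_remove(values, "high", GrubbsConfig(max_iterations=1))
                assert (len(out) == n - 1) == oracle_removes
                if oracle_removes:
                    assert max(values) not in out


def _two_sample_landmarks(pairs):
    """LandmarkSet over samples R/T with prescribed (d, spectrum) pairs."""
    groups, ref_peaks, tgt_peaks = [], [], []
    for i, (d, ref_spec, tgt_spec) in enumerate(pairs):
        rp = zpeak(f"R:{i:04d}", 10.0 * i, 0.0, name=f"c{i}", spectrum=ref_spec)
        tp = zpeak(f"T:{i:04d}", 10.0 * i + d, 0.0, name=f"c{i}", spectrum=tgt_spec)
        ref_peaks.append(rp)
        tgt_peaks.append(tp)
        groups.append(AlignedGroup(members={"R": rp, "T": tp}, kind="landmark",
                                   consensus_name=rp.name))
    samples = [PeakList("R", ref_peaks), PeakList("T", tgt_peaks)]
    return LandmarkSet(groups=groups, reference_id="R"), samples


class TestDeriveThresholds:
    def test_no_outliers_gives_plain_extremes(self):
        rng = np.random.default_rng(1)
        specs = [random_spectrum(rng) for _ in range(4)]
        pairs = [(d, s, s) for d, s in zip([0.10, 0.15, 0.20, 0.12], specs)]
        lm, samples = _two_sample_landmarks(pairs)
        thr = derive_thresholds(lm, samples, MixtureParams(0.5, 100.0))
        assert thr.d0 == pytest.approx(0.20)
        assert thr.sim0 == pytest.approx(1.0, abs=1e-6)  # identical spectra

    def test_distance_outlier_rejected_before_taking_max(self):
        rng = np.random.default_rng(2)
        specs = [random_spectrum(rng) for _ in range(4)]
        pairs = [(d, s, s) for d, s in zip([0.10, 0.15, 0.20, 5.0], specs)]
        lm, samples = _two_sample_landmarks(pairs)
        thr = derive_thresholds(lm, samples, MixtureParams(0.5, 100.0))
        assert thr.d0 == pytest.approx(0.20)

    def test_single_landmark_falls_back_to_its_own_values(self, caplog):
        rng = np.random.default_rng(3)
        s = random_spectrum(rng)
        lm, samples = _two_sample_landmarks([(0.42, s, s)])
        thr = derive_thresholds(lm, samples, MixtureParams(0.5, 100.0))
        assert thr.d0 == pytest.approx(0.42)

    def test_prune_demotes_groups_flagged_by_thresholds(self):
        rng = np.random.default_rng(4)
        specs = [random_spectrum(rng) for _ in range(5)]
        pairs = [(d, s, s) for d, s in zip([0.1, 0.12, 0.15, 0.11], specs)]
        pairs.append((6.0, specs[4], random_spectrum(rng)))  # wrong match
        lm, samples = _two_sample_landmarks(pairs)
        thr = derive_thresholds(lm, samples, MixtureParams(0.5, 100.0))
        kept, demoted = prune_landmarks(lm, samples, thr)
        assert len(kept) == 4
        assert len(demoted) == 1
        assert demoted[0].members["R"].uid == "R:0004"


class TestCorrectRt:
    def _target(self, rts):
        return PeakList("T", [
            make_peak(f"T:{i:04d}", rt1=rt1, rt2=rt2, area=1.0)
            for i, (rt1, rt2) in enumerate(rts)
        ])

    def test_constant_shift_removed_exactly(self):
        anchors = [(100.0, 1.0), (200.0, 2.0), (300.0, 3.0), (400.0, 4.0)]
        pairs = [
            (make_peak(f"T:{i:04d}", rt1=a + 2.0, rt2=b + 0.1),
             make_peak(f"R:{i:04d}", rt1=a, rt2=b))
            for i, (a, b) in enumerate(anchors)
        ]
        target = self._target([(a + 2.0, b + 0.1) for a, b in anchors])
        out = correct_rt(target, pairs, enabled=True)
        for p, (a, b) in zip(out.peaks, anchors):
            assert p.rt1 == pytest.approx(a, abs=1e-9)
            assert p.rt2 == pytest.approx(b, abs=1e-9)

    def test_disabled_is_identity(self):
        target = self._target([(100.0, 1.0), (200.0, 2.0)])
        assert correct_rt(target, [], enabled=False) is target

    def test_too_few_anchors_falls_back_to_identity(self, caplog):
        target = self._target([(100.0, 1.0)])
        pairs = [(make_peak("T:0000", rt1=102.0), make_peak("R:0000", rt1=100.0))]
        out = correct_rt(target, pairs, enabled=True)
        assert out.peaks[0].rt1 == pytest.approx(100.0)

    def test_two_segment_distortion_recovered_against_oracle(self):
        # target frame distorted by a continuous two-slope warp; anchors sample
        # it densely, so the local fit must track both segments. The oracle is
        # independent piecewise-linear interpolation through the same anchors.
        def warp(rt):  # target -> reference
            return rt * 1.02 if rt <= 1000.0 else 1020.0 + (rt - 1000.0) * 0.97

        anchor_rts = np.linspace(200.0, 1800.0, 30)
        pairs = [
            (make_peak(f"T:{i:04d}", rt1=float(a), rt2=1.0 + a / 1000.0),
             make_peak(f"R:{i:04d}", rt1=float(warp(a)), rt2=1.0 + warp(a) / 1000.0))
            for i, a in enumerate(anchor_rts)
        ]
        queries = np.linspace(250.0, 1750.0, 40)
        target = self._target([(float(q), 1.0 + q / 1000.0) for q in queries])
        out = correct_rt(target, pairs, enabled=True)
        oracle = np.interp(queries, anchor_rts, [warp(a) for a in anchor_rts])
        for p, q, o in zip(out.peaks, queries, oracle):
            # the smoother rounds the slope change; allow a bound well below
            # the 5 s merge window but generous around the breakpoint
            assert abs(p.rt1 - warp(q)) < 2.0
            assert abs(p.rt1 - o) < 2.0


def _thr(d0=1.0, sim0=-1.0, ms0=-1.0, w=0.5, d_max=50.0):
    return Thresholds(d0=d0, sim0=sim0, ms0=ms0, w=w, d_max=d_max)


def _greedy_oracle(ref, tgt, thr):
    """Independent brute-force greedy max-mS matcher over the gated pairs."""
    params = MixtureParams(thr.w, thr.d_max)
    cands = []
    for rp in ref:
        for tp in tgt:
            d = rt_distance(rp, tp)
            if not d < thr.d0:
                continue
            sim = spectrum_similarity_or(rp.spectrum, tp.spectrum)
            if not sim > thr.sim0:
                continue
            cands.append((-mixture_similarity(d, sim, params), d, rp.uid, tp.uid, rp, tp))
    cands.sort(key=lambda c: c[:4])
    used_r, used_t, out = set(), set(), []
    for _negms, _d, ruid, tuid, rp, tp in cands:
        if ruid in used_r or tuid in used_t:
            continue
        used_r.add(ruid)
        used_t.add(tuid)
        out.append((ruid, tuid))
    return sorted(out)


class TestAlignPair:
    def _spectra_pool(self, rng, n):
        return [random_spectrum(rng) for _ in range(n)]

    def test_unambiguous_same_name_pairs_all_accepted(self):
        rng = np.random.default_rng(0)
        specs = self._spectra_pool(rng, 3)
        ref = [zpeak(f"R:{i:04d}", 5.0 * i, 0.0, name=f"c{i}", spectrum=specs[i])
               for i in range(3)]
        tgt = [zpeak(f"T:{i:04d}", 5.0 * i + 0.1, 0.0, name=f"c{i}", spectrum=specs[i])
               for i in range(3)]
        pairs = align_pair(ref, tgt, _thr())
        assert sorted((a.uid, b.uid) for a, b in pairs) == [
            ("R:0000", "T:0000"), ("R:0001", "T:0001"), ("R:0002", "T:0002")
        ]

    def test_distance_gate_excludes_candidates(self):
        rng = np.random.default_rng(1)
        s = random_spectrum(rng)
        ref = [zpeak("R:0000", 0.0, 0.0, spectrum=s)]
        tgt = [zpeak("T:0000", 2.0, 0.0, spectrum=s)]
        assert align_pair(ref, tgt, _thr(d0=2.0)) == []  # strict: d < d0

    def test_similarity_gate_excludes_candidates(self):
        ref = [zpeak("R:0000", 0.0, 0.0, spectrum=spec_of((70, 100.0), (80, 2.0)))]
        tgt = [zpeak("T:0000", 0.1, 0.0, spectrum=spec_of((120, 90.0), (130, 80.0)))]
        assert align_pair(ref, tgt, _thr(sim0=0.5)) == []

    def test_contested_name_resolved_by_largest_mixture_similarity(self):
        rng = np.random.default_rng(2)
        s = random_spectrum(rng)
        ref = [zpeak("R:0000", 0.0, 0.0, name="X", spectrum=s)]
        tgt = [
            zpeak("T:0000", 0.30, 0.0, name="X", spectrum=s),
            zpeak("T:0001", 0.05, 0.0, name="X", spectrum=s),
        ]
        thr = _thr()
        pairs = align_pair(ref, tgt, thr)
        # exhaustive check over the toy candidate set
        params = MixtureParams(thr.w, thr.d_max)
        best = max(tgt, key=lambda tp: mixture_similarity(
            rt_distance(ref[0], tp), spectrum_similarity_or(s, tp.spectrum), params))
        assert [(a.uid, b.uid) for a, b in pairs] == [("R:0000", best.uid)]

    def test_same_name_acceptance_purges_conflicting_unnamed_pairs(self):
        rng = np.random.default_rng(3)
        s = random_spectrum(rng)
        ref = [
            zpeak("R:0000", 0.0, 0.0, name="X", spectrum=s),
            zpeak("R:0001", 0.4, 0.0, name="", spectrum=s),
        ]
        tgt = [zpeak("T:0000", 0.1, 0.0, name="X", spectrum=s)]
        pairs = align_pair(ref, tgt, _thr())
        # the named pair wins even though the unnamed one may score higher
        assert [(a.uid, b.uid) for a, b in pairs] == [("R:0000", "T:0000")]

    def test_each_peak_used_at_most_once(self):
        rng = np.random.default_rng(4)
        s = random_spectrum(rng)
        ref = [zpeak(f"R:{i:04d}", 0.1 * i, 0.0, spectrum=s) for i in range(5)]
        tgt = [zpeak(f"T:{i:04d}", 0.1 * i + 0.02, 0.0, spectrum=s) for i in range(5)]
        pairs = align_pair(ref, tgt, _thr())
        ruids = [a.uid for a, _ in pairs]
        tuids = [b.uid for _, b in pairs]
        assert len(ruids) == len(set(ruids))
        assert len(tuids) == len(set(tuids))

    def test_loosened_gates_reduce_to_greedy_max_ms_matching(self):
        """With d0=d_max and sim0=-1, the matcher equals a brute-force greedy
        oracle on small unnamed instances across many random draws."""
        rng = np.random.default_rng(99)
        thr = _thr(d0=50.0, sim0=-1.0, w=0.5, d_max=50.0)
        for trial in range(200):
            specs = self._spectra_pool(rng, 6)
            nr, nt = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            ref = [zpeak(f"R:{i:04d}", float(rng.uniform(-5, 5)), float(rng.uniform(-2, 2)),
                         spectrum=specs[int(rng.integers(6))]) for i in range(nr)]
            tgt = [zpeak(f"T:{i:04d}", float(rng.uniform(-5, 5)), float(rng.uniform(-2, 2)),
                         spectrum=specs[int(rng.integers(6))]) for i in range(nt)]
            got = sorted((a.uid, b.uid) for a, b in align_pair(ref, tgt, thr))
            assert got == _greedy_oracle(ref, tgt, thr), f"trial {trial}"

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(5)
        specs = self._spectra_pool(rng, 4)
        ref = [zpeak(f"R:{i:04d}", float(rng.uniform(-2, 2)), 0.0,
                     spectrum=specs[i]) for i in range(4)]
        tgt = [zpeak(f"T:{i:04d}", float(rng.uniform(-2, 2)), 0.0,
                     spectrum=specs[int(rng.integers(4))]) for i in range(4)]
        thr = _thr()
        a = sorted((x.uid, y.uid) for x, y in align_pair(ref, tgt, thr))
        b = sorted((x.uid, y.uid) for x, y in align_pair(ref[::-1], tgt[::-1], thr))
        assert a == b

    def test_accepted_pairs_satisfy_gates_post_hoc(self):
        rng = np.random.default_rng(6)
        specs = self._spectra_pool(rng, 5)
        ref = [zpeak(f"R:{i:04d}", float(rng.uniform(-3, 3)), float(rng.uniform(-1, 1)),
                     spectrum=specs[i]) for i in range(5)]
        tgt = [zpeak(f"T:{i:04d}", float(rng.uniform(-3, 3)), float(rng.uniform(-1, 1)),
                     spectrum=specs[int(rng.integers(5))]) for i in range(5)]
        thr = _thr(d0=1.5, sim0=0.0)
        for rp, tp in align_pair(ref, tgt, thr):
            assert rt_distance(rp, tp) < thr.d0
            assert spectrum_similarity_or(rp.spectrum, tp.spectrum) > thr.sim0


class TestAlignAll:
    def test_single_sample_gives_singleton_rows(self):
        rng = np.random.default_rng(7)
        s = PeakList("A", [zpeak(f"A:{i:04d}", float(i), 0.0, name=f"c{i}",
                                 spectrum=random_spectrum(rng)) for i in range(4)])
        table = align_all([s], None, None)
        assert len(table) == 4
        assert all(len(r.members) == 1 for r in table.rows)

    def test_no_peak_in_two_rows(self):
        rng = np.random.default_rng(8)
        specs = [random_spectrum(rng) for _ in range(6)]
        lists = []
        for sid in ("R", "T"):
            peaks = [zpeak(f"{sid}:{i:04d}", float(i) + (0.01 if sid == "T" else 0.0),
                           0.0, name=f"c{i}", spectrum=specs[i]) for i in range(6)]
            lists.append(PeakList(sid, peaks))
        lm = LandmarkSet(
            groups=[AlignedGroup(
                members={"R": lists[0].peaks[i], "T": lists[1].peaks[i]},
                kind="landmark", consensus_name=f"c{i}") for i in range(2)],
            reference_id="R",
        )
        table = align_all(lists, lm, _thr(d0=0.5, sim0=-1.0))
        uids = [f"{sid}/{p.uid}" for r in table.rows for sid, p in r.members.items()]
        assert len(uids) == len(set(uids))
        assert sum(r.kind == "landmark" for r in table.rows) == 2
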