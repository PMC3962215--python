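"""Stage-2 partial alignment: data-derived thresholds and pairwise matching.

The landmark pairs found in stage 1 are trusted correspondences measured under
the same instrumental conditions as everything else, so their distance,
spectrum-correlation and mixture-similarity distributions calibrate the
matching gates for the remaining peaks: after one-sided Grubbs outlier
rejection, d0 is the largest retained landmark distance, sim0 the smallest
retained correlation and mS0 the smallest retained mixture similarity. No
user-tuned retention-time window or similarity cutoff is needed.

The pairwise matcher then aligns non-landmark peaks reference-against-target:
candidate pairs pass the d < d0 and sim > sim0 gate, same-name pairs are
resolved first (unique name accepted outright, contested names by largest
mixture similarity), and the remaining candidates are accepted greedily by
mixture similarity, purging any pair that shares a peak with an accepted one.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .model import AlignedGroup, AlignmentTable, ContractError, Peak, PeakList
from .full_alignment import LandmarkSet, target_order
from .similarity import MixtureParams, mixture_similarity, rt_distance, spectrum_similarity_or

log = logging.getLogger("gcalign.partial")

__all__ = [
    "Thresholds",
    "GrubbsConfig",
    "grubbs_critical",
    "grubbs_remove",
    "derive_thresholds",
    "prune_landmarks",
    "correct_rt",
    "align_pair",
    "align_all",
]


@dataclass(frozen=True)
class Thresholds:
    """Data-derived matching gates plus the stage-1 mixture parameters.

    d0: largest allowed z-space distance; sim0: smallest allowed spectrum
    correlation; ms0: smallest landmark mixture similarity (reported, and
    optionally enforced as an extra gate).
    """

    d0: float
    sim0: float
    ms0: float
    w: float
    d_max: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ContractError(f"d0 must be non-negative (got {self.d0})")
        if self.d0 > self.d_max * (1 + 1e-12):
            raise ContractError(f"d0 ({self.d0}) exceeds d_max ({self.d_max})")
        if not -1.0 <= self.sim0 <= 1.0:
            raise ContractError(f"sim0 must be in [-1, 1] (got {self.sim0})")

    @property
    def mixture_params(self) -> MixtureParams:
        return MixtureParams(w=self.w, d_max=self.d_max)


@dataclass(frozen=True)
class GrubbsConfig:
    """Iterative one-sided Grubbs test settings (significance level, cap)."""

    alpha: float = 0.05
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ContractError(f"alpha must be in (0, 1) (got {self.alpha})")
        if self.max_iterations < 1:
            raise ContractError("max_iterations must be positive")


def grubbs_critical(n: int, alpha: float, one_sided: bool = True) -> float:
    """Grubbs critical value from the t distribution.

    One-sided: G = (n-1)/sqrt(n) * sqrt(t^2 / (n-2+t^2)) with t the upper
    alpha/n quantile at n-2 degrees of freedom (alpha/(2n) for two-sided).
    Reproduces the published one-sided 5% table (1.153 at n=3, 2.176 at n=10).
    """
    if n < 3:
        raise ContractError("Grubbs test requires n >= 3")
    p = alpha / n if one_sided else alpha / (2 * n)
    t = sstats.t.ppf(1.0 - p, n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_remove(
    values: list[float], tail: str = "high", cfg: GrubbsConfig = GrubbsConfig()
) -> list[float]:
    """Iteratively strip one-sided outliers from ``values``.

    ``tail="high"`` tests the maximum (used for distances), ``"low"`` the
    minimum (similarities). Each round removes the single most extreme value
    while its G statistic |extreme - mean| / sd exceeds the critical value at
    the configured level; survivors keep their input order. Fewer than three
    values, or zero spread, leaves the input unchanged (with a warning for
    n < 3: the test is undefined).
    """
    if tail not in ("high", "low"):
        raise ContractError(f"tail must be 'high' or 'low' (got {tail!r})")
    out = list(values)
    if len(out) < 3:
        log.warning("Grubbs test undefined for n=%d; values returned unchanged", len(out))
        return out
    for _ in range(cfg.max_iterations):
        n = len(out)
        if n < 3:
            break
        mean = float(np.mean(out))
        sd = float(np.std(out, ddof=1))
        if sd == 0:
            break
        if tail == "high":
            extreme = max(out)
            g = (extreme - mean) / sd
        else:
            extreme = min(out)
            g = (mean - extreme) / sd
        if g > grubbs_critical(n, cfg.alpha):
            out.remove(extreme)  # first occurrence; order of survivors preserved
        else:
            break
    return out


def derive_thresholds(
    landmarks: LandmarkSet,
    samples: list[PeakList],
    params: MixtureParams,
    cfg: GrubbsConfig = GrubbsConfig(),
) -> Thresholds:
    """Derive (d0, sim0, ms0) from the landmark pair statistics.

    Collects d, sim and mS for every landmark group over every
    (reference, target) sample pair, rejects outliers per parameter in its
    suspicious tail (high for d, low for sim and mS), then takes the extreme
    retained value of each collection as the gate.

    Grubbs' test assumes normality. Distances are tested on their raw scale,
    but correlation-type parameters (sim, and mS, which is bounded by 1) are
    strongly left-skewed near their upper bound, so they are tested on the
    Fisher z scale (arctanh) — the standard variance-stabilising transform
    for correlations — and the retained extreme is mapped back. Without the
    transform the iterative test cascades into the legitimate tail and the
    derived gate rejects true matches.
    """
    if not landmarks.groups:
        raise ContractError("cannot derive thresholds from an empty landmark set")
    ref_id = landmarks.reference_id
    target_ids = [s.sample_id for s in target_order(samples, ref_id)]
    ds: list[float] = []
    sims: list[float] = []
    mss: list[float] = []
    for group in landmarks.groups:
        rp = group.members[ref_id]
        for tid in target_ids:
            tp = group.members[tid]
            d = rt_distance(rp, tp)
            sim = spectrum_similarity_or(rp.spectrum, tp.spectrum)  # type: ignore[arg-type]
            ds.append(d)
            sims.append(sim)
            mss.append(mixture_similarity(d, sim, params))
    def min_retained_fisher(values: list[float]) -> float:
        clipped = np.clip(values, -1.0 + 1e-12, 1.0 - 1e-12)
        retained = grubbs_remove([float(v) for v in np.arctanh(clipped)], "low", cfg)
        return float(np.tanh(min(retained))) if retained else float("nan")

    d_ret = grubbs_remove(ds, "high", cfg)
    sim0 = min_retained_fisher(sims)
    ms0 = min_retained_fisher(mss)
    if not d_ret or math.isnan(sim0) or math.isnan(ms0):
        raise ContractError("outlier rejection emptied a landmark statistic")
    thr = Thresholds(
        d0=max(d_ret),
        sim0=sim0,
        ms0=ms0,
        w=params.w,
        d_max=params.d_max,
    )
    log.info(
        "thresholds: d0=%.4g sim0=%.4g ms0=%.4g (from %d landmark pairs, %d distances retained)",
        thr.d0, thr.sim0, thr.ms0, len(ds), len(d_ret),
    )
    return thr


def prune_landmarks(
    landmarks: LandmarkSet,
    samples: list[PeakList],
    thresholds: Thresholds,
) -> tuple[LandmarkSet, list[AlignedGroup]]:
    """Demote landmark groups whose pair statistics were rejected as outliers.

    Stage 2 treats landmark pairs as true alignments; a group whose distance
    exceeds d0 or whose spectrum correlation falls below sim0 in any sample
    pair was flagged by the outlier rejection and cannot be trusted (typical
    cause: a mis-assigned compound name matched across samples). Such groups
    are removed from the landmark set — their peaks re-enter the stage-2 pool
    — and returned separately for reporting. If pruning would empty the set,
    the original is kept with a warning.
    """
    ref_id = landmarks.reference_id
    target_ids = [s.sample_id for s in target_order(samples, ref_id)]
    kept: list[AlignedGroup] = []
    demoted: list[AlignedGroup] = []
    for group in landmarks.groups:
        rp = group.members[ref_id]
        ok = True
        for tid in target_ids:
            tp = group.members[tid]
            d = rt_distance(rp, tp)
            sim = spectrum_similarity_or(rp.spectrum, tp.spectrum)  # type: ignore[arg-type]
            # epsilon guards keep floating-point noise (identical replicate
            # coordinates differing at 1e-16) from demoting exact matches
            if d > thresholds.d0 + 1e-12 or sim < thresholds.sim0 - 1e-12:
                ok = False
                break
        (kept if ok else demoted).append(group)
    if not kept:
        log.warning("outlier pruning would demote every landmark group; keeping all")
        return landmarks, []
    if demoted:
        log.info("demoted %d landmark group(s) with outlier pair statistics", len(demoted))
    return LandmarkSet(groups=kept, reference_id=ref_id), demoted


def _local_linear_map(
    x: np.ndarray, anchors_x: np.ndarray, anchors_y: np.ndarray,
    frac: float = 0.3, min_k: int = 5,
) -> np.ndarray:
    """Local linear fit (LOESS, degree 1) through the anchors, evaluated at x.

    Each query point gets a weighted least-squares line through its k nearest
    anchors (tricube weights), k = max(min_k, frac*n) capped at n. A smoother
    is used instead of exact interpolation because anchor positions carry
    retention-time jitter: interpolating through two anchors that nearly
    coincide in x produces arbitrarily large local slopes, while the local
    fit averages the noise away yet still reproduces any consistent linear
    shift exactly. Queries beyond the anchor range follow the local line of
    the nearest anchors (linear extrapolation).
    """
    n = anchors_x.size
    k = min(n, max(min_k, int(math.ceil(frac * n))))
    out = np.empty(x.size)
    for i, xq in enumerate(x):
        dist = np.abs(anchors_x - xq)
        idx = np.argpartition(dist, k - 1)[:k] if k < n else np.arange(n)
        ax = anchors_x[idx]
        ay = anchors_y[idx]
        h = dist[idx].max()
        if h == 0:
            out[i] = float(np.mean(ay))
            continue
        w = (1.0 - np.minimum(dist[idx] / h, 1.0) ** 3) ** 3
        w = np.maximum(w, 1e-6)  # keep the furthest anchor weakly weighted
        sw = w.sum()
        xm = float(np.dot(w, ax) / sw)
        ym = float(np.dot(w, ay) / sw)
        sxx = float(np.dot(w, (ax - xm) ** 2))
        if sxx <= 0:
            out[i] = ym
            continue
        slope = float(np.dot(w, (ax - xm) * (ay - ym))) / sxx
        out[i] = ym + slope * (xq - xm)
    return out


def correct_rt(
    target: PeakList,
    landmark_pairs: list[tuple[Peak, Peak]],
    enabled: bool = True,
) -> PeakList:
    """Landmark-anchored retention-time correction for one target sample.

    ``landmark_pairs`` are (target_peak, reference_peak) anchors. Each
    dimension is warped independently by a local linear fit taking target
    anchor RTs onto reference anchor RTs, so non-linear drift is handled
    piece by piece; a consistent shift (same offset at every anchor) is
    removed exactly. Disabled, or with fewer than two anchors, the identity
    is returned; z coordinates are cleared and must be recomputed in the
    corrected frame.
    """
    if not enabled:
        return target
    if len(landmark_pairs) < 2:
        log.warning(
            "%s: %d landmark pair(s) is too few for RT correction; identity used",
            target.sample_id, len(landmark_pairs),
        )
        return target

    def anchors(dim: str) -> tuple[np.ndarray, np.ndarray]:
        acc: dict[float, list[float]] = {}
        for tp, rp in landmark_pairs:
            acc.setdefault(getattr(tp, dim), []).append(getattr(rp, dim))
        xs = np.array(sorted(acc))
        ys = np.array([float(np.mean(acc[x])) for x in xs])
        return xs, ys

    x1, y1 = anchors("rt1")
    x2, y2 = anchors("rt2")
    if x1.size < 2 or x2.size < 2:
        log.warning("%s: degenerate anchor set; identity used", target.sample_id)
        return target
    rt1 = np.array([p.rt1 for p in target.peaks])
    rt2 = np.array([p.rt2 for p in target.peaks])
    new1 = _local_linear_map(rt1, x1, y1)
    new2 = _local_linear_map(rt2, x2, y2)
    corrected = [
        p.with_rt(float(a), float(b)) for p, a, b in zip(target.peaks, new1, new2)
    ]
    return PeakList(sample_id=target.sample_id, peaks=corrected, zstats=None)


@dataclass(frozen=True)
class _Candidate:
    ref: Peak
    tgt: Peak
    d: float
    sim: float
    ms: float

    @property
    def rank_key(self) -> tuple[float, float, str, str]:
        # larger mS first, then smaller d, then lexicographic uids
        return (-self.ms, self.d, self.ref.uid, self.tgt.uid)

    @property
    def same_name(self) -> bool:
        return bool(self.ref.name) and self.ref.name == self.tgt.name


def _gate_candidates(
    reference_rest: list[Peak],
    target_rest: list[Peak],
    thresholds: Thresholds,
    enforce_ms0: bool,
) -> list[_Candidate]:
    """All (reference, target) combinations passing d < d0 and sim > sim0.

    The z1 axis is used as an interval index: since d < d0 implies
    |Δz1| < d0, only that window of the rt1-sorted target list is scanned.
    """
    tgt_sorted = sorted(target_rest, key=lambda p: p.z1)  # type: ignore[arg-type]
    tz1 = [p.z1 for p in tgt_sorted]
    params = thresholds.mixture_params
    out: list[_Candidate] = []
    for rp in reference_rest:
        if not rp.has_z:
            raise ContractError("align_pair requires z-transformed peaks")
        lo = bisect.bisect_left(tz1, rp.z1 - thresholds.d0)  # type: ignore[operator]
        hi = bisect.bisect_right(tz1, rp.z1 + thresholds.d0)  # type: ignore[operator]
        for tp in tgt_sorted[lo:hi]:
            d = rt_distance(rp, tp)
            if not d < thresholds.d0:
                continue
            sim = spectrum_similarity_or(rp.spectrum, tp.spectrum)  # type: ignore[arg-type]
            if not sim > thresholds.sim0:
                continue
            ms = mixture_similarity(d, sim, params)
            if enforce_ms0 and ms < thresholds.ms0:
                continue
            out.append(_Candidate(ref=rp, tgt=tp, d=d, sim=sim, ms=ms))
    return out


def align_pair(
    reference_rest: list[Peak],
    target_rest: list[Peak],
    thresholds: Thresholds,
    enforce_ms0: bool = False,
) -> list[tuple[Peak, Peak]]:
    """Align the non-landmark peaks of one (reference, target) sample pair.

    Candidates pass the d < d0 and sim > sim0 gate. Same-name candidates are
    resolved first: a name seen in exactly one pair is accepted outright, a
    contested name keeps its largest-mS pair; every acceptance purges
    candidates sharing either peak. Different-name candidates conflicting with
    the accepted set are then dropped, and the remainder is accepted greedily
    by largest mS (ties: smaller d, then lexicographic peak uid), purging
    conflicts, until none remain. Each peak ends up in at most one pair.
    """
    candidates = _gate_candidates(reference_rest, target_rest, thresholds, enforce_ms0)
    same = sorted((c for c in candidates if c.same_name), key=lambda c: c.rank_key)
    diff = sorted((c for c in candidates if not c.same_name), key=lambda c: c.rank_key)

    accepted: list[_Candidate] = []
    used_ref: set[str] = set()
    used_tgt: set[str] = set()

    def accept(c: _Candidate) -> None:
        accepted.append(c)
        used_ref.add(c.ref.uid)
        used_tgt.add(c.tgt.uid)

    def purge(pool: list[_Candidate]) -> list[_Candidate]:
        return [c for c in pool if c.ref.uid not in used_ref and c.tgt.uid not in used_tgt]

    # same-name resolution: within this pool a shared peak implies a shared
    # name, so each name group can be settled independently
    while same:
        counts: dict[str, int] = {}
        for c in same:
            counts[c.ref.name] = counts.get(c.ref.name, 0) + 1
        name = sorted(counts)[0]
        group = [c for c in same if c.ref.name == name]
        accept(min(group, key=lambda c: c.rank_key))  # unique pair or largest mS
        same = purge(same)

    diff = purge(diff)
    while diff:
        accept(diff[0])  # pools stay rank-sorted; head is the largest-mS pair
        diff = purge(diff)

    accepted.sort(key=lambda c: c.ref.sort_key)
    return [(c.ref, c.tgt) for c in accepted]


def _consensus_name(members: dict[str, Peak]) -> str:
    counts: dict[str, int] = {}
    for p in members.values():
        if p.name:
            counts[p.name] = counts.get(p.name, 0) + 1
    if not counts:
        return ""
    return min(counts, key=lambda n: (-counts[n], n))


def align_all(
    samples: list[PeakList],
    landmarks: LandmarkSet | None,
    thresholds: Thresholds | None,
    enforce_ms0: bool = False,
) -> AlignmentTable:
    """Combine landmark rows with pairwise partial alignment into one table.

    Every (reference, target) pair is aligned with :func:`align_pair`; results
    merge into groups keyed by the reference peak, so every non-landmark
    reference peak yields one row carrying whatever targets matched it
    (possibly none). Compounds absent from the reference cannot be aligned —
    a documented consequence of anchoring everything at the reference sample.
    With a single sample the table is that sample's peaks as singleton rows.
    """
    sample_ids = [s.sample_id for s in samples]
    if len(samples) == 1:
        rows = [
            AlignedGroup(members={samples[0].sample_id: p}, kind="partial",
                         consensus_name=p.name)
            for p in samples[0].peaks
        ]
        return AlignmentTable(rows=rows, samples=sample_ids)
    if landmarks is None or thresholds is None:
        raise ContractError("multi-sample alignment requires landmarks and thresholds")

    ref_id = landmarks.reference_id
    by_id = {s.sample_id: s for s in samples}
    ref_rest = [
        p for p in by_id[ref_id].peaks if p.uid not in landmarks.member_uids(ref_id)
    ]
    partial: dict[str, dict[str, Peak]] = {p.uid: {ref_id: p} for p in ref_rest}

    for target in target_order(samples, ref_id):
        tgt_rest = [
            p for p in target.peaks
            if p.uid not in landmarks.member_uids(target.sample_id)
        ]
        for rp, tp in align_pair(ref_rest, tgt_rest, thresholds, enforce_ms0):
            partial[rp.uid][target.sample_id] = tp

    rows = list(landmarks.groups)
    for rp in ref_rest:  # reference (rt1, rt2) order
        members = partial[rp.uid]
        rows.append(
            AlignedGroup(members=members, kind="partial",
                         consensus_name=_consensus_name(members))
        )
    return AlignmentTable(rows=rows, samples=sample_ids)
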