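"""Stage-1 full alignment: landmark discovery and mixture-weight optimisation.

Landmark peaks are compounds present (under the same assigned name) in every
sample. One sample acts as the reference; each of its named peaks is matched
to the nearest same-name peak of each target sample in z-transformed
retention-time space, and the reference set shrinks to the peaks that found a
partner in every target. The surviving groups anchor stage 2: they calibrate
the contribution factor w of the mixture similarity and, later, the matching
thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import AlignedGroup, ContractError, EmptyLandmarkSetError, Peak, PeakList
from .similarity import rt_distance, spectrum_similarity_or

log = logging.getLogger("gcalign.full")

#: Candidate contribution factors scanned by :func:`optimize_w`.
DEFAULT_W_CANDIDATES: tuple[float, ...] = (
    0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95,
)

__all__ = [
    "DEFAULT_W_CANDIDATES",
    "LandmarkSet",
    "WSearchResult",
    "select_reference",
    "target_order",
    "find_landmarks",
    "optimize_w",
]


@dataclass
class LandmarkSet:
    """Aligned landmark groups (one member per sample) plus the reference id."""

    groups: list[AlignedGroup]
    reference_id: str

    def __len__(self) -> int:
        return len(self.groups)

    def member_uids(self, sample_id: str) -> set[str]:
        return {g.members[sample_id].uid for g in self.groups if sample_id in g.members}


@dataclass
class WSearchResult:
    """Outcome of the w grid search.

    ``per_pair_scores`` maps each candidate w to the summed mixture similarity
    per (reference, target) sample pair; ``totals`` is the global sum that the
    arg-max is taken over.
    """

    w_opt: float
    per_pair_scores: dict[float, dict[str, float]]
    totals: dict[float, float] = field(default_factory=dict)


def select_reference(
    samples: list[PeakList], policy: str = "most_peaks", rng: np.random.Generator | None = None
) -> str:
    """Choose the reference sample.

    ``most_peaks`` (default) picks the largest peak list, ties broken by
    lexicographic sample id, so repeat runs agree. ``random`` draws uniformly
    from the run's seeded generator.
    """
    if len(samples) < 2:
        raise ContractError("need at least 2 samples to align")
    if policy == "most_peaks":
        return min(samples, key=lambda s: (-len(s), s.sample_id)).sample_id
    if policy == "random":
        if rng is None:
            raise ContractError("random reference policy requires a seeded generator")
        ids = sorted(s.sample_id for s in samples)
        return str(rng.choice(ids))
    raise ContractError(f"unknown reference policy {policy!r}")


def target_order(samples: list[PeakList], reference_id: str) -> list[PeakList]:
    """Deterministic target iteration order: descending peak count, then id."""
    targets = [s for s in samples if s.sample_id != reference_id]
    return sorted(targets, key=lambda s: (-len(s), s.sample_id))


def find_landmarks(samples: list[PeakList], reference_id: str) -> LandmarkSet:
    """Find compound groups present, under one name, in every sample.

    For each target in turn, surviving reference peaks are paired with
    same-name target peaks nearest-first in z-space: within each name group
    all (reference, candidate) distances are ranked ascending (ties by peak
    uid) and assigned greedily, so when a name is duplicated — e.g. a
    mis-assigned neighbour carrying the same library hit — the genuinely
    close pair wins and the duplicate cannot steal it. Reference peaks that
    find no partner drop out, so the final groups span all samples. Raises
    :class:`EmptyLandmarkSetError` when nothing survives — downstream
    thresholds cannot be derived without landmarks.
    """
    by_id = {s.sample_id: s for s in samples}
    if reference_id not in by_id:
        raise ContractError(f"unknown reference sample {reference_id!r}")
    reference = by_id[reference_id]
    for s in samples:
        if any(not p.has_z for p in s.peaks):
            raise ContractError(f"{s.sample_id}: peaks must be z-transformed")

    current = [p for p in reference.peaks if p.name]
    partners: dict[str, dict[str, Peak]] = {p.uid: {reference_id: p} for p in current}

    for target in target_order(samples, reference_id):
        by_name: dict[str, list[Peak]] = {}
        for p in target.peaks:
            if p.name:
                by_name.setdefault(p.name, []).append(p)
        ref_by_name: dict[str, list[Peak]] = {}
        for rp in current:
            ref_by_name.setdefault(rp.name, []).append(rp)
        matched: dict[str, Peak] = {}
        for name, refs in ref_by_name.items():
            cands = by_name.get(name)
            if not cands:
                continue
            edges = sorted(
                ((rt_distance(rp, tp), rp.uid, tp.uid, rp, tp)
                 for rp in refs for tp in cands),
                key=lambda e: e[:3],
            )
            used_ref: set[str] = set()
            used_tgt: set[str] = set()
            for _d, ruid, tuid, rp, tp in edges:
                if ruid in used_ref or tuid in used_tgt:
                    continue
                used_ref.add(ruid)
                used_tgt.add(tuid)
                matched[ruid] = tp
        surviving: list[Peak] = []
        for rp in current:  # keep reference (rt1, rt2) order
            tp = matched.get(rp.uid)
            if tp is None:
                continue
            partners[rp.uid][target.sample_id] = tp
            surviving.append(rp)
        current = surviving
        if not current:
            break

    if not current:
        log.warning("no compound name shared by all %d samples", len(samples))
        raise EmptyLandmarkSetError(
            "no landmark peaks: no compound is present under one name in every sample"
        )
    groups = [
        AlignedGroup(members=partners[rp.uid], kind="landmark", consensus_name=rp.name)
        for rp in current
    ]
    log.info("found %d landmark group(s) across %d samples", len(groups), len(samples))
    return LandmarkSet(groups=groups, reference_id=reference_id)


def optimize_w(
    landmarks: LandmarkSet,
    samples: list[PeakList],
    candidates: tuple[float, ...] = DEFAULT_W_CANDIDATES,
    d_max: float = 1.0,
) -> WSearchResult:
    """Grid-search the contribution factor w over the candidate set.

    For each candidate, the mixture similarity is summed over every landmark
    group and every (reference, target) sample pair; the candidate with the
    largest global sum wins, ties going to the smaller w (favouring spectral
    evidence). Landmark pairs are trusted matches, so the winning w is the one
    that scores true correspondences highest.
    """
    if not landmarks.groups:
        raise EmptyLandmarkSetError("cannot optimise w without landmarks")
    if d_max <= 0:
        raise ContractError("d_max must be positive")
    ref_id = landmarks.reference_id
    target_ids = [s.sample_id for s in target_order(samples, ref_id)]

    # mS is affine in w given (d, sim); cache the two per-pair terms
    pair_terms: dict[str, list[tuple[float, float]]] = {t: [] for t in target_ids}
    for group in landmarks.groups:
        rp = group.members[ref_id]
        for tid in target_ids:
            tp = group.members[tid]
            d = rt_distance(rp, tp)
            if d > d_max:
                d = d_max
            sim = spectrum_similarity_or(rp.spectrum, tp.spectrum)  # type: ignore[arg-type]
            pair_terms[tid].append((1.0 - (d / d_max) ** 2, sim))

    per_pair: dict[float, dict[str, float]] = {}
    totals: dict[float, float] = {}
    for w in candidates:
        scores = {
            tid: sum(w * dist_term + (1.0 - w) * sim for dist_term, sim in terms)
            for tid, terms in pair_terms.items()
        }
        per_pair[w] = scores
        totals[w] = sum(scores.values())

    w_opt = min(candidates)
    for w in sorted(candidates):
        if totals[w] > totals[w_opt]:
            w_opt = w
    log.info("optimised w = %g (total mS %.4f)", w_opt, totals[w_opt])
    return WSearchResult(w_opt=w_opt, per_pair_scores=per_pair, totals=totals)
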