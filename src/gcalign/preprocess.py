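"""Stage-1 preprocessing: split-entry merging and z-score RT transformation.

Deconvolution software can report one metabolite as several peak-list rows
(abnormal peak shape, over-sensitive detection). ``merge_entries`` collapses
such groups: peaks chained within a retention-time window in both dimensions
whose spectra correlate above R0 are replaced by one representative whose
area is the sum of the members and whose retention times are the area-weighted
means. ``zscore_transform`` then standardises each sample's retention times
per dimension so the short second-dimension axis contributes on equal footing
with the first, and ``compute_dmax`` measures the largest pairwise distance
over all peaks of all samples, which normalises the mixture similarity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .model import (
    ContractError,
    DegenerateSampleError,
    MassSpectrum,
    Peak,
    PeakList,
    ZScoreStats,
)
from .similarity import spectrum_similarity_or

log = logging.getLogger("gcalign.preprocess")

__all__ = ["MergeConfig", "merge_entries", "zscore_transform", "compute_dmax"]


@dataclass(frozen=True)
class MergeConfig:
    """Split-entry merge gate: RT windows (seconds) and minimum spectrum correlation.

    These are the only user-facing thresholds of the whole pipeline. Defaults:
    5 s in the first dimension (a few modulation periods), 0.1 s in the second,
    and R0 = 0.95 (split entries of one compound share essentially the same
    spectrum).
    """

    rt1_window: float = 5.0
    rt2_window: float = 0.1
    r0: float = 0.95

    def __post_init__(self) -> None:
        if not (self.rt1_window > 0 and self.rt2_window > 0):
            raise ContractError("merge windows must be positive")
        if not 0.0 < self.r0 <= 1.0:
            raise ContractError(f"r0 must be in (0, 1] (got {self.r0})")


def _merge_group(group: list[Peak]) -> Peak:
    """Collapse one connected group into its representative peak.

    Area is the exact sum of member areas; retention times are area-weighted
    means per dimension; the spectrum is the area-weighted average of member
    spectra on the union m/z grid; the name is taken from the largest-area
    member (deconvolution confidence tracks peak size).
    """
    if len(group) == 1:
        return group[0]
    area = math.fsum(p.area for p in group)
    rt1 = math.fsum(p.area * p.rt1 for p in group) / area
    rt2 = math.fsum(p.area * p.rt2 for p in group) / area
    mz = group[0].spectrum.mz  # type: ignore[union-attr]
    for p in group[1:]:
        mz = np.union1d(mz, p.spectrum.mz)  # type: ignore[union-attr]
    inten = np.zeros(mz.size)
    for p in group:
        idx = np.searchsorted(mz, p.spectrum.mz)  # type: ignore[union-attr]
        inten[idx] += (p.area / area) * p.spectrum.intensity  # type: ignore[union-attr]
    largest = max(group, key=lambda p: (p.area, p.uid))
    source_ids = tuple(sorted(i for p in group for i in p.source_ids))
    sid = group[0].uid.rsplit(":", 1)[0]
    return Peak(
        name=largest.name,
        rt1=rt1,
        rt2=rt2,
        area=area,
        spectrum=MassSpectrum(mz, inten),
        source_ids=source_ids,
        uid=f"{sid}:{min(source_ids):04d}",
    )


def merge_entries(sample: PeakList, cfg: MergeConfig = MergeConfig()) -> PeakList:
    """Merge split peak entries within one sample.

    Two peaks are directly linked when |Δrt1| ≤ rt1_window, |Δrt2| ≤ rt2_window
    and their spectrum correlation exceeds r0; groups are the connected
    components of that relation, so chains of split entries merge transitively
    regardless of input order. Total area is conserved.
    """
    peaks = sample.peaks
    n = len(peaks)
    if n == 0:
        return PeakList(sample_id=sample.sample_id, peaks=[])

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # peaks are sorted by rt1, so the inner scan stops at the rt1 window edge
    for i in range(n):
        for j in range(i + 1, n):
            if peaks[j].rt1 - peaks[i].rt1 > cfg.rt1_window:
                break
            if abs(peaks[j].rt2 - peaks[i].rt2) > cfg.rt2_window:
                continue
            if find(i) == find(j):
                continue
            sim = spectrum_similarity_or(peaks[i].spectrum, peaks[j].spectrum)  # type: ignore[arg-type]
            if sim > cfg.r0:
                union(i, j)

    groups: dict[int, list[Peak]] = {}
    for i, p in enumerate(peaks):
        groups.setdefault(find(i), []).append(p)
    merged = [_merge_group(g) for g in groups.values()]
    n_merged = sum(1 for g in groups.values() if len(g) > 1)
    if n_merged:
        log.info("%s: merged %d split group(s), %d -> %d peaks",
                 sample.sample_id, n_merged, n, len(merged))
    return PeakList(sample_id=sample.sample_id, peaks=merged)


def zscore_transform(sample: PeakList) -> PeakList:
    """Standardise retention times per dimension (sample mean 0, sd 1).

    The sd uses the n-1 (sample) convention. Raises
    :class:`DegenerateSampleError` for fewer than two peaks or zero spread in
    either dimension. Original retention times are kept on the peaks; the
    transformed coordinates are stored as z1/z2 and the statistics on the
    returned list's ``zstats``.
    """
    if len(sample) < 2:
        raise DegenerateSampleError(
            f"{sample.sample_id}: need at least 2 peaks to z-transform"
        )
    rt1 = np.array([p.rt1 for p in sample.peaks])
    rt2 = np.array([p.rt2 for p in sample.peaks])
    sd1 = float(np.std(rt1, ddof=1))
    sd2 = float(np.std(rt2, ddof=1))
    if sd1 == 0 or sd2 == 0:
        raise DegenerateSampleError(
            f"{sample.sample_id}: zero retention-time spread (sd1={sd1}, sd2={sd2})"
        )
    stats = ZScoreStats(float(np.mean(rt1)), sd1, float(np.mean(rt2)), sd2)
    transformed = [p.with_z(*stats.transform(p.rt1, p.rt2)) for p in sample.peaks]
    return PeakList(sample_id=sample.sample_id, peaks=transformed, zstats=stats)


def compute_dmax(samples: list[PeakList]) -> float:
    """Maximum pairwise retention-time distance (z-space) over all peaks.

    All within- and cross-sample pairs count. Requires at least two peaks in
    total and z-transformed inputs.
    """
    coords = []
    for s in samples:
        for p in s.peaks:
            if not p.has_z:
                raise ContractError(f"{s.sample_id}: peaks must be z-transformed")
            coords.append((p.z1, p.z2))
    if len(coords) < 2:
        raise ContractError("compute_dmax needs at least 2 peaks in total")
    pts = np.asarray(coords)
    # all-pairs scan; peak lists are a few thousand rows at most
    return float(pdist(pts).max())
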