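"""Domain model for GCxGC/TOF-MS peak lists and alignment results.

A peak list is the per-run output of spectral deconvolution software
(e.g. ChromaTOF): one row per detected peak carrying a (possibly empty)
compound name, two retention times (first and second chromatographic
dimension, both in seconds), a peak area and a fragment-ion mass spectrum.
Alignment groups peaks of the same compound across samples into rows of an
:class:`AlignmentTable`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "GCAlignError",
    "MalformedSpectrumError",
    "FormatError",
    "DegenerateSampleError",
    "UndefinedCorrelationError",
    "ContractError",
    "EmptyLandmarkSetError",
    "StageError",
    "MassSpectrum",
    "Peak",
    "ZScoreStats",
    "PeakList",
    "AlignedGroup",
    "AlignmentTable",
]


class GCAlignError(Exception):
    """Base class for all gcalign errors."""


class MalformedSpectrumError(GCAlignError):
    """A fragment spectrum string could not be parsed or is empty/invalid."""


class FormatError(GCAlignError):
    """An input file does not conform to the expected dialect."""


class DegenerateSampleError(GCAlignError):
    """A sample cannot be z-transformed (fewer than 2 peaks or zero RT spread)."""


class UndefinedCorrelationError(GCAlignError):
    """Pearson correlation is undefined (a spectrum is constant on the union grid)."""


class ContractError(GCAlignError):
    """An operation was called with inputs violating its precondition."""


class EmptyLandmarkSetError(GCAlignError):
    """No compound is present (by name) in every sample; thresholds cannot be derived."""


class StageError(GCAlignError):
    """A pipeline stage failed; carries the stage tag for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class MassSpectrum:
    """Sparse fragment-ion spectrum: intensities on strictly increasing m/z channels.

    m/z values are unit-resolution channels (rounded to the nearest integer on
    input by default); intensities are non-negative with at least one positive.
    """

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.ndim != 1 or inten.ndim != 1 or mz.size != inten.size:
            raise MalformedSpectrumError("m/z and intensity arrays must be 1-D and equal length")
        if mz.size == 0:
            raise MalformedSpectrumError("empty spectrum")
        if np.any(mz <= 0):
            raise MalformedSpectrumError("m/z values must be positive")
        if mz.size > 1 and np.any(np.diff(mz) <= 0):
            raise MalformedSpectrumError("m/z values must be strictly increasing")
        if np.any(inten < 0):
            raise MalformedSpectrumError("negative intensity")
        if not np.any(inten > 0):
            raise MalformedSpectrumError("spectrum has no positive intensity")

    def __len__(self) -> int:
        return int(self.mz.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MassSpectrum):
            return NotImplemented
        return (
            self.mz.shape == other.mz.shape
            and bool(np.all(self.mz == other.mz))
            and bool(np.all(self.intensity == other.intensity))
        )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]]) -> "MassSpectrum":
        """Build a spectrum from (m/z, intensity) pairs; duplicate m/z are summed."""
        acc: dict[float, float] = {}
        for m, i in pairs:
            acc[m] = acc.get(m, 0.0) + float(i)
        if not acc:
            raise MalformedSpectrumError("empty spectrum")
        mz = np.array(sorted(acc), dtype=float)
        inten = np.array([acc[m] for m in mz], dtype=float)
        return cls(mz, inten)

    def to_text(self) -> str:
        """Serialize as whitespace-separated ``mz:intensity`` tokens."""
        return " ".join(f"{m:g}:{i:g}" for m, i in zip(self.mz, self.intensity))


@dataclass(frozen=True)
class Peak:
    """One peak-list entry.

    ``source_ids`` are the original data-row indices that contributed to this
    peak; merging split entries concatenates them. ``uid`` is a stable
    identifier of the form ``<sample_id>:<min source row>``. ``z1``/``z2`` are
    the z-transformed retention-time coordinates, set by the z-score transform.
    """

    name: str
    rt1: float
    rt2: float
    area: float
    spectrum: MassSpectrum | None
    source_ids: tuple[int, ...]
    uid: str = ""
    z1: float | None = None
    z2: float | None = None

    def __post_init__(self) -> None:
        if not (self.rt1 > 0 and self.rt2 > 0):
            raise ContractError(f"retention times must be positive (got {self.rt1}, {self.rt2})")
        if not self.area > 0:
            raise ContractError(f"peak area must be positive (got {self.area})")
        if not self.source_ids:
            raise ContractError("source_ids must be non-empty")

    @property
    def has_z(self) -> bool:
        return self.z1 is not None and self.z2 is not None

    @property
    def sort_key(self) -> tuple[float, float, str]:
        return (self.rt1, self.rt2, self.uid)

    def with_z(self, z1: float, z2: float) -> "Peak":
        return dataclasses.replace(self, z1=z1, z2=z2)

    def with_rt(self, rt1: float, rt2: float) -> "Peak":
        return dataclasses.replace(self, rt1=rt1, rt2=rt2, z1=None, z2=None)


@dataclass(frozen=True)
class ZScoreStats:
    """Per-sample retention-time mean/sd used by the z-score transform."""

    rt1_mean: float
    rt1_sd: float
    rt2_mean: float
    rt2_sd: float

    def __post_init__(self) -> None:
        if not (self.rt1_sd > 0 and self.rt2_sd > 0):
            raise DegenerateSampleError(
                f"retention-time sd must be positive (got {self.rt1_sd}, {self.rt2_sd})"
            )

    def transform(self, rt1: float, rt2: float) -> tuple[float, float]:
        return ((rt1 - self.rt1_mean) / self.rt1_sd, (rt2 - self.rt2_mean) / self.rt2_sd)

    def inverse(self, z1: float, z2: float) -> tuple[float, float]:
        return (z1 * self.rt1_sd + self.rt1_mean, z2 * self.rt2_sd + self.rt2_mean)


@dataclass
class PeakList:
    """Ordered peaks of one sample. Peaks are kept sorted by (rt1, rt2)."""

    sample_id: str
    peaks: list[Peak]
    zstats: ZScoreStats | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ContractError("sample_id must be non-empty")
        self.peaks = sorted(self.peaks, key=lambda p: p.sort_key)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)


@dataclass
class AlignedGroup:
    """One aligned compound group: at most one member peak per sample.

    ``kind`` is ``"landmark"`` (present in every sample, found in stage 1) or
    ``"partial"`` (stage 2). ``consensus_name`` is the agreed compound name,
    possibly empty for unassigned groups.
    """

    members: dict[str, Peak]
    kind: str
    consensus_name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("landmark", "partial"):
            raise ContractError(f"unknown group kind {self.kind!r}")
        if not self.members:
            raise ContractError("aligned group must have at least one member")


@dataclass
class AlignmentTable:
    """Rows = aligned compound groups, columns = samples."""

    rows: list[AlignedGroup]
    samples: list[str]

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("duplicate sample ids in alignment table")
        self.validate()

    def validate(self) -> None:
        """Check structural invariants: membership, landmark completeness, disjointness."""
        sset = set(self.samples)
        seen: set[str] = set()
        for row in self.rows:
            extra = set(row.members) - sset
            if extra:
                raise ContractError(f"row references unknown samples {sorted(extra)}")
            if row.kind == "landmark" and len(row.members) != len(self.samples):
                raise ContractError("landmark row must have one member per sample")
            for sid, peak in row.members.items():
                key = f"{sid}/{peak.uid}"
                if key in seen:
                    raise ContractError(f"peak {peak.uid} of sample {sid} appears in two rows")
                seen.add(key)

    @property
    def full_rows(self) -> list[AlignedGroup]:
        """Rows with a member in every sample (the 'matched peak pairs')."""
        n = len(self.samples)
        return [r for r in self.rows if len(r.members) == n]

    def __len__(self) -> int:
        return len(self.rows)
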