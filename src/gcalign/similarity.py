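"""Distance and similarity kernels.

Two peaks are compared by (i) the Euclidean distance of their z-transformed
two-dimensional retention times, (ii) Pearson's correlation of their fragment
spectra laid out on the union of their m/z grids, and (iii) a mixture
similarity blending the two:

    mS = w * (1 - (d / d_max)^2) + (1 - w) * sim

where w in [0, 1] is the contribution factor and d_max is the maximum
pairwise retention-time distance over all peaks of all samples (z-score
space), so the distance term is normalised to [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .model import ContractError, MassSpectrum, Peak, UndefinedCorrelationError

log = logging.getLogger("gcalign.similarity")

__all__ = [
    "MixtureParams",
    "rt_distance",
    "spectrum_similarity",
    "spectrum_similarity_or",
    "mixture_similarity",
]


@dataclass(frozen=True)
class MixtureParams:
    """Parameters of the mixture similarity: contribution factor w and d_max."""

    w: float
    d_max: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ContractError(f"w must be in [0, 1] (got {self.w})")
        if not self.d_max > 0:
            raise ContractError(f"d_max must be positive (got {self.d_max})")


def rt_distance(a: Peak, b: Peak) -> float:
    """Euclidean distance of two peaks in z-transformed retention-time space."""
    if not (a.has_z and b.has_z):
        raise ContractError("rt_distance requires z-transformed peaks")
    return math.hypot(a.z1 - b.z1, a.z2 - b.z2)  # type: ignore[operator]


def _union_vectors(x: MassSpectrum, y: MassSpectrum) -> tuple[np.ndarray, np.ndarray]:
    mz = np.union1d(x.mz, y.mz)
    xv = np.zeros(mz.size)
    yv = np.zeros(mz.size)
    xv[np.searchsorted(mz, x.mz)] = x.intensity
    yv[np.searchsorted(mz, y.mz)] = y.intensity
    return xv, yv


def spectrum_similarity(x: MassSpectrum, y: MassSpectrum) -> float:
    """Pearson correlation of two fragment spectra on their union m/z grid.

    Channels absent from one spectrum contribute intensity 0, so a fragment
    present in only one spectrum counts as evidence against the match.
    Raises :class:`UndefinedCorrelationError` when either zero-filled vector
    is constant (correlation undefined); callers that need a total order map
    that case to -1 via :func:`spectrum_similarity_or`.
    """
    xv, yv = _union_vectors(x, y)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise UndefinedCorrelationError("spectrum constant on the union m/z grid")
    r = float(np.corrcoef(xv, yv)[0, 1])
    return min(1.0, max(-1.0, r))


def spectrum_similarity_or(x: MassSpectrum, y: MassSpectrum, fallback: float = -1.0) -> float:
    """spectrum_similarity with undefined correlation mapped to ``fallback``.

    The fallback defaults to -1 so that a flat spectrum can never win a
    match over an informative one.
    """
    try:
        return spectrum_similarity(x, y)
    except UndefinedCorrelationError:
        log.debug("undefined spectrum correlation mapped to %g", fallback)
        return fallback


def mixture_similarity(d: float, sim: float, params: MixtureParams) -> float:
    """Mixture similarity mS = w*(1-(d/d_max)^2) + (1-w)*sim.

    ``d`` beyond ``d_max`` is clamped with a warning: non-landmark peak pairs
    can exceed the envelope over which d_max was measured.
    """
    if d < 0:
        raise ContractError(f"distance must be non-negative (got {d})")
    if d > params.d_max:
        log.warning("distance %g exceeds d_max %g; clamping", d, params.d_max)
        d = params.d_max
    ratio = d / params.d_max
    return params.w * (1.0 - ratio * ratio) + (1.0 - params.w) * sim
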