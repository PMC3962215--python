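"""Shared construction helpers for the test suite."""

from __future__ import annotations

import numpy as np

from gcalign.model import MassSpectrum, Peak, PeakList


def spec_of(*pairs: tuple[float, float]) -> MassSpectrum:
    return MassSpectrum.from_pairs(pairs)


def make_peak(
    uid: str = "S:0000",
    name: str = "",
    rt1: float = 100.0,
    rt2: float = 2.0,
    area: float = 10.0,
    spectrum: MassSpectrum | None = None,
    z: tuple[float, float] | None = None,
    src: tuple[int, ...] | None = None,
) -> Peak:
    if spectrum is None:
        spectrum = spec_of((70.0, 100.0), (85.0, 40.0), (120.0, 5.0))
    if src is None:
        tail = uid.rsplit(":", 1)[-1]
        src = (int(tail),) if tail.isdigit() else (0,)
    p = Peak(name=name, rt1=rt1, rt2=rt2, area=area, spectrum=spectrum,
             source_ids=src, uid=uid)
    if z is not None:
        p = p.with_z(*z)
    return p


def zpeak(uid: str, z1: float, z2: float, name: str = "",
          spectrum: MassSpectrum | None = None, area: float = 10.0) -> Peak:
    """Peak with explicit z coordinates (raw RTs derived to stay positive)."""
    return make_peak(uid=uid, name=name, rt1=1000.0 + z1, rt2=10.0 + z2,
                     area=area, spectrum=spectrum, z=(z1, z2))


def random_spectrum(rng: np.random.Generator, n_channels: int = 10) -> MassSpectrum:
    mz = np.sort(rng.choice(np.arange(50, 200), size=n_channels, replace=False))
    inten = rng.uniform(1.0, 999.0, n_channels)
    return MassSpectrum(mz.astype(float), inten)


def naive_pearson(x: list[float], y: list[float]) -> float:
    """Textbook two-pass Pearson correlation, independent of numpy."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx * vy) ** 0.5


def union_vectors(a: MassSpectrum, b: MassSpectrum) -> tuple[list[float], list[float]]:
    """Zero-filled intensity vectors on the union m/z grid (oracle layout)."""
    grid = sorted(set(a.mz.tolist()) | set(b.mz.tolist()))
    da = dict(zip(a.mz.tolist(), a.intensity.tolist()))
    db = dict(zip(b.mz.tolist(), b.intensity.tolist()))
    return [da.get(m, 0.0) for m in grid], [db.get(m, 0.0) for m in grid]
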