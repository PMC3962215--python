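"""Synthetic multi-sample peak lists with known ground truth.

The generator emulates the data regime the aligner targets: replicate
GCxGC/TOF-MS runs of one mixture, each run applying its own retention-time
shift (constant, linear or piecewise-linear drift) plus random jitter,
occasionally splitting a peak into several entries, dropping compounds, and
corrupting assigned names (blanked, swapped with a retention-time neighbour,
or replaced by a random string). Every emitted peak-list row is covered by a
ground-truth map from (sample, row) to compound, so alignment output can be
scored exactly.

The defaults are the documented moderate-noise study conditions; a fixed seed
makes output byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .io import Dialect, write_peak_list, write_truth
from .model import ContractError, MassSpectrum, Peak, PeakList

__all__ = ["SimConfig", "split_peak", "generate", "write_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulator.

    ``rt_jitter_sd`` is the per-peak retention-time noise sd in seconds, per
    dimension; ``shift_model`` selects the per-sample systematic drift;
    ``spectrum_noise_sd`` is the sd of the multiplicative log-normal intensity
    noise; ``split_prob``/``dropout_prob``/``name_error_prob`` are per
    compound-in-sample event probabilities.
    """

    n_compounds: int = 100
    n_samples: int = 4
    rt1_range: tuple[float, float] = (300.0, 3000.0)
    rt2_range: tuple[float, float] = (0.8, 4.8)
    shift_model: str = "linear"  # constant | linear | piecewise
    rt_jitter_sd: tuple[float, float] = (0.3, 0.005)
    split_prob: float = 0.1
    dropout_prob: float = 0.05
    name_error_prob: float = 0.1
    spectrum_channels: int = 200
    spectrum_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("split_prob", "dropout_prob", "name_error_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ContractError(f"{name} must be in [0, 1] (got {v})")
        for rng_name in ("rt1_range", "rt2_range"):
            lo, hi = getattr(self, rng_name)
            if not (0 < lo < hi):
                raise ContractError(f"{rng_name} must be an increasing positive range")
        if self.shift_model not in ("constant", "linear", "piecewise"):
            raise ContractError(f"unknown shift_model {self.shift_model!r}")
        if self.n_compounds < 2 or self.n_samples < 1:
            raise ContractError("need at least 2 compounds and 1 sample")
        if self.spectrum_channels < 25:
            raise ContractError("spectrum_channels must be at least 25")
        if self.spectrum_noise_sd < 0 or min(self.rt_jitter_sd) < 0:
            raise ContractError("noise levels must be non-negative")


def split_peak(
    peak: Peak,
    k: int,
    rng: np.random.Generator,
    rt1_spread: float = 1.5,
    rt2_spread: float = 0.02,
) -> list[Peak]:
    """Split one peak into k sub-entries that merging can invert.

    Sub-areas are a Dirichlet partition of the original area with the last
    share taken as the exact floating-point remainder, so the areas sum back
    exactly; retention-time offsets are centred so the area-weighted mean of
    the sub-peaks equals the original retention time, and their spread stays
    well inside the default merge windows. Sub-spectra are the parent spectrum
    scaled by each area share.
    """
    if k < 2:
        raise ContractError("split requires k >= 2")
    fracs = rng.dirichlet(np.full(k, 5.0))
    # partition the area's 53-bit mantissa into integer shares: every share is
    # exactly representable and their real sum is exactly the original area,
    # so merging (which sums with fsum) inverts the split without area drift
    mant, exp = math.frexp(peak.area)
    m = int(mant * (1 << 53))
    e = exp - 53
    shares = [int(f * m) for f in fracs[:-1]]
    shares.append(m - sum(shares))
    if min(shares) <= 0:  # pathological partition; fall back to equal shares
        shares = [m // k] * (k - 1)
        shares.append(m - (k - 1) * (m // k))
    areas = [math.ldexp(s, e) for s in shares]

    def centred_offsets(spread: float) -> np.ndarray:
        off = rng.uniform(-spread, spread, k)
        return off - math.fsum(a * o for a, o in zip(areas, off)) / peak.area

    off1 = centred_offsets(rt1_spread)
    off2 = centred_offsets(rt2_spread)
    assert peak.spectrum is not None
    subs = []
    for i in range(k):
        subs.append(
            Peak(
                name=peak.name,
                rt1=peak.rt1 + float(off1[i]),
                rt2=peak.rt2 + float(off2[i]),
                area=areas[i],
                spectrum=MassSpectrum(peak.spectrum.mz, peak.spectrum.intensity * fracs[i]),
                source_ids=peak.source_ids,
                uid=f"{peak.uid}#{i}",
            )
        )
    return subs


def _shift_fn(model: str, span: tuple[float, float], offset_sd: float,
              slope_sd: float, rng: np.random.Generator) -> Callable[[float], float]:
    """Per-sample systematic retention-time drift for one dimension."""
    lo, hi = span
    mid = 0.5 * (lo + hi)
    a = rng.normal(0.0, offset_sd)
    if model == "constant":
        return lambda rt: rt + a
    if model == "linear":
        b = 1.0 + rng.normal(0.0, slope_sd)
        return lambda rt: mid + b * (rt - mid) + a
    # piecewise: two slopes meeting continuously at a breakpoint in the middle third
    brk = rng.uniform(lo + (hi - lo) / 3, hi - (hi - lo) / 3)
    b_left = 1.0 + rng.normal(0.0, slope_sd)
    b_right = 1.0 + rng.normal(0.0, slope_sd)

    def warp(rt: float) -> float:
        if rt <= brk:
            return brk + a + b_left * (rt - brk)
        return brk + a + b_right * (rt - brk)

    return warp


def generate(cfg: SimConfig) -> tuple[list[PeakList], dict[tuple[str, int], str]]:
    """Generate the sample peak lists and the ground-truth map.

    Returns one :class:`PeakList` per sample (rows sorted by retention time,
    ``source_ids`` holding the final row index) and a map
    (sample_id, row index) -> compound id covering every generated row.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_compounds

    compound_ids = [f"M{i:03d}" for i in range(n)]
    base_rt1 = rng.uniform(*cfg.rt1_range, n)
    base_rt2 = rng.uniform(*cfg.rt2_range, n)
    base_area = rng.lognormal(mean=11.0, sigma=1.0, size=n)
    mz_lo = 50
    spectra: list[MassSpectrum] = []
    for _ in range(n):
        n_frag = int(rng.integers(8, 21))
        channels = np.sort(rng.choice(np.arange(mz_lo, mz_lo + cfg.spectrum_channels),
                                      size=n_frag, replace=False))
        # EI fragment patterns span decades: base peak at 999, the rest
        # log-uniform down to ~3 per mil, so replicate-run channel noise
        # leaves true-pair Pearson correlation high
        exponents = rng.uniform(0.0, 2.5, n_frag)
        exponents[rng.integers(n_frag)] = 0.0
        inten = 999.0 * 10.0 ** (-exponents)
        spectra.append(MassSpectrum(channels.astype(float), inten))
    # nearest neighbour in rt1, used by the name-swap corruption mode
    order = np.argsort(base_rt1)
    nearest = np.empty(n, dtype=int)
    for pos, ci in enumerate(order):
        if pos == 0:
            nearest[ci] = order[1]
        elif pos == n - 1:
            nearest[ci] = order[-2]
        else:
            left, right = order[pos - 1], order[pos + 1]
            nearest[ci] = left if (base_rt1[ci] - base_rt1[left]
                                   <= base_rt1[right] - base_rt1[ci]) else right

    samples: list[PeakList] = []
    truth: dict[tuple[str, int], str] = {}
    for s in range(cfg.n_samples):
        sid = f"S{s + 1:02d}"
        f1 = _shift_fn(cfg.shift_model, cfg.rt1_range, 5.0, 0.005, rng)
        f2 = _shift_fn(cfg.shift_model, cfg.rt2_range, 0.05, 0.01, rng)
        rows: list[tuple[Peak, str]] = []
        for ci in range(n):
            if rng.random() < cfg.dropout_prob:
                continue
            rt1 = f1(base_rt1[ci]) + rng.normal(0.0, cfg.rt_jitter_sd[0])
            rt2 = max(f2(base_rt2[ci]) + rng.normal(0.0, cfg.rt_jitter_sd[1]), 0.05)
            area = float(base_area[ci] * rng.lognormal(0.0, 0.2))
            base = spectra[ci]
            if cfg.spectrum_noise_sd > 0:
                inten = base.intensity * rng.lognormal(0.0, cfg.spectrum_noise_sd,
                                                       base.intensity.size)
            else:
                inten = base.intensity.copy()
            name = compound_ids[ci]
            if rng.random() < cfg.name_error_prob:
                mode = rng.integers(3)
                if mode == 0:
                    name = ""
                elif mode == 1:
                    name = compound_ids[nearest[ci]]
                else:
                    name = f"X{rng.integers(10**6):06d}"
            peak = Peak(name=name, rt1=float(rt1), rt2=float(rt2), area=area,
                        spectrum=MassSpectrum(base.mz, inten),
                        source_ids=(0,), uid="tmp")
            if rng.random() < cfg.split_prob:
                k = int(rng.integers(2, 4))
                for sub in split_peak(peak, k, rng):
                    rows.append((sub, compound_ids[ci]))
            else:
                rows.append((peak, compound_ids[ci]))
        rows.sort(key=lambda rc: (rc[0].rt1, rc[0].rt2))
        peaks = []
        for idx, (peak, cid) in enumerate(rows):
            peaks.append(
                Peak(name=peak.name, rt1=peak.rt1, rt2=peak.rt2, area=peak.area,
                     spectrum=peak.spectrum, source_ids=(idx,), uid=f"{sid}:{idx:04d}")
            )
            truth[(sid, idx)] = cid
        samples.append(PeakList(sample_id=sid, peaks=peaks))
    return samples, truth


def write_dataset(cfg: SimConfig, outdir: str | Path,
                  dialect: Dialect = Dialect()) -> tuple[list[Path], Path]:
    """Generate and write the peak-list files plus ``truth.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples, truth = generate(cfg)
    paths = []
    for sample in samples:
        path = outdir / f"{sample.sample_id}.csv"
        write_peak_list(sample, path, dialect)
        paths.append(path)
    truth_path = outdir / "truth.csv"
    write_truth(truth, truth_path)
    return paths, truth_path
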