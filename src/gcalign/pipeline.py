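"""End-to-end orchestration of the two-stage alignment workflow.

merge split entries → z-score transform → global d_max → landmark discovery →
w grid search → Grubbs-derived thresholds → (optional RT correction) →
pairwise partial alignment → combined table + machine-readable report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import full_alignment, partial_alignment, preprocess
from .io import Dialect, read_peak_list, write_alignment_table
from .model import AlignmentTable, GCAlignError, PeakList, StageError
from .partial_alignment import GrubbsConfig, Thresholds, correct_rt
from .similarity import MixtureParams

log = logging.getLogger("gcalign.pipeline")

__all__ = ["RunConfig", "align_peak_lists", "run_pipeline"]


@dataclass
class RunConfig:
    """Flat run configuration; keys mirror the module config namespaces."""

    inputs: list[Path] = field(default_factory=list)
    output_dir: Path = Path(".")
    merge_rt1_window: float = 5.0
    merge_rt2_window: float = 0.1
    merge_r0: float = 0.95
    reference_policy: str = "most_peaks"
    w_candidates: tuple[float, ...] = full_alignment.DEFAULT_W_CANDIDATES
    grubbs_alpha: float = 0.05
    enforce_ms0: bool = False
    rt_correction: bool = True
    seed: int | None = None
    log_level: str = "INFO"

    _YAML_KEYS = {
        "merge.rt1_window": "merge_rt1_window",
        "merge.rt2_window": "merge_rt2_window",
        "merge.r0": "merge_r0",
        "full.reference_policy": "reference_policy",
        "full.w_candidates": "w_candidates",
        "partial.grubbs_alpha": "grubbs_alpha",
        "partial.enforce_ms0": "enforce_ms0",
        "partial.rt_correction": "rt_correction",
        "seed": "seed",
        "log_level": "log_level",
    }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            attr = cls._YAML_KEYS.get(key)
            if attr is None:
                raise GCAlignError(f"unknown config key {key!r}")
            if attr == "w_candidates":
                value = tuple(float(v) for v in value)
            setattr(cfg, attr, value)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["inputs"] = [str(p) for p in self.inputs]
        d["output_dir"] = str(self.output_dir)
        d["w_candidates"] = list(self.w_candidates)
        return d


def align_peak_lists(
    raw_samples: list[PeakList], cfg: RunConfig | None = None
) -> tuple[AlignmentTable, dict[str, Any]]:
    """Run the two-stage alignment on in-memory peak lists.

    Returns the combined alignment table and a report with the calibrated
    parameters (w_opt, d_max, d0, sim0, mS0), the landmark count and
    per-stage peak counts. Stage failures raise :class:`StageError` tagged
    with the failing stage.
    """
    cfg = cfg or RunConfig()
    rng = np.random.default_rng(cfg.seed if cfg.seed is not None else 0)
    report: dict[str, Any] = {
        "n_samples": len(raw_samples),
        "peaks_read": {s.sample_id: len(s) for s in raw_samples},
    }

    if len(raw_samples) < 2:
        raise StageError("input", "need at least 2 peak lists to align")

    try:
        merge_cfg = preprocess.MergeConfig(
            rt1_window=cfg.merge_rt1_window, rt2_window=cfg.merge_rt2_window, r0=cfg.merge_r0
        )
        merged = [preprocess.merge_entries(s, merge_cfg) for s in raw_samples]
        report["peaks_after_merge"] = {s.sample_id: len(s) for s in merged}
    except GCAlignError as exc:
        raise StageError("merge", str(exc)) from exc

    try:
        zsamples = [preprocess.zscore_transform(s) for s in merged]
        d_max = preprocess.compute_dmax(zsamples)
        report["d_max"] = d_max
    except GCAlignError as exc:
        raise StageError("zscore", str(exc)) from exc

    try:
        ref_id = full_alignment.select_reference(zsamples, cfg.reference_policy, rng)
        landmarks = full_alignment.find_landmarks(zsamples, ref_id)
        wres = full_alignment.optimize_w(landmarks, zsamples, cfg.w_candidates, d_max)
        report["reference"] = ref_id
        report["n_landmarks"] = len(landmarks)
        report["w_opt"] = wres.w_opt
        report["w_totals"] = {f"{w:g}": t for w, t in sorted(wres.totals.items())}
    except GCAlignError as exc:
        raise StageError("full_alignment", str(exc)) from exc

    try:
        params = MixtureParams(w=wres.w_opt, d_max=d_max)
        thresholds = partial_alignment.derive_thresholds(
            landmarks, zsamples, params, GrubbsConfig(alpha=cfg.grubbs_alpha)
        )
        report["thresholds"] = {
            "d0": thresholds.d0, "sim0": thresholds.sim0, "ms0": thresholds.ms0
        }
        # landmark groups flagged by the outlier rejection are not trusted:
        # they leave the landmark set and re-enter the stage-2 pool
        landmarks, demoted = partial_alignment.prune_landmarks(
            landmarks, zsamples, thresholds
        )
        report["n_landmarks_retained"] = len(landmarks)
        report["n_landmarks_demoted"] = len(demoted)
    except GCAlignError as exc:
        raise StageError("thresholds", str(exc)) from exc

    try:
        if cfg.rt_correction:
            # warp each target onto the reference frame through the retained
            # landmark anchors; thresholds keep describing the uncorrected
            # variation, so they stay valid (conservative) gates afterwards
            ref_stats = next(s for s in zsamples if s.sample_id == ref_id).zstats
            assert ref_stats is not None
            corrected: list[PeakList] = []
            uid_map: dict[str, Peak] = {}
            for s in zsamples:
                if s.sample_id == ref_id:
                    corrected.append(s)
                    for p in s.peaks:
                        uid_map[p.uid] = p
                    continue
                pairs = [
                    (g.members[s.sample_id], g.members[ref_id]) for g in landmarks.groups
                ]
                warped = correct_rt(s, pairs, enabled=True)
                warped = PeakList(
                    sample_id=warped.sample_id,
                    peaks=[p.with_z(*ref_stats.transform(p.rt1, p.rt2)) for p in warped.peaks],
                    zstats=ref_stats,
                )
                corrected.append(warped)
                for p in warped.peaks:
                    uid_map[p.uid] = p
            zsamples = corrected
            # rebind landmark members to the corrected peak objects
            landmarks = full_alignment.LandmarkSet(
                groups=[
                    full_alignment.AlignedGroup(
                        members={sid: uid_map[p.uid] for sid, p in g.members.items()},
                        kind="landmark",
                        consensus_name=g.consensus_name,
                    )
                    for g in landmarks.groups
                ],
                reference_id=ref_id,
            )
        table = partial_alignment.align_all(
            zsamples, landmarks, thresholds, enforce_ms0=cfg.enforce_ms0
        )
    except GCAlignError as exc:
        raise StageError("partial_alignment", str(exc)) from exc

    report["n_rows"] = len(table)
    report["n_full_rows"] = len(table.full_rows)
    report["n_partial_rows"] = len(table) - len(table.full_rows)
    report["config"] = cfg.to_dict()
    return table, report


def run_pipeline(cfg: RunConfig) -> tuple[AlignmentTable, dict[str, Any]]:
    """File-level entry point: read inputs, align, write table and report."""
    samples = []
    for path in cfg.inputs:
        try:
            samples.append(read_peak_list(path, Dialect()))
        except (OSError, GCAlignError) as exc:
            raise StageError("input", f"{path}: {exc}") from exc
    table, report = align_peak_lists(samples, cfg)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    table_path = outdir / "alignment.csv"
    report_path = outdir / "report.json"
    write_alignment_table(table, table_path)
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("wrote %s (%d rows) and %s", table_path, len(table), report_path)
    return table, report
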