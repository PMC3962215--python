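"""Alignment scoring against ground truth: TPR, PPV and F1.

A compound present in all N samples is a *positive peak pair*; a table row
covering all N samples is a *matched peak pair*. A matched row is a true
positive when every member peak traces back to one and the same ground-truth
compound; otherwise it is a false positive. Then

    TPR = TP / (TP + FN),  PPV = TP / (TP + FP),  F1 = 2*TPR*PPV / (TPR+PPV)

with FN = Np - TP and FP = Nm - TP. Rows covering only part of the samples
are reported separately and do not enter the Np/Nm bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .model import AlignmentTable, GCAlignError

log = logging.getLogger("gcalign.evaluation")

__all__ = ["EvaluationResult", "metrics_from_counts", "score"]


@dataclass(frozen=True)
class EvaluationResult:
    n_p: int
    n_m: int
    tp: int
    fp: int
    fn: int
    tpr: float
    ppv: float
    f1: float
    n_partial_rows: int = 0


def metrics_from_counts(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """TPR/PPV/F1 from confusion counts; 0 by convention on a 0 denominator."""
    tpr = tp / (tp + fn) if tp + fn else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * tpr * ppv / (tpr + ppv) if tpr + ppv else 0.0
    if (tp + fn) == 0 or (tp + fp) == 0:
        log.warning("zero denominator in TPR/PPV; metric reported as 0 by convention")
    return tpr, ppv, f1


def _peak_compounds(sample_id: str, source_ids: tuple[int, ...],
                    truth: dict[tuple[str, int], str]) -> set[str]:
    out = set()
    for pid in source_ids:
        key = (sample_id, pid)
        if key not in truth:
            raise GCAlignError(f"peak {sample_id}:{pid} absent from ground truth")
        out.add(truth[key])
    return out


def score(table: AlignmentTable, truth: dict[tuple[str, int], str]) -> EvaluationResult:
    """Score an alignment table against a ground-truth correspondence map.

    ``truth`` maps (sample_id, original row index) to a compound id and must
    cover every peak in the table. A full row whose members mix ground-truth
    compounds (including wrongly merged split entries) counts as one false
    positive — no partial credit.
    """
    n_samples = len(table.samples)

    per_compound: dict[str, set[str]] = {}
    for (sid, _pid), cid in truth.items():
        per_compound.setdefault(cid, set()).add(sid)
    sample_set = set(table.samples)
    positives = {c for c, ss in per_compound.items() if sample_set <= ss}

    tp = 0
    n_m = 0
    n_partial = 0
    for row in table.rows:
        if len(row.members) < n_samples:
            n_partial += 1
            continue
        n_m += 1
        compounds: set[str] = set()
        for sid, peak in row.members.items():
            compounds |= _peak_compounds(sid, peak.source_ids, truth)
        if len(compounds) == 1 and next(iter(compounds)) in positives:
            tp += 1
    fp = n_m - tp
    fn = len(positives) - tp
    tpr, ppv, f1 = metrics_from_counts(tp, fp, fn)
    return EvaluationResult(
        n_p=len(positives), n_m=n_m, tp=tp, fp=fp, fn=fn,
        tpr=tpr, ppv=ppv, f1=f1, n_partial_rows=n_partial,
    )
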