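"""Duplicate-sample reproducibility via Pearson correlation across sensors.

Two breath prints taken minutes apart from the same subject should show
nearly the same 32-sensor pattern.  Agreement is quantified by the Pearson
correlation *across sensors* within each pair (one r per subject), with the
usual t-based two-sided significance test on ``m - 2`` degrees of freedom,
where ``m`` is the number of active sensors (32 by default, 28 under the
humidity mask).  A pair "passes" when r >= 0.8.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import BreathPrint, BreathPrintSet

__all__ = ["ReproducibilityResult", "pearson_pair", "reproducibility_report"]

PASS_THRESHOLD = 0.8


@dataclass(frozen=True)
class ReproducibilityResult:
    subject_id: str
    r: float
    p: float
    m_active: int
    passes: bool


def pearson_pair(
    a: BreathPrint, b: BreathPrint, threshold: float = PASS_THRESHOLD
) -> ReproducibilityResult:
    """Pearson correlation between two prints over their active sensors.

    p comes from ``t = r sqrt(m-2) / sqrt(1-r^2)`` against Student t with
    ``m - 2`` df (two-sided); identical prints report r = 1 with p clamped
    at the smallest positive float.
    """
    if not np.array_equal(a.mask, b.mask):
        raise ValueError("paired prints must share the same sensor mask")
    m = int(a.mask.sum())
    if m < 3:
        raise ValueError("need at least 3 active sensors for a defined p-value")
    xa, xb = a.active_response, b.active_response
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise ValueError("correlation undefined for a constant response vector")
    r, p = stats.pearsonr(xa, xb)
    r = float(min(max(r, -1.0), 1.0))
    p = float(max(p, sys.float_info.min))
    subject = a.subject_id if a.subject_id == b.subject_id else f"{a.subject_id}/{b.subject_id}"
    return ReproducibilityResult(
        subject_id=subject, r=r, p=p, m_active=m, passes=bool(r >= threshold)
    )


def reproducibility_report(
    pairs: BreathPrintSet, threshold: float = PASS_THRESHOLD
) -> tuple[list[ReproducibilityResult], int]:
    """Per-subject duplicate agreement plus the count of pairs with r >= threshold.

    ``pairs`` must contain exactly two prints per subject (any replicate
    order); an unpaired subject is an error.
    """
    if len(pairs) < 2:
        raise ValueError("need at least one duplicate pair")
    by_subject: dict[str, list[BreathPrint]] = {}
    for bp in pairs:
        by_subject.setdefault(bp.subject_id, []).append(bp)
    results = []
    for subject, prints in by_subject.items():
        if len(prints) != 2:
            raise ValueError(
                f"subject {subject!r} has {len(prints)} prints; exactly 2 required"
            )
        first, second = sorted(prints, key=lambda bp: bp.replicate)
        results.append(pearson_pair(first, second, threshold))
    n_pass = sum(res.passes for res in results)
    return results, n_pass
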