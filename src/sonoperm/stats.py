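"""ROI statistics and report assembly.

Group analyses compare the treated (ipsilateral) region to its untreated
mirror (contralateral) within each subject, so the workhorse is the exact
two-tailed Wilcoxon signed-rank test, computed by full enumeration of the
signed-rank null distribution for small n (a dynamic program over attainable
rank sums, with ties mid-ranked) and by the tie-corrected normal
approximation for larger n. Headline changes are reported as percentage
reductions of the contralateral mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mri import QuantMap

__all__ = [
    "PairedSample",
    "RoiReport",
    "WilcoxonResult",
    "extract_roi",
    "relative_change",
    "round_half_away",
    "wilcoxon_exact",
    "paired_report",
    "assemble_report",
]

TIMEPOINTS = ("30min", "60min", "90min", "24h", "d1", "d2", "d3", "d7")


@dataclass
class PairedSample:
    """Matched ipsi/contra measurements for a set of subjects."""

    subject_ids: tuple
    ipsi_values: np.ndarray
    contra_values: np.ndarray
    timepoint: str = "30min"

    def __post_init__(self) -> None:
        self.ipsi_values = np.asarray(self.ipsi_values, dtype=float)
        self.contra_values = np.asarray(self.contra_values, dtype=float)
        if not (
            len(self.subject_ids) == self.ipsi_values.size == self.contra_values.size
        ):
            raise ValueError("subject ids and value arrays must have equal length")
        if np.any(~np.isfinite(self.ipsi_values)) or np.any(
            ~np.isfinite(self.contra_values)
        ):
            raise ValueError("missing pairs are not allowed")


def extract_roi(qmap: QuantMap, roi_mask: np.ndarray) -> tuple[float, int]:
    """Mean of a parametric map over an ROI; returns (mean, voxel count).

    Only voxels inside both the ROI and the map's validity mask contribute.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    sel = roi_mask & qmap.mask & np.isfinite(qmap.values)
    n = int(sel.sum())
    if n == 0:
        raise ValueError("ROI does not overlap the map's valid voxels")
    return float(qmap.values[sel].mean()), n


def round_half_away(x: float) -> int:
    """Nearest integer, ties away from zero (reporting convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def relative_change(mean_ipsi: float, mean_contra: float) -> tuple[float, int]:
    """Percentage reduction of the ipsilateral mean relative to contralateral.

    Returns (raw percent, nearest-integer percent). Positive values mean a
    reduction on the treated side.
    """
    if mean_contra <= 0:
        raise ValueError("contralateral mean must be positive")
    raw = 100.0 * (1.0 - mean_ipsi / mean_contra)
    return raw, round_half_away(raw)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ (sum of positive ranks)
    p_value: float
    n_used: int
    n_zero: int
    method: str  # exact | normal


def _exact_signed_rank_p(ranks2: np.ndarray, w2: float) -> float:
    """Two-tailed exact p for doubled ranks via DP over attainable sums.

    ``ranks2`` are the mid-ranks multiplied by 2 (integers even with ties);
    ``w2`` the doubled observed positive-rank sum. Enumerates the full
    2^n sign null as a subset-sum count table.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in ranks2:
        r = int(r)
        counts[r:] = counts[r:] + counts[:-r] if r > 0 else counts[r:]
    n_assign = 2 ** len(ranks2)
    w2i = int(round(w2))
    p_le = sum(counts[: w2i + 1]) / n_assign
    p_ge = sum(counts[w2i:]) / n_assign
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_exact(pairs: PairedSample, exact_max_n: int = 25) -> WilcoxonResult:
    """Exact two-tailed Wilcoxon signed-rank test of ipsi vs contra.

    Zero differences are dropped (their count is reported); ties among the
    absolute differences are mid-ranked. Up to ``exact_max_n`` non-zero pairs
    the p-value comes from full enumeration of the signed-rank distribution;
    beyond that, from the tie-corrected normal approximation.
    """
    d = pairs.ipsi_values - pairs.contra_values
    nz = d != 0
    n_zero = int((~nz).sum())
    d = d[nz]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    order = np.abs(d)
    # mid-ranks of |d|
    ranks = pd.Series(order).rank(method="average").to_numpy()
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _exact_signed_rank_p(np.round(ranks * 2).astype(int), w_plus * 2)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(order, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        from scipy.stats import norm

        z = (w_plus - mean) / math.sqrt(var)
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
        method = "normal"
    return WilcoxonResult(statistic=w_plus, p_value=p, n_used=n, n_zero=n_zero, method=method)


@dataclass
class RoiReport:
    """Summary of one paired ipsi/contra comparison."""

    mean_ipsi: float
    sd_ipsi: float
    mean_contra: float
    sd_contra: float
    relative_change_pct: float
    relative_change_int: int
    #: mean of per-subject ipsi/contra ratios, the alternative convention
    relative_change_per_subject_pct: float
    p_value: float
    test_name: str
    n: int
    timepoint: str
    quantity: str = ""

    @classmethod
    def from_pairs(cls, pairs: PairedSample, quantity: str = "") -> "RoiReport":
        res = wilcoxon_exact(pairs)
        mi = float(pairs.ipsi_values.mean())
        mc = float(pairs.contra_values.mean())
        raw, as_int = relative_change(mi, mc)
        per_subj = 100.0 * float(np.mean(1.0 - pairs.ipsi_values / pairs.contra_values))
        return cls(
            mean_ipsi=mi,
            sd_ipsi=float(pairs.ipsi_values.std(ddof=1)) if pairs.ipsi_values.size > 1 else 0.0,
            mean_contra=mc,
            sd_contra=float(pairs.contra_values.std(ddof=1)) if pairs.contra_values.size > 1 else 0.0,
            relative_change_pct=raw,
            relative_change_int=as_int,
            relative_change_per_subject_pct=per_subj,
            p_value=res.p_value,
            test_name=f"wilcoxon_{res.method}",
            n=res.n_used,
            timepoint=pairs.timepoint,
            quantity=quantity,
        )

    def to_dict(self) -> dict:
        return {
            "quantity": self.quantity,
            "timepoint": self.timepoint,
            "n": self.n,
            "mean_ipsi": self.mean_ipsi,
            "sd_ipsi": self.sd_ipsi,
            "mean_contra": self.mean_contra,
            "sd_contra": self.sd_contra,
            "relative_change_pct": self.relative_change_pct,
            "relative_change_int": self.relative_change_int,
            "relative_change_per_subject_pct": self.relative_change_per_subject_pct,
            "p_value": self.p_value,
            "test": self.test_name,
        }


paired_report = RoiReport.from_pairs


def assemble_report(
    roi_reports: Sequence[RoiReport] = (),
    verdicts: Sequence = (),
    histology: pd.DataFrame | None = None,
    config: dict | None = None,
) -> dict:
    """Assemble one machine-readable study report.

    Tabulates each paired comparison by quantity and timepoint, summarizes
    cavitation verdicts (counts and fractions per label), and carries the
    histology table and the configuration constants verbatim.
    """
    report: dict = {
        "schema": "sonoperm-report/1",
        "config": dict(config or {}),
        "comparisons": [r.to_dict() for r in roi_reports],
    }
    labels = [getattr(v, "label", v) for v in verdicts]
    n = len(labels)
    summary = {}
    for lab in ("soft", "mild", "hard"):
        k = labels.count(lab)
        summary[lab] = {"count": k, "fraction_pct": (100.0 * k / n) if n else 0.0}
    report["cavitation"] = {"n": n, "by_label": summary, "labels": labels}
    if histology is not None and len(histology):
        report["histology"] = histology.to_dict(orient="records")
    else:
        report["histology"] = []
    return report
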