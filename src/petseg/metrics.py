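"""Segmentation accuracy statistics.

* SOI — spatial overlap index, a Dice-type score:
  SOI = 2|A n B| / (|A| + |B|), in [0, 1].
* CE — voxel classification error:
  CE = (PCE + NCE) / VoIL * 100%, where PCE counts background voxels
  labelled tumour, NCE tumour voxels labelled background, and VoIL is the
  reference (ground-truth) voxel count.  CE may exceed 100%.
* Relative volume error — 100 * (V_seg - V_ref) / V_ref (underestimation
  negative).
* Two-tailed paired t-test on measured vs reference volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volume import BinaryMask, check_congruent

__all__ = [
    "MetricsRecord",
    "TTestResult",
    "spatial_overlap_index",
    "classification_error",
    "relative_volume_error",
    "paired_ttest",
    "evaluate_segmentation",
    "summarize_cohort",
]


@dataclass
class MetricsRecord:
    """All accuracy statistics for one (method, case) pair."""

    soi: float
    pce: int
    nce: int
    voil: int
    ce_percent: float
    seg_volume_cm3: float
    ref_volume_cm3: float
    rel_vol_err_percent: float


@dataclass
class TTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False


def spatial_overlap_index(a: BinaryMask, b: BinaryMask) -> float:
    """2|A n B| / (|A| + |B|).  Symmetric.  Two empty masks agree (1.0);
    exactly one empty mask gives 0."""
    check_congruent(a, b)
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.values & b.values))
    return 2.0 * inter / (na + nb)


def classification_error(seg: BinaryMask, ref: BinaryMask) -> tuple[int, int, float]:
    """(PCE, NCE, CE%) of ``seg`` against the reference ``ref``.

    Not symmetric; CE can exceed 100% for gross over-segmentation.
    """
    check_congruent(seg, ref)
    if ref.is_empty():
        raise ValueError("reference mask is empty: CE is undefined")
    pce = int(np.count_nonzero(seg.values & ~ref.values))
    nce = int(np.count_nonzero(ref.values & ~seg.values))
    voil = ref.n_voxels
    return pce, nce, 100.0 * (pce + nce) / voil


def relative_volume_error(seg: BinaryMask, ref: BinaryMask) -> float:
    """100 * (V_seg - V_ref) / V_ref, percent (negative = underestimation)."""
    check_congruent(seg, ref)
    if ref.is_empty():
        raise ValueError("reference mask is empty")
    return 100.0 * (seg.volume_cm3 - ref.volume_cm3) / ref.volume_cm3


def paired_ttest(measured, reference) -> TTestResult:
    """Classic two-tailed paired t-test on the differences.

    Zero-variance differences are the exact-tie case: identical lists give
    t = 0, p = 1 by convention; constant nonzero differences give an
    infinite t, flagged as degenerate with p = 0.
    """
    x = np.asarray(measured, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("measured and reference must be equal-length 1-D lists")
    n = x.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = x - y
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0.0):
            return TTestResult(0.0, 1.0, df, degenerate=True)
        return TTestResult(float(np.sign(d.mean()) * np.inf), 0.0, df, degenerate=True)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(t, p, df)


def evaluate_segmentation(seg: BinaryMask, ref: BinaryMask) -> MetricsRecord:
    """Full :class:`MetricsRecord` for one segmentation vs its reference."""
    pce, nce, ce = classification_error(seg, ref)
    return MetricsRecord(
        soi=spatial_overlap_index(seg, ref),
        pce=pce,
        nce=nce,
        voil=ref.n_voxels,
        ce_percent=ce,
        seg_volume_cm3=seg.volume_cm3,
        ref_volume_cm3=ref.volume_cm3,
        rel_vol_err_percent=relative_volume_error(seg, ref),
    )


def summarize_cohort(results: pd.DataFrame) -> pd.DataFrame:
    """Per-method benchmark table (mean/SD/range of SOI, mean +/- SD of the
    relative volume error and CE, mean volumes, paired-t p of volumes).

    ``results`` is the long-format table with one row per (case, method):
    columns method, case, soi, ce_percent, seg_volume_cm3, ref_volume_cm3,
    rel_vol_err_percent (rows flagged ``failed`` are excluded).
    """
    df = results
    if "failed" in df.columns:
        df = df[~df["failed"].astype(bool)]
    rows = []
    for method, grp in df.groupby("method", sort=True):
        n = len(grp)
        entry = {
            "method": method,
            "n_cases": n,
            "soi_mean": grp["soi"].mean(),
            "soi_sd": grp["soi"].std(ddof=1) if n > 1 else 0.0,
            "soi_min": grp["soi"].min(),
            "soi_max": grp["soi"].max(),
            "rel_vol_err_mean": grp["rel_vol_err_percent"].mean(),
            "rel_vol_err_sd": grp["rel_vol_err_percent"].std(ddof=1) if n > 1 else 0.0,
            "ce_mean": grp["ce_percent"].mean(),
            "ce_sd": grp["ce_percent"].std(ddof=1) if n > 1 else 0.0,
            "seg_volume_mean_cm3": grp["seg_volume_cm3"].mean(),
            "ref_volume_mean_cm3": grp["ref_volume_cm3"].mean(),
        }
        if n >= 2:
            tt = paired_ttest(grp["seg_volume_cm3"].to_numpy(), grp["ref_volume_cm3"].to_numpy())
            entry["volume_p_value"] = tt.p
        else:
            entry["volume_p_value"] = np.nan
        rows.append(entry)
    return pd.DataFrame(rows).set_index("method")
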