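"""Imputation accuracy and its stratification by LD and MAF.

Accuracy is the per-marker Pearson correlation, over that marker's masked
cells, between the true calls and the imputed dosages; markers whose truth
or dosage is constant yield an undefined correlation and are excluded from
summaries with an explicit count (a constant column carries no
discriminative information, and silently scoring it 0 would bias scenario
comparisons).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .panel import MISSING, ArrayDesign, GeneticMap
from .masking import MaskedPanel, MaskState
from .impute import ImputedPanel

__all__ = [
    "pairwise_r2", "per_marker_accuracy", "max_ld_to_typed",
    "stratify_accuracy", "summarize_accuracy",
    "DEFAULT_MAF_CLASSES", "DEFAULT_LD_BINS",
]

DEFAULT_MAF_CLASSES = (0.0, 0.05, 0.2, 0.5)
DEFAULT_LD_BINS = (0.0, 0.25, 0.5, 0.75, 1.0)


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """LD r² between two biallelic loci on inbred (phased) lines.

    r² = D² / (p(A) p(a) p(B) p(b)) with D = p(AB) − p(A)p(B), haplotype
    frequencies counted directly. Lines missing at either locus are
    dropped pairwise; a locus monomorphic after deletion gives NaN.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    keep = (x != MISSING) & (y != MISSING)
    x, y = x[keep].astype(float), y[keep].astype(float)
    if x.size == 0:
        return float("nan")
    pA, pB = x.mean(), y.mean()
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom == 0:
        return float("nan")
    D = (x * y).mean() - pA * pB
    return float(D * D / denom)


def _true_calls(masked: MaskedPanel) -> np.ndarray:
    """Reconstruct pre-masking calls (MISSING only where originally missing)."""
    return np.where(masked.mask == MaskState.MASKED, masked.truth,
                    np.where(masked.mask == MaskState.OBSERVED,
                             masked.panel.calls, MISSING)).astype(np.int8)


def per_marker_accuracy(masked: MaskedPanel, imputed: ImputedPanel,
                        gmap: Optional[GeneticMap] = None,
                        design: Optional[ArrayDesign] = None,
                        window_cm: float = 5.0) -> pd.DataFrame:
    """One row per marker with >=1 masked cell: cor, n_eval, maf[, max_ld].

    ``cor`` is NaN (undefined) when the truth or the dosage is constant
    over the marker's masked cells. ``maf`` is the minor allele frequency
    of the true (pre-masking) column. When a map and array design are
    given, ``max_ld`` holds the maximum r² to a low-density marker within
    ``window_cm`` (see :func:`max_ld_to_typed`).
    """
    truth_full = _true_calls(masked)
    is_masked = masked.mask == MaskState.MASKED
    rows = []
    for j in np.flatnonzero(is_masked.any(axis=0)):
        sel = is_masked[:, j]
        t = masked.truth[sel, j].astype(float)
        d = imputed.dosages[sel, j]
        if t.std() == 0 or d.std() == 0:
            cor = float("nan")
        else:
            cor = float(np.corrcoef(t, d)[0, 1])
        col = truth_full[:, j]
        p = col[col != MISSING].mean() if (col != MISSING).any() else np.nan
        rows.append({"marker_id": masked.panel.marker_ids[j], "cor": cor,
                     "n_eval": int(sel.sum()), "maf": float(min(p, 1 - p))})
    rec = pd.DataFrame(rows)
    if gmap is not None and design is not None and len(rec):
        rec["max_ld"] = [
            max_ld_to_typed(mid, masked, design, gmap, window_cm)
            for mid in rec["marker_id"]
        ]
    return rec


def summarize_accuracy(records: pd.DataFrame) -> dict:
    """Mean accuracy over defined records plus the undefined count."""
    if len(records) == 0:
        return {"mean_cor": float("nan"), "n_defined": 0, "n_undefined": 0}
    defined = records["cor"].dropna()
    return {"mean_cor": float(defined.mean()) if len(defined) else float("nan"),
            "n_defined": int(len(defined)),
            "n_undefined": int(records["cor"].isna().sum())}


def max_ld_to_typed(marker_id: str, masked: MaskedPanel, design: ArrayDesign,
                    gmap: GeneticMap, window_cm: float = 5.0) -> float:
    """Max r² between a marker's true column and any nearby typed marker.

    Candidates are low-density-array markers within +/- ``window_cm`` on
    the same chromosome; NaN when no pair is evaluable.
    """
    truth_full = _true_calls(masked)
    j = gmap.index_of(marker_id)
    low = design.low_mask(gmap.marker_ids)
    near = ((gmap.chromosome == gmap.chromosome[j])
            & (np.abs(gmap.position_cm - gmap.position_cm[j]) <= window_cm)
            & low & (np.arange(len(gmap)) != j))
    best = float("nan")
    for k in np.flatnonzero(near):
        r2 = pairwise_r2(truth_full[:, j], truth_full[:, k])
        if not np.isnan(r2) and not (best >= r2):
            best = r2
    return best


def stratify_accuracy(records: pd.DataFrame,
                      ld_bins=DEFAULT_LD_BINS,
                      maf_classes=DEFAULT_MAF_CLASSES
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean/SD/CV/count of accuracy in LD-bin x MAF-class cells.

    Returns the table grouped by LD bin within MAF class and the
    transposed view (MAF class within LD bin). Empty cells carry count 0
    and NaN statistics.
    """
    if "max_ld" not in records:
        raise ValueError("records lack max_ld; pass a map and design "
                         "to per_marker_accuracy")
    rec = records.copy()
    rec["ld_bin"] = pd.cut(rec["max_ld"], bins=list(ld_bins), include_lowest=True)
    rec["maf_class"] = pd.cut(rec["maf"], bins=list(maf_classes), include_lowest=True)

    def _agg(keys):
        g = rec.groupby(keys, observed=False)["cor"]
        out = g.agg(mean="mean", sd="std", n="count")
        out["cv"] = out["sd"] / out["mean"].abs()
        return out.reset_index()

    return _agg(["maf_class", "ld_bin"]), _agg(["ld_bin", "maf_class"])
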