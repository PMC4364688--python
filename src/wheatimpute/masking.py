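"""Masking designs that create the imputation scenarios.

Two designs are supported:

* ``LOW2HIGH`` — a nested-array design: lines are split into a reference
  population (typed on the full high-density array) and a test population
  (typed only on the low-density subset); for test lines every
  high-minus-low marker is masked.
* ``GBS_LIKE`` — random depletion: for every line an exact fraction of
  marker cells is masked uniformly at random, mimicking the scattered
  missingness of genotyping-by-sequencing.

Cells that were already missing before masking are tracked separately
(``ORIG_MISSING``) and are never evaluation targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Optional

import numpy as np
import pandas as pd

from .panel import MISSING, ArrayDesign, GenotypePanel

__all__ = [
    "MaskState", "ScenarioSpec", "MaskedPanel",
    "mask_low_to_high", "mask_gbs_like", "expected_missing_rate",
    "CANONICAL_REF_SIZES", "CANONICAL_MISSING_RATES",
]

#: the canonical scenario grid: reference sizes and the GBS missing-value
#: levels that correspond to them for a 371-line, 9,926/8,353-marker design
CANONICAL_REF_SIZES = (50, 100, 200, 300)
CANONICAL_MISSING_RATES = (0.728, 0.615, 0.388, 0.161)


class MaskState(IntEnum):
    OBSERVED = 0
    MASKED = 1
    ORIG_MISSING = 2


@dataclass(frozen=True)
class ScenarioSpec:
    kind: str                           # "low2high" | "gbs"
    ref_size: Optional[int] = None
    missing_rate: Optional[float] = None
    replicate_index: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("low2high", "gbs"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "low2high" and self.ref_size is None:
            raise ValueError("low2high scenario needs ref_size")
        if self.kind == "gbs" and not (self.missing_rate and 0 < self.missing_rate < 1):
            raise ValueError("gbs scenario needs missing_rate in (0, 1)")


@dataclass
class MaskedPanel:
    """A genotype panel with scenario-masked cells and their ground truth.

    ``mask`` holds a :class:`MaskState` per cell. ``truth`` carries the
    pre-masking calls on MASKED cells only (MISSING elsewhere).
    """

    panel: GenotypePanel
    mask: np.ndarray                    # int8, MaskState codes
    truth: np.ndarray                   # int8, defined where mask == MASKED
    spec: ScenarioSpec
    reference_lines: Optional[np.ndarray] = None
    test_lines: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.mask.shape != self.panel.calls.shape:
            raise ValueError("mask shape mismatch")
        masked = self.mask == MaskState.MASKED
        if np.any(self.panel.calls[masked] != MISSING):
            raise ValueError("masked cells must be MISSING in the panel")
        if np.any(self.truth[masked] == MISSING):
            raise ValueError("truth undefined on a masked cell")
        if np.any(self.truth[~masked] != MISSING):
            raise ValueError("truth must be defined exactly on masked cells")

    @property
    def masked_fraction(self) -> float:
        return float(np.mean(self.mask == MaskState.MASKED))

    def write_tsv(self, prefix: str) -> None:
        """Serialize as <prefix>.geno.tsv + <prefix>.mask.tsv (long format)."""
        self.panel.write_tsv(f"{prefix}.geno.tsv")
        rows = np.flatnonzero((self.mask != MaskState.OBSERVED).any(axis=1))
        recs = []
        for i in rows:
            for j in np.flatnonzero(self.mask[i] != MaskState.OBSERVED):
                recs.append((self.panel.line_ids[i], self.panel.marker_ids[j],
                             MaskState(self.mask[i, j]).name,
                             self.truth[i, j] if self.mask[i, j] == MaskState.MASKED else ""))
        pd.DataFrame(recs, columns=["line_id", "marker_id", "state", "truth"]) \
            .to_csv(f"{prefix}.mask.tsv", sep="\t", index=False)


def _base_mask(panel: GenotypePanel) -> np.ndarray:
    mask = np.full(panel.calls.shape, MaskState.OBSERVED, dtype=np.int8)
    mask[panel.calls == MISSING] = MaskState.ORIG_MISSING
    return mask


def _finalize(panel: GenotypePanel, mask: np.ndarray, spec: ScenarioSpec,
              ref=None, test=None) -> MaskedPanel:
    masked = mask == MaskState.MASKED
    truth = np.where(masked, panel.calls, MISSING).astype(np.int8)
    new_calls = panel.calls.copy()
    new_calls[masked] = MISSING
    out = GenotypePanel(panel.line_ids.copy(), panel.marker_ids.copy(), new_calls)
    return MaskedPanel(out, mask, truth, spec, ref, test)


def mask_low_to_high(panel: GenotypePanel, design: ArrayDesign,
                     ref_size: int, seed: int = 0,
                     replicate_index: int = 1) -> MaskedPanel:
    """Mask all impute-set markers for a random test population."""
    if not 0 < ref_size < panel.n_lines:
        raise ValueError("ref_size must lie strictly between 0 and n_lines")
    if set(design.high_set) != set(panel.marker_ids):
        raise ValueError("array design does not match panel markers")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(panel.n_lines)
    ref_idx, test_idx = np.sort(perm[:ref_size]), np.sort(perm[ref_size:])
    mask = _base_mask(panel)
    impute_cols = ~design.low_mask(panel.marker_ids)
    cells = np.ix_(test_idx, np.flatnonzero(impute_cols))
    sub = mask[cells]
    sub[sub == MaskState.OBSERVED] = MaskState.MASKED
    mask[cells] = sub
    spec = ScenarioSpec("low2high", ref_size=ref_size, seed=seed,
                        replicate_index=replicate_index)
    return _finalize(panel, mask, spec,
                     ref=panel.line_ids[ref_idx], test=panel.line_ids[test_idx])


def mask_gbs_like(panel: GenotypePanel, missing_rate: float, seed: int = 0,
                  replicate_index: int = 1) -> MaskedPanel:
    """Mask an exact per-line count of random marker cells."""
    if not 0 < missing_rate < 1:
        raise ValueError("missing_rate must lie in (0, 1)")
    k = int(round(missing_rate * panel.n_markers))
    if k >= panel.n_markers:
        raise ValueError("missing_rate would mask every marker of a line")
    rng = np.random.default_rng(seed)
    mask = _base_mask(panel)
    for i in range(panel.n_lines):
        cols = rng.choice(panel.n_markers, size=k, replace=False)
        row = mask[i, cols]
        row[row == MaskState.OBSERVED] = MaskState.MASKED
        mask[i, cols] = row
    spec = ScenarioSpec("gbs", missing_rate=missing_rate, seed=seed,
                        replicate_index=replicate_index)
    return _finalize(panel, mask, spec)


def expected_missing_rate(n_lines: int, ref_size: int,
                          n_high: int, n_impute: int) -> float:
    """Overall missing fraction induced by a nested-array split.

    ((n_lines - ref_size)/n_lines) * (n_impute/n_high); e.g. the canonical
    371-line, 9,926/8,353-marker design gives 72.8/61.5/38.8/16.1% for
    reference sizes 50/100/200/300.
    """
    if min(n_lines, n_high, n_impute, ref_size) <= 0:
        raise ValueError("all sizes must be positive")
    if ref_size > n_lines or n_impute >= n_high:
        raise ValueError("ref_size <= n_lines and n_impute < n_high required")
    return (n_lines - ref_size) / n_lines * (n_impute / n_high)
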