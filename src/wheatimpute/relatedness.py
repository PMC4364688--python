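"""Rogers' distance, distance-matrix correlation and the Mantel test.

Rogers' distance between two individuals is the per-locus Euclidean
allele-frequency distance averaged over loci,
RD = (1/m) sum_i sqrt(0.5 * sum_j (p_ij - q_ij)^2).  For fully inbred
lines carrying 0/1 calls each locus term is 1 exactly when the calls
differ, so RD reduces to the proportion of differing loci (normalized
Hamming distance) and is linearly related to the coefficient of
co-ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .panel import MISSING, ArrayDesign, GenotypePanel

__all__ = [
    "DistanceMatrix", "MantelResult", "rogers_distance",
    "matrix_correlation", "mantel_test", "rd_benchmark", "rogers_locus_term",
]


@dataclass
class DistanceMatrix:
    line_ids: np.ndarray
    values: np.ndarray                  # symmetric, zero diagonal, in [0, 1]
    n_loci: np.ndarray                  # per-pair evaluated-locus counts

    def __post_init__(self):
        v = self.values
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("Rogers' distances lie in [0, 1]")

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(len(self.values), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "line_id"
        df.to_csv(path, sep="\t")


@dataclass(frozen=True)
class MantelResult:
    correlation: float
    n_permutations: int
    p_value: float


def rogers_locus_term(p: np.ndarray, q: np.ndarray) -> float:
    """Single-locus RD term for general allele-frequency vectors."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    return float(np.sqrt(0.5 * np.sum((p - q) ** 2)))


def _call_matrix(source, marker_subset=None) -> tuple[np.ndarray, np.ndarray]:
    """Extract (line_ids, int8 call matrix); dosages are rounded at 0.5."""
    if isinstance(source, GenotypePanel):
        lids, calls = source.line_ids, source.calls
        mids = source.marker_ids
    else:
        lids, calls, mids = source  # (line_ids, matrix, marker_ids)
    calls = np.asarray(calls)
    if calls.dtype.kind == "f":
        out = np.where(np.isnan(calls), MISSING, (calls >= 0.5)).astype(np.int8)
    else:
        out = calls.astype(np.int8)
    if marker_subset is not None:
        keep = pd.Index(mids).get_indexer(np.asarray(marker_subset, dtype=object))
        if np.any(keep < 0):
            raise ValueError("marker_subset contains unknown markers")
        out = out[:, keep]
    return np.asarray(lids, dtype=object), out


def rogers_distance(source, marker_subset=None,
                    pairwise_complete: bool = False) -> DistanceMatrix:
    """Rogers' distance matrix over lines.

    ``source`` is a :class:`GenotypePanel` or a ``(line_ids, matrix,
    marker_ids)`` triple; float matrices (imputed dosages) are rounded at
    0.5 to allele calls first. With ``pairwise_complete``, loci missing in
    either member of a pair are dropped for that pair and the locus count
    m is pair-specific; a pair with no evaluable locus is an error.
    """
    lids, X = _call_matrix(source, marker_subset)
    obs = (X != MISSING).astype(float)
    if not pairwise_complete and not obs.all():
        raise ValueError("missing calls present; use pairwise_complete=True")
    P = ((X == 1) & (X != MISSING)).astype(float)
    both = obs @ obs.T
    if np.any(both == 0):
        i, j = np.argwhere(both == 0)[0]
        raise ValueError(f"lines {lids[i]!r} and {lids[j]!r} share no observed locus")
    diff = P @ obs.T + obs @ P.T - 2 * (P @ P.T)
    rd = diff / both
    np.fill_diagonal(rd, 0.0)
    rd = np.clip((rd + rd.T) / 2, 0.0, 1.0)          # symmetrize round-off
    return DistanceMatrix(lids, rd, both.astype(np.int64))


def matrix_correlation(A: DistanceMatrix, B: DistanceMatrix) -> float:
    """Pearson correlation over the strict upper triangles."""
    if len(A.line_ids) != len(B.line_ids) or np.any(A.line_ids != B.line_ids):
        raise ValueError("distance matrices are over different lines")
    a, b = A.upper(), B.upper()
    if a.std() == 0 or b.std() == 0:     # constant distances carry no signal
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def mantel_test(A: DistanceMatrix, B: DistanceMatrix,
                n_perm: int = 999, seed: int = 0) -> MantelResult:
    """One-sided (greater) Mantel permutation test.

    p = (#{permuted cor >= observed} + 1) / (n_perm + 1), permuting line
    labels of B (simultaneous row/column permutation).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    obs = matrix_correlation(A, B)
    rng = np.random.default_rng(seed)
    a = A.upper()
    a_c = a - a.mean()
    a_ss = np.sqrt((a_c ** 2).sum())
    iu = np.triu_indices(len(A.values), k=1)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(B.values))
        b = B.values[np.ix_(perm, perm)][iu]
        b_c = b - b.mean()
        r = (a_c @ b_c) / (a_ss * np.sqrt((b_c ** 2).sum()))
        if r >= obs - 1e-12:
            count += 1
    return MantelResult(obs, n_perm, (count + 1) / (n_perm + 1))


def rd_benchmark(panel: GenotypePanel, design: ArrayDesign, masked,
                 imputed_sets: dict) -> pd.DataFrame:
    """RD-matrix correlations against the truth for a masking scenario.

    Nested-array (low2high) scenario: distances are computed among test
    lines over the impute-set markers; the printed benchmark analogue is
    the correlation between RD from the low-density subset and RD from
    the full array. GBS scenario: distances over all lines and markers,
    with the non-imputed benchmark using pairwise-complete deletion.
    """
    rows = []
    if masked.spec.kind == "low2high":
        tmask = np.isin(panel.line_ids, masked.test_lines)
        sub = lambda X: (panel.line_ids[tmask], X[tmask], panel.marker_ids)
        truth_rd = rogers_distance(sub(panel.calls), design.impute_set)
        bench = matrix_correlation(
            rogers_distance(sub(panel.calls), design.low_set),
            rogers_distance(sub(panel.calls), design.high_set))
        rows.append({"data_set": "low_density_benchmark", "correlation": bench})
        for name, imp in imputed_sets.items():
            rd = rogers_distance(sub(imp.dosages.astype(float)), design.impute_set)
            rows.append({"data_set": name,
                         "correlation": matrix_correlation(rd, truth_rd)})
    else:
        truth_rd = rogers_distance(panel)
        non_imp = rogers_distance(masked.panel, pairwise_complete=True)
        rows.append({"data_set": "non_imputed_pairwise_complete",
                     "correlation": matrix_correlation(non_imp, truth_rd)})
        for name, imp in imputed_sets.items():
            rd = rogers_distance((panel.line_ids, imp.dosages.astype(float),
                                  panel.marker_ids))
            rows.append({"data_set": name,
                         "correlation": matrix_correlation(rd, truth_rd)})
    return pd.DataFrame(rows)
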