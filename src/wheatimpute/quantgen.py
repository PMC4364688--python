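"""Phenotype simulation, genomic prediction and the mixed-model scan.

Phenotypes follow the additive model y = g + e with heritability
h² = var(g)/var(y) (default 0.91).  Under the polygenic architecture every
segregating marker contributes equally to the genetic variance; the QTL
architecture places a fraction (default 10%) of the genetic variance on
one focal marker with MAF > 0.3 and spreads the remainder equally over
all other markers.  Because markers are in LD, per-marker contributions
are defined marginally and the summed genetic value is rescaled so that
the realized sample variance of g equals sigma²_G exactly — this makes h²
and the QTL share hold by construction.

Genomic prediction uses the standard single-variance-component mixed
model (RR-BLUP on marker effects; equivalently GBLUP on G = WW'/c), with
the variance ratio estimated by REML via a profile likelihood on the
eigendecomposition of the relationship matrix.  The association scan
tests each marker as a fixed effect in y = mu + alpha*m + Xg + e with
g ~ N(0, 2K sigma²_G), K = 1 - RD; the variance ratio is estimated once
under the null and reused for every marker (the standard
population-parameters-previously-determined approximation), and
significance uses the Wald F statistic on F(1, n-2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .panel import MISSING, ArrayDesign, GeneticMap, GenotypePanel
from .evaluate import pairwise_r2

__all__ = [
    "PhenotypeSim", "PredictionResult", "ScanResult",
    "simulate_polygenic_phenotype", "simulate_qtl_phenotype",
    "build_grm", "fit_rrblup", "predict_rrblup", "fit_gblup", "predict_gblup",
    "mixed_model_scan", "detection_frequency", "power_study",
    "kinship_from_rd", "max_ld_to_low",
]


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeSim:
    y: np.ndarray
    g_true: np.ndarray
    beta: np.ndarray
    h2: float
    sigma2_g: float
    sigma2_e: float
    seed: int
    qtl_marker: Optional[str] = None
    qtl_var_fraction: Optional[float] = None
    qtl_component: Optional[np.ndarray] = None

    @property
    def realized_h2(self) -> float:
        return float(np.var(self.g_true, ddof=1) / np.var(self.y, ddof=1))

    @property
    def realized_qtl_fraction(self) -> Optional[float]:
        if self.qtl_component is None:
            return None
        return float(np.var(self.qtl_component, ddof=1)
                     / np.var(self.g_true, ddof=1))

    def to_frame(self, line_ids) -> pd.DataFrame:
        return pd.DataFrame({"line_id": line_ids, "y": self.y, "g_true": self.g_true})


def _marker_variances(calls: np.ndarray) -> np.ndarray:
    return calls.var(axis=0, ddof=1)


def simulate_polygenic_phenotype(panel: GenotypePanel, h2: float = 0.91,
                                 sigma2_g: float = 1.0, seed: int = 0
                                 ) -> PhenotypeSim:
    """Equal per-marker contributions to the genetic variance.

    beta_i = s_i sqrt(sigma²_G / (m v_i)) with random sign s_i and v_i the
    sample variance of marker i (monomorphic markers get beta = 0 and do
    not count toward m); g is centered and rescaled to sample variance
    sigma²_G exactly; e ~ N(0, sigma²_G (1-h²)/h²).
    """
    if not 0 < h2 <= 1:
        raise ValueError("h2 must lie in (0, 1]")
    if np.any(panel.calls == MISSING):
        raise ValueError("phenotype simulation needs a complete panel")
    rng = np.random.default_rng(seed)
    X = panel.calls.astype(float)
    v = _marker_variances(X)
    seg = v > 0
    m_eff = int(seg.sum())
    if m_eff < 2:
        raise ValueError("need at least two segregating markers")
    beta = np.zeros(panel.n_markers)
    signs = rng.choice((-1.0, 1.0), size=m_eff)
    beta[seg] = signs * np.sqrt(sigma2_g / (m_eff * v[seg]))
    g = X @ beta
    g -= g.mean()
    g *= np.sqrt(sigma2_g / np.var(g, ddof=1))
    sigma2_e = sigma2_g * (1 - h2) / h2
    e = rng.normal(0.0, np.sqrt(sigma2_e), size=panel.n_lines)
    return PhenotypeSim(g + e, g, beta, h2, sigma2_g, sigma2_e, seed)


def max_ld_to_low(panel: GenotypePanel, gmap: GeneticMap, design: ArrayDesign,
                  j: int, window_cm: float = 5.0) -> float:
    """Max r² between marker index j and low-set markers within a window."""
    low = design.low_mask(gmap.marker_ids)
    near = ((gmap.chromosome == gmap.chromosome[j])
            & (np.abs(gmap.position_cm - gmap.position_cm[j]) <= window_cm)
            & low & (np.arange(len(gmap)) != j))
    best = float("nan")
    for k in np.flatnonzero(near):
        r2 = pairwise_r2(panel.calls[:, j], panel.calls[:, k])
        if not np.isnan(r2) and not (best >= r2):
            best = r2
    return best


def simulate_qtl_phenotype(panel: GenotypePanel, h2: float = 0.91,
                           qtl_var_fraction: float = 0.10,
                           sigma2_g: float = 1.0, seed: int = 0,
                           maf_min: float = 0.3,
                           design: Optional[ArrayDesign] = None,
                           gmap: Optional[GeneticMap] = None,
                           target_ld: Optional[float] = None,
                           ld_tol: float = 0.05,
                           window_cm: float = 5.0,
                           qtl_marker: Optional[str] = None) -> PhenotypeSim:
    """One focal QTL plus an equal-contribution polygenic background.

    The QTL is drawn uniformly among markers with MAF > ``maf_min``; when
    ``target_ld`` is given (with a map and array design), candidates are
    further restricted to impute-set markers whose maximum r² to a nearby
    low-density marker lies within ``ld_tol`` of the target — the design
    used to contrast detection power across LD classes.
    """
    if not 0 < qtl_var_fraction <= 1:
        raise ValueError("qtl_var_fraction must lie in (0, 1]")
    if np.any(panel.calls == MISSING):
        raise ValueError("phenotype simulation needs a complete panel")
    rng = np.random.default_rng(seed)
    X = panel.calls.astype(float)
    v = _marker_variances(X)
    maf = panel.maf()
    if qtl_marker is not None:           # caller pins the focal marker
        cand = np.array([list(panel.marker_ids).index(qtl_marker)])
        if v[cand[0]] == 0:
            raise ValueError(f"QTL marker {qtl_marker!r} is monomorphic")
    elif target_ld is not None:
        if design is None or gmap is None:
            raise ValueError("target_ld selection needs design and gmap")
        cand = np.flatnonzero((maf > maf_min) & (v > 0))
        in_impute = ~design.low_mask(panel.marker_ids)
        cand = cand[in_impute[cand]]
        lds = np.array([max_ld_to_low(panel, gmap, design, j, window_cm)
                        for j in cand])
        ok = np.abs(lds - target_ld) <= ld_tol
        if not ok.any():
            raise ValueError(
                f"no QTL candidate with MAF>{maf_min} near LD {target_ld}; "
                f"available LD values: {np.round(np.sort(lds[~np.isnan(lds)]), 3)}")
        cand = cand[ok]
    else:
        cand = np.flatnonzero((maf > maf_min) & (v > 0))
    if cand.size == 0:
        raise ValueError(f"no marker with MAF > {maf_min}")
    q = int(rng.choice(cand))

    beta = np.zeros(panel.n_markers)
    beta[q] = rng.choice((-1.0, 1.0)) * np.sqrt(qtl_var_fraction * sigma2_g / v[q])
    seg = (v > 0) & (np.arange(panel.n_markers) != q)
    m_eff = int(seg.sum())
    signs = rng.choice((-1.0, 1.0), size=m_eff)
    beta[seg] = signs * np.sqrt((1 - qtl_var_fraction) * sigma2_g / (m_eff * v[seg]))

    g = X @ beta
    g -= g.mean()
    scale = np.sqrt(sigma2_g / np.var(g, ddof=1))
    g *= scale
    qtl_comp = (X[:, q] - X[:, q].mean()) * beta[q] * scale
    sigma2_e = sigma2_g * (1 - h2) / h2
    e = rng.normal(0.0, np.sqrt(sigma2_e), size=panel.n_lines)
    return PhenotypeSim(g + e, g, beta * scale, h2, sigma2_g, sigma2_e, seed,
                        qtl_marker=str(panel.marker_ids[q]),
                        qtl_var_fraction=qtl_var_fraction,
                        qtl_component=qtl_comp)


# ---------------------------------------------------------------------------
# genomic relationship matrix and REML machinery
# ---------------------------------------------------------------------------

def build_grm(calls: np.ndarray, pairwise_complete: bool = False) -> np.ndarray:
    """G = WW'/c with W column-centered calls and c the summed marker variance.

    With ``pairwise_complete`` each entry is computed over the markers
    observed in both lines of the pair and normalized by that pair's
    summed marker variance — the paper-style handling of non-imputed
    GBS data.
    """
    X = np.asarray(calls, dtype=float)
    X = np.where(X == MISSING, np.nan, X)
    obs = np.isfinite(X)
    mu = np.nanmean(X, axis=0)
    v = np.nanvar(X, axis=0)
    W = np.where(obs, X - mu, 0.0)
    if not pairwise_complete:
        if not obs.all():
            raise ValueError("missing calls present; use pairwise_complete=True")
        return (W @ W.T) / v.sum()
    O = obs.astype(float)
    num = W @ W.T
    den = O @ (O * v[None, :].repeat(len(X), 0)).T  # sum of v over shared markers
    if np.any(den == 0):
        raise ValueError("a line pair shares no observed marker")
    return num / den


def _reml_ratio(y: np.ndarray, X: np.ndarray, eigvals: np.ndarray,
                U: np.ndarray) -> tuple[float, float, float]:
    """Profile REML of y = Xb + u + e, u ~ N(0, s2g H), e ~ N(0, s2e I).

    H is given by its eigendecomposition (eigvals, U). Returns
    (delta, s2g, s2e) with delta = s2e/s2g, found by bounded search on
    log10(delta).
    """
    n, q = X.shape
    yt = U.T @ y
    Xt = U.T @ X

    def neg_restricted_ll(log10_delta: float) -> float:
        delta = 10.0 ** log10_delta
        w = eigvals + delta
        Xw = Xt / w[:, None]
        XtWX = Xt.T @ Xw
        b = np.linalg.solve(XtWX, Xw.T @ yt)
        r = yt - Xt @ b
        rss = float(r @ (r / w))
        s2g = rss / (n - q)
        ll = -0.5 * ((n - q) * np.log(s2g) + np.log(w).sum()
                     + np.linalg.slogdet(XtWX)[1] + (n - q))
        return -ll

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(-6.0, 6.0),
                                   method="bounded",
                                   options={"xatol": 1e-6})
    delta = float(10.0 ** res.x)
    w = eigvals + delta
    Xw = Xt / w[:, None]
    b = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
    r = yt - Xt @ b
    s2g = float(r @ (r / w)) / (n - X.shape[1])
    return delta, s2g, delta * s2g


def _psd_eigh(H: np.ndarray, jitter: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition with negative eigenvalues clipped to ``jitter``.

    Pairwise-complete relationship matrices are not guaranteed PSD;
    moderate negative eigenvalues are projected away (nearest-PSD
    clipping). A matrix whose negative part rivals its leading eigenvalue
    is rejected as not a plausible kinship.
    """
    vals, vecs = np.linalg.eigh((H + H.T) / 2)
    if vals.min() < -0.25 * vals.max():
        raise ValueError("relationship matrix far from positive semi-definite")
    return np.maximum(vals, jitter), vecs


# ---------------------------------------------------------------------------
# RR-BLUP / GBLUP
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    predicted: np.ndarray
    model: str
    accuracy: Optional[float] = None
    train_lines: Optional[np.ndarray] = None

    def score(self, g_true: np.ndarray) -> float:
        self.accuracy = float(np.corrcoef(self.predicted, g_true)[0, 1])
        return self.accuracy


@dataclass
class _RRBLUPModel:
    u: np.ndarray                       # marker effects
    mu: float
    centers: np.ndarray                 # training marker means
    delta: float
    s2g: float


def fit_rrblup(train_y: np.ndarray, train_markers: np.ndarray) -> _RRBLUPModel:
    """Ridge-regression BLUP of marker effects, shrinkage from REML.

    Solved through the equivalent relationship-matrix formulation:
    G = WW'/c with W centered by the training marker means; marker
    effects u = W' V^{-1} (y - mu) * s2g / c.
    """
    y = np.asarray(train_y, float)
    M = np.asarray(train_markers, float)
    if len(y) < 10:
        raise ValueError("need at least 10 training lines")
    centers = M.mean(axis=0)
    W = M - centers
    c = M.var(axis=0).sum()
    if c == 0:
        raise ValueError("all training markers monomorphic")
    G = (W @ W.T) / c
    vals, U = _psd_eigh(G)
    X = np.ones((len(y), 1))
    delta, s2g, _ = _reml_ratio(y, X, vals, U)
    Vinv = U @ np.diag(1.0 / (vals + delta)) @ U.T   # V / s2g inverted
    ones = np.ones(len(y))
    mu = float((ones @ Vinv @ y) / (ones @ Vinv @ ones))
    u = W.T @ (Vinv @ (y - mu)) / c
    return _RRBLUPModel(u, mu, centers, delta, s2g)


def predict_rrblup(model: _RRBLUPModel, markers: np.ndarray) -> PredictionResult:
    W = np.asarray(markers, float) - model.centers
    return PredictionResult(W @ model.u, "RRBLUP")


@dataclass
class _GBLUPModel:
    alpha: np.ndarray                   # V^{-1}(y - mu) on training lines
    mu: float
    train_idx: np.ndarray
    delta: float
    s2g: float


def fit_gblup(train_y: np.ndarray, kinship: np.ndarray,
              train_idx: Optional[np.ndarray] = None) -> _GBLUPModel:
    """Single-component GBLUP; ``kinship`` covers all lines to predict."""
    y = np.asarray(train_y, float)
    K = np.asarray(kinship, float)
    if train_idx is None:
        train_idx = np.arange(len(y))
    train_idx = np.asarray(train_idx)
    Ktt = K[np.ix_(train_idx, train_idx)]
    vals, U = _psd_eigh(Ktt)
    X = np.ones((len(y), 1))
    delta, s2g, _ = _reml_ratio(y, X, vals, U)
    Vinv = U @ np.diag(1.0 / (vals + delta)) @ U.T
    ones = np.ones(len(y))
    mu = float((ones @ Vinv @ y) / (ones @ Vinv @ ones))
    return _GBLUPModel(Vinv @ (y - mu), mu, train_idx, delta, s2g)


def predict_gblup(model: _GBLUPModel, kinship_rows: np.ndarray) -> PredictionResult:
    """BLUP of genotypic values; ``kinship_rows`` = K[target, train]."""
    Kx = np.asarray(kinship_rows, float)
    return PredictionResult(Kx @ model.alpha, "GBLUP")


# ---------------------------------------------------------------------------
# mixed-model association scan
# ---------------------------------------------------------------------------

def kinship_from_rd(rd_values: np.ndarray) -> np.ndarray:
    """K = 1 - RD, the kinship used for stratification correction."""
    return 1.0 - np.asarray(rd_values, float)


@dataclass
class ScanResult:
    table: pd.DataFrame                 # marker_id, alpha_hat, wald_F, p
    delta: float
    sigma2_g: float
    sigma2_e: float
    n_skipped: int
    kinship: str = "1-RD"

    def min_p_marker(self) -> str:
        t = self.table.dropna(subset=["p"])
        return str(t.loc[t["p"].idxmin(), "marker_id"])


def _scan_context(kinship: np.ndarray):
    """Eigendecomposition of 2K, reusable across phenotype replicates."""
    return _psd_eigh(2.0 * np.asarray(kinship, float))


def mixed_model_scan(calls_or_dosages: np.ndarray, marker_ids, y: np.ndarray,
                     kinship_rd: np.ndarray,
                     context=None) -> ScanResult:
    """Per-marker fixed-effect Wald-F test under y = mu + alpha m + Xg + e.

    g ~ N(0, 2K sigma²_G) with K = 1 - RD; the variance ratio is REML
    estimated once under the null model and reused for every marker; the
    Wald F = alpha_hat²/var(alpha_hat) is referred to F(1, n-2).
    Monomorphic markers are skipped (NaN row) and counted.
    """
    M = np.asarray(calls_or_dosages, float)
    y = np.asarray(y, float)
    n = len(y)
    vals, U = _scan_context(kinship_rd) if context is None else context
    ones = np.ones((n, 1))
    delta, s2g, s2e = _reml_ratio(y, ones, vals, U)
    w = vals + delta

    yt = U.T @ y
    ot = U.T @ np.ones(n)
    Mt = U.T @ M                                      # (n, m)

    iw = 1.0 / w
    a11 = float((ot * ot * iw).sum())
    a12 = (ot * iw) @ Mt
    a22 = (iw[:, None] * Mt * Mt).sum(axis=0)
    b1 = float((ot * iw) @ yt)
    b2 = (iw[:, None] * Mt).T @ yt
    yy = float((yt * yt * iw).sum())

    det = a11 * a22 - a12 ** 2
    mono = M.std(axis=0) == 0
    det_safe = np.where(det <= 0, np.nan, det)
    beta0 = (a22 * b1 - a12 * b2) / det_safe
    alpha = (a11 * b2 - a12 * b1) / det_safe
    rss = yy - (beta0 * b1 + alpha * b2)
    sigma2 = rss / (n - 2)
    var_alpha = sigma2 * a11 / det_safe
    with np.errstate(invalid="ignore", divide="ignore"):
        F = alpha ** 2 / var_alpha
    F = np.where(mono, np.nan, F)
    p = stats.f.sf(F, 1, n - 2)
    table = pd.DataFrame({"marker_id": np.asarray(marker_ids, dtype=object),
                          "alpha_hat": np.where(mono, np.nan, alpha),
                          "wald_F": F, "p": p})
    return ScanResult(table, delta, s2g, s2e, int(mono.sum()))


def detection_frequency(p_values: list, qtl_positions: list,
                        n_tests: int, alpha: float = 0.05,
                        bonferroni: bool = True) -> float:
    """Fraction of runs where the focal marker is significant.

    ``p_values`` holds one p-vector per run, ``qtl_positions`` the focal
    marker's column index per run; the default policy is Bonferroni:
    threshold alpha / n_tests.
    """
    if len(p_values) == 0:
        raise ValueError("no runs supplied")
    thr = alpha / n_tests if bonferroni else alpha
    hits = sum(1 for p, q in zip(p_values, qtl_positions)
               if np.isfinite(p[q]) and p[q] < thr)
    return hits / len(p_values)


def power_study(panel: GenotypePanel, kinship_rd: np.ndarray,
                n_runs: int = 100, h2: float = 0.91,
                qtl_var_fraction: float = 0.10, maf_min: float = 0.3,
                alpha: float = 0.05, seed: int = 0,
                scan_calls: Optional[np.ndarray] = None,
                test_marker: str = "qtl",
                design: Optional[ArrayDesign] = None,
                gmap: Optional[GeneticMap] = None,
                target_ld: Optional[float] = None,
                ld_tol: float = 0.05) -> dict:
    """Detection frequency of the focal QTL over repeated simulations.

    Phenotypes are re-simulated per run (fresh QTL draw); the scan runs on
    ``scan_calls`` (default: the panel itself). ``test_marker`` selects
    which marker's p-value is scored: the QTL's perfect marker ("qtl") or
    the most closely linked low-density marker ("nearest_low").
    """
    M = panel.calls.astype(float) if scan_calls is None else np.asarray(scan_calls, float)
    ctx = _scan_context(kinship_rd)
    midx = {m: j for j, m in enumerate(panel.marker_ids)}
    pvals, qpos = [], []
    rng = np.random.default_rng(seed)
    for _ in range(n_runs):
        sim = simulate_qtl_phenotype(panel, h2=h2,
                                     qtl_var_fraction=qtl_var_fraction,
                                     seed=int(rng.integers(2**31 - 1)),
                                     maf_min=maf_min, design=design,
                                     gmap=gmap, target_ld=target_ld,
                                     ld_tol=ld_tol)
        scan = mixed_model_scan(M, panel.marker_ids, sim.y, kinship_rd,
                                context=ctx)
        j = midx[sim.qtl_marker]
        if test_marker == "nearest_low":
            if design is None or gmap is None:
                raise ValueError("nearest_low scoring needs design and gmap")
            low = np.flatnonzero(design.low_mask(gmap.marker_ids)
                                 & (gmap.chromosome == gmap.chromosome[j]))
            j = int(low[np.argmin(np.abs(gmap.position_cm[low]
                                         - gmap.position_cm[j]))])
        pvals.append(scan.table["p"].to_numpy())
        qpos.append(j)
    freq = detection_frequency(pvals, qpos, n_tests=M.shape[1], alpha=alpha)
    return {"detection_frequency": freq, "n_runs": n_runs,
            "alpha": alpha, "n_tests": M.shape[1]}
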