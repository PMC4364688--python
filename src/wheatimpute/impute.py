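"""Genotype imputation algorithms.

Four imputers fill MASKED cells with continuous dosages in [0, 1]:

* :func:`impute_freq` — observed allele-frequency baseline.
* :func:`impute_random_forest` — map-independent iterative Random Forest
  regression (missForest-style): markers processed in ascending
  missingness order, 100 trees per marker, sqrt(n-1) candidate predictors
  per split, iterated until the imputed values stop changing.
* :func:`impute_window` — map-dependent shrinking-window haplotype
  matcher: donors sharing a window-consistent haplotype vote for the
  target's masked alleles, long windows counting more.
* :func:`impute_ls_hmm` — map-dependent haploid Li-Stephens copying model:
  a hidden Markov model whose states are reference haplotypes, with
  distance-driven switching and an allele-miscopy rate, solved by the
  forward-backward algorithm.

All imputers leave OBSERVED cells untouched and are deterministic under a
fixed seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, asdict, field

import numpy as np

from .panel import MISSING, GeneticMap
from .masking import MaskedPanel, MaskState

logger = logging.getLogger("wheatimpute")

__all__ = [
    "ImputedPanel", "RFParams", "WindowParams", "HMMParams",
    "impute_freq", "impute_random_forest", "impute_window", "impute_ls_hmm",
    "ls_hmm_posteriors", "IMPUTERS",
]


@dataclass
class ImputedPanel:
    """Continuous dosages on the full lines x markers grid.

    OBSERVED cells carry their original calls; MASKED (and originally
    missing) cells carry imputed dosages in [0, 1].
    """

    dosages: np.ndarray
    imputer_name: str
    params: dict = field(default_factory=dict)
    runtime_s: float = 0.0

    def rounded_calls(self) -> np.ndarray:
        """Hard calls for interop: dosage >= 0.5 -> allele 1."""
        return (self.dosages >= 0.5).astype(np.int8)


@dataclass(frozen=True)
class RFParams:
    n_trees: int = 100
    max_iter: int = 10
    convergence_tol: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1 or self.max_iter < 1:
            raise ValueError("n_trees and max_iter must be >= 1")


@dataclass(frozen=True)
class WindowParams:
    initial_window: int = 64
    shrink_factor: int = 2
    min_window: int = 4
    overlap_fraction: float = 0.5

    def __post_init__(self):
        if not self.initial_window >= self.min_window >= 2:
            raise ValueError("initial_window >= min_window >= 2 required")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.shrink_factor < 2:
            raise ValueError("shrink_factor must be >= 2")


@dataclass(frozen=True)
class HMMParams:
    error_rate: float = 0.01            # allele miscopy probability
    switch_intensity: float = 0.1       # haplotype switches per cM
    min_reference_haplotypes: int = 2
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.error_rate < 0.5:
            raise ValueError("error_rate must lie in (0, 0.5)")
        if self.switch_intensity <= 0:
            raise ValueError("switch_intensity must be positive")


def _observed_freq(masked: MaskedPanel) -> np.ndarray:
    """Allele-1 frequency over OBSERVED cells per marker."""
    obs = masked.mask == MaskState.OBSERVED
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        bad = masked.panel.marker_ids[n_obs == 0][:5]
        raise ValueError(f"markers with zero observed calls: {list(bad)} ...")
    return (np.where(obs, masked.panel.calls, 0).sum(axis=0) / n_obs).astype(float)


def _base_dosages(masked: MaskedPanel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Start dosage grid: observed calls in place, frequency elsewhere."""
    freq = _observed_freq(masked)
    obs = masked.mask == MaskState.OBSERVED
    dos = np.where(obs, masked.panel.calls, freq[None, :]).astype(float)
    return dos, obs, freq


# ---------------------------------------------------------------------------
# allele-frequency baseline
# ---------------------------------------------------------------------------

def impute_freq(masked: MaskedPanel) -> ImputedPanel:
    """Fill every masked cell with the marker's observed allele frequency."""
    t0 = time.perf_counter()
    dos, _, _ = _base_dosages(masked)
    return ImputedPanel(dos, "freq", {}, time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# iterative Random Forest (map-independent)
# ---------------------------------------------------------------------------

def impute_random_forest(masked: MaskedPanel,
                         params: RFParams = RFParams()) -> ImputedPanel:
    """missForest-style iterative Random Forest imputation.

    Missing cells are initialized by Bernoulli draws at the observed
    allele frequency; markers are then revisited in ascending missingness
    order, each regressed on all other markers' current values with an
    ensemble of ``n_trees`` regression trees (sqrt(n-1) candidate
    predictors per split) fitted on the lines observed for that marker.
    Iteration stops when the summed squared change of imputed values
    drops below ``convergence_tol``, starts increasing (the previous
    iteration's values are kept), or ``max_iter`` is reached.
    """
    from sklearn.ensemble import RandomForestRegressor

    t0 = time.perf_counter()
    rng = np.random.default_rng(params.seed)
    dos, obs, freq = _base_dosages(masked)
    miss = ~obs                                     # MASKED + ORIG_MISSING
    if not miss.any():
        return ImputedPanel(dos, "rf", asdict(params), time.perf_counter() - t0)

    # Bernoulli initialization of missing cells at the observed frequency
    dos[miss] = (rng.random(miss.sum()) < np.broadcast_to(freq, dos.shape)[miss]).astype(float)

    order = np.argsort(miss.sum(axis=0), kind="stable")
    order = order[miss.sum(axis=0)[order] > 0]

    best = dos.copy()
    prev_delta = np.inf
    for it in range(params.max_iter):
        before = dos[miss].copy()
        for j in order:
            rows_obs = obs[:, j]
            X_cols = np.delete(np.arange(dos.shape[1]), j)
            try:
                rf = RandomForestRegressor(
                    n_estimators=params.n_trees, max_features="sqrt",
                    random_state=int(rng.integers(2**31 - 1)), n_jobs=1)
                rf.fit(dos[np.ix_(rows_obs, X_cols)], masked.panel.calls[rows_obs, j])
                dos[~rows_obs, j] = rf.predict(dos[np.ix_(~rows_obs, X_cols)])
            except Exception:                        # degenerate fit
                logger.warning("RF fit failed for marker %s; frequency fallback",
                               masked.panel.marker_ids[j])
                dos[~rows_obs, j] = freq[j]
        delta = float(np.sum((dos[miss] - before) ** 2))
        if delta > prev_delta:                       # diverging: keep previous
            dos = best
            break
        best = dos.copy()
        if delta < params.convergence_tol:
            break
        prev_delta = delta

    np.clip(dos, 0.0, 1.0, out=dos)
    dos[obs] = masked.panel.calls[obs]
    return ImputedPanel(dos, "rf", asdict(params), time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# shrinking-window haplotype matcher (map-dependent)
# ---------------------------------------------------------------------------

def _window_spans(n: int, width: int, overlap: float):
    step = max(1, int(round(width * (1 - overlap))))
    starts = list(range(0, max(n - width, 0) + 1, step))
    if not starts or starts[-1] + width < n:
        starts.append(max(n - width, 0))
    for s in starts:
        yield s, min(s + width, n)


def impute_window(masked: MaskedPanel, gmap: GeneticMap,
                  params: WindowParams = WindowParams()) -> ImputedPanel:
    """Sliding-window haplotype-consistency voting.

    Window sizes shrink geometrically from ``initial_window`` to
    ``min_window``. Inside a window, donors are lines fully observed there
    that agree with the target at every observed target position; each
    donor votes its allele into the target's masked cells with weight
    equal to the window size, so long consistent segments (closer common
    ancestry) dominate. Cells that collect no votes fall back to the
    allele-frequency baseline.
    """
    if set(gmap.marker_ids) != set(masked.panel.marker_ids):
        raise ValueError("map does not cover panel markers")
    t0 = time.perf_counter()
    calls = masked.panel.calls
    obs = masked.mask == MaskState.OBSERVED
    need = masked.mask == MaskState.MASKED
    votes1 = np.zeros(calls.shape)
    votes = np.zeros(calls.shape)

    widths = []
    w = params.initial_window
    while w >= params.min_window:
        widths.append(w)
        w //= params.shrink_factor
    if not widths:
        widths = [params.min_window]

    for c, idx in gmap.chromosome_slices().items():
        C, O, N = calls[:, idx], obs[:, idx], need[:, idx]
        for width in widths:
            for s, e in _window_spans(len(idx), width, params.overlap_fraction):
                Cw, Ow, Nw = C[:, s:e], O[:, s:e], N[:, s:e]
                donors = Ow.all(axis=1)
                if not donors.any():
                    continue
                Dw = Cw[donors]
                for t in np.flatnonzero(Nw.any(axis=1)):
                    mism = (Dw != Cw[t][None, :]) & Ow[t][None, :]
                    match = ~mism.any(axis=1)
                    n_match = int(match.sum())
                    if n_match == 0:
                        continue
                    cols = np.flatnonzero(Nw[t])
                    gcols = idx[s + cols]
                    votes1[t, gcols] += width * Dw[match][:, cols].sum(axis=0)
                    votes[t, gcols] += width * n_match

    dos, _, freq = _base_dosages(masked)
    has = (votes > 0) & need
    dos[has] = votes1[has] / votes[has]
    return ImputedPanel(dos, "window", asdict(params), time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# Li-Stephens haploid copying HMM (map-dependent)
# ---------------------------------------------------------------------------

def ls_hmm_posteriors(ref: np.ndarray, target: np.ndarray, pos: np.ndarray,
                      error_rate: float, switch_intensity: float
                      ) -> tuple[np.ndarray, float, float]:
    """Forward-backward posteriors of the haploid copying model.

    Parameters
    ----------
    ref : (K, L) int8
        Reference haplotypes over the chromosome's markers (MISSING allowed;
        missing reference sites emit uninformatively).
    target : (L,) int8
        Target alleles; MISSING cells emit uninformatively.
    pos : (L,) float
        cM positions.

    Returns
    -------
    gamma : (L, K) posterior copying probabilities (rows sum to 1)
    loglik_fwd, loglik_bwd : total log-likelihood from each recursion
        (equal up to round-off; both returned as a numerical check).
    """
    K, L = ref.shape
    eps = error_rate
    # emission matrix (L, K)
    em = np.ones((L, K))
    t_obs = target != MISSING
    r_obs = ref != MISSING
    both = t_obs[None, :] & r_obs                    # (K, L)
    match = both & (ref == target[None, :])
    em_T = np.where(match, 1 - eps, np.where(both, eps, 1.0))
    em = em_T.T                                       # (L, K)

    stay = np.exp(-switch_intensity * np.diff(pos))   # (L-1,)

    fwd = np.empty((L, K))
    scale = np.empty(L)
    f = em[0] / K
    scale[0] = f.sum()
    fwd[0] = f / scale[0]
    for j in range(1, L):
        s = stay[j - 1]
        f = (s * fwd[j - 1] + (1 - s) / K) * em[j]
        scale[j] = f.sum()
        fwd[j] = f / scale[j]
    loglik_fwd = float(np.log(scale).sum())

    bwd = np.empty((L, K))
    b = np.ones(K)
    bwd[-1] = b
    bscale = np.zeros(L)
    for j in range(L - 2, -1, -1):
        s = stay[j]
        eb = em[j + 1] * bwd[j + 1]
        b = s * eb + (1 - s) * eb.mean()
        bscale[j] = b.sum()
        bwd[j] = b / bscale[j]
    # backward total likelihood: sum_k pi_k em0_k b0_k, undoing the scaling
    loglik_bwd = float(np.log((em[0] / K * bwd[0]).sum()) + np.log(bscale[:-1]).sum())

    gamma = fwd * bwd
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, loglik_fwd, loglik_bwd


def impute_ls_hmm(masked: MaskedPanel, gmap: GeneticMap,
                  params: HMMParams = HMMParams()) -> ImputedPanel:
    """Impute by posterior allele dosage under the Li-Stephens model.

    Per chromosome, the reference panel is the set of lines fully observed
    there (in the nested-array scenario, the reference population); when
    no line is fully observed — as under GBS-like depletion — all lines
    other than the target serve as partially observed references, with
    their missing sites emitting uninformatively. The dosage at a masked
    cell is the posterior-weighted allele average over references observed
    at that cell; cells where no weighted reference is observed fall back
    to the allele-frequency baseline.
    """
    if set(gmap.marker_ids) != set(masked.panel.marker_ids):
        raise ValueError("map does not cover panel markers")
    t0 = time.perf_counter()
    calls = masked.panel.calls
    obs = masked.mask == MaskState.OBSERVED
    need = masked.mask == MaskState.MASKED
    dos, _, freq = _base_dosages(masked)

    for c, idx in gmap.chromosome_slices().items():
        pos = gmap.position_cm[idx]
        C, O, N = calls[:, idx], obs[:, idx], need[:, idx]
        full = O.all(axis=1)
        targets = np.flatnonzero(N.any(axis=1))
        use_full = int(full.sum()) >= params.min_reference_haplotypes
        if not use_full and masked.panel.n_lines - 1 < params.min_reference_haplotypes:
            raise ValueError(
                "too few reference haplotypes for the copying model; "
                "use impute_window or impute_freq instead")
        for t in targets:
            if use_full:
                ridx = np.flatnonzero(full & (np.arange(len(full)) != t))
            else:
                ridx = np.flatnonzero(np.arange(len(full)) != t)
            R = C[ridx]
            tgt = np.where(O[t], C[t], MISSING).astype(np.int8)
            gamma, _, _ = ls_hmm_posteriors(R, tgt, pos,
                                            params.error_rate,
                                            params.switch_intensity)
            cols = np.flatnonzero(N[t])
            Rcols = R[:, cols]
            w = gamma[cols] * (Rcols.T != MISSING)    # (n_masked, K)
            tot = w.sum(axis=1)
            num = (w * (Rcols.T == 1)).sum(axis=1)
            d = np.where(tot > 0, num / np.where(tot > 0, tot, 1.0),
                         freq[idx[cols]])
            dos[t, idx[cols]] = d
    return ImputedPanel(dos, "lshmm", asdict(params), time.perf_counter() - t0)


#: registry used by the pipeline and CLI
IMPUTERS = {
    "freq": lambda masked, gmap, params: impute_freq(masked),
    "rf": lambda masked, gmap, params: impute_random_forest(
        masked, params if isinstance(params, RFParams) else RFParams(**(params or {}))),
    "window": lambda masked, gmap, params: impute_window(
        masked, gmap, params if isinstance(params, WindowParams) else WindowParams(**(params or {}))),
    "lshmm": lambda masked, gmap, params: impute_ls_hmm(
        masked, gmap, params if isinstance(params, HMMParams) else HMMParams(**(params or {}))),
}
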