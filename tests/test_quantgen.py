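import numpy as np
import pytest

from wheatimpute import (build_grm, designate_arrays, fit_gblup, fit_rrblup,
                         kinship_from_rd, mixed_model_scan, power_study,
                         predict_gblup, predict_rrblup, rogers_distance,
                         simulate_panel, simulate_polygenic_phenotype,
                         simulate_qtl_phenotype)
from wheatimpute.quantgen import _scan_context, detection_frequency
from wheatimpute.simulate import PanelParams


@pytest.fixture(scope="module")
def qg_panel():
    panel, gmap = simulate_panel(PanelParams(n_lines=150, n_markers=200,
                                             n_chrom=2, map_length_cm=450.0,
                                             seed=21))
    return panel, gmap


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------

def test_polygenic_h2_one_means_no_noise(qg_panel):
    panel, _ = qg_panel
    sim = simulate_polygenic_phenotype(panel, h2=1.0, seed=0)
    np.testing.assert_allclose(sim.y, sim.g_true)
    assert np.var(sim.g_true, ddof=1) == pytest.approx(sim.sigma2_g)


def test_polygenic_h2_recovery_and_determinism(qg_panel):
    panel, _ = qg_panel
    h2s = [simulate_polygenic_phenotype(panel, h2=0.91, seed=s).realized_h2
           for s in range(20)]
    assert np.mean(h2s) == pytest.approx(0.91, abs=0.03)
    a = simulate_polygenic_phenotype(panel, seed=9)
    b = simulate_polygenic_phenotype(panel, seed=9)
    np.testing.assert_array_equal(a.y, b.y)


def test_qtl_fraction_recovery_and_maf_filter(qg_panel):
    panel, _ = qg_panel
    fracs, mafs = [], []
    for s in range(20):
        sim = simulate_qtl_phenotype(panel, seed=s)
        fracs.append(sim.realized_qtl_fraction)
        j = list(panel.marker_ids).index(sim.qtl_marker)
        mafs.append(panel.maf()[j])
    assert np.mean(fracs) == pytest.approx(0.10, abs=0.02)
    assert min(mafs) > 0.3


def test_qtl_fraction_one_makes_g_proportional_to_qtl(qg_panel):
    panel, _ = qg_panel
    sim = simulate_qtl_phenotype(panel, qtl_var_fraction=1.0, seed=3)
    j = list(panel.marker_ids).index(sim.qtl_marker)
    x = panel.calls[:, j].astype(float)
    r = abs(np.corrcoef(sim.g_true, x)[0, 1])
    assert r == pytest.approx(1.0, abs=1e-10)


def test_qtl_target_ld_selection_errors_when_unreachable(qg_panel):
    panel, gmap = qg_panel
    design = designate_arrays(gmap, 1573 / 9926)
    with pytest.raises(ValueError, match="no QTL candidate"):
        simulate_qtl_phenotype(panel, design=design, gmap=gmap,
                               target_ld=0.5, ld_tol=1e-9, seed=0)


# ---------------------------------------------------------------------------
# GRM / prediction
# ---------------------------------------------------------------------------

def test_grm_diagonal_mean_is_one_and_duplicates_match(qg_panel):
    panel, _ = qg_panel
    G = build_grm(panel.calls)
    assert np.diag(G).mean() == pytest.approx(1.0, abs=1e-12)
    dup = np.vstack([panel.calls, panel.calls[:1]])
    G2 = build_grm(dup)
    np.testing.assert_allclose(G2[0], G2[-1], atol=1e-12)


def test_grm_pairwise_complete_is_noop_on_complete_data(qg_panel):
    panel, _ = qg_panel
    G = build_grm(panel.calls)
    G2 = build_grm(panel.calls, pairwise_complete=True)
    np.testing.assert_allclose(G, G2, atol=1e-10)


def test_rrblup_equals_gblup(qg_panel):
    # the stated RR-BLUP/GBLUP equivalence, checked through both routes
    panel, _ = qg_panel
    sim = simulate_polygenic_phenotype(panel, seed=13)
    rng = np.random.default_rng(0)
    tr = np.sort(rng.choice(panel.n_lines, 90, replace=False))
    M = panel.calls.astype(float)
    rr = fit_rrblup(sim.y[tr], M[tr])
    pred_rr = predict_rrblup(rr, M).predicted
    W = M - M[tr].mean(axis=0)
    K = W @ W.T / M[tr].var(axis=0).sum()
    gb = fit_gblup(sim.y[tr], K[np.ix_(tr, tr)])
    pred_gb = predict_gblup(gb, K[:, tr]).predicted
    assert np.max(np.abs(pred_rr - pred_gb)) < 1e-6


def test_gblup_identity_kinship_is_uninformative(qg_panel):
    panel, _ = qg_panel
    sim = simulate_polygenic_phenotype(panel, seed=17)
    n = panel.n_lines
    model = fit_gblup(sim.y, np.eye(n))
    pred = predict_gblup(model, np.eye(n)).predicted
    # in-model BLUP shrinks y toward the mean; on an independent re-draw of
    # genotypic values there is no transferable information
    sim2 = simulate_polygenic_phenotype(panel, seed=18)
    acc = abs(np.corrcoef(pred, sim2.g_true)[0, 1])
    assert acc < 0.25


def test_rrblup_training_fit_beats_any_single_marker(qg_panel):
    panel, _ = qg_panel
    sim = simulate_polygenic_phenotype(panel, seed=23)
    M = panel.calls.astype(float)
    rr = fit_rrblup(sim.y, M)
    pred = predict_rrblup(rr, M).predicted
    fit_cor = np.corrcoef(pred, sim.y)[0, 1]
    Mc = M - M.mean(axis=0)
    sd = Mc.std(axis=0)
    ok = sd > 0
    single = np.abs((Mc[:, ok].T @ (sim.y - sim.y.mean()))
                    / (len(sim.y) * sd[ok] * sim.y.std()))
    assert fit_cor >= single.max() - 1e-9


# ---------------------------------------------------------------------------
# mixed-model scan
# ---------------------------------------------------------------------------

def test_scan_duplicate_marker_identical_statistics(qg_panel):
    panel, _ = qg_panel
    rd = rogers_distance(panel)
    K = kinship_from_rd(rd.values)
    sim = simulate_polygenic_phenotype(panel, seed=29)
    M = panel.calls.astype(float)
    M2 = np.column_stack([M, M[:, 7]])
    mids = list(panel.marker_ids) + ["dup"]
    scan = mixed_model_scan(M2, mids, sim.y, K)
    t = scan.table
    assert t.loc[7, "wald_F"] == pytest.approx(t.iloc[-1]["wald_F"], rel=1e-10)
    assert t.loc[7, "p"] == pytest.approx(t.iloc[-1]["p"], rel=1e-10)


def test_scan_type_one_error_on_null_panels():
    # unstructured panel (high switch rate), pure-noise phenotypes
    panel, _ = simulate_panel(PanelParams(n_lines=150, n_markers=300,
                                          n_chrom=3, map_length_cm=675.0,
                                          mosaic_switch_rate=0.5, seed=31))
    rd = rogers_distance(panel)
    K = kinship_from_rd(rd.values)
    ctx = _scan_context(K)
    rng = np.random.default_rng(37)
    fracs = []
    for _ in range(20):
        y = rng.normal(size=panel.n_lines)
        scan = mixed_model_scan(panel.calls.astype(float), panel.marker_ids,
                                y, K, context=ctx)
        fracs.append((scan.table["p"] < 0.05).mean())
    assert np.mean(fracs) == pytest.approx(0.05, abs=0.02)


def test_scan_qtl_attains_genomewide_minimum_p():
    # needs the full-size panel: when the kinship is estimated from few
    # markers, each marker's own pattern contaminates K (proximal
    # contamination) and the QTL signal is absorbed
    panel, _ = simulate_panel(PanelParams(seed=0))
    rd = rogers_distance(panel)
    K = kinship_from_rd(rd.values)
    ctx = _scan_context(K)
    M = panel.calls.astype(float)
    hits = 0
    for s in range(10):
        sim = simulate_qtl_phenotype(panel, seed=300 + s)
        scan = mixed_model_scan(M, panel.marker_ids, sim.y, K, context=ctx)
        j = list(panel.marker_ids).index(sim.qtl_marker)
        # markers duplicating the QTL column tie its p-value exactly
        hits += bool(np.isclose(scan.table["p"].iloc[j],
                                scan.table["p"].min(), rtol=1e-9))
    assert hits >= 6


def test_detection_frequency_alpha_policy():
    p = [np.array([1e-6, 0.5]), np.array([0.2, 0.5])]
    assert detection_frequency(p, [0, 0], n_tests=2, alpha=1.0,
                               bonferroni=False) == 1.0
    assert detection_frequency(p, [0, 0], n_tests=2, alpha=0.05) == 0.5
    with pytest.raises(ValueError):
        detection_frequency([], [], n_tests=2)


def test_power_study_runs_and_reports(qg_panel):
    panel, _ = qg_panel
    rd = rogers_distance(panel)
    res = power_study(panel, kinship_from_rd(rd.values), n_runs=5, seed=3)
    assert res["n_runs"] == 5 and 0 <= res["detection_frequency"] <= 1


def test_gs_imputed_beats_nonimputed_on_gbs_data(qg_panel):
    # GBS-style depletion: GBLUP on imputed genotypes outperforms GBLUP on
    # the pairwise-complete non-imputed relationship matrix
    from wheatimpute import impute_ls_hmm, mask_gbs_like
    panel, gmap = qg_panel
    for rate in (0.388, 0.615):
        non, imp = [], []
        for rep in range(3):
            mp = mask_gbs_like(panel, rate, seed=70 + rep)
            sim = simulate_polygenic_phenotype(panel, h2=0.91, seed=80 + rep)
            K_nc = build_grm(mp.panel.calls, pairwise_complete=True)
            m = fit_gblup(sim.y, K_nc)
            non.append(predict_gblup(m, K_nc).score(sim.g_true))
            K_i = build_grm(impute_ls_hmm(mp, gmap).rounded_calls())
            m2 = fit_gblup(sim.y, K_i)
            imp.append(predict_gblup(m2, K_i).score(sim.g_true))
        assert np.mean(imp) >= np.mean(non), (rate, imp, non)


def test_gs_accuracy_sandwich_low_imputed_full():
    # prediction accuracy: low-density < imputed <= full-density on average
    from wheatimpute import impute_ls_hmm, mask_low_to_high
    panel, gmap = simulate_panel(PanelParams(n_lines=371, n_markers=200,
                                             n_chrom=2, map_length_cm=450.0,
                                             seed=22))
    design = designate_arrays(gmap, 1573 / 9926)
    low_cols = design.low_mask(panel.marker_ids)
    M = panel.calls.astype(float)
    res = {"low": [], "imp": [], "full": []}
    for rep in range(5):
        mp = mask_low_to_high(panel, design, ref_size=300, seed=90 + rep)
        sim = simulate_polygenic_phenotype(panel, h2=0.91, seed=95 + rep)
        tr = np.isin(panel.line_ids, mp.reference_lines)
        te = ~tr
        imp = impute_ls_hmm(mp, gmap)
        for name, X in [("low", M[:, low_cols]), ("full", M),
                        ("imp", imp.dosages)]:
            model = fit_rrblup(sim.y[tr], X[tr])
            pred = predict_rrblup(model, X[te]).predicted
            res[name].append(np.corrcoef(pred, sim.g_true[te])[0, 1])
    assert np.mean(res["low"]) < np.mean(res["imp"]) <= np.mean(res["full"])


def test_detection_frequency_increases_with_ld_class_on_imputed_scans():
    # low-density lines imputed, then scanned: power grows with the LD
    # between the QTL and its closest typed marker
    from wheatimpute import impute_ls_hmm, mask_low_to_high
    from wheatimpute.quantgen import max_ld_to_low
    panel, gmap = simulate_panel(PanelParams(seed=0))
    design = designate_arrays(gmap, 1573 / 9926)
    maf = panel.maf()
    v = panel.calls.astype(float).var(axis=0, ddof=1)
    in_imp = ~design.low_mask(panel.marker_ids)
    cand = np.flatnonzero((maf > 0.3) & (v > 0) & in_imp)
    lds = np.array([max_ld_to_low(panel, gmap, design, j) for j in cand])

    mp = mask_low_to_high(panel, design, ref_size=100, seed=7)
    imp = impute_ls_hmm(mp, gmap)
    rd = rogers_distance(panel)
    K = kinship_from_rd(rd.values)
    ctx = _scan_context(K)
    rng = np.random.default_rng(5)
    freqs = []
    for t in (0.1, 0.5, 0.9):
        cls = cand[np.abs(lds - t) <= 0.05]
        assert cls.size > 0
        hits, runs = 0, 50
        for _ in range(runs):
            qj = int(rng.choice(cls))
            sim = simulate_qtl_phenotype(
                panel, seed=int(rng.integers(2**31 - 1)),
                qtl_marker=str(panel.marker_ids[qj]))
            scan = mixed_model_scan(imp.dosages, panel.marker_ids, sim.y, K,
                                    context=ctx)
            hits += scan.table["p"].iloc[qj] < 0.05 / panel.n_markers
        freqs.append(hits / runs)
    assert freqs[0] <= freqs[1] <= freqs[2], freqs
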