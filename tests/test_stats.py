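import numpy as np
import pandas as pd
import pytest
from numpy.random import default_rng
from scipy import stats as sps

from enisim import CohortConfig, cohort_to_table, generate_cohort
from enisim import stats as st


# -- polarity effect -------------------------------------------------------

def test_polarity_effect_difference_and_missing():
    table = pd.DataFrame(
        dict(
            t_aca_db=[52.0, 45.0, np.nan, 45.17],
            t_cac_db=[48.0, 45.0, 50.0, 50.0],
        )
    )
    out = st.polarity_effect(table)
    assert out.pe_db.tolist()[:2] == [4.0, 0.0]
    assert np.isnan(out.pe_db.iloc[2])
    assert out.pe_missing_reason.iloc[2] == "ACA threshold missing"
    assert out.pe_db.iloc[3] == pytest.approx(-4.83)


# -- rmcorr ---------------------------------------------------------------

def test_rmcorr_perfect_lines():
    subj = np.repeat(["a", "b", "c"], 4)
    x = np.tile(np.arange(4.0), 3)
    offsets = np.repeat([0.0, 5.0, -3.0], 4)
    up = st.rmcorr(x, x + offsets, subj)
    assert up.r_rm == pytest.approx(1.0)
    assert up.p < 1e-12
    down = st.rmcorr(x, -2.0 * x + offsets, subj)
    assert down.r_rm == pytest.approx(-1.0)


def test_rmcorr_matches_brute_force_ancova():
    """Full dummy-variable ANCOVA regression as the independent oracle."""
    rng = default_rng(0)
    subj = np.repeat(np.arange(6), 5)
    x = rng.normal(size=30)
    y = 0.7 * x + np.repeat(rng.normal(0, 2, 6), 5) + rng.normal(0, 1, 30)
    res = st.rmcorr(x, y, subj)
    # oracle: lstsq on [dummies | x], SS decomposition
    D = np.zeros((30, 6))
    D[np.arange(30), subj] = 1.0
    full = np.column_stack([D, x])
    beta_full, *_ = np.linalg.lstsq(full, y, rcond=None)
    sse_full = float(np.sum((y - full @ beta_full) ** 2))
    beta_red, *_ = np.linalg.lstsq(D, y, rcond=None)
    sse_red = float(np.sum((y - D @ beta_red) ** 2))
    ss_x = sse_red - sse_full
    r_oracle = np.sign(beta_full[-1]) * np.sqrt(ss_x / (ss_x + sse_full))
    df = 30 - 6 - 1
    f_oracle = ss_x / (sse_full / df)
    assert res.r_rm == pytest.approx(r_oracle, abs=1e-10)
    assert res.df == df
    assert res.p == pytest.approx(float(sps.f.sf(f_oracle, 1, df)), abs=1e-10)


def test_rmcorr_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = default_rng(3)
    subj = np.repeat(np.arange(8), 5)
    x = rng.normal(size=40)
    y = 0.5 * x + np.repeat(rng.normal(0, 2, 8), 5) + rng.normal(0, 1, 40)
    mine = st.rmcorr(x, y, subj)
    ref = pg.rm_corr(pd.DataFrame(dict(x=x, y=y, s=subj)), x="x", y="y", subject="s")
    assert mine.r_rm == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
    assert mine.df == int(ref["dof"].iloc[0])
    assert mine.p == pytest.approx(float(ref["pval"].iloc[0]), abs=1e-10)


def test_rmcorr_single_subject_equals_pearson():
    rng = default_rng(1)
    x = rng.normal(size=12)
    y = 0.6 * x + rng.normal(0, 0.5, 12)
    res = st.rmcorr(x, y, np.zeros(12, dtype=int))
    r, p = sps.pearsonr(x, y)
    assert res.r_rm == pytest.approx(r, abs=1e-12)
    assert res.p == pytest.approx(p, abs=1e-12)
    assert res.df == 10


def test_rmcorr_rejects_degenerate_x():
    subj = np.repeat([0, 1], 4)
    with pytest.raises(ValueError, match="within-subject variance"):
        st.rmcorr(np.repeat([1.0, 2.0], 4), default_rng(0).normal(size=8), subj)


# -- mixed model -----------------------------------------------------------

def _balanced_one_way(rng, k=8, m=12, sd_u=2.0, sd_e=1.5):
    u = rng.normal(0, sd_u, k)
    y = (u[:, None] + rng.normal(0, sd_e, (k, m))).ravel()
    return y, np.repeat(np.arange(k), m)


def test_lmm_balanced_grand_mean_and_anova_components():
    rng = default_rng(3)
    y, g = _balanced_one_way(rng)
    fit = st.fit_lmm(y, np.ones((len(y), 1)), g, method="REML")
    k, m = 8, 12
    ybar = y.reshape(k, m).mean(axis=1)
    grand = y.mean()
    msb = m * np.sum((ybar - grand) ** 2) / (k - 1)
    mse = np.sum((y.reshape(k, m) - ybar[:, None]) ** 2) / (k * (m - 1))
    assert fit.beta[0] == pytest.approx(grand, abs=1e-10)
    assert fit.var_e == pytest.approx(mse, abs=1e-6)
    assert fit.var_u == pytest.approx((msb - mse) / m, abs=1e-6)


def test_lmm_matches_statsmodels_mixedlm():
    MixedLM = pytest.importorskip(
        "statsmodels.regression.mixed_linear_model"
    ).MixedLM
    rng = default_rng(4)
    y0, g = _balanced_one_way(rng)
    x = rng.normal(size=len(y0))
    y = y0 + 0.8 * x
    X = np.column_stack([np.ones(len(y)), x])
    for method in ("REML", "ML"):
        mine = st.fit_lmm(y, X, g, method=method)
        ref = MixedLM(y, X, groups=g).fit(reml=(method == "REML"))
        assert mine.beta == pytest.approx(np.asarray(ref.fe_params), abs=1e-5)
        assert mine.var_u == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), abs=1e-2)
        assert mine.var_e == pytest.approx(float(ref.scale), abs=1e-3)
        assert mine.loglik == pytest.approx(float(ref.llf), abs=1e-4)


def test_lmm_boundary_fit_flagged_not_raised():
    rng = default_rng(5)
    y = rng.normal(size=60)
    g = np.repeat(np.arange(6), 10)
    y -= np.repeat(y.reshape(6, 10).mean(axis=1), 10)  # zero between-group variance
    fit = st.fit_lmm(y, np.ones((60, 1)), g, method="REML")
    assert fit.boundary
    assert fit.var_u == pytest.approx(0.0, abs=1e-8)


def test_lmm_rejects_rank_deficient_design():
    rng = default_rng(6)
    x = rng.normal(size=40)
    X = np.column_stack([np.ones(40), x, x])  # duplicated predictor
    with pytest.raises(ValueError, match="rank"):
        st.fit_lmm(rng.normal(size=40), X, np.repeat(np.arange(4), 10))


def test_lmm_loglik_is_maximal_at_fitted_variance_ratio():
    from enisim.stats import _profiled_loglik

    rng = default_rng(7)
    y, g = _balanced_one_way(rng)
    X = np.ones((len(y), 1))
    fit = st.fit_lmm(y, X, g, method="REML")
    psi = fit.var_u / fit.var_e
    codes = np.repeat(np.arange(8), 12)
    ll_hat = _profiled_loglik(psi, X, y, codes, 8, "REML")[0]
    for factor in (0.9, 1.1):
        assert ll_hat >= _profiled_loglik(psi * factor, X, y, codes, 8, "REML")[0]


def test_lmm_recovers_emd_sized_slope():
    """11 subjects x 14 channels, true slope 5.46 dB/mm; mean estimate over
    replicates within 10 % of truth."""
    rng = default_rng(8)
    est = []
    for _ in range(100):
        g = np.repeat(np.arange(11), 14)
        x = rng.normal(1.1, 0.4, len(g))
        y = 40.0 + 5.46 * x + np.repeat(rng.normal(0, 4, 11), 14) + rng.normal(0, 2.5, len(g))
        X = np.column_stack([np.ones(len(g)), x])
        est.append(st.fit_lmm(y, X, g, method="REML").beta[1])
    assert np.mean(est) == pytest.approx(5.46, rel=0.10)


# -- AICc / pseudo-R2 ------------------------------------------------------

def test_aicc_formula_and_limits():
    assert st.aicc(-50.0, 2, 10) == pytest.approx(104.0 + 12.0 / 7.0)
    assert st.aicc(-50.0, 2, 10**9) == pytest.approx(104.0, abs=1e-6)
    assert st.aicc(-10.0, 3, 100) == st.aicc(-10.0, 3, 100)
    with pytest.raises(ValueError):
        st.aicc(-50.0, 9, 10)


def test_pseudo_r2_null_and_no_random_variance():
    rng = default_rng(9)
    y, g = _balanced_one_way(rng)
    null = st.fit_lmm(y, np.ones((len(y), 1)), g)
    marg, cond = st.pseudo_r2(null)
    assert marg == pytest.approx(0.0, abs=1e-12)
    assert cond > marg
    # independent noise: variance ratio at boundary -> marginal == conditional
    y2 = rng.normal(size=len(y))
    x = rng.normal(size=len(y))
    flat = st.fit_lmm(y2 + 0.5 * x, np.column_stack([np.ones(len(y)), x]), g)
    if flat.boundary:
        m2, c2 = st.pseudo_r2(flat)
        assert m2 == pytest.approx(c2, abs=1e-10)


def test_pseudo_r2_ordering_on_synthetic_cohorts():
    for seed in range(3):
        table = cohort_to_table(generate_cohort(CohortConfig(seed=seed)))
        comp = st.build_model_sequence(table)
        marg, cond = st.pseudo_r2(comp.full_reml)
        assert 0.0 < marg < cond < 1.0


# -- model sequence --------------------------------------------------------

def test_model_sequence_orders_and_selects(default_cohort):
    table = cohort_to_table(default_cohort)
    comp = st.build_model_sequence(table)
    assert [s.label for s in comp.steps] == [
        "empty",
        "emd_mm",
        "emd_mm + scalar_location",
        "emd_mm + scalar_location + log_r_long",
        "emd_mm + scalar_location + log_r_long + pe_db",
    ]
    assert comp.selected == int(np.argmin([s.aicc for s in comp.steps]))
    frame = comp.as_frame()
    assert frame.selected.sum() == 1


def test_model_sequence_rejects_duplicated_predictor(default_cohort):
    table = cohort_to_table(default_cohort)
    table["log_r_long"] = table["emd_mm"]  # force collinearity
    with pytest.raises(ValueError, match="rank"):
        st.build_model_sequence(table)


def test_null_predictor_rarely_lowers_aicc():
    rng = default_rng(10)
    worse = 0
    reps = 40
    for _ in range(reps):
        g = np.repeat(np.arange(10), 12)
        y = np.repeat(rng.normal(0, 2, 10), 12) + rng.normal(0, 1, 120)
        x = rng.normal(size=120)  # no true effect
        base = st.fit_lmm(y, np.ones((120, 1)), g, method="ML")
        ext = st.fit_lmm(y, np.column_stack([np.ones(120), x]), g, method="ML")
        a0 = st.aicc(base.loglik_ml, base.k_parameters, 120)
        a1 = st.aicc(ext.loglik_ml, ext.k_parameters, 120)
        worse += a1 >= a0
    assert worse / reps > 0.6


# -- per-subject correlations and grouping --------------------------------

def _toy_table():
    rng = default_rng(11)
    rows = []
    for sid, slope in (("s1", 2.0), ("s2", 0.1)):
        x = np.linspace(0.5, 2.0, 8)
        r = rng.uniform(100, 1000, 8)
        pe = rng.normal(0, 1, 8)
        y = 40 + slope * 5 * x + rng.normal(0, 0.1, 8)
        for i in range(8):
            rows.append(
                dict(subject_id=sid, electrode=i + 2, emd_mm=x[i], pe_db=pe[i],
                     r_long_ohm=r[i], t_sqp_db=y[i], scalar_location="ST",
                     t_aca_db=np.nan, t_cac_db=np.nan)
            )
    return pd.DataFrame(rows)


def test_per_subject_correlations_conventions():
    table = _toy_table()
    out = st.per_subject_correlations(table)
    s1 = out[out.subject_id == "s1"].iloc[0]
    assert s1.r_emd > 0.99  # essentially linear
    # Spearman equals rank-then-Pearson by definition
    sub = table[table.subject_id == "s1"]
    ranks_x = sps.rankdata(sub.r_long_ohm)
    ranks_y = sps.rankdata(sub.t_sqp_db)
    assert s1.r_r_long == pytest.approx(np.corrcoef(ranks_x, ranks_y)[0, 1], abs=1e-12)


def test_monotone_nonlinear_spearman_beats_pearson():
    x = np.linspace(0.2, 2.0, 10)
    y = np.exp(3 * x)
    table = pd.DataFrame(
        dict(subject_id="s", electrode=np.arange(10) + 2, emd_mm=x, pe_db=x,
             r_long_ohm=np.exp(x * 2) * 100, t_sqp_db=y, scalar_location="ST",
             t_aca_db=np.nan, t_cac_db=np.nan)
    )
    out = st.per_subject_correlations(table).iloc[0]
    assert out.r_r_long == pytest.approx(1.0)
    assert out.r_emd < 1.0  # Pearson penalizes curvature


def test_too_few_pairs_and_constant_columns_reported():
    table = _toy_table().iloc[:3].copy()  # 3 rows for s1 only
    out = st.per_subject_correlations(table)
    assert np.isnan(out.r_emd.iloc[0])
    assert "fewer than" in out.note_emd.iloc[0]
    t2 = _toy_table()
    t2.loc[t2.subject_id == "s1", "emd_mm"] = 1.0
    out2 = st.per_subject_correlations(t2)
    assert out2[out2.subject_id == "s1"].note_emd.iloc[0] == "constant column"


def test_split_groups_strict_cutoff():
    per = pd.DataFrame(
        dict(subject_id=["a", "b", "c"], r_emd=[0.71, 0.70, 0.69])
    )
    table = _toy_table()
    split = st.split_groups(table, per, cutoff=0.70)
    assert split.labels["a"] == "strong"
    assert split.labels["b"] == "weak-to-moderate"
    assert split.labels["c"] == "weak-to-moderate"


def test_split_groups_pe_relation_stronger_when_position_uninformative():
    """Cohort where half the subjects have position-dominated thresholds:
    the PE-threshold association emerges in the weak threshold-EMD group."""
    rng = default_rng(12)
    rows = []
    for s in range(10):
        position_driven = s < 5
        pe = rng.normal(0, 1.5, 12)
        emd = np.clip(rng.normal(1.1, 0.45, 12), 0.2, 2.2)
        if position_driven:
            y = 40 + 6.0 * emd + rng.normal(0, 0.5, 12)
        else:
            y = 44 + 1.5 * pe + rng.normal(0, 0.5, 12)
        for i in range(12):
            rows.append(
                dict(subject_id=f"s{s}", electrode=i + 2, emd_mm=emd[i],
                     pe_db=pe[i], r_long_ohm=300.0 + i, t_sqp_db=y[i],
                     scalar_location="ST", t_aca_db=np.nan, t_cac_db=np.nan)
            )
    table = pd.DataFrame(rows)
    per = st.per_subject_correlations(table)
    split = st.split_groups(table, per)
    assert split.rmcorr_weak.r_rm > split.rmcorr_strong.r_rm
    assert split.rmcorr_weak.r_rm > 0.5


def test_split_groups_empty_group_noted():
    per = pd.DataFrame(dict(subject_id=["s1", "s2"], r_emd=[0.1, 0.2]))
    split = st.split_groups(_toy_table(), per)
    assert split.rmcorr_strong is None
    assert any("strong" in n for n in split.notes)


# -- duration regression ---------------------------------------------------

def test_duration_regression_exact_line_and_null():
    d = np.array([5.0, 10.0, 20.0, 35.0, 50.0])
    exact = st.duration_regression(0.05 * d - 1.0, d)
    assert exact.r2 == pytest.approx(1.0)
    assert exact.p == pytest.approx(0.0, abs=1e-12)
    flat = st.duration_regression(np.array([1.0, -1.0, 1.0, -1.0, 0.0]), d)
    assert flat.r2 < 0.3


def test_duration_regression_matches_closed_form():
    rng = default_rng(13)
    d = np.array([3.0, 11.0, 24.0, 30.0, 53.0])
    pe = 0.04 * d + rng.normal(0, 0.5, 5)
    res = st.duration_regression(pe, d)
    # normal-equations oracle
    Xo = np.column_stack([np.ones(5), d])
    beta = np.linalg.solve(Xo.T @ Xo, Xo.T @ pe)
    resid = pe - Xo @ beta
    r2 = 1 - resid @ resid / np.sum((pe - pe.mean()) ** 2)
    assert res.slope == pytest.approx(beta[1], abs=1e-12)
    assert res.r2 == pytest.approx(r2, abs=1e-12)
    assert res.adjusted_r2 == pytest.approx(1 - (1 - r2) * 4 / 3, abs=1e-12)
    assert res.df == (1, 3)
    f = r2 / (1 - r2) * 3
    assert res.p == pytest.approx(float(sps.f.sf(f, 1, 3)), abs=1e-12)


def test_duration_regression_rejects_constant_duration():
    with pytest.raises(ValueError, match="constant"):
        st.duration_regression([1.0, 2.0, 3.0], [10.0, 10.0, 10.0])


# -- alpha adjustment and contrasts ---------------------------------------

@pytest.mark.parametrize("m,raw,reported", [(3, 0.05 / 3, 0.017), (1, 0.05, 0.05), (5, 0.01, 0.01)])
def test_bonferroni_adjustment(m, raw, reported):
    got_raw, got_rep = st.adjust_alpha(m)
    assert got_raw == pytest.approx(raw)
    assert got_rep == reported


def test_adjust_alpha_rejects_nonpositive():
    with pytest.raises(ValueError):
        st.adjust_alpha(0)


def test_tukey_scalar_contrasts(default_cohort):
    table = cohort_to_table(default_cohort)
    comp = st.build_model_sequence(table)
    contrasts = st.scalar_pairwise_contrasts(comp.full_reml)
    assert len(contrasts) == 3
    pairs = {frozenset(c.pair) for c in contrasts}
    assert pairs == {
        frozenset({"ST", "intermediate"}),
        frozenset({"ST", "SV"}),
        frozenset({"intermediate", "SV"}),
    }
    for c in contrasts:
        assert c.p_unadjusted <= c.p_tukey + 1e-12
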