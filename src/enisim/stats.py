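"""Multilevel statistics for channel tables.

Implements the analysis chain applied to per-(subject, electrode) threshold
data: the polarity-effect difference score, repeated-measures correlations
(ANCOVA with subject as factor and a common slope), random-intercept linear
mixed models fit by REML or ML with a one-dimensional profile likelihood over
the variance ratio, AICc-ordered nested model building, Nakagawa-style
marginal/conditional pseudo-R2, per-subject Pearson/Spearman correlations
with the 0.70 grouping rule, the duration-of-deafness regression on
subject-mean polarity effects, and Bonferroni/Tukey adjustments.

The repeated-measures correlation r_rm is the common within-subject
association: with x and y centred within subject, r_rm =
sign(slope) * sqrt(SS_x / (SS_x + SS_err)) on N - k - 1 degrees of freedom
(N observations, k subjects).

The mixed model is y = X beta + u_subject + e with u ~ N(0, var_u) and
e ~ N(0, var_e).  The likelihood is profiled over psi = var_u / var_e, using
the closed-form blockwise inverse (I + psi J)^-1 = I - psi/(1 + n_s psi) J,
so each evaluation is O(N p^2).  Per-term F statistics use a
Satterthwaite-type denominator df obtained from numerical derivatives of the
contrast variance with respect to the two variance components and the
inverse curvature of the REML log-likelihood.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "RmcorrResult",
    "LmmFit",
    "FTest",
    "ModelStep",
    "ModelComparison",
    "PairwiseContrast",
    "DurationRegression",
    "GroupSplit",
    "polarity_effect",
    "rmcorr",
    "design_matrix",
    "fit_lmm",
    "aicc",
    "pseudo_r2",
    "build_model_sequence",
    "per_subject_correlations",
    "split_groups",
    "duration_regression",
    "adjust_alpha",
    "scalar_pairwise_contrasts",
    "MODEL_SEQUENCE_TERMS",
]

#: fixed effects added consecutively to the empty model, in analysis order
MODEL_SEQUENCE_TERMS = ["emd_mm", "scalar_location", "log_r_long", "pe_db"]


# --------------------------------------------------------------------------
# polarity effect
# --------------------------------------------------------------------------

def polarity_effect(table: pd.DataFrame) -> pd.DataFrame:
    """Add/refresh the polarity-effect column: PE (dB) = ACA minus CAC.

    Positive values mean the anodic-centred (ACA) threshold is higher
    (worse).  Rows missing either threshold get a missing PE and a reason
    code in ``pe_missing_reason``.
    """
    out = table.copy()
    aca = pd.to_numeric(out["t_aca_db"], errors="coerce")
    cac = pd.to_numeric(out["t_cac_db"], errors="coerce")
    out["pe_db"] = aca - cac
    reason = np.where(
        aca.isna() & cac.isna(), "both thresholds missing",
        np.where(aca.isna(), "ACA threshold missing",
                 np.where(cac.isna(), "CAC threshold missing", "")),
    )
    out["pe_missing_reason"] = reason
    return out


# --------------------------------------------------------------------------
# repeated-measures correlation
# --------------------------------------------------------------------------

@dataclasses.dataclass
class RmcorrResult:
    r_rm: float
    df: int
    ci95: tuple
    p: float
    n_obs: int
    n_subjects: int
    slope: float


def rmcorr(x, y, subjects) -> RmcorrResult:
    """Common within-subject correlation via the ANCOVA decomposition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subjects = np.asarray(subjects)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y, subjects = x[ok], y[ok], subjects[ok]
    codes, uniq = pd.factorize(subjects)
    counts = np.bincount(codes)
    if (counts >= 2).sum() < 1:
        raise ValueError("rmcorr needs subjects with >= 2 paired observations")
    # centre within subject
    xm = np.bincount(codes, weights=x) / counts
    ym = np.bincount(codes, weights=y) / counts
    xc = x - xm[codes]
    yc = y - ym[codes]
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise ValueError("rmcorr undefined: no within-subject variance in x")
    sxy = float(xc @ yc)
    slope = sxy / sxx
    ss_x = sxy * sxy / sxx
    ss_err = float(yc @ yc) - ss_x
    ss_err = max(ss_err, 0.0)
    n, k = len(x), len(uniq)
    df = n - k - 1
    if df < 1:
        raise ValueError("rmcorr needs N - k - 1 >= 1 degrees of freedom")
    denom = ss_x + ss_err
    r = 0.0 if denom == 0 else np.sign(slope) * np.sqrt(ss_x / denom)
    if ss_err == 0:
        p = 0.0
        fstat = np.inf
    else:
        fstat = ss_x / (ss_err / df)
        p = float(sps.f.sf(fstat, 1, df))
    # Fisher-z interval on the error degrees of freedom
    if df > 3 and abs(r) < 1:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(df - 1)
        ci = (float(np.tanh(z - 1.959963984540054 * se)),
              float(np.tanh(z + 1.959963984540054 * se)))
    else:
        ci = (np.nan, np.nan)
    return RmcorrResult(float(r), int(df), ci, p, n, k, float(slope))


# --------------------------------------------------------------------------
# random-intercept mixed model
# --------------------------------------------------------------------------

def design_matrix(df: pd.DataFrame, terms) -> tuple:
    """Fixed-effect design with intercept; categorical terms are dummy-coded
    with 'ST' (when present) as the reference level.

    Returns (X, column names, {term: column indices}).
    """
    n = len(df)
    cols = [np.ones(n)]
    names = ["Intercept"]
    slices: dict = {}
    for t in terms:
        v = df[t]
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(v.dropna()))
            if "ST" in levels:
                levels = ["ST"] + [l for l in levels if l != "ST"]
            idx = []
            for lev in levels[1:]:
                cols.append((v == lev).to_numpy(dtype=float))
                names.append(f"{t}[{lev}]")
                idx.append(len(cols) - 1)
            slices[t] = idx
        else:
            cols.append(pd.to_numeric(v).to_numpy(dtype=float))
            names.append(t)
            slices[t] = [len(cols) - 1]
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient fixed-effect design (collinear predictors)")
    return X, names, slices


@dataclasses.dataclass
class FTest:
    term: str
    fstat: float
    df_num: int
    df_den: float
    p: float


@dataclasses.dataclass
class LmmFit:
    method: str
    fe_names: list
    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    var_u: float
    var_e: float
    loglik_reml: float
    loglik_ml: float
    n_obs: int
    n_groups: int
    converged: bool
    boundary: bool
    f_tests: list
    term_slices: dict
    X: np.ndarray = dataclasses.field(repr=False, default=None)
    y: np.ndarray = dataclasses.field(repr=False, default=None)
    group_codes: np.ndarray = dataclasses.field(repr=False, default=None)

    @property
    def k_parameters(self) -> int:
        """Fixed effects plus the two variance components."""
        return len(self.beta) + 2

    @property
    def loglik(self) -> float:
        return self.loglik_reml if self.method == "REML" else self.loglik_ml

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.beta, "se": self.se}, index=self.fe_names
        )


def _gls_pieces(X, y, codes, n_groups, psi):
    """Blockwise GLS accumulators for Sigma = I + psi * J per group."""
    p = X.shape[1]
    A = np.zeros((p, p))
    b = np.zeros(p)
    q = 0.0
    ldet = 0.0
    for g in range(n_groups):
        m = codes == g
        Xs = X[m]
        ys = y[m]
        ns = len(ys)
        c = psi / (1.0 + ns * psi)
        sx = Xs.sum(axis=0)
        sy = ys.sum()
        A += Xs.T @ Xs - c * np.outer(sx, sx)
        b += Xs.T @ ys - c * sx * sy
        q += ys @ ys - c * sy * sy
        ldet += np.log1p(ns * psi)
    return A, b, q, ldet


def _profiled_loglik(psi, X, y, codes, n_groups, method):
    N, p = X.shape
    A, b, q, ldet = _gls_pieces(X, y, codes, n_groups, psi)
    beta = np.linalg.solve(A, b)
    rss = max(float(q - beta @ b), 1e-300)
    if method == "ML":
        s2 = rss / N
        ll = -0.5 * (N * np.log(2.0 * np.pi * s2) + ldet + N)
    else:
        s2 = rss / (N - p)
        sign, logdet_a = np.linalg.slogdet(A)
        ll = -0.5 * ((N - p) * np.log(2.0 * np.pi * s2) + ldet + logdet_a + (N - p))
    return ll, beta, s2, A


def fit_lmm(
    y,
    X: np.ndarray,
    groups,
    method: str = "REML",
    fe_names=None,
    term_slices=None,
) -> LmmFit:
    """Fit the random-intercept model, profiling psi = var_u / var_e.

    Deterministic given inputs.  A boundary fit (var_u -> 0) is returned with
    ``boundary=True``, not raised.
    """
    if method not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    N, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient fixed-effect design (collinear predictors)")
    codes, uniq = pd.factorize(np.asarray(groups))
    n_groups = len(uniq)
    if n_groups < 2:
        raise ValueError("mixed model needs >= 2 subjects")
    if fe_names is None:
        fe_names = [f"x{j}" for j in range(p)]
    if term_slices is None:
        term_slices = {name: [j] for j, name in enumerate(fe_names) if j > 0}

    def neg(logpsi):
        return -_profiled_loglik(np.exp(logpsi), X, y, codes, n_groups, method)[0]

    opt = optimize.minimize_scalar(
        neg, bounds=(-30.0, 15.0), method="bounded",
        options={"xatol": 1e-13, "maxiter": 500},
    )
    psi_hat = float(np.exp(opt.x))
    ll_zero = _profiled_loglik(0.0, X, y, codes, n_groups, method)[0]
    boundary = False
    if ll_zero >= -opt.fun - 1e-10:
        psi_hat = 0.0
        boundary = True

    _, beta, s2, A = _profiled_loglik(psi_hat, X, y, codes, n_groups, method)
    ll_reml = _profiled_loglik(psi_hat, X, y, codes, n_groups, "REML")[0]
    ll_ml = _profiled_loglik(psi_hat, X, y, codes, n_groups, "ML")[0]
    var_e = float(s2)
    var_u = float(psi_hat * s2)
    cov_beta = s2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov_beta))

    fit = LmmFit(
        method=method,
        fe_names=list(fe_names),
        beta=beta,
        se=se,
        cov_beta=cov_beta,
        var_u=var_u,
        var_e=var_e,
        loglik_reml=float(ll_reml),
        loglik_ml=float(ll_ml),
        n_obs=N,
        n_groups=n_groups,
        converged=bool(opt.success),
        boundary=boundary,
        f_tests=[],
        term_slices=dict(term_slices),
        X=X,
        y=y,
        group_codes=codes,
    )
    fit.f_tests = [_term_f_test(fit, term, idx) for term, idx in fit.term_slices.items()]
    return fit


def _cov_beta_at(theta, X, codes, n_groups):
    """Var(beta_hat) = (X' V^-1 X)^-1 at variance components theta=(vu, ve)."""
    vu, ve = theta
    psi = vu / ve
    p = X.shape[1]
    A = np.zeros((p, p))
    for g in range(n_groups):
        Xs = X[codes == g]
        ns = Xs.shape[0]
        c = psi / (1.0 + ns * psi)
        sx = Xs.sum(axis=0)
        A += Xs.T @ Xs - c * np.outer(sx, sx)
    return ve * np.linalg.inv(A)


def _reml_loglik_theta(theta, X, y, codes, n_groups):
    """REML log-likelihood as a free function of (var_u, var_e)."""
    vu, ve = theta
    if vu < 0 or ve <= 0:
        return -np.inf
    psi = vu / ve
    N, p = X.shape
    A, b, q, ldet = _gls_pieces(X, y, codes, n_groups, psi)
    beta = np.linalg.solve(A, b)
    rss = max(float(q - beta @ b), 1e-300)
    sign, logdet_a = np.linalg.slogdet(A)
    # ln|V| = N ln ve + ldet ; ln|X'V^-1 X| = logdet_a - p ln ve
    return -0.5 * (
        N * np.log(ve) + ldet + logdet_a - p * np.log(ve) + rss / ve
        + (N - p) * np.log(2.0 * np.pi)
    )


def _satterthwaite_df(fit: LmmFit, ell: np.ndarray) -> float:
    """Approximate denominator df for a single contrast ell' beta."""
    fallback = float(fit.n_obs - len(fit.beta))
    if fit.boundary or fit.var_u <= 0 or fit.var_e <= 0:
        return fallback
    theta = np.array([fit.var_u, fit.var_e])
    X, y, codes, ng = fit.X, fit.y, fit.group_codes, fit.n_groups

    def c_of_theta(t):
        return float(ell @ _cov_beta_at(t, X, codes, ng) @ ell)

    h = np.maximum(1e-5 * theta, 1e-12)
    grad = np.empty(2)
    for j in range(2):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        grad[j] = (c_of_theta(tp) - c_of_theta(tm)) / (2 * h[j])

    # observed information of the REML log-likelihood, numeric Hessian
    def ll(t):
        return _reml_loglik_theta(t, X, y, codes, ng)

    H = np.empty((2, 2))
    for j in range(2):
        for k in range(j, 2):
            tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
            tpp[j] += h[j]; tpp[k] += h[k]
            tpm[j] += h[j]; tpm[k] -= h[k]
            tmp[j] -= h[j]; tmp[k] += h[k]
            tmm[j] -= h[j]; tmm[k] -= h[k]
            H[j, k] = H[k, j] = (ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm)) / (4 * h[j] * h[k])
    try:
        W = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return fallback
    denom = float(grad @ W @ grad)
    if denom <= 0:
        return fallback
    c = c_of_theta(theta)
    df = 2.0 * c * c / denom
    return float(np.clip(df, 1.0, fallback))


def _term_f_test(fit: LmmFit, term: str, idx) -> FTest:
    idx = list(idx)
    q = len(idx)
    L = np.zeros((q, len(fit.beta)))
    for r, j in enumerate(idx):
        L[r, j] = 1.0
    est = L @ fit.beta
    C = L @ fit.cov_beta @ L.T
    fstat = float(est @ np.linalg.solve(C, est)) / q
    # per-eigencontrast Satterthwaite dfs, pooled Fai-Cornelius style
    evals, evecs = np.linalg.eigh(C)
    dfs = []
    for m in range(q):
        ell = L.T @ evecs[:, m]
        dfs.append(_satterthwaite_df(fit, ell))
    dfs = np.asarray(dfs)
    if q == 1:
        df_den = float(dfs[0])
    else:
        good = dfs > 2.0
        if good.all():
            E = float(np.sum(dfs / (dfs - 2.0)))
            df_den = 2.0 * E / (E - q) if E > q else float(fit.n_obs - len(fit.beta))
        else:
            df_den = float(fit.n_obs - len(fit.beta))
    p = float(sps.f.sf(fstat, q, df_den))
    return FTest(term=term, fstat=fstat, df_num=q, df_den=df_den, p=p)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 ll + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError("aicc requires n - k - 1 > 0")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def pseudo_r2(fit: LmmFit) -> tuple:
    """(marginal, conditional) variance explained, Nakagawa-style."""
    pred = fit.X @ fit.beta
    var_f = float(np.var(pred))
    total = var_f + fit.var_u + fit.var_e
    if total <= 0:
        raise ValueError("pseudo_r2 undefined: zero total variance")
    return var_f / total, (var_f + fit.var_u) / total


# --------------------------------------------------------------------------
# model sequence
# --------------------------------------------------------------------------

@dataclasses.dataclass
class ModelStep:
    label: str
    terms: list
    k: int
    loglik_ml: float
    aicc: float
    fit: LmmFit


@dataclasses.dataclass
class ModelComparison:
    steps: list
    selected: int
    n_obs: int
    dropped_rows: int
    full_reml: LmmFit

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [s.label for s in self.steps],
                "k": [s.k for s in self.steps],
                "loglik_ml": [s.loglik_ml for s in self.steps],
                "aicc": [s.aicc for s in self.steps],
                "selected": [i == self.selected for i in range(len(self.steps))],
            }
        )


def build_model_sequence(
    table: pd.DataFrame, response: str = "t_sqp_db"
) -> ModelComparison:
    """Empty model plus the four consecutive fixed-effect additions.

    All models are fit on the same complete-case rows.  Cross-model AICc uses
    ML log-likelihoods (fixed effects differ between candidates); the final
    model is additionally refit by REML for coefficient reporting.
    """
    df = table.copy()
    if "log_r_long" not in df.columns:
        df["log_r_long"] = np.log10(pd.to_numeric(df["r_long_ohm"], errors="coerce"))
    needed = [response, "subject_id"] + [
        t for t in MODEL_SEQUENCE_TERMS
    ]
    n_before = len(df)
    df = df.dropna(subset=[c for c in needed if c != "scalar_location"])
    df = df[df["scalar_location"].notna() & (df["scalar_location"] != "extracochlear")]
    dropped = n_before - len(df)
    if len(df) == 0:
        raise ValueError("no complete-case rows available for model building")
    y = pd.to_numeric(df[response]).to_numpy(dtype=float)
    groups = df["subject_id"].to_numpy()

    steps = []
    for i in range(len(MODEL_SEQUENCE_TERMS) + 1):
        terms = MODEL_SEQUENCE_TERMS[:i]
        X, names, slices = design_matrix(df, terms)
        fit = fit_lmm(y, X, groups, method="ML", fe_names=names, term_slices=slices)
        k = fit.k_parameters
        steps.append(
            ModelStep(
                label="empty" if not terms else " + ".join(terms),
                terms=list(terms),
                k=k,
                loglik_ml=fit.loglik_ml,
                aicc=aicc(fit.loglik_ml, k, fit.n_obs),
                fit=fit,
            )
        )
    selected = int(np.argmin([s.aicc for s in steps]))
    X, names, slices = design_matrix(df, MODEL_SEQUENCE_TERMS)
    full_reml = fit_lmm(y, X, groups, method="REML", fe_names=names, term_slices=slices)
    return ModelComparison(
        steps=steps,
        selected=selected,
        n_obs=len(df),
        dropped_rows=dropped,
        full_reml=full_reml,
    )


# --------------------------------------------------------------------------
# per-subject correlations, grouping, duration regression
# --------------------------------------------------------------------------

def per_subject_correlations(
    table: pd.DataFrame, response: str = "t_sqp_db", min_pairs: int = 4
) -> pd.DataFrame:
    """Within-subject correlations of the focused threshold with EMD and the
    polarity effect (Pearson) and with R_long (Spearman, rank-based because
    the resistances are skewed)."""
    recs = []
    for sid, sub in table.groupby("subject_id", sort=True):
        rec = {"subject_id": sid}
        y = pd.to_numeric(sub[response], errors="coerce")
        for label, col, kind in (
            ("emd", "emd_mm", "pearson"),
            ("pe", "pe_db", "pearson"),
            ("r_long", "r_long_ohm", "spearman"),
        ):
            x = pd.to_numeric(sub[col], errors="coerce")
            ok = x.notna() & y.notna()
            rec[f"n_{label}"] = int(ok.sum())
            if ok.sum() < min_pairs:
                rec[f"r_{label}"] = np.nan
                rec[f"p_{label}"] = np.nan
                rec[f"note_{label}"] = f"fewer than {min_pairs} paired observations"
                continue
            xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
            if np.std(xv) == 0 or np.std(yv) == 0:
                rec[f"r_{label}"] = np.nan
                rec[f"p_{label}"] = np.nan
                rec[f"note_{label}"] = "constant column"
                continue
            if kind == "pearson":
                r, p = sps.pearsonr(xv, yv)
            else:
                r, p = sps.spearmanr(xv, yv)
            rec[f"r_{label}"] = float(r)
            rec[f"p_{label}"] = float(p)
            rec[f"note_{label}"] = ""
        recs.append(rec)
    return pd.DataFrame(recs)


@dataclasses.dataclass
class GroupSplit:
    labels: pd.Series  # subject_id -> "strong" / "weak-to-moderate"
    cutoff: float
    rmcorr_strong: RmcorrResult | None
    rmcorr_weak: RmcorrResult | None
    notes: list


def split_groups(
    table: pd.DataFrame,
    per_subject: pd.DataFrame,
    cutoff: float = 0.70,
    response: str = "t_sqp_db",
) -> GroupSplit:
    """Split subjects on the threshold-EMD correlation (strictly > cutoff)
    and compute the PE-threshold repeated-measures correlation per group."""
    labels = pd.Series(
        np.where(per_subject["r_emd"] > cutoff, "strong", "weak-to-moderate"),
        index=per_subject["subject_id"].to_numpy(),
        name="group",
    )
    notes = []
    results = {}
    for name in ("strong", "weak-to-moderate"):
        members = labels.index[labels == name]
        sub = table[table["subject_id"].isin(members)]
        sub = sub.dropna(subset=["pe_db", response])
        try:
            results[name] = rmcorr(sub["pe_db"], sub[response], sub["subject_id"])
        except ValueError as exc:
            results[name] = None
            notes.append(f"{name}: rmcorr skipped ({exc})")
    return GroupSplit(
        labels=labels,
        cutoff=cutoff,
        rmcorr_strong=results["strong"],
        rmcorr_weak=results["weak-to-moderate"],
        notes=notes,
    )


@dataclasses.dataclass
class DurationRegression:
    slope: float
    intercept: float
    r2: float
    adjusted_r2: float
    fstat: float
    df: tuple
    p: float
    n: int


def duration_regression(mean_pe, durations) -> DurationRegression:
    """OLS of subject-mean polarity effect on duration of deafness."""
    ypts = np.asarray(mean_pe, dtype=float)
    xpts = np.asarray(durations, dtype=float)
    ok = np.isfinite(xpts) & np.isfinite(ypts)
    xpts, ypts = xpts[ok], ypts[ok]
    n = len(xpts)
    if n < 3:
        raise ValueError("duration regression needs >= 3 subjects")
    if np.std(xpts) == 0:
        raise ValueError("duration regression undefined: constant duration")
    res = sps.linregress(xpts, ypts)
    r2 = res.rvalue ** 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    if r2 >= 1.0:
        fstat, p = np.inf, 0.0
    else:
        fstat = r2 / (1.0 - r2) * (n - 2)
        p = float(sps.f.sf(fstat, 1, n - 2))
    return DurationRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(r2),
        adjusted_r2=float(adj),
        fstat=float(fstat),
        df=(1, n - 2),
        p=p,
        n=n,
    )


def adjust_alpha(m: int, family_alpha: float = 0.05) -> tuple:
    """Bonferroni-adjusted per-comparison alpha: (raw, reported at 3 dp)."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    raw = family_alpha / m
    return raw, round(raw, 3)


@dataclasses.dataclass
class PairwiseContrast:
    pair: tuple
    estimate: float
    se: float
    tstat: float
    df: float
    p_unadjusted: float
    p_tukey: float


def scalar_pairwise_contrasts(fit: LmmFit, term: str = "scalar_location") -> list:
    """Tukey-adjusted pairwise comparisons among the scalar-location levels.

    The adjusted p uses the studentized-range distribution with the number of
    factor levels; unadjusted p values come from the t distribution on the
    same Satterthwaite df, so p_unadjusted <= p_tukey by construction.
    """
    idx = fit.term_slices.get(term)
    if not idx:
        raise ValueError(f"term {term!r} not in the fitted model")
    p = len(fit.beta)
    # level contrast vectors vs the reference, reference itself is zero
    names = ["ST"] + [fit.fe_names[j].split("[", 1)[1].rstrip("]") for j in idx]
    vecs = [np.zeros(p)]
    for j in idx:
        v = np.zeros(p)
        v[j] = 1.0
        vecs.append(v)
    k_levels = len(vecs)
    out = []
    for a in range(k_levels):
        for b in range(a + 1, k_levels):
            ell = vecs[b] - vecs[a]
            est = float(ell @ fit.beta)
            se = float(np.sqrt(ell @ fit.cov_beta @ ell))
            df = _satterthwaite_df(fit, ell)
            t = est / se
            p_un = float(2.0 * sps.t.sf(abs(t), df))
            p_tk = float(
                np.clip(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k_levels, df), 0, 1)
            )
            out.append(
                PairwiseContrast(
                    pair=(names[a], names[b]),
                    estimate=est,
                    se=se,
                    tstat=float(t),
                    df=float(df),
                    p_unadjusted=p_un,
                    p_tukey=max(p_tk, p_un),
                )
            )
    return out
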