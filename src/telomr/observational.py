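"""Observational arm: LTL adjustment, per-trait regressions, Lasso
stability selection, effective number of tests, and the female
reproductive-phase model.

The cohort is a pandas DataFrame with columns ``id, age, sex, array, ltl``
plus arbitrary trait columns (missingness allowed) and, for females, the
optional reproductive fields ``age_first_birth, age_menopause,
n_live_births, menopause_status``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lasso_path

logger = logging.getLogger(__name__)

CORE_COLUMNS = ["age", "sex", "array", "ltl"]

# average simvastatin effects to add back for medicated participants, mmol/L
STATIN_OFFSETS = {"TC": 1.6, "LDL": 1.4, "TG": 0.4, "HDL": -0.1}


@dataclass
class RegressionResult:
    trait_id: str
    beta: float
    se: float
    pvalue: float
    n_used: int
    usable: bool = True


@dataclass
class LassoSelection:
    selected_traits: list[str]
    selection_frequency: dict[str, float]
    variance_explained: float
    n_fits: int
    freq_cut: float


@dataclass
class PhaseModelResult:
    beta_phase1: float
    beta_phase2: float
    beta_phase3: float
    se_phase1: float
    se_phase2: float
    se_phase3: float
    p_phase1: float
    p_phase2: float
    p_phase3: float
    parity_coef: float
    menopause_coef: float
    n_used: int
    n_excluded: int


def trim_outliers(values, n_sd: float = 5.0) -> np.ndarray:
    """Set entries outside mean +/- ``n_sd`` SD (non-missing stats) to NaN."""
    v = np.asarray(values, dtype=float).copy()
    ok = np.isfinite(v)
    if ok.sum() < 2:
        warnings.warn("trim_outliers: fewer than 2 non-missing values; unchanged")
        return v
    mu = v[ok].mean()
    sd = v[ok].std(ddof=0)
    if sd == 0:
        return v
    out = ok & (np.abs(v - mu) > n_sd * sd)
    v[out] = np.nan
    return v


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS via lstsq; drops aliased columns. Returns (coef, resid, keep_idx)."""
    keep = list(range(X.shape[1]))
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # greedily drop columns until full rank
        keep = []
        for j in range(X.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(X[:, trial]) == len(trial):
                keep.append(j)
        warnings.warn(f"design rank-deficient; dropped columns {sorted(set(range(X.shape[1])) - set(keep))}")
    Xk = X[:, keep]
    coef, *_ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ coef
    return coef, resid, keep


def _design_matrix(df: pd.DataFrame, extra: list[str] | None) -> np.ndarray:
    age = df["age"].to_numpy(float)
    sex = df["sex"].to_numpy(float)
    array = df["array"].to_numpy(float)
    cols = [
        np.ones(len(df)),
        age,
        age**2,
        array,
        sex,
        sex * age,
        sex * age**2,
        sex * array,
    ]
    if extra:
        for c in extra:
            cols.append(df[c].to_numpy(float))
    return np.column_stack(cols)


def adjust_ltl(cohort: pd.DataFrame, extra_covariates: list[str] | None = None) -> pd.Series:
    """Residualize LTL on age, age^2, array, sex and sex interactions.

    Optionally removes additional covariates (e.g. blood counts).  Residuals
    are re-standardized to unit variance; rows with any missing design value
    get NaN.
    """
    needed = CORE_COLUMNS + (extra_covariates or [])
    complete = cohort[needed].notna().all(axis=1)
    sub = cohort.loc[complete]
    X = _design_matrix(sub, extra_covariates)
    y = sub["ltl"].to_numpy(float)
    _, resid, _ = _ols(X, y)
    sd = resid.std(ddof=0)
    if sd > 0:
        resid = resid / sd
    out = pd.Series(np.nan, index=cohort.index, name="ltl_adj")
    out.loc[complete] = resid
    return out


def regress_single_trait(
    adjusted_ltl: pd.Series, trait: pd.Series, trait_id: str = "trait",
    covariates: pd.DataFrame | None = None, min_n: int = 10,
) -> RegressionResult:
    """OLS of adjusted LTL on one scaled trait (complete cases).

    The trait is standardized to zero mean / unit variance on the analysis
    sample, so the slope is in SD_LTL per SD_trait.  Small-sample p-values
    (n <= 200) use the exact t-distribution, larger samples the normal
    approximation.
    """
    df = pd.DataFrame({"y": adjusted_ltl, "x": trait})
    if covariates is not None:
        df = pd.concat([df, covariates], axis=1)
    df = df.dropna()
    n = len(df)
    if n < min_n:
        return RegressionResult(trait_id, np.nan, np.nan, np.nan, n, usable=False)
    x = df["x"].to_numpy(float)
    xs = x.std(ddof=0)
    if xs == 0:
        return RegressionResult(trait_id, np.nan, np.nan, np.nan, n, usable=False)
    x = (x - x.mean()) / xs
    cols = [np.ones(n), x]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(df[c].to_numpy(float))
    X = np.column_stack(cols)
    y = df["y"].to_numpy(float)
    coef, resid, keep = _ols(X, y)
    dof = n - len(keep)
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X[:, keep].T @ X[:, keep])
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(coef[1])
    t = beta / se
    if n > 200:
        p = 2.0 * stats.norm.sf(abs(t))
    else:
        p = 2.0 * stats.t.sf(abs(t), dof)
    return RegressionResult(trait_id, beta, se, float(p), n)


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Welch two-sample t-test (Satterthwaite df), two-sided."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _one_se_lambda(alphas: np.ndarray, cv_mse: np.ndarray) -> float:
    """Largest penalty whose mean CV error is within one SE of the minimum."""
    mean = cv_mse.mean(axis=1)
    se = cv_mse.std(axis=1, ddof=1) / np.sqrt(cv_mse.shape[1])
    i_min = int(np.argmin(mean))
    cutoff = mean[i_min] + se[i_min]
    ok = np.nonzero(mean <= cutoff)[0]
    return float(alphas[ok].max()) if len(ok) else float(alphas[i_min])


def lasso_stability(
    cohort: pd.DataFrame,
    candidate_traits: list[str],
    n_fits: int = 50,
    freq_cut: float = 0.95,
    n_folds: int = 10,
    seed: int | None = 0,
    outcome: str = "ltl",
) -> LassoSelection:
    """Stability selection with one-SE-rule cross-validated Lasso.

    Runs ``n_fits`` cross-validated Lasso fits of (unadjusted) LTL on the
    standardized complete-case candidate matrix, reseeding the fold
    assignment each time; a trait counts as selected in a fit when its
    coefficient at the one-SE lambda is nonzero.  Traits selected in at
    least ``freq_cut`` of fits are returned, with the variance explained
    by a joint OLS refit on the selection.
    """
    cols = [outcome] + list(candidate_traits)
    data = cohort[cols].dropna()
    if data.empty:
        raise ValueError("complete-case submatrix is empty")
    y = data[outcome].to_numpy(float)
    y = y - y.mean()
    X = data[candidate_traits].to_numpy(float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    n = len(y)

    rng = np.random.default_rng(seed)
    alphas, _, _ = lasso_path(X, y, alphas=100)
    counts = np.zeros(len(candidate_traits))
    for _ in range(n_fits):
        folds = rng.integers(0, n_folds, size=n)
        cv_mse = np.empty((len(alphas), n_folds))
        for f in range(n_folds):
            tr, te = folds != f, folds == f
            _, coefs, _ = lasso_path(X[tr], y[tr], alphas=alphas)
            pred = X[te] @ coefs + y[tr].mean()
            cv_mse[:, f] = ((y[te][:, None] - pred) ** 2).mean(axis=0)
        lam = _one_se_lambda(alphas, cv_mse)
        _, coefs, _ = lasso_path(X, y, alphas=[lam])
        counts += (np.abs(coefs[:, 0]) > 1e-12).astype(float)

    freq = counts / n_fits
    frequencies = dict(zip(candidate_traits, freq))
    if freq_cut > 0:
        selected = [t for t, f in frequencies.items() if f >= freq_cut]
    else:
        selected = [t for t, f in frequencies.items() if f > 0]

    if selected:
        idx = [candidate_traits.index(t) for t in selected]
        Xs = np.column_stack([np.ones(n), X[:, idx]])
        coef, *_ = np.linalg.lstsq(Xs, y, rcond=None)
        resid = y - Xs @ coef
        r2 = 1.0 - resid.var() / y.var()
    else:
        r2 = 0.0
    return LassoSelection(selected, frequencies, float(r2), n_fits, freq_cut)


def effective_tests(corr: np.ndarray, variance_fraction: float = 0.995) -> int:
    """Effective number of independent tests from a correlation matrix.

    Smallest k such that the k largest eigenvalues sum to at least
    ``variance_fraction`` of the trace.  Negative eigenvalues (possible
    with pairwise-complete estimation) are clipped to zero with a warning.
    """
    corr = np.asarray(corr, dtype=float)
    corr = 0.5 * (corr + corr.T)
    eig = np.linalg.eigvalsh(corr)[::-1]
    if eig[-1] < -1e-10:
        warnings.warn("correlation matrix not PSD; clipping negative eigenvalues")
    eig = np.clip(eig, 0.0, None)
    target = variance_fraction * corr.shape[0]
    csum = np.cumsum(eig)
    return int(np.searchsorted(csum, target - 1e-12) + 1)


def pairwise_correlation(traits: pd.DataFrame) -> np.ndarray:
    """Pairwise-complete Pearson correlation matrix of trait columns."""
    return traits.corr(method="pearson", min_periods=2).to_numpy()


def phase_durations(age, age_first_birth, age_menopause, n_live_births,
                    menopause_status) -> tuple[float, float, float] | None:
    """Per-woman years spent in each reproductive phase.

    Phase 1: from birth to first live birth (or current age if nulliparous);
    phase 2: premenopausal years after first birth; phase 3: postmenopausal
    years.  Phases 2/3 are zero for nulliparous and premenopausal women
    respectively.  Returns None when the configuration is inconsistent
    (negative duration), signalling exclusion.
    """
    parous = n_live_births is not None and n_live_births > 0
    post = bool(menopause_status)
    if not parous:
        t1 = min(age, age_menopause) if post and age_menopause is not None else age
        t2 = 0.0
        t3 = max(age - age_menopause, 0.0) if post and age_menopause is not None else 0.0
    else:
        if age_first_birth is None or not np.isfinite(age_first_birth):
            return None
        if post:
            if age_menopause is None or not np.isfinite(age_menopause):
                return None
            if age_first_birth > age_menopause:  # first child post-menopause
                return None
            t1 = age_first_birth
            t2 = age_menopause - age_first_birth
            t3 = age - age_menopause
        else:
            t1 = age_first_birth
            t2 = age - age_first_birth
            t3 = 0.0
    if t1 < 0 or t2 < 0 or t3 < 0:
        return None
    return float(t1), float(t2), float(t3)


def reproductive_phases(cohort: pd.DataFrame) -> PhaseModelResult:
    """Joint regression of female LTL on reproductive-phase durations.

    Model: LTL ~ t1 + t2 + t3 + parity indicator + menopause indicator.
    Participants with inconsistent timing (e.g. first birth after
    menopause) or missing required fields are excluded and counted.
    """
    # convention: sex == 0 is female; an explicit 'female' flag overrides
    if "female" in cohort.columns:
        females = cohort.loc[cohort["female"] == 1]
    else:
        females = cohort.loc[cohort["sex"] == 0]
    age = females["age"].to_numpy(float)
    ltl = females["ltl"].to_numpy(float)
    afb = females.get("age_first_birth", pd.Series(np.nan, index=females.index)).to_numpy(float)
    amp = females.get("age_menopause", pd.Series(np.nan, index=females.index)).to_numpy(float)
    nlb = females.get("n_live_births", pd.Series(np.nan, index=females.index)).to_numpy(float)
    status = females.get("menopause_status", pd.Series(np.nan, index=females.index)).to_numpy(float)

    usable = np.isfinite(ltl) & np.isfinite(age) & np.isfinite(status) & np.isfinite(nlb)
    post = status == 1
    parous = nlb > 0
    usable &= ~(post & ~np.isfinite(amp))
    usable &= ~(parous & ~np.isfinite(afb))
    usable &= ~(parous & post & (afb > amp))  # first child post-menopause

    t1 = np.where(parous, afb, np.where(post, amp, age))
    t1 = np.minimum(t1, age)
    t2 = np.where(parous, np.where(post, amp, age) - afb, 0.0)
    t3 = np.where(post, age - amp, 0.0)
    with np.errstate(invalid="ignore"):
        usable &= ~(np.nan_to_num(t1, nan=-1) < 0)
        usable &= ~(np.nan_to_num(t2, nan=-1) < 0) | ~parous
        usable &= ~(np.nan_to_num(t3, nan=-1) < 0) | ~post
    excluded = int((~usable).sum())
    if usable.sum() < 10:
        raise ValueError("too few usable female participants")

    arr = np.column_stack([t1, t2, t3, parous.astype(float), post.astype(float)])[usable]
    X = np.column_stack([np.ones(len(arr)), arr])
    y = ltl[usable]
    coef, resid, keep = _ols(X, y)
    dof = len(arr) - len(keep)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X[:, keep].T @ X[:, keep])
    se = np.sqrt(np.diag(cov))

    def p_of(i):
        t = coef[i] / se[i]
        return float(2.0 * stats.norm.sf(abs(t))) if len(arr) > 200 else float(
            2.0 * stats.t.sf(abs(t), dof)
        )

    return PhaseModelResult(
        beta_phase1=float(coef[1]), beta_phase2=float(coef[2]), beta_phase3=float(coef[3]),
        se_phase1=float(se[1]), se_phase2=float(se[2]), se_phase3=float(se[3]),
        p_phase1=p_of(1), p_phase2=p_of(2), p_phase3=p_of(3),
        parity_coef=float(coef[4]), menopause_coef=float(coef[5]),
        n_used=len(arr), n_excluded=excluded,
    )


def statin_adjust(lipid_values, medicated, lipid_kind: str) -> np.ndarray:
    """Add back the average simvastatin effect for medicated participants.

    Offsets (mmol/L): TC +1.6, LDL +1.4, TG +0.4, HDL -0.1.
    """
    if lipid_kind not in STATIN_OFFSETS:
        raise ValueError(f"unknown lipid kind {lipid_kind!r}; expected one of {sorted(STATIN_OFFSETS)}")
    v = np.asarray(lipid_values, dtype=float).copy()
    flag = np.asarray(medicated, dtype=bool)
    v[flag] += STATIN_OFFSETS[lipid_kind]
    return v


def compare_effects(beta_x: float, se_x: float, beta_y: float, se_y: float) -> tuple[float, float]:
    """Z-test for a difference between two uncorrelated effect estimates."""
    if se_x <= 0 or se_y <= 0:
        raise ValueError("standard errors must be positive")
    t = (beta_x - beta_y) / np.sqrt(se_x**2 + se_y**2)
    return float(t), float(2.0 * stats.norm.sf(abs(t)))
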