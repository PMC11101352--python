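"""Univariable two-sample Mendelian randomization estimators.

All estimators consume an aligned per-instrument table with columns
``BETA_exp, SE_exp, BETA_out, SE_out`` (the output of
:func:`telomr.sumstats.align_pair`, possibly filtered).  The inverse
variance weighted (IVW) and Egger fits use a multiplicative
random-effects model: standard errors are inflated by
``sqrt(max(1, Q/df))`` unless ``fixed_effect=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MREstimate",
    "HeterogeneityStats",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "mode_estimator",
    "bidirectional_mr",
]

REQUIRED_COLUMNS = ("BETA_exp", "SE_exp", "BETA_out", "SE_out")


@dataclass
class MREstimate:
    """A causal-effect estimate from one MR method."""

    method: str
    alpha: float
    se: float
    pvalue: float
    n_iv: int
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None


@dataclass
class HeterogeneityStats:
    """Cochran's Q heterogeneity across instruments."""

    Q: float
    df: int
    pvalue: float


def _check(table: pd.DataFrame, min_iv: int, method: str) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"{method}: missing column {col}")
    if len(table) < min_iv:
        raise ValueError(f"{method} requires >= {min_iv} instruments, got {len(table)}")
    if (table["SE_out"] <= 0).any() or (table["SE_exp"] <= 0).any():
        raise ValueError(f"{method}: standard errors must be positive")
    return table


def _norm_p(z) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> MREstimate:
    """Single-instrument ratio estimate with first-order SE."""
    if beta_exp == 0:
        raise ValueError("wald_ratio undefined for beta_exp = 0")
    alpha = beta_out / beta_exp
    se = abs(se_out / beta_exp)
    return MREstimate("wald", alpha, se, _norm_p(alpha / se), n_iv=1)


def ivw(
    table: pd.DataFrame, fixed_effect: bool = False
) -> tuple[MREstimate, HeterogeneityStats]:
    """Inverse variance weighted estimate.

    Weighted zero-intercept regression of outcome on exposure effects with
    weights ``1/SE_out^2``; equivalently the weighted mean of Wald ratios.
    """
    _check(table, 2, "ivw")
    bx = table["BETA_exp"].to_numpy(dtype=float)
    by = table["BETA_out"].to_numpy(dtype=float)
    w = 1.0 / table["SE_out"].to_numpy(dtype=float) ** 2
    sxx = float(np.sum(w * bx * bx))
    alpha = float(np.sum(w * bx * by)) / sxx
    q = float(np.sum(w * (by - alpha * bx) ** 2))
    df = len(table) - 1
    scale = 1.0 if fixed_effect else np.sqrt(max(1.0, q / df))
    se = scale / np.sqrt(sxx)
    het = HeterogeneityStats(q, df, float(stats.chi2.sf(q, df)))
    return MREstimate("ivw", alpha, se, _norm_p(alpha / se), len(table)), het


def egger(
    table: pd.DataFrame, fixed_effect: bool = False
) -> tuple[MREstimate, HeterogeneityStats]:
    """MR-Egger: weighted regression with intercept.

    Rows are oriented so exposure effects are non-negative before the fit
    (required for intercept identifiability); the intercept estimates
    average directional pleiotropy, the slope a pleiotropy-adjusted effect.
    """
    _check(table, 3, "egger")
    sign = np.sign(table["BETA_exp"].to_numpy(dtype=float))
    sign[sign == 0] = 1.0
    bx = table["BETA_exp"].to_numpy(dtype=float) * sign
    by = table["BETA_out"].to_numpy(dtype=float) * sign
    w = 1.0 / table["SE_out"].to_numpy(dtype=float) ** 2

    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    df = len(table) - 2
    scale2 = 1.0 if fixed_effect else max(1.0, q / df)
    cov = scale2 * np.linalg.inv(xtwx)
    intercept, alpha = float(coef[0]), float(coef[1])
    se_i, se_a = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    het = HeterogeneityStats(q, df, float(stats.chi2.sf(q, df)))
    est = MREstimate(
        "egger",
        alpha,
        se_a,
        _norm_p(alpha / se_a),
        len(table),
        egger_intercept=intercept,
        intercept_se=se_i,
        intercept_p=_norm_p(intercept / se_i),
    )
    return est, het


def _ratios_and_weights(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    bx = table["BETA_exp"].to_numpy(dtype=float)
    by = table["BETA_out"].to_numpy(dtype=float)
    se_out = table["SE_out"].to_numpy(dtype=float)
    if np.any(bx == 0):
        raise ValueError("ratio-based estimators require nonzero exposure effects")
    ratios = by / bx
    se_ratio = np.abs(se_out / bx)  # first-order delta method
    return ratios, 1.0 / se_ratio**2


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    return float(np.interp(0.5, cum, v))


def weighted_median(
    table: pd.DataFrame, n_boot: int = 1000, seed: int | None = 0
) -> MREstimate:
    """Weighted median of per-instrument Wald ratios.

    Consistent when instruments contributing at least half the weight are
    valid.  SE by seeded parametric bootstrap on the instrument effects.
    """
    _check(table, 3, "weighted_median")
    ratios, weights = _ratios_and_weights(table)
    alpha = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    bx = table["BETA_exp"].to_numpy(dtype=float)
    by = table["BETA_out"].to_numpy(dtype=float)
    sx = table["SE_exp"].to_numpy(dtype=float)
    sy = table["SE_out"].to_numpy(dtype=float)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + rng.standard_normal(len(bx)) * sx
        bys = by + rng.standard_normal(len(by)) * sy
        ok = bxs != 0
        r = bys[ok] / bxs[ok]
        w = (np.abs(bxs[ok]) / sy[ok]) ** 2
        boots[b] = _weighted_median(r, w)
    se = float(np.std(boots, ddof=1))
    if se == 0:
        se = np.finfo(float).tiny
    return MREstimate("weighted_median", alpha, se, _norm_p(alpha / se), len(table))


def _mode_point(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    # MAD-based bandwidth rule on the ratio estimates
    mad = np.median(np.abs(ratios - np.median(ratios))) / stats.norm.ppf(0.75)
    s = 0.9 * min(np.std(ratios, ddof=1) if len(ratios) > 1 else mad, mad)
    if s <= 0:
        # degenerate spread: heaviest point mass wins
        uniq = {}
        for r, w in zip(ratios, weights):
            uniq[r] = uniq.get(r, 0.0) + w
        return float(max(uniq, key=uniq.get))
    h = bandwidth_factor * s * len(ratios) ** (-0.2)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    dens = np.zeros_like(grid)
    wn = weights / weights.sum()
    for r, w in zip(ratios, wn):
        dens += w * np.exp(-0.5 * ((grid - r) / h) ** 2)
    return float(grid[np.argmax(dens)])


def mode_estimator(
    table: pd.DataFrame,
    weighted: bool = True,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> MREstimate:
    """Mode of the kernel-smoothed Wald-ratio density (simple or weighted).

    Consistent when the largest group of instruments sharing a ratio is
    valid (ZEMPA).  SE by seeded parametric bootstrap.
    """
    _check(table, 3, "mode")
    ratios, ivw_weights = _ratios_and_weights(table)
    weights = ivw_weights if weighted else np.ones_like(ratios)
    alpha = _mode_point(ratios, weights, bandwidth_factor)

    rng = np.random.default_rng(seed)
    bx = table["BETA_exp"].to_numpy(dtype=float)
    by = table["BETA_out"].to_numpy(dtype=float)
    sx = table["SE_exp"].to_numpy(dtype=float)
    sy = table["SE_out"].to_numpy(dtype=float)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + rng.standard_normal(len(bx)) * sx
        bys = by + rng.standard_normal(len(by)) * sy
        ok = bxs != 0
        r = bys[ok] / bxs[ok]
        w = (np.abs(bxs[ok]) / sy[ok]) ** 2 if weighted else np.ones(ok.sum())
        boots[b] = _mode_point(r, w, bandwidth_factor)
    se = float(np.std(boots, ddof=1))
    if se == 0:
        se = np.finfo(float).tiny
    method = "weighted_mode" if weighted else "simple_mode"
    return MREstimate(method, alpha, se, _norm_p(alpha / se), len(table))


def all_estimators(
    table: pd.DataFrame, seed: int | None = 0, n_boot: int = 1000
) -> dict[str, MREstimate]:
    """Run IVW plus the four sensitivity estimators on one instrument table."""
    out: dict[str, MREstimate] = {}
    est, het = ivw(table)
    out["ivw"] = est
    out["_ivw_het"] = het  # type: ignore[assignment]
    if len(table) >= 3:
        e, _ = egger(table)
        out["egger"] = e
        out["weighted_median"] = weighted_median(table, n_boot=n_boot, seed=seed)
        out["simple_mode"] = mode_estimator(table, weighted=False, n_boot=n_boot, seed=seed)
        out["weighted_mode"] = mode_estimator(table, weighted=True, n_boot=n_boot, seed=seed)
    return out


def bidirectional_mr(
    ltl_ss,
    trait_ss,
    panel,
    ld,
    gw_threshold: float = 5e-8,
    af_max_diff: float = 0.05,
    steiger_threshold: float = -1.96,
    ltl_masks=None,
    trait_masks=None,
    seed: int | None = 0,
    n_boot: int = 200,
):
    """Run the full instrument-selection chain and estimators both ways.

    Forward: LTL as exposure, trait as outcome; reverse: trait as exposure.
    A direction with fewer than two surviving instruments is reported as
    ``None``.  Returns ``{"forward": dict | None, "reverse": dict | None}``
    where each dict carries the estimators' results and the instrument count.
    """
    from telomr import instruments as iv
    from telomr.sumstats import align_pair, harmonize

    ltl_h = harmonize(ltl_ss, panel)
    trait_h = harmonize(trait_ss, panel)
    if ltl_masks is None:
        ltl_masks = [iv.HBB_MASK, iv.HLA_MASK]
    if trait_masks is None:
        trait_masks = [iv.HLA_MASK]

    results = {}
    for tag, (exp, out, masks) in {
        "forward": (ltl_h, trait_h, ltl_masks),
        "reverse": (trait_h, ltl_h, trait_masks),
    }.items():
        ivs = iv.clump(exp, ld, gw_threshold=gw_threshold)
        ivs = iv.apply_region_masks(ivs, masks)
        if len(ivs) < 2:
            results[tag] = None
            continue
        pair = align_pair(exp, out)
        pair = pair.loc[pair["SNP"].isin(ivs.variant_ids)].reset_index(drop=True)
        pair = iv.af_concordance_filter(pair, max_diff=af_max_diff)
        pair = iv.steiger_filter(pair, threshold=steiger_threshold)
        if len(pair) < 2:
            results[tag] = None
            continue
        ests = all_estimators(pair, seed=seed, n_boot=n_boot)
        ests["n_iv"] = len(pair)  # type: ignore[assignment]
        results[tag] = ests
    return results


def results_table(results: dict, exposure: str, outcome: str) -> pd.DataFrame:
    """Tidy one direction's estimator dict into the results TSV layout."""
    rows = []
    het = results.get("_ivw_het")
    for method, est in results.items():
        if method.startswith("_") or not isinstance(est, MREstimate):
            continue
        rows.append(
            {
                "exposure": exposure,
                "outcome": outcome,
                "method": est.method,
                "n_iv": est.n_iv,
                "alpha": est.alpha,
                "se": est.se,
                "p": est.pvalue,
                "Q": het.Q if (het and method == "ivw") else np.nan,
                "Q_df": het.df if (het and method == "ivw") else np.nan,
                "Q_p": het.pvalue if (het and method == "ivw") else np.nan,
                "egger_intercept": est.egger_intercept,
                "intercept_p": est.intercept_p,
            }
        )
    return pd.DataFrame(rows)
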