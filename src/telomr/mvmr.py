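"""Multivariable MR, conditional instrument strength, and mediation.

The mediation decomposition follows the two-exposure design: the total
effect of the exposure on the outcome comes from univariable IVW on the
exposure's instruments; the direct effect from a two-exposure MVMR of the
outcome on exposure and mediator; the indirect effect either by
difference (total - direct, exact by construction) or by product
(exposure-on-mediator IVW times the MVMR mediator-on-outcome effect),
with a regression-dilution correction.  Mediation-proportion confidence
intervals come from 10,000 simulated ratios of normal draws, upper bound
capped at 100%.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from telomr import instruments as iv
from telomr.mr import MREstimate, HeterogeneityStats, ivw
from telomr.sumstats import SummaryStats, align_pair, harmonize

logger = logging.getLogger(__name__)


@dataclass
class MVMRResult:
    """Direct (conditional) effects from a multivariable MR fit."""

    exposure_ids: list[str]
    outcome_id: str
    theta: np.ndarray
    se: np.ndarray
    pvalue: np.ndarray
    conditional_f: np.ndarray
    Q: float
    Q_df: int
    Q_pvalue: float
    n_iv: int

    def effect(self, exposure_id: str) -> tuple[float, float, float]:
        j = self.exposure_ids.index(exposure_id)
        return float(self.theta[j]), float(self.se[j]), float(self.pvalue[j])


@dataclass
class MediationResult:
    """Total/direct/indirect decomposition with mediation proportion."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    alpha_total: float
    se_total: float
    alpha_direct: float
    se_direct: float
    alpha_indirect_product: float
    se_indirect_product: float
    alpha_indirect_difference: float
    p_m: float
    p_m_ci: tuple[float, float]
    n_iv_exposure: int
    n_iv_mediator: int
    cond_f: dict = field(default_factory=dict)
    n_sim: int = 10000
    seed: int | None = None
    computable: bool = True
    unstable: bool = False


def _mvmr_design(table: pd.DataFrame, exposure_ids: list[str]):
    X = np.column_stack([table[f"BETA_{e}"].to_numpy(dtype=float) for e in exposure_ids])
    y = table["BETA_out"].to_numpy(dtype=float)
    w = 1.0 / table["SE_out"].to_numpy(dtype=float) ** 2
    return X, y, w


def mvmr_fit(table: pd.DataFrame, exposure_ids: list[str], outcome_id: str = "outcome",
             fixed_effect: bool = False) -> MVMRResult:
    """Weighted zero-intercept multiple regression of outcome effects on the
    exposure-effect matrix (weights ``1/SE_out^2``).

    ``table`` needs columns ``BETA_<exposure>`` and ``SE_<exposure>`` per
    exposure plus ``BETA_out, SE_out``.  SEs are inflated by
    ``sqrt(max(1, Q/df))`` with ``df = n_iv - n_exposures`` unless
    ``fixed_effect``.  Raises on a rank-deficient exposure matrix.
    """
    k = len(exposure_ids)
    if len(table) < k + 1:
        raise ValueError(f"MVMR needs > {k} instruments, got {len(table)}")
    X, y, w = _mvmr_design(table, exposure_ids)
    if np.linalg.matrix_rank(X) < k:
        raise ValueError(f"collinear exposure effects among {exposure_ids}")
    xtwx = X.T @ (w[:, None] * X)
    theta = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ theta
    q = float(np.sum(w * resid**2))
    df = len(table) - k
    scale2 = 1.0 if fixed_effect else max(1.0, q / df)
    cov = scale2 * np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov))
    p = 2.0 * stats.norm.sf(np.abs(theta / se))
    cond_f = np.array([conditional_f(table, exposure_ids, j) for j in range(k)])
    return MVMRResult(
        exposure_ids=list(exposure_ids),
        outcome_id=outcome_id,
        theta=theta,
        se=se,
        pvalue=p,
        conditional_f=cond_f,
        Q=q,
        Q_df=df,
        Q_pvalue=float(stats.chi2.sf(q, df)),
        n_iv=len(table),
    )


def conditional_f(table: pd.DataFrame, exposure_ids: list[str], j: int) -> float:
    """Instrument strength of exposure ``j`` conditional on the others.

    The exposure-j effects are regressed (weights ``1/SE_j^2``) on the other
    exposures' effects; the weighted residual chi-square ``Q_j`` gives
    ``F = max(Q_j - df, 0) / df``.  With a single exposure this reduces to
    the mean F-statistic ``mean((beta/se)^2)``.
    """
    bj = table[f"BETA_{exposure_ids[j]}"].to_numpy(dtype=float)
    sj = table[f"SE_{exposure_ids[j]}"].to_numpy(dtype=float)
    w = 1.0 / sj**2
    others = [e for i, e in enumerate(exposure_ids) if i != j]
    if not others:
        return float(np.mean((bj / sj) ** 2))
    Z = np.column_stack([table[f"BETA_{e}"].to_numpy(dtype=float) for e in others])
    zwz = Z.T @ (w[:, None] * Z)
    try:
        gamma = np.linalg.solve(zwz, Z.T @ (w * bj))
        resid = bj - Z @ gamma
    except np.linalg.LinAlgError:
        resid = bj
    q_j = float(np.sum(w * resid**2))
    df = len(table) - len(others)
    return max(q_j - df, 0.0) / df


def dilution_correct(alpha: float, beta_exp: np.ndarray, se_exp: np.ndarray,
                     eps: float = 1e-12) -> tuple[float, float]:
    """Correct an estimate for regression dilution from noisy exposure betas.

    Divides by the attenuation factor
    ``lambda = var_signal / (var_signal + mean(se_exp^2))`` with
    ``var_signal = max(var(beta_exp) - mean(se_exp^2), eps)``.
    Returns ``(corrected, lambda)``; when the signal variance sits at the
    floor the correction is capped (lambda reported as computed).
    """
    beta_exp = np.asarray(beta_exp, dtype=float)
    se_exp = np.asarray(se_exp, dtype=float)
    noise = float(np.mean(se_exp**2))
    total_var = float(np.var(beta_exp, ddof=1)) if len(beta_exp) > 1 else noise
    var_signal = max(total_var - noise, eps)
    lam = var_signal / (var_signal + noise)
    if var_signal <= eps:
        logger.warning("dilution_correct: signal variance at floor; correction capped")
        lam = max(lam, 0.5)  # cap the correction at 2x
    return alpha / lam, lam


def mediation_ci(
    alpha_indirect: float,
    se_indirect: float,
    alpha_total: float,
    se_total: float,
    n_sim: int = 10000,
    seed: int | None = None,
) -> tuple[float, float, float, bool]:
    """Mediation proportion (%) with a simulated 95% confidence interval.

    Draws ``n_sim`` pairs from N(alpha_indirect, se_indirect) and
    N(alpha_total, se_total), forms the ratio per draw, and takes the
    2.5th/97.5th percentiles; the upper bound (and the point estimate) are
    capped at 100%.  Returns ``(p_m, lower, upper, unstable)`` where
    ``unstable`` flags a total effect indistinguishable from zero.
    """
    if se_indirect <= 0 or se_total <= 0:
        raise ValueError("standard errors must be positive")
    rng = np.random.default_rng(seed)
    sim_ind = rng.normal(alpha_indirect, se_indirect, size=n_sim)
    sim_tot = rng.normal(alpha_total, se_total, size=n_sim)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = 100.0 * sim_ind / sim_tot
    lower, upper = np.percentile(ratios, [2.5, 97.5])
    upper = min(float(upper), 100.0)
    p_m = min(100.0 * alpha_indirect / alpha_total, 100.0) if alpha_total != 0 else np.nan
    unstable = abs(alpha_total) < 1.96 * se_total
    return float(p_m), float(lower), float(upper), unstable


def _filtered_pair(exposure, outcome, snps, af_max_diff, steiger_threshold):
    pair = align_pair(exposure, outcome)
    pair = pair.loc[pair["SNP"].isin(snps)].reset_index(drop=True)
    pair = iv.af_concordance_filter(pair, max_diff=af_max_diff)
    pair = iv.steiger_filter(pair, threshold=steiger_threshold)
    return pair


def mediate(
    exposure_ss: SummaryStats,
    mediator_ss: SummaryStats,
    outcome_ss: SummaryStats,
    panel,
    ld,
    n_sim: int = 10000,
    seed: int | None = 0,
    gw_threshold: float = 5e-8,
    af_max_diff: float = 0.05,
    steiger_threshold: float = -1.96,
    harmonized: bool = False,
) -> MediationResult:
    """Two-exposure MVMR mediation of exposure -> outcome through a mediator.

    Instruments come from the two-phase clump (exposure priority); Steiger
    filtering is applied to exposure instruments against both outcome and
    mediator, and to mediator instruments against the outcome.  Stages with
    fewer than two instruments yield ``computable=False``.
    """
    if not harmonized:
        exposure_ss = harmonize(exposure_ss, panel)
        mediator_ss = harmonize(mediator_ss, panel)
        outcome_ss = harmonize(outcome_ss, panel)

    exp_ivs, med_ivs = iv.two_phase_mediation_clump(
        exposure_ss, mediator_ss, ld, gw_threshold=gw_threshold
    )

    def not_computable() -> MediationResult:
        return MediationResult(
            exposure_ss.trait_id, mediator_ss.trait_id, outcome_ss.trait_id,
            *(np.nan,) * 8, (np.nan, np.nan), len(exp_ivs), len(med_ivs),
            n_sim=n_sim, seed=seed, computable=False,
        )

    if len(exp_ivs) < 2 or len(med_ivs) < 2:
        return not_computable()

    # Steiger: exposure IVs vs outcome and vs mediator; mediator IVs vs outcome
    exp_vs_out = _filtered_pair(
        exposure_ss, outcome_ss, exp_ivs.variant_ids, af_max_diff, steiger_threshold
    )
    exp_vs_med = _filtered_pair(
        exposure_ss, mediator_ss, exp_ivs.variant_ids, af_max_diff, steiger_threshold
    )
    exp_keep = set(exp_vs_out["SNP"]) & set(exp_vs_med["SNP"])
    med_vs_out = _filtered_pair(
        mediator_ss, outcome_ss, med_ivs.variant_ids, af_max_diff, steiger_threshold
    )
    med_keep = set(med_vs_out["SNP"])
    if len(exp_keep) < 2 or len(med_keep) < 2:
        return not_computable()

    # total effect: univariable IVW of exposure on outcome, exposure IVs only
    total_tbl = exp_vs_out.loc[exp_vs_out["SNP"].isin(exp_keep)]
    total_est, _ = ivw(total_tbl)

    # exposure -> mediator IVW for the product method
    em_tbl = exp_vs_med.loc[exp_vs_med["SNP"].isin(exp_keep)]
    em_est, _ = ivw(em_tbl)

    # MVMR on pooled instruments
    all_snps = sorted(exp_keep | med_keep)
    e_tbl = exposure_ss.table.set_index("SNP")
    m_tbl = mediator_ss.table.set_index("SNP")
    o_tbl = outcome_ss.table.set_index("SNP")
    shared = [s for s in all_snps if s in e_tbl.index and s in m_tbl.index and s in o_tbl.index]
    mv = pd.DataFrame(
        {
            "SNP": shared,
            f"BETA_{exposure_ss.trait_id}": e_tbl.loc[shared, "BETA"].to_numpy(),
            f"SE_{exposure_ss.trait_id}": e_tbl.loc[shared, "SE"].to_numpy(),
            f"BETA_{mediator_ss.trait_id}": m_tbl.loc[shared, "BETA"].to_numpy(),
            f"SE_{mediator_ss.trait_id}": m_tbl.loc[shared, "SE"].to_numpy(),
            "BETA_out": o_tbl.loc[shared, "BETA"].to_numpy(),
            "SE_out": o_tbl.loc[shared, "SE"].to_numpy(),
        }
    )
    if len(mv) < 3:
        return not_computable()
    fit = mvmr_fit(mv, [exposure_ss.trait_id, mediator_ss.trait_id], outcome_ss.trait_id)
    direct, se_direct, _ = fit.effect(exposure_ss.trait_id)
    theta_m, se_theta_m, _ = fit.effect(mediator_ss.trait_id)

    indirect_diff = total_est.alpha - direct
    product_raw = em_est.alpha * theta_m
    # first-order delta-method SE for the product
    se_product = float(
        np.sqrt(em_est.alpha**2 * se_theta_m**2 + theta_m**2 * em_est.se**2)
    )
    # regression dilution correction on the product estimate
    product, lam = dilution_correct(
        product_raw,
        em_tbl["BETA_exp"].to_numpy(float),
        em_tbl["SE_exp"].to_numpy(float),
    )
    se_product_corr = se_product / lam

    p_m, lo, hi, unstable = mediation_ci(
        product, se_product_corr, total_est.alpha, total_est.se, n_sim=n_sim, seed=seed
    )
    return MediationResult(
        exposure_id=exposure_ss.trait_id,
        mediator_id=mediator_ss.trait_id,
        outcome_id=outcome_ss.trait_id,
        alpha_total=total_est.alpha,
        se_total=total_est.se,
        alpha_direct=direct,
        se_direct=se_direct,
        alpha_indirect_product=product,
        se_indirect_product=se_product_corr,
        alpha_indirect_difference=indirect_diff,
        p_m=p_m,
        p_m_ci=(lo, hi),
        n_iv_exposure=len(exp_keep),
        n_iv_mediator=len(med_keep),
        cond_f={
            exposure_ss.trait_id: float(fit.conditional_f[0]),
            mediator_ss.trait_id: float(fit.conditional_f[1]),
        },
        n_sim=n_sim,
        seed=seed,
        unstable=unstable,
    )


def enumerate_mediation_pairs(
    exposures: list[str], outcomes: list[str]
) -> list[tuple[str, str]]:
    """All exposure-outcome pairs for the mediation design, excluding any
    pair where the same trait appears on both sides."""
    return [(e, o) for e, o in itertools.product(exposures, outcomes) if e != o]


@dataclass
class CausalNetwork:
    """Directed MVMR effect network over a trait set."""

    nodes: list[str]
    edges: pd.DataFrame  # source, target, theta, se, p, tier


def build_network(
    ss_map: dict[str, SummaryStats],
    panel,
    ld,
    nominal_p: float = 0.05,
    strict_p: float = 0.05 / 141,
    harmonized: bool = False,
    gw_threshold: float = 5e-8,
) -> CausalNetwork:
    """Build a causal network by one MVMR pass per ordered trait pair.

    For each ordered pair (A -> B), fits an MVMR of B on A with the
    remaining traits as co-exposures using minimum-rank instruments; edges
    retained at nominal significance, tiered at the strict threshold.
    """
    traits = sorted(ss_map)
    if len(traits) < 3:
        raise ValueError("network construction needs at least 3 traits")
    if not harmonized:
        ss_map = {t: harmonize(ss, panel) for t, ss in ss_map.items()}
    rows = []
    for target in traits:
        exposures = [t for t in traits if t != target]
        exp_ss = [ss_map[t] for t in exposures]
        ivset = iv.minrank_clump(exp_ss, ld, gw_threshold=gw_threshold)
        snps = ivset.variant_ids
        if len(snps) < len(exposures) + 1:
            logger.info("network: pair set for outcome %s not computable", target)
            continue
        tbls = {t: ss_map[t].table.set_index("SNP") for t in traits}
        shared = [s for s in snps if all(s in tbls[t].index for t in traits)]
        if len(shared) < len(exposures) + 1:
            continue
        data = {"SNP": shared}
        for t in exposures:
            data[f"BETA_{t}"] = tbls[t].loc[shared, "BETA"].to_numpy()
            data[f"SE_{t}"] = tbls[t].loc[shared, "SE"].to_numpy()
        data["BETA_out"] = tbls[target].loc[shared, "BETA"].to_numpy()
        data["SE_out"] = tbls[target].loc[shared, "SE"].to_numpy()
        try:
            fit = mvmr_fit(pd.DataFrame(data), exposures, target)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.info("network: MVMR for outcome %s failed: %s", target, exc)
            continue
        for j, src in enumerate(exposures):
            p = float(fit.pvalue[j])
            if p < nominal_p:
                rows.append(
                    {
                        "source": src,
                        "target": target,
                        "theta": float(fit.theta[j]),
                        "se": float(fit.se[j]),
                        "p": p,
                        "tier": "strict" if p < strict_p else "nominal",
                    }
                )
    edges = pd.DataFrame(rows, columns=["source", "target", "theta", "se", "p", "tier"])
    return CausalNetwork(nodes=traits, edges=edges)


def mediation_table(results: list[MediationResult]) -> pd.DataFrame:
    """Tidy mediation results into the TSV layout."""
    rows = []
    for r in results:
        rows.append(
            {
                "exposure": r.exposure_id,
                "mediator": r.mediator_id,
                "outcome": r.outcome_id,
                "total": r.alpha_total,
                "total_se": r.se_total,
                "direct": r.alpha_direct,
                "direct_se": r.se_direct,
                "indirect_product": r.alpha_indirect_product,
                "indirect_difference": r.alpha_indirect_difference,
                "P_M": r.p_m,
                "ci_low": r.p_m_ci[0],
                "ci_high": r.p_m_ci[1],
                "n_iv_exposure": r.n_iv_exposure,
                "n_iv_mediator": r.n_iv_mediator,
                "cond_F_exposure": r.cond_f.get(r.exposure_id),
                "cond_F_mediator": r.cond_f.get(r.mediator_id),
                "seed": r.seed,
                "computable": r.computable,
            }
        )
    return pd.DataFrame(rows)
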