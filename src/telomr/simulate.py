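"""Ground-truthed synthetic data for every pipeline stage.

Two generator families:

* GWAS summary-statistic triplets (exposure, mediator, outcome) under the
  linear structural model ``E -> M -> O`` with configurable direct,
  indirect, pleiotropic and reverse-causal paths, block-AR(1) LD, and
  overlapping-sample noise correlation.  The analytic backend samples
  marginal effect estimates directly from their asymptotic distribution;
  the individual-level backend simulates genotypes and regresses, and the
  two agree to Monte-Carlo error.
* An individual-level cohort with age/sex/array structure, planted
  trait-LTL effects, missingness, and female reproductive-phase fields.

Every generator returns its ground truth (a :class:`TruthSet`) so
downstream estimators can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from telomr.instruments import LDMatrix
from telomr.sumstats import ReferencePanel, SummaryStats

# non-palindromic allele pairs only, so harmonization keeps every variant
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]

_BLOCK_SPACING_BP = 1_000_000  # blocks sit beyond the 250 kb clump window
_WITHIN_BLOCK_SPACING_BP = 5_000


@dataclass
class SimulationConfig:
    """Parameters of the structural model and study design."""

    n_snps: int = 300
    n_blocks: int = 30
    within_block_rho: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exp: int = 20_000
    n_med: int = 20_000
    n_out: int = 20_000
    sample_overlap_fraction: float = 0.0
    alpha_EM: float = 0.0
    theta_M: float = 0.0
    theta_direct: float = 0.0
    h2_exp: float = 0.25
    h2_med: float = 0.05
    causal_fraction: float = 0.3
    mediator_snp_fraction: float = 0.1
    pleiotropy_fraction: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    reverse_fraction: float = 0.0
    reverse_effect: float = 0.08
    reverse_leak: float = 0.3
    positive_effects: bool = False  # draw exposure effects > 0 (Egger-style sims)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sample_overlap_fraction", "causal_fraction",
                     "mediator_snp_fraction", "pleiotropy_fraction", "reverse_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("h2_exp", "h2_med"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        for name in ("n_exp", "n_med", "n_out"):
            if getattr(self, name) < 100:
                raise ValueError(f"{name} must be >= 100")
        if self.n_snps % self.n_blocks:
            raise ValueError("n_snps must be a multiple of n_blocks")


@dataclass
class TruthSet:
    """Ground-truth parameters behind one simulated study."""

    snp_effects: pd.DataFrame  # SNP, label, joint effects per trait
    alpha_total: float
    alpha_direct: float
    alpha_indirect: float
    p_m: float  # percent

    def __post_init__(self) -> None:
        if self.alpha_total != 0:
            expect = 100.0 * self.alpha_indirect / self.alpha_total
            assert abs(self.p_m - expect) < 1e-12


@dataclass
class SimulatedStudy:
    exposure: SummaryStats
    mediator: SummaryStats
    outcome: SummaryStats
    panel: ReferencePanel
    ld: LDMatrix
    truth: TruthSet
    cohort: pd.DataFrame | None = None


def simulate_ld(n_blocks: int, block_size: int, rho: float, seed: int | None = None,
                chromosome: int = 1) -> LDMatrix:
    """Block-diagonal LD with AR(1) decay ``rho^|i-j|`` within blocks.

    Blocks are spaced 1 Mb apart (outside the default 250 kb clump window);
    SNPs within a block sit 5 kb apart (inside it).
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    m = n_blocks * block_size
    idx = np.arange(block_size)
    block = rho ** np.abs(idx[:, None] - idx[None, :])
    r = np.zeros((m, m))
    for b in range(n_blocks):
        s = b * block_size
        r[s : s + block_size, s : s + block_size] = block
    ids = [f"rs{i + 1}" for i in range(m)]
    positions = [
        1 + b * _BLOCK_SPACING_BP + j * _WITHIN_BLOCK_SPACING_BP
        for b in range(n_blocks)
        for j in range(block_size)
    ]
    return LDMatrix(ids, r, positions=positions, chromosomes=[chromosome] * m)


def _variant_frame(ld: LDMatrix, rng: np.random.Generator, maf_range) -> pd.DataFrame:
    m = len(ld.variant_ids)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    eaf = rng.uniform(*maf_range, size=m)
    return pd.DataFrame(
        {
            "SNP": ld.variant_ids,
            "CHR": [ld.chromosomes[v] for v in ld.variant_ids],
            "POS": [ld.positions[v] for v in ld.variant_ids],
            "EA": ea,
            "OA": oa,
            "EAF": eaf,
        }
    )


def _draw_joint_effects(cfg: SimulationConfig, rng: np.random.Generator, r: np.ndarray):
    """Assign SNP roles and joint (direct) effect vectors per trait."""
    m = cfg.n_snps
    labels = np.array(["null"] * m, dtype=object)
    roles = rng.permutation(m)
    n_causal = int(round(cfg.causal_fraction * m))
    n_med = min(int(round(cfg.mediator_snp_fraction * m)), m - n_causal)
    n_rev = min(int(round(cfg.reverse_fraction * m)), m - n_causal - n_med)
    causal_idx = roles[:n_causal]
    med_idx = roles[n_causal : n_causal + n_med]
    rev_idx = roles[n_causal + n_med : n_causal + n_med + n_rev]
    labels[causal_idx] = "valid"
    labels[med_idx] = "mediator"
    labels[rev_idx] = "reverse"

    # exposure-causal effects scaled to the target heritability under LD
    b_exp = np.zeros(m)
    if n_causal:
        raw = rng.standard_normal(n_causal)
        if cfg.positive_effects:
            raw = np.abs(raw) + 0.3  # bounded away from zero for stable ratios
        b_exp[causal_idx] = raw
        var = float(b_exp @ r @ b_exp)
        b_exp *= np.sqrt(cfg.h2_exp / var)

    b_med = np.zeros(m)
    if n_med:
        raw = rng.standard_normal(n_med)
        b_med[med_idx] = raw
        tmp = np.zeros(m)
        tmp[med_idx] = raw
        var = float(tmp @ r @ tmp)
        b_med *= np.sqrt(cfg.h2_med / var)

    # pleiotropic subset of the exposure-causal SNPs gains a direct outcome path
    b_plei = np.zeros(m)
    n_plei = int(round(cfg.pleiotropy_fraction * n_causal))
    if n_plei:
        plei_idx = rng.choice(causal_idx, size=n_plei, replace=False)
        labels[plei_idx] = "pleiotropic"
        b_plei[plei_idx] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n_plei)

    # reverse-causal SNPs: large direct outcome effect, small leaked exposure effect
    b_rev = np.zeros(m)
    if n_rev:
        b_rev[rev_idx] = cfg.reverse_effect * rng.choice([-1.0, 1.0], size=n_rev)
        b_exp[rev_idx] += cfg.reverse_leak * b_rev[rev_idx]

    return labels, b_exp, b_med, b_plei, b_rev


def _phenotype_variances(cfg, r, joint_exp, joint_med, joint_out):
    """Residual variances bringing each phenotype to (approximately) unit
    variance; floored so the model stays proper."""
    g_exp = float(joint_exp @ r @ joint_exp)
    sig_e = max(1.0 - g_exp, 0.05)
    g_med = float(joint_med @ r @ joint_med)
    sig_m = max(1.0 - g_med - cfg.alpha_EM**2 * sig_e, 0.05)
    g_out = float(joint_out @ r @ joint_out)
    carried = (cfg.theta_direct + cfg.alpha_EM * cfg.theta_M) ** 2 * sig_e + (
        cfg.theta_M**2
    ) * sig_m
    sig_o = max(1.0 - g_out - carried, 0.05)
    return sig_e, sig_m, sig_o


def _summary_from_marginals(variants, marginal, se, rng_noise, trait_id) -> SummaryStats:
    beta_hat = marginal + rng_noise
    z = beta_hat / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    df = variants.copy()
    df["BETA"] = beta_hat
    df["SE"] = se
    df["P"] = p
    return df, trait_id


def simulate_gwas_triplet(cfg: SimulationConfig, backend: str = "analytic") -> SimulatedStudy:
    """Simulate exposure/mediator/outcome GWAS under the structural model.

    ``backend="analytic"`` samples marginal estimates from
    ``N(R @ joint_beta, R/n)`` with cross-study noise correlation equal to
    ``sample_overlap_fraction``; ``backend="cohort"`` simulates individuals
    and runs per-SNP regressions (slower, for cross-validation).
    """
    rng = np.random.default_rng(cfg.seed)
    block_size = cfg.n_snps // cfg.n_blocks
    ld = simulate_ld(cfg.n_blocks, block_size, cfg.within_block_rho,
                     seed=cfg.seed)
    r = ld.r
    variants = _variant_frame(ld, rng, cfg.maf_range)

    labels, b_exp, b_med, b_plei, b_rev = _draw_joint_effects(cfg, rng, r)

    # joint (direct-path) effect of each SNP on each phenotype
    joint_exp = b_exp
    joint_med = cfg.alpha_EM * b_exp + b_med
    joint_out = (
        cfg.theta_direct * b_exp + cfg.theta_M * joint_med + b_plei + b_rev
    )

    alpha_indirect = cfg.alpha_EM * cfg.theta_M
    alpha_total = cfg.theta_direct + alpha_indirect
    truth = TruthSet(
        snp_effects=pd.DataFrame(
            {
                "SNP": ld.variant_ids,
                "label": labels,
                "beta_exposure": joint_exp,
                "beta_mediator": joint_med,
                "beta_outcome": joint_out,
            }
        ),
        alpha_total=alpha_total,
        alpha_direct=cfg.theta_direct,
        alpha_indirect=alpha_indirect,
        p_m=100.0 * alpha_indirect / alpha_total if alpha_total != 0 else np.nan,
    )

    panel = ReferencePanel(variants.copy())

    if backend == "cohort":
        return _cohort_backend(cfg, ld, variants, joint_exp, b_med, b_plei, b_rev,
                               panel, truth, rng)
    if backend != "analytic":
        raise ValueError(f"unknown backend {backend!r}")

    marg_exp = r @ joint_exp
    marg_med = r @ joint_med
    marg_out = r @ joint_out

    # correlated estimation noise: N(0, R/n) per study, cross-study
    # correlation = overlap fraction (first-order overlapping-cohort model)
    chol = np.linalg.cholesky(r + 1e-10 * np.eye(cfg.n_snps))
    rho = cfg.sample_overlap_fraction
    z_shared = rng.standard_normal(cfg.n_snps)
    noises = []
    for n_k in (cfg.n_exp, cfg.n_med, cfg.n_out):
        z_own = rng.standard_normal(cfg.n_snps)
        z_k = np.sqrt(rho) * z_shared + np.sqrt(1.0 - rho) * z_own
        noises.append(chol @ z_k / np.sqrt(n_k))

    studies = []
    for marg, noise, n_k, tid in (
        (marg_exp, noises[0], cfg.n_exp, "exposure"),
        (marg_med, noises[1], cfg.n_med, "mediator"),
        (marg_out, noises[2], cfg.n_out, "outcome"),
    ):
        se = np.full(cfg.n_snps, 1.0 / np.sqrt(n_k))
        df, _ = _summary_from_marginals(variants, marg, se, noise, tid)
        df["N"] = n_k
        studies.append(SummaryStats(tid, df[
            ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
        ].copy()))

    return SimulatedStudy(studies[0], studies[1], studies[2], panel, ld, truth)


def _simulate_genotypes(rng, n, eaf, chol):
    """Standardized genotype matrix with the configured LD structure."""
    latent = rng.standard_normal((n, len(eaf))) @ chol.T
    thresh = stats.norm.ppf(1.0 - eaf)  # dosage via correlated liabilities
    g = (latent > thresh).astype(float) + (
        rng.standard_normal((n, len(eaf))) @ chol.T > thresh
    ).astype(float)
    g = (g - g.mean(axis=0)) / np.where(g.std(axis=0) > 0, g.std(axis=0), 1.0)
    return g


def _marginal_gwas(g, y):
    n = len(y)
    yc = y - y.mean()
    beta = g.T @ yc / n
    resid_var = np.maximum(yc.var() - beta**2, 1e-12)
    se = np.sqrt(resid_var / n)
    z = beta / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    return beta, se, p


def _cohort_backend(cfg, ld, variants, joint_exp, b_med, b_plei, b_rev, panel, truth, rng):
    sig_e, sig_m, sig_o = _phenotype_variances(
        cfg, ld.r, joint_exp, cfg.alpha_EM * joint_exp + b_med,
        cfg.theta_direct * joint_exp + cfg.theta_M * (cfg.alpha_EM * joint_exp + b_med)
        + b_plei + b_rev,
    )
    chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(cfg.n_snps))
    eaf = variants["EAF"].to_numpy()

    def one_study(n, which):
        g = _simulate_genotypes(rng, n, eaf, chol)
        e = g @ joint_exp + rng.normal(0, np.sqrt(sig_e), n)
        m = cfg.alpha_EM * e + g @ b_med + rng.normal(0, np.sqrt(sig_m), n)
        o = (
            cfg.theta_direct * e
            + cfg.theta_M * m
            + g @ (b_plei + b_rev)
            + rng.normal(0, np.sqrt(sig_o), n)
        )
        y = {"exposure": e, "mediator": m, "outcome": o}[which]
        return _marginal_gwas(g, y)

    studies = []
    for n_k, tid in ((cfg.n_exp, "exposure"), (cfg.n_med, "mediator"), (cfg.n_out, "outcome")):
        beta, se, p = one_study(n_k, tid)
        df = variants.copy()
        df["BETA"], df["SE"], df["P"], df["N"] = beta, se, p, n_k
        studies.append(SummaryStats(tid, df[
            ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
        ].copy()))
    return SimulatedStudy(studies[0], studies[1], studies[2], panel, ld, truth)


@dataclass
class CohortConfig:
    """Generator parameters for the observational cohort."""

    n: int = 10_000
    age_range: tuple[float, float] = (40.0, 70.0)
    age_slope_male: float = -0.025
    age_slope_female: float = -0.021
    sex_effect: float = 0.091  # female LTL offset
    noise_sd: float = 1.0
    trait_effects: dict = field(default_factory=dict)  # trait -> beta (SD/SD)
    trait_missingness: dict = field(default_factory=dict)  # trait -> fraction
    phase_slopes: tuple[float, float, float] | None = None  # per-year, females
    parity_effect: float = 0.0
    menopause_effect: float = 0.0
    mean_age_first_birth: float = 26.0
    mean_age_menopause: float = 50.0
    nulliparous_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        bad = {t: f for t, f in self.trait_missingness.items() if not 0 <= f < 1}
        if bad:
            raise ValueError(f"invalid missingness fractions: {bad}")
        unknown = set(self.trait_missingness) - set(self.trait_effects)
        if unknown:
            raise ValueError(f"missingness specified for unknown traits: {sorted(unknown)}")


def simulate_cohort(cfg: CohortConfig) -> pd.DataFrame:
    """Individual-level cohort with planted LTL structure.

    Sex coding: 0 = female, 1 = male.  LTL follows sex-specific linear age
    slopes plus planted trait effects; when ``phase_slopes`` is set, female
    LTL is instead driven by time spent in the three reproductive phases
    (plus parity and menopause indicators).  Trait values are standard
    normal; missingness is completely at random per trait.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    age = rng.uniform(*cfg.age_range, size=n)
    sex = rng.integers(0, 2, size=n)  # 0 female, 1 male
    array = rng.integers(0, 2, size=n)
    female = sex == 0

    traits = {}
    ltl = np.zeros(n)
    for trait, beta in cfg.trait_effects.items():
        x = rng.standard_normal(n)
        traits[trait] = x
        ltl += beta * x

    # reproductive history for females
    afb = np.full(n, np.nan)
    amp = np.full(n, np.nan)
    nlb = np.full(n, np.nan)
    meno = np.full(n, np.nan)
    idx_f = np.nonzero(female)[0]
    if len(idx_f):
        nulli = rng.random(len(idx_f)) < cfg.nulliparous_fraction
        nlb[idx_f] = np.where(nulli, 0, rng.poisson(1.6, len(idx_f)) + 1)
        afb_f = np.clip(rng.normal(cfg.mean_age_first_birth, 4.0, len(idx_f)), 16, 45)
        afb[idx_f] = np.where(nulli, np.nan, np.minimum(afb_f, age[idx_f]))
        amp_f = np.clip(rng.normal(cfg.mean_age_menopause, 3.0, len(idx_f)), 40, 60)
        post = amp_f < age[idx_f]
        meno[idx_f] = post.astype(float)
        amp[idx_f] = np.where(post, amp_f, np.nan)

    if cfg.phase_slopes is not None:
        s1, s2, s3 = cfg.phase_slopes
        for i in idx_f:
            parous = nlb[i] > 0
            post = meno[i] == 1
            a = age[i]
            if parous and post and afb[i] <= amp[i]:
                t1, t2, t3 = afb[i], amp[i] - afb[i], a - amp[i]
            elif parous and not post:
                t1, t2, t3 = afb[i], a - afb[i], 0.0
            elif not parous and post:
                t1, t2, t3 = amp[i], 0.0, a - amp[i]
            else:
                t1, t2, t3 = a, 0.0, 0.0
            ltl[i] += (
                s1 * t1 + s2 * t2 + s3 * t3
                + cfg.parity_effect * float(parous)
                + cfg.menopause_effect * float(post)
            )
        male = ~female
        ltl[male] += cfg.age_slope_male * age[male]
    else:
        ltl += np.where(female, cfg.age_slope_female, cfg.age_slope_male) * age
        ltl += cfg.sex_effect * female

    ltl += rng.normal(0, cfg.noise_sd, n)

    cohort = pd.DataFrame(
        {
            "id": np.arange(n),
            "age": age,
            "sex": sex,
            "array": array,
            "ltl": ltl,
            "age_first_birth": afb,
            "age_menopause": amp,
            "n_live_births": nlb,
            "menopause_status": meno,
        }
    )
    for trait, x in traits.items():
        x = x.copy()
        frac = cfg.trait_missingness.get(trait, 0.0)
        if frac > 0:
            x[rng.random(n) < frac] = np.nan
        cohort[trait] = x
    return cohort
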