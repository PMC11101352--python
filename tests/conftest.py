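import numpy as np
import pandas as pd
import pytest

from telomr.instruments import LDMatrix
from telomr.simulate import CohortConfig, SimulationConfig, simulate_cohort, simulate_gwas_triplet
from telomr.sumstats import ReferencePanel, SummaryStats


def make_sumstats(trait_id="trait", snps=None, betas=None, ses=None, ps=None,
                  ns=None, eafs=None, chrom=1, positions=None, ea="A", oa="C"):
    """Hand-rolled small summary-statistics table for fixtures."""
    snps = snps or ["rs1", "rs2", "rs3"]
    m = len(snps)
    betas = betas if betas is not None else [0.1] * m
    ses = ses if ses is not None else [0.01] * m
    ps = ps if ps is not None else [1e-10] * m
    ns = ns if ns is not None else [10000] * m
    eafs = eafs if eafs is not None else [0.3] * m
    positions = positions if positions is not None else [1000 * (i + 1) for i in range(m)]
    ea = [ea] * m if isinstance(ea, str) else ea
    oa = [oa] * m if isinstance(oa, str) else oa
    df = pd.DataFrame(
        {"SNP": snps, "CHR": chrom, "POS": positions, "EA": ea, "OA": oa,
         "EAF": eafs, "BETA": betas, "SE": ses, "P": ps, "N": ns}
    )
    return SummaryStats(trait_id, df)


def panel_from(ss: SummaryStats) -> ReferencePanel:
    return ReferencePanel(ss.table[["SNP", "CHR", "POS", "EA", "OA", "EAF"]].copy())


def identity_ld(ss: SummaryStats) -> LDMatrix:
    df = ss.table
    return LDMatrix(list(df["SNP"]), np.eye(len(df)),
                    positions=list(df["POS"]), chromosomes=list(df["CHR"]))


@pytest.fixture
def valid_iv_study():
    """50 independent valid instruments, true causal effect 0.1."""
    cfg = SimulationConfig(
        n_snps=50, n_blocks=50, causal_fraction=1.0, h2_exp=0.25,
        theta_direct=0.1, alpha_EM=0.0, theta_M=0.0, seed=11,
    )
    return simulate_gwas_triplet(cfg)


@pytest.fixture
def mediation_study():
    """Full structural model with planted mediation P_M = 30%."""
    cfg = SimulationConfig(
        n_snps=300, n_blocks=30, within_block_rho=0.4,
        alpha_EM=0.5, theta_M=0.3, theta_direct=0.35,
        mediator_snp_fraction=0.15, h2_med=0.08, seed=7,
    )
    return simulate_gwas_triplet(cfg)


@pytest.fixture
def basic_cohort():
    cfg = CohortConfig(
        n=8000,
        trait_effects={"bmi": -0.04, "igf1": 0.05, "noise1": 0.0, "noise2": 0.0},
        trait_missingness={"bmi": 0.03},
        seed=5,
    )
    return simulate_cohort(cfg)
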