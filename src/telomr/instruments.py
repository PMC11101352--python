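"""Instrument selection: LD clumping, region masks, AF and Steiger filters.

Clumping follows the PLINK convention: genome-wide significant candidates
are greedily selected by ascending p-value, and each selected index SNP
absorbs (removes) every remaining variant with p below the secondary
threshold that lies within the kb window and exceeds the r-squared cutoff.
Only index SNPs are retained as instruments.

Default thresholds: candidate inclusion p < 5e-8; clump p1=1e-4, p2=0.01,
kb=250, r2=0.01; allele-frequency discordance removal at |diff| >= 0.05;
Steiger removal at Z <= -1.96.  Boundary semantics are literal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from telomr.sumstats import SummaryStats, align_pair, standardize_effects

logger = logging.getLogger(__name__)

GW_THRESHOLD = 5e-8
STEIGER_THRESHOLD = -1.96
AF_MAX_DIFF = 0.05

# GRCh37/hg19, 1-based inclusive
HBB_MASK_REGION = (11, 5_246_696, 5_248_301)
HLA_MASK_REGION = (6, 25_000_000, 37_000_000)


@dataclass(frozen=True)
class GenomicMask:
    """A 1-based inclusive genomic interval to exclude from instruments."""

    name: str
    chromosome: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"mask {self.name}: start > end")

    def contains(self, chromosome, position) -> np.ndarray:
        return (np.asarray(chromosome) == self.chromosome) & (
            (np.asarray(position) >= self.start) & (np.asarray(position) <= self.end)
        )


HBB_MASK = GenomicMask("HBB", *HBB_MASK_REGION)
HLA_MASK = GenomicMask("HLA", *HLA_MASK_REGION)


class LDMatrix:
    """Signed pairwise-r matrix over a set of variants, with positions.

    Pairs absent from the matrix are treated as unlinked (r = 0), with a
    warning, mirroring reference-panel coverage gaps.
    """

    def __init__(self, variant_ids, r: np.ndarray, positions=None, chromosomes=None):
        self.variant_ids = list(variant_ids)
        r = np.asarray(r, dtype=float)
        if r.shape != (len(self.variant_ids), len(self.variant_ids)):
            raise ValueError("LD matrix shape does not match variant ids")
        if not np.allclose(r, r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if np.any(np.abs(r) > 1 + 1e-8):
            raise ValueError("|r| must be <= 1")
        self.r = r
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        self.positions = None if positions is None else dict(zip(self.variant_ids, positions))
        self.chromosomes = (
            None if chromosomes is None else dict(zip(self.variant_ids, chromosomes))
        )
        self._warned_missing = False

    def r2(self, id_a: str, id_b: str) -> float:
        ia = self._index.get(id_a)
        ib = self._index.get(id_b)
        if ia is None or ib is None:
            if not self._warned_missing:
                logger.warning("LD lookup for uncovered pair (%s, %s): using r=0", id_a, id_b)
                self._warned_missing = True
            return 0.0
        return float(self.r[ia, ib] ** 2)

    @classmethod
    def from_square_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy())

    @classmethod
    def from_triplets(cls, triplets: pd.DataFrame) -> "LDMatrix":
        """Build from a long table with columns (id_a, id_b, r)."""
        ids = sorted(set(triplets.iloc[:, 0]) | set(triplets.iloc[:, 1]))
        idx = {v: i for i, v in enumerate(ids)}
        r = np.eye(len(ids))
        for a, b, val in triplets.itertuples(index=False):
            r[idx[a], idx[b]] = val
            r[idx[b], idx[a]] = val
        return cls(ids, r)

    def to_square_tsv(self, path) -> None:
        pd.DataFrame(self.r, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t"
        )


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure, with selection provenance.

    ``table`` holds the canonical summary-stat columns for retained index
    SNPs plus a ``clump_index`` column (selection order).
    """

    trait_id: str
    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table["SNP"])

    def __len__(self) -> int:
        return len(self.table)


def _greedy_clump_indices(
    df: pd.DataFrame,
    ld: LDMatrix,
    order: np.ndarray,
    p2: float,
    kb: float,
    r2: float,
) -> list[int]:
    """Greedy index-SNP selection over ``df`` following ``order`` (positions
    into df).  Returns positional indices of retained index SNPs."""
    window_bp = kb * 1000.0
    alive = np.ones(len(df), dtype=bool)
    snp = df["SNP"].to_numpy()
    chrom = df["CHR"].to_numpy()
    pos = df["POS"].to_numpy()
    pval = df["P"].to_numpy()
    selected: list[int] = []
    for i in order:
        if not alive[i]:
            continue
        selected.append(int(i))
        alive[i] = False
        for j in np.nonzero(alive)[0]:
            if chrom[j] != chrom[i]:
                continue
            if abs(pos[j] - pos[i]) > window_bp:
                continue
            if pval[j] >= p2:
                continue
            if ld.r2(snp[i], snp[j]) >= r2:
                alive[j] = False
    return selected


def clump(
    ss: SummaryStats,
    ld: LDMatrix,
    p1: float = 1e-4,
    p2: float = 0.01,
    kb: float = 250.0,
    r2: float = 0.01,
    gw_threshold: float = GW_THRESHOLD,
) -> InstrumentSet:
    """LD-clump genome-wide significant variants to index SNPs.

    Candidates are variants with p < ``gw_threshold`` (also passing ``p1``);
    selection is greedy by ascending p (ties: smaller position, then
    lexicographic id).  Returns an :class:`InstrumentSet` of index SNPs; an
    empty candidate set yields an empty instrument set.
    """
    df = ss.table
    cand = df.loc[(df["P"] < gw_threshold) & (df["P"] < p1)].reset_index(drop=True)
    if cand.empty:
        return InstrumentSet(ss.trait_id, cand.assign(clump_index=pd.Series(dtype=int)))
    order = np.lexsort((cand["SNP"].to_numpy(), cand["POS"].to_numpy(), cand["P"].to_numpy()))
    keep = _greedy_clump_indices(cand, ld, order, p2=p2, kb=kb, r2=r2)
    out = cand.iloc[keep].reset_index(drop=True)
    out["clump_index"] = np.arange(len(out))
    return InstrumentSet(
        ss.trait_id, out, provenance={"n_candidates": len(cand), "n_index": len(out)}
    )


def apply_region_masks(
    ivs: InstrumentSet, masks: list[GenomicMask] | None = None
) -> InstrumentSet:
    """Remove instruments falling inside any mask (1-based inclusive).

    Default masks: the HBB control region for telomere-length instruments
    and the long-range-LD HLA region for all instrument sets.
    """
    if masks is None:
        masks = [HLA_MASK]
    df = ivs.table
    if not masks or df.empty:
        return InstrumentSet(ivs.trait_id, df.copy(), dict(ivs.provenance))
    inside = np.zeros(len(df), dtype=bool)
    for mask in masks:
        inside |= mask.contains(df["CHR"], df["POS"])
    removed = df.loc[inside, "SNP"].tolist()
    out = df.loc[~inside].reset_index(drop=True)
    prov = {**ivs.provenance, "mask_removed": removed}
    if removed:
        logger.info("region masks removed %d instruments: %s", len(removed), removed)
    return InstrumentSet(ivs.trait_id, out, prov)


def af_concordance_filter(pair: pd.DataFrame, max_diff: float = AF_MAX_DIFF) -> pd.DataFrame:
    """Drop rows where |EAF_exp - EAF_out| >= ``max_diff``.

    Rows with a missing frequency on either side are retained and flagged
    in an ``af_flagged`` column.
    """
    diff = (pair["EAF_exp"] - pair["EAF_out"]).abs()
    missing = diff.isna()
    keep = missing | (diff < max_diff)
    out = pair.loc[keep].reset_index(drop=True)
    out = out.assign(af_flagged=missing.loc[keep].to_numpy())
    return out


def steiger_z(r_exp: float, n_exp: float, r_out: float, n_out: float):
    """Directionality statistic comparing exposure vs outcome correlations.

    ``Z = (atanh(|r_exp|) - atanh(|r_out|)) / sqrt(1/(n_exp-3) + 1/(n_out-3))``.
    Negative Z means the variant is more strongly associated with the
    outcome than with the exposure.
    """
    r_exp, r_out = np.asarray(r_exp, dtype=float), np.asarray(r_out, dtype=float)
    n_exp, n_out = np.asarray(n_exp, dtype=float), np.asarray(n_out, dtype=float)
    if np.any(n_exp <= 3) or np.any(n_out <= 3):
        raise ValueError("Steiger test requires n > 3")
    if np.any(np.abs(r_exp) >= 1) or np.any(np.abs(r_out) >= 1):
        raise ValueError("Steiger test requires |r| < 1")
    z_exp = np.arctanh(np.abs(r_exp))
    z_out = np.arctanh(np.abs(r_out))
    return (z_exp - z_out) / np.sqrt(1.0 / (n_exp - 3.0) + 1.0 / (n_out - 3.0))


def _standardized_r(beta: np.ndarray, se: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Signed per-SNP correlation from raw beta/se/n (explained-variance scale)."""
    z = beta / se
    return z / np.sqrt(z**2 + n - 2.0)


def steiger_filter(
    pair: pd.DataFrame,
    threshold: float = STEIGER_THRESHOLD,
    scale_exp: str = "raw",
    scale_out: str = "raw",
) -> pd.DataFrame:
    """Remove rows whose Steiger Z falls at or below ``threshold``.

    Correlations are taken from standardized effects directly when a side is
    already on the explained-variance scale, otherwise derived from z and n.
    """
    if pair.empty:
        return pair.copy()
    if scale_exp == "standardized":
        r_exp = pair["BETA_exp"].to_numpy(dtype=float)
    else:
        r_exp = _standardized_r(
            pair["BETA_exp"].to_numpy(float), pair["SE_exp"].to_numpy(float),
            pair["N_exp"].to_numpy(float),
        )
    if scale_out == "standardized":
        r_out = pair["BETA_out"].to_numpy(dtype=float)
    else:
        r_out = _standardized_r(
            pair["BETA_out"].to_numpy(float), pair["SE_out"].to_numpy(float),
            pair["N_out"].to_numpy(float),
        )
    z = steiger_z(r_exp, pair["N_exp"].to_numpy(float), r_out, pair["N_out"].to_numpy(float))
    keep = ~(z <= threshold)
    out = pair.loc[keep].reset_index(drop=True)
    return out.assign(steiger_z=z[keep])


def multi_trait_steiger_filter(
    exposure: SummaryStats,
    trait_panel: list[SummaryStats],
    ivs: InstrumentSet,
    threshold: float = STEIGER_THRESHOLD,
) -> InstrumentSet:
    """Pleiotropy filter: retain only instruments more strongly associated
    with the exposure than with *every* trait in the panel.

    An instrument absent from any panel trait is excluded (presence across
    the whole panel is required for the comparison to be made).
    """
    exp_std = standardize_effects(exposure)
    surviving = set(ivs.variant_ids)
    removed: dict[str, list[str]] = {}
    exp_tbl = exp_std.table.set_index("SNP")
    for trait in trait_panel:
        if not surviving:
            break
        t_std = standardize_effects(trait)
        t_tbl = t_std.table.set_index("SNP")
        dropped = []
        for snp in sorted(surviving):
            if snp not in t_tbl.index:
                dropped.append(snp)
                continue
            r_exp = exp_tbl.loc[snp, "BETA"]
            r_out = t_tbl.loc[snp, "BETA"]
            z = steiger_z(
                abs(r_exp), exp_tbl.loc[snp, "N"], abs(r_out), t_tbl.loc[snp, "N"]
            )
            if z <= threshold:
                dropped.append(snp)
        if dropped:
            removed[t_std.trait_id] = dropped
            surviving -= set(dropped)
    out = ivs.table.loc[ivs.table["SNP"].isin(surviving)].reset_index(drop=True)
    prov = {**ivs.provenance, "multi_trait_removed": removed}
    return InstrumentSet(ivs.trait_id, out, prov)


def two_phase_mediation_clump(
    exposure: SummaryStats,
    mediator: SummaryStats,
    ld: LDMatrix,
    p1: float = 1e-4,
    p2: float = 0.01,
    kb: float = 250.0,
    r2: float = 0.01,
    gw_threshold: float = GW_THRESHOLD,
) -> tuple[InstrumentSet, InstrumentSet]:
    """Two-phase clumping for mediation: exposure instruments take priority.

    Phase 1 clumps exposure candidates alone.  Phase 2 pools the phase-1
    exposure index SNPs with the mediator's genome-wide significant
    candidates and clumps the pool with every exposure variant ranked
    strictly above every mediator variant (ascending p within each group),
    so an exposure instrument always absorbs a linked mediator candidate
    regardless of their p-value ordering.  Returns disjoint exposure- and
    mediator-instrument sets.
    """
    exp_ivs = clump(exposure, ld, p1=p1, p2=p2, kb=kb, r2=r2, gw_threshold=gw_threshold)
    med = mediator.table
    med_cand = med.loc[(med["P"] < gw_threshold) & (med["P"] < p1)]
    med_cand = med_cand.loc[~med_cand["SNP"].isin(exp_ivs.variant_ids)]

    exp_pool = exp_ivs.table.drop(columns=["clump_index"], errors="ignore").assign(_group=0)
    med_pool = med_cand.assign(_group=1)
    pooled = pd.concat([exp_pool, med_pool], ignore_index=True)
    if pooled.empty:
        empty = pooled.drop(columns=["_group"]).assign(clump_index=pd.Series(dtype=int))
        return (
            InstrumentSet(exposure.trait_id, empty.copy()),
            InstrumentSet(mediator.trait_id, empty.copy()),
        )
    order = np.lexsort(
        (
            pooled["SNP"].to_numpy(),
            pooled["POS"].to_numpy(),
            pooled["P"].to_numpy(),
            pooled["_group"].to_numpy(),  # exposure group first, overriding p
        )
    )
    keep = _greedy_clump_indices(pooled, ld, order, p2=p2, kb=kb, r2=r2)
    kept = pooled.iloc[keep].reset_index(drop=True)
    kept["clump_index"] = np.arange(len(kept))
    exp_out = kept.loc[kept["_group"] == 0].drop(columns="_group").reset_index(drop=True)
    med_out = kept.loc[kept["_group"] == 1].drop(columns="_group").reset_index(drop=True)
    return (
        InstrumentSet(exposure.trait_id, exp_out, {"phase1_n": len(exp_ivs)}),
        InstrumentSet(mediator.trait_id, med_out),
    )


def minrank_clump(
    exposures: list[SummaryStats],
    ld: LDMatrix,
    p1: float = 1e-4,
    p2: float = 0.01,
    kb: float = 250.0,
    r2: float = 0.01,
    gw_threshold: float = GW_THRESHOLD,
) -> InstrumentSet:
    """Minimum-rank clumping across several exposures for multivariable MR.

    Each SNP that is genome-wide significant for at least one exposure is
    ranked by p-value within every exposure; its minimum rank across
    exposures drives the greedy clumping order (ties broken by smaller
    minimum p, then lexicographic id).
    """
    if len(exposures) < 1:
        raise ValueError("need at least one exposure")
    frames = {ss.trait_id: ss.table.set_index("SNP") for ss in exposures}
    cand_ids: set[str] = set()
    for tbl in frames.values():
        sig = tbl.loc[(tbl["P"] < gw_threshold) & (tbl["P"] < p1)]
        cand_ids |= set(sig.index)
    # keep only SNPs present in every exposure so ranks are comparable
    for tbl in frames.values():
        cand_ids &= set(tbl.index)
    if not cand_ids:
        first = exposures[0].table.iloc[0:0].assign(clump_index=pd.Series(dtype=int))
        return InstrumentSet("+".join(frames), first)

    cand_list = sorted(cand_ids)
    ranks = np.full((len(cand_list), len(frames)), np.inf)
    pmins = np.full(len(cand_list), np.inf)
    for k, tbl in enumerate(frames.values()):
        sub = tbl.loc[cand_list, "P"].to_numpy(dtype=float)
        order = np.argsort(sub, kind="stable")
        rk = np.empty(len(cand_list))
        rk[order] = np.arange(1, len(cand_list) + 1)
        ranks[:, k] = rk
        pmins = np.minimum(pmins, sub)
    min_rank = ranks.min(axis=1)

    base = frames[exposures[0].trait_id].loc[cand_list].reset_index()
    base["_minrank"] = min_rank
    base["_minp"] = pmins
    order = np.lexsort(
        (base["SNP"].to_numpy(), base["_minp"].to_numpy(), base["_minrank"].to_numpy())
    )
    keep = _greedy_clump_indices(base, ld, order, p2=p2, kb=kb, r2=r2)
    out = base.iloc[keep].drop(columns=["_minrank", "_minp"]).reset_index(drop=True)
    out["clump_index"] = np.arange(len(out))
    return InstrumentSet("+".join(frames), out)
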