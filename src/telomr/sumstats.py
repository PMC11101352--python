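"""GWAS summary-statistics I/O, validation, harmonization and transforms.

Summary statistics are carried as pandas DataFrames with the canonical
columns ``SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N``; a reference panel
uses the same layout minus the association columns.  All positions are
1-based (GRCh37 convention) and only autosomes (1-22) are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
PANEL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF"]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class SumStatsError(ValueError):
    """Raised on unrecoverable summary-statistics problems."""


@dataclass
class SummaryStats:
    """Per-variant association table for a single trait.

    Attributes
    ----------
    trait_id : str
        Identifier of the trait the effects refer to.
    table : pandas.DataFrame
        Canonical-column table (one row per variant).
    scale : str
        ``"raw"`` or ``"standardized"`` (sqrt of per-SNP explained variance).
    trait_type : str
        ``"continuous"`` or ``"binary"``.
    """

    trait_id: str
    table: pd.DataFrame
    scale: str = "raw"
    trait_type: str = "continuous"
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise SumStatsError(f"missing columns: {missing}")
        if self.scale not in ("raw", "standardized"):
            raise SumStatsError(f"unknown scale {self.scale!r}")
        dup = self.table["SNP"][self.table["SNP"].duplicated()]
        if len(dup):
            raise SumStatsError(f"duplicate variant_id: {dup.iloc[0]!r}")

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def copy(self) -> "SummaryStats":
        return replace(self, table=self.table.copy(), log=dict(self.log))


@dataclass
class ReferencePanel:
    """Variant reference panel (allele orientation + panel frequencies)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.table.columns]
        if missing:
            raise SumStatsError(f"panel missing columns: {missing}")
        if self.table["SNP"].duplicated().any():
            raise SumStatsError("panel has duplicate variant ids")


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop rows violating per-variant invariants; return (clean, counts)."""
    counts: dict[str, int] = {}

    def drop(mask: pd.Series, reason: str) -> pd.DataFrame:
        nonlocal df
        n_bad = int(mask.sum())
        if n_bad:
            counts[reason] = n_bad
            df = df.loc[~mask]
        return df

    drop(~df["CHR"].between(1, 22), "non_autosomal")
    drop(~(df["EA"].isin(_VALID_ALLELES) & df["OA"].isin(_VALID_ALLELES)), "bad_allele")
    drop(df["EA"] == df["OA"], "identical_alleles")
    drop(~(df["SE"] > 0), "nonpositive_se")
    drop(~((df["P"] > 0) & (df["P"] <= 1)), "invalid_pvalue")
    drop(~(df["N"] >= 2), "invalid_n")
    drop(df["POS"] < 1, "invalid_position")
    with np.errstate(invalid="ignore"):
        bad_eaf = df["EAF"].notna() & ~df["EAF"].between(0, 1)
    drop(bad_eaf, "invalid_eaf")
    if counts:
        logger.warning("dropped rows failing validation: %s", counts)
    return df.reset_index(drop=True), counts


def read_summary_stats(
    path: str | Path,
    trait_id: str | None = None,
    column_map: dict[str, str] | None = None,
    sep: str = "\t",
    trait_type: str = "continuous",
) -> SummaryStats:
    """Read a delimited summary-statistics file into a validated table.

    ``column_map`` maps canonical names to the file's header names, e.g.
    ``{"SNP": "rsid", "BETA": "effect"}``.  Rows failing invariant checks
    are dropped with counts recorded in ``result.log``; a missing required
    column or an empty file is a hard error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise SumStatsError(f"empty summary-statistics file: {path}")
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SumStatsError(f"{path}: missing required columns {missing}")
    df = df[CANONICAL_COLUMNS].copy()
    for col in ("CHR", "POS", "N"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    for col in ("EAF", "BETA", "SE", "P"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["EA"] = df["EA"].astype(str).str.upper()
    df["OA"] = df["OA"].astype(str).str.upper()
    df = df.dropna(subset=["SNP", "CHR", "POS", "BETA", "SE", "P", "N"])
    df[["CHR", "POS", "N"]] = df[["CHR", "POS", "N"]].astype(int)
    df, counts = _validate_rows(df)
    ss = SummaryStats(
        trait_id=trait_id or path.stem,
        table=df,
        trait_type=trait_type,
        log={"dropped": counts},
    )
    return ss


def read_reference_panel(
    path: str | Path, column_map: dict[str, str] | None = None, sep: str = "\t"
) -> ReferencePanel:
    """Read a reference panel (canonical columns minus BETA/SE/P/N)."""
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise SumStatsError(f"{path}: panel missing columns {missing}")
    return ReferencePanel(df[PANEL_COLUMNS].copy())


def is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    """A/T and C/G variants, whose strand cannot be resolved across studies."""
    return (ea == oa.map(_COMPLEMENT)).fillna(False)


def harmonize(ss: SummaryStats, panel: ReferencePanel) -> SummaryStats:
    """Orient a summary-statistics table against a reference panel.

    Removes variants absent from the panel and palindromic (A/T, C/G)
    variants; recodes strand-flipped variants (alleles match the panel only
    after complementing both); flips ``BETA -> -BETA`` and
    ``EAF -> 1 - EAF`` where effect/other alleles are swapped relative to
    the panel.  Output rows carry panel allele orientation.  Idempotent.
    """
    df = ss.table.copy()
    n_in = len(df)
    panel_alleles = panel.table.set_index("SNP")[["EA", "OA"]]
    df = df.join(panel_alleles.rename(columns={"EA": "_pEA", "OA": "_pOA"}), on="SNP")
    removed = {"not_in_panel": int(df["_pEA"].isna().sum())}
    df = df.dropna(subset=["_pEA"])

    pal = is_palindromic(df["EA"], df["OA"])
    removed["palindromic"] = int(pal.sum())
    df = df.loc[~pal]

    ea, oa = df["EA"], df["OA"]
    cea = ea.map(_COMPLEMENT)
    coa = oa.map(_COMPLEMENT)
    direct = (ea == df["_pEA"]) & (oa == df["_pOA"])
    swapped = (ea == df["_pOA"]) & (oa == df["_pEA"])
    flip_direct = (cea == df["_pEA"]) & (coa == df["_pOA"])
    flip_swapped = (cea == df["_pOA"]) & (coa == df["_pEA"])

    match_plain = direct | swapped
    match_flip = flip_direct | flip_swapped
    # non-palindromic variants cannot satisfy both interpretations, but an
    # inconsistent panel could; drop rather than guess
    ambiguous = match_plain & match_flip
    unmatched = ~(match_plain | match_flip)
    removed["ambiguous"] = int(ambiguous.sum())
    removed["allele_mismatch"] = int(unmatched.sum())
    df = df.loc[~(ambiguous | unmatched)]

    strand = flip_direct | flip_swapped
    df.loc[strand.loc[df.index], "EA"] = df.loc[strand.loc[df.index], "EA"].map(_COMPLEMENT)
    df.loc[strand.loc[df.index], "OA"] = df.loc[strand.loc[df.index], "OA"].map(_COMPLEMENT)

    swap = (swapped | flip_swapped).loc[df.index]
    df.loc[swap, "BETA"] = -df.loc[swap, "BETA"]
    df.loc[swap, "EAF"] = 1.0 - df.loc[swap, "EAF"]
    df.loc[swap, ["EA", "OA"]] = df.loc[swap, ["OA", "EA"]].to_numpy()

    df = df.drop(columns=["_pEA", "_pOA"]).reset_index(drop=True)
    logger.info(
        "harmonize %s: %d in, %d out, removed %s", ss.trait_id, n_in, len(df), removed
    )
    out = replace(ss, table=df, log={**ss.log, "harmonize_removed": removed})
    return out


def standardize_effects(ss: SummaryStats) -> SummaryStats:
    """Rescale effects to the square root of the per-SNP explained variance.

    Per variant, with ``z = beta/se``: ``r = z / sqrt(z^2 + n - 2)`` and
    ``se_std = 1 / sqrt(z^2 + n - 2)`` (the ``z -> 0`` limit of ``r/z``).
    ``r^2`` equals the variance in a standardized trait explained by the
    SNP in a univariate regression; the z-statistic is preserved exactly.
    A second call is a no-op (guarded by the ``scale`` flag).
    """
    if ss.scale == "standardized":
        return ss
    df = ss.table.copy()
    z = df["BETA"].to_numpy() / df["SE"].to_numpy()
    n = df["N"].to_numpy(dtype=float)
    denom = np.sqrt(z**2 + n - 2.0)
    df["BETA"] = z / denom
    df["SE"] = 1.0 / denom
    return replace(ss, table=df, scale="standardized")


def align_pair(exposure: SummaryStats, outcome: SummaryStats) -> pd.DataFrame:
    """Inner-join two harmonized tables on variant id.

    Returns one row per shared variant with ``_exp`` / ``_out`` suffixed
    association columns in panel allele orientation, plus CHR/POS/alleles.
    """
    left = exposure.table.rename(
        columns={c: f"{c}_exp" for c in ("EAF", "BETA", "SE", "P", "N")}
    )
    right = outcome.table[["SNP", "EAF", "BETA", "SE", "P", "N"]].rename(
        columns={c: f"{c}_out" for c in ("EAF", "BETA", "SE", "P", "N")}
    )
    merged = left.merge(right, on="SNP", how="inner")
    if merged.empty:
        raise SumStatsError(
            f"no shared variants between {exposure.trait_id} and {outcome.trait_id}"
        )
    return merged.reset_index(drop=True)


def derive_difference_trait(
    ss_a: SummaryStats,
    ss_b: SummaryStats,
    sd_a: float,
    sd_b: float,
    trait_id: str | None = None,
) -> SummaryStats:
    """Difference trait from two year-scale GWAS (e.g. reproductive lifespan).

    Back-transforms both sets of effects to the year scale and subtracts:
    ``beta = sd_a*beta_a - sd_b*beta_b``,
    ``se = sqrt(sd_a^2*se_a^2 + sd_b^2*se_b^2)``, ``n = min(n_a, n_b)``
    per variant; two-sided p from beta/se against a standard normal.
    """
    if sd_a <= 0 or sd_b <= 0:
        raise SumStatsError("phenotype SDs must be positive")
    pair = align_pair(ss_a, ss_b)
    beta = sd_a * pair["BETA_exp"] - sd_b * pair["BETA_out"]
    se = np.sqrt(sd_a**2 * pair["SE_exp"] ** 2 + sd_b**2 * pair["SE_out"] ** 2)
    n = np.minimum(pair["N_exp"], pair["N_out"])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.norm.sf(np.abs(t))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    df = pd.DataFrame(
        {
            "SNP": pair["SNP"],
            "CHR": pair["CHR"],
            "POS": pair["POS"],
            "EA": pair["EA"],
            "OA": pair["OA"],
            "EAF": pair["EAF_exp"],
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": n.astype(int),
        }
    )
    return SummaryStats(
        trait_id=trait_id or f"{ss_a.trait_id}-minus-{ss_b.trait_id}",
        table=df,
        scale="raw",
    )


def write_summary_stats(ss: SummaryStats, path: str | Path) -> None:
    """Write canonical TSV."""
    ss.table.to_csv(path, sep="\t", index=False)


def write_reference_panel(panel: ReferencePanel, path: str | Path) -> None:
    panel.table.to_csv(path, sep="\t", index=False)
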