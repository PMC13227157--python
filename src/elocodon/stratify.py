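"""Rank-stratified comparison of expression changes (DM_LFC curves).

Genes are ranked in ascending order of one codon parameter, and for each
percentage class p = 1..50 the p% of genes at each extreme of the ranking
are compared by their log2 fold changes.  The statistic reported is the
difference of median LFCs,

    DM_LFC = Me(LFC, high-codon-load end) - Me(LFC, low-codon-load end),

where for the frequency parameters (F_T, F_S, F_2, F_3, F_4) the
high-load end is the bottom of the ascending ranking (highest values),
and for the spacing parameter D it is the top (shortest distances).
A negative DM_LFC therefore means that codon-loaded genes are shifted
toward downregulation.  Each class comparison carries the dispatch test
on the two LFC samples, BH-adjusted across the percentage classes of one
parameter by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_metrics import PARAMETERS
from .stats import bh_adjust, percentile, two_group_test

log = logging.getLogger(__name__)

__all__ = [
    "FREQUENCY_PARAMETERS",
    "CandidateSet",
    "rank_genes",
    "select_percentage_class",
    "dm_lfc_curve",
    "cross_organ_dm",
    "select_candidates",
    "dm_matrix",
]

FREQUENCY_PARAMETERS = ("F_T", "F_S", "F_2", "F_3", "F_4")

DEFAULT_PCTS = tuple(range(1, 51))


@dataclass
class CandidateSet:
    """Downregulated genes with extreme Elongator-targeted codon load."""

    organ: str | None
    gene_ids: frozenset
    rule: dict
    percentile_values: dict
    table: pd.DataFrame = field(repr=False, default=None)


def rank_genes(profiles: pd.DataFrame, parameter: str) -> list[str]:
    """Gene ids in ascending order of one parameter, ties by gene id."""
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    sub = profiles[["gene_id", parameter]].dropna(subset=[parameter])
    n_missing = len(profiles) - len(sub)
    if n_missing:
        log.info("parameter %s: %d gene(s) with missing value excluded", parameter, n_missing)
    if len(sub) < 2:
        raise ValueError(f"parameter {parameter!r}: fewer than 2 genes with a value")
    sub = sub.sort_values([parameter, "gene_id"], kind="mergesort")
    return sub["gene_id"].tolist()


def select_percentage_class(ranking: list[str], pct: int, end: str) -> set[str]:
    """The pct% of genes at one end of a ranking (at least one gene).

    ``end="top"`` takes the lowest parameter values, ``end="bottom"`` the
    highest.  Class size is ``max(1, floor(N * pct / 100))``.
    """
    if not 1 <= pct <= 50:
        raise ValueError(f"pct must be in [1, 50], got {pct}")
    k = max(1, (len(ranking) * pct) // 100)
    if end == "top":
        return set(ranking[:k])
    if end == "bottom":
        return set(ranking[-k:])
    raise ValueError(f"end must be 'top' or 'bottom', got {end!r}")


def _high_low_ends(parameter: str) -> tuple[str, str]:
    """(high-codon-load end, low-codon-load end) of the ascending ranking."""
    if parameter in FREQUENCY_PARAMETERS:
        return "bottom", "top"   # HF vs LF
    return "top", "bottom"       # SD vs LD for the spacing parameter


def dm_lfc_curve(
    profiles: pd.DataFrame,
    lfc_by_gene: dict,
    parameter: str,
    pcts=DEFAULT_PCTS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """DM_LFC across percentage classes for one parameter.

    Genes without an LFC are dropped before ranking.  Returns one row per
    percentage class with the subset medians, DM_LFC, test and BH-adjusted
    p-value (family = the classes of this parameter).
    """
    have = profiles["gene_id"].isin(lfc_by_gene)
    if (~have).any():
        log.warning("%d gene(s) without LFC dropped before ranking", int((~have).sum()))
    ranking = rank_genes(profiles[have], parameter)
    end_high, end_low = _high_low_ends(parameter)
    rows = []
    for pct in pcts:
        high = select_percentage_class(ranking, pct, end_high)
        low = select_percentage_class(ranking, pct, end_low)
        if len(high) < 3 or len(low) < 3:
            log.warning("parameter %s pct %d: subset smaller than 3, skipped", parameter, pct)
            continue
        lfc_high = np.array([lfc_by_gene[g] for g in high])
        lfc_low = np.array([lfc_by_gene[g] for g in low])
        test = two_group_test(lfc_high, lfc_low)
        rows.append({
            "parameter": parameter,
            "pct": pct,
            "end_high": end_high,
            "end_low": end_low,
            "n_per_subset": len(high),
            "median_high": float(np.median(lfc_high)),
            "median_low": float(np.median(lfc_low)),
            "dm_lfc": float(np.median(lfc_high) - np.median(lfc_low)),
            "statistic": test.statistic,
            "method": test.method,
            "p": test.pvalue,
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["padj"] = bh_adjust(out["p"])
        out["significant"] = out["padj"] <= alpha
    return out


def cross_organ_dm(
    profiles: pd.DataFrame,
    lfc_cot: dict,
    lfc_hyp: dict,
    parameter: str,
    pcts=DEFAULT_PCTS,
    end: str = "bottom",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cotyledon-minus-hypocotyl median LFC within matched percentage classes.

    One joint ranking over all genes carrying the parameter and present in
    either organ; per class, DM_LFC = Me(LFC_cot over class members with a
    cotyledon LFC) - Me(LFC_hyp over class members with a hypocotyl LFC),
    tested between the two organ samples and BH-adjusted across classes.
    """
    universe = set(lfc_cot) | set(lfc_hyp)
    have = profiles["gene_id"].isin(universe)
    ranking = rank_genes(profiles[have], parameter)
    rows = []
    for pct in pcts:
        cls = select_percentage_class(ranking, pct, end)
        cot = np.array([lfc_cot[g] for g in cls if g in lfc_cot])
        hyp = np.array([lfc_hyp[g] for g in cls if g in lfc_hyp])
        if len(cot) < 3 or len(hyp) < 3:
            log.warning("parameter %s pct %d: organ subset smaller than 3, skipped",
                        parameter, pct)
            continue
        test = two_group_test(cot, hyp)
        rows.append({
            "parameter": parameter,
            "pct": pct,
            "end": end,
            "n_cot": len(cot),
            "n_hyp": len(hyp),
            "median_cot": float(np.median(cot)),
            "median_hyp": float(np.median(hyp)),
            "dm_lfc": float(np.median(cot) - np.median(hyp)),
            "statistic": test.statistic,
            "method": test.method,
            "p": test.pvalue,
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["padj"] = bh_adjust(out["p"])
        out["significant"] = out["padj"] <= alpha
    return out


def select_candidates(
    profiles: pd.DataFrame,
    records: pd.DataFrame,
    lfc_cut: float = -1.0,
    alpha: float = 0.05,
    pct_hi: float = 95.0,
    pct_lo: float = 5.0,
    organ: str | None = None,
) -> CandidateSet:
    """Strongly downregulated genes with extreme codon load.

    A gene is selected iff padj <= ``alpha``, LFC <= ``lfc_cut`` and at
    least one frequency parameter lies strictly above its ``pct_hi``-th
    percentile, or D lies strictly below its ``pct_lo``-th percentile.
    Percentile cuts are computed over all profiled genes with a
    non-missing value of the parameter.
    """
    if len(profiles) < 20:
        raise ValueError("need >= 20 profiled genes for stable percentile cuts")
    cuts = {p: percentile(profiles[p], pct_hi) for p in FREQUENCY_PARAMETERS}
    cuts["D"] = percentile(profiles["D"], pct_lo)

    merged = records.merge(profiles, on="gene_id", how="inner")
    n_lost = len(records) - len(merged)
    if n_lost:
        log.info("%d expression record(s) without a profile ignored", n_lost)
    sig = merged["padj"].notna() & (merged["padj"] <= alpha) & (merged["lfc"] <= lfc_cut)
    extreme = pd.Series(False, index=merged.index)
    trig = pd.Series("", index=merged.index)
    for p in FREQUENCY_PARAMETERS:
        hit = merged[p] > cuts[p]
        extreme |= hit.fillna(False)
        trig = trig.where(~hit.fillna(False), trig + p + ";")
    hit_d = merged["D"] < cuts["D"]
    extreme |= hit_d.fillna(False)
    trig = trig.where(~hit_d.fillna(False), trig + "D;")

    chosen = merged[sig & extreme].copy()
    chosen["triggering_parameters"] = trig[chosen.index].str.rstrip(";")
    table = chosen[["gene_id", "lfc", "padj", "triggering_parameters"]].reset_index(drop=True)
    return CandidateSet(
        organ=organ,
        gene_ids=frozenset(chosen["gene_id"]),
        rule={"lfc_cut": lfc_cut, "alpha": alpha, "pct_hi": pct_hi, "pct_lo": pct_lo},
        percentile_values=cuts,
        table=table,
    )


def dm_matrix(profiles: pd.DataFrame, lfc_by_gene: dict, pcts=DEFAULT_PCTS) -> pd.DataFrame:
    """Parameter x percentage-class matrix of DM_LFC values (heat-map layout)."""
    cols = {}
    for param in PARAMETERS:
        try:
            curve = dm_lfc_curve(profiles, lfc_by_gene, param, pcts)
        except ValueError:
            continue
        cols[param] = curve.set_index("pct")["dm_lfc"]
    mat = pd.DataFrame(cols)
    mat.index.name = "pct"
    return mat
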