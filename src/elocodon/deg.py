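"""DEG filtering, cross-organ partitioning and group comparisons.

A gene is called differentially expressed when its BH-adjusted p-value,
absolute log2 fold change and mean expression all clear the thresholds
(defaults: padj <= 0.05, |LFC| >= 0.5, mean count >= 100; all bounds
inclusive).  DEG sets from two organs are partitioned into organ-specific
and shared (same- or opposite-direction) classes, and gene groups are
compared by their median |LFC| or median codon-parameter values with the
normality-dispatched two-group test and Benjamini–Hochberg correction
within each family of comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .codon_metrics import PARAMETERS
from .stats import bh_adjust, two_group_test

log = logging.getLogger(__name__)

__all__ = [
    "OrganPartition",
    "filter_degs",
    "partition_organs",
    "compare_abs_lfc",
    "compare_down_vs_up",
]


@dataclass(frozen=True)
class OrganPartition:
    """Disjoint, exhaustive decomposition of two organs' DEG sets."""

    hyp_only_up: frozenset
    hyp_only_down: frozenset
    cot_only_up: frozenset
    cot_only_down: frozenset
    shared_same_up: frozenset
    shared_same_down: frozenset
    shared_opposite_hyp_up: frozenset      # up in hypocotyl, down in cotyledon
    shared_opposite_hyp_down: frozenset    # down in hypocotyl, up in cotyledon

    def as_dict(self) -> dict[str, frozenset]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"set": name, "n": len(genes), "gene_ids": ";".join(sorted(genes))}
                for name, genes in self.as_dict().items()
            ]
        )


def filter_degs(
    records: pd.DataFrame,
    alpha: float = 0.05,
    lfc_min: float = 0.5,
    min_mean: float = 100.0,
) -> pd.DataFrame:
    """Apply the DEG thresholds to one organ's expression table.

    Returns a DataFrame ``gene_id, organ?, direction, lfc, padj`` of the
    passing genes.  Records with missing padj never pass (they were removed
    upstream by independent filtering, not shown to be significant).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if lfc_min < 0 or min_mean < 0:
        raise ValueError("lfc_min and min_mean must be non-negative")
    rec = records
    ok = (
        rec["padj"].notna()
        & (rec["padj"] <= alpha)
        & (rec["lfc"].abs() >= lfc_min)
        & (rec["base_mean"] >= min_mean)
        & (rec["lfc"] != 0)
    )
    out = rec.loc[ok, [c for c in ("gene_id", "organ", "lfc", "padj") if c in rec.columns]].copy()
    out["direction"] = np.where(out["lfc"] > 0, "up", "down")
    return out.reset_index(drop=True)


def _direction_map(calls: pd.DataFrame, label: str) -> dict[str, str]:
    if calls["gene_id"].duplicated().any():
        dup = calls.loc[calls["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{label}: gene {dup!r} called more than once in one organ")
    return dict(zip(calls["gene_id"], calls["direction"]))


def partition_organs(deg_hyp: pd.DataFrame, deg_cot: pd.DataFrame) -> OrganPartition:
    """Partition hypocotyl and cotyledon DEG calls into the eight classes."""
    hyp = _direction_map(deg_hyp, "hypocotyl")
    cot = _direction_map(deg_cot, "cotyledon")
    shared = set(hyp) & set(cot)
    sets: dict[str, set] = {f.name: set() for f in fields(OrganPartition)}
    for g, d in hyp.items():
        if g not in shared:
            sets[f"hyp_only_{d}"].add(g)
    for g, d in cot.items():
        if g not in shared:
            sets[f"cot_only_{d}"].add(g)
    for g in shared:
        if hyp[g] == cot[g]:
            sets[f"shared_same_{hyp[g]}"].add(g)
        else:
            sets[f"shared_opposite_hyp_{hyp[g]}"].add(g)
    return OrganPartition(**{k: frozenset(v) for k, v in sets.items()})


def _pct_diff(a: float, b: float) -> float:
    return 100.0 * (a - b) / b if b != 0 else np.nan


def _comparison_row(label, a, b, test):
    return {
        "label": label,
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "pct_diff": _pct_diff(float(np.median(a)), float(np.median(b))),
        "statistic": test.statistic,
        "method": test.method,
        "p": test.pvalue,
        "n_a": len(a),
        "n_b": len(b),
    }


def compare_abs_lfc(
    partition: OrganPartition,
    hyp_table: pd.DataFrame,
    cot_table: pd.DataFrame,
    sets: list[str] | None = None,
) -> pd.DataFrame:
    """Compare median |LFC| between organs over selected partition classes.

    For each selected class, ``median_a`` is the median hypocotyl |LFC|
    and ``median_b`` the median cotyledon |LFC| of the class members;
    p-values are BH-adjusted across all reported comparisons.  Classes with
    fewer than 3 genes represented on either side are skipped with a warning.
    """
    classes = partition.as_dict()
    if sets is None:
        sets = list(classes)
    unknown = [s for s in sets if s not in classes]
    if unknown:
        raise ValueError(f"unknown partition set(s) {unknown}")
    hyp_lfc = dict(zip(hyp_table["gene_id"], hyp_table["lfc"]))
    cot_lfc = dict(zip(cot_table["gene_id"], cot_table["lfc"]))
    rows = []
    for name in sets:
        genes = classes[name]
        a = np.abs([hyp_lfc[g] for g in genes if g in hyp_lfc])
        b = np.abs([cot_lfc[g] for g in genes if g in cot_lfc])
        if len(a) < 3 or len(b) < 3:
            log.warning("set %s: fewer than 3 genes per organ, skipped", name)
            continue
        rows.append(_comparison_row(name, a, b, two_group_test(a, b)))
    out = pd.DataFrame(rows)
    if not out.empty:
        out["padj"] = bh_adjust(out["p"])
    return out


def compare_down_vs_up(profiles: pd.DataFrame, degs: pd.DataFrame) -> pd.DataFrame:
    """Compare codon parameters between down- and upregulated DEGs.

    For each of the six parameters, ``median_a`` is the median among
    downregulated genes and ``median_b`` among upregulated ones, so a
    positive ``pct_diff`` means enrichment in the downregulated set.
    P-values are BH-adjusted across the six parameters.
    """
    prof = profiles.set_index("gene_id")
    have = degs["gene_id"].isin(prof.index)
    n_missing = int((~have).sum())
    if n_missing:
        log.warning("%d DEG(s) without a codon profile dropped", n_missing)
    degs = degs[have]
    down = degs.loc[degs["direction"] == "down", "gene_id"]
    up = degs.loc[degs["direction"] == "up", "gene_id"]
    if len(down) < 3 or len(up) < 3:
        raise ValueError(
            f"need >= 3 genes per direction (got {len(down)} down, {len(up)} up)"
        )
    rows = []
    for param in PARAMETERS:
        a = prof.loc[down, param].dropna().to_numpy()
        b = prof.loc[up, param].dropna().to_numpy()
        if len(a) < 3 or len(b) < 3:
            log.warning("parameter %s: too few non-missing values, skipped", param)
            continue
        rows.append(_comparison_row(param, a, b, two_group_test(a, b)))
    out = pd.DataFrame(rows)
    if not out.empty:
        out["padj"] = bh_adjust(out["p"])
    return out
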