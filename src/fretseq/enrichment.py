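"""Frequencies, enrichment ratios and the four-dimensional selection rule.

For variant v with count c_v in a pool of total accepted reads, the
frequency is f_v = c_v / sum_k c_k and the enrichment ratio of a sorted
pool against its unsorted input is E_v = f_v,sorted / f_v,input.  A desired
biosensor is enriched in the high-FRET active-kinase pool and the low-FRET
kinase-dead pool and depleted in the two counterpart pools:

    selected  <=>  E(KAH) > 1  and  E(KDL) > 1  and  E(KAL) < 1  and  E(KDH) < 1

(all inequalities strict).  Candidates are ranked by E(KAH) * E(KDL), and
the parental (wild-type) variant's product is the calibration threshold.
Variants whose input CPM is not strictly above 10 have undefined E and are
excluded rather than smoothed; no pseudocounts anywhere.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .read_processing import PoolCounts

SORTED_GROUPS = ("KAH", "KAL", "KDH", "KDL")
#: input pool feeding each sorted group (per-context inputs; a shared
#: "INPUT" pool may stand in for both).
INPUT_OF_GROUP = {"KAH": "INPUT_KA", "KAL": "INPUT_KA", "KDH": "INPUT_KD", "KDL": "INPUT_KD"}

CPM_THRESHOLD_DEFAULT = 10.0


def to_cpm(counts: PoolCounts) -> dict[str, float]:
    """Counts per million: cpm_v = 1e6 * c_v / total accepted reads."""
    if counts.total_reads <= 0:
        raise ValueError("cannot compute CPM for an empty pool")
    scale = 1e6 / counts.total_reads
    return {v: c * scale for v, c in counts.counts.items()}


def filter_positive(
    cpm: Mapping[str, float], threshold: float = CPM_THRESHOLD_DEFAULT
) -> set[str]:
    """Variants considered positive: CPM strictly above the threshold."""
    return {v for v, x in cpm.items() if x > threshold}


def frequencies(counts: PoolCounts) -> dict[str, float]:
    """Per-variant frequency f_v = c_v / sum_k c_k (sums to 1)."""
    if counts.total_reads <= 0:
        raise ValueError("cannot compute frequencies for an empty pool")
    total = counts.total_reads
    return {v: c / total for v, c in counts.counts.items()}


def enrichment(f_sorted: float, f_input: float) -> float:
    """E_v = f_sorted / f_input; NaN (undefined) when the input frequency is 0."""
    if f_input <= 0:
        return math.nan
    return f_sorted / f_input


def plot_normalize(e_v):
    """Piecewise plot coordinate: log10(E) above 1, E - 1 at or below 1.

    Continuous and monotone non-decreasing on [0, inf); both branches give
    0 at E = 1.  NaN (undefined E) propagates.
    """
    e = np.asarray(e_v, dtype=float)
    out = np.where(e > 1, np.log10(np.where(e > 1, e, 1.0)), e - 1.0)
    if np.isscalar(e_v) or np.ndim(e_v) == 0:
        return float(out)
    return out


def build_enrichment_table(
    pools: Mapping[str, PoolCounts],
    cpm_threshold: float = CPM_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Assemble the per-variant enrichment table from amino-acid pool counts.

    ``pools`` must contain the four sorted groups plus either a shared
    "INPUT" pool or per-context "INPUT_KA" / "INPUT_KD" pools.  The result
    is indexed by amino-acid variant with, per group g: ``count_g``,
    ``cpm_g``, ``f_g``, and for sorted groups ``E_g`` and ``Evn_g``; plus
    ``product_score`` (E_KAH * E_KDL), ``contains_stop`` and ``passes_4d``.
    E is NaN wherever the relevant input CPM fails the strict threshold.
    """
    resolved: dict[str, PoolCounts] = {}
    for g in SORTED_GROUPS:
        if g not in pools:
            raise ValueError(f"missing sorted pool {g}")
        resolved[g] = pools[g]
    for inp in ("INPUT_KA", "INPUT_KD"):
        if inp in pools:
            resolved[inp] = pools[inp]
        elif "INPUT" in pools:
            resolved[inp] = pools["INPUT"]
        else:
            raise ValueError(f"missing input pool ({inp} or INPUT)")
    for name, pc in resolved.items():
        if pc.level != "aa":
            raise ValueError(f"pool {name} is not amino-acid level")
        if pc.total_reads <= 0:
            raise ValueError(f"pool {name} is empty")

    variants = sorted(set().union(*(pc.counts for pc in resolved.values())))
    df = pd.DataFrame(index=pd.Index(variants, name="aa"))
    for name, pc in resolved.items():
        series = pd.Series(pc.counts, dtype="float64").reindex(variants).fillna(0.0)
        df[f"count_{name}"] = series.astype("int64")
        df[f"cpm_{name}"] = series * (1e6 / pc.total_reads)
        df[f"f_{name}"] = series / pc.total_reads

    for g in SORTED_GROUPS:
        inp = INPUT_OF_GROUP[g]
        defined = df[f"cpm_{inp}"] > cpm_threshold
        e = np.where(defined, df[f"f_{g}"] / df[f"f_{inp}"].where(defined), np.nan)
        df[f"E_{g}"] = e
        df[f"Evn_{g}"] = plot_normalize(df[f"E_{g}"].to_numpy())

    df["product_score"] = df["E_KAH"] * df["E_KDL"]
    df["contains_stop"] = df.index.str.contains(r"\*", regex=True)
    e_ok = df[[f"E_{g}" for g in SORTED_GROUPS]].notna().all(axis=1)
    df["passes_4d"] = (
        e_ok
        & ~df["contains_stop"]
        & (df["E_KAH"] > 1)
        & (df["E_KDL"] > 1)
        & (df["E_KAL"] < 1)
        & (df["E_KDH"] < 1)
    )
    return df


def select_4d(table: pd.DataFrame) -> list[str]:
    """Amino-acid variants passing all four strict enrichment criteria."""
    return table.index[table["passes_4d"]].tolist()


@dataclass
class RankingResult:
    """4D candidates ranked by product score with WT calibration."""

    ranked: list[str]
    products: dict[str, float]
    wt_variant: str | None
    wt_product: float | None
    above_wt: list[str] | None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "aa": self.ranked,
                "product_score": [self.products[v] for v in self.ranked],
            }
        )
        if self.wt_product is not None:
            df["above_wt"] = df["product_score"] > self.wt_product
        return df


def rank_and_calibrate(table: pd.DataFrame, wt_variant: str | None = None) -> RankingResult:
    """Rank 4D candidates by E(KAH)*E(KDL), descending; calibrate against WT.

    Ties are broken lexicographically by amino-acid sequence so the order
    is platform-independent.  If the WT variant is absent from the table or
    its product is undefined, the ranking is still returned and the
    above-WT subset is None (calibration unavailable).
    """
    candidates = select_4d(table)
    products = {v: float(table.at[v, "product_score"]) for v in candidates}
    ranked = sorted(candidates, key=lambda v: (-products[v], v))
    wt_product: float | None = None
    above: list[str] | None = None
    if wt_variant is not None and wt_variant in table.index:
        wt_val = float(table.at[wt_variant, "product_score"])
        if not math.isnan(wt_val):
            wt_product = wt_val
            above = [v for v in ranked if products[v] > wt_product]
    return RankingResult(
        ranked=ranked,
        products=products,
        wt_variant=wt_variant,
        wt_product=wt_product,
        above_wt=above,
    )


def write_enrichment_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def read_enrichment_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="aa")


def selection_summary(
    table: pd.DataFrame,
    ranking: RankingResult,
    cpm_threshold: float = CPM_THRESHOLD_DEFAULT,
) -> dict:
    """Machine-readable funnel: thresholds, stage counts, WT calibration."""
    e_defined = int(
        table[[f"E_{g}" for g in SORTED_GROUPS]].notna().all(axis=1).sum()
    )
    return {
        "cpm_threshold": cpm_threshold,
        "n_variants": int(len(table)),
        "n_e_defined": e_defined,
        "n_candidates_4d": len(ranking.ranked),
        "wt_variant": ranking.wt_variant,
        "wt_product": ranking.wt_product,
        "n_above_wt": None if ranking.above_wt is None else len(ranking.above_wt),
    }
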