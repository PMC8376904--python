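"""Evaluation of selections against ground truth or tested-clone tables.

Two evaluation modes:

* simulation mode — compare the selected variant set against the
  generative truth (precision/recall over planted responsive variants,
  cumulative 1D -> 4D criterion sweep, misfolded-variant rejection);
* clone mode — given a table of experimentally tested clones (substrate,
  measured dynamic range, enrichment product), the success rate of
  identifying a biosensor better than the parental WT, with and without
  the WT-product calibration threshold.

Also hosts the end-to-end orchestration: simulate -> count -> enrich ->
evaluate on one config.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import (
    SORTED_GROUPS,
    RankingResult,
    build_enrichment_table,
    rank_and_calibrate,
    select_4d,
)
from .library_design import LibraryLayout, fyn_lib2_layout
from .read_processing import aggregate_to_aa, count_fastq
from .simulation import SimulationConfig, SimulationTruth, simulate_experiment

#: cumulative criterion order for the 1D -> 4D sweep (KAH first, its
#: product partner KDL second, then the depletion arms).
SWEEP_STAGES = (
    ("KAH",),
    ("KAH", "KDL"),
    ("KAH", "KDL", "KAL"),
    ("KAH", "KDL", "KAL", "KDH"),
)


@dataclass
class TestedClone:
    """An experimentally characterized clone from the screen."""

    substrate_aa: str
    dynamic_range: float          # percent FRET-ratio change upon stimulus
    product_score: float          # E(KAH) * E(KDL)


def success_rate(
    clones: Sequence[TestedClone],
    wt_dynamic_range: float,
    wt_product: float,
    use_threshold: bool,
) -> float:
    """Fraction of (threshold-passing) clones beating the WT dynamic range.

    Without the threshold this is the raw success rate over all tested
    clones; with it, the rate among clones whose enrichment product is
    strictly above the WT product.  Returns NaN if the threshold leaves no
    clones (not applicable).
    """
    if not clones:
        raise ValueError("clones must be non-empty")
    pool = [c for c in clones if (not use_threshold) or c.product_score > wt_product]
    if not pool:
        return math.nan
    better = sum(1 for c in pool if c.dynamic_range > wt_dynamic_range)
    return better / len(pool)


def clones_from_tsv(path: str | Path) -> list[TestedClone]:
    df = pd.read_csv(path, sep="\t")
    return [
        TestedClone(
            substrate_aa=str(r.substrate_aa),
            dynamic_range=float(r.dynamic_range),
            product_score=float(r.product_score),
        )
        for r in df.itertuples()
    ]


@dataclass
class RecoveryReport:
    """Selection quality against simulation ground truth."""

    n_selected: int
    n_true_responsive_selected: int
    precision: float
    recall: float
    recall_strong: float
    stage_precision: dict[str, float] = field(default_factory=dict)
    stage_n_selected: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _positives(truth: SimulationTruth) -> set[str]:
    mask = truth.responsive & ~truth.misfolded
    return {truth.aa[i] for i in np.nonzero(mask)[0]}


def recovery_metrics(
    selected: Iterable[str],
    truth: SimulationTruth,
    strong_shift_min: float | None = None,
) -> RecoveryReport:
    """Precision/recall of a selected variant set against planted truth.

    Positives are responsive, non-misfolded variants.  ``recall_strong``
    restricts the denominator to strongly responsive variants
    (shift >= strong_shift_min; defaults to the median planted shift).
    Precision is NaN for an empty selection; recall of an empty positive
    set is NaN.
    """
    sel = set(selected)
    pos = _positives(truth)
    if strong_shift_min is None:
        resp_shifts = truth.shift[truth.responsive & ~truth.misfolded]
        strong_shift_min = float(np.median(resp_shifts)) if len(resp_shifts) else 0.0
    strong = {
        truth.aa[i]
        for i in np.nonzero(
            truth.responsive & ~truth.misfolded & (truth.shift >= strong_shift_min)
        )[0]
    }
    tp = len(sel & pos)
    precision = tp / len(sel) if sel else math.nan
    recall = tp / len(pos) if pos else math.nan
    recall_strong = len(sel & strong) / len(strong) if strong else math.nan
    return RecoveryReport(
        n_selected=len(sel),
        n_true_responsive_selected=tp,
        precision=precision,
        recall=recall,
        recall_strong=recall_strong,
    )


def dimension_sweep(
    table: pd.DataFrame, truth: SimulationTruth
) -> tuple[dict[str, float], dict[str, int]]:
    """Precision at each cumulative selection stage (KAH; +KDL; +KAL; +KDH).

    Only variants with all four E defined enter the sweep, so every stage
    filters the same universe.  A stage with an empty selection reports NaN
    precision.
    """
    pos = _positives(truth)
    e_cols = [f"E_{g}" for g in SORTED_GROUPS]
    universe = table[table[e_cols].notna().all(axis=1) & ~table["contains_stop"]]
    precisions: dict[str, float] = {}
    n_selected: dict[str, int] = {}
    for stage in SWEEP_STAGES:
        mask = pd.Series(True, index=universe.index)
        for g in stage:
            if g in ("KAH", "KDL"):
                mask &= universe[f"E_{g}"] > 1
            else:
                mask &= universe[f"E_{g}"] < 1
        sel = set(universe.index[mask])
        label = f"{len(stage)}D"
        n_selected[label] = len(sel)
        precisions[label] = len(sel & pos) / len(sel) if sel else math.nan
    return precisions, n_selected


def misfolded_rejected(table: pd.DataFrame, truth: SimulationTruth) -> bool:
    """True iff every planted misfolded variant fails selection.

    A misfolded variant present in the table with defined KDH/KDL
    enrichment must violate at least one of the kinase-dead criteria
    (E_KDH < 1, E_KDL > 1); one absent or undefined is not selected either
    way.
    """
    selected = set(select_4d(table))
    for i in np.nonzero(truth.misfolded)[0]:
        aa = truth.aa[i]
        if aa in selected:
            return False
        if aa in table.index:
            e_kdh = table.at[aa, "E_KDH"]
            e_kdl = table.at[aa, "E_KDL"]
            if not (math.isnan(e_kdh) or math.isnan(e_kdl)):
                if e_kdh < 1 and e_kdl > 1:
                    return False
    return True


@dataclass
class ScreenResult:
    """Everything the end-to-end pipeline produced for one config."""

    truth: SimulationTruth
    table: pd.DataFrame
    ranking: RankingResult
    report: RecoveryReport
    misfolded_all_rejected: bool
    qc_stats: dict[str, dict[str, int]]

    def report_dict(self) -> dict:
        out = self.report.to_dict()
        out["misfolded_all_rejected"] = self.misfolded_all_rejected
        out["n_candidates_4d"] = len(self.ranking.ranked)
        return out


def run_screen(
    config: SimulationConfig,
    layout: LibraryLayout | None = None,
    workdir: str | Path = ".",
    min_phred: int = 20,
    cpm_threshold: float = 10.0,
    strong_shift_min: float | None = None,
) -> ScreenResult:
    """Full pipeline on one simulated experiment.

    Simulates the sorted libraries, counts all six FASTQ pools, aggregates
    to amino-acid level, builds the enrichment table, applies the 4D
    selection and scores it against the generative truth.  ``workdir``
    receives the intermediate FASTQ/TSV artifacts.
    """
    if layout is None:
        layout = fyn_lib2_layout()
    truth, paths = simulate_experiment(config, layout, workdir)
    pools = {}
    qc_stats = {}
    for name, path in paths.items():
        dna_counts = count_fastq(path, layout, group=name, min_phred=min_phred)
        pools[name] = aggregate_to_aa(dna_counts)
        qc_stats[name] = dict(dna_counts.qc_stats)
    table = build_enrichment_table(pools, cpm_threshold=cpm_threshold)
    ranking = rank_and_calibrate(table)
    if strong_shift_min is None:
        strong_shift_min = config.shift_mean
    report = recovery_metrics(ranking.ranked, truth, strong_shift_min=strong_shift_min)
    report.stage_precision, report.stage_n_selected = dimension_sweep(table, truth)
    return ScreenResult(
        truth=truth,
        table=table,
        ranking=ranking,
        report=report,
        misfolded_all_rejected=misfolded_rejected(table, truth),
        qc_stats=qc_stats,
    )


def write_report_json(result: ScreenResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.report_dict(), indent=2) + "\n")
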