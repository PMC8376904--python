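"""Scoring for saFRET-based high-throughput drug screens.

A self-activating FRET biosensor carries its target kinase domain, so in a
drug screen the endpoint ECFP/FRET ratio reports direct kinase inhibition:
an effective inhibitor lowers the ratio relative to the solvent (DMSO)
control.  A parallel counter screen with the kinase-dead biosensor catches
compounds whose apparent effect is kinase-independent (auto-fluorescence,
non-specific quenching): a true hit reduces the active-kinase signal but
leaves the kinase-dead signal essentially unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ACTIVE = "active"
DEAD = "dead"
CONTEXTS = (ACTIVE, DEAD)

HIT_THRESHOLD_DEFAULT = 15.0          # percent reduction on the active-kinase arm
NONSPECIFIC_THRESHOLD_DEFAULT = 10.0  # percent reduction tolerated on the dead arm

#: dynamic range below which an assay window is considered marginal for HTDS
MIN_ASSAY_WINDOW_PCT = 20.0


@dataclass
class CellTimecourse:
    """Single-cell ECFP/FRET ratio time course around a stimulation."""

    cell_id: str
    ratios: np.ndarray
    stimulation_index: int

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if not (0 < self.stimulation_index < len(self.ratios)):
            raise ValueError("stimulation_index must lie strictly inside the series")
        if not (self.ratios > 0).all():
            raise ValueError("FRET ratios must be positive")


def baseline_normalize(tc: CellTimecourse) -> np.ndarray:
    """Divide a cell's time course by its own pre-stimulation mean.

    The mean of the normalized pre-stimulation segment is exactly 1, so
    per-cell expression differences cancel.  Idempotent.
    """
    baseline = float(tc.ratios[: tc.stimulation_index].mean())
    if baseline <= 0:
        raise ValueError("non-positive pre-stimulation baseline")
    return tc.ratios / baseline


@dataclass
class ScreenWell:
    """One well of an endpoint screen: a compound in one biosensor context."""

    compound_id: str
    context: str
    ratios: np.ndarray
    solvent_control: bool = False

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if len(self.ratios) < 1:
            raise ValueError("a well needs at least one cell")
        if self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}")

    @property
    def mean_ratio(self) -> float:
        return float(self.ratios.mean())


def endpoint_percent_change(treated: ScreenWell, control: ScreenWell) -> float:
    """Endpoint FRET-ratio change of a treated well vs the solvent control.

    100 * (mean_treated - mean_control) / mean_control; negative values
    mean the compound reduced the biosensor ratio (kinase inhibition on
    the active-kinase arm).
    """
    if treated.context != control.context:
        raise ValueError("treated and control wells must share a biosensor context")
    return 100.0 * (treated.mean_ratio - control.mean_ratio) / control.mean_ratio


def counter_screen(
    ka_changes: Mapping[str, float],
    kd_changes: Mapping[str, float],
    hit_threshold: float = HIT_THRESHOLD_DEFAULT,
    nonspecific_threshold: float = NONSPECIFIC_THRESHOLD_DEFAULT,
) -> dict[str, str]:
    """Classify compounds from paired active/dead percent changes.

    * ``nonspecific`` — the kinase-dead biosensor also dropped by at least
      the nonspecific threshold: the effect is kinase-independent and the
      compound is eliminated, whatever the active arm showed;
    * ``hit`` — active-kinase change <= -hit_threshold with an acceptable
      kinase-dead arm;
    * ``inactive`` — everything else;
    * ``unevaluable`` — no counter-screen measurement for the compound.
    """
    out: dict[str, str] = {}
    for compound, ka in ka_changes.items():
        if compound not in kd_changes:
            out[compound] = "unevaluable"
            continue
        kd = kd_changes[compound]
        if kd <= -nonspecific_threshold:
            out[compound] = "nonspecific"
        elif ka <= -hit_threshold:
            out[compound] = "hit"
        else:
            out[compound] = "inactive"
    return out


def assay_window_ok(dynamic_range_pct: float) -> bool:
    """Advisory check: is the biosensor window wide enough for HTDS (~20%)?"""
    return abs(dynamic_range_pct) >= MIN_ASSAY_WINDOW_PCT


def score_plate(
    plate: pd.DataFrame,
    hit_threshold: float = HIT_THRESHOLD_DEFAULT,
    nonspecific_threshold: float = NONSPECIFIC_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Score a long-format plate table into per-compound classifications.

    ``plate`` columns: well, compound, context ("active"/"dead"), cell_id,
    ratio, solvent_control (bool).  Per context, treated wells are compared
    against the pooled solvent-control cells of that context.  Returns one
    row per compound with ka_change, kd_change and classification, sorted
    by ka_change ascending (strongest apparent inhibition first).
    """
    required = {"compound", "context", "ratio", "solvent_control"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")

    changes: dict[str, dict[str, float]] = {ACTIVE: {}, DEAD: {}}
    for context in CONTEXTS:
        sub = plate[plate["context"] == context]
        if sub.empty:
            continue
        controls = sub[sub["solvent_control"].astype(bool)]
        if controls.empty:
            raise ValueError(f"no solvent-control well in context {context!r}")
        control_mean = controls["ratio"].mean()
        treated = sub[~sub["solvent_control"].astype(bool)]
        for compound, grp in treated.groupby("compound"):
            changes[context][str(compound)] = float(
                100.0 * (grp["ratio"].mean() - control_mean) / control_mean
            )

    classes = counter_screen(
        changes[ACTIVE],
        changes[DEAD],
        hit_threshold=hit_threshold,
        nonspecific_threshold=nonspecific_threshold,
    )
    rows = [
        {
            "compound": compound,
            "ka_change": changes[ACTIVE][compound],
            "kd_change": changes[DEAD].get(compound, np.nan),
            "classification": cls,
        }
        for compound, cls in classes.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["ka_change", "compound"], kind="stable")
        .reset_index(drop=True)
    )


def simulate_plate(
    compound_effects: Mapping[str, tuple[float, float]],
    n_cells_per_well: int = 50,
    baseline_ratio: float = 1.0,
    cell_noise_sd: float = 0.05,
    seed: int = 0,
    solvent_name: str = "DMSO",
) -> pd.DataFrame:
    """Synthetic endpoint plate with planted per-compound effects.

    ``compound_effects`` maps compound -> (active-arm %, dead-arm %)
    true percent changes relative to the solvent control.  Cells draw
    independent Gaussian noise around the shifted well mean.  Returns the
    long-format table :func:`score_plate` consumes.
    """
    rng = np.random.default_rng(seed)
    rows = []
    wells = [(solvent_name, 0.0, 0.0, True)] + [
        (c, ka, kd, False) for c, (ka, kd) in sorted(compound_effects.items())
    ]
    well_no = 0
    for compound, ka_pct, kd_pct, is_control in wells:
        for context, pct in ((ACTIVE, ka_pct), (DEAD, kd_pct)):
            well_no += 1
            mean = baseline_ratio * (1.0 + pct / 100.0)
            ratios = np.clip(
                mean + rng.normal(0.0, cell_noise_sd * baseline_ratio, n_cells_per_well),
                1e-6,
                None,
            )
            for cell_id, r in enumerate(ratios):
                rows.append(
                    {
                        "well": f"W{well_no:03d}",
                        "compound": compound,
                        "context": context,
                        "cell_id": f"{well_no}:{cell_id}",
                        "ratio": float(r),
                        "solvent_control": is_control,
                    }
                )
    return pd.DataFrame(rows)
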