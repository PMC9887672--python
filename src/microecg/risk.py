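"""TdP risk scoring (-1...3) and the two-dimensional risk map.

Each compound receives an integer score from the MID/HIGH threshold calls
and the arrhythmia flag, and a safety margin: the ratio between the
concentration eliciting the scored response (or the maximum tested
concentration when nothing happened) and the free effective therapeutic
plasma concentration (f_ETPC).  Score and margin together place the
compound in a high / intermediate / low risk region, or leave it
uncategorizable when the margin is too small to judge a score-1 effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose import DIR_DOWN, DIR_UP, CompoundCall

CATEGORY_HIGH = "high"
CATEGORY_INTERMEDIATE = "intermediate"
CATEGORY_LOW = "low"
CATEGORY_UNCATEGORIZABLE = "uncategorizable"

SCORES = (-1, 0, 1, 2, 3)


@dataclass
class RiskAssessment:
    compound: str
    score: int
    margin: float | None
    category: str
    margin_concentration: float | None = None  # uM, the concentration used


def assign_score(call: CompoundCall, arrhythmia: bool | None = None) -> int:
    """TdP score from the threshold calls and the arrhythmia flag.

    3 = arrhythmic events; 2 = prolongation beyond HIGH; 1 = prolongation
    between MID and HIGH; -1 = shortening beyond MID; 0 = no effect above
    MID.  The -1/0 split keeps shortening and "no effect" disjoint.
    """
    if arrhythmia is None:
        arrhythmia = call.arrhythmia
    if arrhythmia:
        return 3
    mid = call.at("MID")
    if mid.direction == DIR_UP:
        return 2 if call.at("HIGH").direction == DIR_UP else 1
    if mid.direction == DIR_DOWN:
        return -1
    return 0


def scored_concentration(call: CompoundCall, score: int,
                         use_arrhythmic_dose: bool = True) -> float | None:
    """Concentration eliciting the scored response, in uM.

    Score 3 uses the lowest arrhythmic dose (configurable to the
    FPD-effective dose instead); 2 uses the HIGH crossing; 1 and -1 the MID
    crossing; 0 falls back to the maximum tested concentration.
    """
    if score == 3:
        if use_arrhythmic_dose and call.arrhythmia_lowest_dose is not None:
            return call.arrhythmia_lowest_dose
        for name in ("MID", "HIGH", "LOW"):
            if call.at(name).concentration is not None:
                return call.at(name).concentration
        return call.max_tested
    if score == 2:
        return call.at("HIGH").concentration
    if score in (1, -1):
        return call.at("MID").concentration
    return call.max_tested


def compute_margin(concentration: float | None,
                   f_etpc: float | None) -> float | None:
    """Safety margin = scored concentration / f_ETPC (dimensionless)."""
    if concentration is None or f_etpc is None or f_etpc <= 0:
        return None
    return float(concentration) / float(f_etpc)


def categorize(score: int, margin: float | None) -> str:
    """Map a (score, margin) pair to exactly one risk category.

    High: score >= 2 at margin <= 10.  Intermediate: score 1 at margin in
    (1, 100], or score >= 2 at margin in (10, 100].  Low: score <= 0, or
    score >= 1 at margin > 100.  Uncategorizable: score 1 with margin <= 1
    (insufficient margin to judge), or any scored effect with no margin.
    """
    if score <= 0:
        return CATEGORY_LOW
    if margin is None:
        return CATEGORY_UNCATEGORIZABLE
    if score >= 2:
        if margin <= 10:
            return CATEGORY_HIGH
        if margin <= 100:
            return CATEGORY_INTERMEDIATE
        return CATEGORY_LOW
    # score == 1
    if margin <= 1:
        return CATEGORY_UNCATEGORIZABLE
    if margin <= 100:
        return CATEGORY_INTERMEDIATE
    return CATEGORY_LOW


def assess(call: CompoundCall, use_arrhythmic_dose: bool = True) -> RiskAssessment:
    score = assign_score(call)
    conc = scored_concentration(call, score, use_arrhythmic_dose)
    margin = compute_margin(conc, call.f_etpc)
    return RiskAssessment(compound=call.compound, score=score, margin=margin,
                          category=categorize(score, margin),
                          margin_concentration=conc)


def assess_panel(calls: dict[str, CompoundCall],
                 exclude_vehicle: str | None = "DMSO") -> pd.DataFrame:
    """Risk table (compound, score, margin, category) for a compound set."""
    rows = []
    for name, call in calls.items():
        if exclude_vehicle is not None and name == exclude_vehicle:
            continue
        a = assess(call)
        rows.append({"compound": a.compound, "score": a.score,
                     "margin": a.margin, "category": a.category,
                     "concentration_uM": a.margin_concentration})
    return pd.DataFrame(rows)


def build_risk_map(assessments: pd.DataFrame, path: str | None = None):
    """Score-vs-log(margin) scatter with shaded risk regions.

    Returns the matplotlib Figure; also saves to ``path`` when given.  An
    empty assessment table yields an empty (but valid) map.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    mlo, mhi = 1e-3, 1e6
    if len(assessments) and assessments["margin"].notna().any():
        margins = assessments["margin"].dropna()
        mlo = min(mlo, margins.min() / 10)
        mhi = max(mhi, margins.max() * 10)
    # region shading: high (score >= 2, margin <= 10), intermediate
    # (score 1 in (1, 100] and score >= 2 in (10, 100]), low elsewhere
    ax.fill_betweenx([1.5, 3.5], mlo, 10, color="tab:red", alpha=0.25,
                     label="high risk")
    ax.fill_betweenx([1.5, 3.5], 10, 100, color="gold", alpha=0.35,
                     label="intermediate risk")
    ax.fill_betweenx([0.5, 1.5], 1, 100, color="gold", alpha=0.35)
    ax.fill_betweenx([0.5, 3.5], 100, mhi, color="tab:green", alpha=0.25,
                     label="low risk")
    ax.fill_betweenx([-1.5, 0.5], mlo, mhi, color="tab:green", alpha=0.25)

    markers = {CATEGORY_HIGH: "o", CATEGORY_INTERMEDIATE: "^",
               CATEGORY_LOW: "s", CATEGORY_UNCATEGORIZABLE: "x"}
    for _, row in assessments.iterrows():
        if row["margin"] is None or not np.isfinite(row["margin"]):
            continue
        ax.scatter(row["margin"], row["score"], s=90, c="k", zorder=3,
                   marker=markers.get(row["category"], "o"))
        ax.annotate(str(row["compound"])[:2].upper(),
                    (row["margin"], row["score"]),
                    textcoords="offset points", xytext=(6, 6), fontsize=8)
    ax.set_xscale("log")
    ax.set_xlim(mlo, mhi)
    ax.set_ylim(-1.5, 3.5)
    ax.set_yticks(list(SCORES))
    ax.set_xlabel("effective concentration / f$_{ETPC}$")
    ax.set_ylabel("TdP risk score")
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
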