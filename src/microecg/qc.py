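"""Baseline quality control and cohort statistics.

A microtissue is included in a screen only if its baseline beating is
stable: the coefficient of variation (CV) of the per-beat beating period
must not exceed 25 %.  Dose groups are compared with the Kruskal-Wallis
omnibus test followed by Dunn's pairwise post-hoc comparisons.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .beats import EPSummary
from .errors import InsufficientBeatsError

DEFAULT_CV_THRESHOLD = 25.0


def compute_cv(bp_values) -> float:
    """Coefficient of variation of per-beat BP, in percent (sample SD / mean)."""
    bp = np.asarray(bp_values, dtype=float)
    bp = bp[np.isfinite(bp)]
    if len(bp) < 2:
        raise InsufficientBeatsError(
            f"CV needs at least 2 beat intervals, got {len(bp)}"
        )
    mean = float(np.mean(bp))
    if mean <= 0:
        raise InsufficientBeatsError("mean beating period must be positive")
    return 100.0 * float(np.std(bp, ddof=1)) / mean


def apply_inclusion(cv_percent: float,
                    cv_threshold: float = DEFAULT_CV_THRESHOLD) -> bool:
    """Inclusion rule: discard only tissues with CV strictly above the threshold."""
    return cv_percent <= cv_threshold


@dataclass
class QCReport:
    """Baseline stability report for one microtissue."""

    tissue_id: str
    cv_bp_percent: float
    included: bool
    baseline: EPSummary | None = None

    @classmethod
    def from_baseline(cls, tissue_id: str, bp_values,
                      baseline: EPSummary | None = None,
                      cv_threshold: float = DEFAULT_CV_THRESHOLD) -> "QCReport":
        cv = compute_cv(bp_values)
        return cls(tissue_id=tissue_id, cv_bp_percent=cv,
                   included=apply_inclusion(cv, cv_threshold), baseline=baseline)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn


@dataclass
class GroupComparison:
    """Omnibus Kruskal-Wallis result plus Dunn pairwise comparisons."""

    statistic: float
    pvalue: float
    dunn: pd.DataFrame  # columns: group_a, group_b, z, p_unadjusted, p_adjusted
    adjustment: str
    warning: str | None = None


def _dunn_pairs(groups: dict[str, np.ndarray], pairs: list[tuple[str, str]],
                adjustment: str) -> pd.DataFrame:
    labels = list(groups)
    all_values = np.concatenate([groups[g] for g in labels])
    n_total = len(all_values)
    ranks = stats.rankdata(all_values)
    mean_ranks: dict[str, float] = {}
    pos = 0
    for g in labels:
        k = len(groups[g])
        mean_ranks[g] = float(np.mean(ranks[pos:pos + k]))
        pos += k
    # tie correction for the rank variance
    _, counts = np.unique(all_values, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    m = len(pairs)
    for a, b in pairs:
        na, nb = len(groups[a]), len(groups[b])
        var = base_var * (1.0 / na + 1.0 / nb)
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var)
            p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p * m) if adjustment == "bonferroni" else p
        rows.append({"group_a": a, "group_b": b, "z": z,
                     "p_unadjusted": p, "p_adjusted": p_adj})
    return pd.DataFrame(rows)


def compare_doses(groups: dict[str, "np.ndarray | list"],
                  baseline_group: str | None = None,
                  adjustment: str = "bonferroni") -> GroupComparison:
    """Kruskal-Wallis over dose groups with Dunn's post-hoc comparisons.

    Parameters
    ----------
    groups : mapping of group label to replicate values (e.g. per-dose
        %dFPDcF across tissues).
    baseline_group : str, optional
        When given, Dunn comparisons are made against this group only (the
        usual dose-vs-baseline layout); otherwise all pairs are compared.
    adjustment : str
        Multiple-comparison adjustment recorded in the output; only the
        classical Bonferroni-style Dunn adjustment (or "none") is offered.
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(clean) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in clean.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs at least 2 replicates")

    warning = None
    values = [clean[k] for k in clean]
    if np.ptp(np.concatenate(values)) == 0:
        # all observations identical: midranks make H exactly 0
        stat, p = 0.0, 1.0
        warning = "degenerate input: all observations tied"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = stats.kruskal(*values)

    labels = list(clean)
    if baseline_group is not None:
        if baseline_group not in clean:
            raise ValueError(f"baseline group {baseline_group!r} not in groups")
        pairs = [(baseline_group, g) for g in labels if g != baseline_group]
    else:
        pairs = list(itertools.combinations(labels, 2))
    dunn = _dunn_pairs(clean, pairs, adjustment)
    return GroupComparison(statistic=float(stat), pvalue=float(p), dunn=dunn,
                           adjustment=adjustment, warning=warning)


def cohort_summary(reports: list[QCReport]) -> pd.DataFrame:
    """Cohort means +/- SD of BP, FPD, FPDcF and AMP over included tissues.

    Recomputed from the per-tissue baseline summaries, one row per
    parameter, with the number of tissues that contributed.
    """
    included = [r.baseline for r in reports if r.included and r.baseline]
    rows = []
    for label, attr in (("bp_s", "bp_mean"), ("fpd_s", "fpd_mean"),
                        ("fpd_cf_s", "fpd_cf_mean"), ("amp_uV", "amp_mean")):
        values = np.array([getattr(s, attr) for s in included], dtype=float)
        values = values[np.isfinite(values)]
        rows.append({
            "parameter": label,
            "mean": float(np.mean(values)) if len(values) else np.nan,
            "sd": float(np.std(values, ddof=1)) if len(values) >= 2 else np.nan,
            "n_tissues": int(len(values)),
        })
    return pd.DataFrame(rows)


def qc_table(reports: list[QCReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {"tissue_id": r.tissue_id, "cv_bp_percent": r.cv_bp_percent,
               "included": r.included}
        if r.baseline is not None:
            row.update(r.baseline.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
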