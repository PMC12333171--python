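"""Composite clinical scoring for the humanized myasthenia-gravis mouse model.

Disease severity in NSG mice engrafted with MG thymus is tracked weekly by four
complementary tests: body-weight loss, forelimb grip-strength loss, the time the
animal resists falling from an inverted grid (Tr, capped at 60 s), and a graded
behavioral observation.  Each test maps to an ordinal sub-score and the global
clinical score (GCS) combines them as

    GCS = weight_score + strength_score + (behavior_score + grid_score) / 2

giving a 0-10 scale where 0 is a healthy animal and 10 a dead one.  Scores are
normalized per animal to the week of cell injection, humanization failures
(< 0.4% human CD45+ blood cells) are excluded, and treatment arms are compared
by two-way ANOVA with Tukey multiple comparisons.

Cohort tables are DataFrames with columns
``animal, arm, week, weight, grip, grid_time, behavior, alive, cd45_pct``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ARMS = ("placebo", "rMSC", "cMSC")
BEHAVIOR_GRADES = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0)

MAX_SUBSCORES = {"weight": 3, "strength": 4, "grid": 3, "behavior": 3.0}


@dataclass(frozen=True)
class SubScores:
    weight_score: int
    strength_score: int
    grid_score: int
    behavior_score: float

    def __post_init__(self) -> None:
        if self.weight_score not in range(4):
            raise ValueError(f"weight_score out of range: {self.weight_score}")
        if self.strength_score not in range(5):
            raise ValueError(f"strength_score out of range: {self.strength_score}")
        if self.grid_score not in range(4):
            raise ValueError(f"grid_score out of range: {self.grid_score}")
        if float(self.behavior_score) not in BEHAVIOR_GRADES:
            raise ValueError(
                f"behavior grade {self.behavior_score} not in {BEHAVIOR_GRADES}")


def weight_loss_pct(weight: float, reference_weight: float) -> float:
    """Percent weight loss versus a reference; negative means gain."""
    if reference_weight <= 0:
        raise ValueError("reference_weight must be > 0")
    return 100.0 * (reference_weight - weight) / reference_weight


def score_weight(pct_loss: float, dead: bool = False) -> int:
    """Weight-loss sub-score: <5% -> 0, 5-9.99 -> 1, 10-14.99 -> 2, >=15 or death -> 3."""
    if dead:
        return 3
    if pct_loss < 5:
        return 0
    if pct_loss < 10:
        return 1
    if pct_loss < 15:
        return 2
    return 3


def score_strength(pct_loss: float, dead: bool = False) -> int:
    """Grip-strength loss sub-score; no loss (or training gain) scores 0, death 4."""
    if dead:
        return 4
    if pct_loss <= 0:
        return 0
    if pct_loss < 10:
        return 1
    if pct_loss < 20:
        return 2
    if pct_loss < 30:
        return 3
    return 4


def score_grid(grid_time: float, dead: bool = False) -> int:
    """Inverted-grid sub-score from Tr seconds (0-60): 60 -> 0 ... <30 or death -> 3."""
    if dead:
        return 3
    if not 0 <= grid_time <= 60:
        raise ValueError(f"grid time must be within [0, 60] s, got {grid_time}")
    if grid_time >= 60:
        return 0
    if grid_time >= 45:
        return 1
    if grid_time >= 30:
        return 2
    return 3


def score_behavior(grade: float, dead: bool = False) -> float:
    """Validate the behavioral grade (death scores 3; grade 2.5 does not exist)."""
    if dead:
        return 3.0
    if float(grade) not in BEHAVIOR_GRADES:
        raise ValueError(f"behavior grade {grade} not in {BEHAVIOR_GRADES}")
    return float(grade)


def global_clinical_score(sub: SubScores) -> float:
    """GCS = weight + strength + (behavior + grid)/2, range [0, 10]."""
    return (sub.weight_score + sub.strength_score
            + (sub.behavior_score + sub.grid_score) / 2.0)


def score_record(pct_weight_loss: float, pct_strength_loss: float,
                 grid_time: float, behavior: float, dead: bool = False) -> SubScores:
    """Sub-scores for one animal-week of raw measures."""
    if dead:
        return SubScores(3, 4, 3, 3.0)
    return SubScores(score_weight(pct_weight_loss),
                     score_strength(pct_strength_loss),
                     score_grid(grid_time),
                     score_behavior(behavior))


def score_cohort(cohort: pd.DataFrame,
                 weight_reference: pd.Series | str = "auto",
                 grip_reference_week: int = 0,
                 death_mode: str = "carry_forward") -> pd.DataFrame:
    """Score every animal-week of a cohort table.

    ``weight_reference``: per-week reference weights (Series week -> grams), the
    string ``"sham_mean"`` (weekly mean of a ``sham`` arm), ``"animal_baseline"``
    (each animal's week-``grip_reference_week`` weight), or ``"auto"`` (sham mean
    when a sham arm exists, else animal baseline).  Grip reference is the
    animal's value at the habituation week.  ``death_mode``: ``carry_forward``
    keeps dead animals at the maximal score for all later weeks;
    ``drop_after_death`` removes post-death rows.
    """
    if death_mode not in ("carry_forward", "drop_after_death"):
        raise ValueError(f"unknown death_mode {death_mode!r}")
    cohort = cohort.sort_values(["animal", "week"]).reset_index(drop=True)

    if isinstance(weight_reference, str) and weight_reference == "auto":
        weight_reference = ("sham_mean" if (cohort["arm"] == "sham").any()
                            else "animal_baseline")
    if isinstance(weight_reference, str):
        if weight_reference == "sham_mean":
            sham = cohort[cohort["arm"] == "sham"]
            if sham.empty:
                raise ValueError("sham_mean reference requested but no sham arm")
            ref_by_week = sham.groupby("week")["weight"].mean()
            ref = cohort["week"].map(ref_by_week)
        elif weight_reference == "animal_baseline":
            base = (cohort[cohort["week"] == grip_reference_week]
                    .set_index("animal")["weight"])
            ref = cohort["animal"].map(base)
        else:
            raise ValueError(f"unknown weight_reference {weight_reference!r}")
    else:
        ref = cohort["week"].map(weight_reference)

    grip_base = (cohort[cohort["week"] == grip_reference_week]
                 .set_index("animal")["grip"])

    rows = []
    for (animal, arm), group in cohort.groupby(["animal", "arm"], sort=False):
        died = False
        for idx, rec in group.iterrows():
            dead = died or not bool(rec["alive"])
            if dead and died and death_mode == "drop_after_death":
                continue
            if dead:
                sub = SubScores(3, 4, 3, 3.0)
            else:
                w_loss = weight_loss_pct(rec["weight"], ref.loc[idx])
                g_loss = weight_loss_pct(rec["grip"], grip_base.loc[animal])
                sub = score_record(w_loss, g_loss, rec["grid_time"],
                                   rec["behavior"])
            rows.append({"animal": animal, "arm": arm, "week": rec["week"],
                         "weight_score": sub.weight_score,
                         "strength_score": sub.strength_score,
                         "grid_score": sub.grid_score,
                         "behavior_score": sub.behavior_score,
                         "gcs": global_clinical_score(sub),
                         "dead": dead})
            died = died or not bool(rec["alive"])
    return pd.DataFrame(rows)


def normalize_gcs(scores: pd.DataFrame, baseline_week: int = 2,
                  mode: str = "ratio") -> pd.DataFrame:
    """Normalize each animal's GCS series to its score at the injection week.

    ``ratio`` divides by the baseline (error on a zero baseline), ``difference``
    subtracts it.  The mode is recorded in the output column ``mode``.
    """
    if mode not in ("ratio", "difference"):
        raise ValueError(f"unknown mode {mode!r}")
    out = scores.copy()
    baselines = (scores[scores["week"] == baseline_week]
                 .set_index("animal")["gcs"])
    missing = sorted(set(scores["animal"]) - set(baselines.index))
    if missing:
        raise ValueError(f"animals missing baseline week {baseline_week}: {missing}")
    base = out["animal"].map(baselines)
    if mode == "ratio":
        zero = sorted(out.loc[base == 0, "animal"].unique())
        if zero:
            raise ValueError(
                f"zero baseline GCS for {zero}; use mode='difference'")
        out["normalized_gcs"] = out["gcs"] / base
    else:
        out["normalized_gcs"] = out["gcs"] - base
    out["mode"] = mode
    return out


def humanization_filter(cohort: pd.DataFrame,
                        threshold: float = 0.4) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude animals whose human CD45+ fraction is below the positivity threshold.

    The per-animal CD45+ percentage is the last recorded value (sacrifice).
    Returns (retained cohort, exclusion log with per-arm retained counts noted).
    """
    last = (cohort.sort_values("week").groupby("animal")
            .agg(arm=("arm", "last"), cd45_pct=("cd45_pct", "last")))
    excluded = last[last["cd45_pct"] < threshold].reset_index()
    retained = cohort[~cohort["animal"].isin(excluded["animal"])].copy()
    return retained, excluded


def group_sizes(cohort: pd.DataFrame) -> dict[str, int]:
    return cohort.groupby("arm")["animal"].nunique().to_dict()


@dataclass
class GroupComparison:
    """Group x week summaries plus two-way ANOVA and Tukey pairwise results."""

    summary: pd.DataFrame     # arm, week, mean, sem, n
    anova: pd.DataFrame       # two-way ANOVA table (arm, week, interaction)
    pairwise: pd.DataFrame    # week, group1, group2, meandiff, p_adj, reject


def compare_groups(normalized: pd.DataFrame,
                   excluded_weeks: tuple[int, ...] = (),
                   value_col: str = "normalized_gcs") -> GroupComparison:
    """Compare treatment arms on the normalized score series.

    Drops the excluded weeks, summarises per arm x week (mean +/- SEM), fits a
    two-way ANOVA (arm + week + interaction) and runs Tukey's multiple-
    comparison test between arms within each week.
    """
    data = normalized[~normalized["week"].isin(excluded_weeks)].copy()
    arms = sorted(data["arm"].unique())
    if len(arms) < 2:
        raise ValueError("compare_groups requires at least two treatment arms")
    small = [a for a in arms
             if data[data["arm"] == a]["animal"].nunique() < 2]
    if small:
        raise ValueError(f"arms with fewer than two animals: {small}")

    summary = (data.groupby(["arm", "week"])[value_col]
               .agg(mean="mean", sem="sem", n="count").reset_index())

    model = ols(f"{value_col} ~ C(arm) * C(week)",
                data=data.rename(columns={value_col: value_col})).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    rows = []
    for week, chunk in data.groupby("week"):
        if chunk["arm"].nunique() < 2:
            continue
        if chunk.groupby("arm")[value_col].count().min() < 2:
            continue
        if chunk[value_col].std() == 0:
            # degenerate week (e.g. the baseline): all values identical,
            # no group difference by construction
            for g1, g2 in [(a, b) for i, a in enumerate(sorted(chunk["arm"].unique()))
                           for b in sorted(chunk["arm"].unique())[i + 1:]]:
                rows.append({"week": week, "group1": g1, "group2": g2,
                             "meandiff": 0.0, "p_adj": 1.0, "reject": False})
            continue
        tuk = pairwise_tukeyhsd(chunk[value_col].to_numpy(),
                                chunk["arm"].to_numpy())
        frame = pd.DataFrame(tuk.summary().data[1:],
                             columns=tuk.summary().data[0])
        for _, r in frame.iterrows():
            rows.append({"week": week, "group1": r["group1"],
                         "group2": r["group2"],
                         "meandiff": float(r["meandiff"]),
                         "p_adj": float(r["p-adj"]),
                         "reject": bool(r["reject"])})
    return GroupComparison(summary=summary, anova=anova,
                           pairwise=pd.DataFrame(rows))
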