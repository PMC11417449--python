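"""Pre- versus post-revision comparison of population nutrient intake.

For each nutrient the comparison reports the paired-sample means and
standard errors, the overall difference (post − pre), the post/pre ratio
in percent, the percent change

    change (%) = (post − pre) / pre × 100,

and a paired t-test (t = d̄ / (s_d/√n), two-sided p, n−1 df).  Percent
columns are always computed from full-precision means, never from
rounded display values: percent changes recomputed from means rounded
for display can disagree badly with the full-precision figure, so only
absolute differences are reproducible from a rounded table.

``rank_contributors`` decomposes a population-mean intake change into
per-food contributions.  Because the FFQ/recall estimators are linear in
the composition values, the mean change of nutrient *n* is exactly

    Σ_foods  (mean daily grams of food) × Δ(n per 100 g) / 100,

so the foods driving a change can be ranked by |contribution| — e.g. a
522 mg/100 g sodium drop in a food eaten 100 g/day shifts mean sodium
intake by −522 mg/day on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .intake import IntakeResult
from .model import MISSING, SourceTable


@dataclass(frozen=True)
class ComparisonRow:
    nutrient_id: str
    pre_mean: float
    pre_se: float
    post_mean: float
    post_se: float
    overall_difference: float
    ratio_percent: Optional[float]
    change_percent: Optional[float]
    t_statistic: float
    p_value: float
    n: int
    semantics_warning: Optional[str] = None


def percent_change(pre: float, post: float) -> float:
    """(post − pre)/pre × 100; requires a strictly positive baseline."""
    if pre <= 0:
        raise ValueError("percent change is undefined for a non-positive baseline")
    return (post - pre) / pre * 100.0


def overall_difference(pre: float, post: float) -> float:
    """Absolute change post − pre, in the nutrient's own unit."""
    return post - pre


def intake_frame(results: list[IntakeResult]) -> pd.DataFrame:
    """Person × nutrient intake matrix."""
    return pd.DataFrame(
        {r.person_id: r.intakes for r in results}
    ).T.sort_index()


def paired_t(pre: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test; identical samples report t=0, p=1."""
    d = np.asarray(post, dtype=float) - np.asarray(pre, dtype=float)
    if np.allclose(d.std(ddof=1) if d.size > 1 else 0.0, 0.0):
        return 0.0, 1.0
    t, p = stats.ttest_rel(post, pre)
    return float(t), float(p)


def compare_populations(
    intake_pre: list[IntakeResult] | pd.DataFrame,
    intake_post: list[IntakeResult] | pd.DataFrame,
    semantics_warnings: Optional[dict[str, str]] = None,
) -> list[ComparisonRow]:
    """Per-nutrient paired comparison of two intake tables.

    Both tables must cover exactly the same persons (paired design);
    missing or extra persons on either side are an error listing the ids.
    """
    pre = intake_pre if isinstance(intake_pre, pd.DataFrame) else intake_frame(intake_pre)
    post = intake_post if isinstance(intake_post, pd.DataFrame) else intake_frame(intake_post)
    unpaired = set(pre.index).symmetric_difference(post.index)
    if unpaired:
        raise ValueError(f"unpaired persons: {sorted(unpaired)}")
    post = post.loc[pre.index]
    warnings = semantics_warnings or {}

    rows = []
    n = len(pre)
    for nid in pre.columns:
        if nid not in post.columns:
            continue
        a, b = pre[nid].to_numpy(float), post[nid].to_numpy(float)
        pre_mean, post_mean = float(a.mean()), float(b.mean())
        diff = post_mean - pre_mean
        if pre_mean > 0:
            ratio = post_mean / pre_mean * 100.0
            change = percent_change(pre_mean, post_mean)
        else:
            ratio = None
            change = None  # undefined on a zero baseline, reported blank
        t, p = paired_t(a, b)
        rows.append(
            ComparisonRow(
                nutrient_id=nid,
                pre_mean=pre_mean,
                pre_se=float(a.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
                post_mean=post_mean,
                post_se=float(b.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
                overall_difference=diff,
                ratio_percent=ratio,
                change_percent=change,
                t_statistic=t,
                p_value=p,
                n=n,
                semantics_warning=warnings.get(nid),
            )
        )
    return rows


def comparison_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    """Comparison rows as a DataFrame mirroring the standard table layout."""
    return pd.DataFrame(
        [
            {
                "nutrient_id": r.nutrient_id,
                "pre_mean": r.pre_mean,
                "pre_se": r.pre_se,
                "post_mean": r.post_mean,
                "post_se": r.post_se,
                "overall_difference": r.overall_difference,
                "ratio_percent": r.ratio_percent,
                "change_percent": r.change_percent,
                "t_statistic": r.t_statistic,
                "p_value": r.p_value,
                "semantics_warning": r.semantics_warning or "",
            }
            for r in rows
        ]
    )


@dataclass(frozen=True)
class Contribution:
    food_id: str
    pre_per_100g: float
    post_per_100g: float
    mean_daily_grams: float

    @property
    def contribution(self) -> float:
        """Change in population-mean daily intake attributable to this food."""
        return self.mean_daily_grams * (self.post_per_100g - self.pre_per_100g) / 100.0


def rank_contributors(
    pre_db: SourceTable,
    post_db: SourceTable,
    consumption_weights: dict[str, float],
    nutrient_id: str,
    k: Optional[int] = None,
) -> list[Contribution]:
    """Top-k foods by |contribution| to the mean intake change of a nutrient.

    ``consumption_weights`` is the population-mean daily grams per food
    (see :func:`nutrikit.intake.population_mean_grams`).  A MISSING value
    on either side counts as 0, matching the intake estimator.  Ties are
    broken by food_id.
    """
    pre_foods, post_foods = pre_db.by_id(), post_db.by_id()
    known = any(nutrient_id in f.values for f in pre_db) and any(
        nutrient_id in f.values for f in post_db
    )
    if not known:
        raise ValueError(f"nutrient {nutrient_id!r} absent from one of the databases")
    contribs = []
    for food_id, grams in consumption_weights.items():
        pre_f, post_f = pre_foods.get(food_id), post_foods.get(food_id)
        pre_v = pre_f.get(nutrient_id) if pre_f is not None else MISSING
        post_v = post_f.get(nutrient_id) if post_f is not None else MISSING
        contribs.append(
            Contribution(
                food_id=food_id,
                pre_per_100g=0.0 if pre_v is MISSING else pre_v,
                post_per_100g=0.0 if post_v is MISSING else post_v,
                mean_daily_grams=grams,
            )
        )
    contribs.sort(key=lambda c: (-abs(c.contribution), c.food_id))
    return contribs if k is None else contribs[:k]
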