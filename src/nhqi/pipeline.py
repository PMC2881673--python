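"""End-to-end orchestration: fit, score, and evaluate a set of QIs.

Thin conveniences over the module surfaces; the CLI and batch scripts use
these, and so can library callers who want the whole pipeline in a few
calls.
"""

from __future__ import annotations

import pandas as pd

from .adjustment import RiskAdjustmentModel, RiskAdjustmentResults
from .definitions import QIDefinition
from .evaluation import (
    ComponentScores,
    ValidityModel,
    autocorrelation,
    extract_components,
    impute_elements,
    ValidationElements,
)

__all__ = ["fit_all", "score_all", "reliability_report", "validity_report"]

SCORE_COLUMNS = [
    "qi_id", "facility_id", "quarter", "denominator", "raw_rate",
    "gen2_score", "gen3_score", "relative_quality",
    "low_denominator", "n_strata_empty", "n_stratifier_imputed",
]

_METHOD_COLUMNS = {"raw": "raw_rate", "gen2": "gen2_score", "gen3": "gen3_score"}


def fit_all(
    standard_panel: pd.DataFrame,
    qi_defs: list[QIDefinition],
    min_denominator: int = 5,
) -> dict[str, RiskAdjustmentResults]:
    """Fit one standard-population adjustment artifact per QI."""
    return {
        qi.qi_id: RiskAdjustmentModel(standard_panel, qi, min_denominator).fit()
        for qi in qi_defs
    }


def score_all(
    panel: pd.DataFrame, fitted: dict[str, RiskAdjustmentResults]
) -> pd.DataFrame:
    """Score a panel against every fitted QI; long frame, one row per
    facility-quarter-QI, in the fixed report column order."""
    frames = []
    for qi_id, results in fitted.items():
        scored = results.score(panel)
        scored.insert(0, "qi_id", qi_id)
        frames.append(scored[SCORE_COLUMNS])
    return pd.concat(frames, ignore_index=True)


def reliability_report(scores: pd.DataFrame) -> pd.DataFrame:
    """Quarter-to-quarter autocorrelation per QI and scoring method.

    One row per (qi_id, method, consecutive quarter pair) with the Pearson
    autocorrelation across facilities and the number of complete pairs.
    """
    rows = []
    for qi_id, sub in scores.groupby("qi_id", sort=True):
        quarters = sorted(sub["quarter"].unique())
        for method, col in _METHOD_COLUMNS.items():
            wide = sub.pivot(index="facility_id", columns="quarter", values=col)
            for t, t1 in zip(quarters, quarters[1:]):
                res = autocorrelation(
                    wide[t], wide[t1], qi_id=qi_id, method=method, quarter_pair=(t, t1)
                )
                rows.append({
                    "qi_id": qi_id, "method": method,
                    "quarter_from": t, "quarter_to": t1,
                    "r": res.r, "n_facilities": res.n_facilities,
                })
    return pd.DataFrame(rows)


def components_from_elements(elements: ValidationElements, k: int = 10) -> ComponentScores:
    """Impute the element table and extract k preventive + k responsive
    orthogonal components."""
    completed = impute_elements(elements.values)
    complete = ValidationElements(completed, elements.element_class)
    return ComponentScores(
        preventive=extract_components(complete.subset("preventive"), k=k, prefix="prevPC"),
        responsive=extract_components(complete.subset("responsive"), k=k, prefix="respPC"),
    )


def validity_report(
    scores: pd.DataFrame, elements: ValidationElements, k: int = 10
) -> pd.DataFrame:
    """Validity levels per QI from its most recent quarter of gen-3 scores.

    One row per qi_id: R1 (preventive model), R2 (responsive), R3 (combined)
    and the assigned Level I/II/III.
    """
    comps = components_from_elements(elements, k=k)
    rows = []
    for qi_id, sub in scores.groupby("qi_id", sort=True):
        latest = sub[sub["quarter"] == sub["quarter"].max()]
        facility_scores = latest.set_index("facility_id")["gen3_score"]
        res = ValidityModel(facility_scores, comps, qi_id=qi_id).fit()
        rows.append({
            "qi_id": qi_id, "R1": res.R1, "R2": res.R2, "R3": res.R3,
            "level": res.level,
        })
    return pd.DataFrame(rows)
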