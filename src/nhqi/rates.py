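"""Raw (unadjusted) facility QI rates with restriction handling.

The pipeline here is: evaluate each assessment record (or, for change-type
indicators, each consecutive-quarter record pair) against a QI definition,
keep the denominator members, and aggregate numerator/denominator counts to
the facility-quarter level.  Restriction — dropping residents whose outcomes
do not reflect the facility's care, e.g. new admissions — happens before any
counting.
"""

from __future__ import annotations

from enum import Enum
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .definitions import BASELINE_SUFFIX, QIDefinition, SchemaError

__all__ = [
    "Membership",
    "evaluate_membership",
    "denominator_table",
    "compute_raw_qi",
    "impute_item_means",
    "ID_COLUMNS",
]

#: Structural panel columns that are not assessment items.
ID_COLUMNS = ("resident_id", "facility_id", "quarter", "new_admission")


class Membership(Enum):
    """Status of one record (or record pair) with respect to one QI."""

    EXCLUDED = "excluded"
    OUT_OF_DENOMINATOR = "out_of_denominator"
    DENOMINATOR_ONLY = "denominator_only"
    NUMERATOR = "numerator"


def _pair_view(baseline: Mapping[str, Any], outcome: Mapping[str, Any]) -> dict:
    """Merge a consecutive-quarter record pair into one mapping.

    Bare item names refer to the outcome quarter; ``name@baseline`` refers to
    the earlier quarter.
    """
    view = dict(outcome)
    for k, v in baseline.items():
        view[f"{k}{BASELINE_SUFFIX}"] = v
    return view


def evaluate_membership(record_or_pair, qi_def: QIDefinition) -> Membership:
    """Classify one record (or ordered baseline/outcome pair) for a QI.

    Restriction comes first and short-circuits: a new admission is excluded
    unconditionally, then the QI's own exclusion rules run in order (a rule
    that cannot be evaluated because of missing items does not exclude).
    A record missing an item needed by the denominator or numerator rule is
    out of the denominator — outcomes are never imputed.
    """
    if qi_def.scope == "change":
        baseline, outcome = record_or_pair
        rec = _pair_view(baseline, outcome)
    else:
        rec = dict(record_or_pair)

    if bool(rec.get("new_admission", False)):
        return Membership.EXCLUDED
    for rule in qi_def.exclusions:
        if rule(rec) is True:
            return Membership.EXCLUDED
    denom = qi_def.denominator(rec)
    if denom is not True:
        return Membership.OUT_OF_DENOMINATOR
    num = qi_def.numerator(rec)
    if num is True:
        return Membership.NUMERATOR
    # missing numerator items -> not evaluable -> out of denominator
    return Membership.OUT_OF_DENOMINATOR if num is None else Membership.DENOMINATOR_ONLY


def _change_pairs(panel: pd.DataFrame) -> pd.DataFrame:
    """Join each resident-quarter with the same resident one quarter later.

    Baseline columns keep their names suffixed ``@baseline``; outcome-quarter
    columns are bare.  The event is attributed to the outcome (t+1) quarter
    and facility.
    """
    baseline = panel.copy()
    baseline["quarter"] = baseline["quarter"] + 1
    merged = panel.merge(
        baseline,
        on=("resident_id", "quarter"),
        how="inner",
        suffixes=("", BASELINE_SUFFIX),
    )
    return merged


def denominator_table(panel: pd.DataFrame, qi_def: QIDefinition) -> pd.DataFrame:
    """One row per denominator member of ``qi_def`` in ``panel``.

    Returns a frame with ``resident_id``, ``facility_id``, ``quarter`` (the
    outcome quarter for change QIs), the binary numerator indicator ``y``,
    ``stratifier_value``, and one column per covariate.  For change-scope QIs
    the stratifier and covariates are taken from the baseline quarter, since
    risk adjustment conditions on status before the outcome window.
    """
    qi_def.validate_panel(panel)
    if qi_def.scope == "change":
        table = _change_pairs(panel)
        risk_suffix = BASELINE_SUFFIX
    else:
        table = panel
        risk_suffix = ""

    records = table.to_dict("records")
    keep_idx: list[int] = []
    y: list[int] = []
    exclusions = qi_def.exclusions
    denominator = qi_def.denominator
    numerator = qi_def.numerator
    for i, rec in enumerate(records):
        if bool(rec.get("new_admission", False)):
            continue
        if any(rule(rec) is True for rule in exclusions):
            continue
        if denominator(rec) is not True:
            continue
        num = numerator(rec)
        if num is None:
            continue
        keep_idx.append(i)
        y.append(1 if num else 0)

    out = table.iloc[keep_idx][["resident_id", "facility_id", "quarter"]].copy()
    out["y"] = np.asarray(y, dtype=int)
    strat_col = f"{qi_def.stratifier_name}{risk_suffix}" if qi_def.stratifier_name else None
    out["stratifier_value"] = (
        table.iloc[keep_idx][strat_col].to_numpy() if strat_col else np.nan
    )
    for name in qi_def.covariate_names:
        out[name] = table.iloc[keep_idx][f"{name}{risk_suffix}"].to_numpy()
    return out.reset_index(drop=True)


def compute_raw_qi(
    panel: pd.DataFrame,
    qi_def: QIDefinition,
    min_denominator: int = 5,
) -> pd.DataFrame:
    """Facility-quarter numerator/denominator counts and raw rates.

    One row per facility-quarter with at least one denominator member:
    ``facility_id, quarter, numerator, denominator, raw_rate,
    low_denominator``.  ``low_denominator`` flags (never suppresses)
    facility-quarters whose denominator falls below ``min_denominator`` —
    small denominators exacerbate instability.
    """
    if panel.empty:
        raise SchemaError("empty assessment panel")
    table = denominator_table(panel, qi_def)
    grouped = (
        table.groupby(["facility_id", "quarter"], sort=True)["y"]
        .agg(numerator="sum", denominator="count")
        .reset_index()
    )
    grouped["raw_rate"] = grouped["numerator"] / grouped["denominator"]
    grouped["low_denominator"] = grouped["denominator"] < min_denominator
    return grouped


def impute_item_means(
    panel: pd.DataFrame, item_names
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean-based single imputation of the named items.

    Each missing cell among ``item_names`` is replaced by the panel mean of
    the observed values of that item; observed values are untouched.  Returns
    the completed panel and a boolean mask of imputed cells (same index,
    columns = ``item_names``).

    Raises ``SchemaError`` if an item has no observed value at all.
    """
    item_names = list(item_names)
    missing_cols = sorted(set(item_names) - set(panel.columns))
    if missing_cols:
        raise SchemaError(f"panel lacks item(s) {missing_cols}")
    out = panel.copy()
    mask = out[item_names].isna()
    for name in item_names:
        col = out[name]
        if col.notna().sum() == 0:
            raise SchemaError(f"item {name!r} is fully missing; cannot mean-impute")
        out[name] = col.fillna(col.mean())
    return out, mask
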