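"""Quality-indicator definitions and the declarative rule language.

A quality indicator (QI) is a facility-level fraction: residents triggering
an outcome (numerator) over residents at risk and not otherwise excluded
(denominator).  Definitions are data, not code: numerator, denominator and
exclusion rules are declarative predicate expressions over the items of an
assessment record, parsed from YAML/JSON documents, so new indicators can be
added without touching the package.

Rule expression grammar (YAML/JSON):

    true                                  -- always satisfied
    {item: pain_level, op: ">=", value: 1}
    {all: [<expr>, ...]}                  -- conjunction
    {any: [<expr>, ...]}                  -- disjunction
    {not: <expr>}                         -- negation

Comparison operators: ``==  !=  <  <=  >  >=  in``.  For change-scope QIs
(evaluated on a consecutive-quarter record pair) an item name may carry the
suffix ``@baseline`` to reference the earlier quarter's value; a bare name
refers to the outcome quarter.  The right-hand side of a comparison may also
be another item reference written as ``{item: name}``, which is how
"worsened since baseline" rules are expressed.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "Rule",
    "QIDefinition",
    "SchemaError",
    "load_qi_definitions",
    "load_default_qi_set",
    "BASELINE_SUFFIX",
]

BASELINE_SUFFIX = "@baseline"

_OPS = {
    "==": operator.eq,
    "!=": operator.ne,
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
}


class SchemaError(ValueError):
    """An assessment panel or QI definition violates its declared schema."""


def _is_missing(value: Any) -> bool:
    return value is None or (isinstance(value, float) and value != value) or pd.isna(value)


class Rule:
    """A parsed predicate expression over one record (or record pair).

    Evaluation is three-valued: ``True``, ``False``, or ``None`` when an
    item needed by the rule is missing in the record.  Callers decide what
    a ``None`` means (outcome rules treat it as not evaluable; exclusion
    rules treat it as not triggered).
    """

    def __init__(self, spec: Any):
        self.spec = spec
        self._compiled = self._compile(spec)
        self.item_names = tuple(sorted(self._collect_items(spec)))

    # -- compilation -------------------------------------------------------

    def _compile(self, spec: Any):
        if spec is True or spec is None:
            return lambda rec: True
        if spec is False:
            return lambda rec: False
        if not isinstance(spec, Mapping):
            raise SchemaError(f"rule expression must be a mapping or boolean, got {spec!r}")
        if "all" in spec:
            subs = [self._compile(s) for s in spec["all"]]
            return lambda rec: self._conj(subs, rec)
        if "any" in spec:
            subs = [self._compile(s) for s in spec["any"]]
            return lambda rec: self._disj(subs, rec)
        if "not" in spec:
            sub = self._compile(spec["not"])

            def _neg(rec, sub=sub):
                v = sub(rec)
                return None if v is None else (not v)

            return _neg
        if "item" in spec:
            name = spec["item"]
            op_name = spec.get("op", "==")
            if op_name == "in":
                allowed = list(spec["value"])

                def _member(rec, name=name, allowed=allowed):
                    v = rec.get(name, None)
                    if _is_missing(v):
                        return None
                    return v in allowed

                return _member
            if op_name not in _OPS:
                raise SchemaError(f"unknown rule operator {op_name!r}")
            op = _OPS[op_name]
            rhs = spec["value"]
            if isinstance(rhs, Mapping) and "item" in rhs:
                other = rhs["item"]

                def _cmp_items(rec, name=name, other=other, op=op):
                    a, b = rec.get(name, None), rec.get(other, None)
                    if _is_missing(a) or _is_missing(b):
                        return None
                    return bool(op(a, b))

                return _cmp_items

            def _cmp(rec, name=name, rhs=rhs, op=op):
                v = rec.get(name, None)
                if _is_missing(v):
                    return None
                return bool(op(v, rhs))

            return _cmp
        raise SchemaError(f"cannot parse rule expression {spec!r}")

    @staticmethod
    def _conj(subs, rec):
        saw_none = False
        for s in subs:
            v = s(rec)
            if v is False:
                return False
            if v is None:
                saw_none = True
        return None if saw_none else True

    @staticmethod
    def _disj(subs, rec):
        saw_none = False
        for s in subs:
            v = s(rec)
            if v is True:
                return True
            if v is None:
                saw_none = True
        return None if saw_none else False

    def _collect_items(self, spec: Any) -> set[str]:
        if spec is True or spec is False or spec is None:
            return set()
        names: set[str] = set()
        if "item" in spec:
            names.add(spec["item"])
            rhs = spec.get("value")
            if isinstance(rhs, Mapping) and "item" in rhs:
                names.add(rhs["item"])
        for key in ("all", "any"):
            for sub in spec.get(key, []) if isinstance(spec.get(key), list) else []:
                names |= self._collect_items(sub)
        if "not" in spec:
            names |= self._collect_items(spec["not"])
        return names

    def __call__(self, record: Mapping[str, Any]):
        return self._compiled(record)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Rule({self.spec!r})"


@dataclass(frozen=True)
class QIDefinition:
    """One quality indicator: rules, covariates and stratifier.

    Parameters
    ----------
    qi_id : short code, e.g. ``"PRU01"``.
    scope : ``"cross_sectional"`` (one record) or ``"change"`` (the same
        resident observed in consecutive quarters; baseline = quarter t,
        outcome = quarter t+1).
    numerator_rule, denominator_rule : predicate expressions; the numerator
        implies denominator membership.
    exclusion_rules : ordered restriction predicates applied first (new
        admissions are excluded unconditionally, before these run).
    covariate_names : items entering the stratum logistic models.
    stratifier_name : the continuous item whose 20th/80th standard-population
        percentiles define the low/middle/high risk strata.
    polarity : ``"adverse"`` (higher rate = worse care) or ``"desirable"``.
    """

    qi_id: str
    description: str = ""
    scope: str = "cross_sectional"
    numerator_rule: Any = True
    denominator_rule: Any = True
    exclusion_rules: tuple = ()
    covariate_names: tuple = ()
    stratifier_name: str = ""
    polarity: str = "adverse"
    numerator: Rule = field(init=False, repr=False)
    denominator: Rule = field(init=False, repr=False)
    exclusions: tuple = field(init=False, repr=False)

    def __post_init__(self):
        if self.scope not in ("cross_sectional", "change"):
            raise SchemaError(f"{self.qi_id}: unknown scope {self.scope!r}")
        if self.polarity not in ("adverse", "desirable"):
            raise SchemaError(f"{self.qi_id}: unknown polarity {self.polarity!r}")
        object.__setattr__(self, "numerator", Rule(self.numerator_rule))
        object.__setattr__(self, "denominator", Rule(self.denominator_rule))
        object.__setattr__(self, "exclusions", tuple(Rule(r) for r in self.exclusion_rules))
        outcome_items = {n.removesuffix(BASELINE_SUFFIX) for n in self.numerator.item_names}
        overlap = outcome_items & (set(self.covariate_names) | {self.stratifier_name})
        if overlap:
            raise SchemaError(
                f"{self.qi_id}: covariates/stratifier overlap outcome items: {sorted(overlap)}"
            )

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "QIDefinition":
        return cls(
            qi_id=d["qi_id"],
            description=d.get("description", ""),
            scope=d.get("scope", "cross_sectional"),
            numerator_rule=d.get("numerator_rule", True),
            denominator_rule=d.get("denominator_rule", True),
            exclusion_rules=tuple(d.get("exclusion_rules", ())),
            covariate_names=tuple(d.get("covariate_names", ())),
            stratifier_name=d.get("stratifier_name", ""),
            polarity=d.get("polarity", "adverse"),
        )

    def referenced_items(self) -> set[str]:
        """All panel item names this QI needs (baseline refs stripped)."""
        names: set[str] = set()
        for rule in (self.numerator, self.denominator, *self.exclusions):
            names |= {n.removesuffix(BASELINE_SUFFIX) for n in rule.item_names}
        names |= set(self.covariate_names)
        if self.stratifier_name:
            names.add(self.stratifier_name)
        return names

    def validate_panel(self, panel: pd.DataFrame) -> None:
        """Raise :class:`SchemaError` naming any referenced item missing from the panel."""
        missing = sorted(self.referenced_items() - set(panel.columns))
        if missing:
            raise SchemaError(f"QI {self.qi_id}: panel lacks item(s) {missing}")


def load_qi_definitions(source: str | Path | Iterable[Mapping]) -> list[QIDefinition]:
    """Load QI definitions from a YAML/JSON file path or an iterable of dicts.

    The document is either a list of definition mappings or a mapping with a
    top-level ``qis:`` list.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = list(source)
    if isinstance(doc, Mapping):
        doc = doc.get("qis", [])
    defs = [QIDefinition.from_dict(d) for d in doc]
    seen: set[str] = set()
    for d in defs:
        if d.qi_id in seen:
            raise SchemaError(f"duplicate qi_id {d.qi_id}")
        seen.add(d.qi_id)
    return defs


def load_default_qi_set() -> list[QIDefinition]:
    """The small representative QI library shipped with the package."""
    ref = resources.files("nhqi").joinpath("qi_library/default.yaml")
    with resources.as_file(ref) as path:
        return load_qi_definitions(path)
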