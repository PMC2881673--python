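"""Stratified indirect + direct standardization of facility QI rates.

The adjustment pipeline fitted here, per quality indicator:

1. **Restriction** — handled upstream (:mod:`nhqi.rates`).
2. **Stratification** — residents are sorted into low / middle / high risk
   strata at the 20th and 80th percentiles of a continuous stratifier, with
   the thresholds estimated once from a standard population and then fixed.
3. **Indirect standardization within strata** — a logistic regression of the
   outcome on case-mix covariates is fitted per stratum in the standard
   population; a facility's expected rate E_s is the mean predicted
   probability over its own stratum-s denominator.  The observed rate O_s is
   compared with E_s as a *difference on the log-odds scale*, re-anchored at
   the standard-population stratum rate P_s:

       A_s = expit( logit(O_s) - logit(E_s) + logit(P_s) )

4. **Direct standardization** — the stratum-specific adjusted rates A_s are
   combined with fixed standard-population denominator-share weights w_s
   into a single composite ("third generation" score).  The "second
   generation" comparator applies step 3 with a single unstratified model.

Inference is relative: a facility's quality signal is its composite score
minus the overall standard-population rate, not the absolute score.

The public surface follows the Model/Results idiom:
``RiskAdjustmentModel(standard_panel, qi_def).fit()`` returns a
:class:`RiskAdjustmentResults` whose ``score(panel)`` produces per
facility-quarter raw, gen-2 and gen-3 scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize
import statsmodels.api as sm
from scipy.special import expit, logit

from .definitions import QIDefinition, SchemaError
from .rates import denominator_table, impute_item_means

__all__ = [
    "StrataThresholds",
    "StratumModel",
    "StandardModel",
    "RiskAdjustmentModel",
    "RiskAdjustmentResults",
    "compute_thresholds",
    "assign_stratum",
    "assign_strata",
    "adjust_log_odds",
    "expected_rate",
    "fit_stratum_logit",
    "STRATA",
]

STRATA = ("low", "middle", "high")

#: ridge penalty on slope coefficients for the separation fallback
_RIDGE_PENALTY = 1e-4
#: |coefficient| beyond this on the logit scale is treated as divergence
_COEF_BOUND = 30.0


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrataThresholds:
    """20th/80th-percentile cut points of the stratifier distribution."""

    p20: float
    p80: float

    def __post_init__(self):
        if not (self.p20 <= self.p80):
            raise ValueError(f"p20 ({self.p20}) must not exceed p80 ({self.p80})")


def compute_thresholds(stratifier_values) -> StrataThresholds:
    """Sample 0.20 and 0.80 quantiles (linear interpolation) of the stratifier.

    Missing values are dropped; an all-missing input is an error.
    """
    values = np.asarray(stratifier_values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("stratifier has no non-missing values")
    p20, p80 = np.quantile(values, [0.20, 0.80])
    return StrataThresholds(float(p20), float(p80))


def assign_stratum(value: float, thresholds: StrataThresholds) -> str:
    """Place one stratifier value: below p20 -> low, above p80 -> high,
    else (ties included) -> middle.  Missing -> middle (least extreme)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "middle"
    if value < thresholds.p20:
        return "low"
    if value > thresholds.p80:
        return "high"
    return "middle"


def assign_strata(values, thresholds: StrataThresholds) -> np.ndarray:
    """Vectorized :func:`assign_stratum`; NaN maps to ``"middle"``."""
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, "middle", dtype=object)
    with np.errstate(invalid="ignore"):
        out[v < thresholds.p20] = "low"
        out[v > thresholds.p80] = "high"
    return out


# ---------------------------------------------------------------------------
# log-odds observed/expected adjustment
# ---------------------------------------------------------------------------

def _boundary_correct(observed, denominator):
    """Replace O in {0,1} with (n + 0.5)/(d + 1) so its logit is finite."""
    o = np.asarray(observed, dtype=float)
    d = np.asarray(denominator, dtype=float)
    at_boundary = (o == 0.0) | (o == 1.0)
    corrected = np.where(at_boundary, (o * d + 0.5) / (d + 1.0), o)
    return corrected


def adjust_log_odds(observed, expected, standard, denominator=None):
    """Adjusted rate A = expit( logit(O') - logit(E) + logit(P) ).

    ``observed`` (O) is the facility rate, ``expected`` (E) the model-based
    expectation given the facility's case mix, ``standard`` (P) the anchor
    rate of the standard population.  A boundary O of exactly 0 or 1 is
    corrected to (n + 0.5)/(d + 1), which requires ``denominator``.
    E and P must lie strictly inside (0, 1).  Accepts scalars or arrays.
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    p = np.asarray(standard, dtype=float)
    if np.any((e <= 0) | (e >= 1)) or np.any((p <= 0) | (p >= 1)):
        raise ValueError("expected and standard rates must lie strictly in (0, 1)")
    if np.any((o < 0) | (o > 1)):
        raise ValueError("observed rate outside [0, 1]")
    if np.any((o == 0) | (o == 1)):
        if denominator is None:
            raise ValueError(
                "observed rate at the boundary requires the denominator "
                "for the (n + 0.5)/(d + 1) correction"
            )
        o = _boundary_correct(o, denominator)
    result = expit(logit(o) - logit(e) + logit(p))
    return float(result) if result.ndim == 0 else result


# ---------------------------------------------------------------------------
# per-stratum logistic models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StratumModel:
    """Fixed logistic coefficients for one stratum (or the whole sample)."""

    stratum: str
    intercept: float
    coefficients: dict  # covariate name -> logit-scale slope
    fit_status: str  # converged | penalized_fallback | intercept_only

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(X), self.intercept, dtype=float)
        for name, beta in self.coefficients.items():
            eta += beta * X[name].to_numpy(dtype=float)
        return eta

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted event probabilities expit(alpha + beta . x)."""
        return expit(self.linear_predictor(X))


def _neg_penalized_loglik(params, X, y, penalty):
    eta = X @ params
    # log(1 + exp(eta)) - y*eta, numerically stable
    ll = np.sum(np.logaddexp(0.0, eta) - y * eta)
    return ll + penalty * np.sum(params[1:] ** 2)


def _neg_penalized_grad(params, X, y, penalty):
    mu = expit(X @ params)
    grad = X.T @ (mu - y)
    grad[1:] += 2.0 * penalty * params[1:]
    return grad


def fit_stratum_logit(y, X: pd.DataFrame, stratum: str) -> StratumModel:
    """Maximum-likelihood logistic fit of the numerator indicator on covariates.

    Falls back to a ridge-penalized fit (penalty 1e-4 on slopes, intercept
    free) under separation or non-convergence, then to an intercept-only
    model; the path taken is recorded in ``fit_status``.  A stratum whose
    outcome is constant gets an intercept at the boundary-corrected logit
    (k + 0.5)/(n + 1) so the stored intercept stays finite.
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    n = y.size
    if n == 0:
        raise ValueError(f"stratum {stratum!r} has no denominator members")
    k = y.sum()
    constant = k == 0 or k == n
    if constant or not names:
        rate = (k + 0.5) / (n + 1.0) if constant else k / n
        # the intercept-only MLE is logit(mean); "intercept_only" marks the
        # degenerate (constant-outcome) fallback, not an empty covariate set
        status = "intercept_only" if constant else "converged"
        return StratumModel(stratum, float(logit(rate)), {}, status)

    design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    params = None
    status = "converged"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200, warn_convergence=False)
            if fit.mle_retvals.get("converged", False) and np.all(
                np.abs(fit.params) < _COEF_BOUND
            ):
                params = np.asarray(fit.params, dtype=float)
        except Exception:
            params = None

    if params is None:
        status = "penalized_fallback"
        res = scipy.optimize.minimize(
            _neg_penalized_loglik,
            x0=np.zeros(design.shape[1]),
            jac=_neg_penalized_grad,
            args=(design, y, _RIDGE_PENALTY),
            method="L-BFGS-B",
            options={"maxiter": 500},
        )
        if res.success and np.all(np.abs(res.x) < 2 * _COEF_BOUND):
            params = res.x
        else:
            rate = np.clip(y.mean(), 0.5 / (n + 1.0), 1 - 0.5 / (n + 1.0))
            return StratumModel(stratum, float(logit(rate)), {}, "intercept_only")

    coefs = {name: float(b) for name, b in zip(names, params[1:])}
    return StratumModel(stratum, float(params[0]), coefs, status)


def expected_rate(facility_stratum_records: pd.DataFrame, model: StratumModel) -> float:
    """Mean predicted probability over a facility's stratum denominator."""
    if len(facility_stratum_records) == 0:
        raise ValueError("expected_rate requires at least one denominator record")
    return float(model.predict(facility_stratum_records).mean())


# ---------------------------------------------------------------------------
# the fitted standard-population artifact
# ---------------------------------------------------------------------------

@dataclass
class StandardModel:
    """Everything fixed from the standard population for one QI.

    Holds the strata thresholds, the per-stratum and unstratified logistic
    coefficients, the denominator-share weights w_s (summing to 1), the
    standard-population event rates (overall and per stratum, the anchors of
    the adjustment), and the covariate means used to fill missing covariates
    when scoring new panels.
    """

    qi_id: str
    thresholds: StrataThresholds
    stratum_models: dict  # label -> StratumModel, labels: low/middle/high/unstratified
    weights: dict  # stratum -> w_s, sum 1
    standard_rate_overall: float
    standard_rate_by_stratum: dict
    covariate_means: dict
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"stratum weights sum to {total}, expected 1")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("stratum weights must be non-negative")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "qi_id": self.qi_id,
            "thresholds": {"p20": self.thresholds.p20, "p80": self.thresholds.p80},
            "stratum_models": {
                label: {
                    "intercept": m.intercept,
                    "coefficients": m.coefficients,
                    "fit_status": m.fit_status,
                }
                for label, m in self.stratum_models.items()
            },
            "weights": dict(self.weights),
            "standard_rate_overall": self.standard_rate_overall,
            "standard_rate_by_stratum": dict(self.standard_rate_by_stratum),
            "covariate_means": dict(self.covariate_means),
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardModel":
        return cls(
            qi_id=d["qi_id"],
            thresholds=StrataThresholds(**d["thresholds"]),
            stratum_models={
                label: StratumModel(label, m["intercept"], dict(m["coefficients"]), m["fit_status"])
                for label, m in d["stratum_models"].items()
            },
            weights=dict(d["weights"]),
            standard_rate_overall=d["standard_rate_overall"],
            standard_rate_by_stratum=dict(d["standard_rate_by_stratum"]),
            covariate_means=dict(d["covariate_means"]),
            provenance=dict(d.get("provenance", {})),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "StandardModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class RiskAdjustmentModel:
    """Fits the fixed standard-population adjustment artifact for one QI.

    Parameters
    ----------
    standard_panel : DataFrame
        The reference panel (one row per resident-quarter) from which
        thresholds, coefficients, weights and anchor rates are estimated and
        then held fixed.  Ideally broadly representative of every facility
        that will be scored.
    qi_def : QIDefinition
    min_denominator : int
        Facility-quarters with a smaller denominator are flagged (not
        suppressed) when scoring.
    """

    def __init__(self, standard_panel: pd.DataFrame, qi_def: QIDefinition,
                 min_denominator: int = 5):
        qi_def.validate_panel(standard_panel)
        self.standard_panel = standard_panel
        self.qi_def = qi_def
        self.min_denominator = min_denominator

    def fit(self, timestamp: bool = False) -> "RiskAdjustmentResults":
        """Estimate thresholds, stratum logits, weights and anchor rates."""
        qi = self.qi_def
        panel = self.standard_panel
        covariate_means = {}
        if qi.covariate_names:
            panel, _ = impute_item_means(panel, qi.covariate_names)
            covariate_means = {
                name: float(panel[name].mean()) for name in qi.covariate_names
            }
        table = denominator_table(panel, qi)
        if table.empty:
            raise SchemaError(f"QI {qi.qi_id}: standard panel has no denominator members")

        thresholds = compute_thresholds(table["stratifier_value"])
        strata = assign_strata(table["stratifier_value"], thresholds)
        table = table.assign(stratum=strata)

        covs = list(qi.covariate_names)
        stratum_models: dict[str, StratumModel] = {}
        weights: dict[str, float] = {}
        rate_by_stratum: dict[str, float] = {}
        total = len(table)
        for label in STRATA:
            sub = table[table["stratum"] == label]
            if sub.empty:
                raise SchemaError(
                    f"QI {qi.qi_id}: standard population has no denominator members "
                    f"in stratum {label!r}; unsuitable as a standard"
                )
            stratum_models[label] = fit_stratum_logit(sub["y"], sub[covs], label)
            weights[label] = len(sub) / total
            k, n = sub["y"].sum(), len(sub)
            # corrected anchor if the stratum outcome is constant
            rate_by_stratum[label] = float(
                (k + 0.5) / (n + 1.0) if k in (0, n) else k / n
            )
        stratum_models["unstratified"] = fit_stratum_logit(
            table["y"], table[covs], "unstratified"
        )
        k, n = table["y"].sum(), total
        overall = float((k + 0.5) / (n + 1.0) if k in (0, n) else k / n)

        provenance = {"n_standard_records": total, "n_standard_facilities": int(
            table["facility_id"].nunique())}
        if timestamp:
            provenance["fitted_at"] = datetime.now(timezone.utc).isoformat()

        artifact = StandardModel(
            qi_id=qi.qi_id,
            thresholds=thresholds,
            stratum_models=stratum_models,
            weights=weights,
            standard_rate_overall=overall,
            standard_rate_by_stratum=rate_by_stratum,
            covariate_means=covariate_means,
            provenance=provenance,
        )
        return RiskAdjustmentResults(self, artifact)


class RiskAdjustmentResults:
    """Fitted adjustment artifact plus scoring and reporting.

    Attributes
    ----------
    standard_model : StandardModel
        The serializable fixed-coefficient artifact.
    """

    def __init__(self, model: RiskAdjustmentModel | None, standard_model: StandardModel):
        self.model = model
        self.standard_model = standard_model
        self.qi_def = model.qi_def if model is not None else None
        self.min_denominator = model.min_denominator if model is not None else 5

    # convenience accessors -------------------------------------------------
    @property
    def thresholds(self) -> StrataThresholds:
        return self.standard_model.thresholds

    @property
    def weights(self) -> dict:
        return self.standard_model.weights

    @property
    def standard_rate(self) -> float:
        return self.standard_model.standard_rate_overall

    # -- scoring ------------------------------------------------------------

    def score(self, panel: pd.DataFrame, qi_def: QIDefinition | None = None) -> pd.DataFrame:
        """Score every facility-quarter of ``panel`` against the fixed artifact.

        Returns one row per facility-quarter with a non-empty denominator:
        raw rate, second-generation score (unstratified indirect
        standardization), third-generation score (stratified + directly
        standardized composite), the signed quality signal
        ``relative_quality = gen3 - P_std``, per-stratum observed/expected/
        adjusted rates, and flags.
        """
        qi = qi_def or self.qi_def
        if qi is None:
            raise ValueError("a QIDefinition is required to score a panel")
        art = self.standard_model
        if qi.qi_id != art.qi_id:
            raise SchemaError(
                f"model artifact is for QI {art.qi_id!r}, asked to score {qi.qi_id!r}"
            )
        qi.validate_panel(panel)
        missing_cov = sorted(set(qi.covariate_names) - set(art.covariate_means))
        if missing_cov:
            raise SchemaError(
                f"model artifact lacks covariate(s) {missing_cov} required by {qi.qi_id}"
            )
        work = panel.copy()
        for name in qi.covariate_names:  # fixed standard-population means
            work[name] = work[name].fillna(art.covariate_means[name])
        table = denominator_table(work, qi)
        if table.empty:
            raise SchemaError(f"QI {qi.qi_id}: panel has no denominator members")
        covs = list(qi.covariate_names)
        missing_strat = table["stratifier_value"].isna()
        table = table.assign(
            stratum=assign_strata(table["stratifier_value"], art.thresholds),
            stratifier_imputed=missing_strat,
        )

        p_strat = np.empty(len(table), dtype=float)
        for label in STRATA:
            mask = (table["stratum"] == label).to_numpy()
            if mask.any():
                p_strat[mask] = art.stratum_models[label].predict(table.loc[mask, covs])
        table = table.assign(
            p_stratum=p_strat,
            p_unstratified=art.stratum_models["unstratified"].predict(table[covs]),
        )

        g = table.groupby(["facility_id", "quarter"], sort=True)
        overall = g.agg(
            denominator=("y", "count"),
            raw_rate=("y", "mean"),
            expected_unstratified=("p_unstratified", "mean"),
            n_stratifier_imputed=("stratifier_imputed", "sum"),
        )
        per_stratum = (
            table.groupby(["facility_id", "quarter", "stratum"], sort=True)
            .agg(d=("y", "count"), O=("y", "mean"), E=("p_stratum", "mean"))
        )
        wide = per_stratum.unstack("stratum")

        out = overall.reset_index()
        P_std = art.standard_rate_overall
        out["gen2_score"] = adjust_log_odds(
            out["raw_rate"].to_numpy(),
            out["expected_unstratified"].to_numpy(),
            P_std,
            denominator=out["denominator"].to_numpy(),
        )

        # per-stratum adjusted rates, then direct standardization with
        # standard-population weights renormalized over non-empty strata
        num = np.zeros(len(out))
        wsum = np.zeros(len(out))
        fq_index = pd.MultiIndex.from_frame(out[["facility_id", "quarter"]])
        for label in STRATA:
            P_s = art.standard_rate_by_stratum[label]
            w_s = art.weights[label]
            if ("d", label) in wide.columns:
                d_s = wide[("d", label)].reindex(fq_index).to_numpy()
                O_s = wide[("O", label)].reindex(fq_index).to_numpy()
                E_s = wide[("E", label)].reindex(fq_index).to_numpy()
            else:
                d_s = np.full(len(out), np.nan)
                O_s = np.full(len(out), np.nan)
                E_s = np.full(len(out), np.nan)
            nonempty = ~np.isnan(d_s)
            A_s = np.full(len(out), np.nan)
            if nonempty.any():
                A_s[nonempty] = adjust_log_odds(
                    O_s[nonempty], E_s[nonempty], P_s, denominator=d_s[nonempty]
                )
            out[f"d_{label}"] = d_s
            out[f"observed_{label}"] = O_s
            out[f"expected_{label}"] = E_s
            out[f"adjusted_{label}"] = A_s
            num += np.where(nonempty, w_s * A_s, 0.0)
            wsum += np.where(nonempty, w_s, 0.0)
        out["gen3_score"] = num / wsum
        out["n_strata_empty"] = sum(
            np.isnan(out[f"d_{label}"].to_numpy()).astype(int) for label in STRATA
        )
        out["relative_quality"] = out["gen3_score"] - P_std
        out["low_denominator"] = out["denominator"] < self.min_denominator
        return out

    # -- persistence / reporting -------------------------------------------

    def save(self, path) -> None:
        self.standard_model.save(path)

    @classmethod
    def load(cls, path, qi_def: QIDefinition | None = None,
             min_denominator: int = 5) -> "RiskAdjustmentResults":
        art = StandardModel.load(path)
        res = cls(None, art)
        res.qi_def = qi_def
        res.min_denominator = min_denominator
        return res

    def summary(self) -> str:
        """Plain-text report of the fitted artifact."""
        art = self.standard_model
        lines = [
            f"Risk adjustment artifact: QI {art.qi_id}",
            "=" * 46,
            f"Strata thresholds (stratifier p20/p80): "
            f"{art.thresholds.p20:.4f} / {art.thresholds.p80:.4f}",
            f"Standard-population rate P_std: {art.standard_rate_overall:.4f}",
            "",
            f"{'stratum':>12} {'weight':>8} {'P_s':>8} {'intercept':>10}  "
            f"{'status':<20}",
        ]
        for label in STRATA:
            m = art.stratum_models[label]
            lines.append(
                f"{label:>12} {art.weights[label]:8.4f} "
                f"{art.standard_rate_by_stratum[label]:8.4f} "
                f"{m.intercept:10.4f}  {m.fit_status:<20}"
            )
        m = art.stratum_models["unstratified"]
        lines.append(
            f"{'unstrat.':>12} {1.0:8.4f} {art.standard_rate_overall:8.4f} "
            f"{m.intercept:10.4f}  {m.fit_status:<20}"
        )
        lines.append("")
        lines.append("Coefficients (logit scale):")
        for label in (*STRATA, "unstratified"):
            coefs = art.stratum_models[label].coefficients
            body = ", ".join(f"{k}={v:+.4f}" for k, v in coefs.items()) or "(intercept only)"
            lines.append(f"  {label:>12}: {body}")
        return "\n".join(lines)
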