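"""Reliability and validity evaluation of facility QI scores.

Reliability is quarter-to-quarter stability: the Pearson autocorrelation of
a QI's facility scores across consecutive quarters.  Validity is assessed
against external facility-level care-process measures ("validation
elements", preventive vs responsive): elements are single-imputed with
chained regression + hot-deck replacement, reduced to 10 + 10 orthogonal
principal components, and each QI's facility scores are regressed on the
preventive set (Model 1), the responsive set (Model 2) and both (Model 3).
The multiple correlations R1/R3 classify the QI into validity Level I, II
or III.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA

__all__ = [
    "ReliabilityResult",
    "ValidationElements",
    "ComponentScores",
    "autocorrelation",
    "cross_sectional_correlation",
    "impute_elements",
    "extract_components",
    "fit_validity_models",
    "classify_validity",
    "ValidityModel",
    "ValidityResults",
    "plot_score_densities",
]

# Validity classification cut points on the multiple correlation coefficient.
# Level I: preventive-model R >= 0.45 or combined-model R > 0.55.
# Level II (if not Level I): preventive R in [0.30, 0.45) or combined R in
# (0.40, 0.55].  Everything else is Level III.
LEVEL1_PREVENTIVE_MIN = 0.45
LEVEL1_COMBINED_MIN = 0.55
LEVEL2_PREVENTIVE_MIN = 0.30
LEVEL2_COMBINED_MIN = 0.40


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReliabilityResult:
    qi_id: str
    method: str  # raw | gen2 | gen3
    r: float  # NaN when undefined
    n_facilities: int
    quarter_pair: tuple
    reason: str = ""  # why r is undefined, if it is


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def autocorrelation(
    scores_t,
    scores_t_plus_1,
    qi_id: str = "",
    method: str = "",
    quarter_pair: tuple = (0, 1),
) -> ReliabilityResult:
    """Pearson correlation of facility scores across consecutive quarters.

    Inputs are aligned by position (or by index when both are Series);
    facility pairs with a missing score in either quarter are dropped
    (pairwise-complete).  Requires >= 3 complete pairs; zero variance in
    either quarter leaves ``r`` undefined with a reason.
    """
    if isinstance(scores_t, pd.Series) and isinstance(scores_t_plus_1, pd.Series):
        joined = pd.concat([scores_t, scores_t_plus_1], axis=1, join="inner")
        x = joined.iloc[:, 0].to_numpy(dtype=float)
        y = joined.iloc[:, 1].to_numpy(dtype=float)
    else:
        x = np.asarray(scores_t, dtype=float)
        y = np.asarray(scores_t_plus_1, dtype=float)
        if x.shape != y.shape:
            raise ValueError("score vectors must align facility-by-facility")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete facility pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ReliabilityResult(qi_id, method, float("nan"), n, tuple(quarter_pair),
                                 reason="zero variance in one quarter")
    return ReliabilityResult(qi_id, method, _pearson(x, y), n, tuple(quarter_pair))


def cross_sectional_correlation(adjusted_scores, raw_rates) -> float:
    """Same-quarter Pearson correlation of adjusted scores with raw rates."""
    res = autocorrelation(adjusted_scores, raw_rates, quarter_pair=(0, 0))
    return res.r


@dataclass
class ValidationElements:
    """Facility-by-element matrix of care-process measures.

    ``element_class`` maps each column to ``"preventive"`` (anticipatory
    actions that forestall problems) or ``"responsive"`` (reactions once a
    problem is identified).
    """

    values: pd.DataFrame
    element_class: pd.Series

    def __post_init__(self):
        unknown = set(self.element_class.unique()) - {"preventive", "responsive"}
        if unknown:
            raise ValueError(f"unknown element class(es): {sorted(unknown)}")
        if list(self.element_class.index) != list(self.values.columns):
            raise ValueError("element_class must cover exactly the element columns")

    def subset(self, element_class: str) -> pd.DataFrame:
        cols = self.element_class.index[self.element_class == element_class]
        return self.values[list(cols)]


# ---------------------------------------------------------------------------
# validation-element imputation (chained regression + hot deck)
# ---------------------------------------------------------------------------

def impute_elements(elements: pd.DataFrame, n_cycles: int = 5) -> pd.DataFrame:
    """Single imputation by chained linear regressions with hot-deck donors.

    Missing cells are first filled with column means.  Then, for a fixed
    number of cycles and in fixed (left-to-right) column order, each column
    with missing cells is regressed (OLS) on all other columns over the rows
    where it was observed, its missing cells are predicted, and each
    prediction is replaced by the observed value of that column closest to
    it (first-occurring on ties).  Every imputed cell therefore equals some
    observed value of its own column.  The procedure is deterministic.

    Raises ``ValueError`` if any column has fewer than 2 observed values.
    """
    X = elements.to_numpy(dtype=float).copy()
    n, p = X.shape
    obs_mask = ~np.isnan(X)
    n_obs = obs_mask.sum(axis=0)
    if np.any(n_obs < 2):
        bad = [elements.columns[j] for j in np.where(n_obs < 2)[0]]
        raise ValueError(f"column(s) {bad} have fewer than 2 observed values")
    if obs_mask.all():
        return elements.copy()

    col_means = np.nanmean(X, axis=0)
    work = np.where(obs_mask, X, col_means[None, :])
    incomplete = [j for j in range(p) if not obs_mask[:, j].all()]
    # donor pools: unique observed values per column, sorted for bisection,
    # with the first-occurrence row of each value for tie-breaking
    donors = []
    for j in range(p):
        col = X[obs_mask[:, j], j]
        values, first_idx = np.unique(col, return_index=True)
        donors.append((values, first_idx))

    for _ in range(n_cycles):
        for j in incomplete:
            others = [c for c in range(p) if c != j]
            A = np.column_stack([np.ones(n), work[:, others]])
            rows = obs_mask[:, j]
            coef, *_ = np.linalg.lstsq(A[rows], X[rows, j], rcond=None)
            pred = A[~rows] @ coef
            # hot deck: snap each prediction to the nearest observed value
            # of the same column; exact-distance ties go to the donor that
            # occurs first among the column's observed values
            d, first = donors[j]
            if d.size == 1:
                work[~rows, j] = d[0]
                continue
            pos = np.clip(np.searchsorted(d, pred), 1, d.size - 1)
            lo, hi = d[pos - 1], d[pos]
            dist_lo, dist_hi = np.abs(pred - lo), np.abs(hi - pred)
            take_hi = (dist_hi < dist_lo) | (
                (dist_hi == dist_lo) & (first[pos] < first[pos - 1])
            )
            work[~rows, j] = np.where(take_hi, hi, lo)
    return pd.DataFrame(work, index=elements.index, columns=elements.columns)


# ---------------------------------------------------------------------------
# principal components of the element sets
# ---------------------------------------------------------------------------

@dataclass
class ComponentScores:
    """Facility scores on the first k preventive and responsive components."""

    preventive: pd.DataFrame
    responsive: pd.DataFrame

    def __post_init__(self):
        overlap = set(self.preventive.columns) & set(self.responsive.columns)
        if overlap:
            raise ValueError(
                f"preventive and responsive component names must be distinct "
                f"(shared: {sorted(overlap)})"
            )


def extract_components(elements: pd.DataFrame, k: int = 10,
                       prefix: str = "PC") -> pd.DataFrame:
    """Scores on the first ``k`` principal components of standardized elements.

    Columns are standardized to zero mean and unit (ddof=1) variance, so the
    PCA diagonalizes the element correlation matrix.  Returned score columns
    are ordered by decreasing explained variance and are exactly pairwise
    uncorrelated.  ``k`` must not exceed the matrix rank.
    """
    if elements.isna().any().any():
        raise ValueError("elements must be imputed (complete) before PCA")
    X = elements.to_numpy(dtype=float)
    n, p = X.shape
    if n <= k:
        raise ValueError(f"need more than k={k} facilities, got {n}")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [elements.columns[j] for j in np.where(sd == 0)[0]]
        raise ValueError(f"constant element column(s) {bad} cannot be standardized")
    Z = (X - X.mean(axis=0)) / sd
    rank = np.linalg.matrix_rank(Z)
    if k > rank:
        raise ValueError(f"k={k} exceeds element-matrix rank {rank}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z)
    cols = [f"{prefix}{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=elements.index, columns=cols)


# ---------------------------------------------------------------------------
# validity models and classification
# ---------------------------------------------------------------------------

def _multiple_correlation(y: np.ndarray, X: np.ndarray) -> float:
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} facilities for {p} predictors, got {n}")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return float(np.sqrt(max(fit.rsquared, 0.0)))


def fit_validity_models(qi_facility_scores, components: ComponentScores):
    """Multiple correlations (R1, R2, R3) of a QI with element components.

    Model 1 regresses the adjusted facility QI score on the 10 preventive
    components, Model 2 on the 10 responsive components, Model 3 on all 20;
    R_m is the positive square root of each model's R-squared.  Facilities
    are aligned on index and rows with any missing value are dropped.
    """
    y = pd.Series(qi_facility_scores)
    frame = pd.concat(
        [y.rename("_y"), components.preventive, components.responsive],
        axis=1, join="inner",
    ).dropna()
    yv = frame["_y"].to_numpy(dtype=float)
    prev = frame[components.preventive.columns].to_numpy(dtype=float)
    resp = frame[components.responsive.columns].to_numpy(dtype=float)
    R1 = _multiple_correlation(yv, prev)
    R2 = _multiple_correlation(yv, resp)
    R3 = _multiple_correlation(yv, np.column_stack([prev, resp]))
    return R1, R2, R3


def classify_validity(R1: float, R3: float) -> str:
    """Assign validity Level "I", "II" or "III" from the preventive-model
    and combined-model multiple correlations (Level I rule applied first)."""
    for name, value in (("R1", R1), ("R3", R3)):
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"{name}={value} outside [0, 1]")
    if R1 >= LEVEL1_PREVENTIVE_MIN or R3 > LEVEL1_COMBINED_MIN:
        return "I"
    if (LEVEL2_PREVENTIVE_MIN <= R1 < LEVEL1_PREVENTIVE_MIN) or (
        LEVEL2_COMBINED_MIN < R3 <= LEVEL1_COMBINED_MIN
    ):
        return "II"
    return "III"


class ValidityModel:
    """Validity evaluation of one QI against element components.

    Parameters
    ----------
    qi_facility_scores : Series
        Adjusted (gen-3) facility-level scores, indexed by facility.
    components : ComponentScores
        Orthogonal preventive and responsive component scores per facility.
    """

    def __init__(self, qi_facility_scores, components: ComponentScores,
                 qi_id: str = ""):
        self.qi_facility_scores = pd.Series(qi_facility_scores)
        self.components = components
        self.qi_id = qi_id or getattr(qi_facility_scores, "name", "") or ""

    def fit(self) -> "ValidityResults":
        R1, R2, R3 = fit_validity_models(self.qi_facility_scores, self.components)
        return ValidityResults(self.qi_id, R1, R2, R3)


@dataclass(frozen=True)
class ValidityResults:
    """Multiple correlations and the assigned validity level for one QI."""

    qi_id: str
    R1: float
    R2: float
    R3: float

    @property
    def level(self) -> str:
        return classify_validity(self.R1, self.R3)

    def summary(self) -> str:
        return "\n".join([
            f"Validity evaluation: QI {self.qi_id}",
            "=" * 38,
            f"Model 1 (10 preventive components)  R1 = {self.R1:.4f}",
            f"Model 2 (10 responsive components)  R2 = {self.R2:.4f}",
            f"Model 3 (all 20 components)         R3 = {self.R3:.4f}",
            f"Validity level: {self.level}",
            "(classification uses R1 and R3; R2 is reported only)",
        ])


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_score_densities(scores_by_group, ax=None, title: str = ""):
    """Overlay kernel density estimates of QI scores across named subsets.

    ``scores_by_group`` maps a label (e.g. a jurisdiction or care sector) to
    an array of facility scores.  Useful for judging whether a reference
    population is appropriate for a target facility set.
    """
    from scipy.stats import gaussian_kde
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    for label, values in scores_by_group.items():
        v = np.asarray(values, dtype=float)
        v = v[~np.isnan(v)]
        if v.size < 2 or np.ptp(v) == 0:
            continue
        grid = np.linspace(v.min() - 0.05, v.max() + 0.05, 256)
        ax.plot(grid, gaussian_kde(v)(grid), label=label)
    ax.set_xlabel("QI score")
    ax.set_ylabel("density")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax
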