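"""Outcome models: logistic dementia regression, linear cognitive-slope
regression, forward-AIC stepwise selection, VIF diagnostics and the
tertile-group illustration.

Predictors are the per-subject baseline (intercept) and annualized-change
(slope) estimates extracted by :mod:`svdnet.longmodels`.  By default each
predictor is standardized to unit SD before fitting, so logistic B is the
log-odds change per SD of predictor and linear models additionally report
the standardized coefficient beta = B * sd(x) / sd(y).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "OutcomeModel",
    "OutcomeResults",
    "TertileSummary",
    "fit_logistic_outcome",
    "fit_linear_outcome",
    "stepwise_aic",
    "vif",
    "tertile_illustration",
]

logger = logging.getLogger(__name__)


@dataclass
class OutcomeResults:
    """Per-predictor coefficients and diagnostics for one outcome model."""

    outcome_type: str                      # "binary" | "continuous"
    coefficients: pd.DataFrame             # index: predictor; columns depend on type
    aic: float
    selected_predictors: list[str] = field(default_factory=list)
    vif: pd.Series | None = None
    converged: bool = True
    separation_flag: bool = False
    nobs: int = 0

    def summary(self) -> str:
        kind = "logistic" if self.outcome_type == "binary" else "linear"
        lines = [f"{kind.capitalize()} outcome model "
                 f"(n = {self.nobs}, AIC = {self.aic:.2f})"]
        if not self.converged:
            lines.append("  WARNING: fit did not converge"
                         + (" (possible complete separation)" if self.separation_flag else ""))
        lines.append(self.coefficients.to_string(float_format=lambda v: f"{v:.4f}"))
        if self.vif is not None:
            lines.append("VIF: " + ", ".join(f"{k}={v:.2f}" for k, v in self.vif.items()))
        return "\n".join(lines)


class OutcomeModel:
    """Regression of a per-subject outcome on per-subject predictors.

    Parameters
    ----------
    predictors :
        DataFrame of per-subject predictor values (one row per subject).
    outcome :
        Binary conversion status (0/1) or a continuous value such as the
        per-subject cognitive slope.
    outcome_type :
        ``"binary"`` (logistic) or ``"continuous"`` (linear least squares).
    standardize :
        Scale each predictor to unit SD (default True).
    """

    def __init__(self, predictors: pd.DataFrame | pd.Series, outcome,
                 outcome_type: str, standardize: bool = True):
        if outcome_type not in ("binary", "continuous"):
            raise ValueError("outcome_type must be 'binary' or 'continuous'")
        X = pd.DataFrame(predictors).copy()
        y = np.asarray(outcome, dtype=float)
        if len(X) != len(y):
            raise ValueError("predictors and outcome must have equal length")
        keep = ~(X.isna().any(axis=1).to_numpy() | np.isnan(y))
        X, y = X.loc[keep], y[keep]
        if outcome_type == "binary":
            classes = np.unique(y)
            if not np.array_equal(classes, [0, 1]):
                raise ValueError("binary outcome needs both classes present (0 and 1)")
        self.outcome_type = outcome_type
        self.standardize = standardize
        self.X_raw = X
        self.y = y
        self._sd = X.std(ddof=1)
        if standardize:
            if (self._sd == 0).any():
                bad = list(self._sd.index[self._sd == 0])
                raise ValueError(f"constant predictors cannot be standardized: {bad}")
            self.X = X / self._sd
        else:
            self.X = X

    # ------------------------------------------------------------------
    def fit(self) -> OutcomeResults:
        design = sm.add_constant(self.X, has_constant="add")
        if self.outcome_type == "binary":
            return self._fit_logit(design)
        return self._fit_ols(design)

    def _fit_logit(self, design: pd.DataFrame) -> OutcomeResults:
        model = sm.Logit(self.y, design)
        separation = False
        try:
            import warnings as _w
            with _w.catch_warnings(record=True) as caught:
                _w.simplefilter("always")
                fit = model.fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
            for w in caught:
                if "erfectly" in str(w.message) or "eparation" in str(w.message):
                    separation = True
                    converged = False
        except Exception:  # noqa: BLE001 - PerfectSeparationError et al.
            logger.warning("logistic fit failed: flagged as separation/non-convergence")
            coefs = pd.DataFrame(index=list(self.X.columns),
                                 columns=["B", "se", "p", "OR"], dtype=float)
            return OutcomeResults("binary", coefs, aic=np.inf,
                                  converged=False, separation_flag=True,
                                  nobs=len(self.y))
        names = [c for c in design.columns if c != "const"]
        coefs = pd.DataFrame({
            "B": fit.params[names],
            "se": fit.bse[names],
            "p": fit.pvalues[names],
            "OR": np.exp(fit.params[names]),
        })
        res = OutcomeResults("binary", coefs, aic=float(fit.aic),
                             converged=converged, separation_flag=separation,
                             nobs=int(fit.nobs))
        if len(names) >= 2:
            res.vif = vif(self.X)
        return res

    def _fit_ols(self, design: pd.DataFrame) -> OutcomeResults:
        fit = sm.OLS(self.y, design).fit()
        names = [c for c in design.columns if c != "const"]
        sd_y = float(np.std(self.y, ddof=1))
        beta = fit.params[names] * self.X[names].std(ddof=1) / sd_y
        coefs = pd.DataFrame({
            "B": fit.params[names],
            "se": fit.bse[names],
            "p": fit.pvalues[names],
            "beta": beta,
        })
        res = OutcomeResults("continuous", coefs, aic=float(fit.aic),
                             nobs=int(fit.nobs))
        if len(names) >= 2:
            res.vif = vif(self.X)
        return res


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_logistic_outcome(predictors, converted, standardize: bool = True) -> OutcomeResults:
    """Logistic regression of conversion status on per-subject predictors."""
    return OutcomeModel(predictors, converted, "binary", standardize=standardize).fit()


def fit_linear_outcome(predictors, continuous_outcome, standardize: bool = True) -> OutcomeResults:
    """Linear regression of a continuous per-subject outcome on predictors."""
    return OutcomeModel(predictors, continuous_outcome, "continuous",
                        standardize=standardize).fit()


def stepwise_aic(candidates: pd.DataFrame, outcome, outcome_type: str,
                 standardize: bool = True) -> OutcomeResults:
    """Forward stepwise selection minimizing AIC.

    Starts from the intercept-only model; at each step adds the candidate
    giving the largest AIC decrease, stopping when no addition lowers AIC.
    Candidate order does not matter: exact AIC ties break lexicographically
    by predictor name.  The intercept-only model is a legal final answer
    (``selected_predictors`` empty, coefficient table empty).
    """
    candidates = pd.DataFrame(candidates)
    y = np.asarray(outcome, dtype=float)

    def model_aic(cols: list[str]) -> float:
        X = sm.add_constant(candidates[cols] if cols else
                            pd.DataFrame(index=candidates.index), has_constant="add")
        if outcome_type == "binary":
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        else:
            fit = sm.OLS(y, X).fit()
        return float(fit.aic)

    selected: list[str] = []
    current_aic = model_aic([])
    remaining = sorted(candidates.columns)
    while remaining:
        trials = sorted((model_aic(selected + [c]), c) for c in remaining)
        best_aic, best = trials[0]
        if best_aic >= current_aic - 1e-10:
            break
        selected.append(best)
        remaining.remove(best)
        current_aic = best_aic
    if not selected:
        empty = pd.DataFrame(columns=["B", "se", "p",
                                      "OR" if outcome_type == "binary" else "beta"])
        return OutcomeResults(outcome_type, empty, aic=current_aic,
                              selected_predictors=[], nobs=len(y))
    res = OutcomeModel(candidates[selected], y, outcome_type,
                       standardize=standardize).fit()
    res.selected_predictors = selected
    return res


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j) regressing
    predictor j on the remaining predictors (with intercept).

    Exact collinearity yields ``inf`` for the affected predictors.
    """
    X = pd.DataFrame(design)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]), has_constant="add")
        r2 = sm.OLS(X[col].to_numpy(), others).fit().rsquared
        out[col] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    s = pd.Series(out, name="VIF")
    if np.isinf(s).any():
        logger.warning("exact collinearity: infinite VIF for %s",
                       list(s.index[np.isinf(s)]))
    return s


# ---------------------------------------------------------------------------
# tertile illustration
# ---------------------------------------------------------------------------

@dataclass
class TertileSummary:
    """Conversion and cognition summaries for decline tertiles."""

    group_sizes: tuple[int, int, int]              # (low, middle, high decline)
    cut_points: tuple[float, float]
    conversion_counts: tuple[int, int, int] | None
    conversion_percent: tuple[float, float, float] | None
    mean_cognitive_slopes: tuple[float, float, float] | None
    group_labels: pd.Series = field(repr=False, default=None)  # subject -> low/middle/high

    def summary(self) -> str:
        lines = [f"Tertile groups by annualized change (sizes "
                 f"{self.group_sizes[0]}/{self.group_sizes[1]}/{self.group_sizes[2]}, "
                 f"cut points {self.cut_points[0]:.3f}, {self.cut_points[1]:.3f})"]
        if self.conversion_counts is not None:
            for name, k, n, pct in zip(("low", "middle", "high"),
                                       self.conversion_counts, self.group_sizes,
                                       self.conversion_percent):
                lines.append(f"  {name} decline: {k}/{n} converted ({pct:.1f}%)")
        if self.mean_cognitive_slopes is not None:
            lines.append("  mean fitted cognitive slopes: "
                         + ", ".join(f"{v:.4f}" for v in self.mean_cognitive_slopes))
        return "\n".join(lines)


def tertile_illustration(change_values, converted=None,
                         cognitive_slopes=None) -> TertileSummary:
    """Split subjects into three near-equal groups by annualized change.

    The *high-decline* group holds the most negative changes.  Group sizes
    differ by at most 1; when n is not divisible by 3 the extra subjects go
    to the high-decline group(s) (n = 97 gives 32/32/33).  Ties at a cut
    point break deterministically by subject order.
    """
    change = pd.Series(change_values).astype(float)
    n = len(change)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    base = n // 3
    rem = n % 3
    # sizes listed (low, middle, high); remainder assigned from the high end
    sizes = [base, base, base]
    for k in range(rem):
        sizes[2 - k] += 1
    order = np.lexsort((np.arange(n), -change.to_numpy()))  # least decline first
    group = np.empty(n, dtype=object)
    bounds = np.cumsum([0] + sizes)
    for label, lo, hi in zip(("low", "middle", "high"), bounds[:-1], bounds[1:]):
        group[order[lo:hi]] = label
    groups = pd.Series(group, index=change.index, name="decline_group")
    sorted_change = change.to_numpy()[order]
    cuts = (float(sorted_change[sizes[0] - 1:sizes[0] + 1].mean()),
            float(sorted_change[bounds[2] - 1:bounds[2] + 1].mean()))

    conv_counts = conv_pct = None
    if converted is not None:
        converted = pd.Series(np.asarray(converted, dtype=int), index=change.index)
        conv_counts = tuple(int(converted[groups == g].sum())
                            for g in ("low", "middle", "high"))
        conv_pct = tuple(100.0 * k / s for k, s in zip(conv_counts, sizes))
    cog_means = None
    if cognitive_slopes is not None:
        cs = pd.Series(np.asarray(cognitive_slopes, dtype=float), index=change.index)
        cog_means = tuple(float(cs[groups == g].mean())
                          for g in ("low", "middle", "high"))
    return TertileSummary(group_sizes=tuple(sizes), cut_points=cuts,
                          conversion_counts=conv_counts,
                          conversion_percent=conv_pct,
                          mean_cognitive_slopes=cog_means,
                          group_labels=groups)
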