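"""Causal mediation analysis with a nonparametric bootstrap.

For treatment T, mediator M and outcome Y the mediator model is
``M = alpha0 + a*T`` and the outcome model ``Y = beta0 + c'*T + b*M`` (with a
logistic link when Y is binary).  The average causal mediation effect (ACME)
is the counterfactual indirect effect of shifting T by one contrast while
holding the mediator at the value it would take under each treatment level;
in the linear-linear case this reduces to the Sobel product of coefficients
a*b.  For binary outcomes, effects are computed on the probability
(risk-difference) scale by averaging potential-outcome probabilities over
the mediator's residual distribution (Gauss-Hermite quadrature), with
log-odds-scale output available behind a flag.

Uncertainty comes from a nonparametric bootstrap (resampling subjects with
replacement, default 10,000 samples) with percentile confidence intervals;
ACME/ADE p-values are two-sided bootstrap sign-crossing probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit, roots_hermitenorm

__all__ = ["MediationModel", "MediationResult", "mediate", "mediation_table"]

logger = logging.getLogger(__name__)

_GH_NODES, _GH_WEIGHTS = roots_hermitenorm(32)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _ols2(x1, x2, y):
    """OLS of y on [1, x1] or [1, x1, x2]; returns coefficient vector."""
    cols = [np.ones_like(x1), x1] + ([x2] if x2 is not None else [])
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def _logit_fit(X, y, maxiter=100, tol=1e-10):
    """Newton-Raphson logistic regression (design X includes the intercept)."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        p = expit(X @ beta)
        w = p * (1 - p)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(len(beta)), grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


@dataclass
class _PointEstimates:
    acme: float
    ade: float
    total: float
    proportion: float
    a: float
    b: float
    c_prime: float


def _point_estimates(t, m, y, binary: bool, t0: float, t1: float,
                     scale: str = "risk") -> _PointEstimates:
    alpha0, a = _ols2(t, None, m)[:2]
    resid = m - (alpha0 + a * t)
    sigma = float(np.sqrt(np.mean(resid ** 2)))
    if not binary:
        beta0, c_prime, b = _ols2(t, m, y)
        acme = a * b * (t1 - t0)
        ade = c_prime * (t1 - t0)
        total = acme + ade
    else:
        X = np.column_stack([np.ones_like(t), t, m])
        beta0, c_prime, b = _logit_fit(X, y)

        def e_y(t_y: float, t_m: float) -> float:
            mu_m = alpha0 + a * t_m
            lin = beta0 + c_prime * t_y + b * (mu_m + sigma * _GH_NODES)
            p = float(np.sum(_GH_WEIGHTS * expit(lin)))
            return p

        y11, y10 = e_y(t1, t1), e_y(t1, t0)
        y01, y00 = e_y(t0, t1), e_y(t0, t0)
        if scale == "risk":
            acme = 0.5 * ((y11 - y10) + (y01 - y00))
            ade = 0.5 * ((y11 - y01) + (y10 - y00))
            total = y11 - y00
        elif scale == "logodds":
            l11, l10, l01, l00 = (logit(v) for v in (y11, y10, y01, y00))
            acme = 0.5 * ((l11 - l10) + (l01 - l00))
            ade = 0.5 * ((l11 - l01) + (l10 - l00))
            total = l11 - l00
        else:
            raise ValueError("scale must be 'risk' or 'logodds'")
    proportion = acme / total if total != 0 else np.nan
    return _PointEstimates(acme, ade, total, proportion,
                           float(a), float(b), float(c_prime))


@dataclass
class MediationResult:
    """ACME / ADE / total effect / proportion mediated with bootstrap CIs."""

    acme: float
    ade: float
    total_effect: float
    proportion_mediated: float
    acme_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    total_ci: tuple[float, float]
    proportion_ci: tuple[float, float]
    acme_p: float
    ade_p: float
    n_boot: int
    rng_seed: int | None
    outcome_type: str
    scale: str
    mediator_model: dict = field(default_factory=dict)
    outcome_model: dict = field(default_factory=dict)
    n_redrawn_resamples: int = 0

    def summary(self) -> str:
        def fmt(v, ci):
            return f"{v: .4f} [{ci[0]: .4f}, {ci[1]: .4f}]"
        return "\n".join([
            f"Causal mediation ({self.outcome_type} outcome, {self.scale} scale, "
            f"{self.n_boot} bootstrap samples)",
            f"  ACME:                {fmt(self.acme, self.acme_ci)}  p = {self.acme_p:.4g}",
            f"  ADE (direct):        {fmt(self.ade, self.ade_ci)}  p = {self.ade_p:.4g}",
            f"  Total effect:        {fmt(self.total_effect, self.total_ci)}",
            f"  Proportion mediated: {fmt(self.proportion_mediated, self.proportion_ci)}",
        ])


class MediationModel:
    """Mediation of the treatment -> outcome association through a mediator.

    The treatment contrast for continuous treatments is a 1 SD increase
    (centered at the mean); a 0/1 treatment uses the natural 0 -> 1 contrast.
    """

    def __init__(self, treatment, mediator, outcome, outcome_type: str = "continuous",
                 scale: str = "risk"):
        t = np.asarray(treatment, dtype=float)
        m = np.asarray(mediator, dtype=float)
        y = np.asarray(outcome, dtype=float)
        keep = ~(np.isnan(t) | np.isnan(m) | np.isnan(y))
        self.t, self.m, self.y = t[keep], m[keep], y[keep]
        if len(self.t) < 10:
            raise ValueError("need at least 10 complete cases")
        if outcome_type not in ("continuous", "binary"):
            raise ValueError("outcome_type must be 'continuous' or 'binary'")
        if outcome_type == "binary" and not set(np.unique(self.y)) <= {0.0, 1.0}:
            raise ValueError("binary outcome must be 0/1")
        self.outcome_type = outcome_type
        self.scale = scale
        uniq = np.unique(self.t)
        if set(uniq) <= {0.0, 1.0}:
            self.t0, self.t1 = 0.0, 1.0
        else:
            mu, sd = float(self.t.mean()), float(self.t.std(ddof=1))
            self.t0, self.t1 = mu - sd / 2, mu + sd / 2

    def fit(self, n_boot: int = 10_000, rng_seed: int | None = None,
            ci_level: float = 0.95) -> MediationResult:
        binary = self.outcome_type == "binary"
        est = _point_estimates(self.t, self.m, self.y, binary,
                               self.t0, self.t1, self.scale)
        rng = np.random.default_rng(rng_seed)
        n = len(self.t)
        boots = np.empty((n_boot, 4))
        n_redrawn = 0
        for k in range(n_boot):
            while True:
                idx = rng.integers(0, n, size=n)
                yb = self.y[idx]
                if not binary or (yb.min() == 0 and yb.max() == 1):
                    break
                n_redrawn += 1
            e = _point_estimates(self.t[idx], self.m[idx], yb, binary,
                                 self.t0, self.t1, self.scale)
            boots[k] = (e.acme, e.ade, e.total, e.proportion)
        if n_redrawn:
            logger.info("mediate: %d one-class bootstrap resamples redrawn", n_redrawn)
        lo, hi = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
        qs = np.nanquantile(boots, [lo, hi], axis=0)

        def pval(col):
            frac = np.mean(boots[:, col] <= 0)
            return float(2 * min(frac, 1 - frac))

        return MediationResult(
            acme=est.acme, ade=est.ade, total_effect=est.total,
            proportion_mediated=est.proportion,
            acme_ci=(float(qs[0, 0]), float(qs[1, 0])),
            ade_ci=(float(qs[0, 1]), float(qs[1, 1])),
            total_ci=(float(qs[0, 2]), float(qs[1, 2])),
            proportion_ci=(float(qs[0, 3]), float(qs[1, 3])),
            acme_p=pval(0), ade_p=pval(1),
            n_boot=n_boot, rng_seed=rng_seed,
            outcome_type=self.outcome_type, scale=self.scale,
            mediator_model={"alpha0": None, "a": est.a},
            outcome_model={"b": est.b, "c_prime": est.c_prime},
            n_redrawn_resamples=n_redrawn,
        )


def mediate(treatment, mediator, outcome, outcome_type: str = "continuous",
            n_boot: int = 10_000, rng_seed: int | None = None,
            scale: str = "risk") -> MediationResult:
    """Functional wrapper around :class:`MediationModel`."""
    return MediationModel(treatment, mediator, outcome, outcome_type,
                          scale=scale).fit(n_boot=n_boot, rng_seed=rng_seed)


def mediation_table(predictors: pd.DataFrame, mediator, outcomes: dict,
                    n_boot: int = 1000, rng_seed: int | None = None,
                    screen_alpha: float = 0.05) -> pd.DataFrame:
    """Run mediation for every predictor x outcome pair passing the
    univariate screen.

    ``outcomes`` maps outcome name to ``(values, outcome_type)``.  A
    predictor qualifies for an outcome when its single-predictor outcome
    model p-value is below ``screen_alpha``.  Returns a long table with
    ACME, ADE, total effect, proportion mediated, CIs and significance
    flags; empty (with a log message) when nothing passes the screen.
    """
    from svdnet.outcomes import OutcomeModel

    predictors = pd.DataFrame(predictors)
    rows = []
    seed_seq = np.random.SeedSequence(rng_seed)
    for oname, (values, otype) in outcomes.items():
        for pname in predictors.columns:
            single = OutcomeModel(predictors[[pname]], values, otype).fit()
            p_uni = float(single.coefficients["p"].iloc[0])
            if p_uni >= screen_alpha:
                continue
            child_seed = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
            res = mediate(predictors[pname].to_numpy(), np.asarray(mediator, float),
                          np.asarray(values, float), outcome_type=otype,
                          n_boot=n_boot, rng_seed=child_seed)
            rows.append({
                "outcome": oname, "predictor": pname,
                "univariate_p": p_uni,
                "acme": res.acme, "acme_lo": res.acme_ci[0], "acme_hi": res.acme_ci[1],
                "acme_p": res.acme_p, "acme_significant": res.acme_p < screen_alpha,
                "ade": res.ade, "ade_lo": res.ade_ci[0], "ade_hi": res.ade_ci[1],
                "ade_p": res.ade_p, "ade_significant": res.ade_p < screen_alpha,
                "total_effect": res.total_effect,
                "proportion_mediated": res.proportion_mediated,
                "proportion_lo": res.proportion_ci[0],
                "proportion_hi": res.proportion_ci[1],
            })
    if not rows:
        logger.info("mediation_table: no predictor passed the univariate screen")
        return pd.DataFrame(columns=["outcome", "predictor"])
    return pd.DataFrame(rows)
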