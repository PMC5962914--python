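"""Longitudinal cohort simulation with known ground truth.

Emulates a symptomatic small-vessel-disease cohort followed with annual MRI
(4 visits over 3 years) and annual cognitive assessment (6 visits over 5
years): per-subject random intercepts and slopes for each continuous imaging
measure, marker slopes correlated with the decline in network global
efficiency, logistic dementia conversion driven by the efficiency slope and
baseline efficiency, linear cognitive decline tied to the efficiency slope,
Poisson lacune/microbleed accrual, visit-time jitter and exponential dropout.

Every draw comes from one :class:`numpy.random.Generator`, so a fixed seed
reproduces the cohort exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, roots_hermitenorm

__all__ = [
    "MeasureParams",
    "CohortParams",
    "CohortTable",
    "simulate_cohort",
    "global_cognition_index",
    "MRI_MEASURES",
    "COGNITIVE_MEASURES",
    "COUNT_MEASURES",
]

#: continuous / count measures collected at MRI visits
MRI_MEASURES = [
    "global_efficiency", "local_efficiency", "n_edges", "mean_edge_weight",
    "wmh_load", "brain_volume", "md_nph", "hippocampal_volume",
    "lacune_count", "cmb_count",
]
#: measures collected at cognitive visits
COGNITIVE_MEASURES = ["global_cognition"]
#: count-valued measures (dichotomized downstream rather than slope-fitted)
COUNT_MEASURES = ["lacune_count", "cmb_count"]


@dataclass
class MeasureParams:
    """Random-intercept/random-slope population for one continuous measure.

    ``efficiency_slope_corr`` is the correlation between this measure's
    random slope and the network-global-efficiency random slope, which is the
    latent driver of the whole simulation.
    """

    intercept_mean: float
    intercept_sd: float
    slope_mean: float
    slope_sd: float
    residual_sd: float
    intercept_slope_corr: float = 0.3
    efficiency_slope_corr: float = 1.0

    def __post_init__(self):
        if self.intercept_sd < 0 or self.slope_sd < 0 or self.residual_sd < 0:
            raise ValueError("SDs must be non-negative")
        for r in (self.intercept_slope_corr, self.efficiency_slope_corr):
            if not -1 <= r <= 1:
                raise ValueError("correlations must lie in [-1, 1]")


def _default_measures() -> dict[str, MeasureParams]:
    # Anchors: network global efficiency baseline 7.94 +/- 2.30, mean annual
    # decline -0.1764 with subject slopes spanning roughly [-0.45, 0.10]
    # (slope SD 0.09); the residual SD (0.1) keeps per-subject slope
    # estimates informative over 4 visits, matching the wide spread of
    # individual estimates the study reports.  Other measures are plausible
    # clinical magnitudes with decline correlated to the efficiency decline.
    return {
        "global_efficiency": MeasureParams(7.94, 2.30, -0.1764, 0.09, 0.1,
                                           intercept_slope_corr=0.3,
                                           efficiency_slope_corr=1.0),
        "local_efficiency": MeasureParams(5.0, 1.2, -0.10, 0.05, 0.15,
                                          efficiency_slope_corr=0.7),
        "n_edges": MeasureParams(700.0, 60.0, -8.0, 4.0, 10.0,
                                 efficiency_slope_corr=0.6),
        "mean_edge_weight": MeasureParams(5.0, 0.8, -0.05, 0.03, 0.08,
                                          efficiency_slope_corr=0.6),
        "wmh_load": MeasureParams(0.07, 0.04, 0.006, 0.004, 0.003,
                                  efficiency_slope_corr=-0.5),
        "brain_volume": MeasureParams(1150.0, 90.0, -7.0, 3.0, 5.0,
                                      efficiency_slope_corr=0.5),
        "md_nph": MeasureParams(0.35, 0.06, -0.006, 0.004, 0.004,
                                efficiency_slope_corr=0.5),
        # hippocampal volume: baseline-only variation, no systematic change
        "hippocampal_volume": MeasureParams(6.5, 0.8, 0.0, 0.0, 0.15,
                                            intercept_slope_corr=0.0,
                                            efficiency_slope_corr=0.0),
        # global cognition: subject slope = -0.027 + a 0.55-correlated share
        # of the efficiency decline + independent noise; the tertile-group
        # mean slopes then span roughly -0.0002 to -0.046 as observed
        "global_cognition": MeasureParams(0.0, 0.7, -0.027, 0.035, 0.1,
                                          intercept_slope_corr=0.2,
                                          efficiency_slope_corr=0.55),
    }


@dataclass
class CohortParams:
    """Generating parameters of the simulated cohort.

    The dementia model is ``logit P(convert) = gamma0 + gamma1 * z(slope_eff)
    + gamma2 * z(baseline_eff)`` with standardized efficiency slope/baseline;
    ``gamma0`` is solved so the marginal conversion probability equals
    ``conversion_rate`` (0.175 by default, i.e. 17.5%).
    """

    n_subjects: int = 97
    mri_visit_times: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    cog_visit_times: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    visit_jitter_years: float = 0.15
    measures: dict[str, MeasureParams] = field(default_factory=_default_measures)
    # dementia conversion
    conversion_rate: float = 0.175
    gamma1: float = -1.8
    gamma2: float = -0.5
    conversion_time_mean: float = 3.3
    conversion_time_sd: float = 1.4
    # count accrual (events per year); per-subject rate scales with
    # exp(-count_efficiency_coupling * z(slope_eff)), so faster network
    # decline means more new lesions
    baseline_lacune_mean: float = 2.0
    lacune_rate_per_year: float = 0.28
    baseline_cmb_mean: float = 1.5
    cmb_rate_per_year: float = 0.65
    count_efficiency_coupling: float = 0.5
    # attrition
    dropout_hazard_per_year: float = 0.12
    rng_seed: int | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for times in (self.mri_visit_times, self.cog_visit_times):
            t = np.asarray(times)
            if np.any(t < 0) or np.any(np.diff(t) <= 0):
                raise ValueError("visit times must be non-negative and strictly increasing")
        if not 0 < self.conversion_rate < 1:
            raise ValueError("conversion_rate must be in (0, 1)")
        if self.dropout_hazard_per_year < 0:
            raise ValueError("dropout hazard must be >= 0")
        if "global_efficiency" not in self.measures:
            raise ValueError("measures must include global_efficiency")

    def with_(self, **kwargs) -> "CohortParams":
        return replace(self, **kwargs)


@dataclass
class CohortTable:
    """Long-format cohort: one row per subject-visit-measure, plus subject facts.

    ``long`` columns: subject_id, visit_time_years, measure, value.
    ``subjects`` columns: subject_id, converted, conversion_time_years
    (NaN when censored), dropout_time_years.
    ``truth`` carries the generating per-subject intercepts/slopes and
    conversion probabilities for validation against downstream estimates.
    """

    long: pd.DataFrame
    subjects: pd.DataFrame
    truth: pd.DataFrame

    def measure_frame(self, measure: str) -> pd.DataFrame:
        df = self.long[self.long["measure"] == measure]
        return df.pivot_table(index="subject_id", columns="visit_time_years",
                              values="value")

    def save_csv(self, path) -> None:
        self.long.to_csv(path, index=False)

    def counts_by_visit(self, measure: str) -> dict[int, np.ndarray]:
        """Per-subject ordered count sequences for a count measure."""
        out = {}
        df = self.long[self.long["measure"] == measure]
        for sid, g in df.groupby("subject_id"):
            out[sid] = g.sort_values("visit_time_years")["value"].to_numpy()
        return out


def _solve_gamma0(target: float, sd_lin: float) -> float:
    """gamma0 with E[expit(gamma0 + N(0, sd_lin^2))] = target (Gauss-Hermite)."""
    if sd_lin == 0:
        return float(np.log(target / (1 - target)))
    nodes, weights = roots_hermitenorm(64)
    weights = weights / weights.sum()

    def marginal(g0):
        return float(np.sum(weights * expit(g0 + sd_lin * nodes))) - target

    return float(brentq(marginal, -20, 20))


def simulate_cohort(params: CohortParams | None = None,
                    rng_seed: int | None = None) -> CohortTable:
    """Draw one cohort.  ``rng_seed`` overrides ``params.rng_seed``."""
    params = params or CohortParams()
    seed = rng_seed if rng_seed is not None else params.rng_seed
    rng = np.random.default_rng(seed)
    n = params.n_subjects
    eff = params.measures["global_efficiency"]

    # latent standardized deviates for the efficiency slope
    z_eff = rng.standard_normal(n)

    # per-measure random effects
    intercepts: dict[str, np.ndarray] = {}
    slopes: dict[str, np.ndarray] = {}
    for name, m in params.measures.items():
        rho_e = 1.0 if name == "global_efficiency" else m.efficiency_slope_corr
        z_slope = rho_e * z_eff + np.sqrt(max(0.0, 1 - rho_e ** 2)) * rng.standard_normal(n)
        r = m.intercept_slope_corr
        z_int = r * z_slope + np.sqrt(max(0.0, 1 - r ** 2)) * rng.standard_normal(n)
        slopes[name] = m.slope_mean + m.slope_sd * z_slope
        intercepts[name] = m.intercept_mean + m.intercept_sd * z_int

    z_base = (intercepts["global_efficiency"] - eff.intercept_mean) / eff.intercept_sd

    # dementia conversion
    rho_is = eff.intercept_slope_corr
    sd_lin = np.sqrt(params.gamma1 ** 2 + params.gamma2 ** 2
                     + 2 * params.gamma1 * params.gamma2 * rho_is)
    gamma0 = _solve_gamma0(params.conversion_rate, sd_lin)
    logit_p = gamma0 + params.gamma1 * z_eff + params.gamma2 * z_base
    p_convert = expit(logit_p)
    converted = rng.random(n) < p_convert
    follow_up = max(params.cog_visit_times)
    conv_time = np.full(n, np.nan)
    k = int(converted.sum())
    if k:
        t = params.conversion_time_mean + params.conversion_time_sd * rng.standard_normal(k)
        conv_time[converted] = np.clip(t, 0.25, follow_up)

    # dropout
    if params.dropout_hazard_per_year > 0:
        dropout = rng.exponential(1.0 / params.dropout_hazard_per_year, size=n)
    else:
        dropout = np.full(n, np.inf)

    # count processes: baseline counts + Poisson increments per MRI interval
    rate_scale = np.exp(-params.count_efficiency_coupling * z_eff)
    base_counts = {
        "lacune_count": rng.poisson(params.baseline_lacune_mean, size=n),
        "cmb_count": rng.poisson(params.baseline_cmb_mean, size=n),
    }
    yearly_rates = {
        "lacune_count": params.lacune_rate_per_year * rate_scale,
        "cmb_count": params.cmb_rate_per_year * rate_scale,
    }

    def jittered(times: np.ndarray) -> np.ndarray:
        out = times.copy()
        j = rng.uniform(-params.visit_jitter_years, params.visit_jitter_years,
                        size=max(0, len(times) - 1))
        out[1:] = times[1:] + j  # baseline stays at exactly t = 0
        return out

    rows: list[tuple] = []
    mri_nominal = np.asarray(params.mri_visit_times, dtype=float)
    cog_nominal = np.asarray(params.cog_visit_times, dtype=float)
    continuous_mri = [m for m in MRI_MEASURES if m not in COUNT_MEASURES
                      and m in params.measures]

    for i in range(n):
        t_mri = jittered(mri_nominal)
        t_cog = jittered(cog_nominal)
        keep_mri = t_mri <= dropout[i]
        keep_mri[0] = True
        keep_cog = t_cog <= dropout[i]
        keep_cog[0] = True
        # continuous MRI measures
        for name in continuous_mri:
            m = params.measures[name]
            for t in t_mri[keep_mri]:
                value = (intercepts[name][i] + slopes[name][i] * t
                         + m.residual_sd * rng.standard_normal())
                rows.append((i, t, name, value))
        # counts: cumulative, non-decreasing
        kept_times = t_mri[keep_mri]
        for cname in ("lacune_count", "cmb_count"):
            count = int(base_counts[cname][i])
            prev_t = 0.0
            for j, t in enumerate(kept_times):
                if j > 0:
                    count += rng.poisson(yearly_rates[cname][i] * max(0.0, t - prev_t))
                prev_t = t
                rows.append((i, t, cname, float(count)))
        # cognition
        mcog = params.measures["global_cognition"]
        for t in t_cog[keep_cog]:
            value = (intercepts["global_cognition"][i]
                     + slopes["global_cognition"][i] * t
                     + mcog.residual_sd * rng.standard_normal())
            rows.append((i, t, "global_cognition", value))

    long = pd.DataFrame(rows, columns=["subject_id", "visit_time_years",
                                       "measure", "value"])
    subjects = pd.DataFrame({
        "subject_id": np.arange(n),
        "converted": converted.astype(int),
        "conversion_time_years": conv_time,
        "dropout_time_years": dropout,
    })
    truth = pd.DataFrame({
        "subject_id": np.arange(n),
        "p_convert": p_convert,
        **{f"{name}_intercept": intercepts[name] for name in params.measures},
        **{f"{name}_slope": slopes[name] for name in params.measures},
    })
    return CohortTable(long=long, subjects=subjects, truth=truth)


class CognitionIndex(NamedTuple):
    value: float
    n_missing: int


def global_cognition_index(task_z_scores) -> CognitionIndex:
    """Mean of the available age-scaled task z-scores for one visit.

    Missing tasks (NaN) are skipped and counted; all-missing input raises.
    """
    scores = np.asarray(task_z_scores, dtype=float).ravel()
    if scores.size == 0:
        raise ValueError("no task scores supplied")
    present = ~np.isnan(scores)
    if not present.any():
        raise ValueError("all task scores missing: index undefined")
    return CognitionIndex(value=float(scores[present].mean()),
                          n_missing=int((~present).sum()))
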