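"""Longitudinal change estimation: random-slope mixed models and related rules.

For each measure the model is ``value_it = (b0 + u0_i) + (b1 + u1_i) * t +
e_it`` with correlated subject random effects (u0, u1).  The fixed slope b1
is the group average annualized change; the per-subject quantities passed to
outcome and mediation models are the totals ``b0 + u0_i`` (baseline score)
and ``b1 + u1_i`` (annualized change), where the random effects are the
conditional modes (BLUPs) from the fit.

The default engine is the MixedLM facility of statsmodels; a two-stage
fallback (per-subject OLS followed by DerSimonian-Laird precision-weighted
pooling with empirical-Bayes shrinkage) is available both as an explicit
method and as the automatic fallback when the mixed model fails to converge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from svdnet.cohortsim import CohortTable, COGNITIVE_MEASURES

__all__ = [
    "LongitudinalModel",
    "LongitudinalResults",
    "CensorReport",
    "fit_lmer_slopes",
    "dichotomize_count_change",
    "censor_post_dementia",
]

logger = logging.getLogger(__name__)


@dataclass
class LongitudinalResults:
    """Fitted fixed effects, their test, and per-subject intercept/slope totals."""

    measure_name: str
    fixed_intercept: float
    fixed_slope: float
    fixed_slope_se: float
    fixed_slope_p: float
    df_satterthwaite: float
    subject_effects: pd.DataFrame  # subject_id, intercept, slope, n_visits, shrunk_only
    n_subjects: int
    n_observations: int
    method: str                    # "lmer" | "two_stage"
    converged: bool = True
    fallback_used: bool = False
    covariance_structure: str = "unstructured"  # "diagonal" after a refit

    @property
    def subject_slopes(self) -> pd.Series:
        return self.subject_effects.set_index("subject_id")["slope"]

    @property
    def subject_intercepts(self) -> pd.Series:
        return self.subject_effects.set_index("subject_id")["intercept"]

    def summary(self) -> str:
        lines = [
            f"Longitudinal random-slope fit: {self.measure_name}",
            f"  engine: {self.method}" + ("  (fallback)" if self.fallback_used else ""),
            f"  subjects: {self.n_subjects}   observations: {self.n_observations}",
            f"  fixed intercept: {self.fixed_intercept:.4f}",
            f"  fixed slope (per year): {self.fixed_slope:.4f}"
            f"  (SE {self.fixed_slope_se:.4f}, t-df {self.df_satterthwaite:.1f},"
            f" p {self.fixed_slope_p:.3g})",
            f"  subject slope range: [{self.subject_slopes.min():.4f},"
            f" {self.subject_slopes.max():.4f}]",
        ]
        return "\n".join(lines)


class LongitudinalModel:
    """Random intercept + random slope model of one measure over time.

    Parameters
    ----------
    data :
        Either a :class:`~svdnet.cohortsim.CohortTable` or a long DataFrame
        with columns ``subject_id``, ``visit_time_years``, ``measure``,
        ``value``.
    measure :
        Which measure to model.
    """

    def __init__(self, data: CohortTable | pd.DataFrame, measure: str):
        long = data.long if isinstance(data, CohortTable) else data
        df = long[long["measure"] == measure][
            ["subject_id", "visit_time_years", "value"]].dropna().copy()
        if df.empty:
            raise ValueError(f"no rows for measure {measure!r}")
        self.measure = measure
        self.df = df.rename(columns={"visit_time_years": "time"})
        counts = self.df.groupby("subject_id").size()
        if (counts >= 2).sum() == 0:
            raise ValueError("all subjects have a single visit: slope unidentifiable")

    # ------------------------------------------------------------------
    def fit(self, method: str = "lmer") -> LongitudinalResults:
        if method == "lmer":
            try:
                return self._fit_mixedlm()
            except Exception as exc:  # noqa: BLE001 - any optimizer failure
                logger.warning("MixedLM failed for %s (%s); refitting with "
                               "diagonal covariance", self.measure, exc)
            try:
                res = self._fit_mixedlm(diagonal=True)
                res.covariance_structure = "diagonal"
                return res
            except Exception as exc:  # noqa: BLE001
                logger.warning("diagonal MixedLM also failed for %s (%s); "
                               "using two-stage fallback", self.measure, exc)
                res = self._fit_two_stage()
                res.fallback_used = True
                return res
        if method == "two_stage":
            return self._fit_two_stage()
        raise ValueError(f"unknown method {method!r}")

    # ------------------------------------------------------------------
    def _fit_mixedlm(self, diagonal: bool = False) -> LongitudinalResults:
        df = self.df
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("value ~ time", df, groups=df["subject_id"],
                                re_formula="~time")
            fit_kwargs = {}
            if diagonal:
                from statsmodels.regression.mixed_linear_model import MixedLMParams
                fit_kwargs["free"] = MixedLMParams.from_components(
                    fe_params=np.ones(2), cov_re=np.eye(2))
            fit = model.fit(reml=True, method="powell", **fit_kwargs)
        if not fit.converged:
            raise RuntimeError("MixedLM did not converge")
        b0 = float(fit.params["Intercept"])
        b1 = float(fit.params["time"])
        se1 = float(fit.bse["time"])
        # Satterthwaite-style df for the time slope: in a random-slope model
        # the slope information is dominated by between-subject variation, so
        # the between-subject df (n_subjects - 1) is used as the approximation.
        n_subj = df["subject_id"].nunique()
        dof = float(n_subj - 1)
        tval = b1 / se1
        pval = float(2 * stats.t.sf(abs(tval), dof))

        counts = df.groupby("subject_id").size()
        re = fit.random_effects
        recs = []
        for sid, eff in re.items():
            u0 = float(eff.iloc[0])
            u1 = float(eff.iloc[1]) if len(eff) > 1 else 0.0
            recs.append((sid, b0 + u0, b1 + u1, int(counts[sid]),
                         bool(counts[sid] < 2)))
        subject_effects = pd.DataFrame(
            recs, columns=["subject_id", "intercept", "slope", "n_visits",
                           "shrunk_only"]).sort_values("subject_id",
                                                       ignore_index=True)
        return LongitudinalResults(
            measure_name=self.measure, fixed_intercept=b0, fixed_slope=b1,
            fixed_slope_se=se1, fixed_slope_p=pval, df_satterthwaite=dof,
            subject_effects=subject_effects, n_subjects=n_subj,
            n_observations=len(df), method="lmer", converged=True)

    # ------------------------------------------------------------------
    def _fit_two_stage(self) -> LongitudinalResults:
        """Per-subject OLS + DerSimonian-Laird pooling + EB shrinkage."""
        df = self.df
        slopes, variances, inters, sids, nvis = [], [], [], [], []
        singles = []
        for sid, g in df.groupby("subject_id"):
            t = g["time"].to_numpy()
            y = g["value"].to_numpy()
            if len(g) < 2 or np.ptp(t) == 0:
                singles.append((sid, y.mean(), len(g)))
                continue
            X = np.column_stack([np.ones_like(t), t])
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            dof = len(t) - 2
            if dof > 0 and res.size:
                s2 = float(res[0]) / dof
            else:
                s2 = 0.0
            sxx = float(((t - t.mean()) ** 2).sum())
            slopes.append(float(beta[1]))
            variances.append(s2 / sxx if sxx > 0 else np.inf)
            inters.append(float(beta[0]))
            sids.append(sid)
            nvis.append(len(g))
        slopes = np.array(slopes)
        variances = np.array(variances)
        # DerSimonian-Laird between-subject variance
        w = 1.0 / np.maximum(variances, 1e-12)
        mu_fixed_w = np.sum(w * slopes) / np.sum(w)
        q = np.sum(w * (slopes - mu_fixed_w) ** 2)
        k = len(slopes)
        c = np.sum(w) - np.sum(w ** 2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
        w_star = 1.0 / (variances + tau2)
        b1 = float(np.sum(w_star * slopes) / np.sum(w_star))
        se1 = float(np.sqrt(1.0 / np.sum(w_star)))
        b0 = float(np.mean(inters))
        dof = float(k - 1)
        pval = float(2 * stats.t.sf(abs(b1 / se1), dof))
        # empirical-Bayes shrinkage of subject slopes toward the pooled mean
        v = np.maximum(variances, 1e-12)
        if tau2 > 0:
            shrunk = (slopes / v + b1 / tau2) / (1 / v + 1 / tau2)
        else:
            # no between-subject heterogeneity beyond sampling noise: noisy
            # subject slopes pool completely; exact (zero-variance) ones stay
            shrunk = np.where(variances <= 1e-12, slopes, b1)
        recs = [(sid, it, sl, nv, False)
                for sid, it, sl, nv in zip(sids, inters, shrunk, nvis)]
        recs += [(sid, b0, b1, nv, True) for sid, _, nv in singles]
        subject_effects = pd.DataFrame(
            recs, columns=["subject_id", "intercept", "slope", "n_visits",
                           "shrunk_only"]).sort_values("subject_id",
                                                       ignore_index=True)
        return LongitudinalResults(
            measure_name=self.measure, fixed_intercept=b0, fixed_slope=b1,
            fixed_slope_se=se1, fixed_slope_p=pval, df_satterthwaite=dof,
            subject_effects=subject_effects,
            n_subjects=df["subject_id"].nunique(),
            n_observations=len(df), method="two_stage", converged=True)


def fit_lmer_slopes(cohort: CohortTable | pd.DataFrame, measure: str,
                    method: str = "lmer") -> LongitudinalResults:
    """Functional wrapper: fit the random-slope model for one measure."""
    return LongitudinalModel(cohort, measure).fit(method=method)


# ---------------------------------------------------------------------------
# count change and censoring
# ---------------------------------------------------------------------------

def dichotomize_count_change(counts_by_visit) -> int:
    """1 if the final count exceeds baseline (any new lesion), else 0.

    Count sequences should be non-decreasing; a decrease is reported as a
    data-quality warning and scored 0.
    """
    counts = np.asarray(counts_by_visit, dtype=float)
    if counts.size < 2:
        raise ValueError("need counts from at least 2 visits")
    if np.any(np.diff(counts) < 0):
        warnings.warn("decreasing lesion counts: lesions should not vanish",
                      stacklevel=2)
        if counts[-1] <= counts[0]:
            return 0
    return int(counts[-1] > counts[0])


@dataclass
class CensorReport:
    n_subjects_affected: int
    n_observations_removed: int
    removed_rows: pd.DataFrame = field(repr=False, default=None)


def censor_post_dementia(cohort: CohortTable) -> tuple[CohortTable, CensorReport]:
    """Drop MRI-measure rows acquired after conversion to dementia.

    Cognitive rows are retained regardless of conversion.  Returns the
    censored table and a report of how many subjects/observations were
    removed (one "observation" = one post-conversion MRI visit).
    """
    subj = cohort.subjects.set_index("subject_id")
    conv_time = subj["conversion_time_years"]
    long = cohort.long
    is_mri = ~long["measure"].isin(COGNITIVE_MEASURES)
    ct = long["subject_id"].map(conv_time)
    drop = is_mri & ct.notna() & (long["visit_time_years"] > ct)
    removed = long[drop]
    n_visits_removed = (removed.groupby(["subject_id", "visit_time_years"])
                        .ngroups if not removed.empty else 0)
    n_subjects = removed["subject_id"].nunique()
    logger.info("censor_post_dementia: removed %d MRI observations from %d subjects",
                n_visits_removed, n_subjects)
    new = CohortTable(long=long[~drop].reset_index(drop=True),
                      subjects=cohort.subjects.copy(),
                      truth=cohort.truth.copy() if cohort.truth is not None else None)
    return new, CensorReport(n_subjects_affected=int(n_subjects),
                             n_observations_removed=int(n_visits_removed),
                             removed_rows=removed.reset_index(drop=True))
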