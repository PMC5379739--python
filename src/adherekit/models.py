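"""Landmark outcome derivation and adherence→outcome prediction models.

Virological failure is a single HIV-RNA above the landmark threshold
(>400 copies/ml at week 16, >40 at week 48); genotypic resistance is the
presence of at least one major mutation conferring resistance to a drug in
the participant's regimen, assessable only on samples above the
amplification threshold (>500 copies/ml).

The modelling object follows the statsmodels convention: an
:class:`AdherenceOutcomeModel` is built from data (or a DataFrame via
``from_dataframe``) and its ``fit()`` returns an
:class:`AdherenceOutcomeResults` carrying the per-10% odds ratio with Wald
95% CI and p-value, fitted probabilities, and the ROC/AUC of the fit.
Maximum likelihood is the default; complete separation (common with few
resistance events) triggers a Firth-type penalised fit, flagged on the
results.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
import statsmodels.api as sm

from .config import AnalysisConfig
from .io import METHODS, Cohort
from .measures import select_landmark_vl, tdm_features
from .roc import AucResult, roc_auc

log = logging.getLogger(__name__)

FAILURE = "failure"
RESISTANCE = "resistance"
OUTCOMES = (FAILURE, RESISTANCE)

COVARIATE_COLUMNS = ("age_years", "baseline_cd4", "baseline_log10_vl")

#: major-mutation catalogue: mutation code -> drugs it compromises.  The
#: table is user-supplied config in real analyses; this default covers the
#: common first-line NRTI/NNRTI mutations.
DEFAULT_MAJOR_MUTATION_TABLE: Mapping[str, frozenset[str]] = {
    "K65R": frozenset({"tenofovir"}),
    "M184V": frozenset({"lamivudine", "emtricitabine"}),
    "M184I": frozenset({"lamivudine", "emtricitabine"}),
    "L100I": frozenset({"efavirenz", "nevirapine"}),
    "K101E": frozenset({"efavirenz", "nevirapine"}),
    "K103N": frozenset({"efavirenz", "nevirapine"}),
    "V106M": frozenset({"efavirenz", "nevirapine"}),
    "Y181C": frozenset({"efavirenz", "nevirapine"}),
    "Y188C": frozenset({"efavirenz", "nevirapine"}),
    "Y188L": frozenset({"efavirenz", "nevirapine"}),
    "G190A": frozenset({"efavirenz", "nevirapine"}),
    "G190S": frozenset({"efavirenz", "nevirapine"}),
    "H221Y": frozenset({"efavirenz", "nevirapine"}),
    "F227L": frozenset({"efavirenz", "nevirapine"}),
}

DEFAULT_REGIMEN = frozenset({"tenofovir", "lamivudine", "efavirenz"})


@dataclass(frozen=True)
class ResistanceRule:
    """Classifies a mutation list as resistant for a given regimen."""

    major_mutation_table: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_MAJOR_MUTATION_TABLE))
    regimen: frozenset[str] = DEFAULT_REGIMEN

    def is_resistant(self, mutations: Iterable[str]) -> bool:
        for mut in mutations:
            affected = self.major_mutation_table.get(mut)
            if affected and affected & self.regimen:
                return True
        return False


def derive_outcomes(
    cohort: Cohort,
    landmark: str,
    config: AnalysisConfig | None = None,
    rule: ResistanceRule | None = None,
) -> pd.DataFrame:
    """One outcome row per per-protocol participant at the landmark.

    Columns: participant_id, landmark, vl_date, vl_copies_per_ml, failed,
    genotype_eligible (VL above amplification threshold), amplified,
    resistant, plus the baseline covariates.  ``resistant`` is pandas NA when
    a genotype was eligible but did not amplify (dropped from resistance
    models); participants who did not fail, or failed below the
    amplification threshold, count as not resistant (no detectable major
    mutation).
    """
    config = config or AnalysisConfig()
    rule = rule or ResistanceRule()
    spec = config.landmark(landmark)
    rows = []
    genotypes = cohort.genotypes
    for _, prow in cohort.participants.iterrows():
        pid = prow["participant_id"]
        window = select_landmark_vl(
            cohort.for_participant("labs", pid), prow["randomisation_date"], spec)
        if window is None:
            continue
        vl = window.vl_value
        failed = vl > spec.failure_threshold
        eligible = vl > config.genotype_vl_threshold
        geno = genotypes[
            (genotypes["participant_id"] == pid)
            & (genotypes["sample_date"] >= window.randomisation_date
               + pd.Timedelta(days=spec.window_start_day))
            & (genotypes["sample_date"] <= window.randomisation_date
               + pd.Timedelta(days=spec.window_end_day))
        ]
        amplified = bool(geno["amplified"].any()) if len(geno) else False
        if not failed:
            resistant: object = False
        elif amplified:
            muts = [m for lst in geno.loc[geno["amplified"], "mutations"] for m in lst]
            resistant = rule.is_resistant(muts)
        elif eligible:
            resistant = pd.NA  # eligible but not amplified: unknown
        else:
            resistant = False  # below amplification threshold: undetectable
        rows.append({
            "participant_id": pid,
            "landmark": landmark,
            "vl_date": window.vl_date,
            "vl_copies_per_ml": vl,
            "failed": failed,
            "genotype_eligible": eligible,
            "amplified": amplified,
            "resistant": resistant,
            "age_years": prow["age_years"],
            "baseline_cd4": prow["baseline_cd4"],
            "baseline_log10_vl": prow["baseline_log10_vl"],
        })
    # genotype records inside this landmark's window whose participant has no
    # qualifying lab are unusable: warn, resistance stays absent
    included = {r["participant_id"] for r in rows}
    rand_map = cohort.participants.set_index("participant_id")["randomisation_date"]
    for pid in sorted(set(genotypes["participant_id"]) - included):
        if pid not in rand_map.index:
            continue
        offs = (genotypes.loc[genotypes["participant_id"] == pid, "sample_date"]
                - rand_map[pid]).dt.days
        if ((offs >= spec.window_start_day) & (offs <= spec.window_end_day)).any():
            log.warning("genotype record without in-window lab for %s; "
                        "resistance absent", pid)
    return pd.DataFrame(rows, columns=[
        "participant_id", "landmark", "vl_date", "vl_copies_per_ml", "failed",
        "genotype_eligible", "amplified", "resistant",
        *COVARIATE_COLUMNS]) if rows else pd.DataFrame(columns=[
            "participant_id", "landmark", "vl_date", "vl_copies_per_ml", "failed",
            "genotype_eligible", "amplified", "resistant", *COVARIATE_COLUMNS])


# ---------------------------------------------------------------------------
# Logistic modelling


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 200,
                 tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Firth-penalised logistic regression (Jeffreys-prior score correction).

    Newton iterations on the modified score U*(b) = X'(y - p + h(1/2 - p)),
    h the hat-diagonal of the weighted design.  Returns (beta, covariance);
    the covariance is the inverse observed information at convergence.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        p = expit(X @ beta)
        w = np.clip(p * (1 - p), 1e-12, None)
        XW = X * w[:, None]
        info = X.T @ XW
        info_inv = np.linalg.pinv(info)
        h = w * np.einsum("ij,jk,ik->i", X, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        # step-halving keeps the iteration stable with sparse events
        while np.abs(step).max() > 5.0:
            step *= 0.5
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    p = expit(X @ beta)
    w = np.clip(p * (1 - p), 1e-12, None)
    cov = np.linalg.pinv(X.T @ (X * w[:, None]))
    return beta, cov


@dataclass
class AdherenceOutcomeResults:
    """Fit results: per-10% odds ratio, Wald inference, ROC/AUC."""

    model: "AdherenceOutcomeModel"
    params: pd.Series
    cov_params: pd.DataFrame
    method: str  # "mle" or "firth"
    converged: bool
    flags: list[str] = field(default_factory=list)

    # -- inference ---------------------------------------------------------
    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({
            "lower": self.params - z * self.bse,
            "upper": self.params + z * self.bse,
        })

    # -- adherence effect on the odds scale --------------------------------
    @property
    def adherence_coef(self) -> float:
        return float(self.params[self.model.adherence_name])

    @property
    def or_per_unit(self) -> float:
        """OR per one unit of the scaled predictor (10% adherence, or 1 log
        for drug-concentration models)."""
        return float(np.exp(self.adherence_coef))

    def or_conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        ci = self.conf_int(alpha).loc[self.model.adherence_name]
        return float(np.exp(ci["lower"])), float(np.exp(ci["upper"]))

    @property
    def or_p_value(self) -> float:
        return float(self.pvalues[self.model.adherence_name])

    # -- prediction --------------------------------------------------------
    @property
    def fitted_probabilities(self) -> np.ndarray:
        return expit(self.model.exog @ self.params.to_numpy())

    def auc(self) -> AucResult | None:
        """ROC AUC of the fitted probabilities against the outcome.

        Fitted probabilities orient the curve automatically: for a
        univariate model they are a monotone transform of the predictor, so
        this equals the (sign-oriented) AUC of the raw adherence values.
        """
        return roc_auc(self.fitted_probabilities, self.model.endog)

    def summary(self) -> str:
        res = self.auc()
        lo, hi = self.or_conf_int()
        lines = [
            f"Adherence outcome model [{self.model.name}]",
            f"  estimation: {self.method}" + ("" if self.converged else " (NOT converged)"),
            f"  n = {self.model.nobs}, events = {self.model.n_events}",
            f"  OR per {self.model.scale:g}-unit increase: "
            f"{self.or_per_unit:.3f} (95% CI {lo:.3f}-{hi:.3f}), p = {self.or_p_value:.4g}",
        ]
        if res is not None:
            lines.append(
                f"  AUC = {res.auc:.3f} (95% CI {res.ci_lower:.3f}-{res.ci_upper:.3f})")
        if self.flags:
            lines.append("  flags: " + ", ".join(self.flags))
        header = "=" * 60
        return "\n".join([header, *lines, header])


class AdherenceOutcomeModel:
    """Logistic model of a binary landmark outcome on one adherence measure.

    Parameters
    ----------
    endog : binary outcome vector (virological failure or resistance)
    adherence : adherence values in percent (or log10 mg/L for TDM)
    covariates : optional DataFrame of adjustment variables (the adjusted
        model adds age, baseline CD4 and baseline log10 HIV-RNA)
    scale : predictor divisor; 10.0 reports the odds ratio per 10%
        adherence increase (use 1.0 for a per-1-log concentration OR)
    """

    def __init__(self, endog, adherence, covariates: pd.DataFrame | None = None,
                 scale: float = 10.0, name: str = "adherence",
                 adherence_name: str = "adherence_per_scale"):
        y = np.asarray(endog).astype(float)
        x = np.asarray(adherence, dtype=float)
        if y.shape != x.shape:
            raise ValueError("endog and adherence must have equal length")
        cols = {"const": np.ones_like(x), adherence_name: x / scale}
        if covariates is not None:
            for col in covariates.columns:
                cols[col] = np.asarray(covariates[col], dtype=float)
        exog = pd.DataFrame(cols)
        mask = ~(np.isnan(y) | exog.isna().any(axis=1).to_numpy())
        self.endog = y[mask].astype(int)
        self.exog_frame = exog[mask].reset_index(drop=True)
        self.exog = self.exog_frame.to_numpy()
        self.scale = scale
        self.name = name
        self.adherence_name = adherence_name
        self.n_dropped = int((~mask).sum())

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome_col: str,
                       adherence_col: str,
                       covariate_cols: Sequence[str] = (),
                       scale: float = 10.0,
                       name: str | None = None) -> "AdherenceOutcomeModel":
        covs = data[list(covariate_cols)] if covariate_cols else None
        return cls(data[outcome_col], data[adherence_col], covariates=covs,
                   scale=scale, name=name or adherence_col)

    @property
    def nobs(self) -> int:
        return len(self.endog)

    @property
    def n_events(self) -> int:
        return int(self.endog.sum())

    def _degenerate(self) -> list[str]:
        flags = []
        if self.n_events == 0 or self.n_events == self.nobs:
            flags.append("single_outcome_class")
        if np.ptp(self.exog_frame[self.adherence_name].to_numpy()) == 0:
            flags.append("constant_predictor")
        return flags

    def fit(self, method: str = "auto") -> AdherenceOutcomeResults | None:
        """Maximum-likelihood fit; Firth fallback on (near-)separation.

        ``method`` may be "auto" (MLE, penalised on separation), "mle" or
        "firth".  Returns None when the outcome has a single class or the
        adherence predictor is constant (degenerate model, logged).
        """
        degenerate = self._degenerate()
        if degenerate:
            log.warning("model %s not fitted: %s", self.name, degenerate)
            return None
        names = list(self.exog_frame.columns)
        if method in ("auto", "mle"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = sm.Logit(self.endog, self.exog).fit(disp=0, maxiter=200)
                    converged = bool(res.mle_retvals.get("converged", False))
                    separated = (not converged
                                 or not np.isfinite(res.bse).all()
                                 or np.abs(res.params).max() > 15
                                 or np.max(res.bse) > 50)
                except Exception:
                    separated = True
                    res = None
            if res is not None and not separated:
                return AdherenceOutcomeResults(
                    model=self,
                    params=pd.Series(res.params, index=names),
                    cov_params=pd.DataFrame(res.cov_params(), index=names, columns=names),
                    method="mle", converged=True)
            if method == "mle":
                flags = ["separation_unresolved"]
                if res is None:
                    return None
                return AdherenceOutcomeResults(
                    model=self, params=pd.Series(res.params, index=names),
                    cov_params=pd.DataFrame(res.cov_params(), index=names, columns=names),
                    method="mle", converged=False, flags=flags)
        beta, cov = _firth_logit(self.exog, self.endog.astype(float))
        flags = ["penalized_fallback"] if method == "auto" else []
        return AdherenceOutcomeResults(
            model=self, params=pd.Series(beta, index=names),
            cov_params=pd.DataFrame(cov, index=names, columns=names),
            method="firth", converged=True, flags=flags)


def fit_logistic(y, adherence, covariates: pd.DataFrame | None = None,
                 scale: float = 10.0) -> AdherenceOutcomeResults | None:
    """Functional wrapper: fit a (possibly adjusted) logistic model and
    return the results object (None for degenerate inputs)."""
    return AdherenceOutcomeModel(y, adherence, covariates=covariates, scale=scale).fit()


# ---------------------------------------------------------------------------
# Full report (method x landmark x outcome grid)

REPORT_COLUMNS = (
    "method", "landmark", "outcome", "n", "events",
    "or", "or_lcl", "or_ucl", "p",
    "aor", "aor_lcl", "aor_ucl", "ap",
    "auc", "auc_lcl", "auc_ucl", "flags",
)


def _model_frame(estimates: pd.DataFrame, outcomes: pd.DataFrame,
                 method: str, outcome: str,
                 config: AnalysisConfig) -> pd.DataFrame | None:
    est = estimates[estimates["method"] == method][["participant_id", "value"]]
    if est.empty:
        return None
    data = outcomes.merge(est, on="participant_id", how="inner")
    if outcome == FAILURE:
        data["y"] = data["failed"].astype(float)
    else:
        data = data[data["resistant"].notna()].copy()
        data["y"] = data["resistant"].astype(float)
    if data.empty:
        return None
    if method == "TDM":
        floor = config.efv_log_floor_mg_per_l
        data["predictor"] = [
            tdm_features(v, floor)["log10_value"] for v in data["value"]]
    else:
        data["predictor"] = data["value"]
    return data


def build_table3(
    estimates: pd.DataFrame,
    outcomes: pd.DataFrame,
    config: AnalysisConfig | None = None,
    small_sample_events: int = 5,
) -> tuple[pd.DataFrame, dict[tuple[str, str, str], AucResult]]:
    """Univariate and adjusted per-10% ORs plus AUC for every model cell.

    ``estimates`` and ``outcomes`` may span one or both landmarks; the grid
    is method x landmark x outcome (failure / resistance).  TDM rows use the
    log10 concentration as predictor (OR per 1-log increase); all other
    methods report the OR per 10% adherence increase.  Complete-case per
    method: a participant missing one measure is dropped from that measure's
    models only.  Cells with a single outcome class are left absent and
    logged.  Returns (report frame, ROC results per fitted univariate cell).
    """
    config = config or AnalysisConfig()
    rows = []
    rocs: dict[tuple[str, str, str], AucResult] = {}
    landmarks = sorted(set(outcomes["landmark"])) if len(outcomes) else []
    for landmark in landmarks:
        out_lm = outcomes[outcomes["landmark"] == landmark]
        est_lm = estimates[estimates["landmark"] == landmark]
        for method in METHODS:
            scale = 1.0 if method == "TDM" else 10.0
            for outcome in OUTCOMES:
                data = _model_frame(est_lm, out_lm, method, outcome, config)
                row = {"method": method, "landmark": landmark, "outcome": outcome}
                if data is None or data.empty:
                    rows.append({**row, "flags": "no_data"})
                    continue
                flags = []
                n, events = len(data), int(data["y"].sum())
                row.update(n=n, events=events)
                if 0 < events < small_sample_events or 0 < n - events < small_sample_events:
                    flags.append("small_sample")
                uni = AdherenceOutcomeModel(
                    data["y"], data["predictor"], scale=scale,
                    name=f"{method}/{landmark}/{outcome}").fit()
                if uni is None:
                    rows.append({**row, "flags": ";".join(flags + ["degenerate"])})
                    continue
                lo, hi = uni.or_conf_int()
                row.update({"or": uni.or_per_unit, "or_lcl": lo, "or_ucl": hi,
                            "p": uni.or_p_value})
                flags.extend(uni.flags)
                auc_res = uni.auc()
                if auc_res is not None:
                    row.update(auc=auc_res.auc, auc_lcl=auc_res.ci_lower,
                               auc_ucl=auc_res.ci_upper)
                    rocs[(method, landmark, outcome)] = auc_res
                adj = AdherenceOutcomeModel(
                    data["y"], data["predictor"],
                    covariates=data[list(COVARIATE_COLUMNS)], scale=scale,
                    name=f"{method}/{landmark}/{outcome}/adjusted").fit()
                if adj is not None:
                    alo, ahi = adj.or_conf_int()
                    row.update({"aor": adj.or_per_unit, "aor_lcl": alo,
                                "aor_ucl": ahi, "ap": adj.or_p_value})
                    flags.extend(f"adjusted_{f}" for f in adj.flags)
                row["flags"] = ";".join(flags)
                rows.append(row)
    report = pd.DataFrame(rows)
    for col in REPORT_COLUMNS:
        if col not in report.columns:
            report[col] = np.nan
    return report[list(REPORT_COLUMNS)], rocs
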