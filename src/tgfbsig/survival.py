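"""Risk-score survival evaluation of a gene signature.

Patients are scored by the mean expression of the signature genes
(CLIC1, MAPRE1 and SERPINA3 in the original study), stratified into a
high-risk top quantile versus the remainder, and the groups are compared
by Kaplan-Meier curves with a log-rank test and by uni-/multivariate Cox
proportional-hazards models.  The module also computes Pearson
correlations of signature genes with a reference regulator (TGFB1).

The fitting machinery is lifelines (Kaplan-Meier product-limit,
two-group log-rank, Cox partial likelihood with Efron tie handling);
this module owns the scoring, stratification and reporting surface.

A statsmodels-style pairing :class:`SignatureSurvivalModel` /
:class:`SignatureSurvivalResults` wraps the whole evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

#: Table-3-style dichotomies of the clinical covariates
CLINICAL_CODINGS = {
    "stage_high": "stage 0-1 vs 2-4",
    "post_menopause": "menopause pre vs post",
    "grade_3": "tumor grade 1-2 vs 3",
    "size_ge_31mm": "tumor size <31 mm vs >=31 mm",
}


def encode_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Binary clinical covariates from raw codings.

    Expects columns ``stage`` (0-4), ``menopause`` (pre/post), ``grade``
    (1-3), ``size_mm`` (positive real); returns the four 0/1 columns
    named in :data:`CLINICAL_CODINGS`.
    """
    out = pd.DataFrame(index=df.index)
    out["stage_high"] = (df["stage"] >= 2).astype(int)
    out["post_menopause"] = (df["menopause"].astype(str) == "post").astype(int)
    out["grade_3"] = (df["grade"] >= 3).astype(int)
    out["size_ge_31mm"] = (df["size_mm"] >= 31).astype(int)
    return out


# ---------------------------------------------------------------------------
# scoring and stratification
# ---------------------------------------------------------------------------

def risk_score(expression: pd.DataFrame, signature_genes: Sequence[str],
               standardize: bool = True) -> pd.Series:
    """Per-patient mean expression of the signature genes.

    With ``standardize`` (default) each gene is z-scored across patients
    before averaging, so genes on different scales contribute equally;
    the unstandardized literal mean is available with ``standardize=False``.
    """
    missing = [g for g in signature_genes if g not in expression.columns]
    if missing:
        raise KeyError(f"signature gene(s) not in expression table: {missing}")
    sub = expression[list(signature_genes)].astype(float)
    if standardize:
        sd = sub.std(axis=0, ddof=1)
        zero = sd[sd == 0].index.tolist()
        if zero:
            raise ValueError(f"zero variance in gene(s): {zero}; cannot standardize")
        sub = (sub - sub.mean(axis=0)) / sd
    score = sub.mean(axis=1)
    score.name = "risk_score"
    return score


@dataclass
class RiskStratification:
    """High/low risk partition of a cohort by score quantile."""

    scores: pd.Series
    labels: pd.Series          # "high" / "low", same index as scores
    threshold: float           # smallest score labelled high
    high_fraction: float

    @property
    def n_high(self) -> int:
        return int((self.labels == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == "low").sum())


def stratify(scores: pd.Series, high_fraction: float = 0.25) -> RiskStratification:
    """Top-``high_fraction`` of scores labelled high risk, rest low.

    Exactly ``ceil(high_fraction * N)`` patients are labelled high; ties
    at the threshold are broken by cohort order (first occurrence wins),
    recorded via the returned threshold.
    """
    scores = pd.Series(scores).astype(float)
    n = len(scores)
    if n < 4:
        raise ValueError("need at least 4 patients to stratify")
    if not 0 < high_fraction < 1:
        raise ValueError("high_fraction must lie in (0, 1)")
    vals = scores.to_numpy()
    if np.all(vals == vals[0]):
        raise ValueError("all risk scores identical; no quantile split exists")
    n_high = math.ceil(high_fraction * n)
    order = np.lexsort((np.arange(n), -vals))   # stable: score desc, then position
    labels = pd.Series("low", index=scores.index, name="risk_group")
    labels.iloc[order[:n_high]] = "high"
    threshold = float(vals[order[n_high - 1]])
    return RiskStratification(scores=scores, labels=labels, threshold=threshold,
                              high_fraction=high_fraction)


# ---------------------------------------------------------------------------
# survival estimation
# ---------------------------------------------------------------------------

def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve.

    Returns a frame indexed by time with columns ``survival`` and
    ``at_risk``; censored subjects leave the risk set after their time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("negative follow-up time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    out = pd.DataFrame({"survival": surv, "at_risk": at_risk})
    out.index.name = "time"
    return out


def km_by_group(times, events, groups) -> dict[str, pd.DataFrame]:
    df = pd.DataFrame({"time": np.asarray(times, dtype=float),
                       "event": np.asarray(events, dtype=int),
                       "group": np.asarray(groups)})
    return {str(g): km_estimate(sub["time"], sub["event"])
            for g, sub in df.groupby("group", sort=True)}


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    pvalue: float


def logrank_test(times, events, groups) -> LogrankResult:
    """Two-group log-rank test (chi-square, 1 df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {len(levels)}")
    if events.sum() == 0:
        raise ValueError("no events observed; log-rank undefined")
    a = groups == levels[0]
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    return LogrankResult(statistic=float(res.test_statistic),
                         pvalue=float(res.p_value))


def cox_fit(data: pd.DataFrame, covariates: Sequence[str],
            duration_col: str = "time", event_col: str = "event",
            univariate: bool = False, ties: str = "efron") -> pd.DataFrame:
    """Cox proportional-hazards fit.

    ``univariate=True`` fits each covariate in its own model; otherwise
    all covariates enter one multivariate model.  Returns one row per
    covariate with ``beta``, ``HR``, 95% CI bounds and the Wald p-value.
    Ties are handled by Efron's method (the lifelines default and only
    implementation).
    """
    if ties != "efron":
        raise NotImplementedError(
            "only Efron tie handling is available; Breslow is not implemented")
    covariates = list(covariates)
    for c in covariates:
        col = data[c].to_numpy()
        if not np.all(np.isfinite(col.astype(float))):
            raise ValueError(f"non-finite values in covariate {c!r}")
        if np.all(col == col[0]):
            raise ValueError(f"covariate {c!r} is constant across subjects")
    rows = []
    groups_of = [[c] for c in covariates] if univariate else [covariates]
    for cols in groups_of:
        cph = CoxPHFitter(penalizer=0.0)
        cph.fit(data[[duration_col, event_col, *cols]],
                duration_col=duration_col, event_col=event_col)
        s = cph.summary
        for c in cols:
            rows.append({
                "covariate": c,
                "beta": float(s.loc[c, "coef"]),
                "HR": float(s.loc[c, "exp(coef)"]),
                "ci_lower": float(s.loc[c, "exp(coef) lower 95%"]),
                "ci_upper": float(s.loc[c, "exp(coef) upper 95%"]),
                "p": float(s.loc[c, "p"]),
            })
    return pd.DataFrame(rows).set_index("covariate")


def tgfb_correlation(expression: pd.DataFrame, genes: Sequence[str],
                     reference_gene: str = "TGFB1") -> pd.DataFrame:
    """Pearson correlation of each gene with the reference regulator."""
    if reference_gene not in expression.columns:
        raise KeyError(f"reference gene {reference_gene!r} not in expression table")
    ref = expression[reference_gene].astype(float).to_numpy()
    if len(ref) < 3:
        raise ValueError("need at least 3 samples for a correlation")
    rows = []
    for g in genes:
        x = expression[g].astype(float).to_numpy()
        if np.std(x) == 0 or np.std(ref) == 0:
            rows.append({"gene": g, "r": np.nan, "p": np.nan, "degenerate": True})
            continue
        r, p = stats.pearsonr(x, ref)
        rows.append({"gene": g, "r": float(r), "p": float(p), "degenerate": False})
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------

class SignatureSurvivalModel:
    """Signature risk-score prognosis model on one cohort.

    Parameters
    ----------
    data : DataFrame with per-patient gene expression, follow-up ``time``
        (years), ``event`` flag, and (optionally) clinical covariates.
    genes : signature genes averaged into the risk score.
    covariates : binary clinical covariate columns entering the
        multivariate Cox model alongside the risk group (default: stage
        dichotomy only, mirroring the fitted rows of the original
        multivariate table).
    """

    def __init__(self, data: pd.DataFrame, genes: Sequence[str],
                 time_col: str = "time", event_col: str = "event",
                 covariates: Sequence[str] = ("stage_high",),
                 standardize: bool = True):
        self.data = data
        self.genes = list(genes)
        self.time_col = time_col
        self.event_col = event_col
        self.covariates = [c for c in covariates if c in data.columns]
        self.standardize = standardize

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, genes: Sequence[str],
                       encode_covariates: bool = True, **kwargs
                       ) -> "SignatureSurvivalModel":
        """Build from a raw cohort table, deriving the binary clinical
        covariates from raw codings when present."""
        if encode_covariates and "stage" in data.columns:
            data = pd.concat([data, encode_clinical(data)], axis=1)
            kwargs.setdefault("covariates",
                              ("stage_high", "post_menopause", "grade_3",
                               "size_ge_31mm"))
        return cls(data, genes, **kwargs)

    def fit(self, high_fraction: float = 0.25) -> "SignatureSurvivalResults":
        scores = risk_score(self.data, self.genes, standardize=self.standardize)
        strat = stratify(scores, high_fraction=high_fraction)
        times = self.data[self.time_col]
        events = self.data[self.event_col]
        km = km_by_group(times, events, strat.labels)
        lr = logrank_test(times, events, strat.labels)

        fit_df = pd.DataFrame({
            "time": times.astype(float),
            "event": events.astype(int),
            "risk_high": (strat.labels == "high").astype(int),
        })
        for c in self.covariates:
            fit_df[c] = self.data[c].astype(float)
        uni = cox_fit(fit_df, ["risk_high", *self.covariates], univariate=True)
        multi = cox_fit(fit_df, ["risk_high", *self.covariates], univariate=False)
        return SignatureSurvivalResults(model=self, stratification=strat,
                                        km_curves=km, logrank=lr,
                                        cox_univariate=uni, cox_multivariate=multi)


@dataclass
class SignatureSurvivalResults:
    """Fitted prognosis evaluation: KM curves, log-rank, Cox tables."""

    model: SignatureSurvivalModel
    stratification: RiskStratification
    km_curves: dict[str, pd.DataFrame]
    logrank: LogrankResult
    cox_univariate: pd.DataFrame
    cox_multivariate: pd.DataFrame

    @property
    def hazard_ratio(self) -> float:
        """Univariate HR of high- vs low-risk group."""
        return float(self.cox_univariate.loc["risk_high", "HR"])

    def summary(self) -> str:
        s = self.stratification
        lines = [
            "Signature survival evaluation",
            f"  genes: {', '.join(self.model.genes)}",
            f"  patients: {len(s.scores)} (high {s.n_high} / low {s.n_low}, "
            f"threshold {s.threshold:.4f})",
            f"  log-rank: chi2 = {self.logrank.statistic:.4f}, "
            f"p = {self.logrank.pvalue:.4g}",
            "  univariate Cox:",
        ]
        for name, tbl in (("", self.cox_univariate),
                          ("  multivariate Cox:", self.cox_multivariate)):
            if name:
                lines.append(name)
            for cov, row in tbl.iterrows():
                lines.append(
                    f"    {cov:<14} beta={row['beta']:+.4f}  HR={row['HR']:.4f} "
                    f"(95% CI {row['ci_lower']:.4f}-{row['ci_upper']:.4f})  "
                    f"p={row['p']:.4g}")
        return "\n".join(lines)

    def plot_km(self, ax=None):
        """Kaplan-Meier curves of the two risk groups."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for group, curve in sorted(self.km_curves.items()):
            ax.step(curve.index, curve["survival"], where="post",
                    label=f"{group} (n={int(curve['at_risk'].iloc[0])})")
        ax.set_xlabel("time (years)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
        ax.legend()
        ax.set_title(f"log-rank p = {self.logrank.pvalue:.4g}")
        return ax
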