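"""Validation statistics for the chemosensitivity predictor.

Covers the clinical-validation battery: one-sided rank-sum comparison
of scores between responders and non-responders, correlation of score
with ordinal response, Kaplan–Meier survival with median confidence
intervals, the two-group log-rank test at a score cutoff, ROC/AUC
comparison of biomarkers, a multivariate logistic remission model, and
the endpoint-by-method summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
import statsmodels.api as sm

from .datamodel import PatientRecord, ScoreSet, ValidationError

__all__ = [
    "ResponseCoding",
    "SurvivalCurve",
    "wilcoxon_one_sided",
    "response_correlation",
    "km_curve",
    "median_survival",
    "logrank",
    "roc_auc",
    "MultivariateRemissionFit",
    "multivariate_remission_fit",
    "summary_table",
]

#: Ordinal response coding, best to worst left-to-right on a response plot.
ORDINAL_RESPONSE = {"CR": 5, "CRu": 4, "PR": 3, "SD": 2, "PD": 1, "Dead": 0}


@dataclass
class ResponseCoding:
    """Policy for turning response categories into analysis variables.

    ``responder_def`` is ``"cr_cru"`` (remission = CR + CRu, the default)
    or ``"cr_only"`` (CR versus all other responses).  Unevaluable
    patients are always excluded; patients dead before response
    evaluation are included as non-responders (ordinal code 0) unless
    ``include_dead`` is switched off, which reproduces the sensitivity
    analysis that drops death-by-toxicity from the response comparison.
    """

    responder_def: str = "cr_cru"
    include_dead: bool = True
    ordinal_map: dict = field(default_factory=lambda: dict(ORDINAL_RESPONSE))

    def __post_init__(self) -> None:
        if self.responder_def not in {"cr_cru", "cr_only"}:
            raise ValidationError("responder_def must be 'cr_cru' or 'cr_only'")

    def _usable(self, response: str) -> bool:
        if response == "Unevaluable":
            return False
        if response == "Dead" and not self.include_dead:
            return False
        return True

    def ordinal(self, responses: Sequence[str]) -> pd.Series:
        """Ordinal codes; excluded categories map to NaN."""
        return pd.Series(
            [
                float(self.ordinal_map[r]) if self._usable(r) else np.nan
                for r in responses
            ]
        )

    def responder(self, responses: Sequence[str]) -> pd.Series:
        """1.0 = responder, 0.0 = non-responder, NaN = excluded."""
        good = {"CR"} if self.responder_def == "cr_only" else {"CR", "CRu"}
        return pd.Series(
            [
                (1.0 if r in good else 0.0) if self._usable(r) else np.nan
                for r in responses
            ]
        )


def wilcoxon_one_sided(scores_responders, scores_nonresponders) -> float:
    """One-sided rank-sum p-value, responders hypothesized higher.

    Exact enumeration when the pooled sample has at most 20
    observations and no ties; otherwise the normal approximation with
    tie and continuity corrections.
    """
    x = np.asarray(scores_responders, dtype=float)
    y = np.asarray(scores_nonresponders, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0  # complete ties: no evidence in either direction
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.pvalue)


def response_correlation(
    scores, responses: Sequence[str], coding: ResponseCoding | None = None
) -> tuple[float, float]:
    """Pearson correlation between score and ordinal response code.

    Returns (cc, one-sided p), the alternative being positive
    correlation (higher score, better response); p from the t
    distribution with n − 2 degrees of freedom.  Excluded categories
    (and their scores) are dropped.
    """
    coding = coding or ResponseCoding()
    scores = np.asarray(scores, dtype=float)
    codes = coding.ordinal(responses).to_numpy()
    keep = ~np.isnan(codes) & ~np.isnan(scores)
    if keep.sum() < 3:
        raise ValidationError("need at least 3 evaluable patients")
    res = stats.pearsonr(scores[keep], codes[keep], alternative="greater")
    return float(res.statistic), float(res.pvalue)


@dataclass
class SurvivalCurve:
    """A Kaplan–Meier product-limit curve.

    ``survival`` is non-increasing with S(0) = 1; ``censor_times`` marks
    censored observations for plotting.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray
    _kmf: KaplanMeierFitter = field(repr=False, compare=False, default=None)

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_curve(times, events, ci_level: float = 0.90) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate of a survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValidationError("no observations")
    if (times < 0).any():
        raise ValidationError("survival times must be non-negative")
    kmf = KaplanMeierFitter(alpha=1.0 - ci_level)
    kmf.fit(times, event_observed=events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy()
    )
    return SurvivalCurve(
        times=timeline,
        survival=surv,
        at_risk=at_risk,
        censor_times=np.sort(times[~events]),
        _kmf=kmf,
    )


def median_survival(
    curve: SurvivalCurve, ci_level: float = 0.90
) -> tuple[float, tuple[float, float]]:
    """Median survival with a log−log confidence interval.

    Median = earliest time with S(t) <= 0.5.  A median (or bound) never
    reached is reported as ``inf``.  The interval uses the exponential-
    Greenwood (log−log) construction at ``ci_level``.
    """
    kmf = curve._kmf
    if kmf is None:
        raise ValidationError("median_survival requires a curve built by km_curve")
    if abs((1.0 - kmf.alpha) - ci_level) > 1e-12:
        refit = KaplanMeierFitter(alpha=1.0 - ci_level)
        refit.fit(kmf.durations, event_observed=kmf.event_observed)
        kmf = refit
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return median, (lo, hi)


def logrank(groups: Sequence[tuple]) -> tuple[float, float]:
    """Log-rank test over two or more (times, events) groups.

    Returns (chi-square statistic, p).  Two groups give the standard
    1-df statistic; k groups give the k−1-df extension.
    """
    if len(groups) < 2:
        raise ValidationError("log-rank test needs at least two groups")
    times, events, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if t.size == 0:
            raise ValidationError(f"log-rank group {g} is empty")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, g))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events)
    )
    return float(res.test_statistic), float(res.p_value)


def roc_auc(scores, binary_labels) -> tuple[pd.DataFrame, float]:
    """ROC curve over all distinct thresholds plus AUC.

    The AUC equals the Mann–Whitney concordance probability, with half
    credit for tied scores.
    """
    y = np.asarray(binary_labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present for a ROC curve")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return curve, float(roc_auc_score(y, s))


@dataclass
class MultivariateRemissionFit:
    """Result of the multivariate logistic remission model
    remission ~ A·Prediction + B·IPI (+ C·subtype score)."""

    params: pd.Series
    bse: pd.Series
    one_sided_p: pd.Series
    converged: bool
    separation_flagged: bool
    notes: tuple[str, ...] = ()

    def wald_ci(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )


def _ridge_logit(X: np.ndarray, y: np.ndarray, alpha: float = 1e-2, n_iter: int = 100):
    """Ridge-penalized logistic fit by IRLS (intercept unpenalized).

    Fallback for separated data; returns (coefficients, standard errors
    from the penalized information matrix).
    """
    n, p = X.shape
    beta = np.zeros(p)
    pen = np.full(p, alpha)
    pen[0] = 0.0
    for _ in range(n_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        info = X.T @ (X * w[:, None]) + np.diag(pen)
        grad = X.T @ (y - mu) - pen * beta
        step = np.linalg.solve(info, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1 - mu), 1e-10)
    cov = np.linalg.inv(X.T @ (X * w[:, None]) + np.diag(pen))
    return beta, np.sqrt(np.diag(cov))


#: hypothesized coefficient signs for the one-sided Wald tests
_HYPOTHESIZED_SIGN = {"prediction": 1.0, "ipi": -1.0, "gcb_abc": 1.0}


def multivariate_remission_fit(
    normalized_scores,
    ipi,
    remission_labels,
    gcb_abc=None,
) -> MultivariateRemissionFit:
    """Fit remission ~ prediction + IPI (+ subtype score) by logistic ML.

    ``remission_labels`` is a binary responder indicator.  One-sided
    Wald p-values test the hypothesized directions: prediction helps
    (A > 0), IPI hurts (B < 0), GCB-like subtype helps (C > 0).
    Covariates without variation are dropped and reported as
    inestimable; complete separation triggers a small-ridge fallback
    with a warning flag.
    """
    cols = {"prediction": np.asarray(normalized_scores, dtype=float),
            "ipi": np.asarray(ipi, dtype=float)}
    if gcb_abc is not None:
        cols["gcb_abc"] = np.asarray(gcb_abc, dtype=float)
    y = np.asarray(remission_labels, dtype=float)
    if np.isnan(y).any() or any(np.isnan(v).any() for v in cols.values()):
        raise ValidationError("missing covariates or labels are not allowed")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("remission labels must be binary")

    notes = []
    active = {}
    for name, v in cols.items():
        if np.ptp(v) == 0:
            notes.append(f"{name} has no variation; coefficient inestimable")
        else:
            active[name] = v
    if not active:
        raise ValidationError("no covariate with variation")

    design = sm.add_constant(pd.DataFrame(active), has_constant="add")
    converged, separation = True, False
    try:
        import warnings as _warnings

        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # separation handled below
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        params = res.params
        bse = res.bse
        converged = bool(res.mle_retvals.get("converged", True))
        if not converged or np.abs(params.to_numpy()).max() > 20 or not np.all(
            np.isfinite(bse.to_numpy())
        ):
            separation = True
    except Exception:
        separation = True

    if separation:
        beta, se = _ridge_logit(design.to_numpy(), y)
        params = pd.Series(beta, index=design.columns)
        bse = pd.Series(se, index=design.columns)
        converged = True
        notes.append("separation detected; small-ridge penalized fit reported")

    index = ["const"] + list(cols)
    full_params = pd.Series(np.nan, index=index)
    full_bse = pd.Series(np.nan, index=index)
    for name in params.index:
        full_params[name] = params[name]
        full_bse[name] = bse[name]

    one_sided = pd.Series(np.nan, index=index)
    for name, sign in _HYPOTHESIZED_SIGN.items():
        if name in params.index and bse[name] > 0:
            z = sign * params[name] / bse[name]
            one_sided[name] = stats.norm.sf(z)

    return MultivariateRemissionFit(
        params=full_params,
        bse=full_bse,
        one_sided_p=one_sided,
        converged=converged,
        separation_flagged=separation,
        notes=tuple(notes),
    )


def _logrank_split(times, events, split_mask) -> float:
    """Log-rank p for a boolean split; NaN when one side is empty."""
    split_mask = np.asarray(split_mask, dtype=bool)
    if split_mask.all() or (~split_mask).all():
        return np.nan
    _, p = logrank(
        [
            (times[split_mask], events[split_mask]),
            (times[~split_mask], events[~split_mask]),
        ]
    )
    return p


def summary_table(
    records: Sequence[PatientRecord],
    scores: ScoreSet,
    gcb_scores=None,
    coding: ResponseCoding | None = None,
    ipi_cutoff: int = 3,
    combined_cutoff: float = 0.0,
    gcb_cutoff: float = 0.0,
) -> pd.DataFrame:
    """Endpoint x method p-value table.

    Rows: remission, overall survival, progression-free survival.
    Columns: Prediction (normalized score), IPI, Combined, GCB/ABC.
    The remission row uses the one-sided rank-sum test of each score
    between responders and non-responders (IPI entered with its natural
    order reversed, low IPI being favorable); the survival rows use the
    two-group log-rank test at each method's cutoff (prediction at the
    score-set cutoff, IPI at >= ``ipi_cutoff`` as the high-risk split,
    combined and subtype scores at their natural zero).  Cells with a
    degenerate split are NaN.  The GCB/ABC column is NaN throughout when
    no subtype scores are supplied.
    """
    coding = coding or ResponseCoding()
    order = list(scores.patient_ids)
    by_id = {r.patient_id: r for r in records}
    missing = [p for p in order if p not in by_id]
    if missing:
        raise ValidationError(f"score set patients without clinical record: {missing}")
    recs = [by_id[p] for p in order]

    norm = np.asarray(scores.normalized_scores)
    comb = np.asarray(scores.combined_scores)
    ipi = np.asarray([r.ipi for r in recs], dtype=float)
    gcb = None
    if gcb_scores is not None:
        gcb = (
            gcb_scores.reindex(order).to_numpy()
            if isinstance(gcb_scores, pd.Series)
            else np.asarray(gcb_scores, dtype=float)
        )

    responder = coding.responder([r.response for r in recs]).to_numpy()
    evaluable = ~np.isnan(responder)

    def remission_p(values, reverse=False):
        if values is None:
            return np.nan
        v = -values if reverse else values
        resp = v[evaluable & (responder == 1)]
        nonresp = v[evaluable & (responder == 0)]
        if resp.size == 0 or nonresp.size == 0:
            return np.nan
        return wilcoxon_one_sided(resp, nonresp)

    os_t = np.asarray([r.os_days for r in recs])
    os_e = np.asarray([r.os_event for r in recs])
    pfs_t = np.asarray([r.pfs_days for r in recs])
    pfs_e = np.asarray([r.pfs_event for r in recs])

    splits = {
        "Prediction": norm >= scores.cutoff,
        "IPI": ipi >= ipi_cutoff,
        "Combined": comb >= combined_cutoff,
        "GCB/ABC": (gcb >= gcb_cutoff) if gcb is not None else None,
    }

    table = pd.DataFrame(
        index=["Remission", "Overall survival", "Progression-free survival"],
        columns=["Prediction", "IPI", "Combined", "GCB/ABC"],
        dtype=float,
    )
    table.loc["Remission"] = [
        remission_p(norm),
        remission_p(ipi, reverse=True),
        remission_p(comb),
        remission_p(gcb),
    ]
    for endpoint, (t, e) in {
        "Overall survival": (os_t, os_e),
        "Progression-free survival": (pfs_t, pfs_e),
    }.items():
        table.loc[endpoint] = [
            _logrank_split(t, e, m) if m is not None else np.nan
            for m in splits.values()
        ]
    return table
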