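"""Scoring patient expression profiles against a response signature.

The prediction score of a sample is the unweighted mean of the
signature features' log2 expression values.  Raw scores are rescaled to
0–100 by a min–max linear transform over the normalization population
(by default the patients of the same treatment arm), and the combined
score subtracts a weighted IPI term (weight 25 makes the IPI range,
125, commensurate with the 0–100 prediction scale).  A sample is called
sensitive when its normalized score is at or above the cutoff
(default 50).
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .datamodel import (
    ExpressionMatrix,
    PatientRecord,
    ResponseSignature,
    ScoreSet,
    SubtypeProfile,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ChemosensitivityScorer",
    "raw_prediction_score",
    "raw_prediction_scores",
    "normalize_scores",
    "combination_score",
    "gcb_abc_score",
    "gcb_abc_scores",
    "classify",
    "quantile_normalize_log2",
    "score_cohort",
]


def _signature_means(values: pd.DataFrame, feature_ids: Sequence[str], what: str) -> pd.Series:
    """Mean over available signature features, column-wise.

    Missing features (absent rows or NaN cells) are dropped from the
    mean with a warning; a sample with no signature feature at all is an
    error.
    """
    present = [f for f in feature_ids if f in values.index]
    if not present:
        raise ValidationError(f"none of the {what} features are present in the matrix")
    absent = [f for f in feature_ids if f not in values.index]
    sub = values.loc[present]
    if absent or sub.isna().to_numpy().any():
        warnings.warn(
            f"{what}: missing values for some features; using the mean over "
            f"non-missing features ({len(absent)} absent from the matrix)",
            stacklevel=3,
        )
    means = sub.mean(axis=0, skipna=True)
    if means.isna().any():
        bad = means.index[means.isna()].tolist()
        raise ValidationError(f"samples with no non-missing {what} feature: {bad}")
    return means


def raw_prediction_scores(
    expr: ExpressionMatrix, signature: ResponseSignature
) -> pd.Series:
    """Raw prediction score per sample: equal-weight mean of the
    signature features' expression."""
    scores = _signature_means(expr.values, signature.feature_ids, signature.treatment_name)
    scores.name = f"{signature.treatment_name}_raw"
    return scores


def raw_prediction_score(sample_expr: pd.Series, signature: ResponseSignature) -> float:
    """Raw prediction score of a single sample (Series indexed by feature id)."""
    frame = sample_expr.to_frame(name="_sample")
    return float(
        _signature_means(frame, signature.feature_ids, signature.treatment_name)[
            "_sample"
        ]
    )


def normalize_scores(raw_scores) -> pd.Series | np.ndarray:
    """Min–max rescale raw scores to 0–100 over the given population.

    Requires at least two distinct raw scores; the minimum maps to 0 and
    the maximum to 100.
    """
    values = np.asarray(raw_scores, dtype=float)
    lo, hi = np.nanmin(values), np.nanmax(values)
    if not hi > lo:
        raise ValidationError(
            "all raw scores are equal; the 0-100 linear transform is degenerate"
        )
    out = (values - lo) / (hi - lo) * 100.0  # division first: extremes exact
    if isinstance(raw_scores, pd.Series):
        return pd.Series(out, index=raw_scores.index, name="normalized")
    return out


def combination_score(normalized, ipi, weight: float = 25.0):
    """Combined score = normalized prediction − weight · IPI.

    With the default weight the IPI term spans 125 over IPI 0–5, making
    it commensurate with the 0–100 prediction scale; the combined score
    ranges over [−125, 100].
    """
    ipi_arr = np.asarray(ipi)
    if np.any((ipi_arr < 0) | (ipi_arr > 5) | (ipi_arr != np.floor(ipi_arr))):
        raise ValidationError(f"IPI must be an integer in 0..5, got {ipi!r}")
    out = np.asarray(normalized, dtype=float) - float(weight) * ipi_arr
    if np.isscalar(normalized) or np.ndim(normalized) == 0:
        return float(out)
    if isinstance(normalized, pd.Series):
        return pd.Series(out, index=normalized.index, name="combined")
    return out


def gcb_abc_scores(expr: ExpressionMatrix, profile: SubtypeProfile) -> pd.Series:
    """Subtype score per sample: mean(GCB features) − mean(ABC features)."""
    gcb = _signature_means(expr.values, profile.gcb_features, "GCB")
    abc = _signature_means(expr.values, profile.abc_features, "ABC")
    out = gcb - abc
    out.name = "gcb_abc"
    return out


def gcb_abc_score(sample_expr: pd.Series, profile: SubtypeProfile) -> float:
    frame = sample_expr.to_frame(name="_sample")
    gcb = _signature_means(frame, profile.gcb_features, "GCB")["_sample"]
    abc = _signature_means(frame, profile.abc_features, "ABC")["_sample"]
    return float(gcb - abc)


def classify(score, cutoff: float = 50.0):
    """Dichotomize scores at a cutoff: ``score >= cutoff`` is sensitive.

    The boundary itself is classified sensitive (one convention,
    documented and tested).
    """
    arr = np.asarray(score, dtype=float)
    calls = np.where(arr >= cutoff, "sensitive", "resistant")
    if np.ndim(score) == 0:
        return str(calls[()])
    return calls


def quantile_normalize_log2(raw: pd.DataFrame) -> ExpressionMatrix:
    """Quantile-normalize positive intensities across columns, then log2.

    Every column is mapped onto the common distribution of row-sorted
    column means (ties receive the average of the tied quantiles), which
    leaves within-column rank order intact.  This is a generic quantile
    stand-in for array preprocessing, not an RMA implementation — inputs
    to the pipeline proper are expected to be pre-normalized.
    """
    logger.info("quantile_normalize_log2: generic quantile + log2 (not RMA)")
    raw = pd.DataFrame(raw).astype(float)
    if (raw.to_numpy() <= 0).any() or raw.isna().to_numpy().any():
        raise ValidationError("quantile normalization requires positive intensities")
    ref = np.sort(raw.to_numpy(), axis=0).mean(axis=1)
    ranks = raw.rank(method="average")  # 1-based, average over ties
    normalized = pd.DataFrame(
        np.interp(ranks.to_numpy(), np.arange(1, len(ref) + 1), ref),
        index=raw.index,
        columns=raw.columns,
    )
    return ExpressionMatrix(np.log2(normalized))


class ChemosensitivityScorer(BaseEstimator):
    """Score samples against a response signature, scikit-learn style.

    ``fit`` learns the cohort min–max normalization from the raw
    prediction scores of the fitted population; ``transform`` returns
    normalized 0–100 scores and ``predict`` the sensitive/resistant
    calls at the cutoff.

    Parameters
    ----------
    signature : ResponseSignature
        The treatment signature (equal-weight feature list).
    ipi_weight : float, default 25.0
        Weight of the IPI term in the combined score.
    cutoff : float, default 50.0
        Call threshold on the normalized scale.
    """

    def __init__(
        self,
        signature: ResponseSignature | None = None,
        ipi_weight: float = 25.0,
        cutoff: float = 50.0,
    ):
        self.signature = signature
        self.ipi_weight = ipi_weight
        self.cutoff = cutoff

    def _raw(self, X: pd.DataFrame) -> pd.Series:
        if self.signature is None:
            raise ValidationError("ChemosensitivityScorer requires a signature")
        X = pd.DataFrame(X)
        return _signature_means(
            X.T, self.signature.feature_ids, self.signature.treatment_name
        )

    def fit(self, X: pd.DataFrame, y=None):
        """Learn the 0–100 normalization from a samples x features frame."""
        raw = self._raw(X)
        lo, hi = float(raw.min()), float(raw.max())
        if not hi > lo:
            raise ValidationError(
                "all raw scores equal in the normalization population"
            )
        self.raw_min_ = lo
        self.raw_max_ = hi
        self.n_features_in_ = pd.DataFrame(X).shape[1]
        return self

    def score_samples(self, X: pd.DataFrame) -> pd.Series:
        """Raw (un-normalized) prediction scores."""
        return self._raw(X)

    def transform(self, X: pd.DataFrame) -> pd.Series:
        """Normalized 0–100 scores under the fitted linear map.

        Samples outside the fitted population may fall outside [0, 100];
        they are not clipped.
        """
        check_is_fitted(self, "raw_min_")
        raw = self._raw(X)
        out = (raw - self.raw_min_) / (self.raw_max_ - self.raw_min_) * 100.0
        out.name = "normalized"
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Sensitive/resistant call at the cutoff."""
        return classify(self.transform(X).to_numpy(), cutoff=self.cutoff)

    def combine(self, X: pd.DataFrame, ipi) -> pd.Series:
        """Combined scores (normalized − ipi_weight · IPI)."""
        norm = self.transform(X)
        if isinstance(ipi, pd.Series):
            ipi = ipi.reindex(norm.index)
        return combination_score(norm, ipi, weight=self.ipi_weight)

    def score_set(self, X: pd.DataFrame, ipi) -> ScoreSet:
        """Bundle raw, normalized, combined scores and calls."""
        raw = self._raw(X)
        norm = self.transform(X)
        comb = self.combine(X, ipi)
        return ScoreSet(
            patient_ids=tuple(norm.index),
            raw_scores=tuple(raw),
            normalized_scores=tuple(norm),
            combined_scores=tuple(comb),
            calls=tuple(classify(norm.to_numpy(), cutoff=self.cutoff)),
            cutoff=self.cutoff,
        )


def score_cohort(
    expr: ExpressionMatrix,
    records: Sequence[PatientRecord],
    signatures: Mapping[str, ResponseSignature],
    ipi_weight: float = 25.0,
    cutoff: float = 50.0,
    norm_population: str = "arm",
) -> ScoreSet:
    """Score a clinical cohort, one signature per treatment arm.

    ``signatures`` maps each treatment label occurring in the cohort to
    the signature used for that arm.  With ``norm_population="arm"``
    (default) each arm's scores are min–max normalized over that arm's
    patients; with ``"cohort"`` every signature's raw scores are
    normalized over all patients before each patient takes the value
    from their own arm's signature.
    """
    if norm_population not in {"arm", "cohort"}:
        raise ValueError("norm_population must be 'arm' or 'cohort'")
    aligned = {r.patient_id: r for r in records}
    missing = [s for s in expr.sample_ids if s not in aligned]
    if missing:
        raise ValidationError(f"expression samples without clinical record: {missing}")
    treatments = {aligned[s].treatment for s in expr.sample_ids}
    unknown = sorted(t for t in treatments if t not in signatures)
    if unknown:
        raise ValidationError(f"no signature supplied for treatment(s): {unknown}")

    raw = pd.Series(index=expr.sample_ids, dtype=float)
    norm = pd.Series(index=expr.sample_ids, dtype=float)
    for treatment in sorted(treatments):
        sig = signatures[treatment]
        arm_ids = [s for s in expr.sample_ids if aligned[s].treatment == treatment]
        if norm_population == "arm":
            arm_raw = raw_prediction_scores(expr.subset_samples(arm_ids), sig)
            raw.loc[arm_ids] = arm_raw
            norm.loc[arm_ids] = normalize_scores(arm_raw)
        else:
            all_raw = raw_prediction_scores(expr, sig)
            all_norm = normalize_scores(all_raw)
            raw.loc[arm_ids] = all_raw.loc[arm_ids]
            norm.loc[arm_ids] = all_norm.loc[arm_ids]

    ipi = pd.Series({s: aligned[s].ipi for s in expr.sample_ids})
    comb = combination_score(norm, ipi, weight=ipi_weight)
    # arm-wise normalization can leave the pooled minimum/maximum away
    # from 0/100 only in degenerate single-arm corner cases; ScoreSet
    # enforces the contract.
    return ScoreSet(
        patient_ids=tuple(expr.sample_ids),
        raw_scores=tuple(raw),
        normalized_scores=tuple(norm),
        combined_scores=tuple(comb),
        calls=tuple(classify(norm.to_numpy(), cutoff=cutoff)),
        cutoff=cutoff,
    )
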