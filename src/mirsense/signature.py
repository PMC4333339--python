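"""Construction of drug-combination response signatures from a cell-line
screen.

The method: sum the component drugs' −log10(GI50) vectors over cell
lines with complete data (unweighted, no standardization), correlate
every expression feature with the summed combination-sensitivity
vector (Pearson), and keep features with r strictly above the selection
threshold (default 0.25).  Only positively correlated features are
eligible — higher expression marks sensitivity; negatively correlated
features carry no predictive signal for this method.

:class:`SignatureSelector` wraps the procedure as a scikit-learn style
feature selector (``fit(X, y)`` on a cell-lines x features frame and
the combination-sensitivity vector); the module-level functions are the
thin functional surface over the same computation.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .datamodel import (
    CombinationSpec,
    DrugResponsePanel,
    ExpressionMatrix,
    ResponseSignature,
    ValidationError,
)

__all__ = [
    "SignatureSelector",
    "combination_sensitivity_vector",
    "feature_correlations",
    "select_signature",
    "build_signature",
]


def combination_sensitivity_vector(
    panel: DrugResponsePanel, spec: CombinationSpec
) -> pd.Series:
    """Sum the component drugs' −log10(GI50) vectors.

    A cell line is retained only if it has a measurement for every
    component drug; fewer than three retained lines is an error (a
    correlation over them would be meaningless).
    """
    missing = [d for d in spec.component_drugs if d not in panel.values.index]
    if missing:
        raise ValidationError(f"component drugs not in panel: {missing}")
    sub = panel.values.loc[list(spec.component_drugs)]
    complete = sub.notna().all(axis=0)
    retained = sub.loc[:, complete]
    if retained.shape[1] < 3:
        raise ValidationError(
            f"only {retained.shape[1]} cell lines with complete data for "
            f"{spec.treatment_name}; need at least 3"
        )
    out = retained.sum(axis=0)
    out.name = spec.treatment_name
    return out


def feature_correlations(expr: ExpressionMatrix, sens: pd.Series) -> pd.DataFrame:
    """Per-feature Pearson correlation with a sensitivity vector.

    Cell lines missing either the expression value or the sensitivity
    value are dropped pairwise per feature, with the per-feature n
    recorded.  Zero-variance features get an undefined r and are marked
    excluded.  Two-sided p-values come from the t distribution with
    n − 2 degrees of freedom.

    Returns a frame indexed by feature id with columns
    ``r``, ``p``, ``n``, ``excluded``.
    """
    sens = sens.dropna()
    common = [s for s in expr.sample_ids if s in set(sens.index)]
    if len(common) < 3:
        raise ValidationError(
            f"only {len(common)} cell lines shared between expression and "
            "sensitivity; need at least 3"
        )
    X = expr.values[common]
    y = sens.loc[common].astype(float)

    if not X.isna().to_numpy().any():
        xv = X.to_numpy()
        yv = y.to_numpy()
        xc = xv - xv.mean(axis=1, keepdims=True)
        yc = yv - yv.mean()
        sy = float(np.sqrt((yc**2).sum()))
        sx = np.sqrt((xc**2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where((sx > 0) & (sy > 0), (xc @ yc) / (sx * sy), np.nan)
        n = np.full(len(r), len(common))
    else:
        r = X.T.corrwith(y).to_numpy()
        n = (X.notna() & y.notna()).sum(axis=1).to_numpy()

    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(np.maximum(n - 2, 0) / np.maximum(1 - r**2, 0))
    p = 2 * stats.t.sf(np.abs(t), df=np.maximum(n - 2, 1))
    p = np.where(np.isnan(r), np.nan, np.where(np.isinf(t), 0.0, p))
    return pd.DataFrame(
        {"r": r, "p": p, "n": n, "excluded": np.isnan(r)}, index=expr.feature_ids
    )


def select_signature(
    correlations: pd.DataFrame | pd.Series,
    threshold: float = 0.25,
    treatment_name: str = "signature",
) -> ResponseSignature:
    """Keep features with Pearson r strictly above ``threshold``.

    Only positive correlations are eligible (the threshold must be
    positive); excluded (undefined-r) features never qualify.  Entries
    are sorted by feature id for determinism.
    """
    if not threshold > 0:
        raise ValidationError(f"selection threshold must be positive, got {threshold}")
    r = correlations["r"] if isinstance(correlations, pd.DataFrame) else correlations
    r = r.dropna()
    kept = r[r > threshold].sort_index()
    if kept.empty:
        raise ValidationError(
            f"no features with correlation above {threshold}; "
            "review the threshold or the input screen"
        )
    return ResponseSignature(
        treatment_name=treatment_name,
        entries=tuple(zip(kept.index, kept.to_numpy())),
        threshold=threshold,
    )


class SignatureSelector(BaseEstimator):
    """Select sensitivity-biomarker features by Pearson correlation.

    Parameters
    ----------
    threshold : float, default 0.25
        Strict lower bound on the Pearson correlation between a
        feature's expression and the combination-sensitivity vector.
    treatment_name : str, default "signature"
        Label stored on the fitted :class:`ResponseSignature`.

    Attributes
    ----------
    correlations_ : pandas.Series
        Per-feature Pearson r (NaN for zero-variance features).
    pvalues_ : pandas.Series
        Two-sided p-values (t distribution, df = n − 2).
    n_obs_ : pandas.Series
        Pairwise-complete sample size per feature.
    signature_ : ResponseSignature
        The selected signature.
    selected_features_ : list of str
        Feature ids in the signature, sorted.
    """

    def __init__(self, threshold: float = 0.25, treatment_name: str = "signature"):
        self.threshold = threshold
        self.treatment_name = treatment_name

    def fit(self, X: pd.DataFrame, y):
        """Fit on a cell-lines x features frame against a sensitivity vector.

        ``y`` may be a Series indexed like ``X`` or a plain array in row
        order.
        """
        X = pd.DataFrame(X)
        if isinstance(y, pd.Series):
            y = y.reindex(X.index)
        else:
            y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        expr = ExpressionMatrix(X.T)
        corr = feature_correlations(expr, y)
        self.correlations_ = corr["r"]
        self.pvalues_ = corr["p"]
        self.n_obs_ = corr["n"]
        self.signature_ = select_signature(
            corr, threshold=self.threshold, treatment_name=self.treatment_name
        )
        self.selected_features_ = self.signature_.feature_ids
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Restrict a cell-lines/samples x features frame to the signature."""
        check_is_fitted(self, "signature_")
        X = pd.DataFrame(X)
        missing = [f for f in self.selected_features_ if f not in X.columns]
        if missing:
            raise ValidationError(f"selected features missing from input: {missing}")
        return X[self.selected_features_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "signature_")
        selected = set(self.selected_features_)
        return np.asarray([f in selected for f in self.feature_names_in_])


def build_signature(
    panel: DrugResponsePanel,
    expr_cells: ExpressionMatrix,
    spec: CombinationSpec,
    threshold: float = 0.25,
) -> ResponseSignature:
    """Full signature construction: sum component −log10(GI50) vectors,
    correlate against baseline expression, select above the threshold.

    Deterministic given its inputs.
    """
    sens = combination_sensitivity_vector(panel, spec)
    corr = feature_correlations(expr_cells, sens)
    return select_signature(
        corr, threshold=threshold, treatment_name=spec.treatment_name
    )
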