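"""Core data containers for the chemosensitivity-prediction pipeline.

Everything downstream of file parsing operates on the small set of types
defined here: drug-sensitivity panels from cell-line screens, log2
expression matrices, per-treatment response signatures, patient clinical
records and per-patient score sets.  The containers wrap pandas objects
and enforce their invariants at construction time, so pipeline code can
assume well-formed inputs throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Clinical response categories (Cheson criteria plus the two bookkeeping
#: categories used in the cohort: death before response evaluation and
#: unevaluable response).
RESPONSE_CATEGORIES: tuple[str, ...] = (
    "CR", "CRu", "PR", "SD", "PD", "Dead", "Unevaluable",
)

_CANONICAL_RESPONSE = {c.lower(): c for c in RESPONSE_CATEGORIES}


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


def canonical_response(label: str) -> str:
    """Map a response label to its canonical spelling, case-insensitively."""
    try:
        return _CANONICAL_RESPONSE[str(label).strip().lower()]
    except KeyError:
        raise ValidationError(
            f"unknown response label {label!r}; allowed labels: "
            + ", ".join(RESPONSE_CATEGORIES)
        ) from None


def _check_unique(ids: Iterable[str], what: str) -> None:
    idx = pd.Index(list(ids))
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dup}")


@dataclass
class ExpressionMatrix:
    """A log2 expression matrix, features x samples.

    Feature identifiers are opaque strings (probe-set suffixes such as
    ``_st`` / ``_x_st`` are kept verbatim).  Missing values are allowed
    and stored as NaN; infinities are rejected.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (features x samples)")
        df = self.values.astype(float)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        _check_unique(df.index, "feature ids")
        _check_unique(df.columns, "sample ids")
        if np.isinf(df.to_numpy()).any():
            raise ValidationError("expression values must be finite where present")
        df.index.name = None
        df.columns.name = None
        self.values = df

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        """Expression vector of one sample, indexed by feature id."""
        return self.values[sample_id]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"sample ids not in matrix: {missing}")
        return ExpressionMatrix(self.values[list(sample_ids)].copy())


@dataclass
class DrugResponsePanel:
    """Per-drug sensitivity over a shared cell-line screen.

    ``values`` holds −log10(GI50), drugs x cell lines (higher = more
    sensitive, molar-scale logs).  Every drug must have at least three
    non-missing cell lines, otherwise a correlation against it is
    meaningless.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (drugs x cell lines)")
        df = self.values.astype(float)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        _check_unique(df.index, "drug names")
        _check_unique(df.columns, "cell line ids")
        if np.isinf(df.to_numpy()).any():
            raise ValidationError("panel values must be finite where present")
        n_ok = df.notna().sum(axis=1)
        if (n_ok < 3).any():
            bad = n_ok[n_ok < 3].index.tolist()
            raise ValidationError(
                f"drugs with fewer than 3 non-missing cell lines: {bad}"
            )
        df.index.name = None
        df.columns.name = None
        self.values = df

    @property
    def drug_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.values.columns)

    def sensitivity(self, drug: str) -> pd.Series:
        """−log10(GI50) vector of one drug over the cell lines."""
        if drug not in self.values.index:
            raise ValidationError(f"drug {drug!r} not in panel")
        return self.values.loc[drug]


@dataclass
class ResponseSignature:
    """A treatment's response signature: selected features and their
    selection correlations (Pearson r against the combination
    sensitivity vector on the training screen).

    Every selection correlation must exceed ``threshold`` strictly; this
    encodes the selection rule itself (only positively correlated probes
    above the cutoff are biomarkers of sensitivity).
    """

    treatment_name: str
    entries: tuple[tuple[str, float], ...]
    threshold: float = 0.25
    #: optional transcription columns carried alongside a packaged or
    #: user-supplied signature file (ignored by all computations)
    extra: pd.DataFrame | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        entries = tuple((str(f), float(r)) for f, r in self.entries)
        if not entries:
            raise ValidationError("signature has no entries")
        _check_unique((f for f, _ in entries), "signature feature ids")
        thr = float(self.threshold)
        if not np.isfinite(thr):
            raise ValidationError("threshold must be finite")
        bad = [(f, r) for f, r in entries if not (r > thr)]
        if bad:
            raise ValidationError(
                f"signature entries at or below threshold {thr}: {bad}"
            )
        self.entries = entries
        self.threshold = thr
        self.treatment_name = str(self.treatment_name)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def feature_ids(self) -> list[str]:
        return [f for f, _ in self.entries]

    @property
    def correlations(self) -> pd.Series:
        return pd.Series(
            {f: r for f, r in self.entries}, name="selection_correlation"
        )


@dataclass
class PatientRecord:
    """One patient's clinical record.

    OS and PFS are both measured from first diagnosis, in days.  When
    both events are recorded, progression cannot postdate death.
    """

    patient_id: str
    ipi: int
    treatment: str
    response: str
    os_days: float
    os_event: bool
    pfs_days: float
    pfs_event: bool
    relapse: bool = False
    relapse_regimens: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.patient_id = str(self.patient_id)
        ipi = int(self.ipi)
        if not 0 <= ipi <= 5:
            raise ValidationError(
                f"patient {self.patient_id}: IPI must be in 0..5, got {self.ipi}"
            )
        self.ipi = ipi
        self.treatment = str(self.treatment)
        self.response = canonical_response(self.response)
        self.os_days = float(self.os_days)
        self.pfs_days = float(self.pfs_days)
        if self.os_days < 0 or self.pfs_days < 0:
            raise ValidationError(
                f"patient {self.patient_id}: survival times must be non-negative"
            )
        self.os_event = bool(self.os_event)
        self.pfs_event = bool(self.pfs_event)
        if self.os_event and self.pfs_event and self.pfs_days > self.os_days:
            raise ValidationError(
                f"patient {self.patient_id}: pfs_days ({self.pfs_days}) exceeds "
                f"os_days ({self.os_days}) with both events recorded"
            )
        self.relapse = bool(self.relapse)
        self.relapse_regimens = tuple(str(r) for r in self.relapse_regimens)


@dataclass
class ScoreSet:
    """Per-patient scores of one cohort under one signature.

    ``normalized_scores`` live on the 0–100 scale (min–max over the
    normalization population), ``combined_scores`` subtract the weighted
    IPI, and ``calls`` dichotomize the normalized score at ``cutoff``
    (score >= cutoff is called sensitive).
    """

    patient_ids: tuple[str, ...]
    raw_scores: tuple[float, ...]
    normalized_scores: tuple[float, ...]
    combined_scores: tuple[float, ...]
    calls: tuple[str, ...]
    cutoff: float = 50.0

    def __post_init__(self) -> None:
        self.patient_ids = tuple(str(p) for p in self.patient_ids)
        _check_unique(self.patient_ids, "patient ids")
        self.raw_scores = tuple(float(x) for x in self.raw_scores)
        self.normalized_scores = tuple(float(x) for x in self.normalized_scores)
        self.combined_scores = tuple(float(x) for x in self.combined_scores)
        self.calls = tuple(str(c) for c in self.calls)
        n = len(self.patient_ids)
        for name in ("raw_scores", "normalized_scores", "combined_scores", "calls"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length does not match patient_ids")
        self.cutoff = float(self.cutoff)
        norm = np.asarray(self.normalized_scores)
        if len(set(self.raw_scores)) >= 2 and n >= 2:
            if not (np.isclose(norm.min(), 0.0) and np.isclose(norm.max(), 100.0)):
                raise ValidationError(
                    "normalized scores must attain 0 and 100 for a "
                    "non-degenerate cohort"
                )
        expect = np.where(norm >= self.cutoff, "sensitive", "resistant")
        if not all(c == e for c, e in zip(self.calls, expect)):
            raise ValidationError("calls inconsistent with cutoff on normalized scores")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "raw": self.raw_scores,
                "normalized": self.normalized_scores,
                "combined": self.combined_scores,
                "call": self.calls,
            }
        ).set_index("patient_id")

    @property
    def normalized(self) -> pd.Series:
        return pd.Series(self.normalized_scores, index=list(self.patient_ids))

    @property
    def combined(self) -> pd.Series:
        return pd.Series(self.combined_scores, index=list(self.patient_ids))


@dataclass
class SubtypeProfile:
    """Cell-of-origin subtype profile: the score is
    mean(GCB features) − mean(ABC features)."""

    gcb_features: tuple[str, ...]
    abc_features: tuple[str, ...]

    def __post_init__(self) -> None:
        self.gcb_features = tuple(str(f) for f in self.gcb_features)
        self.abc_features = tuple(str(f) for f in self.abc_features)
        if not self.gcb_features or not self.abc_features:
            raise ValidationError("both GCB and ABC feature lists must be non-empty")
        _check_unique(self.gcb_features, "GCB features")
        _check_unique(self.abc_features, "ABC features")
        overlap = set(self.gcb_features) & set(self.abc_features)
        if overlap:
            raise ValidationError(f"GCB/ABC feature lists overlap: {sorted(overlap)}")


@dataclass
class CombinationSpec:
    """A combination regimen as the set of screened component drugs whose
    −log10(GI50) vectors are summed (unweighted) into a single
    combination-sensitivity vector."""

    treatment_name: str
    component_drugs: tuple[str, ...]
    aggregation: str = "sum"

    def __post_init__(self) -> None:
        self.treatment_name = str(self.treatment_name)
        self.component_drugs = tuple(str(d) for d in self.component_drugs)
        if not self.component_drugs:
            raise ValidationError("combination must have at least one component drug")
        _check_unique(self.component_drugs, "component drugs")
        if self.aggregation != "sum":
            raise ValidationError(
                f"unsupported aggregation {self.aggregation!r}; only 'sum' is defined"
            )
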