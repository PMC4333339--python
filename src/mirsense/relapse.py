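"""Second/third-line regimen scoring and selection for relapse patients.

A relapse patient's score against a candidate regimen is that regimen's
prediction score normalized to 0–100 across the relapse cohort being
analyzed (the normalization context).  The patient's relapse score is
the mean of the normalized scores of the regimens actually received;
the cohort is split at a cutoff either optimized for survival
separation (log-rank) or chosen to yield a fixed number of predicted-
sensitive patients.  Because an optimized cutoff is selected on the
outcome, results carry an explicit machine-readable caveat: the
associated p-values are descriptive, not valid tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, PatientRecord, ResponseSignature, ValidationError
from .scoring import classify, normalize_scores, raw_prediction_scores
from .validation import SurvivalCurve, km_curve, logrank, median_survival

__all__ = [
    "RegimenPanel",
    "regimen_score_table",
    "relapse_score",
    "relapse_scores",
    "CutoffResult",
    "optimize_cutoff",
    "compare_relapse_survival",
    "recommend_regimens",
    "biopsy_concordance",
    "post_relapse_survival",
]


@dataclass
class RegimenPanel:
    """A library of response signatures, one per candidate regimen."""

    signatures: dict[str, ResponseSignature]

    def __post_init__(self) -> None:
        if not self.signatures:
            raise ValidationError("regimen panel is empty")
        for label, sig in self.signatures.items():
            if not isinstance(sig, ResponseSignature):
                raise ValidationError(f"panel entry {label!r} is not a signature")

    @property
    def regimens(self) -> list[str]:
        return sorted(self.signatures)


def regimen_score_table(expr: ExpressionMatrix, panel: RegimenPanel) -> pd.DataFrame:
    """Normalized 0–100 score of every patient against every regimen.

    Normalization is per regimen, across the relapse cohort in ``expr``
    (the normalization context for all relapse analyses).
    """
    cols = {}
    for label in panel.regimens:
        raw = raw_prediction_scores(expr, panel.signatures[label])
        cols[label] = normalize_scores(raw)
    return pd.DataFrame(cols, index=expr.sample_ids)


def relapse_score(
    patient_id: str, received_regimens: Sequence[str], score_table: pd.DataFrame
) -> float:
    """Mean of the patient's normalized scores over the regimens received.

    Order of the received regimens is irrelevant.  An unknown regimen is
    an error naming it.
    """
    if not received_regimens:
        raise ValidationError(f"patient {patient_id!r} received no regimens")
    unknown = [r for r in received_regimens if r not in score_table.columns]
    if unknown:
        raise ValidationError(
            f"regimen(s) {unknown} not in the regimen panel "
            f"(have: {sorted(score_table.columns)})"
        )
    return float(score_table.loc[patient_id, list(received_regimens)].mean())


def relapse_scores(
    records: Sequence[PatientRecord], score_table: pd.DataFrame
) -> pd.Series:
    """Relapse score per patient with received regimens from the records."""
    out = {}
    for r in records:
        if r.patient_id in score_table.index:
            out[r.patient_id] = relapse_score(
                r.patient_id, r.relapse_regimens, score_table
            )
    if not out:
        raise ValidationError("no scored patients among the records")
    return pd.Series(out, name="relapse_score")


@dataclass
class CutoffResult:
    """A chosen sensitive/resistant cutoff.

    ``data_optimized`` is True when the cutoff was selected on the
    survival outcome itself; any log-rank p computed at such a cutoff is
    descriptive only (selection bias), never a valid test.
    """

    cutoff: float
    statistic: float
    p_value: float
    n_sensitive: int
    n_resistant: int
    data_optimized: bool
    mode: str


def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    uniq = np.unique(scores)
    return (uniq[:-1] + uniq[1:]) / 2.0


def optimize_cutoff(
    scores,
    times,
    events,
    min_group: int = 3,
    mode: str = "logrank",
    target_n_sensitive: int | None = None,
) -> CutoffResult:
    """Choose the cutoff splitting the cohort into sensitive/resistant.

    ``mode="logrank"`` scans the midpoints of sorted unique scores and
    returns the cutoff maximizing the two-group log-rank chi-square,
    subject to both groups holding at least ``min_group`` patients; ties
    break toward the cutoff nearest the median score.  ``mode="fixed_n"``
    instead picks the cutoff that yields exactly ``target_n_sensitive``
    predicted-sensitive patients.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n = scores.size
    if n < 2 * min_group:
        raise ValidationError(
            f"need at least {2 * min_group} patients to split (have {n})"
        )

    if mode == "fixed_n":
        if target_n_sensitive is None or not 0 < target_n_sensitive < n:
            raise ValidationError(
                "fixed_n mode needs 0 < target_n_sensitive < n_patients"
            )
        order = np.sort(scores)[::-1]
        hi = order[target_n_sensitive - 1]
        lo = order[target_n_sensitive]
        if hi == lo:
            raise ValidationError(
                f"tied scores prevent a split with exactly {target_n_sensitive} "
                "sensitive patients"
            )
        cutoff = (hi + lo) / 2.0
        sens = scores >= cutoff
        stat, p = logrank([(times[sens], events[sens]), (times[~sens], events[~sens])])
        return CutoffResult(
            cutoff=float(cutoff),
            statistic=stat,
            p_value=p,
            n_sensitive=int(sens.sum()),
            n_resistant=int((~sens).sum()),
            data_optimized=False,
            mode=mode,
        )
    if mode != "logrank":
        raise ValidationError("mode must be 'logrank' or 'fixed_n'")

    median = np.median(scores)
    best = None
    for cutoff in _candidate_cutoffs(scores):
        sens = scores >= cutoff
        n_s, n_r = int(sens.sum()), int((~sens).sum())
        if n_s < min_group or n_r < min_group:
            continue
        stat, p = logrank([(times[sens], events[sens]), (times[~sens], events[~sens])])
        key = (stat, -abs(cutoff - median))
        if best is None or key > best[0]:
            best = (key, cutoff, stat, p, n_s, n_r)
    if best is None:
        raise ValidationError(
            f"no cutoff leaves at least {min_group} patients in each group"
        )
    _, cutoff, stat, p, n_s, n_r = best
    return CutoffResult(
        cutoff=float(cutoff),
        statistic=float(stat),
        p_value=float(p),
        n_sensitive=n_s,
        n_resistant=n_r,
        data_optimized=True,
        mode=mode,
    )


def compare_relapse_survival(
    scores, cutoff: float, times, events, ci_level: float = 0.90
) -> dict[str, dict]:
    """Kaplan–Meier comparison of predicted-sensitive versus
    predicted-resistant relapse patients.

    Returns per-group curve, median and CI; both groups must be
    non-empty.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    calls = classify(scores, cutoff=cutoff)
    out: dict[str, dict] = {}
    for group in ("sensitive", "resistant"):
        mask = calls == group
        if not mask.any():
            raise ValidationError(
                f"all patients fall on one side of cutoff {cutoff}; "
                "no survival comparison possible"
            )
        curve = km_curve(times[mask], events[mask], ci_level=ci_level)
        median, ci = median_survival(curve, ci_level=ci_level)
        out[group] = {
            "n": int(mask.sum()),
            "curve": curve,
            "median": median,
            "ci": ci,
        }
    return out


def recommend_regimens(
    patient_id: str, score_table: pd.DataFrame, cutoff: float = 50.0
) -> pd.DataFrame:
    """Rank all panel regimens for one patient, best first.

    Ties in score break alphabetically by regimen label; calls use the
    supplied cutoff on the normalized scale.
    """
    if patient_id not in score_table.index:
        raise ValidationError(f"patient {patient_id!r} not in the score table")
    row = score_table.loc[patient_id]
    ranked = row.sort_index().sort_values(ascending=False, kind="stable")
    return pd.DataFrame(
        {
            "regimen": ranked.index,
            "normalized_score": ranked.to_numpy(),
            "call": classify(ranked.to_numpy(), cutoff=cutoff),
        }
    ).reset_index(drop=True)


def biopsy_concordance(primary_scores, relapse_scores) -> dict:
    """Concordance between paired primary and relapse biopsy scores.

    Returns the paired Pearson correlation (NaN when undefined, e.g. a
    single pair or zero variance) and the diagonal balance: counts of
    pairs where the relapse score exceeds, trails, or equals the primary
    score.  A balanced diagonal argues against systematic resistance
    drift under treatment.
    """
    x = np.asarray(primary_scores, dtype=float)
    y = np.asarray(relapse_scores, dtype=float)
    if x.size != y.size:
        raise ValidationError("paired score vectors must have equal length")
    if x.size == 0:
        raise ValidationError("no pairs")
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return {
        "r": r,
        "n": int(x.size),
        "above_diagonal": int((y > x).sum()),
        "below_diagonal": int((y < x).sum()),
        "on_diagonal": int((y == x).sum()),
    }


def post_relapse_survival(records: Sequence[PatientRecord]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Survival after progression for relapse patients.

    Returns (times, events, patient_ids) with time measured from
    progression (os_days − pfs_days) for every record flagged as
    relapse.
    """
    times, events, ids = [], [], []
    for r in records:
        if r.relapse:
            times.append(max(r.os_days - r.pfs_days, 0.0))
            events.append(r.os_event)
            ids.append(r.patient_id)
    if not ids:
        raise ValidationError("no relapse patients in the records")
    return np.asarray(times), np.asarray(events, dtype=bool), ids
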