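"""Synthetic cell-line panels and patient cohorts.

The generators emulate the statistical structure the pipeline assumes,
so every stage is testable without external downloads.

Cell-line panel: each cell line carries a latent chemosensitivity
``s ~ N(0,1)``; a drug's −log10(GI50) is a loading times ``s`` plus
assay noise, and each planted expression feature is ``gamma * s`` plus
noise on a log2 scale around a baseline of 7.  The three default drug
loadings mirror the observed pattern that vincristine and doxorubicin
dominate a CHOP signature while cyclophosphamide (an inactive prodrug
in vitro, with only a 2.8-fold GI50 spread) contributes little.

Patient cohort: a per-patient latent sensitivity drives the same
planted features and, together with the IPI, an ordinal response latent
that is thresholded into the clinical categories at the study cohort's
observed frequencies.  Survival is exponential with hazard increasing
in non-response and IPI; censoring is independent uniform.  A separate
subtype latent drives GCB/ABC features and a prognostic (not
predictive) survival effect.

All generators are pure functions of (params, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import (
    DrugResponsePanel,
    ExpressionMatrix,
    PatientRecord,
    ResponseSignature,
)
from .relapse import RegimenPanel

__all__ = [
    "PanelSimParams",
    "CohortSimParams",
    "RelapseSimParams",
    "simulate_cell_line_panel",
    "simulate_patient_cohort",
    "simulate_relapse_cohort",
    "response_thresholds",
]

DEFAULT_SEED = 20150218

#: study-cohort IPI distribution (counts over 116 patients)
IPI_COUNTS = (10, 28, 37, 18, 16, 7)
#: ordinal response category counts among the 111 evaluable patients,
#: worst to best (death before evaluation, progressive disease, stable
#: disease, partial remission, unconfirmed CR, CR)
ORDINAL_CATEGORY_COUNTS = {"Dead": 5, "PD": 2, "SD": 0, "PR": 5, "CRu": 42, "CR": 57}
_ORDINAL_ORDER = ("Dead", "PD", "SD", "PR", "CRu", "CR")
UNEVALUABLE_FRACTION = 5 / 116
TREATMENT_COUNTS = {"R-CHOP": 95, "R-CHOEP": 21}

RELAPSE_REGIMEN_POOL = ("COPE", "DHAP", "CVP", "HDMTX", "MVBCNS")
ALTERNATIVE_REGIMENS = ("ICE", "bendamustine")


def _feature_ids(n_features: int) -> list[str]:
    return [f"sim-miR-{i:04d}_st" for i in range(n_features)]


@dataclass
class PanelSimParams:
    """Conditions of the simulated cell-line screen.

    ``drug_loadings`` couple each drug's −log10(GI50) to the latent
    sensitivity; ``drug_noise_sd`` is the per-drug assay noise (the
    3-drug summed vector then carries noise sd ≈ 0.87, about one unit on
    the combination scale).  ``gamma`` couples planted features to the
    latent; ``noise_sd`` is the per-feature expression noise.
    """

    n_cell_lines: int = 60
    n_features: int = 1756
    n_informative: int = 20
    drug_loadings: dict = field(
        default_factory=lambda: {
            "vincristine": 0.6,
            "doxorubicin": 0.6,
            "cyclophosphamide": 0.1,
        }
    )
    gamma: float = 0.8
    noise_sd: float = 1.0
    drug_noise_sd: float = 0.5
    baseline: float = 7.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if not all(np.isfinite(list(self.drug_loadings.values()))):
            raise ValueError("drug loadings must be finite")


@dataclass
class PanelTruth:
    latent_sensitivity: pd.Series
    planted_features: tuple[str, ...]


def simulate_cell_line_panel(
    params: PanelSimParams | None = None,
) -> tuple[DrugResponsePanel, ExpressionMatrix, PanelTruth]:
    """Simulate a drug screen and matched baseline expression.

    Returns the −log10(GI50) panel, the cell-line expression matrix and
    the ground truth (latent sensitivities and planted feature ids) for
    recovery tests.
    """
    params = params or PanelSimParams()
    rng = np.random.default_rng(params.seed)
    cells = [f"CL{i:02d}" for i in range(1, params.n_cell_lines + 1)]
    s = rng.standard_normal(params.n_cell_lines)

    drug_rows = {}
    for drug, beta in params.drug_loadings.items():
        drug_rows[drug] = beta * s + params.drug_noise_sd * rng.standard_normal(
            params.n_cell_lines
        )
    panel = DrugResponsePanel(
        pd.DataFrame(drug_rows, index=cells).T + 6.0  # typical micromolar scale
    )

    features = _feature_ids(params.n_features)
    planted = tuple(features[: params.n_informative])
    expr = params.baseline + params.noise_sd * rng.standard_normal(
        (params.n_features, params.n_cell_lines)
    )
    expr[: params.n_informative] += params.gamma * s
    matrix = ExpressionMatrix(pd.DataFrame(expr, index=features, columns=cells))
    truth = PanelTruth(
        latent_sensitivity=pd.Series(s, index=cells), planted_features=planted
    )
    return panel, matrix, truth


@dataclass
class CohortSimParams:
    """Conditions of the simulated patient cohort.

    Effect sizes: ``a1`` couples the latent sensitivity to the ordinal
    response latent and ``a2`` couples the IPI to it (both calibrated
    once so that the score-response correlation sits near the observed
    ≈0.24 at n = 116, then frozen).  Response-category thresholds are
    computed analytically from the latent mixture CDF at the study
    frequencies.  Survival hazards (per day) were calibrated once
    against the study margins — about 19% deaths, about 12% relapses,
    median observation ≈ 1270 days — and frozen.
    """

    n_patients: int = 116
    ipi_probs: tuple = tuple(np.asarray(IPI_COUNTS) / sum(IPI_COUNTS))
    treatment_probs: dict = field(
        default_factory=lambda: {
            t: c / sum(TREATMENT_COUNTS.values()) for t, c in TREATMENT_COUNTS.items()
        }
    )
    a1: float = 0.5
    a2: float = 0.5
    response_noise_sd: float = 1.0
    n_features: int = 1756
    n_informative: int = 20
    n_gcb: int = 10
    n_abc: int = 8
    gamma: float = 0.8
    delta: float = 0.8
    noise_sd: float = 1.0
    baseline: float = 7.0
    unevaluable_fraction: float = UNEVALUABLE_FRACTION
    base_hazard: float = np.log(2) / 12000.0
    ipi_log_hr: float = 0.25
    nonresponder_log_hr: float = 1.2
    gcb_log_hr: float = 0.3
    dead_median_days: float = 60.0
    prog_base_hazard: float = np.log(2) / 15000.0
    prog_ipi_log_hr: float = 0.2
    prog_nonresponder_log_hr: float = 1.5
    censor_window: tuple = (600.0, 2400.0)
    relapse_regimen_pool: tuple = RELAPSE_REGIMEN_POOL
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        probs = np.asarray(self.ipi_probs, dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("ipi_probs must be a probability vector")
        for h in (self.base_hazard, self.prog_base_hazard):
            if not h > 0:
                raise ValueError("hazards must be positive")
        if self.n_informative + self.n_gcb + self.n_abc > self.n_features:
            raise ValueError("planted feature groups exceed n_features")


def response_thresholds(params: CohortSimParams) -> np.ndarray:
    """Ordinal thresholds hitting the study category frequencies.

    The response latent is ``u = a1*s − a2*IPI + eps`` so, conditional
    on IPI, ``u`` is normal; the marginal CDF is a mixture over the IPI
    distribution.  Thresholds are the mixture quantiles at the
    cumulative category frequencies (deterministic, no sampling).
    """
    counts = np.asarray([ORDINAL_CATEGORY_COUNTS[c] for c in _ORDINAL_ORDER], float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    sd_u = float(np.hypot(params.a1, params.response_noise_sd))
    probs = np.asarray(params.ipi_probs)

    def mixture_cdf(t: float) -> float:
        return float(
            np.sum(probs * stats.norm.cdf((t + params.a2 * np.arange(6)) / sd_u))
        )

    lo, hi = -50.0, 50.0
    return np.asarray(
        [optimize.brentq(lambda t, c=c: mixture_cdf(t) - c, lo, hi) for c in cum]
    )


@dataclass
class CohortTruth:
    latent_sensitivity: pd.Series
    subtype_latent: pd.Series
    planted_features: tuple[str, ...]
    gcb_features: tuple[str, ...]
    abc_features: tuple[str, ...]
    ordinal_category: pd.Series
    responder: pd.Series


def simulate_patient_cohort(
    params: CohortSimParams | None = None,
) -> tuple[ExpressionMatrix, list[PatientRecord], CohortTruth]:
    """Simulate a treated cohort: expression, clinical records, truth.

    Planted features occupy the same identifiers as in the cell-line
    generator, so a signature built on a simulated screen scores a
    simulated cohort end-to-end.
    """
    params = params or CohortSimParams()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    ids = [f"P{i:03d}" for i in range(1, n + 1)]

    ipi = rng.choice(6, size=n, p=np.asarray(params.ipi_probs))
    s = rng.standard_normal(n)
    g = rng.standard_normal(n)
    treatments = rng.choice(
        list(params.treatment_probs),
        size=n,
        p=list(params.treatment_probs.values()),
    )

    u = (
        params.a1 * s
        - params.a2 * ipi
        + params.response_noise_sd * rng.standard_normal(n)
    )
    thresholds = response_thresholds(params)
    cat_idx = np.searchsorted(thresholds, u)
    categories = np.asarray(_ORDINAL_ORDER, dtype=object)[cat_idx]
    responder = np.isin(categories, ["CR", "CRu"])
    unevaluable = rng.random(n) < params.unevaluable_fraction
    observed_response = np.where(unevaluable, "Unevaluable", categories)

    # expression: planted sensitivity features, subtype features, nulls
    features = _feature_ids(params.n_features)
    planted = tuple(features[: params.n_informative])
    gcb = tuple(features[params.n_informative : params.n_informative + params.n_gcb])
    abc = tuple(
        features[
            params.n_informative
            + params.n_gcb : params.n_informative
            + params.n_gcb
            + params.n_abc
        ]
    )
    expr = params.baseline + params.noise_sd * rng.standard_normal(
        (params.n_features, n)
    )
    expr[: params.n_informative] += params.gamma * s
    i0 = params.n_informative
    expr[i0 : i0 + params.n_gcb] += params.delta * g
    expr[i0 + params.n_gcb : i0 + params.n_gcb + params.n_abc] -= params.delta * g
    matrix = ExpressionMatrix(pd.DataFrame(expr, index=features, columns=ids))

    # survival (days from diagnosis)
    hazard_death = params.base_hazard * np.exp(
        params.ipi_log_hr * ipi
        + params.nonresponder_log_hr * (~responder)
        - params.gcb_log_hr * g
    )
    hazard_death = np.where(
        categories == "Dead", np.log(2) / params.dead_median_days, hazard_death
    )
    t_death = rng.exponential(1.0 / hazard_death)
    hazard_prog = params.prog_base_hazard * np.exp(
        params.prog_ipi_log_hr * ipi
        + params.prog_nonresponder_log_hr * (~responder)
    )
    t_prog = rng.exponential(1.0 / hazard_prog)
    censor = rng.uniform(*params.censor_window, size=n)

    os_days = np.minimum(t_death, censor)
    os_event = t_death <= censor
    t_pfs = np.minimum(t_prog, t_death)
    pfs_days = np.minimum(t_pfs, censor)
    pfs_event = t_pfs <= censor
    relapse = (t_prog < t_death) & (t_prog <= censor) & (categories != "Dead")

    records = []
    for i, pid in enumerate(ids):
        regimens: tuple[str, ...] = ()
        if relapse[i]:
            k = 1 + int(rng.random() < 0.5)
            regimens = tuple(
                rng.choice(params.relapse_regimen_pool, size=k, replace=False)
            )
        records.append(
            PatientRecord(
                patient_id=pid,
                ipi=int(ipi[i]),
                treatment=str(treatments[i]),
                response=str(observed_response[i]),
                os_days=float(os_days[i]),
                os_event=bool(os_event[i]),
                pfs_days=float(pfs_days[i]),
                pfs_event=bool(pfs_event[i]),
                relapse=bool(relapse[i]),
                relapse_regimens=regimens,
            )
        )
    truth = CohortTruth(
        latent_sensitivity=pd.Series(s, index=ids),
        subtype_latent=pd.Series(g, index=ids),
        planted_features=planted,
        gcb_features=gcb,
        abc_features=abc,
        ordinal_category=pd.Series(categories, index=ids),
        responder=pd.Series(responder, index=ids),
    )
    return matrix, records, truth


@dataclass
class RelapseSimParams:
    """Conditions of the simulated relapse cohort (matched biopsy pairs).

    Each patient holds a latent sensitivity per candidate regimen
    (correlated across regimens through a shared component with weight
    ``shared_rho``).  The relapse biopsy equals the primary biopsy plus
    independent per-feature drift noise — no systematic resistance
    shift, so pairs scatter symmetrically about the diagonal.
    Post-relapse survival is exponential with log-hazard decreasing in
    the patient's mean latent sensitivity to the regimens received.
    """

    n_patients: int = 13
    n_features: int = 1756
    n_per_regimen: int = 20
    regimens: tuple = RELAPSE_REGIMEN_POOL + ALTERNATIVE_REGIMENS
    received_pool: tuple = RELAPSE_REGIMEN_POOL
    shared_rho: float = 0.5
    gamma: float = 0.8
    noise_sd: float = 1.0
    drift_sd: float = 1.0
    baseline: float = 7.0
    base_median_days: float = 600.0
    survival_log_hr: float = 0.9
    censor_horizon_days: float = 2000.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_per_regimen * len(self.regimens) > self.n_features:
            raise ValueError("regimen planted sets exceed n_features")
        if not 0 <= self.shared_rho <= 1:
            raise ValueError("shared_rho must lie in [0, 1]")


@dataclass
class RelapseSim:
    primary: ExpressionMatrix
    relapse: ExpressionMatrix
    records: list[PatientRecord]
    panel: RegimenPanel
    regimen_latents: pd.DataFrame
    received_mean_latent: pd.Series


def simulate_relapse_cohort(params: RelapseSimParams | None = None) -> RelapseSim:
    """Simulate matched primary/relapse biopsy pairs of relapse patients.

    Returns the two expression matrices, post-relapse clinical records
    (OS measured from diagnosis; time from progression to death is
    ``os_days − pfs_days``), the regimen signature panel and the latent
    truth.  Panel signatures list each regimen's planted features with
    their population selection correlation ``gamma / sqrt(gamma² +
    noise²)`` as nominal entries.
    """
    params = params or RelapseSimParams()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    ids = [f"R{i:02d}" for i in range(1, n + 1)]
    regimens = list(params.regimens)

    shared = rng.standard_normal(n)
    latents = {}
    for reg in regimens:
        own = rng.standard_normal(n)
        latents[reg] = params.shared_rho * shared + np.sqrt(
            1 - params.shared_rho**2
        ) * own
    latent_df = pd.DataFrame(latents, index=ids)

    features = _feature_ids(params.n_features)
    expr = params.baseline + params.noise_sd * rng.standard_normal(
        (params.n_features, n)
    )
    signatures = {}
    nominal_r = params.gamma / float(np.hypot(params.gamma, params.noise_sd))
    for j, reg in enumerate(regimens):
        block = slice(j * params.n_per_regimen, (j + 1) * params.n_per_regimen)
        expr[block] += params.gamma * latent_df[reg].to_numpy()
        signatures[reg] = ResponseSignature(
            treatment_name=reg,
            entries=tuple((f, nominal_r) for f in features[block]),
            threshold=0.25,
        )
    primary = ExpressionMatrix(pd.DataFrame(expr, index=features, columns=ids))
    relapse_expr = ExpressionMatrix(
        pd.DataFrame(
            expr + params.drift_sd * rng.standard_normal(expr.shape),
            index=features,
            columns=ids,
        )
    )

    received = []
    for _ in ids:
        k = 1 + int(rng.random() < 0.5)
        received.append(tuple(rng.choice(params.received_pool, size=k, replace=False)))
    z = np.asarray(
        [latent_df.loc[pid, list(regs)].mean() for pid, regs in zip(ids, received)]
    )

    rate = (np.log(2) / params.base_median_days) * np.exp(-params.survival_log_hr * z)
    t_post = rng.exponential(1.0 / rate)
    post_days = np.minimum(t_post, params.censor_horizon_days)
    event = t_post <= params.censor_horizon_days
    time_to_relapse = rng.uniform(100.0, 800.0, size=n)

    records = []
    for i, pid in enumerate(ids):
        records.append(
            PatientRecord(
                patient_id=pid,
                ipi=int(rng.choice(6, p=np.asarray(IPI_COUNTS) / sum(IPI_COUNTS))),
                treatment="R-CHOP",
                response=str(rng.choice(["CR", "CRu"])),
                os_days=float(time_to_relapse[i] + post_days[i]),
                os_event=bool(event[i]),
                pfs_days=float(time_to_relapse[i]),
                pfs_event=True,
                relapse=True,
                relapse_regimens=received[i],
            )
        )
    return RelapseSim(
        primary=primary,
        relapse=relapse_expr,
        records=records,
        panel=RegimenPanel(signatures),
        regimen_latents=latent_df,
        received_mean_latent=pd.Series(z, index=ids),
    )


def truth_to_json(truth, path) -> None:
    """Serialize a truth object (planted ids and latent values) to JSON."""
    def _convert(obj):
        if isinstance(obj, pd.Series):
            return obj.to_dict()
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict()
        if isinstance(obj, tuple):
            return list(obj)
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    data = {k: _convert(v) for k, v in asdict(truth).items()}
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, default=_convert)
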