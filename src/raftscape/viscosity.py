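"""Perrin-equation apparent microviscosity of raft membranes.

Steady-state fluorescence anisotropy of a membrane-anchored probe
(TMA-DPH) reports rotational restriction at the membrane plane.  Under
the steady-state Perrin convention for DPH-family probes the apparent
microviscosity is

    eta_app = C * r / (r0 - r)

where ``r`` is the measured anisotropy, ``r0`` the limiting (frozen)
anisotropy of the probe (default 0.362 for TMA-DPH) and ``C`` a
calibration constant in poise (default 2.4).  The map is strictly
increasing on [0, r0) and has the exact inverse r = r0*eta/(C + eta).

Because the anisotropy <-> viscosity transform only rescales, every
relative quantity (percent fluidity change, Cohen's d between groups)
is invariant to the calibration constant.

The module also ships a linear composition -> viscosity regression
(ordinary least squares of eta on a configurable set of derived lipid
indexes), used both to fit observed anisotropies and, in reverse, by the
synthetic generator to forward-synthesize them.  Membrane fluidity is
taken as 1/eta, so a viscosity decrease reads as a percent fluidity
increase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .lipid_core import DerivedIndexSet, SubjectRecord
from .stats_pipeline import cohens_d

__all__ = [
    "ViscosityParams",
    "ViscosityResult",
    "perrin_viscosity",
    "anisotropy_from_viscosity",
    "predict_viscosity",
    "fit_viscosity_model",
    "compare_group_viscosity",
    "calibrate_intercept",
    "DEFAULT_PREDICTORS",
]

#: default predictor set: the indexes reported to drive the fluidity change
DEFAULT_PREDICTORS = ("sat_unsat_ratio", "total_n6_lcpufa", "pct_18_1n9")

#: default slope coefficients (poise per unit), chosen with conventional
#: signs — a higher saturate/unsaturate ratio stiffens the membrane, more
#: n-6 LCPUFA and more oleate fluidify it — and with magnitudes giving the
#: three predictors comparable contributions to the cohort-scale viscosity
#: variation, so each is identifiable from realistic data.
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "sat_unsat_ratio": 4.0,
    "total_n6_lcpufa": -0.3,
    "pct_18_1n9": -0.2,
}


@dataclass
class ViscosityParams:
    """Perrin constants plus the linear composition model."""

    r0: float = 0.362
    calib_c: float = 2.4
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    intercept: float = 0.0
    r_squared: float = float("nan")
    coef_se: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.r0 < 0.4):
            raise ValueError(f"r0 must lie in (0, 0.4), got {self.r0}")
        if self.calib_c <= 0:
            raise ValueError(f"calibration constant must be positive, got {self.calib_c}")


@dataclass
class ViscosityResult:
    """Group comparison of apparent microviscosity."""

    eta_app: dict[str, float]
    group_means: dict[str, float]
    pct_fluidity_change: float
    effect_d: float
    effect_ci: tuple[float, float]
    groups: tuple[str, str]  # (reference, contrast)


def perrin_viscosity(r: float | np.ndarray, params: ViscosityParams) -> float | np.ndarray:
    """eta_app = C * r / (r0 - r); domain 0 <= r < r0."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr >= params.r0):
        raise ValueError(f"anisotropy must lie in [0, r0={params.r0}), got {r!r}")
    out = params.calib_c * r_arr / (params.r0 - r_arr)
    return float(out) if np.isscalar(r) else out


def anisotropy_from_viscosity(eta: float | np.ndarray, params: ViscosityParams) -> float | np.ndarray:
    """Exact inverse of :func:`perrin_viscosity`: r = r0*eta/(C + eta)."""
    eta_arr = np.asarray(eta, dtype=float)
    if np.any(eta_arr < 0):
        raise ValueError(f"viscosity must be non-negative, got {eta!r}")
    out = params.r0 * eta_arr / (params.calib_c + eta_arr)
    return float(out) if np.isscalar(eta) else out


def _predictor_value(idx: DerivedIndexSet, record: SubjectRecord | None, name: str) -> float:
    if name == "pct_18_1n9":
        if record is not None:
            return float(record.fatty_acids.values.get("18:1n-9", 0.0))
        raise ValueError("pct_18_1n9 needs the full subject record")
    if name in ("CHO", "SM"):
        if record is not None:
            return record.lipid_classes.get(name)
        raise ValueError(f"{name} needs the full subject record")
    try:
        return float(getattr(idx, name))
    except AttributeError as exc:
        raise ValueError(f"unknown viscosity predictor {name!r}") from exc


def _design(records: Sequence[SubjectRecord], predictors: Sequence[str]) -> np.ndarray:
    rows = []
    for rec in records:
        idx = rec.indexes()
        rows.append([_predictor_value(idx, rec, p) for p in predictors])
    return np.asarray(rows, dtype=float)


def predict_viscosity(
    idx: DerivedIndexSet, params: ViscosityParams, record: SubjectRecord | None = None
) -> float:
    """eta from the linear composition model for one subject."""
    eta = params.intercept
    for name, beta in params.coefficients.items():
        eta += beta * _predictor_value(idx, record, name)
    return float(eta)


def predict_cohort_viscosity(
    records: Sequence[SubjectRecord], params: ViscosityParams
) -> dict[str, float]:
    X = _design(records, list(params.coefficients))
    beta = np.array([params.coefficients[p] for p in params.coefficients])
    eta = params.intercept + X @ beta
    return {rec.subject_id: float(e) for rec, e in zip(records, eta)}


def calibrate_intercept(
    records: Sequence[SubjectRecord],
    params: ViscosityParams,
    target_pct_fluidity: float = 14.8,
    reference: str = "NSL",
    contrast: str = "ALS",
) -> ViscosityParams:
    """Solve the model intercept so the group fluidity contrast hits a target.

    With fixed slopes, the intercept shifts both group-mean viscosities
    equally; the intercept making eta_ref/eta_con = 1 + target/100 (at the
    group means of the linear predictor) is solved in closed form.  Used
    by the synthetic generator to pin the planted fluidity change.
    """
    X = _design(records, list(params.coefficients))
    beta = np.array([params.coefficients[p] for p in params.coefficients])
    lin = X @ beta
    labels = np.array([r.group for r in records])
    l_ref = float(lin[labels == reference].mean())
    l_con = float(lin[labels == contrast].mean())
    rho = 1.0 + target_pct_fluidity / 100.0
    if abs(rho - 1.0) < 1e-12:
        raise ValueError("target fluidity change must be nonzero")
    b0 = (l_ref - rho * l_con) / (rho - 1.0)
    eta_con = b0 + l_con
    if eta_con <= 0 or b0 + l_ref <= 0:
        raise ValueError("calibrated intercept yields non-positive viscosity")
    out = ViscosityParams(
        r0=params.r0,
        calib_c=params.calib_c,
        coefficients=dict(params.coefficients),
        intercept=b0,
    )
    return out


def fit_viscosity_model(
    records: Sequence[SubjectRecord],
    eta_obs: Mapping[str, float],
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    r0: float = 0.362,
    calib_c: float = 2.4,
    condition_threshold: float = 1e8,
) -> ViscosityParams:
    """OLS of observed eta on the configured predictor set.

    Requires at least p+2 subjects for p predictors; refuses collinear
    designs (condition number above ``condition_threshold``), naming the
    most strongly coupled predictor pair.
    """
    recs = [r for r in records if r.subject_id in eta_obs]
    p = len(predictors)
    if len(recs) < p + 2:
        raise ValueError(f"need at least {p + 2} subjects for {p} predictors, got {len(recs)}")
    X = _design(recs, predictors)
    y = np.array([eta_obs[r.subject_id] for r in recs], dtype=float)
    Xc = sm.add_constant(X)
    if np.linalg.cond(Xc) > condition_threshold:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"collinear predictors: {predictors[i]!r} and {predictors[j]!r} "
            f"(|r|={abs(corr[i, j]):.4f})"
        )
    fit = sm.OLS(y, Xc).fit()
    coefs = {name: float(b) for name, b in zip(predictors, fit.params[1:])}
    ses = {name: float(s) for name, s in zip(predictors, fit.bse[1:])}
    return ViscosityParams(
        r0=r0,
        calib_c=calib_c,
        coefficients=coefs,
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        coef_se=ses,
    )


def compare_group_viscosity(
    records: Sequence[SubjectRecord],
    params: ViscosityParams | None = None,
    eta_obs: Mapping[str, float] | None = None,
    reference: str = "NSL",
    contrast: str = "ALS",
) -> ViscosityResult:
    """Percent fluidity change and effect size of eta between groups.

    Fluidity is 1/eta; pct change = 100*(mean fluidity contrast group /
    mean fluidity reference group - 1).  Cohen's d follows the pipeline
    sign convention (reference minus contrast), so a viscosity drop in
    the contrast group gives a positive d.
    """
    if eta_obs is None:
        if params is None:
            raise ValueError("need either fitted params or observed eta")
        eta_obs = predict_cohort_viscosity(records, params)
    eta = {r.subject_id: float(eta_obs[r.subject_id]) for r in records}
    if any(e <= 0 for e in eta.values()):
        bad = [s for s, e in eta.items() if e <= 0]
        raise ValueError(f"non-positive viscosity for subjects {bad}")
    ref = np.array([eta[r.subject_id] for r in records if r.group == reference])
    con = np.array([eta[r.subject_id] for r in records if r.group == contrast])
    if len(ref) == 0 or len(con) == 0:
        raise ValueError(f"both groups {reference!r} and {contrast!r} must be present")
    fl_ref = float(np.mean(1.0 / ref))
    fl_con = float(np.mean(1.0 / con))
    pct = 100.0 * (fl_con / fl_ref - 1.0)
    es = cohens_d(ref, con)
    return ViscosityResult(
        eta_app=eta,
        group_means={reference: float(ref.mean()), contrast: float(con.mean())},
        pct_fluidity_change=pct,
        effect_d=es.d,
        effect_ci=(es.ci_low, es.ci_high),
        groups=(reference, contrast),
    )
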