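"""Quasi-stiffness, excursion, and propulsive-work extraction.

The quasi-stiffness of a phase is the slope of the ordinary-least-squares
line fit to that phase's moment-angle points. The propulsive work is the
area enclosed by the moment-angle loop over the progression period b–e,
computed with the shoelace rule; an equivalent closed form from the fitted
transition moments and excursions is

    E = ½ |M_d·(Γ_pf − Γ_dl,signed) − M_c·(Γ_df + Γ_dl,signed)|.

Near the singular gait speed the dual-flexion excursion vanishes, the
regression line becomes vertical, and the joint theoretically locks with
infinite quasi-stiffness; such segments are flagged rather than fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import PhaseSegment
from .types import DomainError, GaitTrial, JointSummary, PhaseLandmarks

#: dual excursions below this magnitude (rad) are treated as singular.
SINGULAR_EXCURSION_RAD = 1e-4


@dataclass(frozen=True)
class PhaseFit:
    slope: float  # N·m/rad
    intercept: float  # N·m
    r2: float
    singular: bool = False


def fit_phase_line(
    angle: np.ndarray | PhaseSegment,
    moment: np.ndarray | None = None,
    singular_tol: float = SINGULAR_EXCURSION_RAD,
) -> PhaseFit:
    """OLS line fit of moment on angle over one phase.

    Accepts either a :class:`PhaseSegment` or raw (angle, moment) arrays.
    A segment whose angle spread is below ``singular_tol`` is reported as
    singular: slope and intercept are non-finite and no fit is attempted
    (the joint effectively locks there).
    """
    if isinstance(angle, PhaseSegment):
        seg = angle
        angle, moment = seg.angle, seg.moment
    angle = np.asarray(angle, dtype=float)
    moment = np.asarray(moment, dtype=float)
    if angle.size < 3:
        raise DomainError(f"phase fit needs >= 3 samples, got {angle.size}")
    if np.ptp(angle) < singular_tol:
        return PhaseFit(np.inf, np.nan, np.nan, singular=True)
    slope, intercept = np.polyfit(angle, moment, 1)
    resid = moment - (slope * angle + intercept)
    ss_tot = float(np.sum((moment - moment.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return PhaseFit(float(slope), float(intercept), float(r2))


def excursion(angle: np.ndarray | PhaseSegment) -> dict:
    """Signed and magnitude angular excursion of a phase.

    Signed = final angle − initial angle, so the result is independent of
    the absolute joint angle.
    """
    if isinstance(angle, PhaseSegment):
        angle = angle.angle
    angle = np.asarray(angle, dtype=float)
    if angle.size < 2:
        raise DomainError("excursion needs >= 2 samples")
    signed = float(angle[-1] - angle[0])
    return {"signed": signed, "magnitude": abs(signed)}


def loop_work(trial: GaitTrial, lm: PhaseLandmarks) -> float:
    """Area enclosed by the moment-angle loop over b..e (shoelace rule).

    The polygon is the sampled path b..e closed by the chord e→b; the
    absolute enclosed area in joules is returned. Noisy, self-intersecting
    loops still return the (signed-sum) shoelace value.
    """
    sl = slice(lm.idx_b, lm.idx_e + 1)
    x = trial.angle[sl]
    y = trial.moment[sl]
    return abs(_shoelace(x, y))


def _shoelace(x: np.ndarray, y: np.ndarray) -> float:
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def work_from_fits(
    M_c: float,
    M_d: float,
    Gamma_df: float,
    Gamma_dl_signed: float,
    Gamma_pf: float,
) -> float:
    """Propulsive work of the idealized piecewise-linear loop.

    Equals the shoelace area of the quadrilateral (0, 0), (Γ_df, M_c),
    (Γ_df+Γ_dl,signed, M_d), (Γ_df+Γ_dl,signed−Γ_pf, 0).
    """
    if Gamma_df < 0 or Gamma_pf < 0:
        raise DomainError("Gamma_df and Gamma_pf must be >= 0")
    return 0.5 * abs(
        M_d * (Gamma_pf - Gamma_dl_signed) - M_c * (Gamma_df + Gamma_dl_signed)
    )


def summarize_trial(
    trial: GaitTrial,
    lm: PhaseLandmarks,
    singular_tol: float = SINGULAR_EXCURSION_RAD,
) -> JointSummary:
    """Extract the full per-trial summary from a segmented trial.

    ``E_loop`` integrates the raw samples (shoelace); ``E_fit`` uses the
    fitted-line transition moments evaluated at the phase excursions.
    """
    from .segmentation import slice_phases

    dorsi, dual, plantar = slice_phases(trial, lm)
    fit_df = fit_phase_line(dorsi, singular_tol=singular_tol)
    fit_dl = fit_phase_line(dual, singular_tol=singular_tol)
    fit_pf = fit_phase_line(plantar, singular_tol=singular_tol)
    exc_df = excursion(dorsi)
    exc_dl = excursion(dual)
    exc_pf = excursion(plantar)

    # transition moments from the fitted lines, evaluated at the landmarks
    th_c = trial.angle[lm.idx_c]
    th_d = trial.angle[lm.idx_d]
    M_c_fit = fit_df.slope * th_c + fit_df.intercept
    M_d_fit = fit_pf.slope * th_d + fit_pf.intercept
    E_fit = (
        work_from_fits(
            M_c_fit, M_d_fit, exc_df["magnitude"], exc_dl["signed"], exc_pf["magnitude"]
        )
        if np.isfinite(M_c_fit) and np.isfinite(M_d_fit)
        else np.nan
    )

    return JointSummary(
        subject_id=trial.subject_id,
        speed=trial.speed,
        K_df=fit_df.slope,
        K_dl=fit_dl.slope,
        K_pf=fit_pf.slope,
        Gamma_df=exc_df["magnitude"],
        Gamma_dl=exc_dl["magnitude"],
        Gamma_pf=exc_pf["magnitude"],
        Gamma_dl_signed=exc_dl["signed"],
        r2_df=fit_df.r2,
        r2_dl=fit_dl.r2,
        r2_pf=fit_pf.r2,
        E_loop=loop_work(trial, lm),
        E_fit=float(E_fit),
        singular=fit_dl.singular or exc_dl["magnitude"] < singular_tol,
    )
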