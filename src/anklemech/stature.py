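"""Stature-based model reduction.

Walkers of different sizes prefer a common Froude number
Fr = V²/(g·l) ≈ 0.25, and the leg length scales with height as
l ≈ 0.53·H, so the preferred speed is predicted from stature alone:

    V_opt(H) = sqrt(Fr_opt · g · 0.53 · H).

Substituting V_opt for the speed and cohort-mean preferred-speed excursions
for the Γ's reduces a general-form model (in W, H, V, Γ) to a *stature-based*
model in W and H only: each monomial W^a·H^b·V^c·Γ^d collapses to
κ^c·Γ̄^d · W^a·H^(b+c/2) with κ = sqrt(Fr_opt·g·0.53). Stature-based models
are intended for sizing assistive devices around the preferred speed; the
dual-flexion reduction is flagged low-confidence because that stiffness is
highly excursion-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import FittedModel, Term
from .types import DomainError, JointSummary, SubjectProfile, cohort_by_id

FROUDE_OPT = 0.25
LEG_COEFF = 0.53
G = 9.81


def optimal_speed(
    H: float,
    froude_opt: float = FROUDE_OPT,
    leg_coeff: float = LEG_COEFF,
    g: float = G,
) -> float:
    """Froude-optimal ("preferred") walking speed for a given height."""
    if H <= 0:
        raise DomainError(f"height must be > 0, got {H}")
    return float(np.sqrt(froude_opt * g * leg_coeff * H))


@dataclass(frozen=True)
class MeanExcursions:
    """Cohort-mean phase excursions at the preferred speed (rad).

    ``dl_signed`` keeps the dual-phase direction (positive below the
    singular speed); df and pf are magnitudes.
    """

    df: float
    dl_signed: float
    pf: float

    def as_gammas(self) -> dict[str, float]:
        return {"df": self.df, "dl": self.dl_signed, "pf": self.pf}


def nearest_preferred_trials(
    summaries: Sequence[JointSummary],
    cohort: Sequence[SubjectProfile],
    froude_opt: float = FROUDE_OPT,
    leg_coeff: float = LEG_COEFF,
    g: float = G,
) -> dict[str, JointSummary]:
    """Per subject, the trial whose speed is closest to the Froude-optimal
    speed for that subject's height; exact ties go to the slower trial."""
    subjects = cohort_by_id(cohort)
    best: dict[str, JointSummary] = {}
    for s in summaries:
        subj = subjects.get(s.subject_id)
        if subj is None:
            raise DomainError(f"unknown subject {s.subject_id!r}")
        v_opt = optimal_speed(subj.height, froude_opt, leg_coeff, g)
        cur = best.get(s.subject_id)
        if cur is None:
            best[s.subject_id] = s
            continue
        d_new, d_cur = abs(s.speed - v_opt), abs(cur.speed - v_opt)
        if d_new < d_cur or (d_new == d_cur and s.speed < cur.speed):
            best[s.subject_id] = s
    return best


def mean_excursions_at_preferred(
    selected: Sequence[JointSummary] | dict[str, JointSummary],
) -> MeanExcursions:
    """Arithmetic mean excursions over the preferred-speed trials."""
    if isinstance(selected, dict):
        selected = list(selected.values())
    if len(selected) == 0:
        raise DomainError("empty preferred-trial selection")
    return MeanExcursions(
        df=float(np.mean([s.Gamma_df for s in selected])),
        dl_signed=float(np.mean([s.Gamma_dl_signed for s in selected])),
        pf=float(np.mean([s.Gamma_pf for s in selected])),
    )


@dataclass
class StatureModel:
    """A general-form model reduced to weight and height only.

    ``reduced`` maps (w_exp, h_half_exp) to a coefficient, where the
    monomial is W^w_exp · H^(h_half_exp/2); half-integer height exponents
    arise from V_opt ∝ sqrt(H).
    """

    response: str
    froude_opt: float
    leg_coeff: float
    g: float
    mean_excursions: MeanExcursions
    reduced: dict[tuple[int, int], float]
    low_confidence: bool = False
    source_terms: list[str] = field(default_factory=list)

    def predict(self, W: float, H: float) -> float:
        if W <= 0 or H <= 0:
            raise DomainError("W and H must be > 0")
        return float(
            sum(c * W**w * H ** (hh / 2.0) for (w, hh), c in self.reduced.items())
        )

    def formula(self) -> str:
        parts = []
        for (w, hh), c in sorted(self.reduced.items()):
            mono = []
            if w:
                mono.append("W" if w == 1 else f"W^{w}")
            if hh:
                mono.append("H" if hh == 2 else f"H^{hh / 2:g}")
            parts.append(f"{c:+.4g}" + ("*" + "*".join(mono) if mono else ""))
        return " ".join(parts) if parts else "0"

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "froude_opt": self.froude_opt,
            "leg_coeff": self.leg_coeff,
            "g": self.g,
            "mean_excursions": {
                "df": self.mean_excursions.df,
                "dl_signed": self.mean_excursions.dl_signed,
                "pf": self.mean_excursions.pf,
            },
            "reduced": [
                {"w_exp": w, "h_exp": hh / 2.0, "coeff": c}
                for (w, hh), c in sorted(self.reduced.items())
            ],
            "formula": self.formula(),
            "low_confidence": self.low_confidence,
            "source_terms": self.source_terms,
        }


def reduce_model(
    model: FittedModel,
    mean_excursions: MeanExcursions,
    froude_opt: float = FROUDE_OPT,
    leg_coeff: float = LEG_COEFF,
    g: float = G,
) -> StatureModel:
    """Substitute V = V_opt(H) and Γ = Γ̄ into a fitted general-form model.

    The substitution is exact: at the operating point
    (W, H, V_opt(H), Γ̄) the reduced model reproduces the source model's
    prediction to machine precision.
    """
    kappa = float(np.sqrt(froude_opt * g * leg_coeff))
    gbar = mean_excursions.as_gammas()
    terms = {t.name: t for t in model.basis.all_terms}
    reduced: dict[tuple[int, int], float] = {}
    for name, coeff in model.coefficients.items():
        t: Term = terms[name]
        c = coeff * kappa**t.v
        if t.phase is not None and t.g_exp != 0:
            gv = gbar[t.phase]
            if gv == 0:
                raise DomainError(
                    f"cannot reduce term {name}: zero mean excursion {t.phase}"
                )
            c *= gv**t.g_exp
        key = (t.w, 2 * t.h + t.v)  # H exponent in halves
        reduced[key] = reduced.get(key, 0.0) + c
    return StatureModel(
        response=model.basis.response,
        froude_opt=froude_opt,
        leg_coeff=leg_coeff,
        g=g,
        mean_excursions=mean_excursions,
        reduced=reduced,
        low_confidence=model.basis.response == "K_dl",
        source_terms=list(model.coefficients),
    )
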