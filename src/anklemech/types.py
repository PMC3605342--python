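"""Core domain containers for stance-phase ankle mechanics.

Conventions used throughout the package: angles are in radians with
dorsiflexion positive; moments are in N·m with the extensor
(plantar-flexor) moment positive; quasi-stiffness is the slope of the
moment-angle regression line in N·m/rad; work is in joules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class DomainError(ValueError):
    """Invalid domain object or argument."""


@dataclass(frozen=True)
class SubjectProfile:
    """One walker: identity, stature, and speed landmarks.

    ``preferred_speed`` is the Froude-optimal walking speed predicted from
    height; ``singular_speed`` is the (subject-specific) speed at which the
    dual-flexion excursion changes sign and the dual-phase quasi-stiffness
    diverges. It lies above the preferred speed.
    """

    subject_id: str
    weight: float  # body mass, kg
    height: float  # m
    preferred_speed: float  # m/s
    singular_speed: float  # m/s

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise DomainError(f"weight must be > 0, got {self.weight}")
        if self.height <= 0:
            raise DomainError(f"height must be > 0, got {self.height}")
        if self.singular_speed <= self.preferred_speed:
            raise DomainError(
                "singular_speed must exceed preferred_speed "
                f"({self.singular_speed} <= {self.preferred_speed})"
            )


@dataclass(frozen=True)
class GenerativeTruth:
    """Ground-truth loop geometry and mechanics for one synthetic trial.

    ``M_c`` / ``M_d`` are the sagittal ankle moments at the dorsi→dual and
    dual→plantar transitions; the Γ's are phase excursions (``Gamma_dl_signed``
    carries the dual-phase direction: positive below the singular speed,
    negative above it). Stiffnesses and work follow from the piecewise-linear
    loop:

        K_df = M_c / Γ_df
        K_dl = (M_d − M_c) / Γ_dl,signed
        K_pf = M_d / Γ_pf
        E    = ½ |M_d (Γ_pf − Γ_dl,signed) − M_c (Γ_df + Γ_dl,signed)|
    """

    M_c: float
    M_d: float
    Gamma_df: float
    Gamma_pf: float
    Gamma_dl_signed: float
    K_df: float = field(default=np.nan)
    K_dl: float = field(default=np.nan)
    K_pf: float = field(default=np.nan)
    E: float = field(default=np.nan)

    @classmethod
    def from_loop(
        cls,
        M_c: float,
        M_d: float,
        Gamma_df: float,
        Gamma_pf: float,
        Gamma_dl_signed: float,
    ) -> "GenerativeTruth":
        """Build a truth record, deriving K's and E from the loop invariants."""
        if Gamma_df <= 0 or Gamma_pf <= 0:
            raise DomainError("Gamma_df and Gamma_pf must be positive")
        K_df = M_c / Gamma_df
        K_pf = M_d / Gamma_pf
        K_dl = (
            (M_d - M_c) / Gamma_dl_signed if Gamma_dl_signed != 0.0 else np.inf
        )
        E = 0.5 * abs(
            M_d * (Gamma_pf - Gamma_dl_signed) - M_c * (Gamma_df + Gamma_dl_signed)
        )
        return cls(M_c, M_d, Gamma_df, Gamma_pf, Gamma_dl_signed, K_df, K_dl, K_pf, E)


@dataclass
class GaitTrial:
    """One stance-phase moment-angle record at a known speed.

    ``gait_pct`` is percent of the gait cycle (strictly increasing, covering
    at least [5, 65]); ``angle`` in rad, ``moment`` in N·m. ``noise_sd`` is
    generator metadata (None for measured data).
    """

    subject_id: str
    speed: float
    gait_pct: np.ndarray
    angle: np.ndarray
    moment: np.ndarray
    noise_sd: float | tuple | None = None

    def __post_init__(self) -> None:
        self.gait_pct = np.asarray(self.gait_pct, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        self.moment = np.asarray(self.moment, dtype=float)
        n = self.gait_pct.size
        if not (n == self.angle.size == self.moment.size):
            raise DomainError("gait_pct, angle, moment must have equal length")
        if n < 30:
            raise DomainError(f"trial needs >= 30 samples, got {n}")
        if np.any(np.diff(self.gait_pct) <= 0):
            bad = int(np.argmax(np.diff(self.gait_pct) <= 0)) + 1
            raise DomainError(f"gait_pct not strictly increasing at sample {bad}")
        if self.gait_pct[0] > 5.0 or self.gait_pct[-1] < 65.0:
            raise DomainError(
                "trial must cover at least [5, 65] percent of the gait cycle"
            )

    @property
    def n_samples(self) -> int:
        return int(self.gait_pct.size)


@dataclass(frozen=True)
class PhaseLandmarks:
    """Indices of the landmark samples b, c, d, e on a trial.

    b: local angle minimum after heel strike (start of dorsiflexion);
    c: dorsi→dual transition (~30% of the cycle); d: moment maximum
    (dual→plantar transition); e: angle minimum after d (toe-off end).
    """

    idx_b: int
    idx_c: int
    idx_d: int
    idx_e: int

    def __post_init__(self) -> None:
        pairs = [("b", "c"), ("c", "d"), ("d", "e")]
        vals = {
            "b": self.idx_b,
            "c": self.idx_c,
            "d": self.idx_d,
            "e": self.idx_e,
        }
        for lo, hi in pairs:
            if vals[lo] >= vals[hi]:
                raise DomainError(
                    f"landmark ordering violated: idx_{lo} ({vals[lo]}) >= "
                    f"idx_{hi} ({vals[hi]})"
                )


@dataclass
class JointSummary:
    """Per-trial quasi-stiffnesses, excursions, fit quality, and work."""

    subject_id: str
    speed: float
    K_df: float
    K_dl: float
    K_pf: float
    Gamma_df: float
    Gamma_dl: float
    Gamma_pf: float
    Gamma_dl_signed: float
    r2_df: float
    r2_dl: float
    r2_pf: float
    E_loop: float
    E_fit: float
    singular: bool = False

    FIELDS = (
        "subject_id",
        "speed",
        "K_df",
        "K_dl",
        "K_pf",
        "Gamma_df",
        "Gamma_dl",
        "Gamma_pf",
        "Gamma_dl_signed",
        "r2_df",
        "r2_dl",
        "r2_pf",
        "E_loop",
        "E_fit",
        "singular",
    )

    def as_row(self) -> dict:
        return {f: getattr(self, f) for f in self.FIELDS}


def cohort_by_id(cohort: Sequence[SubjectProfile]) -> dict[str, SubjectProfile]:
    return {s.subject_id: s for s in cohort}
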