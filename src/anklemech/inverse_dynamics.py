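"""Single-segment (foot) ankle-moment balance and its sagittal reduction.

Coordinates: X anterior, Y up, Z mediolateral (right-handed); the sagittal
plane is X-Y and sagittal moments act about Z. The full Newton-Euler
balance of the foot segment gives the ankle moment

    M_A = I·α + ω×(I·ω) − r_GA×F_G − M_G − r_CA×(m·g) + r_CA×(m·a_com)

with r_GA = cop − ankle (lever from ankle to center of pressure) and
r_CA = com − ankle. During the loaded phase transitions of stance the
ground-reaction moment, foot weight, and foot inertial terms are small
relative to the GRF lever term, leaving the simplified expression
M_A ≈ −r_GA×F_G; the residual of that approximation is audited by
:func:`assumption_gap`.

Scalar sagittal moments are reported extensor- (plantar-flexor-) positive,
i.e. as the negative Z-component of the vector balance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import DomainError

_ZERO3 = (0.0, 0.0, 0.0)


def _vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise DomainError(f"expected a 3-vector, got shape {v.shape}")
    return v


@dataclass
class FootState:
    """Mechanical state of the foot segment at one instant."""

    F_G: np.ndarray = field(default_factory=lambda: np.zeros(3))  # GRF, N
    M_G: np.ndarray = field(default_factory=lambda: np.zeros(3))  # GRM, N·m
    cop: np.ndarray = field(default_factory=lambda: np.zeros(3))  # m
    ankle: np.ndarray = field(default_factory=lambda: np.zeros(3))  # m
    com: np.ndarray = field(default_factory=lambda: np.zeros(3))  # m
    foot_mass: float = 0.0  # kg
    inertia: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))  # kg·m²
    omega: np.ndarray = field(default_factory=lambda: np.zeros(3))  # rad/s
    alpha: np.ndarray = field(default_factory=lambda: np.zeros(3))  # rad/s²
    acc_com: np.ndarray = field(default_factory=lambda: np.zeros(3))  # m/s²
    g: float = 9.81  # m/s²

    def __post_init__(self) -> None:
        for name in ("F_G", "M_G", "cop", "ankle", "com", "omega", "alpha", "acc_com"):
            setattr(self, name, _vec3(getattr(self, name)))
        self.inertia = np.asarray(self.inertia, dtype=float)
        if self.inertia.shape != (3, 3):
            raise DomainError("inertia must be a 3x3 tensor")
        if self.foot_mass < 0:
            raise DomainError("foot_mass must be >= 0")
        if not np.allclose(self.inertia, self.inertia.T, atol=1e-9):
            raise DomainError("inertia tensor must be symmetric")
        if np.any(np.linalg.eigvalsh((self.inertia + self.inertia.T) / 2) < -1e-9):
            raise DomainError("inertia tensor must be positive semi-definite")

    def to_json(self) -> str:
        d = {
            name: (getattr(self, name).tolist() if name not in ("foot_mass", "g")
                   else getattr(self, name))
            for name in (
                "F_G", "M_G", "cop", "ankle", "com", "foot_mass", "inertia",
                "omega", "alpha", "acc_com", "g",
            )
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str | Path) -> "FootState":
        if isinstance(text, Path):
            text = text.read_text()
        return cls(**json.loads(text))


def foot_moment_full(state: FootState) -> np.ndarray:
    """Ankle moment 3-vector from the full Newton-Euler foot balance."""
    I = state.inertia
    gravity = np.array([0.0, -state.g, 0.0])
    r_ga = state.cop - state.ankle
    r_ca = state.com - state.ankle
    return (
        I @ state.alpha
        + np.cross(state.omega, I @ state.omega)
        - np.cross(r_ga, state.F_G)
        - state.M_G
        - np.cross(r_ca, state.foot_mass * gravity)
        + np.cross(r_ca, state.foot_mass * state.acc_com)
    )


def foot_moment_sagittal(state: FootState) -> float:
    """Simplified sagittal ankle moment, extensor-positive.

    Neglects GRM, foot weight, and all foot inertial terms:
    the extensor-positive Z-component of −(cop − ankle)×F_G.
    """
    r_ga = state.cop - state.ankle
    return float(np.cross(r_ga, state.F_G)[2])


def full_moment_sagittal(state: FootState) -> float:
    """Extensor-positive sagittal component of the full balance."""
    return float(-foot_moment_full(state)[2])


def assumption_gap(state: FootState) -> dict:
    """Audit the neglected terms of the simplified sagittal moment.

    Returns ``eps_z`` (full minus simplified sagittal moment, N·m, both
    extensor-positive), ``relative_gap`` = |eps_z| / |full|, and a
    ``degenerate`` flag set when the full sagittal moment is zero (the
    relative gap is then undefined and reported as NaN).
    """
    full = full_moment_sagittal(state)
    simplified = foot_moment_sagittal(state)
    eps_z = full - simplified
    if full == 0.0:
        return {"eps_z": eps_z, "relative_gap": float("nan"), "degenerate": True}
    return {"eps_z": eps_z, "relative_gap": abs(eps_z) / abs(full), "degenerate": False}
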