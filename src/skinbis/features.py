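"""Ratiometric time-difference impedance features.

From the complex impedances Z_l, Z_h measured at a low/high frequency pair,
four derived quantities are formed:

    Z' = |Z_l| / |Z_h|                 (magnitude ratio, dimensionless)
    theta' = arg(Z_l) - arg(Z_h)       (phase difference, degrees)
    R' = Re(Z_l) / |Z_h|               (resistance ratio)
    X' = Im(Z_l) / |Z_h|               (reactance ratio)

and the classifier inputs are their relative changes between a measurement at
time t and a baseline at t0:

    alpha_x = (x_t - x_t0) / x_t0      for x in {Z', theta', R', X'}.

Because each quantity is a ratio (or difference of phases) of simultaneous
measurements, a common multiplicative gain or a common phase offset applied
to all raw impedances cancels exactly — the features isolate tissue change
from instrument drift.

A baseline quantity can be degenerate (e.g. theta'_t0 = 0 when the two
phases coincide); the relative change is then undefined.  Such components
fall back to the absolute difference x_t - x_t0 and the record is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dielectric import InvalidInputError

__all__ = [
    "DerivedQuantities",
    "FeatureVector",
    "derived_quantities",
    "impedance_inputs",
    "profile_subset",
    "PROFILES",
    "profiles_by_size",
    "COMPONENTS",
]

#: Canonical component order of the four inputs.
COMPONENTS = ("a_mag", "a_phase", "a_res", "a_react")

#: Guard below which a baseline denominator is treated as degenerate
#: (in the quantity's natural units: dimensionless ratios / degrees).
DEGENERACY_GUARD = 1e-9


@dataclass(frozen=True)
class DerivedQuantities:
    """The two-frequency derived quantities at one time point."""

    z_ratio: float  # Z' [-]
    theta_diff: float  # theta' [deg]
    r_ratio: float  # R' [-]
    x_ratio: float  # X' [-]
    pair: tuple[float, float]  # (f_low, f_high) [Hz]

    def __post_init__(self) -> None:
        if not self.z_ratio > 0:
            raise InvalidInputError("magnitude ratio must be positive")
        if self.r_ratio**2 + self.x_ratio**2 > self.z_ratio**2 + 1e-9:
            raise InvalidInputError("inconsistent derived quantities")


@dataclass(frozen=True)
class FeatureVector:
    """The four relative-change inputs for one (t, t0, frequency pair)."""

    a_mag: float
    a_phase: float
    a_res: float
    a_react: float
    pair: tuple[float, float]
    baseline_id: str = "t0"
    case_meta: dict = field(default_factory=dict)
    degenerate: tuple[str, ...] = ()  # components computed by the fallback

    def as_array(self) -> np.ndarray:
        return np.array([self.a_mag, self.a_phase, self.a_res, self.a_react])

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise InvalidInputError("feature components must be finite")


def derived_quantities(
    Z_low: complex, Z_high: complex, pair: tuple[float, float]
) -> DerivedQuantities:
    """Compute (Z', theta', R', X') from the pair of complex impedances."""
    if abs(Z_low) == 0 or abs(Z_high) == 0:
        raise InvalidInputError("zero-magnitude impedance")
    mag_h = abs(Z_high)
    theta = math.degrees(np.angle(Z_low) - np.angle(Z_high))
    return DerivedQuantities(
        z_ratio=abs(Z_low) / mag_h,
        theta_diff=theta,
        r_ratio=Z_low.real / mag_h,
        x_ratio=Z_low.imag / mag_h,
        pair=(float(pair[0]), float(pair[1])),
    )


def impedance_inputs(
    measured: DerivedQuantities,
    baseline: DerivedQuantities,
    baseline_id: str = "t0",
    case_meta: dict | None = None,
) -> FeatureVector:
    """Relative change of each derived quantity between measurement and baseline.

    Components whose baseline magnitude falls below the degeneracy guard are
    computed as the absolute difference instead and reported in
    ``FeatureVector.degenerate``.
    """
    if measured.pair != baseline.pair:
        raise InvalidInputError(
            f"frequency pair mismatch: {measured.pair} vs {baseline.pair}"
        )
    names = ("z_ratio", "theta_diff", "r_ratio", "x_ratio")
    values = {}
    degenerate = []
    for comp, name in zip(COMPONENTS, names):
        x_t = getattr(measured, name)
        x_t0 = getattr(baseline, name)
        if abs(x_t0) < DEGENERACY_GUARD:
            values[comp] = x_t - x_t0
            degenerate.append(comp)
        else:
            values[comp] = (x_t - x_t0) / x_t0
    return FeatureVector(
        pair=measured.pair,
        baseline_id=baseline_id,
        case_meta=dict(case_meta or {}),
        degenerate=tuple(degenerate),
        **values,
    )


# --------------------------------------------------------------------------
# Matrix-profile catalogue: which of the four inputs feed the classifier.
# The three-input family deliberately omits Z'+R'+X'; pass
# include_missing_three=True to profiles_by_size to add it.
# --------------------------------------------------------------------------

_Z, _T, _R, _X = "Z", "theta", "R", "X"
_COMP_OF = {_Z: "a_mag", _T: "a_phase", _R: "a_res", _X: "a_react"}

PROFILES: dict[str, tuple[str, ...]] = {
    # one matrix (4)
    "Z": (_Z,), "theta": (_T,), "R": (_R,), "X": (_X,),
    # two matrices (6)
    "Z+theta": (_Z, _T), "Z+R": (_Z, _R), "Z+X": (_Z, _X),
    "theta+R": (_T, _R), "theta+X": (_T, _X), "R+X": (_R, _X),
    # three matrices (3, as catalogued)
    "Z+theta+R": (_Z, _T, _R), "Z+theta+X": (_Z, _T, _X), "theta+R+X": (_T, _R, _X),
    # four matrices (1)
    "Z+theta+R+X": (_Z, _T, _R, _X),
}

_EXTRA_THREE = {"Z+R+X": (_Z, _R, _X)}


def profiles_by_size(include_missing_three: bool = False) -> dict[int, list[str]]:
    """Profile names grouped by input count: {1: [...4], 2: [...6], 3: [...3], 4: [...1]}."""
    cat = dict(PROFILES)
    if include_missing_three:
        cat.update(_EXTRA_THREE)
    out: dict[int, list[str]] = {1: [], 2: [], 3: [], 4: []}
    for name, comps in cat.items():
        out[len(comps)].append(name)
    return out


def profile_components(profile: str, include_missing_three: bool = False) -> tuple[str, ...]:
    """FeatureVector attribute names selected by a profile, canonical order."""
    cat = dict(PROFILES)
    if include_missing_three:
        cat.update(_EXTRA_THREE)
    if profile not in cat:
        raise InvalidInputError(f"unknown matrix profile {profile!r}")
    return tuple(_COMP_OF[c] for c in cat[profile])


def profile_subset(fv: FeatureVector, profile: str,
                   include_missing_three: bool = False) -> tuple[float, ...]:
    """The selected alpha components of a feature vector, canonical order."""
    return tuple(getattr(fv, a) for a in profile_components(profile, include_missing_three))
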