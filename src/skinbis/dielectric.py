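"""Four-layer skin dielectric model.

The skin is modelled as a stack of four planar layers — stratum corneum (S),
epidermis (E), dermis (D) and fat (F) — each with a thickness and a
frequency-dependent conductivity ``sigma(f)`` [S/m] and relative permittivity
``eps_r(f)``.  At angular frequency ``w = 2*pi*f`` a layer behaves as the
quasi-static complex admittivity

    sigma* = sigma(f) + j * w * eps0 * eps_r(f)   [S/m]

which is what the forward solver consumes.  Dispersion tables are sampled on a
frequency grid and interpolated linearly in log10(f); outside the table the
nearest sample is held constant.

Published per-layer dielectric curves for skin are plotted rather than
tabulated in most of the literature, so the default tables shipped here are
declared configuration values chosen inside the literature ranges (stratum
corneum least conductive, dermis most conductive); they are not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

EPS0 = 8.8541878128e-12  # vacuum permittivity [F/m]

LAYER_NAMES = ("S", "E", "D", "F")

#: Conductivity-changed-layer selectors: index 1..10 -> affected layer names.
PSI_COMBOS: dict[int, tuple[str, ...]] = {
    1: ("S",),
    2: ("E",),
    3: ("D",),
    4: ("F",),
    5: ("S", "E"),
    6: ("E", "D"),
    7: ("D", "F"),
    8: ("S", "E", "D"),
    9: ("E", "D", "F"),
    10: ("S", "E", "D", "F"),
}

PSI_NAMES: dict[int, str] = {k: "+".join(v) for k, v in PSI_COMBOS.items()}
PSI_BY_NAME: dict[str, int] = {v: k for k, v in PSI_NAMES.items()}


class InvalidInputError(ValueError):
    """Raised when an argument violates a documented precondition."""


@dataclass(frozen=True)
class LayerDielectric:
    """One skin layer: thickness plus sampled dispersion tables."""

    name: str
    thickness: float  # [m]
    freqs: np.ndarray  # [Hz], strictly increasing
    sigma: np.ndarray  # [S/m], > 0
    eps_r: np.ndarray  # [-], >= 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        object.__setattr__(self, "eps_r", np.asarray(self.eps_r, dtype=float))
        if self.name not in LAYER_NAMES:
            raise InvalidInputError(f"unknown layer name {self.name!r}")
        if not self.thickness > 0:
            raise InvalidInputError("layer thickness must be positive")
        if self.freqs.ndim != 1 or len(self.freqs) < 1:
            raise InvalidInputError("frequency table must be a 1-D array")
        if len(self.freqs) != len(self.sigma) or len(self.freqs) != len(self.eps_r):
            raise InvalidInputError("dispersion tables must share the frequency grid")
        if np.any(np.diff(self.freqs) <= 0):
            raise InvalidInputError("frequency samples must be strictly increasing")
        if np.any(self.freqs <= 0):
            raise InvalidInputError("table frequencies must be positive")
        if np.any(self.sigma <= 0):
            raise InvalidInputError("conductivities must be positive")
        if np.any(self.eps_r < 1):
            raise InvalidInputError("relative permittivities must be >= 1")

    def sigma_at(self, f: float | np.ndarray) -> np.ndarray:
        """Conductivity at ``f`` [Hz], log-frequency interpolation."""
        return _loginterp(f, self.freqs, self.sigma)

    def eps_r_at(self, f: float | np.ndarray) -> np.ndarray:
        return _loginterp(f, self.freqs, self.eps_r)

    def scaled_sigma(self, factor: float) -> "LayerDielectric":
        """Copy with conductivity multiplied by ``factor`` at all frequencies."""
        if factor <= 0:
            raise InvalidInputError("conductivity scale factor must be positive")
        return replace(self, sigma=self.sigma * factor)


def _loginterp(f, table_f, table_v):
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise InvalidInputError("frequency must be non-negative")
    # clamp so the DC query falls back to the lowest tabulated sample
    fq = np.clip(f, table_f[0], table_f[-1])
    out = np.interp(np.log10(fq), np.log10(table_f), table_v)
    return out if out.ndim else float(out)


def layer_admittivity(layer: LayerDielectric, f: float) -> complex:
    """Complex admittivity sigma(f) + j*2*pi*f*eps0*eps_r(f) of one layer [S/m].

    At f = 0 the reactive part vanishes and the DC conductivity is returned.
    """
    if f < 0:
        raise InvalidInputError("frequency must be non-negative")
    sig = layer.sigma_at(f)
    epsr = layer.eps_r_at(f)
    return complex(sig, 2.0 * np.pi * f * EPS0 * epsr)


@dataclass(frozen=True)
class SkinStack:
    """Ordered layer stack from the skin surface downward (S, E, D, F)."""

    layers: tuple[LayerDielectric, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        names = tuple(l.name for l in self.layers)
        if names != LAYER_NAMES:
            raise InvalidInputError(
                f"stack must be ordered exactly {LAYER_NAMES}, got {names}"
            )

    @property
    def total_thickness(self) -> float:
        return float(sum(l.thickness for l in self.layers))

    @property
    def interfaces(self) -> np.ndarray:
        """Depths of layer boundaries from the surface: [0, hS, hS+hE, ...]."""
        return np.concatenate([[0.0], np.cumsum([l.thickness for l in self.layers])])

    def layer(self, name: str) -> LayerDielectric:
        for l in self.layers:
            if l.name == name:
                return l
        raise InvalidInputError(f"no layer named {name!r}")

    def admittivities(self, f: float) -> np.ndarray:
        """Per-layer complex admittivity at ``f``, ordered S, E, D, F."""
        return np.array([layer_admittivity(l, f) for l in self.layers])


# --------------------------------------------------------------------------
# Default dispersion tables (declared configuration; literature ranges).
# Sampled at the five study frequencies plus anchors one decade out.
# --------------------------------------------------------------------------

_DEFAULT_FREQS = np.array([1e3, 2e3, 1e4, 3.5e4, 1e5, 2.25e5, 1e6])

_DEFAULT_TABLES: Mapping[str, tuple[float, Sequence[float], Sequence[float]]] = {
    # layer: (thickness m, sigma S/m, eps_r)
    "S": (50e-6, [2.0e-4, 3.0e-4, 6.0e-4, 1.2e-3, 2.5e-3, 4.0e-3, 1.0e-2],
          [2.0e4, 1.5e4, 6.0e3, 3.0e3, 1.5e3, 9.0e2, 3.0e2]),
    "E": (0.45e-3, [0.10, 0.11, 0.13, 0.16, 0.20, 0.24, 0.35],
          [3.0e4, 2.2e4, 1.2e4, 6.0e3, 3.0e3, 1.8e3, 6.0e2]),
    "D": (2.5e-3, [0.40, 0.42, 0.46, 0.52, 0.58, 0.64, 0.80],
          [5.0e4, 3.5e4, 1.8e4, 9.0e3, 4.5e3, 2.5e3, 8.0e2]),
    "F": (5e-3, [0.022, 0.023, 0.024, 0.026, 0.028, 0.031, 0.040],
          [2.0e4, 1.2e4, 3.0e3, 1.0e3, 3.0e2, 1.5e2, 5.0e1]),
}


def default_skin_stack() -> SkinStack:
    """Default four-layer stack: hS=50 um, hE=0.45 mm, hD=2.5 mm, hF=5 mm."""
    layers = []
    for name in LAYER_NAMES:
        thick, sig, epsr = _DEFAULT_TABLES[name]
        layers.append(
            LayerDielectric(name, thick, _DEFAULT_FREQS.copy(),
                            np.array(sig, float), np.array(epsr, float))
        )
    return SkinStack(tuple(layers))


def _resolve_psi(psi: int | str) -> tuple[str, ...]:
    if isinstance(psi, str):
        if psi in PSI_BY_NAME:
            return PSI_COMBOS[PSI_BY_NAME[psi]]
        if psi.lower().startswith("psi"):
            try:
                return PSI_COMBOS[int(psi[3:])]
            except (ValueError, KeyError):
                pass
        raise InvalidInputError(f"unknown conductivity-change selector {psi!r}")
    try:
        return PSI_COMBOS[int(psi)]
    except (ValueError, KeyError, TypeError):
        raise InvalidInputError(f"unknown conductivity-change selector {psi!r}")


def apply_conductivity_change(
    stack: SkinStack, psi: int | str, dsigma_pct: float
) -> SkinStack:
    """Scale the conductivity of the layers selected by ``psi`` by (1 + dsigma/100).

    ``psi`` is a selector index 1..10 (or a combo name such as ``"S+E+D"``);
    permittivity tables and unselected layers are untouched, and a new stack is
    returned.  ``dsigma_pct = 0`` reproduces the input stack.
    """
    if dsigma_pct < -100:
        raise InvalidInputError("conductivity change below -100% is unphysical")
    selected = _resolve_psi(psi)
    factor = 1.0 + dsigma_pct / 100.0
    layers = tuple(
        l.scaled_sigma(factor) if l.name in selected else l for l in stack.layers
    )
    return SkinStack(layers)


# --------------------------------------------------------------------------
# Configuration file I/O
# --------------------------------------------------------------------------

def load_dielectric_config(path: str | Path) -> SkinStack:
    """Load a stack from YAML/JSON: per-layer thickness plus dispersion triples.

    Schema::

        layers:
          - name: S
            thickness_m: 5.0e-5
            dispersion:             # rows of [frequency_hz, sigma_s_per_m, eps_r]
              - [1.0e+3, 2.0e-4, 2.0e+4]
              ...
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "layers" not in doc:
        raise InvalidInputError(f"{path}: expected a mapping with a 'layers' list")
    layers = []
    for entry in doc["layers"]:
        try:
            name = entry["name"]
            thickness = float(entry["thickness_m"])
            rows = np.array(entry["dispersion"], dtype=float)
        except (KeyError, TypeError, ValueError) as exc:
            raise InvalidInputError(f"{path}: malformed layer entry: {exc}") from exc
        if rows.ndim != 2 or rows.shape[1] != 3:
            raise InvalidInputError(f"{path}: dispersion must be rows of 3 numbers")
        layers.append(LayerDielectric(name, thickness, rows[:, 0], rows[:, 1], rows[:, 2]))
    return SkinStack(tuple(layers))


def dump_dielectric_config(stack: SkinStack, path: str | Path) -> None:
    doc = {
        "format_version": 1,
        "layers": [
            {
                "name": l.name,
                "thickness_m": float(l.thickness),
                "dispersion": [
                    [float(f), float(s), float(e)]
                    for f, s, e in zip(l.freqs, l.sigma, l.eps_r)
                ],
            }
            for l in stack.layers
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
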