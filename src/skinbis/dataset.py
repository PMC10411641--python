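"""Simulation training grid: case enumeration, forward runs, labels.

The study grid crosses
  * 2 injection patterns (I bipolar, II tetrapolar),
  * 3 electrode-length-to-skin-thickness regimes, labelled D/H<1, D/H=1,
    D/H>1 and realized as electrode diameters d_e = 1, 2, 3 mm
    (categorical labels — the arithmetic D/H is not asserted),
  * 10 conductivity-changed-layer selectors psi_1..psi_10,
  * 17 conductivity-change levels -20..+20 % in 2.5 % steps (0 % = standard),
  * 10 low/high frequency pairs drawn from {2, 10, 35, 100, 225} kHz,

for 2 x 3 x 10 x 17 x 10 = 10,200 cases, each identified by the canonical id
"phi_deltab_psi_dsigma_flow&fhigh", e.g. "I_D/H<1_S_-20_2&10".

Labels collapse the 10 selectors onto 5 classes: any combination containing
the dermis is labelled dermis (its response dominates), leaving S, E, D, F
and S+E.  That skews class counts 1:1:6:1:1 per grid cell, so balancing is
applied at assembly (inverse-frequency class weights by default, or seeded
stratified subsampling to the minority count).

Each case's feature vector compares the perturbed stack against the
standard (0 %) stack of the same configuration; spectra are cached per
unique physics configuration so every CEM solve runs once even though cases
share baselines across selectors, levels and pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import forward_cem
from .dielectric import (
    PSI_BY_NAME,
    PSI_NAMES,
    InvalidInputError,
    SkinStack,
    apply_conductivity_change,
    default_skin_stack,
)
from .features import FeatureVector, derived_quantities, impedance_inputs
from .forward_cem import (
    ElectrodeArray,
    ImpedanceSpectrum,
    InjectionPattern,
    MeshResolution,
)

__all__ = [
    "CaseDescriptor",
    "LabeledDataset",
    "GridConfig",
    "generate_grid",
    "label_case",
    "parse_case_id",
    "DatasetBuilder",
    "assemble_dataset",
    "CLASS_NAMES",
    "DSIGMA_LEVELS",
    "FREQ_PAIRS_KHZ",
    "STUDY_FREQS_KHZ",
    "DELTA_B",
]

#: 5-class source-indicator names, k = 1..5.
CLASS_NAMES = {1: "S", 2: "E", 3: "D", 4: "F", 5: "S+E"}

#: Conductivity-change grid [%], 17 levels, 0 is the standard.
DSIGMA_LEVELS: tuple[float, ...] = tuple(np.arange(-20.0, 20.01, 2.5))

#: The ten low/high frequency pairs [kHz].
FREQ_PAIRS_KHZ: tuple[tuple[int, int], ...] = (
    (2, 10), (2, 35), (2, 100), (2, 225), (10, 35),
    (10, 100), (10, 225), (35, 100), (35, 225), (100, 225),
)

#: Study frequencies [kHz].
STUDY_FREQS_KHZ: tuple[int, ...] = (2, 10, 35, 100, 225)

#: D/H regime label -> electrode diameter d_e [m] (labels are categorical).
DELTA_B: dict[str, float] = {"D/H<1": 1e-3, "D/H=1": 2e-3, "D/H>1": 3e-3}

PATTERNS = ("I", "II")  # I = bipolar, II = tetrapolar


def _fmt_num(v: float) -> str:
    return f"{v:g}"


@dataclass(frozen=True)
class CaseDescriptor:
    """One grid point: (pattern, D/H regime, selector, change level, pair)."""

    phi: str  # "I" | "II"
    delta_b: str  # "D/H<1" | "D/H=1" | "D/H>1"
    psi: int  # 1..10
    dsigma: float  # percent
    pair_khz: tuple[int, int]  # (f_low, f_high) [kHz]

    def __post_init__(self) -> None:
        if self.phi not in PATTERNS:
            raise InvalidInputError(f"unknown injection pattern {self.phi!r}")
        if self.delta_b not in DELTA_B:
            raise InvalidInputError(f"unknown D/H regime {self.delta_b!r}")
        if self.psi not in PSI_NAMES:
            raise InvalidInputError(f"unknown selector psi{self.psi}")

    @property
    def case_id(self) -> str:
        fl, fh = self.pair_khz
        return (f"{self.phi}_{self.delta_b}_{PSI_NAMES[self.psi]}_"
                f"{_fmt_num(self.dsigma)}_{_fmt_num(fl)}&{_fmt_num(fh)}")

    @property
    def label(self) -> int:
        return label_case(self.psi)

    @property
    def pair_hz(self) -> tuple[float, float]:
        return (self.pair_khz[0] * 1e3, self.pair_khz[1] * 1e3)

    @property
    def pattern(self) -> InjectionPattern:
        return (InjectionPattern.bipolar() if self.phi == "I"
                else InjectionPattern.tetrapolar())

    @property
    def electrode_diameter(self) -> float:
        return DELTA_B[self.delta_b]


def parse_case_id(case_id: str) -> CaseDescriptor:
    """Invert the canonical id "phi_deltab_psi_dsigma_flow&fhigh"."""
    parts = case_id.split("_")
    if len(parts) != 5:
        raise InvalidInputError(f"malformed case id {case_id!r}")
    phi, db, psi_name, dsig, pair = parts
    if psi_name not in PSI_BY_NAME:
        raise InvalidInputError(f"unknown layer combination {psi_name!r} in {case_id!r}")
    m = re.fullmatch(r"([0-9.]+)&([0-9.]+)", pair)
    if not m:
        raise InvalidInputError(f"malformed frequency pair in {case_id!r}")
    return CaseDescriptor(
        phi=phi,
        delta_b=db,
        psi=PSI_BY_NAME[psi_name],
        dsigma=float(dsig),
        pair_khz=(int(float(m.group(1))), int(float(m.group(2)))),
    )


def label_case(psi: int) -> int:
    """Collapse selector psi -> class k: combinations containing D map to D."""
    if psi not in PSI_NAMES:
        raise InvalidInputError(f"unknown selector psi{psi!r}")
    mapping = {1: 1, 2: 2, 3: 3, 4: 4, 5: 5, 6: 3, 7: 3, 8: 3, 9: 3, 10: 3}
    return mapping[psi]


@dataclass(frozen=True)
class GridConfig:
    """Enumeration axes of the simulation grid (defaults = the full study grid)."""

    patterns: tuple[str, ...] = PATTERNS
    delta_b: tuple[str, ...] = tuple(DELTA_B)
    psi: tuple[int, ...] = tuple(range(1, 11))
    dsigma: tuple[float, ...] = DSIGMA_LEVELS
    pairs_khz: tuple[tuple[int, int], ...] = FREQ_PAIRS_KHZ

    def size(self) -> int:
        return (len(self.patterns) * len(self.delta_b) * len(self.psi)
                * len(self.dsigma) * len(self.pairs_khz))


def generate_grid(config: GridConfig | None = None) -> list[CaseDescriptor]:
    """Full Cartesian product of the grid axes, deterministic lexicographic order."""
    cfg = config or GridConfig()
    for name in ("patterns", "delta_b", "psi", "dsigma", "pairs_khz"):
        if not getattr(cfg, name):
            raise InvalidInputError(f"grid axis {name} is empty")
    out = []
    for phi in cfg.patterns:
        for db in cfg.delta_b:
            for psi in cfg.psi:
                for ds in cfg.dsigma:
                    for pair in cfg.pairs_khz:
                        out.append(CaseDescriptor(phi, db, psi, float(ds), tuple(pair)))
    return out


# --------------------------------------------------------------------------
# Forward simulation with caching
# --------------------------------------------------------------------------

class DatasetBuilder:
    """Runs the forward model for grid cases with per-configuration caching.

    Spectra are keyed on the physics configuration (pattern, d_e, selector,
    level) at the five study frequencies; the standard (0 %) spectrum of each
    (pattern, d_e) is the shared baseline.  Meshes are cached per d_e.
    """

    def __init__(
        self,
        stack: SkinStack | None = None,
        gap: float = 1e-3,
        contact_impedance: float = 50.0,
        current: float = 1e-3,
        resolution: MeshResolution | None = None,
        frequencies_khz: Sequence[float] = STUDY_FREQS_KHZ,
    ):
        self.stack = stack or default_skin_stack()
        self.gap = gap
        self.contact_impedance = contact_impedance
        self.current = current
        self.resolution = resolution or MeshResolution()
        self.frequencies = np.array(sorted(frequencies_khz), dtype=float) * 1e3
        self._meshes: dict[float, forward_cem.LayeredMesh] = {}
        self._spectra: dict[tuple, ImpedanceSpectrum] = {}
        self.n_solves = 0

    def _array(self, d_e: float) -> ElectrodeArray:
        return ElectrodeArray(diameter=d_e, gap=self.gap,
                              contact_impedance=self.contact_impedance)

    def _mesh(self, d_e: float, stack: SkinStack):
        if d_e not in self._meshes:
            self._meshes[d_e] = forward_cem.build_mesh(
                stack, self._array(d_e), self.resolution
            )
        return self._meshes[d_e]

    def _pattern(self, phi: str) -> InjectionPattern:
        return (InjectionPattern.bipolar(self.current) if phi == "I"
                else InjectionPattern.tetrapolar(self.current))

    def spectrum(self, phi: str, delta_b: str, psi: int | None,
                 dsigma: float) -> ImpedanceSpectrum:
        """Cached spectrum at the study frequencies; psi=None or dsigma=0 is baseline."""
        if psi is None or dsigma == 0.0:
            key = (phi, delta_b, None, 0.0)
            stack = self.stack
        else:
            key = (phi, delta_b, psi, float(dsigma))
            stack = apply_conductivity_change(self.stack, psi, dsigma)
        if key not in self._spectra:
            d_e = DELTA_B[delta_b]
            mesh = self._mesh(d_e, self.stack)
            spec = forward_cem.sweep_spectrum(
                stack, self._array(d_e), self._pattern(phi), self.frequencies,
                mesh=mesh,
                meta={"phi": phi, "delta_b": delta_b,
                      "psi": 0 if psi is None else psi, "dsigma_pct": dsigma},
            )
            self._spectra[key] = spec
            self.n_solves += len(self.frequencies)
        return self._spectra[key]

    def simulate_case(self, case: CaseDescriptor) -> FeatureVector:
        """Features of one case against its standard-conductivity baseline."""
        try:
            base = self.spectrum(case.phi, case.delta_b, None, 0.0)
            meas = self.spectrum(case.phi, case.delta_b, case.psi, case.dsigma)
            fl, fh = case.pair_hz
            dq_t0 = derived_quantities(base.at(fl), base.at(fh), (fl, fh))
            dq_t = derived_quantities(meas.at(fl), meas.at(fh), (fl, fh))
        except Exception as exc:
            raise type(exc)(f"case {case.case_id}: {exc}") from exc
        return impedance_inputs(
            dq_t, dq_t0,
            baseline_id=f"{case.phi}_{case.delta_b}_standard",
            case_meta={"case_id": case.case_id, "phi": case.phi,
                       "delta_b": case.delta_b, "psi": case.psi,
                       "dsigma_pct": case.dsigma},
        )

    def build(self, cases: Iterable[CaseDescriptor],
              progress: bool = False) -> pd.DataFrame:
        """Feature rows (one per case) in the dataset CSV dialect."""
        rows = []
        for case in cases:
            fv = self.simulate_case(case)
            rows.append({
                "case_id": case.case_id,
                "phi_s": case.phi,
                "delta_b": case.delta_b,
                "psi_p": case.psi,
                "dsigma_pct": case.dsigma,
                "f_low_hz": case.pair_hz[0],
                "f_high_hz": case.pair_hz[1],
                "a_mag": fv.a_mag,
                "a_phase": fv.a_phase,
                "a_res": fv.a_res,
                "a_react": fv.a_react,
                "label": case.label,
                "degenerate_flag": ";".join(fv.degenerate),
            })
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Labeled dataset with balancing
# --------------------------------------------------------------------------

@dataclass
class LabeledDataset:
    """Feature rows plus 5-class labels and the balancing policy applied."""

    df: pd.DataFrame
    policy: str = "none"
    class_weights: dict[int, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.df) == 0:
            raise InvalidInputError("empty dataset")
        if self.df["case_id"].duplicated().any():
            raise InvalidInputError("duplicate case ids in dataset")
        bad = set(self.df["label"]) - set(CLASS_NAMES)
        if bad:
            raise InvalidInputError(f"labels outside 1..5: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.df)

    def select(self, phi: str | None = None,
               pair_hz: tuple[float, float] | None = None) -> "LabeledDataset":
        df = self.df
        if phi is not None:
            df = df[df["phi_s"] == phi]
        if pair_hz is not None:
            df = df[np.isclose(df["f_low_hz"], pair_hz[0])
                    & np.isclose(df["f_high_hz"], pair_hz[1])]
        return replace(self, df=df.reset_index(drop=True))

    def matrices(self, components: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X, y, sample_weights) for the chosen feature components."""
        X = self.df[list(components)].to_numpy(dtype=float)
        y = self.df["label"].to_numpy(dtype=int)
        if self.class_weights:
            w = np.array([self.class_weights[k] for k in y])
        else:
            w = np.ones(len(y))
        return X, y, w

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# format_version: 1\n")
            fh.write(f"# balancing_policy: {self.policy}\n")
            if self.seed is not None:
                fh.write(f"# seed: {self.seed}\n")
            self.df.to_csv(fh, index=False)

    @staticmethod
    def read_csv(path: str | Path) -> "LabeledDataset":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("#"):
                    body = line[1:].strip()
                    if ":" in body:
                        k, v = body.split(":", 1)
                        meta[k.strip()] = v.strip()
                    pos = fh.tell()
                else:
                    fh.seek(pos)
                    break
            df = pd.read_csv(fh)
        if "degenerate_flag" in df.columns:
            df["degenerate_flag"] = df["degenerate_flag"].fillna("")
        else:
            df["degenerate_flag"] = ""
        seed = meta.get("seed")
        return LabeledDataset(df, policy=meta.get("balancing_policy", "none"),
                              seed=None if seed is None else int(seed))


def assemble_dataset(
    features_df: pd.DataFrame,
    policy: str = "class-weights",
    seed: int | None = None,
) -> LabeledDataset:
    """Attach labels (already present per case) and apply the balancing policy.

    Policies: ``none`` keeps rows untouched; ``class-weights`` attaches
    inverse-frequency class weights normalized to sum to the class count;
    ``subsample`` stratified-subsamples every class down to the minority
    class count with a seeded shuffle.
    """
    if len(features_df) == 0:
        raise InvalidInputError("no feature rows to assemble")
    if policy == "none":
        return LabeledDataset(features_df.reset_index(drop=True), policy="none")
    if policy == "class-weights":
        counts = features_df["label"].value_counts()
        k = len(counts)
        weights = {int(c): float(len(features_df) / (k * n)) for c, n in counts.items()}
        # normalize so the weights sum to the number of classes
        tot = sum(weights.values())
        weights = {c: w * k / tot for c, w in weights.items()}
        return LabeledDataset(features_df.reset_index(drop=True),
                              policy="class-weights", class_weights=weights)
    if policy == "subsample":
        rng = np.random.default_rng(seed)
        n_min = features_df["label"].value_counts().min()
        parts = []
        for label in sorted(features_df["label"].unique()):
            sub = features_df[features_df["label"] == label]
            idx = rng.choice(len(sub), size=n_min, replace=False)
            parts.append(sub.iloc[np.sort(idx)])
        df = pd.concat(parts).reset_index(drop=True)
        return LabeledDataset(df, policy="subsample", seed=seed)
    raise InvalidInputError(f"unknown balancing policy {policy!r}")
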