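"""Complete-electrode-model (CEM) forward solver on a layered skin domain.

Solves the quasi-static conduction problem

    div( sigma*(r) grad phi(r) ) = 0        in the domain,
    phi + z_l sigma* dphi/dn = U_l          on electrode l,
    integral_{e_l} sigma* dphi/dn dS = I_l  (total current per electrode),
    sigma* dphi/dn = 0                      elsewhere on the boundary,

for a colinear surface array of four circular electrodes on a four-layer skin
stack, and returns complex inter-electrode impedances.  ``sigma*`` is the
complex admittivity of each layer (see :mod:`skinbis.dielectric`), ``z_l`` the
effective contact impedance of electrode l, and the potential gauge is fixed
by grounding the current-sink electrode (U = 0).

Discretization: a structured tensor-product grid with (bi/tri)linear elements
and strongly graded vertical spacing so even the 50-um stratum corneum is
resolved by multiple element rows.  The default is a 2-D per-unit-depth
section through the array axis (fast; exact for the planar limit of the strip
approximation of the electrodes); a 3-D grid with circular electrode
footprints approximated by top-surface element faces is available through
``MeshResolution(dim=3)``.  Since each layer has a spatially constant
admittivity, the global stiffness matrix is assembled once per layer with unit
admittivity and the frequency sweep only recombines the four precomputed
blocks, so a full spectrum costs one sparse factorization per frequency.

The lumped contact impedance Z_c [Ohm] of an electrode is converted to the
distributed coefficient z_l = Z_c * |e_l| so that a uniform current density
produces a series voltage drop of Z_c * I.  With Z_c = 0 the Robin coupling
degenerates; that limit is handled exactly by the shunt model (all electrode
nodes tied to the electrode potential).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .dielectric import InvalidInputError, SkinStack

__all__ = [
    "ElectrodeArray",
    "InjectionPattern",
    "MeshResolution",
    "LayeredMesh",
    "ImpedanceSpectrum",
    "SolveResult",
    "ConfigurationError",
    "build_mesh",
    "assemble_and_solve",
    "measure_impedance",
    "sweep_spectrum",
    "write_spectrum_csv",
    "read_spectrum_csv",
]


class ConfigurationError(ValueError):
    """Raised for unusable geometry / discretization requests."""


class SolverError(RuntimeError):
    """Raised when the linear solve fails or returns non-finite values."""


# 1-D linear element matrices on [0, h]: stiffness/h and mass*h factors.
_D1 = np.array([[1.0, -1.0], [-1.0, 1.0]])
_M1 = np.array([[1 / 3, 1 / 6], [1 / 6, 1 / 3]])


@dataclass(frozen=True)
class ElectrodeArray:
    """Colinear four-electrode surface array.

    ``diameter`` d_e and ``gap`` d_g define the pitch d_e + d_g; centers are
    symmetric about x = 0 on the top surface.  ``contact_impedance`` is the
    lumped Z_c [Ohm] per electrode.
    """

    n_electrodes: int = 4
    diameter: float = 1e-3  # d_e [m]
    gap: float = 1e-3  # d_g [m]
    contact_impedance: float = 50.0  # Z_c [Ohm]

    def __post_init__(self) -> None:
        if self.n_electrodes < 2:
            raise InvalidInputError("need at least two electrodes")
        if self.diameter <= 0 or self.gap <= 0:
            raise InvalidInputError("electrode diameter and gap must be positive")
        if self.contact_impedance < 0:
            raise InvalidInputError("contact impedance must be >= 0")

    @property
    def pitch(self) -> float:
        return self.diameter + self.gap

    @property
    def positions(self) -> np.ndarray:
        """Electrode center x-coordinates [m], symmetric about 0."""
        n = self.n_electrodes
        return (np.arange(n) - (n - 1) / 2.0) * self.pitch

    @property
    def electrode_length(self) -> float:
        """D = d_g + d_e, the penetration-depth proxy."""
        return self.gap + self.diameter

    @property
    def span(self) -> float:
        """Outer extent of the array along x."""
        return (self.n_electrodes - 1) * self.pitch + self.diameter


@dataclass(frozen=True)
class InjectionPattern:
    """Drive/sense electrode assignment (0-based indices).

    Bipolar: the two central pads both drive the current and sense the
    voltage.  Tetrapolar: outer pads drive (e1 source, e4 ground), inner pads
    sense (e2 high, e3 low).
    """

    mode: str  # "bipolar" | "tetrapolar"
    drive_pair: tuple[int, int]  # (source, sink/ground)
    sense_pair: tuple[int, int]  # (high, low)
    current: float = 1e-3  # i [A]

    def __post_init__(self) -> None:
        if self.mode not in ("bipolar", "tetrapolar"):
            raise InvalidInputError(f"unknown injection mode {self.mode!r}")
        if self.drive_pair[0] == self.drive_pair[1]:
            raise InvalidInputError("drive electrodes must be distinct")
        if self.mode == "bipolar" and self.sense_pair != self.drive_pair:
            raise InvalidInputError("bipolar sensing must use the drive pair")
        if self.mode == "tetrapolar":
            if set(self.sense_pair) & set(self.drive_pair):
                raise InvalidInputError(
                    "tetrapolar sense electrodes must differ from drive electrodes"
                )
        if self.sense_pair[0] == self.sense_pair[1]:
            raise InvalidInputError("sense electrodes must be distinct")

    @property
    def ground(self) -> int:
        return self.drive_pair[1]

    @staticmethod
    def bipolar(current: float = 1e-3, pair: tuple[int, int] = (1, 2)) -> "InjectionPattern":
        return InjectionPattern("bipolar", pair, pair, current)

    @staticmethod
    def tetrapolar(
        current: float = 1e-3,
        drive: tuple[int, int] = (0, 3),
        sense: tuple[int, int] = (1, 2),
    ) -> "InjectionPattern":
        return InjectionPattern("tetrapolar", drive, sense, current)


@dataclass(frozen=True)
class MeshResolution:
    """Discretization request for :func:`build_mesh`.

    ``layer_rows`` is the number of element rows per layer (S, E, D, F);
    lateral margins extend ``margin_factor`` times the array span on each
    side with geometrically growing element sizes (ratio ``growth``).
    """

    elements_per_electrode: int = 8
    elements_per_gap: int = 4
    layer_rows: tuple[int, int, int, int] = (3, 5, 10, 7)
    margin_factor: float = 5.0
    growth: float = 1.5
    dim: int = 2
    elements_across_y: int = 4  # 3-D only: elements across the electrode diameter

    def refined(self, factor: int = 2) -> "MeshResolution":
        return MeshResolution(
            self.elements_per_electrode * factor,
            self.elements_per_gap * factor,
            tuple(r * factor for r in self.layer_rows),
            self.margin_factor,
            self.growth ** (1.0 / factor),
            self.dim,
            self.elements_across_y * factor,
        )


@dataclass
class ImpedanceSpectrum:
    """Frequencies [Hz] with complex impedance [Ohm] and acquisition metadata."""

    frequencies: np.ndarray
    Z: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.Z = np.asarray(self.Z, dtype=complex)
        if self.frequencies.shape != self.Z.shape:
            raise InvalidInputError("frequency and impedance arrays must match")
        if len(self.frequencies) and np.any(np.diff(self.frequencies) <= 0):
            raise InvalidInputError("frequencies must be strictly increasing")
        if np.any(~np.isfinite(self.Z)) or np.any(np.abs(self.Z) <= 0):
            raise InvalidInputError("impedances must be finite and nonzero")

    def at(self, f: float) -> complex:
        idx = np.argmin(np.abs(self.frequencies - f))
        if not np.isclose(self.frequencies[idx], f, rtol=1e-9, atol=0.0):
            raise InvalidInputError(f"frequency {f} Hz not in spectrum")
        return complex(self.Z[idx])


@dataclass
class SolveResult:
    """One CEM solve: electrode potentials, field, per-electrode currents."""

    U: np.ndarray  # complex electrode potentials [V]
    phi: np.ndarray  # complex nodal potentials [V]
    electrode_currents: np.ndarray  # complex [A], + into the tissue
    frequency: float


# --------------------------------------------------------------------------
# Meshing
# --------------------------------------------------------------------------

def _graded_extension(h0: float, total: float, growth: float) -> np.ndarray:
    """Geometrically growing element widths from h0 covering >= total."""
    widths = []
    h, cum = h0, 0.0
    while cum < total:
        h *= growth
        widths.append(h)
        cum += h
    return np.array(widths)


def _axis_with_electrodes(array: ElectrodeArray, n_e: int, n_g: int,
                          margin: float, growth: float) -> np.ndarray:
    """Node coordinates along the array axis; electrode edges are nodes."""
    de, centers = array.diameter, array.positions
    pts = [centers[0] - de / 2]
    for k, c in enumerate(centers):
        left, right = c - de / 2, c + de / 2
        pts.extend(np.linspace(left, right, n_e + 1)[1:])
        if k + 1 < len(centers):
            nxt = centers[k + 1] - de / 2
            pts.extend(np.linspace(right, nxt, n_g + 1)[1:])
    core = np.array(pts)
    h0 = de / n_e
    ext = _graded_extension(h0, margin, growth)
    left = core[0] - np.cumsum(ext)[::-1]
    right = core[-1] + np.cumsum(ext)
    return np.concatenate([left, core, right])


def _axis_across(array: ElectrodeArray, n_y: int, margin: float, growth: float) -> np.ndarray:
    de = array.diameter
    core = np.linspace(-de / 2, de / 2, n_y + 1)
    ext = _graded_extension(de / n_y, margin, growth)
    return np.concatenate([core[0] - np.cumsum(ext)[::-1], core, core[-1] + np.cumsum(ext)])


def _depth_axis(stack: SkinStack, layer_rows: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Depth nodes (z >= 0 downward) and per-element-row layer index."""
    zs = [0.0]
    layer_of_row = []
    depth = 0.0
    for i, (layer, rows) in enumerate(zip(stack.layers, layer_rows)):
        if rows < 2:
            raise ConfigurationError(
                f"layer {layer.name} requested with {rows} element rows; at least 2 "
                "rows per layer are required to resolve the layered structure — "
                "increase MeshResolution.layer_rows"
            )
        edges = depth + np.linspace(0.0, layer.thickness, rows + 1)[1:]
        zs.extend(edges.tolist())
        layer_of_row.extend([i] * rows)
        depth += layer.thickness
    return np.array(zs), np.array(layer_of_row, dtype=int)


class LayeredMesh:
    """Structured tensor-product grid with per-layer unit stiffness blocks.

    Nodes are ordered x-major (then y in 3-D, then depth z).  ``K_layers[i]``
    is the stiffness matrix of layer i assembled with unit admittivity, so the
    physical system matrix at any frequency is ``sum_i sigma*_i K_layers[i]``.
    """

    def __init__(self, stack: SkinStack, array: ElectrodeArray,
                 resolution: MeshResolution):
        if resolution.elements_per_electrode < 1 or resolution.elements_per_gap < 1:
            raise ConfigurationError("need >= 1 element per electrode and per gap")
        if resolution.dim not in (2, 3):
            raise ConfigurationError("dim must be 2 or 3")
        self.dim = resolution.dim
        self.array = array
        self.resolution = resolution
        margin = resolution.margin_factor * array.electrode_length * array.n_electrodes
        self.x = _axis_with_electrodes(array, resolution.elements_per_electrode,
                                       resolution.elements_per_gap, margin,
                                       resolution.growth)
        self.z, self.layer_of_row = _depth_axis(stack, resolution.layer_rows)
        self.layer_thicknesses = tuple(l.thickness for l in stack.layers)
        if self.dim == 3:
            ymargin = resolution.margin_factor * array.electrode_length
            self.y = _axis_across(array, resolution.elements_across_y,
                                  ymargin, resolution.growth)
        else:
            self.y = None
        self._build()

    # -- construction ------------------------------------------------------

    def _node_index(self, ix, iy, iz):
        nz = len(self.z)
        if self.dim == 2:
            return ix * nz + iz
        ny = len(self.y)
        return (ix * ny + iy) * nz + iz

    def _build(self) -> None:
        x, z = self.x, self.z
        hx = np.diff(x)
        hz = np.diff(z)
        nz = len(z)
        if self.dim == 2:
            self.n_nodes = len(x) * nz
            KA = np.kron(_D1, _M1)  # d/dx block
            KB = np.kron(_M1, _D1)  # d/dz block
            ex, ez = np.meshgrid(np.arange(len(hx)), np.arange(len(hz)), indexing="ij")
            ex, ez = ex.ravel(), ez.ravel()
            n00 = self._node_index(ex, None, ez)
            nodes = np.stack([n00, n00 + 1, n00 + nz, n00 + nz + 1], axis=1)
            a, b = hx[ex], hz[ez]
            kloc = (b / a)[:, None, None] * KA + (a / b)[:, None, None] * KB
            layer_of_elem = self.layer_of_row[ez]
        else:
            y = self.y
            hy = np.diff(y)
            ny = len(y)
            self.n_nodes = len(x) * ny * nz
            KA = np.kron(_D1, np.kron(_M1, _M1))
            KB = np.kron(_M1, np.kron(_D1, _M1))
            KC = np.kron(_M1, np.kron(_M1, _D1))
            ex, ey, ez = np.meshgrid(np.arange(len(hx)), np.arange(len(hy)),
                                     np.arange(len(hz)), indexing="ij")
            ex, ey, ez = ex.ravel(), ey.ravel(), ez.ravel()
            n000 = self._node_index(ex, ey, ez)
            offs = [self._node_index(a_, b_, c_) for a_ in (0, 1) for b_ in (0, 1)
                    for c_ in (0, 1)]
            nodes = n000[:, None] + np.array(offs)[None, :]
            a, b, c = hx[ex], hy[ey], hz[ez]
            kloc = ((b * c / a)[:, None, None] * KA
                    + (a * c / b)[:, None, None] * KB
                    + (a * b / c)[:, None, None] * KC)
            layer_of_elem = self.layer_of_row[ez]

        rows = np.repeat(nodes, nodes.shape[1], axis=1)
        cols = np.tile(nodes, (1, nodes.shape[1]))
        self.K_layers = []
        for li in range(len(self.layer_thicknesses)):
            m = layer_of_elem == li
            K = sp.coo_matrix(
                (kloc[m].ravel(), (rows[m].ravel(), cols[m].ravel())),
                shape=(self.n_nodes, self.n_nodes),
            ).tocsr()
            self.K_layers.append(K)
        self.n_elements = nodes.shape[0]
        self._build_electrodes()

    def _build_electrodes(self) -> None:
        """Top-surface (z=0) electrode faces: mass matrices, load vectors, areas."""
        x = self.x
        centers = self.array.positions
        rad = self.array.diameter / 2.0
        self.electrodes = []
        if self.dim == 2:
            xm = 0.5 * (x[:-1] + x[1:])
            for c in centers:
                segs = np.nonzero(np.abs(xm - c) <= rad * (1 + 1e-12))[0]
                if len(segs) == 0:
                    raise ConfigurationError("electrode footprint contains no mesh face")
                r_, c_, v_, s = [], [], np.zeros(0), np.zeros(self.n_nodes)
                data = []
                for e in segs:
                    h = x[e + 1] - x[e]
                    n0 = self._node_index(e, None, 0)
                    n1 = self._node_index(e + 1, None, 0)
                    for (i, j, w) in ((n0, n0, h / 3), (n0, n1, h / 6),
                                      (n1, n0, h / 6), (n1, n1, h / 3)):
                        r_.append(i); c_.append(j); data.append(w)
                    s[n0] += h / 2
                    s[n1] += h / 2
                M = sp.coo_matrix((data, (r_, c_)),
                                  shape=(self.n_nodes, self.n_nodes)).tocsr()
                area = float(s.sum())
                nodesets = np.unique(np.array(r_))
                self.electrodes.append(
                    {"M": M, "s": s, "area": area, "nodes": nodesets}
                )
        else:
            y = self.y
            xm = 0.5 * (x[:-1] + x[1:])
            ym = 0.5 * (y[:-1] + y[1:])
            Mface = np.kron(_M1, _M1)
            for c in centers:
                EX, EY = np.meshgrid(np.arange(len(xm)), np.arange(len(ym)),
                                     indexing="ij")
                inside = (xm[EX] - c) ** 2 + ym[EY] ** 2 <= rad ** 2 * (1 + 1e-12)
                faces = np.argwhere(inside)
                if len(faces) == 0:
                    raise ConfigurationError("electrode footprint contains no mesh face")
                r_, c_, data = [], [], []
                s = np.zeros(self.n_nodes)
                area = 0.0
                for ex_, ey_ in faces:
                    hx_ = x[ex_ + 1] - x[ex_]
                    hy_ = y[ey_ + 1] - y[ey_]
                    ns = [self._node_index(ex_ + a_, ey_ + b_, 0)
                          for a_ in (0, 1) for b_ in (0, 1)]
                    w = hx_ * hy_
                    for i in range(4):
                        for j in range(4):
                            r_.append(ns[i]); c_.append(ns[j])
                            data.append(w * Mface[i, j])
                        s[ns[i]] += w / 4
                    area += w
                M = sp.coo_matrix((data, (r_, c_)),
                                  shape=(self.n_nodes, self.n_nodes)).tocsr()
                self.electrodes.append(
                    {"M": M, "s": s, "area": area, "nodes": np.unique(np.array(r_))}
                )

    # -- helpers -----------------------------------------------------------

    def system_matrix(self, admittivities: np.ndarray) -> sp.csr_matrix:
        K = admittivities[0] * self.K_layers[0]
        for sig, Kl in zip(admittivities[1:], self.K_layers[1:]):
            K = K + sig * Kl
        return K


def build_mesh(stack: SkinStack, array: ElectrodeArray,
               resolution: MeshResolution | None = None) -> LayeredMesh:
    """Discretize the layered domain for the given electrode array."""
    return LayeredMesh(stack, array, resolution or MeshResolution())


# --------------------------------------------------------------------------
# CEM solve
# --------------------------------------------------------------------------

def _electrode_current_targets(pattern: InjectionPattern, n_el: int) -> np.ndarray:
    I = np.zeros(n_el)
    I[pattern.drive_pair[0]] += pattern.current
    I[pattern.drive_pair[1]] -= pattern.current
    return I


def assemble_and_solve(
    mesh: LayeredMesh,
    stack: SkinStack | None,
    array: ElectrodeArray,
    pattern: InjectionPattern,
    f: float,
    admittivities: np.ndarray | None = None,
) -> SolveResult:
    """Solve the CEM problem at one frequency.

    ``admittivities`` overrides the per-layer complex admittivity (ordered
    S, E, D, F); otherwise it is evaluated from ``stack`` at ``f``.
    """
    if f < 0:
        raise InvalidInputError("frequency must be non-negative")
    for idx in (*pattern.drive_pair, *pattern.sense_pair):
        if not 0 <= idx < len(mesh.electrodes):
            raise InvalidInputError(f"electrode index {idx} outside the array")
    if admittivities is None:
        if stack is None:
            raise InvalidInputError("either a stack or explicit admittivities required")
        admittivities = stack.admittivities(f)
    admittivities = np.asarray(admittivities, dtype=complex)
    if np.all(np.abs(admittivities) == 0):
        raise SolverError("all-insulating admittivity: singular system")

    K = mesh.system_matrix(admittivities)
    n_el = len(mesh.electrodes)
    I_target = _electrode_current_targets(pattern, n_el)
    g = pattern.ground

    if array.contact_impedance > 0:
        U, phi = _solve_robin(mesh, K, array, I_target, g)
    else:
        U, phi = _solve_shunt(mesh, K, I_target, g)

    if not (np.all(np.isfinite(U)) and np.all(np.isfinite(phi))):
        raise SolverError("linear solve produced non-finite values")

    currents = _electrode_currents(mesh, K, array, U, phi)
    return SolveResult(U=U, phi=phi, electrode_currents=currents, frequency=f)


def _solve_robin(mesh, K, array, I_target, g):
    n, n_el = mesh.n_nodes, len(mesh.electrodes)
    zeff = [array.contact_impedance * e["area"] for e in mesh.electrodes]
    A = K.astype(complex).tolil()
    for e, z in zip(mesh.electrodes, zeff):
        A = A + e["M"] / z
    # electrode unknowns except the grounded one
    keep = [l for l in range(n_el) if l != g]
    cols = []
    for l in keep:
        cols.append(-mesh.electrodes[l]["s"] / zeff[l])
    B = sp.csr_matrix(np.array(cols).T) if cols else sp.csr_matrix((n, 0))
    Dd = sp.diags([mesh.electrodes[l]["area"] / zeff[l] for l in keep])
    sys = sp.bmat([[A.tocsr(), B], [B.T, Dd]], format="csc")
    rhs = np.zeros(n + len(keep), dtype=complex)
    rhs[n:] = I_target[keep]
    sol = spsolve(sys, rhs)
    phi = sol[:n]
    U = np.zeros(n_el, dtype=complex)
    U[keep] = sol[n:]
    return U, phi


def _solve_shunt(mesh, K, I_target, g):
    """Z_c = 0 limit: electrode surfaces are equipotential with U_l."""
    n, n_el = mesh.n_nodes, len(mesh.electrodes)
    owner = np.full(n, -1, dtype=int)
    for l, e in enumerate(mesh.electrodes):
        owner[e["nodes"]] = l
    free = np.nonzero(owner < 0)[0]
    col_of_node = np.full(n, -1, dtype=int)
    col_of_node[free] = np.arange(len(free))
    keep = [l for l in range(n_el) if l != g]
    col_of_el = {l: len(free) + i for i, l in enumerate(keep)}
    rows, cols, vals = [], [], []
    for node in range(n):
        l = owner[node]
        if l == g:
            continue  # grounded: phi = 0
        c = col_of_node[node] if l < 0 else col_of_el[l]
        rows.append(node); cols.append(c); vals.append(1.0)
    P = sp.coo_matrix((vals, (rows, cols)), shape=(n, len(free) + len(keep))).tocsr()
    Kr = (P.T @ K @ P).tocsc()
    rhs = np.zeros(len(free) + len(keep), dtype=complex)
    for l in keep:
        rhs[col_of_el[l]] = I_target[l]
    sol = spsolve(Kr, rhs)
    phi = P @ sol
    U = np.zeros(n_el, dtype=complex)
    for l in keep:
        U[l] = sol[col_of_el[l]]
    return U, phi


def _electrode_currents(mesh, K, array, U, phi):
    """Current into the tissue through each electrode."""
    n_el = len(mesh.electrodes)
    out = np.zeros(n_el, dtype=complex)
    if array.contact_impedance > 0:
        for l, e in enumerate(mesh.electrodes):
            z = array.contact_impedance * e["area"]
            out[l] = (e["area"] * U[l] - e["s"] @ phi) / z
    else:
        r = K @ phi
        for l, e in enumerate(mesh.electrodes):
            out[l] = r[e["nodes"]].sum()
    return out


def measure_impedance(result: SolveResult, pattern: InjectionPattern) -> complex:
    """Transfer impedance Z = (U_high - U_low) / I for the sense pair."""
    if pattern.current == 0:
        raise InvalidInputError("injected current must be nonzero")
    hi, lo = pattern.sense_pair
    return complex((result.U[hi] - result.U[lo]) / pattern.current)


def sweep_spectrum(
    stack: SkinStack,
    array: ElectrodeArray,
    pattern: InjectionPattern,
    frequencies: Iterable[float],
    mesh: LayeredMesh | None = None,
    resolution: MeshResolution | None = None,
    meta: dict | None = None,
) -> ImpedanceSpectrum:
    """Solve the CEM problem at each frequency and collect the spectrum."""
    freqs = np.asarray(list(frequencies), dtype=float)
    if len(freqs) == 0:
        raise InvalidInputError("frequency list must be non-empty")
    if mesh is None:
        mesh = build_mesh(stack, array, resolution)
    Z = np.empty(len(freqs), dtype=complex)
    for i, f in enumerate(freqs):
        res = assemble_and_solve(mesh, stack, array, pattern, f)
        Z[i] = measure_impedance(res, pattern)
    md = {
        "pattern": pattern.mode,
        "d_e_mm": array.diameter * 1e3,
        "d_g_mm": array.gap * 1e3,
        "z_c_ohm": array.contact_impedance,
        "current_a": pattern.current,
    }
    if meta:
        md.update(meta)
    return ImpedanceSpectrum(freqs, Z, md)


# --------------------------------------------------------------------------
# Spectrum CSV dialect
# --------------------------------------------------------------------------

def write_spectrum_csv(spectrum: ImpedanceSpectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# format_version: 1\n")
        for k, v in spectrum.meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("frequency_hz,z_real_ohm,z_imag_ohm\n")
        for f, z in zip(spectrum.frequencies, spectrum.Z):
            fh.write(f"{float(f)!r},{float(z.real)!r},{float(z.imag)!r}\n")


def read_spectrum_csv(path: str | Path) -> ImpedanceSpectrum:
    meta: dict = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = _parse_meta_value(v.strip())
                continue
            if line.startswith("frequency_hz"):
                continue
            f, re_, im_ = (float(tok) for tok in line.split(","))
            rows.append((f, complex(re_, im_)))
    if not rows:
        raise InvalidInputError(f"{path}: no spectrum rows found")
    freqs = np.array([r[0] for r in rows])
    Z = np.array([r[1] for r in rows])
    return ImpedanceSpectrum(freqs, Z, meta)


def _parse_meta_value(v: str):
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    return v
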