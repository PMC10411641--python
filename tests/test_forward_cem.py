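import numpy as np
import pytest

from skinbis.dielectric import InvalidInputError
from skinbis.forward_cem import (
    ConfigurationError,
    ElectrodeArray,
    ImpedanceSpectrum,
    InjectionPattern,
    MeshResolution,
    SolveResult,
    assemble_and_solve,
    build_mesh,
    measure_impedance,
    read_spectrum_csv,
    sweep_spectrum,
    write_spectrum_csv,
)

STUDY_FREQS = [2e3, 1e4, 3.5e4, 1e5, 2.25e5]


@pytest.fixture(scope="module")
def mesh(stack, array, coarse_resolution):
    return build_mesh(stack, array, coarse_resolution)


class TestMesh:
    def test_stratum_corneum_resolved_by_multiple_rows(self, mesh, stack):
        rows_in_sc = np.sum(mesh.layer_of_row == 0)
        assert rows_in_sc >= 2
        # the rows actually span the stratum corneum thickness
        assert mesh.z[rows_in_sc] == pytest.approx(stack.layers[0].thickness)

    def test_refinement_increases_elements_keeps_layer_map(self, stack, array,
                                                           coarse_resolution):
        fine = build_mesh(stack, array, coarse_resolution.refined(2))
        coarse = build_mesh(stack, array, coarse_resolution)
        assert fine.n_elements > coarse.n_elements
        # layer boundaries still coincide with grid planes
        bounds = np.cumsum([l.thickness for l in stack.layers])
        for b in bounds:
            assert np.any(np.isclose(fine.z, b))

    def test_degenerate_row_request_rejected(self, stack, array):
        with pytest.raises(ConfigurationError):
            build_mesh(stack, array, MeshResolution(layer_rows=(0, 4, 4, 4)))

    def test_electrode_faces_cover_diameter(self, mesh, array):
        for el in mesh.electrodes:
            assert el["area"] == pytest.approx(array.diameter, rel=1e-9)


class TestCEMPhysics:
    def test_homogeneous_real_conductivity_gives_real_impedance(self, mesh, array):
        arr0 = ElectrodeArray(contact_impedance=0.0)
        pat = InjectionPattern.bipolar()
        res = assemble_and_solve(mesh, None, arr0, pat, 0.0,
                                 admittivities=np.full(4, 0.3, dtype=complex))
        z = measure_impedance(res, pat)
        assert z.imag == pytest.approx(0.0, abs=1e-12 * abs(z))
        assert z.real > 0

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_conductivity_scaling(self, mesh, array, c):
        arr0 = ElectrodeArray(contact_impedance=0.0)
        pat = InjectionPattern.bipolar()
        adm = np.array([0.1, 0.2, 0.5, 0.03], dtype=complex)
        z1 = measure_impedance(assemble_and_solve(mesh, None, arr0, pat, 0.0,
                                                  admittivities=adm), pat)
        z2 = measure_impedance(assemble_and_solve(mesh, None, arr0, pat, 0.0,
                                                  admittivities=c * adm), pat)
        assert z2 == pytest.approx(z1 / c, rel=1e-10)

    def test_tetrapolar_reciprocity(self, mesh, stack, array):
        p1 = InjectionPattern.tetrapolar()
        p2 = InjectionPattern("tetrapolar", (1, 2), (0, 3), 1e-3)
        z1 = measure_impedance(assemble_and_solve(mesh, stack, array, p1, 1e4), p1)
        z2 = measure_impedance(assemble_and_solve(mesh, stack, array, p2, 1e4), p2)
        assert abs(z1 - z2) / abs(z1) < 1e-8

    @pytest.mark.parametrize("zc", [0.0, 50.0])
    def test_current_conservation(self, mesh, stack, zc):
        arr = ElectrodeArray(contact_impedance=zc)
        pat = InjectionPattern.tetrapolar()
        res = assemble_and_solve(mesh, stack, arr, pat, 1e5)
        assert abs(res.electrode_currents.sum()) < 1e-10 * pat.current
        # drive electrodes carry +/- I, passive electrodes ~0
        assert res.electrode_currents[0] == pytest.approx(pat.current, rel=1e-8)
        assert res.electrode_currents[3] == pytest.approx(-pat.current, rel=1e-8)

    def test_mesh_convergence_under_refinement(self, stack, array):
        # default discretization vs 2x refinement: |Z| drift below 1 %
        pat_b = InjectionPattern.bipolar()
        pat_t = InjectionPattern.tetrapolar()
        m1 = build_mesh(stack, array)
        m2 = build_mesh(stack, array, MeshResolution().refined(2))
        for pat in (pat_b, pat_t):
            for f in (2e3, 2.25e5):
                z1 = measure_impedance(assemble_and_solve(m1, stack, array, pat, f), pat)
                z2 = measure_impedance(assemble_and_solve(m2, stack, array, pat, f), pat)
                assert abs(abs(z2) - abs(z1)) / abs(z1) < 0.01

    def test_bipolar_magnitude_exceeds_tetrapolar(self, mesh, stack, array):
        for f in STUDY_FREQS:
            zb = measure_impedance(
                assemble_and_solve(mesh, stack, array, InjectionPattern.bipolar(), f),
                InjectionPattern.bipolar())
            zt = measure_impedance(
                assemble_and_solve(mesh, stack, array, InjectionPattern.tetrapolar(), f),
                InjectionPattern.tetrapolar())
            assert abs(zb) > abs(zt)

    def test_bipolar_includes_contact_impedance(self, mesh, stack):
        # raising Z_c by dZ raises bipolar Re(Z) by ~2*dZ (two series contacts)
        pat = InjectionPattern.bipolar()
        z50 = measure_impedance(
            assemble_and_solve(mesh, stack, ElectrodeArray(contact_impedance=50.0),
                               pat, 1e4), pat)
        z150 = measure_impedance(
            assemble_and_solve(mesh, stack, ElectrodeArray(contact_impedance=150.0),
                               pat, 1e4), pat)
        assert (z150 - z50).real == pytest.approx(200.0, rel=0.05)

    def test_complex_admittivity_linearity(self, mesh):
        # homogeneous material, Z_c = 0: Z(c * sigma*) = Z(sigma*) / c for complex c
        arr0 = ElectrodeArray(contact_impedance=0.0)
        pat = InjectionPattern.bipolar()
        c = 0.8 + 0.3j
        adm = np.full(4, 0.2 + 0.05j)
        z1 = measure_impedance(assemble_and_solve(mesh, None, arr0, pat, 0.0,
                                                  admittivities=adm), pat)
        z2 = measure_impedance(assemble_and_solve(mesh, None, arr0, pat, 0.0,
                                                  admittivities=c * adm), pat)
        assert z2 == pytest.approx(z1 / c, rel=1e-10)

    def test_permittivity_increase_raises_reactance_below_corner(self, mesh):
        # while omega*eps << sigma, added permittivity increases |Im Z|
        arr0 = ElectrodeArray(contact_impedance=0.0)
        pat = InjectionPattern.bipolar()
        z0 = measure_impedance(assemble_and_solve(
            mesh, None, arr0, pat, 0.0,
            admittivities=np.full(4, 0.3 + 0.003j)), pat)
        z1 = measure_impedance(assemble_and_solve(
            mesh, None, arr0, pat, 0.0,
            admittivities=np.full(4, 0.3 + 0.006j)), pat)
        assert abs(z1.imag) > abs(z0.imag)

    def test_all_insulating_rejected(self, mesh, array):
        from skinbis.forward_cem import SolverError
        pat = InjectionPattern.bipolar()
        with pytest.raises(SolverError):
            assemble_and_solve(mesh, None, array, pat, 0.0,
                               admittivities=np.zeros(4, dtype=complex))

    def test_three_dimensional_solver_consistency(self, stack):
        """3-D circular-footprint solve: same physics invariants as 2-D."""
        arr = ElectrodeArray()
        res3 = MeshResolution(dim=3, elements_per_electrode=4, elements_per_gap=2,
                              layer_rows=(2, 3, 4, 3), elements_across_y=4,
                              growth=2.0, margin_factor=3.0)
        mesh3 = build_mesh(stack, arr, res3)
        pat = InjectionPattern.tetrapolar()
        res = assemble_and_solve(mesh3, stack, arr, pat, 1e4)
        assert abs(res.electrode_currents.sum()) < 1e-10 * pat.current
        p2 = InjectionPattern("tetrapolar", (1, 2), (0, 3), 1e-3)
        z1 = measure_impedance(res, pat)
        z2 = measure_impedance(assemble_and_solve(mesh3, stack, arr, p2, 1e4), p2)
        assert abs(z1 - z2) / abs(z1) < 1e-8


class TestMeasurement:
    def test_equal_sense_potentials_give_zero(self):
        pat = InjectionPattern.tetrapolar()
        res = SolveResult(U=np.array([1, 0.5, 0.5, 0], dtype=complex),
                          phi=np.zeros(1), electrode_currents=np.zeros(4),
                          frequency=0.0)
        assert measure_impedance(res, pat) == 0

    def test_impedance_arithmetic(self):
        pat = InjectionPattern.tetrapolar()
        res = SolveResult(U=np.array([0, 1e-3 + 2e-3j, 0, 0], dtype=complex),
                          phi=np.zeros(1), electrode_currents=np.zeros(4),
                          frequency=0.0)
        assert measure_impedance(res, pat) == pytest.approx(1 + 2j)

    def test_zero_current_rejected(self):
        pat = InjectionPattern("bipolar", (1, 2), (1, 2), 0.0)
        res = SolveResult(np.zeros(4, complex), np.zeros(1), np.zeros(4), 0.0)
        with pytest.raises(InvalidInputError):
            measure_impedance(res, pat)

    def test_pattern_invariants(self):
        with pytest.raises(InvalidInputError):
            InjectionPattern("bipolar", (1, 2), (0, 3), 1e-3)
        with pytest.raises(InvalidInputError):
            InjectionPattern("tetrapolar", (0, 3), (0, 2), 1e-3)
        with pytest.raises(InvalidInputError):
            InjectionPattern("bipolar", (1, 1), (1, 1), 1e-3)


class TestSpectrum:
    def test_study_sweep_returns_five_points(self, stack, array, mesh):
        spec = sweep_spectrum(stack, array, InjectionPattern.bipolar(),
                              STUDY_FREQS, mesh=mesh)
        assert len(spec.Z) == 5
        assert spec.meta["pattern"] == "bipolar"

    def test_single_frequency_sweep(self, stack, array, mesh):
        spec = sweep_spectrum(stack, array, InjectionPattern.bipolar(), [1e4],
                              mesh=mesh)
        assert len(spec.Z) == 1

    def test_empty_frequency_list_rejected(self, stack, array, mesh):
        with pytest.raises(InvalidInputError):
            sweep_spectrum(stack, array, InjectionPattern.bipolar(), [], mesh=mesh)

    def test_csv_round_trip(self, stack, array, mesh, tmp_path):
        spec = sweep_spectrum(stack, array, InjectionPattern.tetrapolar(),
                              STUDY_FREQS, mesh=mesh, meta={"case_id": "demo"})
        path = tmp_path / "spec.csv"
        write_spectrum_csv(spec, path)
        back = read_spectrum_csv(path)
        assert np.array_equal(back.frequencies, spec.frequencies)
        assert np.array_equal(back.Z, spec.Z)
        assert back.meta["case_id"] == "demo"
        assert back.meta["pattern"] == "tetrapolar"

    def test_unsorted_frequencies_rejected(self):
        with pytest.raises(InvalidInputError):
            ImpedanceSpectrum(np.array([2.0, 1.0]), np.array([1 + 0j, 1 + 0j]))
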