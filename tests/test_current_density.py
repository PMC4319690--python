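"""Finite-volume Laplace solver against closed-form conductor solutions."""

import numpy as np
import pytest

from tremorsync import current_density as cd
from tremorsync.io_core import DegenerateInputError, SolverError, ValidationError


def plate_model(n=16, sigma=0.33, labels_override=None):
    """Box of uniform conductivity with air padding on the x/y faces."""
    labels = np.full((n + 4, n + 4, n), cd.AIR, dtype=np.int16)
    labels[2:-2, 2:-2, :] = cd.GRAY
    if labels_override is not None:
        labels_override(labels)
    conductivity = dict(cd.DEFAULT_CONDUCTIVITY)
    conductivity[cd.GRAY] = sigma
    return cd.VoxelHeadModel(labels=labels, voxel_size_mm=2.0,
                             conductivity=conductivity)


def plate_electrodes(model):
    """Full opposite z-faces of the conductive box at +-1 V."""
    lab = model.labels
    tissue = lab != cd.AIR
    low, high = [], []
    for i, j in np.ndindex(lab.shape[0], lab.shape[1]):
        col = np.flatnonzero(tissue[i, j])
        if col.size:
            low.append((i, j, col[0]))
            high.append((i, j, col[-1]))
    source = cd.ElectrodeSpec(np.array(high), "source", +1.0)
    ret = cd.ElectrodeSpec(np.array(low), "return", -1.0)
    return source, ret


class TestPhantom:
    def test_tissue_conductivities(self):
        model = cd.build_phantom(
            [("skin", 40.0), ("bone", 36.0), ("csf", 32.0),
             ("gray", 28.0), ("white", 20.0)],
            voxel_size_mm=4.0,
            shoulders=True,
        )
        sigma = model.conductivity_volume()
        assert sigma[model.labels == cd.BONE].mean() == pytest.approx(0.0064)
        assert sigma[model.labels == cd.CSF].mean() == pytest.approx(1.79)
        assert np.any(model.labels == cd.AVERAGE)
        assert sigma[model.labels == cd.AVERAGE].mean() == pytest.approx(0.08)
        assert model.boundary_is_air()

    def test_layers_out_of_order_rejected(self):
        with pytest.raises(ValidationError):
            cd.build_phantom([("skin", 30.0), ("bone", 35.0)])

    def test_missing_conductivity_rejected(self):
        with pytest.raises(ValidationError):
            cd.VoxelHeadModel(
                labels=np.full((4, 4, 4), 99, dtype=np.int16), voxel_size_mm=2.0
            )


class TestAttachElectrode:
    def test_footprint_and_saline_layer(self):
        model = cd.build_phantom([("skin", 60.0)], voxel_size_mm=2.0, pad_voxels=4)
        nx, ny, nz = model.labels.shape
        center = [nx / 2 * 2.0, ny / 2 * 2.0, nz * 2.0 - 1.0]
        spec = cd.attach_electrode(model, center, size_mm=(50.0, 70.0),
                                   direction="+z", role="source")
        area_mm2 = spec.pad_voxels.shape[0] * 2.0**2
        # footprint within one voxel ring of 50 x 70 mm^2 over the dome
        ring = (2 * (25 + 35) + 4) * 2.0**2
        assert abs(area_mm2 - 3500.0) <= ring
        assert np.any(model.labels == cd.SALINE)
        sigma = model.conductivity_volume()
        assert sigma[model.labels == cd.SALINE].mean() == pytest.approx(0.367)

    def test_overlapping_pad_rejected(self):
        model = cd.build_phantom([("skin", 40.0)], voxel_size_mm=2.0, pad_voxels=4)
        nx, ny, nz = model.labels.shape
        center = [nx / 2 * 2.0, ny / 2 * 2.0, nz * 2.0 - 1.0]
        cd.attach_electrode(model, center, size_mm=(20, 20), direction="+z")
        with pytest.raises(ValidationError):
            cd.attach_electrode(model, center, size_mm=(20, 20), direction="+z")

    def test_off_surface_center_rejected(self):
        model = cd.build_phantom([("skin", 30.0)], voxel_size_mm=2.0, pad_voxels=4)
        with pytest.raises(ValidationError):
            cd.attach_electrode(model, [2.0, 2.0, 2.0], size_mm=(10, 10),
                                direction="+z")


class TestSolverClosedForms:
    def test_parallel_plate_uniform_field(self):
        n = 16
        model = plate_model(n=n)
        source, ret = plate_electrodes(model)
        sol = cd.solve_laplace(model, [source, ret])
        h_m = 2.0e-3
        length = (n - 1) * h_m  # plate-center to plate-center
        expected_e = 2.0 / length
        interior = np.zeros(model.labels.shape, dtype=bool)
        interior[6:-6, 6:-6, 3:-3] = True
        e_mag = np.sqrt((sol.efield**2).sum(axis=0))
        np.testing.assert_allclose(e_mag[interior], expected_e, rtol=0.01)
        # potential is linear along z in the interior
        phi_line = sol.phi[model.labels.shape[0] // 2,
                           model.labels.shape[1] // 2, :]
        diffs = np.diff(phi_line[2:-2])
        np.testing.assert_allclose(diffs, diffs.mean(), rtol=0.01)

    def test_two_layer_slab_series_circuit(self):
        n = 16
        s1, s2 = 0.2, 0.1  # 2:1 contrast

        def relabel(labels):
            labels[2:-2, 2:-2, n // 2:] = cd.WHITE

        model = plate_model(n=n, sigma=s1, labels_override=relabel)
        model.conductivity[cd.WHITE] = s2
        source, ret = plate_electrodes(model)
        sol = cd.solve_laplace(model, [source, ret])
        i, j = model.labels.shape[0] // 2, model.labels.shape[1] // 2
        ez = -sol.efield[2]
        jz = -sol.current[2]
        # evaluate mid-layer, away from interface and plates
        e1, e2 = ez[i, j, 4], ez[i, j, n - 5]
        j1, j2 = jz[i, j, 4], jz[i, j, n - 5]
        assert j1 == pytest.approx(j2, rel=0.01)  # normal J continuous
        assert e2 / e1 == pytest.approx(s1 / s2, rel=0.01)  # |E| ratio 1:2
        # closed form: J = dV / sum(L_k / sigma_k) per unit area
        h_m = 2.0e-3
        l1 = (n // 2 - 0.5) * h_m
        l2 = (n // 2 - 0.5) * h_m
        expected_j = 2.0 / (l1 / s1 + l2 / s2)
        assert abs(j1) == pytest.approx(expected_j, rel=0.01)

    def test_current_conservation_in_closed_region(self):
        model = plate_model(n=12)
        source, ret = plate_electrodes(model)
        sol = cd.solve_laplace(model, [source, ret], tol=1e-10)
        region = np.zeros(model.labels.shape, dtype=bool)
        region[4:-4, 4:-4, 3:-3] = True  # contains no electrode voxel
        flux = cd.region_outflux(sol.phi, sol.sigma, 2.0e-3, region)
        assert abs(flux) <= 1e-6 * sol.injected_current


class TestSolverProperties:
    @pytest.fixture()
    def small_sphere(self):
        model = cd.build_phantom([("skin", 24.0), ("gray", 18.0)],
                                 voxel_size_mm=3.0, pad_voxels=4)
        nx, ny, nz = model.labels.shape
        cx, cy = nx / 2 * 3.0, ny / 2 * 3.0
        src = cd.attach_electrode(model, [cx, cy, nz * 3.0 - 1], size_mm=(9, 9),
                                  direction="+z", role="source", potential=1.0)
        ret = cd.attach_electrode(model, [cx, cy, 1.0], size_mm=(9, 9),
                                  direction="-z", role="return", potential=-1.0)
        return model, src, ret

    def test_swapping_electrodes_negates_potential(self, small_sphere):
        model, src, ret = small_sphere
        sol = cd.solve_laplace(model, [src, ret], tol=1e-10)
        src_swapped = cd.ElectrodeSpec(ret.pad_voxels, "source", +1.0)
        ret_swapped = cd.ElectrodeSpec(src.pad_voxels, "return", -1.0)
        swapped = cd.solve_laplace(model, [src_swapped, ret_swapped], tol=1e-10)
        scale = np.max(np.abs(sol.phi))
        # geometric antisymmetry: potentials negate
        assert np.max(np.abs(swapped.phi + sol.phi)) < 1e-5 * scale

    def test_linearity_in_electrode_potential(self, small_sphere):
        model, src, ret = small_sphere
        sol1 = cd.solve_laplace(model, [src, ret], tol=1e-10)
        src2 = cd.ElectrodeSpec(src.pad_voxels, "source", +2.0)
        ret2 = cd.ElectrodeSpec(ret.pad_voxels, "return", -2.0)
        sol2 = cd.solve_laplace(model, [src2, ret2], tol=1e-10)
        assert sol2.injected_current == pytest.approx(
            2.0 * sol1.injected_current, rel=1e-6
        )
        np.testing.assert_allclose(sol2.jmag, 2.0 * sol1.jmag,
                                   rtol=1e-5, atol=1e-12)

    def test_scale_to_current(self, small_sphere):
        model, src, ret = small_sphere
        sol = cd.solve_laplace(model, [src, ret])
        scaled = cd.scale_to_current(sol, 1e-3)
        assert scaled.injected_current == 1e-3
        k = 1e-3 / sol.injected_current
        np.testing.assert_allclose(scaled.phi, k * sol.phi)
        # identity and multiplicative composition
        same = cd.scale_to_current(sol, sol.injected_current)
        np.testing.assert_allclose(same.phi, sol.phi)
        twice = cd.scale_to_current(cd.scale_to_current(sol, 2e-3), 1e-3)
        np.testing.assert_allclose(twice.jmag, scaled.jmag, rtol=1e-12)

    def test_nonconvergence_raises(self, small_sphere):
        model, src, ret = small_sphere
        with pytest.raises(SolverError):
            cd.solve_laplace(model, [src, ret], tol=1e-12, max_iter=3)

    def test_electrode_roles_validated(self, small_sphere):
        model, src, ret = small_sphere
        with pytest.raises(ValidationError):
            cd.solve_laplace(model, [src, src])


class TestRoiOperators:
    def _uniform_solution(self, value=2.0):
        shape = (6, 6, 6)
        return cd.FieldSolution(
            phi=np.zeros(shape),
            efield=np.zeros((3,) + shape),
            current=np.zeros((3,) + shape),
            jmag=np.full(shape, value),
            injected_current=1e-3,
            sigma=np.ones(shape),
            voxel_size_mm=2.0,
        )

    def test_uniform_field_mean(self):
        sol = self._uniform_solution(2.0)
        mask = np.zeros(sol.jmag.shape, dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        assert cd.roi_mean_density(sol, mask) == pytest.approx(2.0)

    def test_single_voxel_mask(self):
        sol = self._uniform_solution(1.0)
        sol.jmag[2, 3, 4] = 7.5
        mask = np.zeros(sol.jmag.shape, dtype=bool)
        mask[2, 3, 4] = True
        assert cd.roi_mean_density(sol, mask) == pytest.approx(7.5)

    def test_union_is_size_weighted_mean(self, rng):
        sol = self._uniform_solution(0.0)
        sol.jmag[:] = rng.uniform(0.5, 1.5, sol.jmag.shape)
        m1 = np.zeros(sol.jmag.shape, dtype=bool)
        m2 = np.zeros(sol.jmag.shape, dtype=bool)
        m1[0:2] = True
        m2[4:5] = True
        n1, n2 = m1.sum(), m2.sum()
        expected = (
            cd.roi_mean_density(sol, m1) * n1 + cd.roi_mean_density(sol, m2) * n2
        ) / (n1 + n2)
        assert cd.roi_mean_density(sol, m1 | m2) == pytest.approx(expected)

    def test_empty_mask_rejected(self):
        sol = self._uniform_solution()
        with pytest.raises(ValidationError):
            cd.roi_mean_density(sol, np.zeros(sol.jmag.shape, dtype=bool))

    def test_montage_contrast_arithmetic(self):
        a = self._uniform_solution(1.072)
        b = self._uniform_solution(1.000)
        mask = np.ones(a.jmag.shape, dtype=bool)
        assert cd.montage_contrast(a, b, mask) == pytest.approx(7.2)
        assert cd.montage_contrast(a, a, mask) == 0.0

    def test_zero_reference_rejected(self):
        a = self._uniform_solution(1.0)
        b = self._uniform_solution(0.0)
        mask = np.ones(a.jmag.shape, dtype=bool)
        with pytest.raises(DegenerateInputError):
            cd.montage_contrast(a, b, mask)


class TestNiftiExport:
    def test_round_trip_through_nibabel(self, tmp_path, rng):
        import nibabel as nib

        vol = rng.uniform(0, 1, (8, 8, 8)).astype(np.float32)
        cd.export_nifti(vol, 2.0, tmp_path / "v.nii")
        img = nib.load(tmp_path / "v.nii")
        np.testing.assert_allclose(np.asarray(img.dataobj), vol, rtol=1e-6)
        assert img.header.get_zooms()[0] == pytest.approx(2.0)
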