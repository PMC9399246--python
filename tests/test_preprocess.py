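"""Volume loading, isosurface extraction and frontal depth rendering."""

import numpy as np
import pytest

from anoscore.phantoms import PhantomSpec, make_phantom_volume
from anoscore.preprocess import (RenderedImage, VolumeGrid, depth_map,
                                 extract_isosurface, load_dicom_series,
                                 mesh_surface_area, render_frontal,
                                 resize_normalize)

from conftest import sphere_volume


class TestDicom:
    def test_rescale_to_hounsfield(self, dicom_series_dir):
        # stored value 1024 with slope 1, intercept -1024 -> 0 HU
        vol = load_dicom_series(dicom_series_dir())
        assert vol.values.min() >= 0.0            # first slice maps to 0 HU
        assert np.isclose(vol.values.flat[0], 0.0)
        assert vol.spacing[0] == pytest.approx(0.7)

    def test_sort_invariance(self, dicom_series_dir, tmp_path):
        ordered = load_dicom_series(dicom_series_dir())
        shuffled = load_dicom_series(dicom_series_dir(shuffle_names=True))
        np.testing.assert_array_equal(ordered.values, shuffled.values)

    def test_inconsistent_spacing_rejected_by_name(self, dicom_series_dir):
        with pytest.raises(ValueError, match="PixelSpacing"):
            load_dicom_series(dicom_series_dir(break_spacing=True))


class TestIsosurface:
    def test_sphere_vertex_radii(self):
        vol = sphere_volume(radius_mm=10.0, spacing=1.0)
        mesh = extract_isosurface(vol, 0.0)
        center = (np.array(vol.values.shape) - 1) / 2.0
        radii = np.linalg.norm(mesh.vertices - center, axis=1)
        assert np.abs(radii - 10.0).max() <= 0.5   # within half a voxel

    def test_constant_volume_rejected_with_range(self):
        vol = VolumeGrid(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError, match=r"\[0\.0, 0\.0\]"):
            extract_isosurface(vol, 0.5)

    def test_surface_area_converges_to_sphere(self):
        analytic = 4.0 * np.pi * 10.0**2
        errors = []
        for spacing in (2.0, 1.0, 0.5):
            vol = sphere_volume(radius_mm=10.0, spacing=spacing)
            mesh = extract_isosurface(vol, 0.0)
            errors.append(abs(mesh_surface_area(mesh) - analytic))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] / analytic < 0.05


class TestFrontalRender:
    def test_hemisphere_depth_matches_closed_form(self):
        vol = sphere_volume(radius_mm=10.0, spacing=1.0)
        depth, hit = depth_map(vol, 0.0)
        n = vol.values.shape[0]
        c = (n - 1) / 2.0
        ys, zs = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
        rho2 = ys**2 + zs**2
        inside = rho2 <= 9.0**2                   # avoid the tangent rim
        expected = c - np.sqrt(10.0**2 - rho2[inside])
        assert hit[inside].all()
        assert np.abs(depth[inside] - expected).max() <= 1.0  # one voxel

    def test_mesh_render_matches_closed_form_sphere(self):
        # rasterized mesh depth vs analytic sphere depth, sub-voxel
        vol = sphere_volume(radius_mm=10.0, spacing=1.0)
        mesh = extract_isosurface(vol, 0.0)
        from anoscore.preprocess import _depth_from_mesh
        n = 65
        depth, hit = _depth_from_mesh(mesh, n)
        ys = np.linspace(mesh.vertices[:, 1].min(),
                         mesh.vertices[:, 1].max(), n)
        zs = np.linspace(mesh.vertices[:, 2].min(),
                         mesh.vertices[:, 2].max(), n)
        c = (vol.values.shape[0] - 1) / 2.0
        yy, zz = np.meshgrid(ys - c, zs - c, indexing="ij")
        rho2 = yy**2 + zz**2
        inside = rho2 <= 9.0**2
        expected = (c - np.sqrt(100.0 - rho2[inside])) \
            - mesh.vertices[:, 0].min()
        assert hit[inside].all()
        assert np.nanmax(np.abs(depth[inside] - expected)) <= 0.5
        img = render_frontal(mesh, 64)
        assert img.pixels.shape == (64, 64)
        assert (img.pixels == 1.0).any()

    def test_mirrored_volume_gives_mirrored_image(self):
        vol = make_phantom_volume(PhantomSpec(
            anomaly_kind="asymmetry", severity=1.0, seed=5, noise_sd=0.0))
        mirrored = VolumeGrid(vol.values[:, ::-1, :].copy(), vol.spacing)
        img = render_frontal(vol, 64)
        img_m = render_frontal(mirrored, 64)
        np.testing.assert_array_equal(img.pixels, img_m.pixels[:, ::-1])

    def test_background_is_exactly_white(self):
        img = render_frontal(make_phantom_volume(PhantomSpec(seed=0)), 64)
        background = img.pixels == 1.0
        assert background.any()
        assert img.pixels[~background].max() <= 0.95

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            render_frontal(VolumeGrid(np.zeros((1, 1, 1))), 32)


class TestResize:
    def test_idempotent_at_same_size(self):
        img = RenderedImage(np.random.default_rng(0).random((32, 32)))
        out = resize_normalize(img, 32)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_constant_image_stays_constant(self):
        img = RenderedImage(np.full((50, 50), 0.5))
        out = resize_normalize(img, 23)
        np.testing.assert_allclose(out.pixels, 0.5)

    def test_render_resize_pipeline_sizes(self):
        # 500x500 intermediate render downsampled to the 256x256 network input
        img = render_frontal(make_phantom_volume(PhantomSpec(seed=1)), 500)
        assert img.size == 500
        small = resize_normalize(img, 256)
        assert small.pixels.shape == (256, 256)
        assert small.pixels.min() >= 0.0 and small.pixels.max() <= 1.0

    def test_end_to_end_render_deterministic(self):
        spec = PhantomSpec(seed=3)
        a = resize_normalize(render_frontal(make_phantom_volume(spec), 64), 32)
        b = resize_normalize(render_frontal(make_phantom_volume(spec), 64), 32)
        np.testing.assert_array_equal(a.pixels, b.pixels)
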