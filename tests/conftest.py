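"""Shared fixtures: tiny trained models and synthetic DICOM series.

The session-scoped ``tiny_model`` is a seconds-scale training run used by
unit tests that need a trained-but-rough model; ``toy_model`` is the
minutes-scale study configuration (64x64 renders, 200 normals, 2000
generator steps) used by the discrimination and monotonicity checks, and
is trained at most once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from anoscore.anogan import GanHyperparams, train_encoder, train_wgan
from anoscore.phantoms import PhantomSpec, generate_image_dataset

TINY_HP = GanHyperparams(input_size=32, latent_dim=8, hidden_dim=32,
                         batch_size=16, n_steps=120, encoder_steps=120,
                         seed=0)


@pytest.fixture(scope="session")
def tiny_images():
    return generate_image_dataset(40, 0, PhantomSpec(image_size=32), seed=0).images


@pytest.fixture(scope="session")
def tiny_model(tiny_images):
    model = train_wgan(tiny_images, TINY_HP)
    return train_encoder(model, tiny_images, TINY_HP)


@pytest.fixture(scope="session")
def toy_model():
    """Study-scale model: 200 normal 64x64 phantoms, 2000 generator steps."""
    from anoscore.experiments import train_toy_model
    model, train_images = train_toy_model(n_normal=200, seed=0)
    return model, train_images


@pytest.fixture()
def dicom_series_dir(tmp_path):
    """Write a tiny synthetic 3-slice CT series; returns its directory."""
    def make(n_slices=3, shuffle_names=False, break_spacing=False):
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        series_uid = generate_uid()
        rng = np.random.default_rng(0)
        order = list(range(n_slices))
        names = [f"slice_{i:02d}.dcm" for i in range(n_slices)]
        if shuffle_names:
            names = names[::-1]
        for i, name in zip(order, names):
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
            meta.MediaStorageSOPInstanceUID = generate_uid()
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds = FileDataset(name, {}, file_meta=meta, preamble=b"\0" * 128)
            ds.SOPClassUID = meta.MediaStorageSOPClassUID
            ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
            ds.SeriesInstanceUID = series_uid
            ds.Modality = "CT"
            ds.Rows = ds.Columns = 8
            spacing = [0.7, 0.7] if not (break_spacing and i == 1) else [0.9, 0.9]
            ds.PixelSpacing = spacing
            ds.SliceThickness = 2.0
            ds.ImagePositionPatient = [0.0, 0.0, float(2 * i)]
            ds.RescaleSlope = 1.0
            ds.RescaleIntercept = -1024.0
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            pixels = np.full((8, 8), 1024 + 10 * i, dtype=np.uint16)
            pixels[2:6, 2:6] += rng.integers(0, 5, size=(4, 4)).astype(np.uint16)
            ds.PixelData = pixels.tobytes()
            ds.save_as(tmp_path / name, enforce_file_format=True)
        return tmp_path
    return make


def sphere_volume(radius_mm=10.0, spacing=1.0, margin=4.0):
    """Signed sphere field (radius - r): the zero level set is the exact
    sphere surface and linear interpolation of the field is sub-voxel
    accurate, so marching cubes and depth casting at iso level 0 can be
    compared against closed forms."""
    from anoscore.preprocess import VolumeGrid
    half = radius_mm + margin
    n = int(round(2 * half / spacing)) + 1
    coords = (np.arange(n) - (n - 1) / 2.0) * spacing
    x, y, z = np.meshgrid(coords, coords, coords, indexing="ij")
    r = np.sqrt(x**2 + y**2 + z**2)
    return VolumeGrid(radius_mm - r, spacing=(spacing, spacing, spacing))
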