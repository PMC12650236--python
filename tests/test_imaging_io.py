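"""I/O: HU rescale, DICOM/NIfTI round-trips, plist annotations, rasterization."""

import numpy as np
import pydicom
import pytest
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from cacseg.imaging_io import (ARTERY_LABELS, CocaAnnotation, CTVolume,
                               FormatError, InvalidMetadataError, LabelVolume,
                               Polygon, apply_rescale, parse_coca_xml,
                               rasterize_polygons, read_dicom_series,
                               read_nifti, write_nifti)
from cacseg.phantom import generate_coca_like_xml


# ---------------------------------------------------------------------------
# apply_rescale
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("raw,slope,intercept,expected", [
    (100, 1.0, -1024.0, -924.0),
    (0, 1.0, 0.0, 0.0),
    (2048, 2.0, -1000.0, 3096.0),
])
def test_rescale_affine(raw, slope, intercept, expected):
    vol = apply_rescale(np.full((2, 2, 2), raw, dtype=np.int32), slope, intercept)
    assert np.allclose(vol.voxels, expected)


def test_rescale_zero_slope_rejected():
    with pytest.raises(InvalidMetadataError):
        apply_rescale(np.zeros((2, 2, 2), dtype=np.int16), 0.0, 0.0)


def test_ct_volume_invariants():
    with pytest.raises(ValueError):
        CTVolume(np.zeros((2, 2, 2)), spacing=(0.0, 1.0, 1.0))
    with pytest.raises(ValueError):
        CTVolume(np.full((2, 2, 2), np.nan))


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _write_series(directory, n_slices=3, shuffle=False, second_uid=False):
    """Minimal synthetic axial series written slice by slice."""
    series_uid = generate_uid(entropy_srcs=["fixture"])
    other_uid = generate_uid(entropy_srcs=["other"])
    rng = np.random.default_rng(0)
    raw = rng.integers(0, 500, size=(n_slices, 8, 8)).astype(np.uint16)
    order = list(range(n_slices))
    if shuffle:
        order = order[::-1]
    for file_idx, z in enumerate(order):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[f"s{z}"])
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = other_uid if (second_uid and z == 0) else series_uid
        ds.Modality = "CT"
        ds.Rows, ds.Columns = 8, 8
        ds.PixelSpacing = [0.5, 0.75]
        ds.SliceThickness = 2.5
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [10.0, 20.0, 5.0 + 2.5 * z]
        ds.InstanceNumber = n_slices - z  # deliberately reversed numbering
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = raw[z].tobytes()
        ds.save_as(str(directory / f"f{file_idx}.dcm"), enforce_file_format=True)
    return raw


def test_dicom_roundtrip_and_geometry(tmp_path):
    raw = _write_series(tmp_path)
    vol = read_dicom_series(tmp_path)
    assert vol.shape == (3, 8, 8)
    assert vol.spacing == (2.5, 0.5, 0.75)
    assert np.allclose(vol.voxels, raw.astype(np.float32) - 1024.0)


def test_dicom_order_insensitive(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    d1.mkdir(); d2.mkdir()
    _write_series(d1, shuffle=False)
    _write_series(d2, shuffle=True)
    v1, v2 = read_dicom_series(d1), read_dicom_series(d2)
    assert np.array_equal(v1.voxels, v2.voxels)


def test_dicom_mixed_series_rejected(tmp_path):
    _write_series(tmp_path, second_uid=True)
    with pytest.raises(FormatError):
        read_dicom_series(tmp_path)


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def test_nifti_image_roundtrip(tmp_path, rng):
    vol = CTVolume(rng.normal(0, 300, (8, 8, 8)).astype(np.float32),
                   spacing=(2.0, 0.7, 0.7), origin=(1.0, -2.0, 3.0))
    path = write_nifti(vol, tmp_path / "v.nii.gz")
    back = read_nifti(path, kind="image")
    assert np.array_equal(back.voxels, vol.voxels)
    assert np.allclose(back.spacing, vol.spacing, atol=1e-6)


def test_nifti_label_roundtrip(tmp_path, rng):
    lab = LabelVolume(rng.choice([0, 1, 2], size=(6, 6, 6)).astype(np.int16))
    back = read_nifti(write_nifti(lab, tmp_path / "m.nii"), kind="label")
    assert back.labels() == {0, 1, 2}
    assert np.array_equal(back.voxels, lab.voxels)


def test_nifti_truncated_rejected(tmp_path):
    p = tmp_path / "bad.nii"
    p.write_bytes(b"not a nifti file")
    with pytest.raises(FormatError):
        read_nifti(p)


# ---------------------------------------------------------------------------
# COCA-style plist XML
# ---------------------------------------------------------------------------

FIXTURE_XML = """<?xml version="1.0" encoding="UTF-8"?>
<!DOCTYPE plist PUBLIC "-//Apple//DTD PLIST 1.0//EN" "http://www.apple.com/DTDs/PropertyList-1.0.dtd">
<plist version="1.0"><dict>
<key>Images</key><array>
  <dict>
    <key>ImageIndex</key><integer>4</integer>
    <key>SomeUnknownKey</key><string>ignored</string>
    <key>ROIs</key><array>
      <dict><key>Name</key><string>LAD</string>
            <key>Point_px</key><array>
              <string>(1.0, 1.0)</string><string>(5.0, 1.0)</string>
              <string>(5.0, 5.0)</string><string>(1.0, 5.0)</string>
            </array></dict>
      <dict><key>Name</key><string>RCA</string>
            <key>Point_px</key><array>
              <string>(7.5, 2.0)</string><string>(8.5, 2.0)</string>
              <string>(8.0, 3.5)</string>
            </array></dict>
    </array>
  </dict>
  <dict>
    <key>ImageIndex</key><integer>9</integer>
    <key>ROIs</key><array>
      <dict><key>Name</key><string>LCX</string>
            <key>Point_px</key><array>
              <string>(2.0, 2.0)</string><string>(4.0, 2.0)</string>
              <string>(3.0, 4.0)</string>
            </array></dict>
    </array>
  </dict>
</array>
</dict></plist>
"""


def test_parse_fixture_xml():
    ann = parse_coca_xml(FIXTURE_XML)
    assert ann.n_annotated_slices == 2
    assert ann.n_lesions == 3
    assert ann.annotated_slices == (4, 9)
    assert {p.artery for p in ann.polygons} == {"LAD", "RCA", "LCX"}


def test_parse_empty_roi_list():
    xml = generate_coca_like_xml(CocaAnnotation())
    ann = parse_coca_xml(xml)
    assert ann.n_annotated_slices == 0 and ann.n_lesions == 0


def test_parse_rejects_non_xml():
    with pytest.raises(FormatError):
        parse_coca_xml("this is not xml at all")


def test_parse_rejects_missing_coordinates():
    bad = FIXTURE_XML.replace("Point_px", "Point_mm")
    with pytest.raises(FormatError):
        parse_coca_xml(bad)


def test_xml_writer_parser_inverse(default_phantom):
    """parse(generate(A)) == A for phantom-derived annotations."""
    ann = default_phantom.annotation
    back = parse_coca_xml(generate_coca_like_xml(ann))
    assert back.polygons == ann.polygons


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _oracle_mask(poly: Polygon, shape):
    """Brute-force even-odd point-in-polygon over every pixel centre."""
    ny, nx = shape
    out = np.zeros(shape, dtype=bool)
    verts = poly.vertices
    n = len(verts)
    for y in range(ny):
        for x in range(nx):
            inside = False
            on_edge = False
            for i in range(n):
                x1, y1 = verts[i]
                x2, y2 = verts[(i + 1) % n]
                cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
                if (min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12
                        and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12
                        and abs(cross) < 1e-9):
                    on_edge = True
                if (y1 <= y) != (y2 <= y):
                    xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
                    if x < xint:
                        inside = not inside
            out[y, x] = inside or on_edge
    return out


def test_rasterize_axis_aligned_square():
    poly = Polygon(0, ((2.0, 2.0), (5.0, 2.0), (5.0, 5.0), (2.0, 5.0)))
    mask = rasterize_polygons(CocaAnnotation((poly,)), (1, 10, 10))
    assert int(mask.voxels.sum()) == 16  # 4x4 block of pixel centres


def test_rasterize_degenerate_collinear():
    poly = Polygon(0, ((1.25, 1.25), (2.25, 2.25), (3.25, 3.25)))
    mask = rasterize_polygons(CocaAnnotation((poly,)), (1, 8, 8))
    assert int(mask.voxels.sum()) == 0


def test_rasterize_two_disjoint_polygons_two_components():
    from scipy import ndimage
    polys = (Polygon(0, ((1.0, 1.0), (3.0, 1.0), (2.0, 3.0))),
             Polygon(0, ((6.0, 6.0), (8.0, 6.0), (7.0, 8.0))))
    mask = rasterize_polygons(CocaAnnotation(polys), (1, 12, 12))
    _, n = ndimage.label(mask.voxels[0])
    assert n == 2


def test_rasterize_out_of_bounds_clipped_with_warning():
    poly = Polygon(0, ((-3.0, 2.0), (4.0, -3.0), (4.0, 4.0)))
    with pytest.warns(UserWarning):
        mask = rasterize_polygons(CocaAnnotation((poly,)), (1, 6, 6))
    assert mask.voxels.sum() > 0  # in-bounds part survives


@pytest.mark.parametrize("seed", range(8))
def test_rasterize_matches_bruteforce_oracle(seed):
    """Random concave/convex polygons up to 12 vertices, pixel-exact."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 13))
    # random star-shaped (possibly concave) polygon around a centre
    angles = np.sort(rng.uniform(0, 2 * np.pi, n))
    radii = rng.uniform(1.0, 6.0, n)
    cx, cy = rng.uniform(5, 9, 2)
    verts = tuple((float(cx + r * np.cos(a)), float(cy + r * np.sin(a)))
                  for a, r in zip(angles, radii))
    poly = Polygon(0, verts)
    mask = rasterize_polygons(CocaAnnotation((poly,)), (1, 16, 16))
    assert np.array_equal(mask.voxels[0] > 0, _oracle_mask(poly, (16, 16)))


def test_rasterize_per_artery_labels():
    polys = (Polygon(0, ((1.0, 1.0), (3.0, 1.0), (2.0, 3.0)), artery="LAD"),
             Polygon(1, ((1.0, 1.0), (3.0, 1.0), (2.0, 3.0)), artery="LM"))
    mask = rasterize_polygons(CocaAnnotation(polys), (2, 8, 8), per_artery=True)
    assert mask.labels() == {0, ARTERY_LABELS.index("LAD") + 1,
                             ARTERY_LABELS.index("LM") + 1}
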