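"""scan_io: image round trips, label dialect arithmetic, box geometry."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scintidet.errors import DecodeError, LabelParseError, ValidationError
from scintidet.phantom import PhantomConfig, generate_scan
from scintidet.scan_io import (
    Box,
    Category,
    DatasetManifest,
    ManifestEntry,
    flip_box,
    read_labels,
    read_manifest,
    read_scan,
    split_frame_boxes,
    write_labels,
    write_manifest,
    write_scan,
)
from scintidet.scan_io import RawScan


class TestScanRoundTrip:
    def test_zero_image_reads_back_with_zero_sum(self, tmp_path):
        scan = RawScan(pixels=np.zeros((1024, 512), dtype=np.uint16), scan_id="z")
        path = write_scan(scan, tmp_path / "z.png")
        back = read_scan(path)
        assert back.pixels.sum() == 0
        assert back.shape == (1024, 512)

    def test_phantom_round_trip_is_pixel_identical(self, tmp_path):
        scan, _, _ = generate_scan(PhantomConfig(seed=3, n_metastases=2, n_benign=1))
        for suffix in (".png", ".tif"):
            path = write_scan(scan, tmp_path / f"s{suffix}")
            back = read_scan(path)
            assert np.array_equal(back.pixels, scan.pixels)

    def test_extreme_count_preserved_and_agrees_with_imageio(self, tmp_path):
        px = np.zeros((32, 16), dtype=np.uint16)
        px[0, 0] = 65535
        path = write_scan(RawScan(pixels=px, scan_id="hot"), tmp_path / "hot.png")
        back = read_scan(path)
        assert back.pixels[0, 0] == 65535
        import imageio.v3 as iio  # independent reader as oracle

        assert np.array_equal(iio.imread(path), back.pixels)

    def test_unreadable_file_raises_decode_error_naming_path(self, tmp_path):
        bad = tmp_path / "junk.png"
        bad.write_bytes(b"not an image")
        with pytest.raises(DecodeError, match="junk.png"):
            read_scan(bad)

    def test_counts_are_immutable_after_load(self):
        scan = RawScan(pixels=np.ones((4, 4), dtype=np.uint16), scan_id="x")
        with pytest.raises(ValueError):
            scan.pixels[0, 0] = 5

    def test_dicom_read(self, tmp_path):
        pydicom = pytest.importorskip("pydicom")
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = generate_uid()
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(str(tmp_path / "t.dcm"), {}, file_meta=meta, preamble=b"\0" * 128)
        arr = np.arange(64, dtype=np.uint16).reshape(8, 8)
        ds.Rows, ds.Columns = 8, 8
        ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = arr.tobytes()
        ds.save_as(str(tmp_path / "t.dcm"), enforce_file_format=True)
        back = read_scan(tmp_path / "t.dcm")
        assert np.array_equal(back.pixels, arr)


class TestLabels:
    def test_full_frame_box(self, tmp_path):
        p = tmp_path / "l.txt"
        p.write_text("0 0.5 0.5 1.0 1.0\n")
        (box,) = read_labels(p, width=100, height=200)
        assert box.category == Category.METASTASIS
        assert (box.x_min, box.y_min, box.x_max, box.y_max) == (0, 0, 100, 200)

    def test_normalized_arithmetic(self, tmp_path):
        p = tmp_path / "l.txt"
        p.write_text("1 0.25 0.5 0.1 0.2\n")
        (box,) = read_labels(p, width=512, height=950)
        assert box.category == Category.NORMAL_HOTSPOT
        np.testing.assert_allclose(
            (box.x_min, box.y_min, box.x_max, box.y_max), (102.4, 380.0, 153.6, 570.0)
        )

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "l.txt"
        p.write_text("0 0.5 0.5 1.0 1.0\n0 0.5 0.5\n")
        with pytest.raises(LabelParseError, match=":2"):
            read_labels(p, 100, 100)

    def test_escaping_box_rejected(self, tmp_path):
        p = tmp_path / "l.txt"
        p.write_text("0 0.9 0.5 0.5 0.2\n")  # x_max = 1.15 * width
        with pytest.raises(ValidationError):
            read_labels(p, 100, 100)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(list(Category)),
                st.floats(0.05, 0.9),
                st.floats(0.05, 0.9),
                st.floats(0.02, 0.1),
                st.floats(0.02, 0.1),
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_write_read_round_trip(self, specs):
        import tempfile
        from pathlib import Path

        tmp = Path(tempfile.mkdtemp())
        boxes = [
            Box(category=c, x_min=(x - w / 2) * 512, y_min=(y - h / 2) * 950,
                x_max=(x + w / 2) * 512, y_max=(y + h / 2) * 950)
            for c, x, y, w, h in specs
        ]
        path = write_labels(boxes, tmp / "rt.txt", 512, 950)
        back = read_labels(path, 512, 950)
        assert len(back) == len(boxes)
        for a, b in zip(boxes, back):
            assert a.category == b.category
            np.testing.assert_allclose(
                [a.x_min, a.y_min, a.x_max, a.y_max],
                [b.x_min, b.y_min, b.x_max, b.y_max],
                atol=1e-4,
            )


class TestBoxGeometry:
    def test_flip_examples(self):
        b = Box(category=Category.METASTASIS, x_min=0, y_min=0, x_max=10, y_max=10)
        f = flip_box(b, 100)
        assert (f.x_min, f.y_min, f.x_max, f.y_max) == (90, 0, 100, 10)
        centered = Box(category=Category.METASTASIS, x_min=45, y_min=5, x_max=55, y_max=15)
        assert flip_box(centered, 100) == centered

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(0, 400), st.floats(0, 400),
        st.floats(1, 100), st.floats(1, 100),
        st.floats(0.1, 1.0),
    )
    def test_flip_is_involution(self, x, y, w, h, conf):
        b = Box(category=Category.EQUIVOCAL, x_min=x, y_min=y, x_max=x + w, y_max=y + h,
                confidence=conf)
        bb = flip_box(flip_box(b, 600), 600)
        # double mirror restores coordinates (up to float round-off)
        np.testing.assert_allclose(
            [bb.x_min, bb.y_min, bb.x_max, bb.y_max],
            [b.x_min, b.y_min, b.x_max, b.y_max],
            rtol=0, atol=1e-9,
        )

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValidationError):
            Box(category=Category.METASTASIS, x_min=5, y_min=0, x_max=5, y_max=10)

    def test_split_frame_boxes_reassigns_pa_origin(self):
        ap = Box(category=Category.METASTASIS, x_min=10, y_min=5, x_max=30, y_max=25)
        pa = Box(category=Category.METASTASIS, x_min=300, y_min=5, x_max=320, y_max=25)
        got_ap, got_pa = split_frame_boxes([ap, pa])
        assert got_ap == [ap]
        assert got_pa[0].x_min == 300 - 256 and got_pa[0].x_max == 320 - 256


class TestManifest:
    def test_round_trip_and_positive_count(self, tmp_path):
        entries = [
            ManifestEntry(f"scans/{i}.png", f"labels/{i}.txt", f"p{i}", "synthetic", i < 2)
            for i in range(5)
        ]
        m = DatasetManifest(entries=entries)
        path = write_manifest(m, tmp_path / "manifest.csv")
        back = read_manifest(path)
        assert back.entries == entries
        assert back.n_positive == 2

    def test_duplicate_paths_rejected(self):
        e = ManifestEntry("a.png", "a.txt", "p", "synthetic", False)
        with pytest.raises(ValidationError):
            DatasetManifest(entries=[e, e])
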