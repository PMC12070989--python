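import numpy as np
import pytest
from skimage.draw import disk

from lesiongraph.errors import EmptyMaskError, FormatError, UndefinedTextureError
from lesiongraph.features import (
    CSV_HEADER,
    FEATURE_NAMES,
    FeatureTable,
    GlcmConfig,
    Region,
    extract_feature_table,
    extract_regions,
    geometric_features,
    glcm_features,
    glcm_matrix,
    read_csv,
    write_csv,
)


def region_from_mask(binary):
    return Region(label=1, coords=np.argwhere(np.asarray(binary, dtype=bool)))


class TestExtractRegions:
    def test_single_block(self):
        mask = np.zeros((8, 8), dtype=int)
        mask[2:5, 2:5] = 1
        regions = extract_regions(mask)
        assert len(regions) == 1 and regions[0].area == 9

    def test_diagonal_pixels_are_one_region_under_8_connectivity(self):
        mask = np.zeros((8, 8), dtype=int)
        mask[2, 2] = mask[3, 3] = 1
        # oracle: scipy 8-connected labeling
        from scipy import ndimage

        _, n8 = ndimage.label(mask > 0, structure=np.ones((3, 3)))
        regions = extract_regions(mask)
        assert n8 == 1 and len(regions) == 1

    def test_two_labels_ordered(self):
        mask = np.zeros((8, 8), dtype=int)
        mask[1:3, 1:3] = 2
        mask[5:7, 5:7] = 1
        regions = extract_regions(mask)
        assert [r.label for r in regions] == [1, 2]

    def test_same_label_components_scanline_ordered(self):
        mask = np.zeros((8, 8), dtype=int)
        mask[5:7, 0:2] = 1
        mask[0:2, 5:7] = 1
        regions = extract_regions(mask)
        firsts = [tuple(r.coords[0]) for r in regions]
        assert firsts == sorted(firsts)

    def test_all_zero_mask(self):
        with pytest.raises(EmptyMaskError):
            extract_regions(np.zeros((8, 8), dtype=int))


class TestGeometric:
    def test_filled_square(self):
        binary = np.zeros((14, 14), dtype=bool)
        binary[2:12, 2:12] = True
        f = geometric_features(region_from_mask(binary))
        assert f["area"] == 100
        assert f["eccentricity"] == pytest.approx(0.0, abs=1e-9)
        assert f["aspect_ratio"] == pytest.approx(1.0, abs=1e-9)
        assert f["solidity"] == pytest.approx(1.0)
        # border-chain perimeter of an axis-aligned square of side 10 is 4*9
        assert f["perimeter"] == pytest.approx(36.0)
        assert f["circularity"] == pytest.approx(4 * np.pi * 100 / 36.0**2)
        assert f["compactness"] == pytest.approx(1.0 / f["circularity"])

    def test_disk_area_oracle_and_circularity(self):
        binary = np.zeros((50, 50), dtype=bool)
        rr, cc = disk((25, 25), 20)
        binary[rr, cc] = True
        # independent pixel-enumeration oracle for the area
        oracle_area = sum(
            1
            for r in range(50)
            for c in range(50)
            if (r - 25) ** 2 + (c - 25) ** 2 < 20**2
        )
        f = geometric_features(region_from_mask(binary))
        assert f["area"] == oracle_area
        assert 0.9 <= f["circularity"] <= 1.1
        assert f["solidity"] > 0.95

    def test_line_region(self):
        binary = np.zeros((5, 24), dtype=bool)
        binary[2, 2:22] = True
        f = geometric_features(region_from_mask(binary))
        assert f["aspect_ratio"] > 5
        assert f["eccentricity"] > 0.95
        assert f["eccentricity"] < 1.0

    def test_single_pixel_degenerate(self):
        binary = np.zeros((5, 5), dtype=bool)
        binary[2, 2] = True
        with pytest.warns(UserWarning):
            f = geometric_features(region_from_mask(binary))
        assert f["eccentricity"] == 0.0
        assert f["minor_axis"] == 1.0
        assert f["area"] == 1.0

    def test_minor_never_exceeds_major(self, rng):
        for _ in range(10):
            binary = rng.random((12, 12)) > 0.6
            if not binary.any():
                continue
            from skimage.measure import label as sklabel

            lab = sklabel(binary, connectivity=2)
            coords = np.argwhere(lab == 1)
            f = geometric_features(Region(label=1, coords=coords))
            assert f["minor_axis"] <= f["major_axis"] + 1e-9


class TestGlcm:
    """Hand-enumerated pair-count oracles on 2x2 images, 2 gray levels."""

    image = np.array([[0.0, 0.0], [1.0, 1.0]])
    region = Region(label=1, coords=np.argwhere(np.ones((2, 2), dtype=bool)))

    def test_horizontal_offset(self):
        cfg = GlcmConfig(levels=2, angles=(0,))
        contrast, correlation, energy, homogeneity = glcm_features(
            self.image, self.region, cfg
        )
        # pairs (0,0) and (1,1): P = [[.5,0],[0,.5]]
        assert contrast == pytest.approx(0.0)
        assert energy == pytest.approx(0.5)
        assert homogeneity == pytest.approx(1.0)
        assert correlation == pytest.approx(1.0)

    def test_vertical_offset(self):
        cfg = GlcmConfig(levels=2, angles=(90,))
        contrast, correlation, energy, homogeneity = glcm_features(
            self.image, self.region, cfg
        )
        # pairs (1,0) and (1,0), symmetrized: P = [[0,.5],[.5,0]]
        assert contrast == pytest.approx(1.0)
        assert energy == pytest.approx(0.5)
        assert homogeneity == pytest.approx(0.5)
        assert correlation == pytest.approx(-1.0)

    def test_constant_region_conventions(self):
        image = np.full((3, 3), 0.4)
        region = Region(label=1, coords=np.argwhere(np.ones((3, 3), dtype=bool)))
        contrast, correlation, energy, homogeneity = glcm_features(
            image, region, GlcmConfig(levels=4)
        )
        assert contrast == pytest.approx(0.0)
        assert energy == pytest.approx(1.0)
        assert homogeneity == pytest.approx(1.0)
        assert correlation == 0.0  # convention for zero variance

    def test_matrix_normalized_and_nonnegative(self, rng):
        image = rng.random((6, 6))
        region = Region(label=1, coords=np.argwhere(np.ones((6, 6), dtype=bool)))
        cfg = GlcmConfig(levels=8)
        for offset in cfg.offsets():
            mat, n_pairs = glcm_matrix(image, region, cfg, offset)
            assert (mat >= 0).all()
            if n_pairs:
                assert mat.sum() == pytest.approx(1.0)

    def test_region_restriction(self):
        """Pairs crossing the region boundary must not be counted."""
        image = np.array([[0.0, 1.0, 0.0]])
        region = Region(label=1, coords=np.array([[0, 0], [0, 1]]))
        cfg = GlcmConfig(levels=2, angles=(0,))
        mat, n_pairs = glcm_matrix(image, region, cfg, (0, 1))
        assert n_pairs == 1  # only the (0,0)-(0,1) pair, not (0,1)-(0,2)

    def test_energy_below_one_unless_constant(self, rng):
        image = rng.random((5, 5))
        region = Region(label=1, coords=np.argwhere(np.ones((5, 5), dtype=bool)))
        _, _, energy, _ = glcm_features(image, region, GlcmConfig(levels=16))
        assert energy < 1.0

    def test_too_small_region(self):
        image = np.ones((4, 4)) * 0.5
        region = Region(label=1, coords=np.array([[0, 0]]))
        with pytest.raises(UndefinedTextureError):
            glcm_features(image, region, GlcmConfig(levels=2))

    def test_exhaustive_pair_oracle_small_images(self, rng):
        """Full agreement with a per-pixel loop oracle on random 4x4 images."""
        cfg = GlcmConfig(levels=4, angles=(0, 45, 90, 135))
        offsets = {(0, 1), (-1, 1), (-1, 0), (-1, -1)}
        for trial in range(10):
            image = rng.random((4, 4))
            inreg = rng.random((4, 4)) > 0.3
            if inreg.sum() < 4:
                continue
            region = Region(label=1, coords=np.argwhere(inreg))
            q = np.clip((image * 4).astype(int), 0, 3)
            stats = []
            for dr, dc in offsets:
                mat = np.zeros((4, 4))
                for r in range(4):
                    for c in range(4):
                        r2, c2 = r + dr, c + dc
                        if 0 <= r2 < 4 and 0 <= c2 < 4 and inreg[r, c] and inreg[r2, c2]:
                            mat[q[r, c], q[r2, c2]] += 1
                if mat.sum() == 0:
                    continue
                p = mat + mat.T
                p = p / p.sum()
                i, j = np.indices((4, 4))
                contrast = (p * (i - j) ** 2).sum()
                energy = (p**2).sum()
                homog = (p / (1 + (i - j) ** 2)).sum()
                mu = (p * i).sum()
                var = (p * (i - mu) ** 2).sum()
                corr = ((p * (i - mu) * (j - mu)).sum() / var) if var > 0 else 0.0
                stats.append((contrast, corr, energy, homog))
            if not stats:
                continue
            expected = np.mean(stats, axis=0)
            got = glcm_features(image, region, cfg)
            assert np.allclose(got, expected, atol=1e-12)


class TestFeatureTable:
    def test_row_count_and_columns(self, tiny_profile):
        from lesiongraph.synth import generate_synthetic_case

        image, mask = generate_synthetic_case(tiny_profile, 4)
        table = extract_feature_table(image, mask, "toy")
        assert len(table) == mask.max()
        assert table.feature_matrix().shape == (len(table), 14)
        for row in table.rows:
            row.validate()

    def test_translation_invariance(self):
        mask = np.zeros((32, 32), dtype=int)
        mask[4:12, 4:14] = 1
        rng = np.random.default_rng(0)
        image = np.clip(rng.random((32, 32)), 0, 1)
        t1 = extract_feature_table(image, mask, "t")
        image2 = np.roll(image, (7, 5), axis=(0, 1))
        mask2 = np.roll(mask, (7, 5), axis=(0, 1))
        t2 = extract_feature_table(image2, mask2, "t")
        assert np.allclose(t1.feature_matrix(), t2.feature_matrix())

    def test_duplicate_region_ids_rejected(self):
        from conftest import make_row

        row = make_row(1, np.ones(14))
        with pytest.raises(FormatError):
            FeatureTable(class_label="x", rows=[row, make_row(1, np.ones(14))])


class TestCsv:
    def test_round_trip(self, tiny_profile, tmp_path):
        from lesiongraph.synth import generate_synthetic_case

        image, mask = generate_synthetic_case(tiny_profile, 2)
        table = extract_feature_table(image, mask, "toy")
        path = tmp_path / "f.csv"
        write_csv(table, path)
        back = read_csv(path)
        assert back.approx_equal(table)

    def test_header_order(self, tmp_path, tiny_profile):
        from lesiongraph.synth import generate_synthetic_case

        image, mask = generate_synthetic_case(tiny_profile, 2)
        write_csv(extract_feature_table(image, mask, "toy"), tmp_path / "f.csv")
        header = (tmp_path / "f.csv").read_text().splitlines()[0]
        assert header == ",".join(CSV_HEADER)

    def test_empty_table_write_rejected(self, tmp_path):
        table = FeatureTable(class_label="x", rows=[])
        with pytest.raises(FormatError):
            write_csv(table, tmp_path / "empty.csv")

    def test_header_mismatch_on_read(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(FormatError):
            read_csv(p)

    def test_ten_significant_digits(self, tmp_path):
        from conftest import make_table

        values = np.full((1, 14), 0.123456789012345)
        values[0, 0] = 987.6543210987  # area
        table = make_table(values, "x")
        write_csv(table, tmp_path / "p.csv")
        back = read_csv(tmp_path / "p.csv")
        assert back.approx_equal(table, rtol=1e-9)
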