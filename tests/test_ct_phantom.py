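"""CT loading, resampling, HU conversion and phantom file round trips."""

import numpy as np
import pytest

from rtmc.ct_phantom import (
    DEFAULT_TABLE,
    HUConversionTable,
    ImageVolume,
    VoxelPhantom,
    apply_conversion,
    load_ct_series,
    read_egsphant,
    read_penvox,
    resample_volume,
    write_egsphant,
    write_penvox,
)
from rtmc.errors import CapacityError, ConversionError, GeometryError
from rtmc.fixtures import CaseKind, FixtureSpec, make_ct

SIMPLE_TABLE = HUConversionTable(
    material_bins=[(-1100.0, -500.0, "AIR", 0), (-500.0, 3000.0, "WATER", 1)],
    density_breakpoints=[(-1000.0, 0.001), (0.0, 1.000), (1000.0, 1.6)],
)


class TestLoadCT:
    def test_fixture_series_round_trip(self, case_dirs):
        spec = case_dirs[CaseKind.MARC_HN]["spec"]
        vol = load_ct_series(case_dirs[CaseKind.MARC_HN]["ct_dir"])
        assert vol.dims == spec.dims
        assert vol.spacing_mm == spec.spacing_mm
        # center voxel is water (HU 0), corner is air (HU -1000)
        cx, cy, cz = (d // 2 for d in vol.dims)
        assert vol.hu[cx, cy, cz] == 0.0
        assert vol.hu[0, 0, 0] == -1000.0

    def test_single_slice_series_is_legal(self, tmp_path):
        spec = FixtureSpec(dims=(8, 8, 1), seed=1)
        vol = load_ct_series(make_ct(spec, tmp_path / "ct"))
        assert vol.dims == (8, 8, 1)

    def test_nonuniform_slice_gap_rejected(self, tmp_path):
        spec = FixtureSpec(dims=(8, 8, 3), spacing_mm=(4, 4, 2.5), seed=1)
        make_ct(spec, tmp_path / "ct", z_positions=[0.0, 2.5, 7.5])
        with pytest.raises(GeometryError, match="slice spacing"):
            load_ct_series(tmp_path / "ct")


class TestResample:
    def test_quad_average_downsampling(self):
        hu = np.array([[0.0, 200.0], [100.0, 300.0]]).reshape(2, 2, 1)
        vol = ImageVolume(hu=hu, spacing_mm=(1, 1, 1), origin_mm=(0, 0, 0))
        out = resample_volume(vol, (2, 2, 1))
        assert out.dims == (1, 1, 1)
        assert out.hu[0, 0, 0] == pytest.approx(150.0)

    def test_identity_resampling_is_bit_identical(self, case_dirs):
        vol = load_ct_series(case_dirs[CaseKind.MARC_HN]["ct_dir"])
        out = resample_volume(vol, vol.spacing_mm)
        assert np.array_equal(out.hu, vol.hu)
        assert out.origin_mm == vol.origin_mm

    def test_constant_field_is_invariant(self):
        vol = ImageVolume(hu=np.zeros((6, 6, 4)), spacing_mm=(2, 2, 3),
                          origin_mm=(0, 0, 0))
        for spacing in [(3, 3, 3), (1, 1, 1), (5, 7, 11)]:
            assert np.allclose(resample_volume(vol, spacing).hu, 0.0)

    def test_spacing_beyond_extent_rejected(self):
        vol = ImageVolume(hu=np.zeros((4, 4, 4)), spacing_mm=(1, 1, 1),
                          origin_mm=(0, 0, 0))
        with pytest.raises(GeometryError):
            resample_volume(vol, (10, 1, 1))

    def test_mass_conservation_under_downsampling(self, case_dirs):
        vol = load_ct_series(case_dirs[CaseKind.MARC_HN]["ct_dir"])
        coarse = resample_volume(vol, (8.0, 8.0, 10.0))
        m_fine = apply_conversion(vol, SIMPLE_TABLE).total_mass_g()
        m_coarse = apply_conversion(coarse, SIMPLE_TABLE).total_mass_g()
        assert m_coarse == pytest.approx(m_fine, rel=0.005)


class TestConversion:
    @pytest.mark.parametrize("hu,density", [
        (0.0, 1.000),        # breakpoint hit
        (-500.0, 0.5005),    # linear interpolation midpoint
        (2000.0, 1.6),       # clamped above the last breakpoint
        (-1000.0, 0.001),
    ])
    def test_density_interpolation(self, hu, density):
        assert SIMPLE_TABLE.density_of(np.array([hu]))[0] == pytest.approx(density)

    def test_material_binning_and_monotonicity(self):
        hus = np.linspace(-1050.0, 2900.0, 1000)
        mats = SIMPLE_TABLE.material_of(hus)
        assert set(mats) == {0, 1}
        dens = SIMPLE_TABLE.density_of(hus)
        assert np.all(np.diff(dens) >= 0)  # monotone table -> monotone density

    def test_hu_outside_bins_reports_value(self):
        vol = ImageVolume(hu=np.full((1, 1, 1), -2000.0), spacing_mm=(1, 1, 1),
                          origin_mm=(0, 0, 0))
        with pytest.raises(ConversionError, match="-2000"):
            apply_conversion(vol, SIMPLE_TABLE)

    def test_default_table_covers_clinical_range(self):
        hus = np.linspace(-1024.0, 3000.0, 500)
        mats = DEFAULT_TABLE.material_of(hus)
        assert set(mats) <= {0, 1, 2, 3}


@pytest.fixture()
def two_material_phantom():
    rng = np.random.default_rng(9)
    material = rng.integers(0, 2, size=(4, 3, 2))
    density = np.where(material == 0, 0.25, 1.0) * (1 + 0.1 * rng.random((4, 3, 2)))
    return VoxelPhantom(material=material, density=density, spacing_mm=(2, 2, 5),
                        origin_mm=(-3, -2, -2.5),
                        material_names={0: "LUNG", 1: "WATER"})


class TestPhantomFiles:
    def test_egsphant_minimal_water(self, tmp_path):
        ph = VoxelPhantom(material=np.ones((2, 2, 1), dtype=int),
                          density=np.ones((2, 2, 1)), spacing_mm=(1, 1, 1),
                          origin_mm=(0, 0, 0), material_names={1: "WATER"})
        path = tmp_path / "w.egsphant"
        write_egsphant(ph, path)
        text = path.read_text()
        assert text.splitlines()[0] == "1"
        assert text.splitlines()[1] == "WATER"
        assert "1111" in text.replace("\n", "")

    def test_egsphant_round_trip_and_second_write_byte_identical(
        self, tmp_path, two_material_phantom
    ):
        p1, p2 = tmp_path / "a.egsphant", tmp_path / "b.egsphant"
        write_egsphant(two_material_phantom, p1)
        back = read_egsphant(p1)
        assert np.array_equal(
            back.material, np.vectorize({0: 0, 1: 1}.get)(two_material_phantom.material)
        )
        assert np.allclose(back.density, two_material_phantom.density, rtol=1e-6)
        assert [back.material_names[k] for k in sorted(back.material_names)] == [
            "LUNG", "WATER",
        ]
        write_egsphant(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_egsphant_material_capacity(self, tmp_path):
        n = 95
        ph = VoxelPhantom(material=np.arange(n).reshape(n, 1, 1),
                          density=np.ones((n, 1, 1)), spacing_mm=(1, 1, 1),
                          origin_mm=(0, 0, 0),
                          material_names={i: f"M{i}" for i in range(n)})
        with pytest.raises(CapacityError):
            write_egsphant(ph, tmp_path / "x.egsphant")

    def test_penvox_round_trip(self, tmp_path, two_material_phantom):
        path = tmp_path / "p.penvox"
        write_penvox(two_material_phantom, path)
        back = read_penvox(path)
        assert np.array_equal(back.material, two_material_phantom.material)
        assert np.allclose(back.density, two_material_phantom.density, rtol=1e-6)
        assert np.allclose(back.spacing_mm, two_material_phantom.spacing_mm)
        assert np.allclose(back.origin_mm, two_material_phantom.origin_mm)

    def test_penvox_single_voxel(self, tmp_path):
        ph = VoxelPhantom(material=np.ones((1, 1, 1), dtype=int),
                          density=np.ones((1, 1, 1)), spacing_mm=(1, 1, 1),
                          origin_mm=(0, 0, 0), material_names={1: "WATER"})
        path = tmp_path / "w.penvox"
        write_penvox(ph, path)
        body = [ln for ln in path.read_text().splitlines()][-1]
        assert body.split()[0] == "1"
        assert float(body.split()[1]) == pytest.approx(1.0)

    def test_negative_density_refused_at_construction(self):
        with pytest.raises(ValueError):
            VoxelPhantom(material=np.zeros((1, 1, 1), dtype=int),
                         density=np.full((1, 1, 1), -0.5), spacing_mm=(1, 1, 1),
                         origin_mm=(0, 0, 0), material_names={0: "X"})
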