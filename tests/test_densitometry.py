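import numpy as np
import pytest

from hiphase.densitometry import (
    AtomSite,
    DensityMap,
    OmitRegion,
    difference_map,
    electrons_by_reference,
    integrate_positive,
    peak_sigma_levels,
    read_map_json,
    read_sites_csv,
    read_sites_pdb,
    render_map,
    write_map_json,
    write_sites_csv,
)
from hiphase.errors import (
    CalibrationError,
    CoverageError,
    DomainError,
    GeometryError,
)

GRID = dict(origin=(0.0, 0.0, 0.0), voxel=0.25, dims=(49, 49, 49))
CENTER = (6.0, 6.0, 6.0)


def site(n_electrons=48.0, occupancy=1.0, position=CENTER, b_factor=10.0):
    return AtomSite(position, "C", n_electrons, occupancy, b_factor)


class TestRenderMap:
    def test_electron_conservation_within_half_percent(self):
        m = render_map([site(48.0, 0.9)], **GRID)
        assert m.total_electrons() == pytest.approx(48.0 * 0.9, rel=5e-3)

    def test_occupancy_linearity(self):
        full = render_map([site(occupancy=1.0)], **GRID)
        half = render_map([site(occupancy=0.5)], **GRID)
        assert full.total_electrons() == pytest.approx(
            2 * half.total_electrons(), rel=1e-9
        )

    def test_superposition_of_distant_sites(self):
        a, b = (3.5, 3.5, 3.5), (9.0, 9.0, 9.0)
        both = render_map([site(position=a), site(position=b, n_electrons=20.0)], **GRID)
        ia = integrate_positive(both, OmitRegion(a, 2.0))
        ib = integrate_positive(both, OmitRegion(b, 2.0))
        assert ia == pytest.approx(48.0, rel=1e-2)
        assert ib == pytest.approx(20.0, rel=1e-2)

    def test_insufficient_margin_raises(self):
        with pytest.raises(CoverageError):
            render_map([site(position=(0.2, 6.0, 6.0))], **GRID)


class TestDifferenceMap:
    def test_self_difference_is_zero(self):
        m = render_map([site()], **GRID)
        assert np.allclose(difference_map(m, m).values, 0.0)

    def test_antisymmetry(self):
        a = render_map([site(48.0)], **GRID)
        b = render_map([site(30.0)], **GRID)
        d1 = difference_map(a, b)
        d2 = difference_map(b, a)
        assert np.allclose(d1.values, -d2.values)

    def test_planted_contrast_integral(self):
        # Gd rendered with 57 then 32 electrons at occupancy 0.8:
        # difference integrates to 25 * occupancy
        lf = render_map([site(57.0, 0.8)], **GRID)
        hf = render_map([site(32.0, 0.8)], **GRID)
        diff = difference_map(lf, hf)
        got = integrate_positive(diff, OmitRegion(CENTER, 2.0))
        assert got == pytest.approx(25.0 * 0.8, rel=1e-2)

    def test_grid_mismatch(self):
        a = render_map([site()], **GRID)
        b = render_map([site()], origin=(0.5, 0.0, 0.0), voxel=0.25, dims=(49, 49, 49))
        with pytest.raises(GeometryError):
            difference_map(a, b)


class TestIntegratePositive:
    def test_zero_map(self):
        m = DensityMap((0.0, 0.0, 0.0), 0.5, np.zeros((10, 10, 10)))
        assert integrate_positive(m, OmitRegion((2.0, 2.0, 2.0), 1.5)) == 0.0

    def test_threshold_above_maximum(self):
        m = render_map([site()], **GRID)
        assert integrate_positive(m, OmitRegion(CENTER, 2.0), threshold=1e9) == 0.0

    def test_reference_recovers_48_times_occupancy(self):
        m = render_map([site(48.0, 0.7)], **GRID)
        got = integrate_positive(m, OmitRegion(CENTER, 2.0))
        assert got == pytest.approx(48.0 * 0.7, rel=1e-2)

    def test_region_outside_grid(self):
        m = render_map([site()], **GRID)
        with pytest.raises(GeometryError):
            integrate_positive(m, OmitRegion((50.0, 6.0, 6.0), 1.0))


class TestElectronsByReference:
    def test_target_equals_reference(self):
        m = render_map([site(48.0)], **GRID)
        region = OmitRegion(CENTER, 2.0)
        est = electrons_by_reference(m, region, 1.0, region, 1.0, 48.0)
        assert est.electrons == pytest.approx(48.0)

    def test_scale_invariance(self):
        m = render_map(
            [site(48.0), site(25.0, position=(9.0, 9.0, 9.0))], **GRID
        )
        scaled = DensityMap(m.origin, m.voxel, 7.3 * m.values)
        target = OmitRegion((9.0, 9.0, 9.0), 2.0)
        ref = OmitRegion(CENTER, 2.0)
        e1 = electrons_by_reference(m, target, 1.0, ref, 1.0, 48.0)
        e2 = electrons_by_reference(scaled, target, 1.0, ref, 1.0, 48.0)
        assert e1.electrons == pytest.approx(e2.electrons, rel=1e-12)

    def test_occupancy_correction(self):
        m = render_map(
            [site(48.0), site(30.0, occupancy=0.6, position=(9.0, 9.0, 9.0))],
            **GRID,
        )
        est = electrons_by_reference(
            m, OmitRegion((9.0, 9.0, 9.0), 2.0), 0.6, OmitRegion(CENTER, 2.0), 1.0, 48.0
        )
        assert est.electrons == pytest.approx(30.0, rel=2e-2)

    def test_uncertainty_from_extra_references(self):
        m = render_map(
            [
                site(48.0),
                site(48.0, position=(9.5, 3.5, 9.5)),
                site(25.0, position=(9.0, 9.0, 3.5)),
            ],
            **GRID,
        )
        est = electrons_by_reference(
            m,
            OmitRegion((9.0, 9.0, 3.5), 2.0),
            1.0,
            OmitRegion(CENTER, 2.0),
            1.0,
            48.0,
            extra_references=[[OmitRegion((9.5, 3.5, 9.5), 2.0)]],
        )
        assert est.relative_uncertainty is not None
        assert est.relative_uncertainty < 0.05  # noiseless references agree

    def test_nonpositive_reference(self):
        m = DensityMap((0.0, 0.0, 0.0), 0.5, np.zeros((12, 12, 12)))
        with pytest.raises(CalibrationError):
            electrons_by_reference(
                m, OmitRegion((2.0, 2.0, 2.0), 1.0), 1.0,
                OmitRegion((4.0, 4.0, 4.0), 1.0), 1.0, 48.0,
            )


class TestPeakSigmaLevels:
    def test_spike_is_maximal(self):
        values = np.full((11, 11, 11), 0.1)
        values[5, 5, 5] = 4.0
        m = DensityMap((0.0, 0.0, 0.0), 1.0, values)
        levels = peak_sigma_levels(m, [(5.0, 5.0, 5.0), (2.0, 2.0, 2.0)])
        assert levels[0] > levels[1]
        assert levels[0] == pytest.approx(values.max() / values.std())

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(9, 9, 9))
        a = DensityMap((0.0, 0.0, 0.0), 1.0, values)
        b = DensityMap((0.0, 0.0, 0.0), 1.0, 12.5 * values)
        pos = [(4.0, 4.0, 4.0)]
        assert peak_sigma_levels(a, pos) == pytest.approx(peak_sigma_levels(b, pos))

    def test_higher_occupancy_higher_sigma(self):
        lf = render_map(
            [site(57.0, 1.0), site(57.0, 0.7, position=(9.0, 9.0, 9.0))], **GRID
        )
        hf = render_map(
            [site(32.0, 1.0), site(32.0, 0.7, position=(9.0, 9.0, 9.0))], **GRID
        )
        diff = difference_map(lf, hf)
        levels = peak_sigma_levels(diff, [CENTER, (9.0, 9.0, 9.0)])
        assert levels[0] > levels[1]

    def test_zero_variance_map(self):
        m = DensityMap((0.0, 0.0, 0.0), 1.0, np.zeros((5, 5, 5)))
        with pytest.raises(DomainError):
            peak_sigma_levels(m, [(2.0, 2.0, 2.0)])


class TestIO:
    def test_sites_csv_roundtrip(self, tmp_path):
        sites = [site(57.0, 0.8), site(25.0, position=(9.0, 9.0, 9.0))]
        path = tmp_path / "sites.csv"
        write_sites_csv(sites, path)
        back = read_sites_csv(path)
        assert len(back) == 2
        assert back[0].n_electrons == pytest.approx(57.0)
        assert back[0].occupancy == pytest.approx(0.8)

    def test_map_json_roundtrip(self, tmp_path):
        m = render_map([site()], origin=(0.0, 0.0, 0.0), voxel=0.5, dims=(25, 25, 25))
        path = tmp_path / "map.json"
        write_map_json(m, path)
        back = read_map_json(path)
        assert back.dims == m.dims
        assert np.allclose(back.values, m.values)

    def test_read_minimal_pdb(self, tmp_path):
        pdb = tmp_path / "sites.pdb"
        pdb.write_text(
            "HETATM    1 GD    GD A   1       6.000   6.000   6.000  0.80 10.00          GD\n"
            "ATOM      2  CA  TRP A   2       9.000   9.000   9.000  1.00 12.00           C\n"
            "END\n"
        )
        sites = read_sites_pdb(pdb)
        assert len(sites) == 2
        gd = next(s for s in sites if s.element == "GD")
        assert gd.n_electrons == 64.0
        assert gd.occupancy == pytest.approx(0.8)
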