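"""Union-of-spheres coverage against closed-form geometric oracles."""

import numpy as np
import pytest

from ieegcoverage.coverage import (
    RoiSweepConfig,
    coverage_sweep,
    region_coverage,
    regional_inclusion,
    sphere_mask,
    union_mask,
    weighted_volume,
)
from ieegcoverage.electrodes import Contact, ElectrodeSet
from ieegcoverage.grid import VolumeGrid
from ieegcoverage.volumes import TissueProbabilityVolumes


def sphere_volume(r: float) -> float:
    return 4.0 / 3.0 * np.pi * r**3


def lens_volume(r: float, d: float) -> float:
    """Intersection volume of two equal spheres with center distance d."""
    if d >= 2 * r:
        return 0.0
    return np.pi * (4 * r + d) * (2 * r - d) ** 2 / 12.0


def _uniform_tissue(grid: VolumeGrid, tissue="gm") -> TissueProbabilityVolumes:
    one, zero = np.ones(grid.shape), np.zeros(grid.shape)
    maps = {"gm": zero, "wm": zero, "csf": zero}
    maps[tissue] = one
    return TissueProbabilityVolumes(grid, maps["gm"], maps["wm"], maps["csf"])


class TestSphereMask:
    def test_unit_sphere_on_lattice_is_seven_voxels(self):
        grid = VolumeGrid.from_spacing((11, 11, 11), 1.0)  # centers at integers
        mask = sphere_mask((5.0, 5.0, 5.0), 1.0, grid)
        assert mask.sum() == 7  # center + 6 face neighbors

    @pytest.mark.parametrize("r,h", [(2.5, 0.25), (5.0, 1.0), (10.0, 1.0), (15.0, 1.0)])
    def test_volume_matches_analytic(self, r, h):
        # 2% needs the voxel edge well below the radius; r=2.5 mm uses a finer
        # grid because binary 1 mm voxelization of so small a sphere carries
        # >10% lattice error regardless of placement
        n = int((2 * r + 6) / h)
        grid = VolumeGrid.from_spacing((n, n, n), h, (h / 2,) * 3)
        c = ((n // 2 + 0.5) * h,) * 3  # on a voxel center
        vol = sphere_mask(c, r, grid).sum() * grid.voxel_volume
        assert vol == pytest.approx(sphere_volume(r), rel=0.02)

    def test_nesting_across_sweep(self, fine_grid):
        prev = None
        for r in np.arange(1.0, 15.1, 0.5):
            mask = sphere_mask((20.0, 20.0, 20.0), r, fine_grid)
            if prev is not None:
                assert (mask | prev).sum() == mask.sum()  # prev subset of mask
            prev = mask

    def test_outside_grid_warns_and_is_empty(self, fine_grid):
        with pytest.warns(UserWarning):
            mask = sphere_mask((500.0, 500.0, 500.0), 2.0, fine_grid)
        assert not mask.any()


class TestUnionMask:
    def test_two_sphere_union_matches_lens_formula(self):
        r, d = 5.0, 5.0
        grid = VolumeGrid.from_spacing((60, 52, 52), 0.5, (0.25, 0.25, 0.25))
        a = sphere_mask((10.0, 13.0, 13.0), r, grid)
        b = sphere_mask((15.0, 13.0, 13.0), r, grid)
        union = union_mask([a, b]).sum() * grid.voxel_volume
        expected = 2 * sphere_volume(r) - lens_volume(r, d)  # 883.57 mm^3
        assert expected == pytest.approx(883.57, abs=0.5)
        assert union == pytest.approx(expected, rel=0.02)

    def test_identical_and_disjoint(self, fine_grid):
        a = sphere_mask((10.0, 20.0, 20.0), 4.0, fine_grid)
        b = sphere_mask((30.0, 20.0, 20.0), 4.0, fine_grid)
        assert union_mask([a, a]).sum() == a.sum()
        assert union_mask([a, b]).sum() == a.sum() + b.sum()

    def test_grid_mismatch_rejected(self, fine_grid):
        a = np.zeros((5, 5, 5), dtype=bool)
        b = np.zeros((6, 6, 6), dtype=bool)
        with pytest.raises(ValueError):
            union_mask([a, b])


class TestWeightedVolume:
    def test_half_probability(self):
        grid = VolumeGrid.from_spacing((10, 10, 10), 1.0)
        mask = np.zeros(grid.shape, dtype=bool)
        mask.flat[:10] = True
        assert weighted_volume(mask, np.full(grid.shape, 0.5), grid) == 5.0

    def test_exclusion_zeroes_contribution(self):
        grid = VolumeGrid.from_spacing((10, 10, 10), 1.0)
        mask = np.ones(grid.shape, dtype=bool)
        p = np.ones(grid.shape)
        assert weighted_volume(mask, p, grid, exclusion=mask) == 0.0

    def test_bad_probabilities_rejected(self):
        grid = VolumeGrid.from_spacing((4, 4, 4), 1.0)
        with pytest.raises(ValueError):
            weighted_volume(
                np.ones(grid.shape, bool), np.full(grid.shape, 1.5), grid
            )


def _single_contact_set(pos, modality="depth"):
    return ElectrodeSet(
        [Contact("c1", "l1", modality, np.asarray(pos, float))], "p1",
        "D" if modality == "depth" else "S",
    )


class TestCoverageSweep:
    def test_single_deep_contact_matches_sphere_volume(self):
        grid = VolumeGrid.from_spacing((40, 40, 40), 1.0, (0.5, 0.5, 0.5))
        tissue = _uniform_tissue(grid)
        es = _single_contact_set((20.0, 20.0, 20.0))
        curve = coverage_sweep(es, tissue, None, None)
        assert curve.value(10.0, "gm", "total") == pytest.approx(
            sphere_volume(10.0), rel=0.02
        )
        assert curve.value(10.0, "gm", "per_contact") == curve.value(
            10.0, "gm", "total"
        )

    def test_lead_redundancy_reduces_per_contact_coverage(self):
        """Collinear 5 mm-spaced spheres overlap: per-contact coverage falls
        below the isolated-sphere volume, matching the capsule closed form."""
        grid = VolumeGrid.from_spacing((140, 80, 80), 0.5, (0.25, 0.25, 0.25))
        tissue = _uniform_tissue(grid)
        n, d, r = 8, 5.0, 5.0
        contacts = [
            Contact(f"c{i}", "l1", "depth", np.array([15.0 + i * d, 20.0, 20.0]))
            for i in range(n)
        ]
        es = ElectrodeSet(contacts, "p1", "D")
        curve = coverage_sweep(es, tissue, None, None)
        per = curve.value(r, "gm", "per_contact")
        assert per < sphere_volume(r)
        expected_union = n * sphere_volume(r) - (n - 1) * lens_volume(r, d)
        assert curve.value(r, "gm", "total") == pytest.approx(expected_union, rel=0.02)

    def test_three_sphere_union_closed_form(self):
        grid = VolumeGrid.from_spacing((120, 80, 80), 0.5, (0.25, 0.25, 0.25))
        tissue = _uniform_tissue(grid)
        r, d = 6.0, 7.0
        contacts = [
            Contact(f"c{i}", "l1", "depth", np.array([16.0 + i * d, 20.0, 20.0]))
            for i in range(3)
        ]
        es = ElectrodeSet(contacts, "p1", "D")
        curve = coverage_sweep(
            es, tissue, None, None, RoiSweepConfig(radii_mm=(r,))
        )
        # collinear: triple overlap equals the far-pair lens, so
        # |A u B u C| = 3V - 2 lens(d) (the lens(2d) terms cancel)
        expected = 3 * sphere_volume(r) - 2 * lens_volume(r, d)
        assert curve.value(r, "gm", "total") == pytest.approx(expected, rel=0.02)

    def test_curves_non_decreasing(self, phantom, phantom_spec):
        tissue, atlas, hemis = phantom
        es = _single_contact_set((30.0, 40.0, 80.0))
        curve = coverage_sweep(es, tissue, atlas, hemis, midline_x=phantom_spec.midline_x)
        for tissue_name in ("gm", "wm"):
            for scope in ("total", "per_contact"):
                v = curve.series(tissue_name, scope).values
                assert (np.diff(v) >= -1e-9).all()

    def test_empty_electrode_set_rejected(self, phantom):
        tissue, atlas, hemis = phantom
        with pytest.raises(ValueError):
            coverage_sweep(ElectrodeSet([], "p", "D"), tissue, atlas, hemis)

    def test_exclusion_parcels_subtract_from_totals(self, phantom, phantom_spec):
        """A sphere inside the cerebellum parcel contributes nothing."""
        tissue, atlas, hemis = phantom
        es = _single_contact_set((40.0, 10.0, 15.0))  # cerebellum block interior
        curve = coverage_sweep(
            es, tissue, atlas, hemis,
            RoiSweepConfig(radii_mm=(5.0,)), phantom_spec.midline_x,
        )
        assert curve.value(5.0, "gm", "total") == 0.0


class TestRegionCoverage:
    def test_sphere_inside_one_parcel_only(self, phantom, phantom_spec):
        tissue, atlas, _ = phantom
        # hippocampus box interior (left hemisphere)
        rc = region_coverage(
            ElectrodeSet(
                [Contact("c1", "l1", "depth", np.array([34.0, 35.0, 37.0]))],
                "p1", "D",
            ),
            atlas, tissue, 4.0, midline_x=phantom_spec.midline_x,
        )
        assert rc.volume("hippocampus") > 0
        assert rc.volume("frontal") == 0.0
        assert rc.volume("amygdala") == 0.0

    def test_region_sum_bounded_by_total(self, phantom, phantom_spec):
        tissue, atlas, hemis = phantom
        es = _single_contact_set((34.0, 45.0, 40.0))
        rc = region_coverage(es, atlas, tissue, 10.0, hemis, phantom_spec.midline_x)
        curve = coverage_sweep(
            es, tissue, atlas, hemis, RoiSweepConfig(radii_mm=(10.0,)),
            phantom_spec.midline_x,
        )
        assert rc.table.volume_mm3.sum() <= curve.value(10.0, "gm", "total") + 1e-6

    def test_straddling_sphere_partitions_exactly(self, phantom, phantom_spec):
        """Per-parcel volumes of a sphere straddling two parcels sum to the
        sphere's labeled-GM coverage (brute-force voxel labeling)."""
        tissue, atlas, _ = phantom
        pos = np.array([34.0, 45.0, 37.0])  # hippocampus/amygdala boundary
        es = _single_contact_set(pos)
        rc = region_coverage(es, atlas, tissue, 6.0, midline_x=phantom_spec.midline_x)
        mask = sphere_mask(pos, 6.0, tissue.grid)
        labeled = np.isin(atlas.label, atlas.analysis_ids)
        brute = tissue.p_gm[mask & labeled].sum() * tissue.grid.voxel_volume
        assert rc.table.volume_mm3.sum() == pytest.approx(brute, abs=1e-9)

    def test_unknown_region_rejected(self, phantom):
        _, atlas, _ = phantom
        with pytest.raises(KeyError):
            atlas.mask(99)


class TestRegionalInclusion:
    def _rc(self, volume):
        import pandas as pd

        from ieegcoverage.coverage import RegionCoverage

        return RegionCoverage(
            "p1", "D", 5.0,
            pd.DataFrame([{"region_id": 3, "region": "hippocampus", "volume_mm3": volume}]),
        )

    def test_zero_coverage_excluded(self):
        assert regional_inclusion(self._rc(0.0)) == {"hippocampus": False}

    def test_small_coverage_included(self):
        assert regional_inclusion(self._rc(0.3)) == {"hippocampus": True}

    def test_threshold_configurable(self):
        assert regional_inclusion(self._rc(0.3), threshold_mm3=1.0) == {
            "hippocampus": False
        }
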