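import numpy as np
import pytest

from sctqa.core import Geometry, StructureError, StructureSet, VolumeGrid
from sctqa.structural import (
    build_sd,
    distance_map,
    laplace_field_radial,
    laplace_field_tubular,
    organ_field,
    select_template,
)


GEO2 = Geometry((20, 20, 20), (2.0, 2.0, 2.0))


def sphere_mask(geo, center_mm, radius_mm):
    ax = geo.coordinate_axes()
    x, y, z = np.meshgrid(*ax, indexing="ij")
    return ((x - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2
            + (z - center_mm[2]) ** 2) <= radius_mm**2


class TestDistanceMap:
    def test_single_voxel_neighbour_distance(self):
        mask = np.zeros(GEO2.shape, bool)
        mask[10, 10, 10] = True
        d = distance_map(mask, GEO2).values
        assert d[11, 10, 10] == pytest.approx(2.0)
        assert d[10, 10, 10] < 0

    def test_sphere_centre_depth(self):
        geo = Geometry((24, 24, 24), (2.0, 2.0, 2.0))
        mask = sphere_mask(geo, (23, 23, 23), 14.0)
        d = distance_map(mask, geo).values
        centre = tuple(np.round(np.array([23, 23, 23]) / 2).astype(int))
        diag = np.sqrt(3) * 2.0
        assert abs(abs(d[centre]) - 14.0) <= diag

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(0)
        geo = Geometry((12, 12, 12), (1.5, 1.5, 1.5))
        from scipy import ndimage
        blob = ndimage.binary_dilation(rng.random(geo.shape) > 0.97,
                                       iterations=2)
        if not blob.any():
            blob[5, 5, 5] = True
        d = distance_map(blob, geo).values
        spacing = np.array(geo.spacing)
        fg = np.argwhere(blob) * spacing
        bg = np.argwhere(~blob) * spacing
        for idx in rng.integers(0, 12, size=(30, 3)):
            p = idx * spacing
            if blob[tuple(idx)]:
                expected = -np.sqrt(((bg - p) ** 2).sum(axis=1)).min()
            else:
                expected = np.sqrt(((fg - p) ** 2).sum(axis=1)).min()
            assert d[tuple(idx)] == pytest.approx(expected, abs=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(StructureError):
            distance_map(np.zeros(GEO2.shape, bool), GEO2)


def cylinder_mask(geo, radius_mm, axis_xy_mm):
    ax = geo.coordinate_axes()
    x, y, z = np.meshgrid(*ax, indexing="ij")
    return ((x - axis_xy_mm[0]) ** 2 + (y - axis_xy_mm[1]) ** 2) <= radius_mm**2


class TestLaplaceTubular:
    def test_cylinder_field_is_radial_and_monotone(self):
        """A straight tube's field depends only on radius; the profile
        matches a fine 1D radial harmonic oracle (log(r) profile)."""
        geo = Geometry((21, 21, 12), (1.0, 1.0, 1.0))
        mask = cylinder_mask(geo, 7.2, (10, 10))
        f = laplace_field_tubular(mask, geo).values
        mid = f[:, :, 6]
        x, y = np.meshgrid(np.arange(21) - 10.0, np.arange(21) - 10.0,
                           indexing="ij")
        r = np.sqrt(x**2 + y**2)
        inside = mask[:, :, 6]
        # monotone in radius (bin means strictly increase)
        bins = np.floor(r[inside]).astype(int)
        means = [mid[inside][bins == b].mean() for b in range(0, 7)]
        assert all(np.diff(means) > 0)
        assert mid[10, 10] == 0.0
        # harmonic oracle in 2D: u(r) ~ log(r/r0)/log(R/r0); compare shape
        rr = np.array([2, 3, 4, 5], dtype=float)
        oracle = np.log(rr / 1.0) / np.log(7.2 / 1.0)
        measured = np.array([mid[inside][bins == int(b)].mean() for b in rr])
        assert np.corrcoef(oracle, measured)[0, 1] > 0.98

    def test_thin_tube_is_all_surface(self):
        geo = Geometry((9, 9, 6), (2.0, 2.0, 2.0))
        mask = np.zeros(geo.shape, bool)
        mask[4, 4, :] = True  # one-voxel-thick tube
        f = laplace_field_tubular(mask, geo).values
        # every mask voxel is on the path here -> sink dominates
        assert (f[mask] == 0.0).all() or (f[mask] == 1.0).all()

    def test_interior_voxels_are_harmonic(self):
        geo = Geometry((15, 15, 10), (1.0, 1.0, 1.0))
        mask = cylinder_mask(geo, 5.2, (7, 7))
        f = laplace_field_tubular(mask, geo).values
        from scipy import ndimage
        surface = mask & ~ndimage.binary_erosion(mask)
        sink = f == 0.0
        interior = mask & ~surface & ~sink
        for i, j, k in np.argwhere(interior)[:50]:
            nb = (f[i - 1, j, k] + f[i + 1, j, k] + f[i, j - 1, k]
                  + f[i, j + 1, k] + f[i, j, k - 1] + f[i, j, k + 1]) / 6.0
            assert f[i, j, k] == pytest.approx(nb, abs=1e-6)

    def test_disconnected_mask_rejected(self):
        geo = Geometry((10, 10, 10), (1, 1, 1))
        mask = np.zeros(geo.shape, bool)
        mask[1, 1, 1] = mask[8, 8, 8] = True
        with pytest.raises(StructureError):
            laplace_field_tubular(mask, geo)


class TestLaplaceRadial:
    def test_sphere_monotone_in_radius(self):
        geo = Geometry((17, 17, 17), (1.0, 1.0, 1.0))
        mask = sphere_mask(geo, (8, 8, 8), 6.2)
        f = laplace_field_radial(mask, geo).values
        ax = geo.coordinate_axes()
        x, y, z = np.meshgrid(*ax, indexing="ij")
        r = np.sqrt((x - 8) ** 2 + (y - 8) ** 2 + (z - 8) ** 2)
        bins = np.floor(r[mask]).astype(int)
        means = [f[mask][bins == b].mean() for b in range(0, 6)]
        assert all(np.diff(means) > 0)
        assert f[8, 8, 8] == 0.0

    def test_ellipsoid_extrema(self):
        geo = Geometry((19, 15, 11), (1.0, 1.0, 1.0))
        ax = geo.coordinate_axes()
        x, y, z = np.meshgrid(*ax, indexing="ij")
        mask = ((x - 9) / 7) ** 2 + ((y - 7) / 5) ** 2 + ((z - 5) / 3) ** 2 <= 1
        f = laplace_field_radial(mask, geo).values
        from scipy import ndimage
        surface = mask & ~ndimage.binary_erosion(mask)
        assert f[9, 7, 5] == 0.0
        assert (f[surface] == 1.0).all()
        assert f[mask].max() <= 1.0 and f[mask].min() >= 0.0


def test_organ_field_range_and_surface_level():
    geo = Geometry((16, 16, 16), (2.0, 2.0, 2.0))
    mask = sphere_mask(geo, (15, 15, 15), 8.0)
    for kind in ("distance", "radial"):
        f = organ_field(mask, geo, kind=kind).values
        assert f.min() >= 0.0 and f.max() <= 1.0
        assert (f[mask] <= 0.5 + 1e-9).all()      # inside at or below surface
        far = distance_map(mask, geo).values > 25
        assert np.allclose(f[far], 1.0)           # flat far outside


class TestBuildSd:
    def test_w0_is_normalized_mri(self, case):
        sd = build_sd(case.mri, case.structures, w_sd=0.0)
        np.testing.assert_allclose(sd.merged.values, sd.mri_norm.values)

    def test_w1_is_mri_independent(self, case):
        sd1 = build_sd(case.mri, case.structures, w_sd=1.0)
        other = case.mri.like(case.mri.values * 2.0 + 10.0)
        sd2 = build_sd(other, case.structures, w_sd=1.0)
        np.testing.assert_allclose(sd1.merged.values, sd2.merged.values)

    def test_contributions_occupy_their_bands(self, case):
        sd = build_sd(case.mri, case.structures)
        from sctqa.structural import DEFAULT_BANDS
        for organ, amp in DEFAULT_BANDS.items():
            c = sd.contributions[organ].values
            assert c.min() >= 0.0
            assert c.max() == pytest.approx(amp, abs=1e-9)
            inside = case.structures[organ]
            assert np.allclose(c[inside], amp)
        # the global organ SD keeps each organ at its own distinct level
        merged = sd.organ_merged.values
        assert np.allclose(merged[case.structures["bladder"]], 1.0)

    def test_missing_structure_rejected(self, case):
        st = StructureSet(case.geometry)
        st.add("body", case.structures["body"])
        with pytest.raises(StructureError):
            build_sd(case.mri, st)


class TestSelectTemplate:
    @staticmethod
    def _fake_case(cid, geo, scale):
        from sctqa.core import PatientCase
        st = StructureSet(geo)
        base = {"bladder": 5, "rectum": 4, "prostate": 3}
        for organ, r in base.items():
            m = np.zeros(geo.shape, bool)
            n = int(r * scale)
            m[:n, :n, :n] = True
            st.add(organ, m)
        vol = VolumeGrid(np.zeros(geo.shape), geo.spacing)
        return PatientCase(id=cid, mri=vol, ct=vol.like(vol.values, "HU"),
                           structures=st)

    def test_exact_median_patient_wins(self):
        geo = Geometry((20, 20, 20), (1, 1, 1))
        cohort = [self._fake_case(f"p{i}", geo, s)
                  for i, s in enumerate([1.0, 2.0, 3.0])]
        assert select_template(cohort) == "p1"

    def test_tie_breaks_to_lowest_id(self):
        geo = Geometry((20, 20, 20), (1, 1, 1))
        cohort = [self._fake_case(f"p{i}", geo, 2.0) for i in range(3)]
        assert select_template(cohort) == "p0"

    def test_matches_brute_force_scoring(self, small_params):
        from sctqa.phantom import generate_cohort
        cohort = generate_cohort(small_params, 6, seed=13)
        chosen = select_template(cohort)
        vols = {c.id: np.array([c.structures.volume_cm3(o)
                                for o in ("bladder", "rectum", "prostate")])
                for c in cohort}
        med = np.median(np.stack(list(vols.values())), axis=0)
        scores = {cid: (np.abs(v - med) / med).sum() for cid, v in vols.items()}
        best = sorted(scores, key=lambda c: (scores[c], c))[0]
        assert chosen == best
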