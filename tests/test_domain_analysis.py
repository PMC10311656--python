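import numpy as np
import pytest

from chromstem import domain_analysis as da
from chromstem import voxel_imaging as vi
from chromstem.phantoms import PlantedDomain, gaussian_blob_stack, planted_domain_stack

PARAMS = da.DomainParams()


def brute_force_radial(stack, centroid, bin_nm, r_max):
    """Per-voxel loop oracle for the radial mass/density profiles."""
    vs = stack.grid.voxel_size
    n_bins = int(np.ceil(r_max / bin_nm))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for m in range(stack.grid.shape[0]):
        for n in range(stack.grid.shape[1]):
            for z in range(stack.grid.shape[2]):
                r = np.sqrt(
                    ((m - centroid[0]) * vs) ** 2
                    + ((n - centroid[1]) * vs) ** 2
                    + ((z - centroid[2]) * vs) ** 2
                )
                b = int(r / bin_nm)
                if b < n_bins:
                    sums[b] += stack.data[m, n, z]
                    counts[b] += 1
    return np.cumsum(sums), np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


@pytest.fixture(scope="module")
def random_stack():
    rng = np.random.default_rng(0)
    grid = vi.GridSpec(shape=(20, 18, 8), voxel_size=3.0)
    return vi.VoxelStack(data=rng.random((20, 18, 8)), grid=grid, normalized=True)


class TestEnhanceMap:
    def test_constant_stack_stays_constant(self):
        stack = vi.VoxelStack(
            data=np.full((16, 16, 8), 0.5), grid=vi.GridSpec(shape=(16, 16, 8)), normalized=True
        )
        out = da.enhance_map(stack)
        assert np.ptp(out) < 1e-9

    def test_single_blob_peak_preserved(self):
        stack = gaussian_blob_stack([(24, 24, 8)], sigma_vox=3.0)
        out = da.enhance_map(stack)
        peak = np.unravel_index(np.argmax(out), out.shape)
        assert np.all(np.abs(np.array(peak) - np.array([24, 24, 8])) <= 1)

    def test_two_blobs_give_two_maxima(self):
        stack = gaussian_blob_stack([(12, 24, 8), (36, 24, 8)], sigma_vox=2.5)
        out = da.enhance_map(stack)
        cents = da.find_centroids(out, stack.grid.voxel_size)
        assert len(cents) == 2


class TestFindCentroids:
    def test_single_blob_single_centroid(self):
        stack = gaussian_blob_stack([(20, 28, 8)], sigma_vox=3.0)
        out = da.enhance_map(stack)
        cents = da.find_centroids(out, 3.0)
        assert len(cents) == 1
        assert np.all(np.abs(np.array(cents[0]) - np.array([20, 28, 8])) <= 1)

    def test_planted_blobs_recovered(self):
        planted = [(10, 10, 5), (10, 38, 10), (38, 10, 5), (38, 38, 10)]
        stack = gaussian_blob_stack(planted, sigma_vox=2.0)
        cents = da.find_centroids(da.enhance_map(stack), 3.0)
        assert len(cents) == 4
        for p in planted:
            dmin = min(np.linalg.norm(np.array(c) - np.array(p)) for c in cents)
            assert dmin <= 1.5

    def test_zero_stack_no_centroids(self):
        stack = vi.VoxelStack(
            data=np.zeros((16, 16, 8)), grid=vi.GridSpec(shape=(16, 16, 8)), normalized=True
        )
        assert da.find_centroids(da.enhance_map(stack), 3.0) == []


class TestMassProfile:
    def test_uniform_ball_cubic_growth(self):
        ball = PlantedDomain(center_nm=(72, 72, 36), D=3.0, radius_nm=45)
        stack = planted_domain_stack([ball], shape=(48, 48, 24))
        radii, mass = da.mass_profile(stack, (24, 24, 12))
        sel = (radii >= 12) & (radii <= 39)
        slope = np.polyfit(np.log(radii[sel]), np.log(mass[sel]), 1)[0]
        assert slope == pytest.approx(3.0, abs=0.15)

    def test_point_mass_constant_profile(self):
        data = np.zeros((16, 16, 8))
        data[8, 8, 4] = 1.0
        stack = vi.VoxelStack(data=data, grid=vi.GridSpec(shape=(16, 16, 8)), normalized=True)
        radii, mass = da.mass_profile(stack, (8, 8, 4))
        assert np.all(mass == 1.0)

    def test_matches_brute_force_loop(self, random_stack):
        radii, mass = da.mass_profile(random_stack, (10, 9, 4))
        oracle_mass, _ = brute_force_radial(random_stack, (10, 9, 4), 3.0, PARAMS.r_max_nm)
        np.testing.assert_allclose(mass, oracle_mass, atol=1e-9)

    def test_monotone_non_decreasing(self, random_stack):
        _, mass = da.mass_profile(random_stack, (5, 5, 2))
        assert np.all(np.diff(mass) >= 0)


class TestFitScaling:
    def test_exact_power_law_self_consistency(self):
        radii = (np.arange(1, 50) + 1) * 3.0
        mass = 2.0 * radii**2.5
        d, rf1 = da.fit_scaling(radii, mass)
        assert d == pytest.approx(2.5, abs=0.01)
        assert rf1 == PARAMS.r_max_nm  # no 5% breakpoint on an exact law

    def test_uniform_ball_geometry(self):
        ball = PlantedDomain(center_nm=(144, 144, 48), D=3.0, radius_nm=45)
        stack = planted_domain_stack([ball], shape=(96, 96, 32))
        radii, mass = da.mass_profile(stack, (48, 48, 16))
        d, rf1 = da.fit_scaling(radii, mass)
        assert d == pytest.approx(3.0, abs=0.1)
        assert abs(rf1 - 45.0) <= PARAMS.radial_bin_nm  # breakdown at the edge

    def test_planted_breakpoint_recovered(self):
        radii = (np.arange(1, 50) + 1) * 3.0
        r0 = 60.0
        mass = np.where(radii <= r0, radii**2.5, r0**2.5)  # flat past r0
        _, rf1 = da.fit_scaling(radii, mass)
        assert abs(rf1 - r0) <= PARAMS.radial_bin_nm

    def test_zero_bins_excluded(self):
        radii = (np.arange(1, 30) + 1) * 3.0
        mass = radii**2.0
        mass[5] = 0.0  # an empty shell must not poison the log fit
        d, _ = da.fit_scaling(radii, mass)
        assert np.isfinite(d)


class TestRadialDensity:
    def test_two_domains_dip_between(self):
        d1 = PlantedDomain(center_nm=(104, 144, 48), D=3.0, radius_nm=35)
        d2 = PlantedDomain(center_nm=(184, 144, 48), D=3.0, radius_nm=35)
        stack = planted_domain_stack([d1, d2], shape=(96, 96, 32))
        (_, _), rf2 = da.radial_density(stack, (35, 48, 16))
        assert 34.0 <= rf2 <= 48.0  # dip between edge (35) and midpoint (40) bins

    def test_isolated_domain_returns_rmax(self):
        dom = PlantedDomain(center_nm=(144, 144, 48), D=2.5, radius_nm=60)
        stack = planted_domain_stack([dom], shape=(96, 96, 32))
        (_, _), rf2 = da.radial_density(stack, (48, 48, 16))
        assert rf2 == PARAMS.r_max_nm

    def test_matches_brute_force_loop(self, random_stack):
        (edges, density), _ = da.radial_density(random_stack, (10, 9, 4))
        _, oracle_density = brute_force_radial(random_stack, (10, 9, 4), 3.0, PARAMS.r_max_nm)
        np.testing.assert_allclose(density, oracle_density, atol=1e-9, equal_nan=True)


class TestDomainSizeAndCVC:
    @pytest.mark.parametrize("rf1,rf2,expected", [(60, 90, 60), (90, 60, 60), (70, 70, 70)])
    def test_min_rule(self, rf1, rf2, expected):
        assert da.domain_size(rf1, rf2) == expected

    def test_full_ball_cvc_one(self):
        ball = PlantedDomain(center_nm=(72, 72, 36), D=3.0, radius_nm=40)
        stack = planted_domain_stack([ball], shape=(48, 48, 24))
        assert da.cvc(stack, (24, 24, 12), 35.0) == 1.0

    def test_empty_ball_cvc_zero(self):
        stack = vi.VoxelStack(
            data=np.zeros((24, 24, 12)), grid=vi.GridSpec(shape=(24, 24, 12)), normalized=True
        )
        assert da.cvc(stack, (12, 12, 6), 20.0) == 0.0

    def test_half_filled_ball(self):
        # fill only the m >= center half of the ball
        shape = (48, 48, 24)
        grid = vi.GridSpec(shape=shape, voxel_size=3.0)
        mesh = np.meshgrid(*[np.arange(s) * 3.0 for s in shape], indexing="ij")
        r = np.sqrt(sum((g - c) ** 2 for g, c in zip(mesh, (72, 72, 36))))
        data = np.where((r <= 36) & (mesh[0] >= 72), 0.8, 0.0)
        stack = vi.VoxelStack(data=data, grid=grid, normalized=True)
        assert da.cvc(stack, (24, 24, 12), 36.0) == pytest.approx(0.5, abs=0.05)


class TestAnalyzeStack:
    def test_empty_stack_flagged_undefined(self):
        stack = vi.VoxelStack(
            data=np.zeros((24, 24, 12)), grid=vi.GridSpec(shape=(24, 24, 12)), normalized=True
        )
        domains, summary = da.analyze_stack(stack)
        assert domains == []
        assert summary == {"n_domains": 0, "defined": False}

    def test_invariants_on_planted_field(self):
        rng = np.random.default_rng(7)
        planted = [
            PlantedDomain(center_nm=(100, 100, 48), D=2.4, radius_nm=45),
            PlantedDomain(center_nm=(280, 150, 48), D=2.7, radius_nm=50),
            PlantedDomain(center_nm=(150, 320, 48), D=2.6, radius_nm=40),
        ]
        stack = planted_domain_stack(planted, shape=(140, 140, 32))
        domains, summary = da.analyze_stack(stack)
        assert summary["defined"]
        for d in domains:
            assert d.Rf == min(d.Rf1, d.Rf2)
            assert 0.0 <= d.CVC <= 1.0
            assert d.D > 0
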