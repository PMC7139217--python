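import numpy as np
import pytest

from densedock import (
    SimulationParams,
    VoxelMap,
    ccc,
    difference_map,
    find_difference_peaks,
    scale_amplitudes,
    simulate_map,
    smoc,
)
from densedock.errors import CongruenceError
from densedock.map_compare import pearson, proximity_mask
from densedock.synthetic import _helix_chain
from densedock.io_formats import AtomicModel


def random_map(rng, shape=(16, 16, 16)):
    return VoxelMap(rng.normal(size=shape), 1.0, (0, 0, 0))


def brute_pearson(x, y):
    """Per-voxel loop Pearson, the independent oracle for CCC."""
    xs = ys = xx = yy = xy = 0.0
    n = 0
    for a, b in zip(x.ravel(), y.ravel()):
        xs += a
        ys += b
        xx += a * a
        yy += b * b
        xy += a * b
        n += 1
    num = xy - xs * ys / n
    den = np.sqrt((xx - xs * xs / n) * (yy - ys * ys / n))
    return num / den


class TestScaleAmplitudes:
    def test_scaling_undoes_global_doubling(self):
        rng = np.random.default_rng(0)
        a = random_map(rng)
        b = a.copy(data=2.0 * a.data)
        scaled = scale_amplitudes(b, a)
        np.testing.assert_allclose(scaled.data, a.data, atol=1e-8)

    def test_white_noise_acquires_target_radial_profile(self):
        # oracle: radially averaged power computed directly, in coarse
        # shells that are whole multiples of the scaling shell width
        rng = np.random.default_rng(1)
        shape = (24, 24, 24)
        # target with a decaying radial spectrum: a blurred random field
        from scipy.ndimage import gaussian_filter

        a = VoxelMap(gaussian_filter(rng.normal(size=shape), 1.5), 1.0, (0, 0, 0))
        b = VoxelMap(rng.normal(size=shape), 1.0, (0, 0, 0))
        width = 0.005  # A^-1
        scaled = scale_amplitudes(b, a, shell_width=width)

        def shell_power(vmap, coarse=20 * width, n_bins=5):
            f = np.fft.fftn(vmap.data)
            freqs = [np.fft.fftfreq(n, d=v)
                     for n, v in zip(vmap.shape, vmap.voxel_size)]
            s = np.sqrt(
                freqs[0][:, None, None] ** 2
                + freqs[1][None, :, None] ** 2
                + freqs[2][None, None, :] ** 2
            )
            idx = np.floor(s / coarse).astype(int)
            return np.array([
                (np.abs(f[(idx == k) & (s > 0)]) ** 2).sum()
                for k in range(n_bins)
            ])

        pa = shell_power(a)
        pb = shell_power(scaled)
        np.testing.assert_allclose(pb, pa, rtol=0.01)

    def test_single_shell_equals_global_mean_std_matching(self):
        rng = np.random.default_rng(2)
        a = random_map(rng, (12, 12, 12))
        b = random_map(rng, (12, 12, 12))
        scaled = scale_amplitudes(b, a, shell_width=np.inf)
        expected = (b.data - b.data.mean()) / b.data.std() * a.data.std() + a.data.mean()
        np.testing.assert_allclose(scaled.data, expected, atol=1e-8)

    def test_grid_mismatch_raises(self):
        rng = np.random.default_rng(3)
        a = random_map(rng, (12, 12, 12))
        b = random_map(rng, (10, 10, 10))
        with pytest.raises(CongruenceError):
            scale_amplitudes(b, a)


class TestDifferenceMap:
    def test_self_difference_is_zero(self):
        rng = np.random.default_rng(4)
        a = random_map(rng)
        result = difference_map(a, a)
        np.testing.assert_allclose(result.difference.data, 0.0, atol=1e-8)
        np.testing.assert_allclose(result.positive.data, 0.0, atol=1e-8)

    def test_antisymmetry_for_spectrum_matched_pair(self):
        # a circularly shifted copy has identical amplitudes -> scaling is
        # the identity and the difference is antisymmetric in its arguments
        rng = np.random.default_rng(5)
        a = random_map(rng)
        b = a.copy(data=np.roll(a.data, 3, axis=0))
        d_ab = difference_map(a, b).difference.data
        d_ba = difference_map(b, a).difference.data
        np.testing.assert_allclose(d_ab, -d_ba, atol=1e-8)

    def test_planted_ligand_peak_localization(self, clean_scene):
        result = difference_map(clean_scene.map_with, clean_scene.map_without)
        peaks = find_difference_peaks(result.positive, threshold_sigma=3.0)
        assert peaks
        err = np.linalg.norm(peaks[0].centroid - clean_scene.true_pose.centroid)
        assert err <= float(np.max(clean_scene.map_with.voxel_size))


class TestCCC:
    def test_self_simulated_map_correlates_perfectly(self, sim_params):
        atoms = _helix_chain("A", 8, offset=np.zeros(3))
        model = AtomicModel(atoms=atoms)
        sim = simulate_map(model, sim_params)
        result = ccc(sim, model, sim_params, mask_mode="whole-map")
        assert result.value == pytest.approx(1.0, abs=1e-10)

    def test_negated_map_gives_minus_one(self, sim_params):
        atoms = _helix_chain("A", 8, offset=np.zeros(3))
        model = AtomicModel(atoms=atoms)
        sim = simulate_map(model, sim_params)
        neg = sim.copy(data=-sim.data)
        result = ccc(neg, model, sim_params, mask_mode="whole-map")
        assert result.value == pytest.approx(-1.0, abs=1e-10)

    def test_matches_bruteforce_loop_on_random_maps(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            shape = tuple(rng.integers(6, 25, size=3))
            x = rng.normal(size=shape)
            y = 0.4 * x + rng.normal(size=shape)
            assert pearson(x, y) == pytest.approx(brute_pearson(x, y), abs=1e-10)

    def test_tiny_mask_flagged_unreliable(self, sim_params):
        from densedock import Atom

        model = AtomicModel(
            atoms=[Atom("A", 1, "LIG", "C1", "C", [0.0, 0.0, 0.0])]
        )
        sim = simulate_map(model, sim_params)
        with pytest.warns(UserWarning, match="unreliable"):
            result = ccc(sim, model, sim_params, mask_mode="sim-contour",
                         contour_frac=0.999)
        assert not result.reliable
        assert result.mask_voxel_count < 30


@pytest.fixture(scope="module")
def helix_model():
    return AtomicModel(atoms=_helix_chain("A", 24, offset=np.zeros(3)))


class TestSMOC:
    def test_self_map_gives_near_perfect_profile(self, helix_model, sim_params):
        sim = simulate_map(helix_model, sim_params)
        profile = smoc(helix_model, sim, sim_params, window=9)
        assert len(profile.records) == 24
        assert np.all(profile.values() >= 0.99)

    def test_displaced_residue_marks_profile_minimum(self, helix_model, sim_params):
        from dataclasses import replace

        sim = simulate_map(helix_model, sim_params)
        displaced_atoms = [
            replace(a, xyz=a.xyz + np.array([0.0, 0.0, 10.0]))
            if a.res_num == 12 else replace(a)
            for a in helix_model.atoms
        ]
        broken = AtomicModel(atoms=displaced_atoms)
        profile = smoc(broken, sim, sim_params, window=9)
        worst = profile.minimum()
        assert abs(worst["res_num"] - 12) <= 1

    def test_wider_window_smooths_the_profile(self, helix_model, sim_params):
        rng = np.random.default_rng(7)
        sim = simulate_map(helix_model, sim_params)
        noisy = sim.copy(data=sim.data + rng.normal(0, 0.05 * sim.data.max(),
                                                    sim.shape))
        v1 = smoc(helix_model, noisy, sim_params, window=1).values()
        v9 = smoc(helix_model, noisy, sim_params, window=9).values()
        assert v9.var() < v1.var()

    def test_renumbering_offset_does_not_change_profile(self, helix_model,
                                                        sim_params):
        from dataclasses import replace

        sim = simulate_map(helix_model, sim_params)
        renumbered = AtomicModel(
            atoms=[replace(a, res_num=a.res_num + 100) for a in helix_model.atoms]
        )
        base = smoc(helix_model, sim, sim_params).values()
        shifted = smoc(renumbered, sim, sim_params).values()
        np.testing.assert_allclose(shifted, base, atol=1e-12)

    def test_even_window_rejected(self, helix_model, sim_params):
        sim = simulate_map(helix_model, sim_params)
        with pytest.raises(ValueError, match="odd"):
            smoc(helix_model, sim, sim_params, window=8)


class TestDifferencePeaks:
    def test_zero_map_has_no_peaks(self):
        vmap = VoxelMap(np.zeros((12, 12, 12)), 1.0, (0, 0, 0))
        assert find_difference_peaks(vmap) == []

    def test_two_planted_blobs_found_at_their_centers(self):
        shape = (32, 20, 20)
        grid = VoxelMap(np.zeros(shape), 1.0, (0, 0, 0))
        centers = [np.array([8.0, 10.0, 10.0]), np.array([24.0, 10.0, 10.0])]
        idx = np.indices(shape).astype(float)
        for c in centers:
            r2 = sum((idx[d] - c[d]) ** 2 for d in range(3))
            grid.data += np.exp(-r2 / (2 * 1.5**2))
        peaks = find_difference_peaks(grid, threshold_sigma=3.0, min_volume=3)
        assert len(peaks) == 2
        found = sorted(p.centroid[0] for p in peaks)
        for got, c in zip(found, centers):
            assert got == pytest.approx(c[0], abs=1.0)

    def test_threshold_above_maximum_gives_empty_list(self):
        rng = np.random.default_rng(8)
        vmap = VoxelMap(rng.normal(size=(12, 12, 12)), 1.0, (0, 0, 0))
        assert find_difference_peaks(vmap, threshold_sigma=50.0) == []

    def test_peak_count_non_increasing_in_threshold(self, clean_scene):
        result = difference_map(clean_scene.map_with, clean_scene.map_without)
        counts = [
            len(find_difference_peaks(result.positive, threshold_sigma=t,
                                      min_volume=3))
            for t in (2, 3, 4, 5)
        ]
        assert counts == sorted(counts, reverse=True)


class TestProximityMask:
    def test_mask_radius_semantics(self):
        grid = VoxelMap(np.zeros((11, 11, 11)), 1.0, (0, 0, 0))
        mask = proximity_mask(grid, np.array([[5.0, 5.0, 5.0]]), radius=2.5)
        assert mask[5, 5, 5]
        assert mask[5, 5, 7]     # 2.0 A away
        assert not mask[5, 5, 8]  # 3.0 A away
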