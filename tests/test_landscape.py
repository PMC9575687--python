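import numpy as np
import pandas as pd
import pytest

from esper.landscape import (EnergyLandscape, OccupancyMapND, PDResult,
                             SenseMap, align_senses, fsc, intersect_indices,
                             occupancy_to_energy, resolution_at)


def make_result(pd_id, truth, bins_per_cm, B=10, r2=None, meta_extra=None):
    """PDResult built directly from a ground-truth table (no images)."""
    meta = pd.DataFrame({f"state_{g}": truth[:, g] for g in range(truth.shape[1])})
    meta["image_id"] = np.arange(len(truth)) + pd_id * 100000
    if meta_extra:
        for k, v in meta_extra.items():
            meta[k] = v
    return PDResult(pd_id=pd_id, bins=bins_per_cm,
                    r2=r2 or {g: 0.95 for g in bins_per_cm}, B=B, meta=meta)


@pytest.fixture
def truth_2d():
    rng = np.random.default_rng(0)
    return rng.integers(0, 10, size=(600, 2))


class TestAlignSenses:
    def test_forward_bins_labeled_with_positive_sense(self, truth_2d):
        res = make_result(0, truth_2d, {1: truth_2d[:, 0].copy(),
                                        2: truth_2d[:, 1].copy()})
        sm = align_senses([res], mode="ground_truth")
        assert sm.assignments[(0, 1)] == (1, 1)
        assert sm.assignments[(0, 2)] == (2, 1)

    def test_reversed_bins_get_negative_sense(self, truth_2d):
        res = make_result(0, truth_2d, {1: 9 - truth_2d[:, 0]})
        sm = align_senses([res], mode="ground_truth")
        assert sm.assignments[(0, 1)] == (1, -1)
        corrected = sm.corrected_bins(res, 1)
        np.testing.assert_array_equal(corrected, truth_2d[:, 0])

    def test_noisy_bins_labeled_correctly_across_pds(self):
        """Several PDs with noisy, possibly flipped binnings all map back to
        the right global CM."""
        rng = np.random.default_rng(1)
        correct = 0
        for pd_id in range(10):
            truth = rng.integers(0, 10, size=(400, 2))
            noise = rng.integers(-1, 2, size=400)
            flip = pd_id % 2 == 1
            b1 = np.clip(truth[:, 1] + noise, 0, 9)        # local 1 is CM_2
            b2 = np.clip(truth[:, 0] + noise, 0, 9)
            if flip:
                b1 = 9 - b1
            res = make_result(pd_id, truth, {1: b1, 2: b2})
            sm = align_senses([res], mode="ground_truth")
            g1, s1 = sm.assignments[(pd_id, 1)]
            g2, s2 = sm.assignments[(pd_id, 2)]
            if g1 == 2 and g2 == 1 and s1 == (-1 if flip else 1):
                correct += 1
        assert correct >= 9

    def test_reference_mode_matches_by_occupancy_profile(self):
        rng = np.random.default_rng(2)
        # a skewed occupancy profile makes the orientation identifiable
        states = rng.choice(10, size=800, p=np.linspace(1, 3, 10) / 20.0)
        truth = states[:, None]
        ref = make_result(0, truth, {1: states.copy()})
        other = make_result(1, truth, {1: 9 - states})   # flipped sense
        sm = align_senses([ref, other], mode="reference_pd")
        assert sm.assignments[(0, 1)] == (1, 1)
        g, s = sm.assignments[(1, 1)]
        assert (g, s) == (1, -1)


class TestIntersectIndices:
    def test_lossless_single_pd_counts_match_generator(self, truth_2d):
        res = make_result(0, truth_2d, {1: truth_2d[:, 0].copy(),
                                        2: truth_2d[:, 1].copy()})
        sm = align_senses([res], mode="ground_truth")
        occ = intersect_indices([res], sm, n=2)
        expected = np.zeros((10, 10), dtype=int)
        np.add.at(expected, (truth_2d[:, 0], truth_2d[:, 1]), 1)
        np.testing.assert_array_equal(occ.counts, expected)

    def test_one_dimensional_needs_no_intersection(self, truth_2d):
        res = make_result(0, truth_2d[:, :1], {1: truth_2d[:, 0].copy()})
        sm = align_senses([res], mode="ground_truth")
        occ = intersect_indices([res], sm, n=1)
        np.testing.assert_array_equal(occ.counts, np.bincount(truth_2d[:, 0],
                                                              minlength=10))

    def test_sense_flip_leaves_occupancy_invariant(self, truth_2d):
        forward = make_result(0, truth_2d, {1: truth_2d[:, 0].copy(),
                                            2: truth_2d[:, 1].copy()})
        flipped = make_result(0, truth_2d, {1: 9 - truth_2d[:, 0],
                                            2: truth_2d[:, 1].copy()})
        occs = []
        for res in (forward, flipped):
            sm = align_senses([res], mode="ground_truth")
            occs.append(intersect_indices([res], sm, n=2).counts)
        np.testing.assert_array_equal(occs[0], occs[1])

    def test_gate_excludes_poor_fits(self, truth_2d):
        good = make_result(0, truth_2d, {1: truth_2d[:, 0].copy(),
                                         2: truth_2d[:, 1].copy()})
        bad = make_result(1, truth_2d, {1: truth_2d[:, 0].copy(),
                                        2: truth_2d[:, 1].copy()},
                          r2={1: 0.95, 2: 0.4})
        sm = align_senses([good, bad], mode="ground_truth")
        occ = intersect_indices([good, bad], sm, n=2, r2_min=0.7)
        assert occ.contributing_pds == [0]
        assert occ.counts.sum() == 600

    def test_image_conservation(self, truth_2d):
        results = []
        for pd_id in range(3):
            results.append(make_result(pd_id, truth_2d,
                                       {1: truth_2d[:, 0].copy(),
                                        2: truth_2d[:, 1].copy()}))
        sm = align_senses(results, mode="ground_truth")
        occ = intersect_indices(results, sm, n=2)
        assert occ.counts.sum() == 3 * 600


class TestEnergy:
    def _occ(self, counts):
        return OccupancyMapND(counts=np.asarray(counts), contributing_pds=[0],
                              gate=0.7)

    def test_uniform_counts_flat_landscape(self):
        e = occupancy_to_energy(self._occ(np.full((4, 4), 7)))
        np.testing.assert_allclose(e.delta_g, 0.0)

    def test_e_fold_ratio_is_one_kt(self):
        counts = np.array([[int(round(100 * np.e)), 100]])
        e = occupancy_to_energy(self._occ(counts))
        assert e.delta_g[0, 1] - e.delta_g[0, 0] == pytest.approx(1.0, abs=1e-2)

    def test_rescaling_counts_leaves_energies_unchanged(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 50, size=(5, 5))
        e1 = occupancy_to_energy(self._occ(counts))
        e2 = occupancy_to_energy(self._occ(counts * 2))
        np.testing.assert_allclose(e1.delta_g, e2.delta_g, atol=1e-12)

    def test_empty_cells_masked_and_reference_at_zero(self):
        counts = np.array([[10, 0], [5, 2]])
        e = occupancy_to_energy(self._occ(counts))
        assert e.mask[0, 1]
        assert np.isnan(e.delta_g[0, 1])
        assert e.delta_g[e.reference_bin] == 0.0
        assert np.nanmin(e.delta_g) == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            occupancy_to_energy(self._occ(np.zeros((3, 3), dtype=int)))


class TestExportStateStacks:
    def test_export_partitions_images_and_round_trips(self, tmp_path, truth_2d):
        from esper.landscape import export_state_stacks
        from esper.mrc import read_mrcs
        from esper.synthetic import ImageStack

        rng = np.random.default_rng(3)
        n = len(truth_2d)
        images = rng.normal(size=(n, 16, 16)).astype(np.float32)
        quat = {"q_w": 1.0, "q_x": 0.0, "q_y": 0.0, "q_z": 0.0,
                "defocus_um": 1.0}
        res = make_result(0, truth_2d, {1: truth_2d[:, 0].copy(),
                                        2: truth_2d[:, 1].copy()},
                          meta_extra=quat)
        stack = ImageStack(images=images, pixel_size_A=1.5, meta=res.meta)
        sm = align_senses([res], mode="ground_truth")
        cells = [(i, j) for i in range(10) for j in range(10)]
        manifest = export_state_stacks([res], sm, {0: stack}, cells,
                                       tmp_path, n=2)
        seen = []
        for cell, entry in manifest.states.items():
            imgs, pixel = read_mrcs(entry["stack"])
            assert pixel == pytest.approx(1.5)
            sel = (truth_2d[:, 0] == cell[0]) & (truth_2d[:, 1] == cell[1])
            np.testing.assert_array_equal(imgs, images[sel])
            seen.extend(entry["image_ids"])
        # every image lands in exactly one state stack
        assert sorted(seen) == sorted(res.meta["image_id"].tolist())

    def test_monotone_composition_along_diagonal_path(self, tmp_path):
        """Cells along the CM_1 axis contain images whose true CM_1 index
        increases with the path step."""
        from esper.landscape import export_state_stacks
        from esper.synthetic import ImageStack

        rng = np.random.default_rng(4)
        truth = np.stack([np.repeat(np.arange(10), 40),
                          rng.integers(0, 10, 400)], axis=1)
        noisy_b1 = np.clip(truth[:, 0] + rng.integers(-1, 2, 400), 0, 9)
        res = make_result(0, truth, {1: noisy_b1, 2: truth[:, 1].copy()},
                          meta_extra={"q_w": 1.0, "q_x": 0.0, "q_y": 0.0,
                                      "q_z": 0.0, "defocus_um": 1.0})
        stack = ImageStack(images=np.zeros((400, 8, 8), dtype=np.float32),
                           pixel_size_A=1.0, meta=res.meta)
        sm = align_senses([res], mode="ground_truth")
        path = [(b, 4) for b in range(10)]
        manifest = export_state_stacks([res], sm, {0: stack}, path, tmp_path, n=2)
        means = []
        for b in range(10):
            if (b, 4) not in manifest.states:
                continue
            ids = manifest.states[(b, 4)]["image_ids"]
            sel = res.meta["image_id"].isin(ids)
            means.append(res.meta.loc[sel, "state_0"].mean())
        assert (np.diff(means) > -0.5).all() and means[-1] > means[0]


class TestFSC:
    def _vol(self, seed=0, P=48):
        rng = np.random.default_rng(seed)
        from scipy import ndimage
        return ndimage.gaussian_filter(rng.normal(size=(P, P, P)), 2.0)

    def test_self_correlation_is_unity(self):
        v = self._vol()
        freq, curve = fsc(v, v, pixel_size=1.0)
        np.testing.assert_allclose(curve, 1.0, atol=1e-10)

    def test_independent_noise_decorrelates(self):
        P = 64
        rng = np.random.default_rng(1)
        va, vb = rng.normal(size=(P,) * 3), rng.normal(size=(P,) * 3)
        freq, curve = fsc(va, vb, pixel_size=1.0)
        assert np.abs(curve[4:]).max() < 0.1

    def test_lowpass_pair_crosses_at_cutoff(self):
        """Correlating a volume against its sharply low-passed copy drops
        the FSC at the filter cutoff, within one shell."""
        P = 48
        rng = np.random.default_rng(2)
        v = rng.normal(size=(P,) * 3)
        F = np.fft.fftn(v)
        k = np.fft.fftfreq(P) * P
        kr = np.sqrt(k[:, None, None] ** 2 + k[None, :, None] ** 2
                     + k[None, None, :] ** 2)
        cutoff = 10
        filtered = np.fft.ifftn(F * (kr <= cutoff)).real
        freq, curve = fsc(v, filtered, pixel_size=1.0)
        res = resolution_at(freq, curve, threshold=0.143)
        cutoff_res = 1.0 / (cutoff / P)
        shell_res = 1.0 / ((cutoff + 1) / P)
        assert shell_res <= res <= 1.0 / ((cutoff - 1) / P)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="cubic"):
            fsc(np.zeros((8, 8, 8)), np.zeros((10, 10, 10)))

    def test_resolution_never_crossing_is_nyquist(self):
        v = self._vol()
        freq, curve = fsc(v, v, pixel_size=2.0)
        assert resolution_at(freq, curve) == pytest.approx(1.0 / freq[-1])
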