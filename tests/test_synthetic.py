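import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.spatial.distance import pdist

from esper import (MicroscopeParams, OccupancySpec, ProjectionDirection,
                   add_noise, apply_ctf, assemble_dataset, build_toy_model,
                   fibonacci_hemisphere, generate_state_space, project,
                   render_density, render_projection)
from esper.synthetic import ctf_array


class TestToyModels:
    def test_two_arm_v_has_two_hinged_arms_and_core(self):
        m = build_toy_model("two_arm_v", atoms_per_domain=12)
        assert m.n_mobile == 2
        assert set(np.unique(m.domain_of_atom)) == {0, 1, 2}
        for motion in m.motions.values():
            assert np.isclose(np.linalg.norm(motion.axis), 1.0)

    def test_zero_angle_state_reproduces_seed_coordinates(self):
        m = build_toy_model("two_arm_v")
        coords = m.conformation([0.0, 0.0])
        np.testing.assert_allclose(coords, m.atoms)

    def test_rigid_hinge_preserves_intra_domain_distances(self):
        m = build_toy_model("two_arm_v")
        moved = m.conformation([25.0, 10.0])
        for dom in (1, 2):
            sel = m.domain_of_atom == dom
            np.testing.assert_allclose(pdist(moved[sel]), pdist(m.atoms[sel]),
                                       atol=1e-9)

    def test_mouth_wings_motion_is_non_rigid_translation_field(self):
        m = build_toy_model("mouth_wings")
        assert m.n_mobile == 2
        lo, hi = m.motions[1].theta_range
        moved = m.conformation([hi, lo])
        mouth = m.domain_of_atom == 1
        # concerted per-atom translations change intra-domain distances
        assert np.abs(pdist(moved[mouth]) - pdist(m.atoms[mouth])).max() > 0.1

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            build_toy_model("helix")
        with pytest.raises(ValueError, match="atoms_per_domain"):
            build_toy_model("two_arm_v", atoms_per_domain=2)


class TestStateSpace:
    @pytest.mark.parametrize("n,M,expected", [(2, 20, 400), (1, 20, 20), (1, 2, 2)])
    def test_state_counts(self, toy_model, n, M, expected):
        space = generate_state_space(toy_model, n=n, M=M)
        assert space.n_states == expected
        assert space.states().shape == (expected, n)

    def test_two_point_grid_hits_range_endpoints(self, toy_model):
        space = generate_state_space(toy_model, n=1, M=2)
        lo, hi = toy_model.motions[1].theta_range
        np.testing.assert_allclose(space.value_grids[0], [lo, hi])

    def test_angles_equispaced(self, toy_model):
        space = generate_state_space(toy_model, n=2, M=7)
        for grid in space.value_grids:
            np.testing.assert_allclose(np.diff(grid), np.diff(grid)[0])

    def test_too_many_motions_rejected(self, toy_model):
        with pytest.raises(ValueError, match="mobile domains"):
            generate_state_space(toy_model, n=3, M=5)


class TestRendering:
    def test_single_blob_has_unit_integral(self, toy_model):
        space = generate_state_space(toy_model, n=1, M=2)
        vol = render_density(toy_model, space, [0], grid_size=64, blob_sigma=1.5)
        n_atoms = len(toy_model.atoms)
        assert abs(vol.sum() - n_atoms) < 1e-3 * n_atoms
        assert (vol >= 0).all()

    def test_volume_is_sum_of_disjoint_blob_groups(self):
        from esper.synthetic import Hinge, ToyModel
        hinge = Hinge(anchor=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]),
                      theta_range=(0.0, 10.0))
        left = np.array([[-8.0, 0, 0], [-8, 1, 0], [-8, 0, 1]])
        right = np.array([[8.0, 0, 0], [8, 1, 0], [8, 0, 1]])
        dom = np.array([0, 0, 0, 1, 1, 1])

        def vol_of(atoms):
            m = ToyModel(atoms, dom[:len(atoms)], {1: hinge})
            space = generate_state_space(m, n=1, M=2)
            return render_density(m, space, [0], grid_size=48, blob_sigma=1.2)

        vol_ab = vol_of(np.vstack([left, right]))
        # disjoint groups superpose: each half carries its own atoms' mass
        assert abs(vol_ab[:, :24, :].sum() - 3.0) < 1e-2
        assert abs(vol_ab[:, 24:, :].sum() - 3.0) < 1e-2
        assert abs(vol_ab.sum() - 6.0) < 2e-2

    def test_atom_outside_grid_names_atom_and_state(self, toy_model):
        space = generate_state_space(toy_model, n=1, M=2)
        with pytest.raises(ValueError, match="atom .* state"):
            render_density(toy_model, space, [1], grid_size=24)

    def test_identity_projection_equals_axis_sum(self, toy_model, identity_pd):
        space = generate_state_space(toy_model, n=1, M=2)
        vol = render_density(toy_model, space, [0])
        img = project(vol, identity_pd)
        np.testing.assert_allclose(img, vol.sum(axis=2), atol=1e-9)

    def test_mass_conserved_under_rotation(self, toy_model):
        space = generate_state_space(toy_model, n=1, M=2)
        vol = render_density(toy_model, space, [0])
        for pd_ in fibonacci_hemisphere(3):
            img = project(vol, pd_)
            assert abs(img.sum() - vol.sum()) < 1e-3 * vol.sum()

    def test_analytic_projection_matches_volume_route(self, toy_model):
        space = generate_state_space(toy_model, n=1, M=3)
        pd_ = fibonacci_hemisphere(5)[2]
        vol = render_density(toy_model, space, [1])
        via_volume = project(vol, pd_)
        direct = render_projection(toy_model, space, [1], pd_)
        # interpolation error only
        assert np.abs(via_volume - direct).max() < 0.05 * direct.max()

    def test_in_plane_motion_displaces_more_than_down_axis_view(self, toy_model):
        """A view with the arm swing in-plane separates consecutive states
        more than a view looking down the motion plane."""
        space = generate_state_space(toy_model, n=1, M=5)
        in_plane = ProjectionDirection(id=0, orientation=(1, 0, 0, 0))
        # rotate 90 deg about y: view along the x axis (motion mostly along z)
        s = np.sin(np.pi / 4)
        side = ProjectionDirection(id=1, orientation=(np.cos(np.pi / 4), 0, s, 0))
        def step(pd_):
            imgs = [render_projection(toy_model, space, [i], pd_) for i in range(5)]
            return np.mean([np.linalg.norm(imgs[i + 1] - imgs[i]) for i in range(4)])
        assert step(in_plane) > step(side)


class TestCTF:
    params = MicroscopeParams()

    def test_dc_component_scaled_by_minus_amplitude_contrast(self):
        img = np.random.default_rng(0).normal(size=(64, 64))
        out = apply_ctf(img, 1.5, self.params)
        np.testing.assert_allclose(out.sum(), -self.params.amplitude_contrast * img.sum(),
                                   rtol=1e-10)

    def test_first_zero_matches_root_of_analytic_curve(self):
        ctf = ctf_array(256, 1.5, self.params)
        radial = ctf[0, :128]          # along one frequency axis
        k = np.fft.fftfreq(256, d=self.params.pixel_size_A)[:128]
        lam = self.params.wavelength_A
        cs = self.params.spherical_aberration_mm * 1e7
        A = self.params.amplitude_contrast
        def analytic(kk):
            chi = np.pi * lam * kk ** 2 * (1.5e4 - 0.5 * lam ** 2 * cs * kk ** 2)
            return -(np.sqrt(1 - A ** 2) * np.sin(chi) + A * np.cos(chi))
        # brute-force scan for the first sign change, then root-find
        kk = np.linspace(1e-4, k[-1], 20000)
        vals = analytic(kk)
        i = np.nonzero(np.sign(vals[1:]) != np.sign(vals[:-1]))[0][0]
        k_zero = brentq(analytic, kk[i], kk[i + 1])
        j = np.nonzero(np.sign(radial[1:]) != np.sign(radial[:-1]))[0][0]
        assert k[j] <= k_zero <= k[j + 2]

    def test_double_application_is_ctf_squared(self):
        img = np.random.default_rng(1).normal(size=(64, 64))
        twice = apply_ctf(apply_ctf(img, 1.0, self.params), 1.0, self.params)
        ctf = ctf_array(64, 1.0, self.params)
        direct = np.fft.ifft2(np.fft.fft2(img) * ctf ** 2).real
        np.testing.assert_allclose(twice, direct, atol=1e-10)

    def test_overfocus_warns(self):
        with pytest.warns(UserWarning, match="overfocus"):
            apply_ctf(np.zeros((32, 32)), -0.5, self.params)


class TestNoise:
    def test_infinite_snr_is_passthrough(self):
        img = np.random.default_rng(0).normal(size=(4, 16, 16))
        out, _ = add_noise(img, np.inf, rng_seed=1)
        np.testing.assert_array_equal(out, img)

    def test_snr_calibration_within_five_percent(self, ss2_stack):
        clean = ss2_stack.images.astype(float)[:400]
        noisy, _ = add_noise(clean, 0.5, rng_seed=3)
        measured = clean.var() / (noisy - clean).var()
        assert abs(measured - 0.5) < 0.05 * 0.5

    def test_same_seed_bit_identical(self):
        img = np.random.default_rng(0).normal(size=(8, 32, 32))
        a, seeds_a = add_noise(img, 0.2, rng_seed=7)
        b, seeds_b = add_noise(img, 0.2, rng_seed=7)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(seeds_a, seeds_b)

    def test_nonpositive_snr_rejected(self):
        with pytest.raises(ValueError, match="snr"):
            add_noise(np.zeros((2, 8, 8)), -1.0, rng_seed=0)


class TestAssembleDataset:
    def test_ss1_datatype_i_yields_one_image_per_state(self, ss1_stack):
        assert ss1_stack.n_images == 20
        assert ss1_stack.meta["image_id"].is_unique

    def test_ss2_tau10_grouping(self, toy_model, identity_pd):
        space = generate_state_space(toy_model, n=2, M=5)
        stacks = assemble_dataset(toy_model, space, [identity_pd],
                                  OccupancySpec(mode="uniform", tau=4), "II",
                                  snr=1.0, seed=0)
        stack = stacks[0]
        assert stack.n_images == 100
        groups = stack.meta.groupby("state_0").size()
        assert (groups == 20).all()     # 5 CM_2 states x 4 copies

    def test_degenerate_weighting_puts_all_images_on_one_state(self, toy_model, identity_pd):
        space = generate_state_space(toy_model, n=1, M=5)
        w = np.zeros(5); w[2] = 1.0
        stacks = assemble_dataset(
            toy_model, space, [identity_pd],
            OccupancySpec(mode="weighted", tau=3, weights=w), "IV",
            snr=1.0, seed=0)
        assert (stacks[0].meta["state_0"] == 2).all()
        assert stacks[0].n_images == 15

    def test_datatype_constraints_enforced(self, toy_model, identity_pd):
        space = generate_state_space(toy_model, n=1, M=3)
        with pytest.raises(ValueError, match="data-type I"):
            assemble_dataset(toy_model, space, [identity_pd],
                             OccupancySpec(mode="uniform", tau=2), "I")
        with pytest.raises(ValueError, match="weighted"):
            assemble_dataset(toy_model, space, [identity_pd],
                             OccupancySpec(mode="uniform", tau=1), "IV", snr=1.0)

    def test_datatype_i_bit_reproducible(self, toy_model, identity_pd):
        space = generate_state_space(toy_model, n=1, M=4)
        a = assemble_dataset(toy_model, space, [identity_pd], OccupancySpec(), "I")
        b = assemble_dataset(toy_model, space, [identity_pd], OccupancySpec(), "I")
        np.testing.assert_array_equal(a[0].images, b[0].images)

    def test_cumulative_path_is_strictly_monotone(self, ss1_stack):
        imgs = ss1_stack.images.astype(float)
        steps = [np.linalg.norm(imgs[i + 1] - imgs[i]) for i in range(19)]
        assert min(steps) > 0

    def test_defocus_drawn_per_image_within_range(self, toy_model, identity_pd):
        space = generate_state_space(toy_model, n=1, M=4)
        stacks = assemble_dataset(toy_model, space, [identity_pd],
                                  OccupancySpec(mode="uniform", tau=3), "III",
                                  snr=1.0, seed=5)
        df = stacks[0].meta["defocus_um"]
        assert df.between(0.5, 2.5).all()
        assert df.nunique() > 1


class TestProjectionDirections:
    def test_fibonacci_quaternions_unit_and_deterministic(self):
        a = fibonacci_hemisphere(16)
        b = fibonacci_hemisphere(16)
        for pa, pb in zip(a, b):
            assert pa.orientation == pb.orientation
            assert np.isclose(np.linalg.norm(pa.orientation), 1.0)

    def test_directions_cover_upper_hemisphere(self):
        for pd_ in fibonacci_hemisphere(32):
            # the rotation maps the viewing direction v to +z
            R = pd_.matrix()
            v = R.T @ np.array([0.0, 0.0, 1.0])
            assert v[2] > 0
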