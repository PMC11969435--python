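"""Chain metrics, layer thickness, volume fractions and brush scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pegshell.core import CenterConvention, Trajectory
from pegshell.polymer import (
    chain_metrics,
    daoud_cotton_fit,
    end_to_end,
    grafting_density,
    layer_thickness,
    peg_np_distance,
    radius_of_gyration,
    unwrap_chain,
    volume_fraction_profile,
)
from pegshell.profiles import RadialProfile, cumulative_fraction
from pegshell.synthetic import (
    generate_grafted_np,
    generate_power_law_profile,
    generate_water_bath,
)

from conftest import make_frame

CENTER0 = CenterConvention("fixed-atom-index", atom_index=0)


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_atoms_two_angstrom_apart(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(pos) == pytest.approx(1.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pairwise_sum_identity(self, seed):
        """Unweighted Rg² equals (1/2N²)ΣᵢΣⱼ|rᵢ−rⱼ|² exactly."""
        pos = np.random.default_rng(seed).uniform(-10, 10, size=(20, 3))
        diff = pos[:, None, :] - pos[None, :, :]
        pairwise = np.sqrt((diff**2).sum(-1).sum() / (2 * 20**2))
        assert radius_of_gyration(pos) == pytest.approx(pairwise, abs=1e-10)

    def test_mass_weighted_mode_shifts_center(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        rg_w = radius_of_gyration(pos, weights=np.array([3.0, 1.0]))
        # weighted center at 0.5; Rg² = (3·0.25 + 1·2.25)/4
        assert rg_w == pytest.approx(np.sqrt(0.75))


class TestEndToEnd:
    def test_straight_chain(self):
        pos = np.array([[0, 0, 1.5 * k] for k in range(11)], dtype=float)
        assert end_to_end(pos) == pytest.approx(15.0)

    def test_closed_loop_is_zero(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 0, 0]])
        assert end_to_end(pos) == 0.0

    def test_single_atom_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            end_to_end(np.zeros((1, 3)))

    def test_fjc_mean_square_matches_closed_form(self):
        # 100-bond freely-jointed chains, b = 1.5 Å: <h²> = N·b² = 225 Ų
        topo, traj, _ = generate_grafted_np(
            n_chains=50, n_bonds=100, bond_length=1.5, core_radius=10.0,
            n_frames=40, seed=42,
        )
        metrics = chain_metrics(traj, topo, CENTER0)
        h2 = metrics.h.ravel() ** 2
        se = h2.std(ddof=1) / np.sqrt(h2.size)
        assert abs(h2.mean() - 225.0) < 3 * se

    def test_fjc_h2_over_rg2_approaches_six(self):
        topo, traj, _ = generate_grafted_np(
            n_chains=50, n_bonds=200, bond_length=1.5, core_radius=10.0,
            n_frames=30, seed=7,
        )
        metrics = chain_metrics(traj, topo, CENTER0)
        ratio = (metrics.h**2).mean() / (metrics.rg**2).mean()
        assert ratio == pytest.approx(6.0, rel=0.05)


class TestPegNpDistance:
    def test_terminus_on_axis(self):
        pos = np.array([[10.0, 0, 0], [30.0, 0, 0]])
        assert peg_np_distance(pos, np.zeros(3)) == pytest.approx(30.0)

    def test_straight_grafted_chains_all_at_same_distance(self):
        topo, traj, meta = generate_grafted_np(
            n_chains=4, n_bonds=10, bond_length=1.5, core_radius=10.0,
            mode="straight", seed=3,
        )
        metrics = chain_metrics(traj, topo, CENTER0)
        np.testing.assert_allclose(metrics.d, meta["expected_d_straight"], rtol=1e-12)

    def test_ensemble_mean_equals_direct_average(self):
        topo, traj, _ = generate_grafted_np(n_chains=20, n_bonds=15, n_frames=3, seed=9)
        metrics = chain_metrics(traj, topo, CENTER0)
        acc = []
        for frame in traj:
            c = frame.positions[0]
            for cid in sorted(topo.chains):
                term = topo.chains[cid][-1]
                acc.append(np.linalg.norm(frame.positions[term] - c))
        assert metrics.d_mean == pytest.approx(np.mean(acc), abs=1e-12)


class TestUnwrap:
    def test_wrapped_chain_is_restitched(self):
        box = np.array([20.0, 20.0, 20.0])
        # chain walks out of the box in +x; stored wrapped
        true = np.array([[19.0, 5, 5], [20.5, 5, 5], [22.0, 5, 5]])
        wrapped = true % 20.0
        out = unwrap_chain(wrapped, box)
        np.testing.assert_allclose(out - out[0], true - true[0], atol=1e-12)

    def test_wrapped_chain_detected_when_not_unwrapping(self):
        topo, traj, _ = generate_grafted_np(n_chains=2, n_bonds=4, seed=1)
        box = traj[0].box[0]
        pos = traj[0].positions.copy()
        order = topo.chains[0]
        # displace the chain's tail by one full period, as a PBC writer would
        pos[order[2:]] += np.array([box, 0.0, 0.0])
        bad = Trajectory([make_frame(pos, box=box)])
        with pytest.raises(ValueError, match="unwrap"):
            chain_metrics(bad, topo, CENTER0, auto_unwrap=False)
        # the default path restitches it and reproduces the clean metrics
        clean = chain_metrics(traj, topo, CENTER0)
        fixed = chain_metrics(bad, topo, CENTER0)
        np.testing.assert_allclose(fixed.rg, clean.rg, atol=1e-9)


class TestLayerThickness:
    def _cdf_from_density(self, values, bin_width=0.1):
        edges = bin_width * np.arange(len(values) + 1)
        return cumulative_fraction(RadialProfile(edges, values, "number_density"))

    def test_uniform_shell_closed_form(self):
        mid = 0.1 * np.arange(250) + 0.05
        values = np.where((mid > 10) & (mid < 20), 1.0, 0.0)
        thk, r_min, r_max = layer_thickness(self._cdf_from_density(values))
        # CDF(r) = (r³−1000)/7000: crossings at 1350^(1/3), 7650^(1/3)
        assert r_min == pytest.approx(1350.0 ** (1 / 3), abs=0.01)
        assert r_max == pytest.approx(7650.0 ** (1 / 3), abs=0.01)
        assert thk == pytest.approx(8.65, abs=0.02)

    def test_uniform_ball_closed_form(self):
        mid = 0.1 * np.arange(250) + 0.05
        values = np.where(mid < 20, 1.0, 0.0)
        thk, _, _ = layer_thickness(self._cdf_from_density(values))
        expected = 20.0 * (0.95 ** (1 / 3) - 0.05 ** (1 / 3))  # ≈ 12.29
        assert thk == pytest.approx(expected, abs=0.02)

    def test_delta_shell_thickness_within_one_bin(self):
        values = np.zeros(300)
        values[152] = 4.0
        thk, _, _ = layer_thickness(self._cdf_from_density(values))
        assert thk <= 0.1 + 1e-9

    def test_amplitude_invariance(self, rng):
        values = rng.uniform(0, 1, size=200)
        t1 = layer_thickness(self._cdf_from_density(values))
        t2 = layer_thickness(self._cdf_from_density(12.5 * values))
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_wrong_profile_kind_rejected(self):
        prof = RadialProfile(0.1 * np.arange(11), np.ones(10), "rdf")
        with pytest.raises(ValueError, match="cumulative_fraction"):
            layer_thickness(prof)


class TestVolumeFraction:
    def test_single_water_molecule_shell_arithmetic(self):
        topo, traj, _ = generate_water_bath(box=40.0, density=0.0, seed=1)
        # hand-place one water molecule at 10.05 Å from the center marker
        from pegshell.core import AtomRecord, Frame, Topology

        atoms = [AtomRecord("X", mass=100.0),
                 AtomRecord("O", charge=-0.834, mass=15.999),
                 AtomRecord("H", charge=0.417, mass=1.008, is_heavy=False),
                 AtomRecord("H", charge=0.417, mass=1.008, is_heavy=False)]
        topo = Topology(atoms, bonds=[(1, 2), (1, 3)],
                        groups={"NP_CORE": [0], "WATER": [1, 2, 3]})
        c = np.array([20.0, 20, 20])
        pos = np.array([c, c + [10.05, 0, 0], c + [10.6, 0, 0], c + [10.6, 0.9, 0]])
        traj = Trajectory([Frame(pos, box=np.array([40.0] * 3))])
        profs = volume_fraction_profile(traj, topo, CENTER0)
        v_shell = 4 * np.pi / 3 * (10.1**3 - 10.0**3)
        k = 100
        assert profs["water"].values[k] == pytest.approx(30.0 / v_shell, rel=1e-9)
        assert profs["water"].values[k] == pytest.approx(0.236, abs=0.001)

    def test_empty_shells_are_zero(self):
        topo, traj, _ = generate_grafted_np(n_chains=2, n_bonds=3, core_radius=8.0,
                                            mode="straight", seed=2)
        profs = volume_fraction_profile(traj, topo, CENTER0)
        poly = profs["polymer"]
        assert np.all(poly.values[poly.r_mid < 7.9] == 0)

    def test_matches_membership_oracle_per_bin(self):
        topo, traj, _ = generate_grafted_np(n_chains=10, n_bonds=18, seed=11)
        profs = volume_fraction_profile(traj, topo, CENTER0)
        poly = profs["polymer"]
        center = traj[0].positions[0]
        peg = topo.groups["PEG"]
        r = np.linalg.norm(traj[0].positions[peg] - center, axis=1)
        for k in range(0, poly.values.size, 7):
            lo, hi = poly.bin_edges[k], poly.bin_edges[k + 1]
            expected = 20.0 * np.sum((r >= lo) & (r < hi)) / (
                4 * np.pi / 3 * (hi**3 - lo**3)
            )
            assert poly.values[k] == pytest.approx(expected, rel=1e-9, abs=1e-15)


class TestBrushFit:
    def test_noiseless_daoud_cotton_exponent(self):
        prof, _ = generate_power_law_profile(exponent=-4.0 / 3.0, r_lo=5, r_hi=30)
        fit = daoud_cotton_fit(prof, (6.0, 28.0))
        assert fit.exponent == pytest.approx(-4.0 / 3.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_prefactor_recovery(self):
        prof, _ = generate_power_law_profile(exponent=-1.0, amplitude=5.0,
                                             r_lo=5, r_hi=30)
        fit = daoud_cotton_fit(prof, (6.0, 28.0))
        assert fit.exponent == pytest.approx(-1.0, abs=1e-10)
        assert fit.prefactor == pytest.approx(5.0, rel=1e-8)

    def test_constant_profile_gives_zero_exponent(self):
        prof, _ = generate_power_law_profile(exponent=0.0, r_lo=5, r_hi=30)
        fit = daoud_cotton_fit(prof, (6.0, 28.0))
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("alpha", [-2.0, -4.0 / 3.0, -1.0, 0.0])
    def test_planted_exponent_recovery_with_noise(self, alpha):
        prof, _ = generate_power_law_profile(
            exponent=alpha, r_lo=10.0, r_hi=20.0, noise=0.01, seed=5
        )
        assert prof.values.size == 100
        fit = daoud_cotton_fit(prof, (10.0, 20.0))
        assert abs(fit.exponent - alpha) < 0.02

    def test_window_measured_from_surface(self):
        # φ(r) = (r − R0)^(−4/3) in distance-from-surface coordinates
        edges = 0.1 * np.arange(100, 401)  # absolute radii 10..40
        mid = 0.5 * (edges[:-1] + edges[1:])
        surface = 10.0
        values = (mid - surface) ** (-4.0 / 3.0)
        prof = RadialProfile(edges, values, "volume_fraction")
        fit = daoud_cotton_fit(prof, (8.0, 18.0), surface_radius=surface)
        assert fit.exponent == pytest.approx(-4.0 / 3.0, abs=1e-10)

    def test_nonpositive_bins_dropped_with_warning(self):
        prof, _ = generate_power_law_profile(exponent=-1.0, r_lo=5, r_hi=30)
        prof.values[20:30] = 0.0
        with pytest.warns(UserWarning, match="nonpositive"):
            fit = daoud_cotton_fit(prof, (6.0, 28.0))
        assert fit.exponent == pytest.approx(-1.0, abs=1e-6)

    def test_too_few_bins_rejected(self):
        prof, _ = generate_power_law_profile(exponent=-1.0, r_lo=5, r_hi=30)
        with pytest.raises(ValueError, match=">= 5"):
            daoud_cotton_fit(prof, (6.0, 6.3))


class TestGraftingDensity:
    def test_dense_coating_on_five_nm_core(self):
        area = 4 * np.pi * 2.5**2  # nm²
        assert grafting_density(360, area) == pytest.approx(4.6, abs=0.05)

    def test_zero_chains(self):
        assert grafting_density(0, 10.0) == 0.0

    def test_implied_area_inversion(self):
        # 50 chains at 2.3 chains/nm² imply ~21.7 nm² of effective surface
        area = 50 / 2.3
        assert grafting_density(50, area) == pytest.approx(2.3)
        assert area == pytest.approx(21.7, abs=0.05)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            grafting_density(10, 0.0)
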