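import numpy as np
import pytest

from helpers import flux_oracle
from pore_annotate.hydration import (
    DensityProfile,
    PoreCylinder,
    boltzmann_invert,
    count_permeation_events,
    density_profile,
    hydration_numbers,
    occupancy_and_dewetting,
    water_axial_tracks,
)
from pore_annotate.structure_io import AtomSet, Trajectory
from pore_annotate.synthetic import (
    PotentialSpec,
    random_walk_tracks,
    sample_water_trajectory,
)
from pore_annotate.units import thermal_energy

CYL = PoreCylinder(radius=8.0, z_lo=-20.0, z_hi=20.0)


def _water_traj(positions):
    """Trajectory of oxygen-only waters from an (F, N, 3) array."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[1]
    topo = AtomSet(
        serial=np.arange(1, n + 1), name=np.full(n, "O"),
        resname=np.full(n, "HOH"), resid=np.arange(1, n + 1),
        chain=np.full(n, "W"), element=np.full(n, "O"), coords=positions[0],
    )
    times = np.arange(positions.shape[0], dtype=float)
    return Trajectory(topology=topo, frames=positions, times=times, timestep=1.0)


def test_stationary_water_inside_is_tracked_every_frame():
    pos = np.tile([[1.0, 0.0, 3.0]], (5, 1, 1))
    tracks = water_axial_tracks(_water_traj(pos), "name O", CYL)
    np.testing.assert_allclose(tracks.z[:, 0], 3.0)
    assert tracks.in_pore.all()


def test_water_outside_radius_is_masked():
    pos = np.tile([[12.0, 0.0, 0.0]], (4, 1, 1))
    tracks = water_axial_tracks(_water_traj(pos), "name O", CYL)
    assert not tracks.in_pore.any()


def test_in_pore_set_matches_brute_force_cylinder_test():
    rng = np.random.default_rng(0)
    pos = rng.uniform(-25, 25, size=(20, 100, 3))
    tracks = water_axial_tracks(_water_traj(pos), "name O", CYL)
    expected = (
        (np.sqrt(pos[:, :, 0] ** 2 + pos[:, :, 1] ** 2) <= CYL.radius)
        & (pos[:, :, 2] >= CYL.z_lo)
        & (pos[:, :, 2] <= CYL.z_hi)
    )
    np.testing.assert_array_equal(tracks.in_pore, expected)


def test_empty_selection_errors():
    pos = np.zeros((2, 1, 3))
    with pytest.raises(ValueError, match="no atoms"):
        water_axial_tracks(_water_traj(pos), "resname XXX", CYL)


# ---------------------------------------------------------------------------
# occupancy / dewetting


@pytest.mark.parametrize(
    "z_pattern, expected",
    [
        (np.zeros(10), 0.0),  # always in the gate
        (np.full(10, 15.0), 1.0),  # never in the gate
        (np.where(np.arange(10) % 2 == 0, 0.0, 15.0), 0.5),  # alternating
    ],
)
def test_dewetted_fraction(z_pattern, expected):
    pos = np.zeros((10, 1, 3))
    pos[:, 0, 2] = z_pattern
    tracks = water_axial_tracks(_water_traj(pos), "name O", CYL)
    _, dewetted = occupancy_and_dewetting(tracks, (-5.0, 5.0))
    assert dewetted == expected


def test_dewetted_fraction_invariant_under_frame_permutation():
    rng = np.random.default_rng(3)
    pos = rng.uniform(-20, 20, size=(50, 5, 3))
    tracks = water_axial_tracks(_water_traj(pos), "name O", CYL)
    _, a = occupancy_and_dewetting(tracks, (-5, 5))
    perm = rng.permutation(50)
    tracks_p = water_axial_tracks(_water_traj(pos[perm]), "name O", CYL)
    _, b = occupancy_and_dewetting(tracks_p, (-5, 5))
    assert a == b


# ---------------------------------------------------------------------------
# permeation events


def test_single_monotone_traverse_counts_one_up():
    z = np.linspace(-15, 15, 30).reshape(-1, 1)
    res = count_permeation_events(z, -10.0, 10.0)
    assert (res.events_up, res.events_down) == (1, 0)
    assert res.event_log[0][3] == "up"


def test_oscillation_across_one_gate_counts_nothing():
    z = np.array([-12, -8, -12, -8, -12, -8, -12], dtype=float).reshape(-1, 1)
    res = count_permeation_events(z, -10.0, 10.0)
    assert res.total == 0


def test_random_walks_match_state_machine_oracle():
    z = random_walk_tracks(n_particles=300, n_frames=150, seed=9)
    res = count_permeation_events(z, -10.0, 10.0)
    up, down = flux_oracle(z, -10.0, 10.0)
    assert (res.events_up, res.events_down) == (up, down)
    assert res.total > 0  # the fixture does produce traversals


def test_time_reversal_swaps_directions():
    z = random_walk_tracks(n_particles=200, n_frames=120, seed=4)
    fwd = count_permeation_events(z, -10.0, 10.0)
    rev = count_permeation_events(z[::-1], -10.0, 10.0)
    assert (rev.events_up, rev.events_down) == (fwd.events_down, fwd.events_up)
    assert rev.total == fwd.total


def test_rate_is_total_over_duration():
    z = np.linspace(-15, 15, 11).reshape(-1, 1)
    res = count_permeation_events(z, -10.0, 10.0, times=np.arange(11) * 0.5)
    assert res.rate == pytest.approx(res.total / 5.0)


def test_inverted_gates_error():
    with pytest.raises(ValueError, match="z_lo"):
        count_permeation_events(np.zeros((3, 1)), 5.0, -5.0)


# ---------------------------------------------------------------------------
# density and Boltzmann inversion


def test_density_bin_sum_conservation():
    rng = np.random.default_rng(1)
    pos = rng.uniform(-22, 22, size=(40, 60, 3))
    tracks = water_axial_tracks(_water_traj(pos), "name O", CYL)
    dens = density_profile(tracks, bin_width=1.0)
    total_obs = int(tracks.in_pore.sum())
    assert int(round(dens.counts.sum() * dens.n_frames)) == total_obs


def test_flat_density_inverts_to_zero_energy():
    dens = DensityProfile(
        bin_edges=np.arange(11.0), counts=np.full(10, 4.2), n_frames=100, bin_width=1.0
    )
    fe = boltzmann_invert(dens, temperature=310.0)
    np.testing.assert_allclose(fe.energy, 0.0, atol=1e-12)
    assert not fe.lower_bound_mask.any()


def test_dip_to_hundredth_of_bulk_gives_closed_form_barrier():
    counts = np.full(20, 1.0)
    counts[10] = 0.01
    dens = DensityProfile(
        bin_edges=np.arange(21.0), counts=counts, n_frames=1000, bin_width=1.0
    )
    fe = boltzmann_invert(dens, temperature=310.0)
    kt = thermal_energy(310.0)
    assert kt == pytest.approx(2.577, abs=0.001)
    assert fe.energy[10] == pytest.approx(-kt * np.log(0.01), abs=1e-9)
    assert fe.energy[10] == pytest.approx(11.9, abs=0.05)


def test_inversion_roundtrip_recovers_density_up_to_constant():
    rng = np.random.default_rng(2)
    counts = rng.uniform(0.5, 3.0, size=15)
    dens = DensityProfile(
        bin_edges=np.arange(16.0), counts=counts, n_frames=50, bin_width=1.0
    )
    fe = boltzmann_invert(dens, temperature=310.0)
    kt = thermal_energy(310.0)
    recovered = np.exp(-fe.energy / kt)
    ratio = counts / recovered
    np.testing.assert_allclose(ratio, ratio[0], rtol=1e-10)


def test_empty_bins_get_lower_bound_and_mask():
    counts = np.full(12, 2.0)
    counts[5:7] = 0.0
    dens = DensityProfile(
        bin_edges=np.arange(13.0), counts=counts, n_frames=200, bin_width=1.0
    )
    with pytest.warns(UserWarning, match="lower bound"):
        fe = boltzmann_invert(dens, temperature=310.0)
    kt = thermal_energy(310.0)
    expected_bound = -kt * np.log((1 / 200) / 2.0)
    assert fe.lower_bound_mask[5] and fe.lower_bound_mask[6]
    np.testing.assert_allclose(fe.energy[5:7], expected_bound)
    assert np.all(np.isfinite(fe.energy))


def test_all_zero_density_errors():
    dens = DensityProfile(
        bin_edges=np.arange(4.0), counts=np.zeros(3), n_frames=10, bin_width=1.0
    )
    with pytest.raises(ValueError):
        boltzmann_invert(dens)


def test_metropolis_sampled_density_matches_target():
    """Sampler is the oracle: n(z) ∝ exp(−U/kT) within sampling error."""
    barrier = 5.0
    U = PotentialSpec(kind="gaussian_barrier", height=barrier, width=3.0)
    traj = sample_water_trajectory(U, CYL, n_waters=150, n_frames=2000, seed=12)
    tracks = water_axial_tracks(traj, "name O", CYL)
    fe = boltzmann_invert(density_profile(tracks, 1.0), temperature=310.0)
    assert fe.barrier((-4, 4)) == pytest.approx(barrier, abs=0.5)


# ---------------------------------------------------------------------------
# hydration shells


def _ion_plus_waters(water_coords):
    coords = np.vstack([[0.0, 0.0, 0.0], water_coords])
    n = len(coords)
    topo = AtomSet(
        serial=np.arange(1, n + 1),
        name=np.array(["NA"] + ["O"] * (n - 1)),
        resname=np.array(["NA"] + ["HOH"] * (n - 1)),
        resid=np.arange(1, n + 1),
        chain=np.array(["I"] + ["W"] * (n - 1)),
        element=np.array(["Na"] + ["O"] * (n - 1)),
        coords=coords,
    )
    return Trajectory(
        topology=topo, frames=coords[None], times=np.array([0.0]), timestep=1.0
    )


def test_six_waters_at_2p3_form_the_first_shell():
    dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])
    traj = _ion_plus_waters(2.3 * dirs)
    shells = hydration_numbers(traj, "name NA", "name O", 3.0, 5.5)
    assert shells[0, 0] == 6
    assert shells[0, 1] == 0


def test_no_waters_within_cutoffs_gives_zero_zero():
    traj = _ion_plus_waters(np.array([[20.0, 0.0, 0.0]]))
    shells = hydration_numbers(traj, "name NA", "name O", 3.2, 5.5)
    assert tuple(shells[0]) == (0, 0)


def test_random_cloud_matches_brute_force_count():
    rng = np.random.default_rng(8)
    waters = rng.uniform(-8, 8, size=(200, 3))
    traj = _ion_plus_waters(waters)
    shells = hydration_numbers(traj, "name NA", "name O", 3.2, 5.5)
    d = np.linalg.norm(waters, axis=1)
    assert shells[0, 0] == int(np.sum(d <= 3.2))
    assert shells[0, 1] == int(np.sum((d > 3.2) & (d <= 5.5)))


def test_ion_selection_must_be_single_atom():
    traj = _ion_plus_waters(np.array([[3.0, 0.0, 0.0], [0.0, 3.0, 0.0]]))
    with pytest.raises(ValueError, match="exactly one"):
        hydration_numbers(traj, "name O", "name O", 3.2, 5.5)
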