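"""Synthetic fixtures with known ground truth for every analysis stage.

Model pores (cylinder / hourglass walls of pseudo-atoms) exercise the
probe-sphere profiler against closed-form radii; Metropolis-sampled water
coordinates on prescribed 1-D potentials exercise the density and
Boltzmann-inversion analyses; biased Metropolis windows exercise WHAM; and
charged parallel slabs exercise the Poisson integrator against the
capacitor formula ΔV = σd/ε0.

Only stationary distributions matter for the analyses under test, so
Metropolis sampling (not Langevin dynamics) is used; traversal fixtures for
the event detector use bounded-step random walks instead, which do produce
genuine crossings.  Every generator is a pure function of its arguments and
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hydration import PoreCylinder
from .pmf_wham import UmbrellaDataset, UmbrellaWindow
from .structure_io import AtomSet, Trajectory
from .units import bias_energy, thermal_energy


@dataclass
class PotentialSpec:
    """1-D potential U(z) in kJ/mol along the pore axis.

    kinds: ``flat``; ``harmonic`` (½·κ·(z−center)², κ in kJ/mol/Ų);
    ``gaussian_barrier`` (height·exp(−(z−center)²/2σ²)); ``double_well``
    (height·[((z−center)/width)² − 1]²).
    """

    kind: str = "flat"
    height: float = 0.0  # kJ/mol (κ for harmonic)
    width: float = 3.0  # Å (σ for gaussian_barrier)
    center: float = 0.0  # Å

    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        if self.kind == "flat":
            return np.zeros_like(z)
        if self.kind == "harmonic":
            return 0.5 * self.height * (z - self.center) ** 2
        if self.kind == "gaussian_barrier":
            return self.height * np.exp(-((z - self.center) ** 2) / (2 * self.width**2))
        if self.kind == "double_well":
            u = (z - self.center) / self.width
            return self.height * (u**2 - 1) ** 2
        raise ValueError(f"unknown potential kind {self.kind!r}")


# ---------------------------------------------------------------------------
# model pore walls


def _wall_atoms(radius_of_z, length: float, atom_spacing: float, vdw: float) -> AtomSet:
    if atom_spacing <= 0 or length <= 0 or vdw <= 0:
        raise ValueError("length, atom_spacing and vdw must be positive")
    n_rings = int(round(length / atom_spacing)) + 1
    zs = np.linspace(-length / 2, length / 2, n_rings)
    coords = []
    for z in zs:
        r = radius_of_z(z)
        if r <= 0:
            raise ValueError("wall radius must stay positive")
        n_az = max(6, int(math.ceil(2 * math.pi * r / atom_spacing)))
        phi = 2 * math.pi * np.arange(n_az) / n_az
        ring = np.column_stack([r * np.cos(phi), r * np.sin(phi), np.full(n_az, z)])
        coords.append(ring)
    ring_sizes = [len(ring) for ring in coords]
    coords = np.vstack(coords)
    n = len(coords)
    # one residue per ring, leucine-like naming so gate detection sees an
    # apolar lining
    resid = np.repeat(np.arange(1, len(zs) + 1), ring_sizes)
    return AtomSet(
        serial=np.arange(1, n + 1),
        name=np.full(n, "CW"),
        resname=np.full(n, "LEU"),
        resid=resid,
        chain=np.full(n, "A"),
        element=np.full(n, "C"),
        coords=coords,
        vdw_radius=np.full(n, float(vdw)),
        provenance="synthetic",
    )


def make_cylinder_pore(
    wall_radius: float = 10.0,
    length: float = 30.0,
    atom_spacing: float = 1.0,
    vdw: float = 1.85,
) -> AtomSet:
    """Cylindrical pseudo-atom pore; expected pore radius = wall − vdw.

    With spacing s the lattice gaps perturb the inscribed radius by at most
    ≈ s²/(8·wall_radius); the defaults keep that below 0.05 Å.
    """
    if wall_radius <= vdw:
        raise ValueError("wall radius must exceed the vdW radius")
    return _wall_atoms(lambda z: wall_radius, length, atom_spacing, vdw)


def make_hourglass_pore(
    mouth_radius: float = 10.0,
    waist_radius: float = 4.0,
    waist_z: float = 0.0,
    waist_width: float = 5.0,
    length: float = 30.0,
    atom_spacing: float = 1.0,
    vdw: float = 1.85,
) -> AtomSet:
    """Hourglass pore with a smooth (Gaussian) constriction at ``waist_z``.

    Expected minimum pore radius = waist_radius − vdw, attained at waist_z.
    With waist equal to mouth this degenerates to the cylinder.
    """
    if waist_radius > mouth_radius:
        raise ValueError("waist must not exceed the mouth radius")
    if waist_radius <= vdw:
        raise ValueError("waist radius must exceed the vdW radius")

    def radius_of_z(z):
        return mouth_radius - (mouth_radius - waist_radius) * math.exp(
            -((z - waist_z) ** 2) / (2 * waist_width**2)
        )

    return _wall_atoms(radius_of_z, length, atom_spacing, vdw)


# ---------------------------------------------------------------------------
# Metropolis samplers


def _metropolis_chain(u, z0, n_steps, kt, step, rng, z_lo, z_hi, thin=1):
    """Vectorised Metropolis chains over a batch of walkers on [z_lo, z_hi]."""
    z = np.array(z0, dtype=float)
    out = np.empty((n_steps // thin, len(z)))
    e = u(z)
    accepted = 0
    total = 0
    k = 0
    for step_i in range(n_steps):
        cand = z + rng.uniform(-step, step, size=len(z))
        inside = (cand >= z_lo) & (cand <= z_hi)
        e_cand = np.where(inside, u(np.clip(cand, z_lo, z_hi)), np.inf)
        accept = inside & (rng.random(len(z)) < np.exp(np.clip((e - e_cand) / kt, -700, 0)))
        z = np.where(accept, cand, z)
        e = np.where(accept, e_cand, e)
        accepted += int(accept.sum())
        total += len(z)
        if (step_i + 1) % thin == 0:
            out[k] = z
            k += 1
    if total and accepted / total < 0.01:
        raise RuntimeError(
            "Metropolis acceptance collapsed (<1%); reduce the proposal step "
            "or lower the barrier"
        )
    return out


def sample_water_trajectory(
    potential: PotentialSpec,
    cyl: PoreCylinder | None = None,
    n_waters: int = 100,
    n_frames: int = 1000,
    temperature: float = 310.0,
    seed: int = 0,
    step: float = 4.0,
    burn_in: int = 500,
) -> Trajectory:
    """Equilibrium water pseudo-trajectory with density ∝ exp(−U(z)/kT).

    Each water is an independent Metropolis chain along z (bounded proposal
    steps preserve particle identity continuity); x,y perform a reflected
    random walk inside the cylinder.  The first ``burn_in`` sweeps are
    discarded.  Oxygen-only waters (united-atom style), 1 ns timestep.
    """
    cyl = cyl or PoreCylinder()
    kt = thermal_energy(temperature)
    rng = np.random.default_rng(seed)
    z0 = rng.uniform(cyl.z_lo, cyl.z_hi, size=n_waters)
    zs = _metropolis_chain(
        potential, z0, burn_in + n_frames, kt, step, rng, cyl.z_lo, cyl.z_hi
    )[burn_in:]
    # in-plane reflected random walk
    xy = np.empty((n_frames, n_waters, 2))
    r0 = cyl.radius * np.sqrt(rng.random(n_waters))
    phi0 = rng.uniform(0, 2 * math.pi, n_waters)
    cur = np.column_stack([r0 * np.cos(phi0), r0 * np.sin(phi0)])
    for f in range(n_frames):
        prop = cur + rng.normal(scale=0.5, size=cur.shape)
        rad = np.linalg.norm(prop, axis=1)
        outside = rad > cyl.radius
        prop[outside] = cur[outside]
        cur = prop
        xy[f] = cur
    frames = np.empty((n_frames, n_waters, 3))
    frames[:, :, 0] = xy[:, :, 0] + cyl.center[0]
    frames[:, :, 1] = xy[:, :, 1] + cyl.center[1]
    frames[:, :, 2] = zs + cyl.center[2]
    n = n_waters
    topo = AtomSet(
        serial=np.arange(1, n + 1),
        name=np.full(n, "O"),
        resname=np.full(n, "HOH"),
        resid=np.arange(1, n + 1),
        chain=np.full(n, "W"),
        element=np.full(n, "O"),
        coords=frames[0],
        vdw_radius=np.full(n, 1.4),
        provenance="synthetic",
    )
    times = np.arange(n_frames, dtype=float)
    return Trajectory(topology=topo, frames=frames, times=times, timestep=1.0)


def make_umbrella_dataset(
    potential: PotentialSpec,
    centers: np.ndarray | None = None,
    force_constant: float = 1000.0,
    n_samples: int = 2000,
    temperature: float = 310.0,
    seed: int = 0,
    step: float = 1.2,
    burn_in: int = 500,
    thin: int = 5,
    timestep: float = 0.001,
) -> UmbrellaDataset:
    """Biased window samples from exp(−(U + ½k(z−c)²)/kT) per window.

    Defaults follow the standard protocol for single-particle pore PMFs:
    1 Å window spacing and k = 1000 kJ mol⁻¹ nm⁻².  ``timestep`` (ns per
    sample) only populates the per-sample times used by convergence
    analysis.
    """
    if centers is None:
        centers = np.arange(-10.0, 10.0 + 0.5, 1.0)
    centers = np.asarray(centers, dtype=float)
    kt = thermal_energy(temperature)
    rng = np.random.default_rng(seed)
    windows = []
    lo, hi = centers.min() - 5.0, centers.max() + 5.0
    for c in centers:
        def u_tot(z, c=c):
            return potential(z) + bias_energy(z, c, force_constant)

        chain = _metropolis_chain(
            u_tot,
            np.full(1, c),
            burn_in + n_samples * thin,
            kt,
            step,
            rng,
            lo,
            hi,
            thin=thin,
        )[burn_in // thin:, 0][:n_samples]
        times = np.arange(n_samples) * timestep
        windows.append(
            UmbrellaWindow(center=float(c), force_constant=force_constant, samples=chain, times=times)
        )
    return UmbrellaDataset(windows=windows, temperature=temperature)


# ---------------------------------------------------------------------------
# charged slabs


def make_charged_slabs(
    sigma: float = 1e-3,
    separation: float = 40.0,
    box: tuple = (50.0, 50.0, 100.0),
    n_side: int = 10,
) -> tuple:
    """Two oppositely charged planar pseudo-atom sheets (a parallel-plate
    capacitor) centred in the box: the Poisson-integrator oracle.

    ``sigma`` is the surface charge density in e/Å²; the sheet at the lower
    z carries +σ.  Returns ``(AtomSet, charges)`` with the frame net-neutral
    by construction; analytic ΔV = σ·d/ε0.
    """
    box = np.asarray(box, dtype=float)
    if separation <= 0 or separation >= box[2]:
        raise ValueError("separation must lie inside the box")
    xs = (np.arange(n_side) + 0.5) * box[0] / n_side
    ys = (np.arange(n_side) + 0.5) * box[1] / n_side
    gx, gy = np.meshgrid(xs, ys)
    n_per = n_side * n_side
    z1 = box[2] / 2 - separation / 2
    z2 = box[2] / 2 + separation / 2
    coords = np.vstack(
        [
            np.column_stack([gx.ravel(), gy.ravel(), np.full(n_per, z1)]),
            np.column_stack([gx.ravel(), gy.ravel(), np.full(n_per, z2)]),
        ]
    )
    q_per = sigma * box[0] * box[1] / n_per
    charges = np.concatenate([np.full(n_per, q_per), np.full(n_per, -q_per)])
    n = len(coords)
    atoms = AtomSet(
        serial=np.arange(1, n + 1),
        name=np.full(n, "Q"),
        resname=np.full(n, "SLB"),
        resid=np.repeat([1, 2], n_per),
        chain=np.full(n, "S"),
        element=np.full(n, "X"),
        coords=coords,
        vdw_radius=np.full(n, 1.0),
        box=box,
        provenance="synthetic",
    )
    assert abs(charges.sum()) < 1e-12 * max(1.0, abs(q_per)) * n
    return atoms, charges


def random_walk_tracks(
    n_particles: int = 100,
    n_frames: int = 200,
    z_lo: float = -10.0,
    z_hi: float = 10.0,
    step: float = 3.0,
    seed: int = 0,
) -> np.ndarray:
    """Unbounded 1-D random walks spanning the gate region.

    Fixture for the traversal detector: genuine crossings, boundary jitter,
    and returns.  Shape (n_frames, n_particles).
    """
    rng = np.random.default_rng(seed)
    start = rng.uniform(z_lo - 5 * step, z_hi + 5 * step, size=n_particles)
    steps = rng.normal(scale=step, size=(n_frames - 1, n_particles))
    return np.vstack([start[None, :], start[None, :] + np.cumsum(steps, axis=0)])
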