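"""Pore-hydration analysis: water tracks, dewetting, flux, density and
Boltzmann-inversion free-energy profiles, and ion hydration shells.

The presence of water in a narrow hydrophobic pore is a proxy for ion
permeability: a pore that dewets (spends most of the time empty at its
constriction) is functionally closed regardless of its steric radius.  The
equilibrium water density n(z) along the pore axis converts to a free-energy
profile through the Boltzmann relation

    E(z) = −kT ln n(z) + kT ln C

with the constant C fixed by requiring E = 0 in the bulk-like regions at the
two ends of the pore.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structure_io import AtomSet, Trajectory
from .units import thermal_energy


@dataclass
class PoreCylinder:
    """Cylindrical pore region: axis through ``center``, mouths at z_lo/z_hi.

    z is measured along ``axis`` relative to ``center``.
    """

    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 10.0
    z_lo: float = -20.0
    z_hi: float = 20.0

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")
        if not self.z_lo < self.z_hi:
            raise ValueError("z_lo must be < z_hi")


@dataclass
class WaterTracks:
    """Per-particle axial coordinates over time with in-pore masks."""

    z: np.ndarray  # (n_frames, n_particles), axial coordinate, unwrapped
    in_pore: np.ndarray  # (n_frames, n_particles) bool
    ids: np.ndarray  # particle identifiers (topology serials)
    times: np.ndarray  # ns
    cylinder: PoreCylinder

    @property
    def n_frames(self) -> int:
        return self.z.shape[0]


@dataclass
class DensityProfile:
    """Binned particle counts: expected in-pore particles per bin per frame."""

    bin_edges: np.ndarray
    counts: np.ndarray  # mean count per frame, length len(bin_edges)-1
    n_frames: int
    bin_width: float

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class FreeEnergyProfile:
    """E(z) in kJ/mol from Boltzmann inversion; empty bins carry lower bounds."""

    z: np.ndarray
    energy: np.ndarray
    temperature: float
    reference: str
    lower_bound_mask: np.ndarray

    def barrier(self, z_window: tuple | None = None) -> float:
        """Peak height (kJ/mol) relative to the zero-set bulk reference."""
        if z_window is None:
            mask = np.ones(len(self.z), dtype=bool)
        else:
            mask = (self.z >= z_window[0]) & (self.z <= z_window[1])
        return float(np.max(self.energy[mask]))


@dataclass
class FluxResult:
    """Completed traversals through the pore, by direction."""

    events_up: int
    events_down: int
    duration: float  # ns
    event_log: list  # (particle id, start frame, end frame, direction)

    @property
    def total(self) -> int:
        return self.events_up + self.events_down

    @property
    def rate(self) -> float:
        """Total bidirectional traversal rate in ns⁻¹."""
        return self.total / self.duration if self.duration > 0 else 0.0


# ---------------------------------------------------------------------------


def _axial_coords(traj: Trajectory, indices: np.ndarray, cyl: PoreCylinder):
    """Axial (z) and radial distances of selected atoms, all frames.

    Radial distances apply the minimum-image convention when the topology
    carries a box; z is unwrapped per particle between consecutive frames so
    traversal detection is insensitive to periodic jumps.
    """
    rel = traj.frames[:, indices, :] - cyl.center  # (F, N, 3)
    box = traj.topology.box
    if box is not None:
        rel = rel - np.round(rel / box) * box
    z = rel @ cyl.axis
    radial_vec = rel - z[..., None] * cyl.axis
    radial = np.linalg.norm(radial_vec, axis=-1)
    if box is not None and len(z) > 1:
        # unwrap along the axis: undo jumps larger than half the axial box span
        span = float(abs(box @ cyl.axis))
        if span > 0:
            dz = np.diff(z, axis=0)
            shift = -np.cumsum(np.round(dz / span), axis=0) * span
            z[1:] += shift
    return z, radial


def water_axial_tracks(
    traj: Trajectory, waters: str | np.ndarray, cyl: PoreCylinder
) -> WaterTracks:
    """Track water axial positions through the pore cylinder.

    ``waters`` selects one reference atom per water (typically the oxygen),
    either as a selection expression or an index array.  Identities are
    preserved across frames.
    """
    if isinstance(waters, str):
        from .structure_io import selection_mask

        mask = selection_mask(traj.topology, waters)
        indices = np.nonzero(mask)[0]
    else:
        indices = np.asarray(waters, dtype=int)
    if len(indices) == 0:
        raise ValueError("water selection matched no atoms")
    z, radial = _axial_coords(traj, indices, cyl)
    in_pore = (radial <= cyl.radius) & (z >= cyl.z_lo) & (z <= cyl.z_hi)
    return WaterTracks(
        z=z,
        in_pore=in_pore,
        ids=traj.topology.serial[indices],
        times=traj.times,
        cylinder=cyl,
    )


def occupancy_and_dewetting(tracks: WaterTracks, gate: tuple) -> tuple:
    """Per-frame water count in the gate slab and the dewetted fraction.

    The dewetted fraction is the fraction of frames in which the slab
    contains no water at all — the vapor-state signature of a hydrophobic
    gate.
    """
    z_min, z_max = gate
    in_gate = tracks.in_pore & (tracks.z >= z_min) & (tracks.z <= z_max)
    occupancy = in_gate.sum(axis=1)
    dewetted_fraction = float(np.mean(occupancy == 0))
    return occupancy, dewetted_fraction


def count_permeation_events(
    tracks: WaterTracks | np.ndarray,
    z_lo: float,
    z_hi: float,
    times: np.ndarray | None = None,
    ids: np.ndarray | None = None,
) -> FluxResult:
    """Count completed traversals between two gate planes (with hysteresis).

    An event requires entering from beyond one plane and exiting beyond the
    other without returning past the entry plane in between; oscillation
    across a single plane therefore never counts.  Both directions are
    counted and logged.
    """
    if z_lo >= z_hi:
        raise ValueError("z_lo must be < z_hi")
    if isinstance(tracks, WaterTracks):
        z = tracks.z
        times = tracks.times
        ids = tracks.ids
    else:
        z = np.asarray(tracks, dtype=float)
        if times is None:
            times = np.arange(z.shape[0], dtype=float)
        if ids is None:
            ids = np.arange(z.shape[1])
    # region code per sample: 0 below z_lo, 1 between, 2 above z_hi
    region = np.where(z < z_lo, 0, np.where(z > z_hi, 2, 1))
    events_up = 0
    events_down = 0
    log = []
    for p in range(z.shape[1]):
        outside = np.nonzero(region[:, p] != 1)[0]
        if len(outside) < 2:
            continue
        codes = region[outside, p]
        change = np.nonzero(np.diff(codes) != 0)[0]
        for c in change:
            start_frame = int(outside[c])
            end_frame = int(outside[c + 1])
            if codes[c] == 0 and codes[c + 1] == 2:
                events_up += 1
                log.append((int(ids[p]), start_frame, end_frame, "up"))
            elif codes[c] == 2 and codes[c + 1] == 0:
                events_down += 1
                log.append((int(ids[p]), start_frame, end_frame, "down"))
    duration = float(times[-1] - times[0]) if len(times) > 1 else 0.0
    return FluxResult(
        events_up=events_up, events_down=events_down, duration=duration, event_log=log
    )


def density_profile(tracks: WaterTracks, bin_width: float = 1.0) -> DensityProfile:
    """Axial density n(z): mean in-pore particle count per bin per frame."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    cyl = tracks.cylinder
    n_bins = max(1, int(round((cyl.z_hi - cyl.z_lo) / bin_width)))
    edges = np.linspace(cyl.z_lo, cyl.z_hi, n_bins + 1)
    zs = tracks.z[tracks.in_pore]
    hist, _ = np.histogram(zs, bins=edges)
    return DensityProfile(
        bin_edges=edges,
        counts=hist / tracks.n_frames,
        n_frames=tracks.n_frames,
        bin_width=float(edges[1] - edges[0]),
    )


def boltzmann_invert(
    density: DensityProfile,
    temperature: float = 310.0,
    n_reference_bins: int = 3,
) -> FreeEnergyProfile:
    """Free-energy profile from an axial density by Boltzmann inversion.

    E(z) = −kT ln n(z) + kT ln C with C the mean density over the outermost
    ``n_reference_bins`` bins at each pore end, so E averages to zero in
    bulk.  Bins never visited give a finite *lower bound*
    E ≥ −kT ln(1/n_frames) + kT ln C, flagged in ``lower_bound_mask`` — a
    closed pore then serialises cleanly instead of producing infinities.
    """
    counts = density.counts
    if np.all(counts == 0):
        raise ValueError("density is identically zero; nothing to invert")
    ref = np.concatenate([counts[:n_reference_bins], counts[-n_reference_bins:]])
    if np.all(ref == 0):
        raise ValueError("reference (end) bins are empty; cannot set the zero")
    c = float(np.mean(ref))
    kt = thermal_energy(temperature)
    floor = 1.0 / density.n_frames
    lower_bound = counts <= 0
    if lower_bound.any():
        warnings.warn(
            f"{int(lower_bound.sum())} empty bins: reporting free-energy lower bounds",
            stacklevel=2,
        )
    eff = np.where(lower_bound, floor, counts)
    energy = -kt * np.log(eff / c)
    return FreeEnergyProfile(
        z=density.bin_centers,
        energy=energy,
        temperature=temperature,
        reference=f"mean of outermost {n_reference_bins} bins at each end set to zero",
        lower_bound_mask=lower_bound,
    )


def hydration_numbers(
    traj: Trajectory,
    ion: str | np.ndarray,
    waters: str | np.ndarray = "resname HOH SOL and name O OW",
    first_cutoff: float = 3.2,
    second_cutoff: float = 5.5,
) -> np.ndarray:
    """Per-frame first- and second-shell water counts around a single ion.

    Returns an (n_frames, 2) array: waters with O within ``first_cutoff`` of
    the ion, and within (first_cutoff, second_cutoff].  Defaults suit Na⁺;
    for Cl⁻ use ≈3.9/6.2 Å.  Minimum-image distances are used when a box is
    present.
    """
    if not 0 < first_cutoff < second_cutoff:
        raise ValueError("cutoffs must satisfy 0 < first < second")
    from .structure_io import selection_mask

    def _indices(sel):
        if isinstance(sel, str):
            return np.nonzero(selection_mask(traj.topology, sel))[0]
        return np.asarray(sel, dtype=int)

    ion_idx = _indices(ion)
    if len(ion_idx) != 1:
        raise ValueError(f"ion selection must match exactly one atom, got {len(ion_idx)}")
    wat_idx = _indices(waters)
    rel = traj.frames[:, wat_idx, :] - traj.frames[:, ion_idx, :]
    box = traj.topology.box
    if box is not None:
        rel = rel - np.round(rel / box) * box
    d = np.linalg.norm(rel, axis=-1)
    first = (d <= first_cutoff).sum(axis=1)
    second = ((d > first_cutoff) & (d <= second_cutoff)).sum(axis=1)
    return np.column_stack([first, second])
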