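"""Computational-electrophysiology post-analysis.

In a double-bilayer (compartmentalised) simulation an ion imbalance between
the two aqueous compartments sustains a transmembrane potential.  This
module computes the slab charge-density profile ρ(z), integrates the 1-D
Poisson equation twice,

    φ(z) = −(1/ε0 εr) ∫₀^z ∫₀^{z'} ρ(z'') dz'' dz',

with φ = dφ/dz = 0 at the lower box edge (the g_potential convention), reads
ΔV between the two bulk compartments, performs per-frame compartment
bookkeeping, and counts ion crossings through each membrane's pore with the
same hysteresis detector the water-flux analysis uses.  The ion-swap engine
that *maintains* the gradient is an MD-runtime procedure and is not part of
this package; this module analyses its outputs (or synthetic stand-ins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .hydration import FluxResult, PoreCylinder, count_permeation_events, water_axial_tracks
from .structure_io import Trajectory
from .units import POISSON_VOLT_FACTOR


@dataclass
class ChargeDensityProfile:
    """Frame-averaged slab charge density along z, in e/Å³."""

    bin_edges: np.ndarray  # Å
    rho: np.ndarray  # e/Å³
    cross_section: float  # Å², slab area used for volume normalisation

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_charge(self) -> float:
        widths = np.diff(self.bin_edges)
        return float(np.sum(self.rho * widths * self.cross_section))


@dataclass
class VoltageProfile:
    z: np.ndarray  # Å
    phi: np.ndarray  # volts, phi[0] = 0 at the lower box edge
    dV: float | None = None  # volts between declared compartments


@dataclass
class CompartmentAssignment:
    """Per-frame, per-species ion counts in the α and β compartments."""

    labels: dict  # species -> (n_frames, 2) counts, columns (alpha, beta)
    membrane_slabs: tuple

    def imbalance(self, species: str) -> np.ndarray:
        """α − β count per frame: the driving gradient of a CE setup."""
        counts = self.labels[species]
        return counts[:, 0] - counts[:, 1]


# ---------------------------------------------------------------------------


def charge_density_profile(
    traj: Trajectory,
    charges: np.ndarray | dict,
    bin_width: float = 1.0,
    bin_edges: np.ndarray | None = None,
) -> ChargeDensityProfile:
    """Slab-binned charge density ρ(z) averaged over frames.

    ``charges`` is a per-atom array (e) aligned with the topology, or a
    mapping serial → charge; every atom must be covered.  Volume
    normalisation uses the box cross-section (Lx·Ly), which must be present.
    """
    top = traj.topology
    if isinstance(charges, dict):
        try:
            q = np.array([charges[int(s)] for s in top.serial], dtype=float)
        except KeyError as exc:
            raise ValueError(f"no charge for atom serial {exc.args[0]}") from None
    else:
        q = np.asarray(charges, dtype=float)
        if len(q) != len(top):
            raise ValueError(f"got {len(q)} charges for {len(top)} atoms")
    if np.any(~np.isfinite(q)):
        bad = int(top.serial[np.nonzero(~np.isfinite(q))[0][0]])
        raise ValueError(f"non-finite charge for atom serial {bad}")
    if top.box is None:
        raise ValueError("charge density needs box dimensions for volume normalisation")
    lz = float(top.box[2])
    area = float(top.box[0] * top.box[1])
    if bin_edges is None:
        n_bins = max(1, int(round(lz / bin_width)))
        bin_edges = np.linspace(0.0, lz, n_bins + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    z = np.mod(traj.frames[:, :, 2], lz)  # wrap into the box
    rho = np.zeros(len(bin_edges) - 1)
    for f in range(traj.n_frames):
        hist, _ = np.histogram(z[f], bins=bin_edges, weights=q)
        rho += hist
    widths = np.diff(bin_edges)
    rho /= traj.n_frames * widths * area
    return ChargeDensityProfile(bin_edges=bin_edges, rho=rho, cross_section=area)


def poisson_potential(
    rho: ChargeDensityProfile,
    eps_r: float = 1.0,
    alpha_region: tuple | None = None,
    beta_region: tuple | None = None,
) -> VoltageProfile:
    """Electrostatic potential by cumulative trapezoid double integration.

    εr defaults to 1 (charges are explicit; no implicit dielectric), the
    convention of the GROMACS potential tool.  ΔV, when bulk regions are
    given, is mean φ over the α region minus mean φ over β.
    """
    if len(rho.rho) == 0:
        raise ValueError("empty charge-density profile")
    z = rho.bin_centers
    field_integral = cumulative_trapezoid(rho.rho, z, initial=0.0)
    phi_raw = -cumulative_trapezoid(field_integral, z, initial=0.0)
    phi = phi_raw * POISSON_VOLT_FACTOR / eps_r
    dv = None
    if alpha_region is not None and beta_region is not None:
        am = (z >= alpha_region[0]) & (z <= alpha_region[1])
        bm = (z >= beta_region[0]) & (z <= beta_region[1])
        if not am.any() or not bm.any():
            raise ValueError("bulk regions do not overlap the profile")
        dv = float(np.mean(phi[am]) - np.mean(phi[bm]))
    return VoltageProfile(z=z, phi=phi, dV=dv)


def assign_compartments(
    traj: Trajectory,
    membrane_slabs: tuple,
    species: dict,
) -> CompartmentAssignment:
    """Count ions per compartment and frame in a double-bilayer box.

    ``membrane_slabs`` is two (z_lo, z_hi) intervals in box coordinates; the
    region *between* them (slab1_hi → slab2_lo) is labelled α, the rest of
    the periodic box β.  ``species`` maps a label to a selection expression
    or index array.  Ions inside a membrane slab are assigned to the nearer
    compartment boundary (every ion lands in exactly one compartment).
    """
    (a_lo, a_hi), (b_lo, b_hi) = sorted(membrane_slabs)
    if a_hi > b_lo:
        raise ValueError("membrane slabs overlap")
    if traj.topology.box is None:
        raise ValueError("compartment assignment needs box dimensions")
    lz = float(traj.topology.box[2])
    from .structure_io import selection_mask

    labels = {}
    for name, sel in species.items():
        if isinstance(sel, str):
            idx = np.nonzero(selection_mask(traj.topology, sel))[0]
        else:
            idx = np.asarray(sel, dtype=int)
        z = np.mod(traj.frames[:, idx, 2], lz)
        mid1 = 0.5 * (a_lo + a_hi)
        mid2 = 0.5 * (b_lo + b_hi)
        in_alpha = (z > mid1) & (z < mid2)
        counts = np.column_stack([in_alpha.sum(axis=1), (~in_alpha).sum(axis=1)])
        labels[name] = counts
    return CompartmentAssignment(labels=labels, membrane_slabs=((a_lo, a_hi), (b_lo, b_hi)))


def count_ion_crossings(
    traj: Trajectory,
    species: dict,
    pores: dict,
) -> dict:
    """Permeation events per species and per membrane pore.

    ``pores`` maps a membrane label to a :class:`PoreCylinder`; the gate
    planes are the cylinder mouths.  Reuses the hysteresis traversal
    detector, so boundary jitter never double-counts.  Zero counts are a
    meaningful outcome (a closed gate).
    """
    results: dict = {}
    for sp, sel in species.items():
        results[sp] = {}
        for mem, cyl in pores.items():
            tracks = water_axial_tracks(traj, sel, cyl)
            results[sp][mem] = count_permeation_events(tracks, cyl.z_lo, cyl.z_hi)
    return results
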