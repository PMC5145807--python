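"""HOLE-style pore-radius profiling and hydrophobic-gate detection.

The pore radius at an axial position z is the radius of the largest probe
sphere, centered in the plane normal to the channel axis at z, that touches
no atom: for an in-plane center c,

    r(c) = min_i ( |c − x_i| − vdw_i )

with |·| the full 3-D distance, maximised over c by Monte Carlo simulated
annealing followed by a deterministic simplex polish.  Marching the plane
along the axis, seeding each plane with the previous optimum, yields the
radius profile; narrow apolar stretches of the profile are candidate
hydrophobic gates.  Channels with a hydrophobic constriction narrower than
about 4–5 Å tend to dewet and block ion flow even without steric occlusion,
which is what the gate threshold default encodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .structure_io import AtomSet

#: Sentinel radius when no atom bounds the probe sphere.
UNBOUNDED = math.inf

#: Residues counted as hydrophobic per hydropathy classification.  "kd" is
#: the positive side of the Kyte–Doolittle scale.
HYDROPATHY_SCALES = {
    "kd": frozenset({"ALA", "VAL", "LEU", "ILE", "PHE", "MET", "CYS"}),
}


@dataclass
class AnnealSchedule:
    """Geometric simulated-annealing schedule for the in-plane search."""

    n_stages: int = 30
    moves_per_stage: int = 50
    t_start: float = 1.0  # Å of objective scale
    t_end: float = 0.01
    step_start: float = 1.0  # Å
    step_end: float = 0.1
    polish: bool = True

    def temperatures(self) -> np.ndarray:
        return np.geomspace(self.t_start, self.t_end, self.n_stages)

    def steps(self) -> np.ndarray:
        return np.geomspace(self.step_start, self.step_end, self.n_stages)


@dataclass
class PoreProfile:
    """Pore radius and center line as a function of axial coordinate."""

    z: np.ndarray  # Å, strictly increasing, uniform step
    radius: np.ndarray  # Å
    center: np.ndarray  # (n, 2) in-plane centers, axis frame
    step: float
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if np.any(self.radius < 0):
            raise ValueError("pore radius must be non-negative")
        dz = np.diff(self.z)
        if len(dz) and (np.any(dz <= 0) or not np.allclose(dz, dz[0], atol=1e-9)):
            raise ValueError("z must be strictly increasing with uniform step")

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "z_A": self.z,
                "radius_A": self.radius,
                "cx_A": self.center[:, 0],
                "cy_A": self.center[:, 1],
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.4f")


@dataclass
class GateRegion:
    """A contiguous sub-threshold constriction — a candidate gate."""

    z_min: float
    z_max: float
    min_radius: float
    z_at_min: float
    lining_residues: list  # (resname, resid, chain)
    hydrophobic_fraction: float

    def __post_init__(self):
        if not self.z_min <= self.z_max:
            raise ValueError("z_min must be <= z_max")


# ---------------------------------------------------------------------------
# geometry helpers


def axis_frame(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix whose rows (e1, e2, axis) form a right-handed frame."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("axis must be a non-zero vector")
    a = axis / norm
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return np.vstack([e1, e2, a])


def principal_axis(atoms: AtomSet) -> np.ndarray:
    """Default channel axis: direction of maximal coordinate variance.

    For a transmembrane helix bundle this is the membrane normal through the
    pore.  Sign is fixed so the axis points toward +z of the input frame.
    """
    centered = atoms.coords - atoms.coords.mean(axis=0)
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    if axis[2] < 0:
        axis = -axis
    return axis


def _plane_atoms(coords_f, radii, z, reach):
    """Atoms able to bound a probe of radius <= reach at plane z."""
    keep = np.abs(coords_f[:, 2] - z) <= radii + reach
    return coords_f[keep], radii[keep]


def _objective(center2, pts, radii, z):
    """Largest probe radius centered at (cx, cy, z): min over atoms."""
    d = np.sqrt(
        (pts[:, 0] - center2[0]) ** 2
        + (pts[:, 1] - center2[1]) ** 2
        + (pts[:, 2] - z) ** 2
    )
    return float(np.min(d - radii))


def max_sphere_radius_at(
    atoms: AtomSet,
    z: float,
    axis: np.ndarray = (0.0, 0.0, 1.0),
    start_center: tuple = (0.0, 0.0),
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
    reach: float = 15.0,
    origin: np.ndarray | None = None,
) -> tuple:
    """Radius and in-plane center of the largest probe sphere at plane z.

    ``schedule=None`` disables optimisation and evaluates at
    ``start_center``.  Coordinates are expressed in the axis frame (rows of
    :func:`axis_frame`); ``origin`` is subtracted first (default: centroid).
    Returns ``(radius, (cx, cy))``; radius is ``UNBOUNDED`` when no atom is
    within reach of the plane.
    """
    if not atoms.has_radii:
        raise ValueError("atoms need vdW radii; run assign_vdw_radii first")
    frame = axis_frame(np.asarray(axis, dtype=float))
    if origin is None:
        origin = atoms.coords.mean(axis=0)
    coords_f = (atoms.coords - origin) @ frame.T
    pts, radii = _plane_atoms(coords_f, atoms.vdw_radius, z, reach)
    if len(pts) == 0:
        return UNBOUNDED, tuple(start_center)
    center = np.asarray(start_center, dtype=float)
    best_c = center.copy()
    best_f = _objective(center, pts, radii, z)
    if schedule is None:
        return max(best_f, 0.0), (best_c[0], best_c[1])
    rng = np.random.default_rng(seed)
    f_cur = best_f
    c_cur = center.copy()
    for temp, step in zip(schedule.temperatures(), schedule.steps()):
        for _ in range(schedule.moves_per_stage):
            cand = c_cur + rng.normal(scale=step, size=2)
            f_cand = _objective(cand, pts, radii, z)
            # a center overlapping an atom is not a valid probe position:
            # never step from a valid center into overlap (this also keeps
            # the walk from tunnelling through the pore wall and escaping)
            if f_cand < 0 and f_cand < f_cur:
                continue
            if f_cand >= f_cur or rng.random() < math.exp((f_cand - f_cur) / temp):
                c_cur, f_cur = cand, f_cand
                if f_cur > best_f:
                    best_f, best_c = f_cur, c_cur.copy()
    if schedule.polish:
        res = minimize(
            lambda c: -_objective(c, pts, radii, z),
            best_c,
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 500},
        )
        if -res.fun > best_f:
            best_f, best_c = -res.fun, res.x
    if best_f >= reach:
        return UNBOUNDED, (best_c[0], best_c[1])
    return max(best_f, 0.0), (best_c[0], best_c[1])


def compute_profile(
    atoms: AtomSet,
    axis: np.ndarray | str = "auto",
    z_range: tuple = None,
    step: float = 0.25,
    seed: int = 0,
    schedule: AnnealSchedule | None = None,
    start_center: tuple = (0.0, 0.0),
    origin: np.ndarray | None = None,
    reach: float = 15.0,
) -> PoreProfile:
    """March a probe plane along the axis and record the radius profile.

    Each plane starts from the previous plane's optimised center, so the
    center line stays continuous through tilted or off-axis pores.  The same
    seed yields the same profile.
    """
    if isinstance(axis, str):
        if axis != "auto":
            raise ValueError("axis must be a vector or 'auto'")
        axis_vec = principal_axis(atoms)
    else:
        axis_vec = np.asarray(axis, dtype=float)
    if origin is None:
        origin = atoms.coords.mean(axis=0)
    if schedule is None:
        schedule = AnnealSchedule()
    if step <= 0:
        raise ValueError("step must be positive")
    if z_range is None:
        zf = (atoms.coords - origin) @ axis_frame(axis_vec).T
        z_range = (float(zf[:, 2].min()), float(zf[:, 2].max()))
    z_lo, z_hi = map(float, z_range)
    if not z_lo < z_hi:
        raise ValueError("z_range must satisfy z_lo < z_hi")
    n = int(round((z_hi - z_lo) / step)) + 1
    zs = z_lo + step * np.arange(n)
    radii = np.empty(n)
    centers = np.empty((n, 2))
    rng = np.random.default_rng(seed)
    center = tuple(start_center)
    for i, z in enumerate(zs):
        r, c = max_sphere_radius_at(
            atoms,
            z,
            axis=axis_vec,
            start_center=center,
            schedule=schedule,
            seed=int(rng.integers(2**31 - 1)),
            reach=reach,
            origin=origin,
        )
        radii[i] = r
        centers[i] = c
        if math.isfinite(r):
            center = c
    return PoreProfile(
        z=zs, radius=radii, center=centers, step=step, axis=axis_vec, origin=np.asarray(origin)
    )


def min_radius(profile: PoreProfile, z_window: tuple | None = None) -> tuple:
    """Global minimum radius in the window; ties resolve to the smaller z."""
    if z_window is None:
        mask = np.ones(len(profile.z), dtype=bool)
    else:
        lo, hi = z_window
        mask = (profile.z >= lo) & (profile.z <= hi)
    if not mask.any():
        raise ValueError("z_window does not overlap the profile")
    idx = np.nonzero(mask)[0]
    best = idx[np.argmin(profile.radius[idx])]  # argmin returns first => smaller z
    return float(profile.z[best]), float(profile.radius[best])


def identify_gate(
    profile: PoreProfile,
    atoms: AtomSet,
    radius_threshold: float = 4.5,
    lining_cutoff: float = 2.8,
    hydropathy: str = "kd",
) -> list:
    """Candidate hydrophobic gates: contiguous runs with radius < threshold.

    Lining residues are those with any heavy atom whose surface lies within
    ``lining_cutoff`` of the local probe-sphere surface.  Regions are sorted
    by their minimum radius (tightest constriction first).
    """
    hydrophobic = HYDROPATHY_SCALES[hydropathy]
    below = profile.radius < radius_threshold
    regions = []
    frame = axis_frame(profile.axis)
    coords_f = (atoms.coords - profile.origin) @ frame.T
    i = 0
    while i < len(below):
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(below) and below[j + 1]:
            j += 1
        idx = np.arange(i, j + 1)
        k = idx[np.argmin(profile.radius[idx])]
        lining: dict = {}
        heavy = atoms.element != "H"
        for p in idx:
            c = np.array([profile.center[p, 0], profile.center[p, 1], profile.z[p]])
            d = np.linalg.norm(coords_f - c, axis=1) - atoms.vdw_radius
            near = heavy & (d <= profile.radius[p] + lining_cutoff)
            for a in np.nonzero(near)[0]:
                lining[(str(atoms.resname[a]), int(atoms.resid[a]), str(atoms.chain[a]))] = None
        residues = sorted(lining)
        if residues:
            frac = sum(1 for r in residues if r[0] in hydrophobic) / len(residues)
        else:
            frac = 0.0
        regions.append(
            GateRegion(
                z_min=float(profile.z[i]),
                z_max=float(profile.z[j]),
                min_radius=float(profile.radius[k]),
                z_at_min=float(profile.z[k]),
                lining_residues=residues,
                hydrophobic_fraction=frac,
            )
        )
        i = j + 1
    regions.sort(key=lambda g: g.min_radius)
    return regions
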