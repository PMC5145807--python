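"""Potential-of-mean-force reconstruction from umbrella-sampling windows.

Windows carry time series of a particle's axial position sampled under a
harmonic bias w_i(z) = ½ k (z − c_i)²; the weighted histogram analysis
method (WHAM) merges the biased histograms self-consistently:

    P(z_b) = Σ_i n_i(z_b) / Σ_i N_i exp[(F_i − w_i(z_b)) / kT]
    F_i    = −kT ln Σ_b P(z_b) exp[−w_i(z_b) / kT]

iterated until the window free energies F_i stop moving, after which
E(z_b) = −kT ln P(z_b), zero-shifted to the bulk ends.  Errors come from a
bootstrap over each window's samples; convergence is monitored by
recomputing the central barrier on cumulative time slices.

Force constants are quoted in kJ mol⁻¹ nm⁻² while coordinates are in Å; the
conversion is centralized in :func:`pore_annotate.units.bias_energy`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .units import bias_energy, thermal_energy


class WhamConvergenceError(RuntimeError):
    def __init__(self, max_iter: int, residual: float):
        super().__init__(
            f"WHAM did not converge in {max_iter} iterations (last max|ΔF| = {residual:.3e} kJ/mol)"
        )
        self.residual = residual


@dataclass
class UmbrellaWindow:
    """One biased window: anchor, spring constant, and its sample series."""

    center: float  # Å
    force_constant: float  # kJ mol⁻¹ nm⁻²
    samples: np.ndarray  # Å
    times: np.ndarray | None = None  # ns, optional

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.force_constant < 0:
            raise ValueError("force constant must be non-negative")
        if self.samples.size == 0:
            raise ValueError("window has no samples")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != len(self.samples):
                raise ValueError("times must align with samples")

    def bias(self, z):
        return bias_energy(z, self.center, self.force_constant)


@dataclass
class UmbrellaDataset:
    windows: list
    temperature: float = 310.0

    def __post_init__(self):
        self.windows = sorted(self.windows, key=lambda w: w.center)
        if not self.windows:
            raise ValueError("dataset needs at least one window")

    def check_overlap(self, bins: np.ndarray) -> None:
        """Warn when adjacent windows share no occupied histogram bin."""
        for a, b in zip(self.windows, self.windows[1:]):
            ha = np.histogram(a.samples, bins=bins)[0] > 0
            hb = np.histogram(b.samples, bins=bins)[0] > 0
            if not np.any(ha & hb):
                warnings.warn(
                    f"windows at {a.center} and {b.center} Å share no occupied bin; "
                    "the PMF may be disconnected there",
                    stacklevel=2,
                )

    def default_bins(self, bin_width: float = 0.5) -> np.ndarray:
        """Uniform bins over the window-center range.

        Restricting the histogram to the anchored stretch of the reaction
        coordinate keeps the estimate away from the far tails of the end
        windows, where the bias varies steeply within a bin and the
        discretised estimator degrades.
        """
        lo = min(w.center for w in self.windows)
        hi = max(w.center for w in self.windows)
        if hi <= lo:  # single window: fall back to the sample span
            lo = float(min(w.samples.min() for w in self.windows))
            hi = float(max(w.samples.max() for w in self.windows))
        n = max(1, int(np.ceil((hi - lo) / bin_width - 1e-9)))
        return lo + (hi - lo) / n * np.arange(n + 1)


@dataclass
class PMF:
    z: np.ndarray  # bin centers, Å
    energy: np.ndarray  # kJ/mol, zero-shifted; NaN in unsampled bins
    error: np.ndarray | None  # kJ/mol per bin, bootstrap
    window_free_energies: np.ndarray
    n_iterations: int
    temperature: float
    reference: str = "mean over outermost sampled bins at each end"

    def barrier(self, z_window: tuple | None = None) -> float:
        mask = np.isfinite(self.energy)
        if z_window is not None:
            mask &= (self.z >= z_window[0]) & (self.z <= z_window[1])
        return float(np.nanmax(self.energy[mask]))

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame({"z_A": self.z, "E_kJ_mol": self.energy})
        df["err_kJ_mol"] = self.error if self.error is not None else np.nan
        df.to_csv(path, sep="\t", index=False, float_format="%.5f")


# ---------------------------------------------------------------------------
# loading


def load_umbrella_windows(
    metadata: "list[tuple] | str | Path", temperature: float = 310.0
) -> UmbrellaDataset:
    """Build a dataset from (path, center_Å, k_kJ_mol_nm2) records.

    ``metadata`` is either a list of such tuples or the path to a TSV with
    columns ``path``, ``center_A``, ``k_kJ_mol_nm2`` (paths relative to the
    TSV's directory).  Each window file is two-column text: time (ns) and
    reaction coordinate (Å).
    """
    if isinstance(metadata, (str, Path)):
        import pandas as pd

        meta_path = Path(metadata)
        df = pd.read_csv(meta_path, sep="\t")
        records = [
            (meta_path.parent / row["path"], float(row["center_A"]), float(row["k_kJ_mol_nm2"]))
            for _, row in df.iterrows()
        ]
    else:
        records = [(Path(p), float(c), float(k)) for p, c, k in metadata]
    windows = []
    for path, center, k in records:
        times, values = _read_two_column(path)
        windows.append(UmbrellaWindow(center=center, force_constant=k, samples=values, times=times))
    dataset = UmbrellaDataset(windows=windows, temperature=temperature)
    dataset.check_overlap(dataset.default_bins())
    return dataset


def _read_two_column(path: Path):
    times, values = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "@")):
                continue
            parts = stripped.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {stripped!r}")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric row {stripped!r}") from None
    if not values:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(times), np.asarray(values)


# ---------------------------------------------------------------------------
# WHAM core


def _zero_shift(energy, kt, n_reference_bins: int = 3):
    """Shift so the mean *density* over the outermost sampled bins is zero
    energy — the same normalisation-constant convention the equilibrium
    Boltzmann inversion uses (C = mean n over the two end regions)."""
    finite = np.nonzero(np.isfinite(energy))[0]
    if len(finite) == 0:
        raise ValueError("no sampled bins")
    take = min(n_reference_bins, max(1, len(finite) // 2))
    ref_idx = np.concatenate([finite[:take], finite[-take:]])
    shift = -kt * np.log(np.mean(np.exp(-energy[ref_idx] / kt)))
    return energy - shift


def wham(
    dataset: UmbrellaDataset,
    bins: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    initial_f: np.ndarray | None = None,
) -> PMF:
    """Self-consistent WHAM solve.

    ``tol`` is in units of kT on the window free energies F_i.  Unsampled
    bins are masked (NaN), not interpolated.  Raises
    :class:`WhamConvergenceError` at ``max_iter``.
    """
    kt = thermal_energy(dataset.temperature)
    if bins is None:
        bins = dataset.default_bins()
    bins = np.asarray(bins, dtype=float)
    centers = 0.5 * (bins[:-1] + bins[1:])
    n_win = len(dataset.windows)
    counts = np.stack(
        [np.histogram(w.samples, bins=bins)[0] for w in dataset.windows]
    )  # (W, B)
    n_total = counts.sum(axis=0)  # per bin
    # count only samples that fell inside the histogram range, otherwise the
    # normalisation of windows whose tails spill past the bin range is wrong
    n_samples = counts.sum(axis=1).astype(float)
    if np.any(n_samples == 0):
        empty = int(np.nonzero(n_samples == 0)[0][0])
        raise ValueError(
            f"window {empty} (center {dataset.windows[empty].center} Å) has no samples "
            "inside the bin range"
        )
    bias = np.stack([w.bias(centers) for w in dataset.windows])  # (W, B)
    boltz = np.exp(-bias / kt)
    f = np.zeros(n_win) if initial_f is None else np.asarray(initial_f, dtype=float).copy()
    sampled = n_total > 0
    converged = False
    n_iter = 0
    resid = np.inf
    for n_iter in range(1, max_iter + 1):
        # denominators per bin: Σ_i N_i exp[(F_i − w_ib)/kT]
        denom = np.einsum("w,wb->b", n_samples * np.exp(f / kt), boltz)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(sampled & (denom > 0), n_total / denom, 0.0)
        norm = p.sum()
        if norm <= 0:
            raise ValueError("all probability mass vanished; check the input windows")
        p /= norm
        f_new = -kt * np.log(np.clip(boltz @ p, 1e-300, None))
        f_new -= f_new[0]
        resid = float(np.max(np.abs(f_new - f)))
        f = f_new
        if resid < tol * kt:
            converged = True
            break
    if not converged:
        raise WhamConvergenceError(max_iter, resid)
    with np.errstate(divide="ignore"):
        energy = np.where(sampled, -kt * np.log(np.where(sampled, p, 1.0)), np.nan)
    energy = _zero_shift(energy, kt)
    return PMF(
        z=centers,
        energy=energy,
        error=None,
        window_free_energies=f,
        n_iterations=n_iter,
        temperature=dataset.temperature,
    )


def bootstrap_errors(
    dataset: UmbrellaDataset,
    bins: np.ndarray | None = None,
    n_boot: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Per-bin PMF standard deviation from a within-window bootstrap.

    Each replicate resamples every window's sample vector with replacement
    (window identity preserved) and re-runs WHAM; the reported error is the
    standard deviation across replicates.  Seeded and reproducible.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    if bins is None:
        bins = dataset.default_bins()
    rng = np.random.default_rng(seed)
    replicates = []
    for _ in range(n_boot):
        windows = []
        for w in dataset.windows:
            idx = rng.integers(0, len(w.samples), size=len(w.samples))
            windows.append(
                UmbrellaWindow(center=w.center, force_constant=w.force_constant, samples=w.samples[idx])
            )
        rep = wham(
            UmbrellaDataset(windows=windows, temperature=dataset.temperature),
            bins=bins,
            tol=tol,
            max_iter=max_iter,
        )
        replicates.append(rep.energy)
    stacked = np.stack(replicates)
    return np.nanstd(stacked, axis=0, ddof=1)


def convergence_series(
    dataset: UmbrellaDataset,
    segment: float = 0.1,
    barrier_region: tuple = (-5.0, 5.0),
    bins: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Central barrier height versus cumulative sampling time.

    Re-runs WHAM on each window truncated to the first m·``segment`` ns
    (m = 1, 2, …) and records the barrier in ``barrier_region``; a flat
    series indicates equilibrated sampling, a drifting one does not.
    Windows must carry times; ``segment`` must fit into the common duration.
    """
    for w in dataset.windows:
        if w.times is None:
            raise ValueError("convergence analysis needs per-sample times")
    duration = min(w.times[-1] - w.times[0] for w in dataset.windows)
    if segment > duration + 1e-12:
        raise ValueError(f"segment {segment} ns exceeds common window duration {duration:.3g} ns")
    n_seg = int(round(duration / segment))
    heights = []
    for m in range(1, n_seg + 1):
        t_cut = m * segment
        windows = []
        for w in dataset.windows:
            keep = (w.times - w.times[0]) <= t_cut + 1e-12
            windows.append(
                UmbrellaWindow(
                    center=w.center,
                    force_constant=w.force_constant,
                    samples=w.samples[keep],
                    times=w.times[keep],
                )
            )
        pmf = wham(
            UmbrellaDataset(windows=windows, temperature=dataset.temperature),
            bins=bins,
            tol=tol,
            max_iter=max_iter,
        )
        heights.append(pmf.barrier(barrier_region))
    return np.asarray(heights)
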