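"""Umbrella-sampling bookkeeping and a 1-D WHAM solver with block errors.

The free-energy profile of a cation along the membrane normal z is computed
from umbrella windows: harmonic biases U_i(z) = 1/2 k (z - c_i)^2 on a grid
of centers, each contributing a sample series of the reaction coordinate.
The weighted histogram analysis method (WHAM) self-consistently unbiases the
window histograms into one profile:

    P(z_b) = sum_i n_i(b) / sum_i N_i exp(-beta (U_i(z_b) - f_i))
    f_i    = -kT ln sum_b P(z_b) exp(-beta U_i(z_b))

iterated until the window free-energy shifts f_i stop changing.  Statistical
errors come from block averaging: the windows are split into contiguous
blocks, WHAM is solved per block, and the standard error over aligned block
profiles is reported per grid point; a Monte-Carlo bootstrap over blocks is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

KB_KCAL = 0.0019872041  # Boltzmann constant, kcal/(mol K)


@dataclass(frozen=True)
class UmbrellaWindow:
    """One umbrella window: harmonic bias center, force constant, and samples."""

    center: float
    force_constant: float  # kcal/(mol A^2)
    samples: np.ndarray
    equilibration_cut: float = 0.0  # ps already discarded

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples")

    def bias(self, z: np.ndarray) -> np.ndarray:
        return 0.5 * self.force_constant * (np.asarray(z) - self.center) ** 2


@dataclass(frozen=True)
class RestraintSpec:
    """Flat-bottom cylindrical restraint confining xy motion (metadata only;
    no standard-state volume correction is applied to the profile)."""

    cylinder_radius: float = 15.0
    style: str = "flat-bottom"

    def __post_init__(self) -> None:
        if self.cylinder_radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class WhamConfig:
    temperature: float = 310.0  # K
    bin_width: float = 0.05  # A
    tolerance: float = 1e-7  # kcal/mol, max change in window shifts
    max_iterations: int = 100_000
    n_blocks: int = 3

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.tolerance <= 0 or self.bin_width <= 0:
            raise ValueError("temperature, tolerance, bin_width must be positive")

    @property
    def kt(self) -> float:
        return KB_KCAL * self.temperature


@dataclass
class PMFProfile:
    """Free-energy curve on a z grid, aligned min-zero by default."""

    grid: np.ndarray
    free_energy: np.ndarray
    errors: np.ndarray | None = None
    reference: str = "min-zero"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    def value_at(self, z: float) -> float:
        finite = np.isfinite(self.free_energy)
        return float(np.interp(z, self.grid[finite], self.free_energy[finite]))


def make_windows(z_min: float, z_max: float, spacing: float,
                 force_constant: float = 10.0) -> list[UmbrellaWindow]:
    """Empty windows on the inclusive grid z_min, z_min+spacing, ..., z_max.

    The default study grid -1.5 .. 25.0 Å with 0.25 Å spacing yields 107
    windows at k = 10 kcal/(mol Å²).
    """
    if z_min >= z_max:
        raise ValueError("z_min must be < z_max")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    span = z_max - z_min
    n = round(span / spacing)
    if abs(n * spacing - span) > 1e-9 * max(1.0, abs(span)):
        raise ValueError(f"spacing {spacing} not commensurate with [{z_min}, {z_max}]")
    centers = z_min + spacing * np.arange(n + 1)
    return [UmbrellaWindow(center=float(c), force_constant=force_constant,
                           samples=np.empty(0)) for c in centers]


def discard_equilibration(window: UmbrellaWindow, cut: float = 500.0,
                          sample_interval: float = 1.0) -> UmbrellaWindow:
    """Drop samples from the first ``cut`` ps (default 500 ps of a 2 ns run)."""
    if cut < 0:
        raise ValueError("cut must be >= 0")
    duration = len(window.samples) * sample_interval
    if cut >= duration and cut > 0:
        raise ValueError(f"cut {cut} ps >= window duration {duration} ps")
    n_drop = int(round(cut / sample_interval))
    return replace(window, samples=window.samples[n_drop:],
                   equilibration_cut=window.equilibration_cut + cut)


def _histogram_windows(windows, config):
    lo = min(w.samples.min() for w in windows if w.samples.size)
    hi = max(w.samples.max() for w in windows if w.samples.size)
    # bin edges anchored on a global lattice of the bin width, so subsets of
    # the data (blocks, bootstrap draws) histogram onto identical grids
    w_ = config.bin_width
    first = int(np.floor(lo / w_))
    last = int(np.ceil(hi / w_))
    if last == first:
        last += 1
    edges = w_ * np.arange(first, last + 1).astype(float)
    edges[-1] += 1e-12
    mids = 0.5 * (edges[:-1] + edges[1:])
    counts = np.array([np.histogram(w.samples, bins=edges)[0] for w in windows])
    return mids, counts


def check_overlap(windows: list[UmbrellaWindow], config: WhamConfig | None = None) -> list[int]:
    """Indices of windows whose histograms do not overlap any other window's.

    A disconnected histogram makes the relative free energies of the two
    fragments undetermined; callers should treat a nonempty result as a
    sampling diagnostic.
    """
    config = config or WhamConfig()
    mids, counts = _histogram_windows(windows, config)
    occupied = counts > 0
    bad = []
    for i in range(len(windows)):
        others = occupied[np.arange(len(windows)) != i].any(axis=0)
        if len(windows) > 1 and not np.any(occupied[i] & others):
            bad.append(i)
    return bad


def wham_solve(windows: list[UmbrellaWindow], config: WhamConfig | None = None,
               check_convergence: bool = True) -> PMFProfile:
    """Self-consistent WHAM over binned samples; profile aligned min-zero."""
    config = config or WhamConfig()
    windows = [w for w in windows if w.samples.size]
    if not windows:
        raise ValueError("need at least one window with samples")
    kt = config.kt
    mids, counts = _histogram_windows(windows, config)
    n_i = counts.sum(axis=1).astype(float)  # samples per window
    n_b = counts.sum(axis=0).astype(float)  # total counts per bin
    bias = np.array([w.bias(mids) for w in windows])  # (n_windows, n_bins)
    boltz = np.exp(-bias / kt)

    f = np.zeros(len(windows))  # window shifts, kcal/mol
    for _ in range(config.max_iterations):
        denom = (n_i * np.exp(f / kt)) @ boltz  # (n_bins,)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, n_b / denom, 0.0)
        z_i = boltz @ p
        f_new = -kt * np.log(z_i)
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < config.tolerance:
            f = f_new
            break
        f = f_new
    else:
        if check_convergence:
            raise RuntimeError(f"WHAM did not converge in {config.max_iterations} iterations")

    denom = (n_i * np.exp(f / kt)) @ boltz
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, n_b / denom, 0.0)
        free = np.where(p > 0, -kt * np.log(p), np.inf)
    finite = np.isfinite(free)
    free[finite] -= free[finite].min()
    return PMFProfile(grid=mids, free_energy=free, reference="min-zero")


def _align_profiles(profiles: list[PMFProfile], grid: np.ndarray,
                    weights: np.ndarray | None = None) -> np.ndarray:
    """Interpolate profiles onto a common grid and remove each one's
    (count-weighted) mean over the bins where all are defined.

    Weighting the alignment by histogram counts keeps noisy, barely sampled
    edge bins from dominating the additive constant of each profile.
    """
    rows = []
    for p in profiles:
        fin = np.isfinite(p.free_energy)
        row = np.interp(grid, p.grid[fin], p.free_energy[fin])
        row[(grid < p.grid[fin].min()) | (grid > p.grid[fin].max())] = np.nan
        rows.append(row)
    mat = np.vstack(rows)
    common = np.all(np.isfinite(mat), axis=0)
    w = np.ones(int(common.sum())) if weights is None else weights[common]
    mat -= (mat[:, common] * w).sum(axis=1, keepdims=True) / w.sum()
    return mat


def block_errors(windows: list[UmbrellaWindow], config: WhamConfig | None = None,
                 n_blocks: int | None = None, bootstrap: int = 0,
                 seed: int | None = None) -> PMFProfile:
    """WHAM profile with per-grid-point standard errors from block averaging.

    Each window's sample series is cut into ``n_blocks`` contiguous blocks;
    WHAM is solved per block (block b of every window together), block
    profiles are aligned by their common mean, and the standard error across
    blocks is attached to the full-data profile.  With ``bootstrap`` > 0 the
    error is instead the standard deviation over that many Monte-Carlo
    resamplings of blocks with replacement.
    """
    config = config or WhamConfig()
    nb = n_blocks or config.n_blocks
    if any(w.samples.size < nb for w in windows if w.samples.size):
        raise ValueError(f"every sampled window needs >= {nb} samples")
    full = wham_solve(windows, config)
    _, counts = _histogram_windows([w for w in windows if w.samples.size], config)
    bin_weights = counts.sum(axis=0).astype(float)

    block_profiles = []
    blocks_per_window = [np.array_split(w.samples, nb) for w in windows]
    for b in range(nb):
        ws = [replace(w, samples=blocks_per_window[i][b]) for i, w in enumerate(windows)]
        block_profiles.append(wham_solve(ws, config, check_convergence=False))

    mat = _align_profiles(block_profiles, full.grid, weights=bin_weights)
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        stats = []
        for _ in range(bootstrap):
            pick = rng.integers(0, nb, size=nb)
            stats.append(mat[pick].mean(axis=0))
        err = np.std(np.vstack(stats), axis=0, ddof=1)
    else:
        err = np.std(mat, axis=0, ddof=1) / np.sqrt(nb)
    return PMFProfile(grid=full.grid, free_energy=full.free_energy, errors=err,
                      reference=full.reference)


# ---------------------------------------------------------------------------
# Window-sample text I/O (grossfield-WHAM style layout)
# ---------------------------------------------------------------------------

def write_window(window: UmbrellaWindow, path) -> None:
    """Two-column sample file: time_ps  z_A (time = sample index in ps)."""
    with open(path, "w") as fh:
        for t, z in enumerate(window.samples):
            fh.write(f"{float(t):.1f}\t{z:.6f}\n")


def read_window_samples(path) -> np.ndarray:
    data = np.loadtxt(path)
    return np.atleast_2d(data)[:, 1]


def write_metadata(windows: list[UmbrellaWindow], sample_paths: list[str], path,
                   temperature: float = 310.0) -> None:
    with open(path, "w") as fh:
        fh.write(f"# temperature_K {temperature}\n")
        fh.write("# sample_file center_A force_constant_kcal_mol_A2\n")
        for w, p in zip(windows, sample_paths):
            fh.write(f"{p}\t{w.center:.6f}\t{w.force_constant:.6f}\n")


def read_metadata(path) -> tuple[list[UmbrellaWindow], float]:
    """Read a window metadata file plus its sample files."""
    from pathlib import Path

    path = Path(path)
    temperature = 310.0
    windows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line.split()
            if len(parts) >= 3 and parts[1] == "temperature_K":
                temperature = float(parts[2])
            continue
        fname, center, k = line.split()
        sample_path = Path(fname)
        if not sample_path.is_absolute():
            sample_path = path.parent / sample_path
        windows.append(UmbrellaWindow(center=float(center), force_constant=float(k),
                                      samples=read_window_samples(sample_path)))
    return windows, temperature


def write_profile(profile: PMFProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# reference={profile.reference}\n")
        fh.write("z_A\tfree_energy_kcal_mol\terror_kcal_mol\n")
        for i, z in enumerate(profile.grid):
            err = profile.errors[i] if profile.errors is not None else float("nan")
            fh.write(f"{z:.4f}\t{profile.free_energy[i]:.6f}\t{err:.6f}\n")
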