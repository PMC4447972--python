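"""Synthetic fixtures with known ground truth for every analysis path.

Generators here produce chemically sane toy structures (ideal helix or
extended backbones), condition ensembles with planted interaction
probabilities and tunable frame autocorrelation, exactly-sampled umbrella
windows of analytic 1-D potentials, and noisy cation-site distance traces.
They validate code, not biology: none attempts to mimic real transporter
dynamics.  All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import (ConditionEnsemble, ConditionManifest, ReplicaSpec,
                    StructureFrame)
from .interactions import InteractionFrequencyTable, Pair, table_from_frame_sets
from .pmf import KB_KCAL, UmbrellaWindow


def place_fourth_atom(a, b, c, bond_length: float, bond_angle: float,
                      dihedral: float) -> np.ndarray:
    """Place atom d given three predecessors (NeRF construction).

    ``bond_length`` = |c-d|, ``bond_angle`` = angle b-c-d (degrees),
    ``dihedral`` = torsion a-b-c-d (degrees).
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    theta = np.radians(bond_angle)
    chi = np.radians(dihedral)
    d_local = bond_length * np.array([
        -np.cos(theta),
        np.sin(theta) * np.cos(chi),
        -np.sin(theta) * np.sin(chi),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


# ideal backbone internal coordinates
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O, _A_N_CA_CB = 111.2, 116.2, 121.7, 120.5, 110.5

_GEOMETRIES = {"helix": (-57.0, -47.0), "extended": (-135.0, 135.0)}


def make_toy_structure(n_residues: int, geometry: str = "helix",
                       seed: int = 0, residue_name: str = "ALA") -> StructureFrame:
    """An ideal-geometry peptide backbone (N, CA, C, O, CB) of one chain.

    ``helix`` uses alpha-helical torsions (phi -57, psi -47) whose i/i+4
    backbone N...O distances satisfy the heavy-only hydrogen-bond criterion;
    ``extended`` uses beta-strand torsions with no such contacts.  The seed
    only perturbs nothing here (the construction is deterministic) but is
    accepted for interface uniformity with the other generators.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    phi, psi = _GEOMETRIES[geometry]
    omega = 180.0

    names, coords, resids = [], [], []
    # seed the first three backbone atoms
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([_B_N_CA, 0.0, 0.0])
    # orientation of the first C is arbitrary (phi of residue 1 is undefined)
    c0 = place_fourth_atom(n0 + np.array([0.0, 1.0, 0.0]), n0, ca0,
                           _B_CA_C, _A_N_CA_C, phi)
    backbone = {1: {"N": n0, "CA": ca0, "C": c0}}
    for i in range(2, n_residues + 1):
        prev = backbone[i - 1]
        n = place_fourth_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca = place_fourth_atom(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, omega)
        c = place_fourth_atom(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phi)
        backbone[i] = {"N": n, "CA": ca, "C": c}

    for i in range(1, n_residues + 1):
        bb = backbone[i]
        res_atoms = [("N", "N", bb["N"]), ("CA", "C", bb["CA"]), ("C", "C", bb["C"])]
        if i < n_residues:
            nxt = backbone[i + 1]["N"]
            o = place_fourth_atom(bb["CA"], nxt, bb["C"], _B_C_O, _A_CA_C_O, 180.0)
        else:
            o = place_fourth_atom(bb["N"], bb["CA"], bb["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
        res_atoms.append(("O", "O", o))
        cb = place_fourth_atom(bb["C"], bb["N"], bb["CA"], _B_CA_CB, _A_N_CA_CB, 122.5)
        res_atoms.append(("CB", "C", cb))
        for name, elem, xyz in res_atoms:
            names.append((name, elem))
            coords.append(xyz)
            resids.append(i)

    n_atoms = len(names)
    return StructureFrame(
        atom_names=np.array([n for n, _ in names], dtype="U8"),
        elements=np.array([e for _, e in names], dtype="U4"),
        residue_indices=np.array(resids, dtype=int),
        residue_names=np.full(n_atoms, residue_name, dtype="U8"),
        chain_ids=np.full(n_atoms, "A", dtype="U4"),
        coordinates=np.array(coords),
    )


# ---------------------------------------------------------------------------
# Planted interaction ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedInteractionModel:
    """Ground truth for a planted-interaction ensemble.

    ``pair_probabilities`` maps condition name -> {residue pair: stationary
    interaction probability}.  Per-frame pair states follow a two-state
    Markov chain with lag-1 autocorrelation ``persistence``.  Each residue
    may belong to at most one planted pair (the geometric realization moves
    whole residues), and planted pairs must be farther than 4 apart in
    sequence so the contact channel sees them.
    """

    n_residues: int
    pair_probabilities: dict[str, dict[Pair, float]]
    persistence: float = 0.0
    n_frames: int = 100
    n_replicas: int = 1
    seed: int = 0
    stride_ps: float = 240.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.persistence < 1.0):
            raise ValueError("persistence must be in [0, 1)")
        for cond, probs in self.pair_probabilities.items():
            used: set[int] = set()
            for (a, b), p in probs.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError("probabilities must be in [0, 1]")
                if a in used or b in used:
                    raise ValueError("each residue may appear in one planted pair only")
                used.update((a, b))
                if abs(a - b) <= 4:
                    raise ValueError("planted pairs must be > 4 apart in sequence")
                if not (1 <= a <= self.n_residues and 1 <= b <= self.n_residues):
                    raise ValueError("pair outside residue range")


def markov_chain(p: float, persistence: float, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Stationary 2-state chain: P(on) = p, lag-1 autocorrelation = persistence."""
    x = np.empty(n, dtype=bool)
    x[0] = rng.random() < p
    redraw = rng.random(n) >= persistence
    fresh = rng.random(n) < p
    for t in range(1, n):
        x[t] = fresh[t] if redraw[t] else x[t - 1]
    return x


#: geometry realization: CA-bead distance when a planted pair is on/off.
#: contact threshold for two carbons is 1.70 + 1.70 + 0.6 = 4.0 A, so the
#: on/off placements sit 0.5 A inside/outside it.
PAIR_ON_DISTANCE = 3.5
PAIR_OFF_DISTANCE = 4.5
_GRID_SPACING = 25.0


def make_interaction_trajectory(
    model: PlantedInteractionModel,
) -> tuple[dict[str, ConditionEnsemble], dict[str, dict[Pair, float]]]:
    """Realize the planted model as geometric ensembles, one per condition.

    Residues are single-carbon beads on a sparse grid; a planted pair "on"
    places the partner bead within vdW-contact range of its mate, "off"
    places it just outside.  Returns the ensembles and the ground-truth
    stationary probabilities.
    """
    rng = np.random.default_rng(model.seed)
    ensembles: dict[str, ConditionEnsemble] = {}
    for cond, probs in sorted(model.pair_probabilities.items()):
        partner_of = {}
        for (a, b) in probs:
            partner_of[b] = a
        base = np.zeros((model.n_residues, 3))
        for r in range(model.n_residues):
            base[r] = ((r + 1) * _GRID_SPACING, 0.0, 0.0)
        replicas = []
        for _ in range(model.n_replicas):
            chains = {pair: markov_chain(p, model.persistence, model.n_frames, rng)
                      for pair, p in sorted(probs.items())}
            frames = []
            for t in range(model.n_frames):
                coords = base.copy()
                for (a, b), chain in chains.items():
                    d = PAIR_ON_DISTANCE if chain[t] else PAIR_OFF_DISTANCE
                    coords[b - 1] = coords[a - 1] + np.array([d, 0.0, 0.0])
                frames.append(StructureFrame(
                    atom_names=np.full(model.n_residues, "CA", dtype="U8"),
                    elements=np.full(model.n_residues, "C", dtype="U4"),
                    residue_indices=np.arange(1, model.n_residues + 1),
                    residue_names=np.full(model.n_residues, "ALA", dtype="U8"),
                    chain_ids=np.full(model.n_residues, "A", dtype="U4"),
                    coordinates=coords,
                    frame_time=t * model.stride_ps,
                ))
            replicas.append(frames)
        manifest = ConditionManifest(
            condition_name=cond,
            replicas=tuple(
                ReplicaSpec(trajectory="synthetic://", topology="synthetic://",
                            replica_id=f"r{i + 1}",
                            length_ns=model.n_frames * model.stride_ps / 1000.0)
                for i in range(model.n_replicas)
            ),
        )
        ensembles[cond] = ConditionEnsemble(manifest=manifest,
                                            stride_ps=model.stride_ps,
                                            frames=replicas)
    return ensembles, dict(model.pair_probabilities)


def simulate_frequency_tables(
    model: PlantedInteractionModel,
    seed: int | None = None,
) -> dict[str, InteractionFrequencyTable]:
    """Frequency tables drawn directly from the planted Markov chains.

    Statistically identical to running :func:`make_interaction_trajectory`
    through the geometric interaction detector, at a fraction of the cost —
    used for Monte-Carlo calibration of the differential test.
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    tables = {}
    for cond, probs in sorted(model.pair_probabilities.items()):
        replica_sets: list[list[set[Pair]]] = []
        for _ in range(model.n_replicas):
            chains = {pair: markov_chain(p, model.persistence, model.n_frames, rng)
                      for pair, p in sorted(probs.items())}
            frame_sets = [
                {pair for pair, chain in chains.items() if chain[t]}
                for t in range(model.n_frames)
            ]
            replica_sets.append(frame_sets)
        tables[cond] = table_from_frame_sets(cond, replica_sets)
    return tables


# ---------------------------------------------------------------------------
# Umbrella-window sampling of analytic potentials
# ---------------------------------------------------------------------------

def harmonic_potential(a: float):
    """U(z) = a z^2 (kcal/mol); tagged so sampling can use the exact Gaussian."""
    def u(z):
        return a * np.asarray(z) ** 2
    u.quadratic_coeff = a
    return u


def double_well_potential(barrier: float = 3.0):
    """U(z) = barrier * (z^2 - 1)^2: minima at z = +/-1, barrier at z = 0."""
    def u(z):
        z = np.asarray(z)
        return barrier * (z ** 2 - 1.0) ** 2
    return u


def make_umbrella_samples(
    potential,
    windows: list[UmbrellaWindow],
    temperature: float = 310.0,
    n_per_window: int = 5000,
    seed: int = 0,
) -> list[UmbrellaWindow]:
    """Exact draws from each window's biased Boltzmann density.

    For quadratic potentials (tagged with ``quadratic_coeff``) the biased
    density is a closed-form Gaussian and is sampled directly; otherwise a
    dense numerical inverse-CDF of exp(-(U + bias)/kT) is used.
    """
    rng = np.random.default_rng(seed)
    kt = KB_KCAL * temperature
    out = []
    a = getattr(potential, "quadratic_coeff", None)
    for w in windows:
        k, c = w.force_constant, w.center
        if a is not None:
            coeff = a + 0.5 * k
            mean = 0.5 * k * c / coeff
            sd = np.sqrt(kt / (2.0 * coeff))
            samples = rng.normal(mean, sd, size=n_per_window)
        else:
            sd_bias = np.sqrt(kt / max(k, 1e-9))
            half = max(6.0 * sd_bias, 2.5)
            grid = np.linspace(c - half, c + half, 4001)
            logp = -(potential(grid) + w.bias(grid)) / kt
            p = np.exp(logp - logp.max())
            cdf = np.concatenate([[0.0], np.cumsum((p[1:] + p[:-1]) * 0.5)])
            cdf /= cdf[-1]
            samples = np.interp(rng.random(n_per_window), cdf, grid)
        out.append(UmbrellaWindow(center=c, force_constant=k, samples=samples))
    return out


# ---------------------------------------------------------------------------
# Cation-site distance traces
# ---------------------------------------------------------------------------

STATE_CENTERS = {"Na1": 7.0, "transition": 9.5, "Na1prime": 12.5}


def make_cation_trace(state_sequence: list[str], noise_sd: float = 0.0,
                      seed: int = 0, dt_ps: float = 240.0):
    """Distance series at class-center values plus Gaussian noise.

    Warns when 3 * noise_sd crosses a class boundary (closest margin is
    1.2 Å, transition center 9.5 to the 8.3/10.7 Å thresholds).
    """
    import warnings as _w

    for s in state_sequence:
        if s not in STATE_CENTERS:
            raise ValueError(f"unknown state {s!r}")
    if noise_sd > 0 and 3.0 * noise_sd > 1.2:
        _w.warn("noise_sd large enough for state misclassification", stacklevel=2)
    rng = np.random.default_rng(seed)
    centers = np.array([STATE_CENTERS[s] for s in state_sequence])
    dists = centers + rng.normal(0.0, noise_sd, size=len(centers))
    times = dt_ps * np.arange(len(centers))
    return times, np.clip(dists, 0.0, None)


# ---------------------------------------------------------------------------
# On-disk fixture realization (standard formats, re-loadable by the readers)
# ---------------------------------------------------------------------------

def write_ensemble(ensemble: ConditionEnsemble, directory: str | Path) -> Path:
    """Write an in-memory ensemble as PDB topology + XTC per replica, plus a
    manifest YAML; returns the manifest path (loadable by ``read_manifest`` +
    ``load_ensemble``)."""
    import MDAnalysis as mda
    import yaml

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    replicas = []
    for r, frames in enumerate(ensemble.frames):
        first = frames[0]
        top = directory / f"{ensemble.condition_name}.r{r + 1}.pdb"
        traj = directory / f"{ensemble.condition_name}.r{r + 1}.xtc"
        from .model import write_structure
        write_structure(first, top)
        u = mda.Universe(str(top))
        with mda.Writer(str(traj), n_atoms=first.n_atoms) as writer:
            for t, f in enumerate(frames):
                u.atoms.positions = f.coordinates
                u.trajectory.ts.time = t * ensemble.stride_ps
                u.trajectory.ts.frame = t
                u.trajectory.ts.dt = ensemble.stride_ps
                writer.write(u.atoms)
        replicas.append({
            "trajectory": traj.name, "topology": top.name,
            "replica_id": f"r{r + 1}",
            "length_ns": len(frames) * ensemble.stride_ps / 1000.0,
        })
    manifest_path = directory / f"{ensemble.condition_name}.manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(
        {"condition": ensemble.condition_name, "replicas": replicas}
    ))
    return manifest_path
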