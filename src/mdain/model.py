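"""Core data model: structures, trajectories, condition manifests, subsegment schemes.

The unit of analysis is a :class:`ConditionEnsemble` — the strided,
equilibration-masked frames of every replica simulated under one condition
(e.g. ``WT.Na.ns`` = wild type, Na+ bound, no substrate).  Interaction
frequencies, observables and differential statistics all operate on these
ensembles.  File I/O (PDB, DCD, XTC) is delegated to MDAnalysis; frames are
held as plain numpy arrays in :class:`StructureFrame` so the geometric
analyses stay vectorised and trajectory-engine independent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: residue names treated as water / monatomic ions (excluded from residue-pair
#: analysis by default, but retained in StructureFrame for observables).
WATER_NAMES = frozenset({"HOH", "TIP3", "TIP", "WAT", "SOL", "SPC", "H2O"})
ION_NAMES = frozenset({"NA", "SOD", "CL", "CLA", "K", "POT", "LI", "LIT",
                       "MG", "CAL", "ZN", "CS"})

_TWO_LETTER_ELEMENTS = {"NA", "CL", "BR", "MG", "FE", "ZN", "SE", "LI", "CS", "MN", "CU"}


def _infer_element(atom_name: str, residue_name: str) -> str:
    """Infer a chemical element from a PDB atom name.

    The PDB element column is preferred wherever present; this fallback
    handles MD-derived files that omit it.  Hydrogens follow the PDB v3
    convention: names starting with H, or a digit followed by H (e.g. 1HB).
    """
    name = atom_name.strip().upper()
    if not name:
        raise ValueError("empty atom name")
    if name[0] in "1234" and len(name) > 1 and name[1] == "H":
        return "H"
    resname = residue_name.strip().upper()
    if resname in ION_NAMES and name in _TWO_LETTER_ELEMENTS:
        return name
    # mono-atomic ion residues named like the element (SOD/POT handled below)
    if resname in {"SOD"}:
        return "NA"
    if resname in {"POT"}:
        return "K"
    if resname in {"CLA"}:
        return "CL"
    if resname in {"LIT"}:
        return "LI"
    if name[0] == "H":
        return "H"
    if name[:2] in _TWO_LETTER_ELEMENTS and resname not in WATER_NAMES:
        # protein atom names never start with these two-letter pairs
        if name[:2] in {"NA", "CL"} and resname not in ION_NAMES:
            return name[0]
        return name[:2]
    if name[0] in "CNOSPFKI":
        return name[0]
    raise ValueError(f"cannot infer element for atom {atom_name!r} in {residue_name!r}")


@dataclass(frozen=True)
class AtomRecord:
    """A single atom of one frame (convenience view; bulk data lives in arrays)."""

    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    coordinates: np.ndarray

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class StructureFrame:
    """One frame of a structure/trajectory as parallel numpy arrays.

    Atom order is identical across all frames of a trajectory.  ``box`` is the
    MDAnalysis-style cell ``[lx, ly, lz, alpha, beta, gamma]`` in Angstrom /
    degrees, or None for a non-periodic frame.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    residue_indices: np.ndarray
    residue_names: np.ndarray
    chain_ids: np.ndarray
    coordinates: np.ndarray
    frame_time: float = 0.0
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = len(self.atom_names)
        if self.coordinates.shape != (n, 3):
            raise ValueError("coordinates must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        if n and int(np.min(self.residue_indices)) < 1:
            raise ValueError("residue indices must be 1-based")
        if self.frame_time < 0:
            raise ValueError("frame_time must be non-negative")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def is_heavy(self) -> np.ndarray:
        return self.elements != "H"

    @property
    def is_water(self) -> np.ndarray:
        return np.isin(self.residue_names, sorted(WATER_NAMES))

    @property
    def is_ion(self) -> np.ndarray:
        return np.isin(self.residue_names, sorted(ION_NAMES))

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            atom_name=str(self.atom_names[i]),
            element=str(self.elements[i]),
            residue_index=int(self.residue_indices[i]),
            residue_name=str(self.residue_names[i]),
            chain_id=str(self.chain_ids[i]),
            coordinates=self.coordinates[i],
        )

    def residue_ids(self) -> list[tuple[str, int]]:
        """Unique (chain, residue_index) pairs in atom order."""
        seen, out = set(), []
        for c, r in zip(self.chain_ids, self.residue_indices):
            key = (str(c), int(r))
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def select(self, *, residue_name: str | None = None, residue_index: int | None = None,
               atom_name: str | None = None, element: str | None = None) -> np.ndarray:
        """Indices of atoms matching all given criteria."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if residue_name is not None:
            mask &= self.residue_names == residue_name
        if residue_index is not None:
            mask &= self.residue_indices == residue_index
        if atom_name is not None:
            mask &= self.atom_names == atom_name
        if element is not None:
            mask &= self.elements == element
        return np.flatnonzero(mask)


def load_structure(path: str | Path) -> StructureFrame:
    """Read a PDB file (ATOM + HETATM; waters and ions retained) into a frame.

    Elements come from the PDB element column when present, otherwise they are
    inferred from atom names.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    if u.atoms.n_atoms == 0:
        raise ValueError(f"no atoms in {path}")
    return _frame_from_atomgroup(u.atoms, frame_time=0.0)


def _frame_from_atomgroup(ag, frame_time: float) -> StructureFrame:
    names = ag.names.astype(str)
    resnames = ag.resnames.astype(str)
    try:
        elements = np.array([e.strip().upper() for e in ag.elements], dtype=object)
        missing = np.array([not e for e in elements])
    except Exception:
        elements = np.array([""] * len(names), dtype=object)
        missing = np.ones(len(names), dtype=bool)
    for i in np.flatnonzero(missing):
        elements[i] = _infer_element(names[i], resnames[i])
    try:
        chains = ag.chainIDs.astype(str)
    except Exception:
        try:
            chains = ag.segids.astype(str)
        except Exception:
            chains = np.array(["A"] * len(names))
    chains = np.where(np.char.strip(chains.astype(str)) == "", "A", chains)
    box = None
    dims = ag.dimensions
    if dims is not None and np.all(np.asarray(dims)[:3] > 0):
        box = np.asarray(dims, dtype=float).copy()
    return StructureFrame(
        atom_names=names.astype("U8"),
        elements=elements.astype("U4"),
        residue_indices=ag.resids.astype(int),
        residue_names=resnames.astype("U8"),
        chain_ids=chains.astype("U4"),
        coordinates=np.asarray(ag.positions, dtype=float),
        frame_time=float(frame_time),
        box=box,
    )


def write_structure(frame: StructureFrame, path: str | Path) -> None:
    """Write a frame as PDB text (round-trips coordinates to 3 decimals)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("REMARK generated by mdain\n")
        for i in range(frame.n_atoms):
            resname = str(frame.residue_names[i])
            record = "HETATM" if (resname in WATER_NAMES or resname in ION_NAMES) else "ATOM"
            name = str(frame.atom_names[i])
            # PDB alignment: 4-char names start at col 13, shorter at col 14
            name_f = name if len(name) == 4 else f" {name:<3s}"
            x, y, z = frame.coordinates[i]
            fh.write(
                f"{record:<6s}{(i % 99999) + 1:>5d} {name_f:<4s} {resname:<4s}"
                f"{str(frame.chain_ids[i])[0]}{int(frame.residue_indices[i]):>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{str(frame.elements[i]):>2s}\n"
            )
        fh.write("END\n")


def fetch_pdb(pdb_id: str, dest: str | Path) -> Path:
    """Convenience download of an RCSB entry (never used by the test suite)."""
    from urllib.request import urlopen

    dest = Path(dest)
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urlopen(url, timeout=60) as resp:
        dest.write_bytes(resp.read())
    return dest


# ---------------------------------------------------------------------------
# Condition manifests and ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplicaSpec:
    trajectory: str
    topology: str
    replica_id: str
    length_ns: float


@dataclass(frozen=True)
class ConditionManifest:
    """Which replica trajectories belong to one simulated condition."""

    condition_name: str
    replicas: tuple[ReplicaSpec, ...]

    def __post_init__(self) -> None:
        if not self.condition_name:
            raise ValueError("condition_name must be nonempty")
        if len(self.replicas) < 1:
            raise ValueError("manifest needs at least one replica")
        for r in self.replicas:
            if r.length_ns <= 0:
                raise ValueError("declared replica length must be > 0")

    @property
    def declared_lengths(self) -> list[float]:
        return [r.length_ns for r in self.replicas]


def read_manifest(path: str | Path) -> ConditionManifest:
    """Read a condition manifest from YAML.

    Schema::

        condition: WT.Na.ns
        replicas:
          - {trajectory: rep1.dcd, topology: top.pdb, replica_id: r1, length_ns: 1200}

    Relative trajectory/topology paths are resolved against the manifest file.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    base = path.parent
    reps = tuple(
        ReplicaSpec(
            trajectory=str((base / r["trajectory"]).resolve())
            if not Path(r["trajectory"]).is_absolute() else r["trajectory"],
            topology=str((base / r["topology"]).resolve())
            if not Path(r["topology"]).is_absolute() else r["topology"],
            replica_id=str(r.get("replica_id", f"r{i + 1}")),
            length_ns=float(r["length_ns"]),
        )
        for i, r in enumerate(doc["replicas"])
    )
    return ConditionManifest(condition_name=str(doc["condition"]), replicas=reps)


def manifest_totals(manifests: list[ConditionManifest] | list[dict]) -> tuple[int, float]:
    """Sum replica counts and declared simulation time (ns) over conditions.

    Accepts full manifests or lightweight inventory dicts with keys
    ``n_replicas`` and ``total_ns`` (as in the packaged condition inventory).
    """
    n_rep, total = 0, 0.0
    for m in manifests:
        if isinstance(m, ConditionManifest):
            n_rep += len(m.replicas)
            total += sum(m.declared_lengths)
        else:
            n_rep += int(m["n_replicas"])
            total += float(m["total_ns"])
    return n_rep, total


def leut_condition_inventory() -> list[dict]:
    """The packaged inventory of LeuT MD conditions (name, replicas, total ns)."""
    doc = yaml.safe_load(
        resources.files("mdain.data").joinpath("leut_conditions.yaml").read_text()
    )
    return doc["conditions"]


@dataclass
class ConditionEnsemble:
    """Strided frames of every replica of one condition, with equilibration masks."""

    manifest: ConditionManifest
    stride_ps: float
    frames: list[list[StructureFrame]]
    masks: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stride_ps <= 0:
            raise ValueError("stride must be positive")
        if not self.masks:
            self.masks = [np.ones(len(f), dtype=bool) for f in self.frames]
        for fr, m in zip(self.frames, self.masks):
            if len(fr) != len(m):
                raise ValueError("mask length must equal frame count")

    @property
    def n_replicas(self) -> int:
        return len(self.frames)

    @property
    def condition_name(self) -> str:
        return self.manifest.condition_name

    def masked_frames(self, replica: int) -> list[StructureFrame]:
        mask = self.masks[replica]
        return [f for f, keep in zip(self.frames[replica], mask) if keep]

    def masked_counts(self) -> list[int]:
        return [int(m.sum()) for m in self.masks]


def load_ensemble(manifest: ConditionManifest, stride_ps: float = 240.0) -> ConditionEnsemble:
    """Load all replicas of a condition, subsampled to ``stride_ps``.

    The default 240 ps stride is the analysis time resolution used throughout
    the frequency statistics.  The equilibration mask starts all-true; apply
    :func:`set_equilibration_mask` to discard pre-equilibrium frames.
    """
    import MDAnalysis as mda

    all_frames: list[list[StructureFrame]] = []
    for rep in manifest.replicas:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(rep.topology, rep.trajectory)
        dt = float(u.trajectory.dt) or stride_ps
        if stride_ps < dt - 1e-9:
            raise ValueError(
                f"stride {stride_ps} ps is smaller than the trajectory save interval {dt} ps"
            )
        step = int(round(stride_ps / dt))
        if abs(step * dt - stride_ps) > 1e-6 * stride_ps:
            raise ValueError(f"stride {stride_ps} ps not a multiple of save interval {dt} ps")
        rep_frames = []
        for ts in u.trajectory[::step]:
            rep_frames.append(_frame_from_atomgroup(u.atoms, frame_time=float(ts.time)))
        all_frames.append(rep_frames)
    return ConditionEnsemble(manifest=manifest, stride_ps=stride_ps, frames=all_frames)


def _kabsch_rmsd(coords: np.ndarray, ref: np.ndarray) -> float:
    """RMSD after optimal rigid superposition (Kabsch)."""
    x = coords - coords.mean(axis=0)
    y = ref - ref.mean(axis=0)
    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = x @ rot - y
    return float(np.sqrt((diff ** 2).sum() / len(x)))


def set_equilibration_mask(
    ensemble: ConditionEnsemble,
    method: str = "rmsd_plateau",
    *,
    discard_fraction: float = 0.25,
    tolerance: float = 1.0,
    ranges: list[list[tuple[int, int]]] | None = None,
) -> ConditionEnsemble:
    """Return a copy of the ensemble with updated equilibration masks.

    ``fixed_discard``  — drop the first ``discard_fraction`` of frames per replica.
    ``rmsd_plateau``   — per replica, compute the Cα RMSD of each frame to the
        mean structure of the final 10% of frames; the plateau begins at the
        earliest frame from which the remaining RMSD series stays within a
        band of width ``tolerance`` (Å).  If no plateau exists the whole
        replica is flagged unequilibrated and a warning logged.
    ``explicit``       — ``ranges[replica]`` lists inclusive 1-based frame
        ranges to keep.
    """
    new_masks = []
    for r, frames in enumerate(ensemble.frames):
        n = len(frames)
        mask = np.zeros(n, dtype=bool)
        if method == "fixed_discard":
            start = int(np.ceil(discard_fraction * n))
            mask[start:] = True
        elif method == "explicit":
            if ranges is None:
                raise ValueError("explicit method requires ranges")
            for lo, hi in ranges[r]:
                mask[lo - 1:hi] = True
        elif method == "rmsd_plateau":
            ca = frames[0].select(atom_name="CA")
            if len(ca) == 0:
                raise ValueError("no CA atoms for rmsd_plateau")
            tail = max(1, int(np.ceil(0.10 * n)))
            ref = np.mean([frames[i].coordinates[ca] for i in range(n - tail, n)], axis=0)
            rmsd = np.array([_kabsch_rmsd(f.coordinates[ca], ref) for f in frames])
            plateau = None
            # a plateau shorter than the reference tail is not a plateau
            min_len = max(2, tail)
            for t in range(n - min_len + 1):
                seg = rmsd[t:]
                if seg.max() - seg.min() <= tolerance:
                    plateau = t
                    break
            if plateau is None:
                logger.warning(
                    "replica %d of %s: no RMSD plateau found; flagged unequilibrated",
                    r, ensemble.condition_name,
                )
            else:
                mask[plateau:] = True
        else:
            raise ValueError(f"unknown equilibration method {method!r}")
        new_masks.append(mask)
    return ConditionEnsemble(
        manifest=ensemble.manifest, stride_ps=ensemble.stride_ps,
        frames=ensemble.frames, masks=new_masks,
    )


# ---------------------------------------------------------------------------
# Subsegment scheme
# ---------------------------------------------------------------------------

REGIONS = ("e", "m", "i", "loop", "terminus")


@dataclass(frozen=True)
class SubsegmentEntry:
    name: str
    first_residue: int
    last_residue: int
    region: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if not (1 <= self.first_residue <= self.last_residue):
            raise ValueError(f"bad range for {self.name}")


@dataclass(frozen=True)
class SubsegmentScheme:
    """Ordered partition of the sequence into named residue ranges."""

    entries: tuple[SubsegmentEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("subsegment names must be unique")

    @property
    def last_residue(self) -> int:
        return max(e.last_residue for e in self.entries)

    def lookup(self, residue_index: int) -> str:
        for e in self.entries:
            if e.first_residue <= residue_index <= e.last_residue:
                return e.name
        raise KeyError(f"residue {residue_index} not covered by scheme")

    def region_of(self, name: str) -> str:
        for e in self.entries:
            if e.name == name:
                return e.region
        raise KeyError(name)


def leut_default_scheme() -> SubsegmentScheme:
    """The 44-subsegment parsing of LeuT (residues 1-515): TM sections split
    into extracellular/middle/intracellular thirds, plus loops and N terminus."""
    doc = yaml.safe_load(
        resources.files("mdain.data").joinpath("leut_subsegments.yaml").read_text()
    )
    return SubsegmentScheme(entries=tuple(
        SubsegmentEntry(e["name"], int(e["first"]), int(e["last"]), e["region"])
        for e in doc["entries"]
    ))


def read_scheme(path: str | Path) -> SubsegmentScheme:
    doc = yaml.safe_load(Path(path).read_text())
    return SubsegmentScheme(entries=tuple(
        SubsegmentEntry(e["name"], int(e["first"]), int(e["last"]), e["region"])
        for e in doc["entries"]
    ))


def validate_scheme(scheme: SubsegmentScheme, n_residues: int) -> list[str]:
    """Report gaps, overlaps, and out-of-range entries; empty list means valid."""
    report: list[str] = []
    covered: dict[int, str] = {}
    for e in scheme.entries:
        if e.last_residue > n_residues:
            report.append(f"{e.name}: extends past residue {n_residues}")
        for r in range(e.first_residue, e.last_residue + 1):
            if r in covered:
                report.append(f"overlap at residue {r} ({covered[r]} / {e.name})")
            covered[r] = e.name
    for r in range(1, n_residues + 1):
        if r not in covered:
            report.append(f"gap at residue {r}")
    # contiguity in listed order
    prev = scheme.entries[0]
    for e in scheme.entries[1:]:
        if e.first_residue != prev.last_residue + 1:
            report.append(f"{prev.name} -> {e.name}: not contiguous")
        prev = e
    return report
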