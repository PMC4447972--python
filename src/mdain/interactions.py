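"""Per-frame residue interactions, per-condition frequencies, differential statistics.

Two residues interact in a frame if they are in van der Waals contact (any
heavy-atom pair closer than the sum of the atoms' vdW radii plus a margin,
default 0.6 Å) or form a polar interaction under hydrogen-bond geometric
criteria.  The contact channel excludes residue pairs within a short sequence
separation (default 4), whose packing is insensitive to conformational
change; the polar channel tests all pairs precisely so that local backbone
hydrogen-bond changes are still seen.

Interaction frequency = fraction of equilibrated frames in which a pair
interacts.  A pair discriminates two conditions when the difference of its
frequencies is statistically significantly different from zero; the default
test treats replica-level frequencies as independent units (Welch t),
with Benjamini-Hochberg FDR control across all tested pairs, and a circular
block bootstrap is available for single-replica conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .model import ConditionEnsemble, StructureFrame, WATER_NAMES, ION_NAMES

logger = logging.getLogger(__name__)

Pair = tuple[int, int]


def load_radii_table() -> dict[str, float]:
    doc = yaml.safe_load(resources.files("mdain.data").joinpath("vdw_radii.yaml").read_text())
    table = {k.upper(): float(v) for k, v in doc["radii"].items()}
    table["__default__"] = float(doc.get("default", 1.70))
    return table


def load_hbond_templates() -> dict:
    return yaml.safe_load(
        resources.files("mdain.data").joinpath("hbond_templates.yaml").read_text()
    )


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric criteria of the van der Waals contact channel."""

    vdw_margin: float = 0.6
    sequence_exclusion: int = 4
    radii_table: dict = field(default_factory=load_radii_table)

    def __post_init__(self) -> None:
        if self.vdw_margin < 0 or self.sequence_exclusion < 0:
            raise ValueError("margin and sequence exclusion must be >= 0")
        if any(v <= 0 for v in self.radii_table.values()):
            raise ValueError("all radii must be positive")

    def radius(self, element: str) -> float:
        return self.radii_table.get(element.upper(), self.radii_table["__default__"])


@dataclass(frozen=True)
class HBondCriteria:
    """Hydrogen-bond geometry for the polar channel (HBPLUS-style defaults).

    When hydrogens are present the donor-hydrogen...acceptor test applies;
    structures stripped of hydrogens fall back to a tighter heavy-atom
    donor-acceptor cutoff.
    """

    donor_acceptor_max: float = 3.9
    hydrogen_acceptor_max: float = 2.5
    dha_angle_min: float = 90.0
    heavy_only_da_max: float = 3.5

    def __post_init__(self) -> None:
        if min(self.donor_acceptor_max, self.hydrogen_acceptor_max,
               self.heavy_only_da_max) <= 0:
            raise ValueError("distances must be positive")
        if not (0.0 <= self.dha_angle_min <= 180.0):
            raise ValueError("angle must be in [0, 180]")


def _canonical(a: int, b: int) -> Pair:
    return (a, b) if a < b else (b, a)


def _minimum_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return delta
    lengths = box[:3]
    if not np.allclose(box[3:], 90.0):
        return delta  # non-orthorhombic cells: raw distances
    return delta - lengths * np.round(delta / lengths)


def _protein_heavy_mask(frame: StructureFrame, include_waters_ions: bool) -> np.ndarray:
    mask = frame.is_heavy.copy()
    if not include_waters_ions:
        mask &= ~frame.is_water
        mask &= ~frame.is_ion
    return mask


def frame_contact_pairs(
    frame: StructureFrame,
    criteria: ContactCriteria | None = None,
    include_waters_ions: bool = False,
) -> set[Pair]:
    """All residue pairs in vdW contact in one frame.

    A pair is in contact iff some heavy-atom pair (u, v) satisfies the strict
    inequality d(u, v) < r(u) + r(v) + margin.  Same-chain pairs within the
    sequence-exclusion separation are never reported.
    """
    criteria = criteria or ContactCriteria()
    mask = _protein_heavy_mask(frame, include_waters_ions)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return set()
    coords = frame.coordinates[idx]
    radii = np.array([criteria.radius(e) for e in frame.elements[idx]])
    resid = frame.residue_indices[idx]
    chain = frame.chain_ids[idx]
    cutoff = 2.0 * radii.max() + criteria.vdw_margin

    box = frame.box
    use_pbc = box is not None and np.allclose(box[3:], 90.0)
    if use_pbc:
        wrapped = np.mod(coords, box[:3])
        tree = cKDTree(wrapped, boxsize=box[:3])
        candidates = tree.query_pairs(r=cutoff, output_type="ndarray")
        q = wrapped
    else:
        tree = cKDTree(coords)
        candidates = tree.query_pairs(r=cutoff, output_type="ndarray")
        q = coords

    pairs: set[Pair] = set()
    if len(candidates) == 0:
        return pairs
    i, j = candidates[:, 0], candidates[:, 1]
    delta = _minimum_image(q[i] - q[j], box if use_pbc else None)
    dist = np.linalg.norm(delta, axis=1)
    hit = dist < radii[i] + radii[j] + criteria.vdw_margin
    for a, b in zip(i[hit], j[hit]):
        ra, rb = int(resid[a]), int(resid[b])
        if ra == rb:
            continue
        if chain[a] == chain[b] and abs(ra - rb) <= criteria.sequence_exclusion:
            continue
        pairs.add(_canonical(ra, rb))
    return pairs


def residues_in_contact(
    frame: StructureFrame, res_a: int, res_b: int,
    criteria: ContactCriteria | None = None,
) -> bool:
    """Whether two specific residues are in vdW contact in this frame."""
    criteria = criteria or ContactCriteria()
    heavy = frame.is_heavy
    ia = np.flatnonzero((frame.residue_indices == res_a) & heavy)
    ib = np.flatnonzero((frame.residue_indices == res_b) & heavy)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("residue with zero heavy atoms")
    ca, cb = frame.chain_ids[ia[0]], frame.chain_ids[ib[0]]
    if ca == cb and abs(res_a - res_b) <= criteria.sequence_exclusion:
        return False
    delta = frame.coordinates[ia][:, None, :] - frame.coordinates[ib][None, :, :]
    if frame.box is not None and np.allclose(frame.box[3:], 90.0):
        delta = _minimum_image(delta, frame.box)
    dist = np.linalg.norm(delta, axis=-1)
    ra = np.array([criteria.radius(e) for e in frame.elements[ia]])
    rb = np.array([criteria.radius(e) for e in frame.elements[ib]])
    thr = ra[:, None] + rb[None, :] + criteria.vdw_margin
    return bool(np.any(dist < thr))


def _donor_acceptor_atoms(frame: StructureFrame, templates: dict,
                          include_waters_ions: bool):
    """Resolve donor (with attached hydrogens) and acceptor atom indices.

    Returns (donors, acceptors) where donors is a list of
    (atom_index, [hydrogen indices]) and acceptors a list of atom indices.
    Residues without a template are skipped with a single warning each.
    """
    backbone = templates["backbone"]
    residues = templates["residues"]
    donors: list[tuple[int, list[int]]] = []
    acceptors: list[int] = []
    warned: set[str] = set()

    order = np.lexsort((frame.residue_indices, frame.chain_ids))
    # group atom indices by residue
    groups: dict[tuple[str, int], list[int]] = {}
    for i in order:
        groups.setdefault((str(frame.chain_ids[i]), int(frame.residue_indices[i])), []).append(i)

    for (_, _), atom_idx in groups.items():
        resname = str(frame.residue_names[atom_idx[0]])
        if resname in WATER_NAMES or resname in ION_NAMES:
            if not include_waters_ions:
                continue
        tpl = residues.get(resname)
        if tpl is None and resname not in WATER_NAMES and resname not in ION_NAMES:
            if resname not in warned:
                logger.warning("no H-bond template for residue %s; skipped", resname)
                warned.add(resname)
            continue
        by_name: dict[str, list[int]] = {}
        for i in atom_idx:
            by_name.setdefault(str(frame.atom_names[i]), []).append(i)

        donor_specs = list(tpl["donors"]) if tpl else []
        acceptor_names = list(tpl["acceptors"]) if tpl else []
        if tpl is not None and not tpl.get("no_backbone_donor", False):
            donor_specs += backbone["donors"]
        if tpl is not None:
            acceptor_names += backbone["acceptors"]
        for dname, hnames in donor_specs:
            for di in by_name.get(dname, []):
                hs = [h for hn in hnames for h in by_name.get(hn, [])]
                donors.append((di, hs))
        for aname in acceptor_names:
            acceptors.extend(by_name.get(aname, []))
    return donors, acceptors


def frame_polar_pairs(
    frame: StructureFrame,
    criteria: HBondCriteria | None = None,
    include_waters_ions: bool = False,
    templates: dict | None = None,
) -> set[Pair]:
    """Residue pairs joined by a polar (hydrogen-bond) interaction in one frame.

    No sequence-separation exclusion applies: this channel exists to catch
    changes in short-range polar contacts such as backbone hydrogen bonds.
    """
    criteria = criteria or HBondCriteria()
    templates = templates or load_hbond_templates()
    donors, acceptors = _donor_acceptor_atoms(frame, templates, include_waters_ions)
    if not donors or not acceptors:
        return set()
    acc = np.asarray(acceptors)
    acc_tree = cKDTree(frame.coordinates[acc])
    pairs: set[Pair] = set()
    for di, hs in donors:
        d_xyz = frame.coordinates[di]
        near = acc_tree.query_ball_point(d_xyz, r=criteria.donor_acceptor_max)
        for k in near:
            ai = int(acc[k])
            res_d = int(frame.residue_indices[di])
            res_a = int(frame.residue_indices[ai])
            if res_d == res_a and frame.chain_ids[di] == frame.chain_ids[ai]:
                continue
            # the peptide-bond amide N(i+1) and carbonyl O(i) are covalently
            # adjacent (1-3 through C), never a hydrogen bond
            if (res_d == res_a + 1 and frame.chain_ids[di] == frame.chain_ids[ai]
                    and str(frame.atom_names[di]) == "N"
                    and str(frame.atom_names[ai]) in ("O", "OXT")):
                continue
            a_xyz = frame.coordinates[ai]
            if hs:
                ok = False
                for hi in hs:
                    h_xyz = frame.coordinates[hi]
                    if np.linalg.norm(h_xyz - a_xyz) > criteria.hydrogen_acceptor_max:
                        continue
                    v1 = d_xyz - h_xyz
                    v2 = a_xyz - h_xyz
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    if ang >= criteria.dha_angle_min:
                        ok = True
                        break
                if not ok:
                    continue
            else:
                if np.linalg.norm(d_xyz - a_xyz) > criteria.heavy_only_da_max:
                    continue
            pairs.add(_canonical(res_d, res_a))
    return pairs


def frame_interactions(
    frame: StructureFrame,
    contact_criteria: ContactCriteria | None = None,
    hbond_criteria: HBondCriteria | None = None,
) -> set[Pair]:
    """Union of the contact and polar channels for one frame."""
    return frame_contact_pairs(frame, contact_criteria) | frame_polar_pairs(
        frame, hbond_criteria
    )


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

@dataclass
class InteractionFrequencyTable:
    """Residue-pair interaction frequencies of one condition.

    ``per_replica[pair]`` holds one frequency per replica; the overall
    frequency is the frame-weighted mean.  ``per_frame`` (optional) retains
    the boolean presence series per replica for block-bootstrap testing.
    """

    condition: str
    n_frames: list[int]
    per_replica: dict[Pair, np.ndarray]
    per_frame: dict[Pair, list[np.ndarray]] | None = None

    def __post_init__(self) -> None:
        for pair, freqs in self.per_replica.items():
            if np.any((freqs < 0) | (freqs > 1)):
                raise ValueError(f"frequency outside [0,1] for pair {pair}")

    @property
    def n_replicas(self) -> int:
        return len(self.n_frames)

    def pairs(self) -> set[Pair]:
        return set(self.per_replica)

    def frequency(self, pair: Pair) -> float:
        freqs = self.per_replica.get(pair)
        if freqs is None:
            return 0.0
        w = np.asarray(self.n_frames, dtype=float)
        return float(np.dot(freqs, w) / w.sum())

    def replica_frequencies(self, pair: Pair) -> np.ndarray:
        freqs = self.per_replica.get(pair)
        if freqs is None:
            return np.zeros(self.n_replicas)
        return np.asarray(freqs, dtype=float)


def table_from_frame_sets(
    condition: str,
    replica_frame_sets: list[list[set[Pair]]],
    keep_per_frame: bool = True,
) -> InteractionFrequencyTable:
    """Build a frequency table from per-replica lists of per-frame pair sets."""
    n_frames = [len(fs) for fs in replica_frame_sets]
    if any(n == 0 for n in n_frames):
        raise ValueError("every replica needs at least one frame")
    universe: set[Pair] = set()
    for fs in replica_frame_sets:
        for s in fs:
            universe |= s
    per_replica: dict[Pair, np.ndarray] = {}
    per_frame: dict[Pair, list[np.ndarray]] = {}
    for pair in universe:
        series = [np.array([pair in s for s in fs], dtype=bool) for fs in replica_frame_sets]
        per_frame[pair] = series
        per_replica[pair] = np.array([s.mean() for s in series])
    return InteractionFrequencyTable(
        condition=condition, n_frames=n_frames, per_replica=per_replica,
        per_frame=per_frame if keep_per_frame else None,
    )


def ensemble_frequencies(
    ensemble: ConditionEnsemble,
    contact_criteria: ContactCriteria | None = None,
    hbond_criteria: HBondCriteria | None = None,
    keep_per_frame: bool = True,
) -> InteractionFrequencyTable:
    """Interaction frequency of every residue pair over the masked-in frames."""
    replica_sets: list[list[set[Pair]]] = []
    for r in range(ensemble.n_replicas):
        frames = ensemble.masked_frames(r)
        if not frames:
            raise ValueError(f"replica {r} has no masked-in frames")
        replica_sets.append(
            [frame_interactions(f, contact_criteria, hbond_criteria) for f in frames]
        )
    return table_from_frame_sets(ensemble.condition_name, replica_sets, keep_per_frame)


# ---------------------------------------------------------------------------
# Differential statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DifferentialEdge:
    """A residue pair whose interaction frequency differs between two conditions."""

    pair: Pair
    freq_a: float
    freq_b: float
    p_value: float
    q_value: float

    @property
    def delta(self) -> float:
        return self.freq_a - self.freq_b

    @property
    def direction(self) -> str:
        return "higher_in_a" if self.delta > 0 else "higher_in_b"


def _welch_p(x: np.ndarray, y: np.ndarray) -> float:
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        return 1.0 if x.mean() == y.mean() else 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def _block_bootstrap_p(
    series_a: list[np.ndarray], series_b: list[np.ndarray],
    block_length: int, n_boot: int, rng: np.random.Generator,
) -> float:
    """Two-sided circular block bootstrap p-value for H0: freq difference = 0."""
    def resample_mean(series: list[np.ndarray]) -> float:
        total, count = 0.0, 0
        for s in series:
            n = len(s)
            b = min(block_length, n)
            n_blocks = int(np.ceil(n / b))
            starts = rng.integers(0, n, size=n_blocks)
            idx = (starts[:, None] + np.arange(b)[None, :]) % n
            sel = s[idx].ravel()[:n]
            total += sel.sum()
            count += n
        return total / count

    obs = (np.concatenate(series_a).mean() - np.concatenate(series_b).mean())
    boots = np.array([resample_mean(series_a) - resample_mean(series_b)
                      for _ in range(n_boot)])
    centered = boots - boots.mean()
    # p: how often the centered bootstrap difference is as extreme as observed
    p = (np.sum(np.abs(centered) >= abs(obs)) + 1) / (n_boot + 1)
    return float(min(1.0, p))


def differential_pairs(
    table_a: InteractionFrequencyTable,
    table_b: InteractionFrequencyTable,
    alpha: float = 0.05,
    method: str = "replica_t",
    block_length: int = 20,
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[DifferentialEdge]:
    """Residue pairs whose interaction frequency differs significantly.

    ``replica_t`` (default, needs >= 2 replicas in each condition): Welch
    unequal-variance t-test on per-replica frequencies.  ``block_bootstrap``:
    circular block bootstrap over the per-frame presence series (robust for
    single-replica conditions).  q-values are Benjamini-Hochberg over all
    tested pairs; returned edges have q <= alpha, sorted by |delta| then pair.
    """
    pairs = sorted(table_a.pairs() | table_b.pairs())
    if not pairs:
        return []
    if method == "replica_t":
        if table_a.n_replicas < 2 or table_b.n_replicas < 2:
            raise ValueError("replica_t requires >= 2 replicas per condition")
        pvals = [
            _welch_p(table_a.replica_frequencies(p), table_b.replica_frequencies(p))
            for p in pairs
        ]
    elif method == "block_bootstrap":
        if table_a.per_frame is None or table_b.per_frame is None:
            raise ValueError("block_bootstrap requires per-frame series")
        rng = np.random.default_rng(seed)

        def series(table: InteractionFrequencyTable, pair: Pair) -> list[np.ndarray]:
            pf = table.per_frame.get(pair)
            if pf is None:
                pf = [np.zeros(n, dtype=bool) for n in table.n_frames]
            return [s.astype(float) for s in pf]

        pvals = [
            _block_bootstrap_p(series(table_a, p), series(table_b, p),
                               block_length, n_boot, rng)
            for p in pairs
        ]
    else:
        raise ValueError(f"unknown method {method!r}")

    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    edges = []
    for pair, p, q in zip(pairs, pvals, qvals):
        if q <= alpha:
            fa, fb = table_a.frequency(pair), table_b.frequency(pair)
            if fa == fb:
                continue  # identical frequencies carry no direction
            edges.append(DifferentialEdge(pair=pair, freq_a=fa, freq_b=fb,
                                          p_value=float(p), q_value=float(q)))
    edges.sort(key=lambda e: (-abs(e.delta), e.pair))
    return edges


def minmax_range_filter(
    tables: list[InteractionFrequencyTable],
    threshold: float = 0.3,
    anchor_residues: set[int] | None = None,
    anchor_distance: float = 3.0,
    frames: list[StructureFrame] | None = None,
) -> list[Pair]:
    """Pairs whose frequency range (max - min) across conditions meets the threshold.

    With ``anchor_residues`` given (e.g. the intracellular-gate residues), the
    result is restricted to pairs having any atom within ``anchor_distance``
    of an anchor residue in any of the supplied ``frames``.
    """
    if len(tables) < 2:
        raise ValueError("need at least two condition tables")
    universe: set[Pair] = set()
    for t in tables:
        universe |= t.pairs()
    kept = [
        p for p in sorted(universe)
        if max(t.frequency(p) for t in tables) - min(t.frequency(p) for t in tables)
        >= threshold
    ]
    if anchor_residues is None:
        return kept
    if frames is None:
        raise ValueError("anchor filtering requires frames to measure proximity")
    near: set[int] = set()
    for frame in frames:
        anchor_idx = np.flatnonzero(np.isin(frame.residue_indices, sorted(anchor_residues)))
        if len(anchor_idx) == 0:
            continue
        tree = cKDTree(frame.coordinates[anchor_idx])
        d, _ = tree.query(frame.coordinates, k=1)
        near |= {int(r) for r in frame.residue_indices[d <= anchor_distance]}
    return [p for p in kept if p[0] in near or p[1] in near]


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def write_frequency_table(table: InteractionFrequencyTable, path) -> None:
    """Tab-separated frequencies: res_a, res_b, frequency, then one column per replica."""
    with open(path, "w") as fh:
        reps = "\t".join(f"rep{i + 1}" for i in range(table.n_replicas))
        fh.write(f"# condition={table.condition}\n")
        fh.write(f"# n_frames={','.join(map(str, table.n_frames))}\n")
        fh.write(f"res_a\tres_b\tfrequency\t{reps}\n")
        for pair in sorted(table.pairs()):
            freqs = "\t".join(f"{v:.6f}" for v in table.replica_frequencies(pair))
            fh.write(f"{pair[0]}\t{pair[1]}\t{table.frequency(pair):.6f}\t{freqs}\n")


def read_frequency_table(path) -> InteractionFrequencyTable:
    condition, n_frames, per_replica = "unknown", None, {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# condition="):
                condition = line.split("=", 1)[1]
            elif line.startswith("# n_frames="):
                n_frames = [int(x) for x in line.split("=", 1)[1].split(",")]
            elif line.startswith("res_a") or not line:
                continue
            else:
                parts = line.split("\t")
                pair = (int(parts[0]), int(parts[1]))
                per_replica[pair] = np.array([float(x) for x in parts[3:]])
    if n_frames is None:
        raise ValueError("missing n_frames header")
    return InteractionFrequencyTable(condition=condition, n_frames=n_frames,
                                     per_replica=per_replica)


def write_differential_edges(edges: list[DifferentialEdge], path,
                             condition_a: str = "a", condition_b: str = "b") -> None:
    with open(path, "w") as fh:
        fh.write(f"res_a\tres_b\tfreq_{condition_a}\tfreq_{condition_b}\tdelta\tp\tq\tdirection\n")
        for e in edges:
            fh.write(f"{e.pair[0]}\t{e.pair[1]}\t{e.freq_a:.6f}\t{e.freq_b:.6f}"
                     f"\t{e.delta:.6f}\t{e.p_value:.3e}\t{e.q_value:.3e}\t{e.direction}\n")


def read_differential_edges(path) -> list[DifferentialEdge]:
    edges = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            parts = line.split("\t")
            edges.append(DifferentialEdge(
                pair=(int(parts[0]), int(parts[1])),
                freq_a=float(parts[2]), freq_b=float(parts[3]),
                p_value=float(parts[5]), q_value=float(parts[6]),
            ))
    return edges
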