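"""Per-frame geometric observables: vestibule water counts, cation binding-site
states, chi1 rotamers, and conditional occupancy summaries.

The extracellular-vestibule (EV) openness of a transporter frame is measured
as the number of water molecules inside a user-defined region (the convex
hull of lining-residue heavy atoms, or an explicit cylinder).  Cation
binding-site states are classified from the distance between the mobile
cation near the Na1/Na1' sites and the cation fixed in the Na2 site:
Na1-bound below 8.3 Å, in transition up to 10.7 Å, and in the alternative
Na1' state beyond.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .model import ConditionEnsemble, StructureFrame

STATES = ("Na1", "transition", "Na1prime")

#: gamma heavy atom defining chi1 per residue type
CHI1_GAMMA = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "HSD": "CG", "HSE": "CG", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "TRP": "CG", "TYR": "CG",
    "SER": "OG", "THR": "OG1", "CYS": "SG", "VAL": "CG1", "ILE": "CG1",
}


class UndefinedDihedral(ValueError):
    """Raised when a residue lacks the atoms that define chi1 (Gly/Ala)."""


@dataclass(frozen=True)
class RegionSpec:
    """A spatial region: convex hull of lining residues, or an explicit cylinder."""

    mode: str = "convex_hull"  # or "cylinder"
    lining_residues: frozenset[int] = frozenset()
    cylinder_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cylinder_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    cylinder_radius: float = 0.0
    z_bounds: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.mode == "convex_hull" and not self.lining_residues:
            raise ValueError("convex_hull mode needs lining residues")
        if self.mode == "cylinder":
            if self.cylinder_radius <= 0 or self.z_bounds[0] >= self.z_bounds[1]:
                raise ValueError("cylinder needs radius > 0 and z_bounds lo < hi")
        if self.mode not in ("convex_hull", "cylinder"):
            raise ValueError(f"unknown region mode {self.mode!r}")


def count_region_waters(frame: StructureFrame, region: RegionSpec) -> int:
    """Number of water oxygens inside the region (closed: boundary counts in)."""
    water_ox = np.flatnonzero(frame.is_water & (frame.elements == "O"))
    if len(water_ox) == 0:
        return 0
    pts = frame.coordinates[water_ox]
    if region.mode == "cylinder":
        axis = np.asarray(region.cylinder_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        rel = pts - np.asarray(region.cylinder_origin, dtype=float)
        z = rel @ axis
        radial = np.linalg.norm(rel - np.outer(z, axis), axis=1)
        inside = (
            (z >= region.z_bounds[0]) & (z <= region.z_bounds[1])
            & (radial <= region.cylinder_radius)
        )
        return int(inside.sum())
    lining = np.flatnonzero(
        np.isin(frame.residue_indices, sorted(region.lining_residues)) & frame.is_heavy
    )
    hull_pts = frame.coordinates[lining]
    if len(hull_pts) < 4 or np.linalg.matrix_rank(hull_pts - hull_pts.mean(axis=0)) < 3:
        raise ValueError("degenerate hull: need >= 4 non-coplanar lining atoms")
    tri = Delaunay(hull_pts)
    return int(np.sum(tri.find_simplex(pts) >= 0))


@dataclass(frozen=True)
class CationStateThresholds:
    """Distance thresholds (Å, cation-to-Na2 distance) separating the states."""

    na1_max: float = 8.3
    transition_max: float = 10.7

    def __post_init__(self) -> None:
        if not (0.0 < self.na1_max < self.transition_max):
            raise ValueError("need 0 < na1_max < transition_max")


def classify_cation_state(distance: float,
                          thresholds: CationStateThresholds | None = None) -> str:
    """Na1 if d < na1_max; transition if na1_max <= d < transition_max; else Na1prime."""
    thresholds = thresholds or CationStateThresholds()
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if distance < thresholds.na1_max:
        return "Na1"
    if distance < thresholds.transition_max:
        return "transition"
    return "Na1prime"


@dataclass
class SiteTrace:
    """Per-frame cation-to-Na2 distances and their state classification."""

    times: np.ndarray
    distances: np.ndarray
    states: list[str]
    thresholds: CationStateThresholds = field(default_factory=CationStateThresholds)

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.distances) == len(self.states)):
            raise ValueError("times, distances, states must have equal length")

    def segments(self) -> list[tuple[str, int, int]]:
        """Contiguous same-state runs as (state, first_index, last_index)."""
        if not self.states:
            return []
        out, start = [], 0
        for i in range(1, len(self.states)):
            if self.states[i] != self.states[start]:
                out.append((self.states[start], start, i - 1))
                start = i
        out.append((self.states[start], start, len(self.states) - 1))
        return out


def trace_from_distances(times, distances,
                         thresholds: CationStateThresholds | None = None) -> SiteTrace:
    thresholds = thresholds or CationStateThresholds()
    distances = np.asarray(distances, dtype=float)
    states = [classify_cation_state(d, thresholds) for d in distances]
    return SiteTrace(times=np.asarray(times, dtype=float), distances=distances,
                     states=states, thresholds=thresholds)


def _resolve_single_atom(frame: StructureFrame, selector: dict) -> int:
    idx = frame.select(**selector)
    if len(idx) != 1:
        raise ValueError(f"selector {selector} resolved to {len(idx)} atoms (need 1)")
    return int(idx[0])


def site_trace(
    ensemble: ConditionEnsemble,
    cation_selector: dict,
    na2_selector: dict,
    thresholds: CationStateThresholds | None = None,
) -> list[SiteTrace]:
    """One state trace per replica from the mobile-cation-to-Na2 distance.

    Selectors are keyword dicts for :meth:`StructureFrame.select` (e.g.
    ``{"residue_name": "SOD", "residue_index": 601}``) and must resolve to
    exactly one atom per frame.
    """
    thresholds = thresholds or CationStateThresholds()
    traces = []
    for r in range(ensemble.n_replicas):
        frames = ensemble.masked_frames(r)
        times, dists = [], []
        for f in frames:
            ci = _resolve_single_atom(f, cation_selector)
            ni = _resolve_single_atom(f, na2_selector)
            times.append(f.frame_time)
            dists.append(float(np.linalg.norm(f.coordinates[ci] - f.coordinates[ni])))
        traces.append(trace_from_distances(times, dists, thresholds))
    return traces


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral of four points, degrees in (-180, 180] (-180 -> +180)."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 + 1e-12 else ang


def chi1_angle(frame: StructureFrame, residue_index: int, chain_id: str | None = None) -> float:
    """Side-chain chi1 dihedral N-CA-CB-gamma of one residue, in (-180, 180]."""
    sel: dict = {"residue_index": residue_index}
    if chain_id is not None:
        sel["chain_id"] = chain_id
    mask = frame.residue_indices == residue_index
    if chain_id is not None:
        mask &= frame.chain_ids == chain_id
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise KeyError(f"residue {residue_index} not in frame")
    resname = str(frame.residue_names[idx[0]])
    gamma_name = CHI1_GAMMA.get(resname)
    if gamma_name is None:
        raise UndefinedDihedral(f"chi1 undefined for residue type {resname}")
    coords = {}
    for name in ("N", "CA", "CB", gamma_name):
        hit = idx[frame.atom_names[idx] == name]
        if len(hit) == 0:
            raise UndefinedDihedral(f"residue {residue_index} lacks atom {name}")
        coords[name] = frame.coordinates[int(hit[0])]
    return dihedral_angle(coords["N"], coords["CA"], coords["CB"], coords[gamma_name])


def rotamer_label(chi1: float) -> str:
    """gauche- for chi1 in [-120, 0), gauche+ for [0, 120), trans otherwise."""
    if not np.isfinite(chi1):
        raise ValueError("chi1 must be finite")
    x = ((chi1 + 180.0) % 360.0) - 180.0  # wrap into (-180, 180]
    if x == -180.0:
        x = 180.0
    if -120.0 <= x < 0.0:
        return "gauche_minus"
    if 0.0 <= x < 120.0:
        return "gauche_plus"
    return "trans"


def conditional_occupancy(
    openness: np.ndarray,
    states: list[str],
    fraction: float = 0.20,
) -> tuple[float, int, int]:
    """Na1 : Na1' occupancy ratio among the most-open fraction of frames.

    ``openness`` (e.g. EV water counts) and ``states`` are pooled, frame
    aligned, across all conditions of interest.  The top ``fraction`` frames
    by openness are kept (ties broken toward inclusion), transition frames
    are excluded, and the ratio #Na1 / #Na1prime is returned together with
    both counts.  With zero Na1' frames the ratio is ``inf``.
    """
    openness = np.asarray(openness, dtype=float)
    if len(openness) != len(states):
        raise ValueError("openness and states must be frame-aligned")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    n_keep = max(1, int(np.ceil(fraction * len(openness))))
    order = np.argsort(-openness, kind="stable")
    top = order[:n_keep]
    n_na1 = sum(1 for i in top if states[i] == "Na1")
    n_prime = sum(1 for i in top if states[i] == "Na1prime")
    ratio = float("inf") if n_prime == 0 else n_na1 / n_prime
    return ratio, n_na1, n_prime


def write_trace(trace: SiteTrace, path) -> None:
    """Tab-separated observable series: time_ps, distance_A, state."""
    with open(path, "w") as fh:
        fh.write("time_ps\tdistance_A\tstate\n")
        for t, d, s in zip(trace.times, trace.distances, trace.states):
            fh.write(f"{t:.3f}\t{d:.4f}\t{s}\n")
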