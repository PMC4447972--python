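"""Independent brute-force oracles used to cross-check the analysis code.

These deliberately avoid the package's vectorised/KD-tree code paths: plain
double loops over residues and atoms, recomputing every criterion from its
definition.  They share only the packaged data tables (radii, donor/acceptor
typing), never the detection code.
"""

import numpy as np

from mdain.interactions import load_hbond_templates, load_radii_table
from mdain.model import ION_NAMES, WATER_NAMES, StructureFrame

Pair = tuple[int, int]


def _residue_atoms(frame: StructureFrame) -> dict[tuple[str, int], list[int]]:
    groups: dict[tuple[str, int], list[int]] = {}
    for i in range(frame.n_atoms):
        groups.setdefault(
            (str(frame.chain_ids[i]), int(frame.residue_indices[i])), []
        ).append(i)
    return groups


def brute_force_contacts(frame: StructureFrame, vdw_margin: float = 0.6,
                         sequence_exclusion: int = 4) -> set[Pair]:
    radii = load_radii_table()
    groups = _residue_atoms(frame)
    keys = [k for k in groups
            if str(frame.residue_names[groups[k][0]]) not in WATER_NAMES | ION_NAMES]
    pairs: set[Pair] = set()
    for ii in range(len(keys)):
        for jj in range(ii + 1, len(keys)):
            (ca, ra), (cb, rb) = keys[ii], keys[jj]
            if ca == cb and abs(ra - rb) <= sequence_exclusion:
                continue
            hit = False
            for u in groups[keys[ii]]:
                if frame.elements[u] == "H":
                    continue
                for v in groups[keys[jj]]:
                    if frame.elements[v] == "H":
                        continue
                    d = float(np.linalg.norm(frame.coordinates[u] - frame.coordinates[v]))
                    r_u = radii.get(str(frame.elements[u]).upper(), radii["__default__"])
                    r_v = radii.get(str(frame.elements[v]).upper(), radii["__default__"])
                    if d < r_u + r_v + vdw_margin:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                pairs.add((min(ra, rb), max(ra, rb)))
    return pairs


def brute_force_polar(frame: StructureFrame, donor_acceptor_max: float = 3.9,
                      hydrogen_acceptor_max: float = 2.5, dha_angle_min: float = 90.0,
                      heavy_only_da_max: float = 3.5) -> set[Pair]:
    templates = load_hbond_templates()
    backbone = templates["backbone"]
    residues = templates["residues"]
    groups = _residue_atoms(frame)

    def res_donors_acceptors(key):
        idx = groups[key]
        resname = str(frame.residue_names[idx[0]])
        tpl = residues.get(resname)
        if tpl is None:
            return [], []
        by_name: dict[str, list[int]] = {}
        for i in idx:
            by_name.setdefault(str(frame.atom_names[i]), []).append(i)
        donors = []
        specs = list(tpl["donors"])
        if not tpl.get("no_backbone_donor", False):
            specs += backbone["donors"]
        for dname, hnames in specs:
            for di in by_name.get(dname, []):
                donors.append((di, [h for hn in hnames for h in by_name.get(hn, [])]))
        acceptors = []
        for aname in list(tpl["acceptors"]) + backbone["acceptors"]:
            acceptors.extend(by_name.get(aname, []))
        return donors, acceptors

    keys = list(groups)
    pairs: set[Pair] = set()
    for ka in keys:
        for kb in keys:
            if ka == kb:
                continue
            donors, _ = res_donors_acceptors(ka)
            _, acceptors = res_donors_acceptors(kb)
            for di, hs in donors:
                for ai in acceptors:
                    res_d = int(frame.residue_indices[di])
                    res_a = int(frame.residue_indices[ai])
                    if (ka[0] == kb[0] and res_d == res_a + 1
                            and str(frame.atom_names[di]) == "N"
                            and str(frame.atom_names[ai]) in ("O", "OXT")):
                        continue  # covalent amide adjacency
                    d_xyz = frame.coordinates[di]
                    a_xyz = frame.coordinates[ai]
                    if np.linalg.norm(d_xyz - a_xyz) > donor_acceptor_max:
                        continue
                    if hs:
                        ok = False
                        for hi in hs:
                            h_xyz = frame.coordinates[hi]
                            if np.linalg.norm(h_xyz - a_xyz) > hydrogen_acceptor_max:
                                continue
                            v1, v2 = d_xyz - h_xyz, a_xyz - h_xyz
                            cosang = np.dot(v1, v2) / (
                                np.linalg.norm(v1) * np.linalg.norm(v2))
                            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= dha_angle_min:
                                ok = True
                                break
                        if not ok:
                            continue
                    else:
                        if np.linalg.norm(d_xyz - a_xyz) > heavy_only_da_max:
                            continue
                    pairs.add((min(res_d, res_a), max(res_d, res_a)))
    return pairs


def brute_force_interactions(frame: StructureFrame) -> set[Pair]:
    return brute_force_contacts(frame) | brute_force_polar(frame)
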