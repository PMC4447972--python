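"""Contact/polar detection, frequency tables, differential statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdain.interactions import (ContactCriteria, HBondCriteria,
                                differential_pairs, ensemble_frequencies,
                                frame_contact_pairs, frame_interactions,
                                frame_polar_pairs, minmax_range_filter,
                                read_frequency_table, residues_in_contact,
                                table_from_frame_sets, write_frequency_table)
from mdain.model import StructureFrame
from mdain.synthetic import (PlantedInteractionModel,
                             make_interaction_trajectory,
                             simulate_frequency_tables)

from .oracles import brute_force_interactions, brute_force_polar
from .conftest import random_frame


def two_carbon_frame(distance: float, res_sep: int = 6) -> StructureFrame:
    return StructureFrame(
        atom_names=np.array(["CA", "CA"]),
        elements=np.array(["C", "C"]),
        residue_indices=np.array([1, 1 + res_sep]),
        residue_names=np.array(["ALA", "ALA"]),
        chain_ids=np.array(["A", "A"]),
        coordinates=np.array([[0.0, 0, 0], [distance, 0, 0]]),
    )


class TestContacts:
    def test_carbon_pair_inside_threshold(self):
        # threshold = 1.70 + 1.70 + 0.6 = 4.00 A
        frame = two_carbon_frame(3.90)
        assert residues_in_contact(frame, 1, 7)

    def test_boundary_is_strict(self):
        frame = two_carbon_frame(4.00)
        assert not residues_in_contact(frame, 1, 7)

    @pytest.mark.parametrize("sep", [0, 1, 4])
    def test_sequence_exclusion(self, sep):
        if sep == 0:
            return
        frame = two_carbon_frame(1.0, res_sep=sep)
        assert not residues_in_contact(frame, 1, 1 + sep)
        assert frame_contact_pairs(frame) == set()

    def test_five_apart_not_excluded(self):
        frame = two_carbon_frame(3.0, res_sep=5)
        assert frame_contact_pairs(frame) == {(1, 6)}

    def test_margin_monotonicity(self):
        rng = np.random.default_rng(11)
        frame = random_frame(20, rng)
        small = frame_contact_pairs(frame, ContactCriteria(vdw_margin=0.3))
        large = frame_contact_pairs(frame, ContactCriteria(vdw_margin=0.9))
        assert small <= large

    def test_periodic_contact_through_boundary(self):
        frame = two_carbon_frame(0.0)
        frame.coordinates = np.array([[0.5, 5.0, 5.0], [19.5, 5.0, 5.0]])
        frame.box = np.array([20.0, 10.0, 10.0, 90.0, 90.0, 90.0])
        assert frame_contact_pairs(frame) == {(1, 7)}  # 1 A through the wall

    def test_zero_heavy_atom_residue_rejected(self):
        frame = two_carbon_frame(3.0)
        frame.elements = np.array(["H", "C"])
        with pytest.raises(ValueError, match="zero heavy"):
            residues_in_contact(frame, 1, 7)


class TestPolar:
    def test_canonical_helix_hbond_with_hydrogen(self):
        # N-H...O at 2.9 A donor-acceptor, D-H-A 160 degrees
        o = np.array([0.0, 0.0, 0.0])
        h = np.array([1.95, 0.0, 0.0])
        d = h + 1.0 * np.array([np.cos(np.radians(20)), np.sin(np.radians(20)), 0])
        frame = StructureFrame(
            atom_names=np.array(["O", "N", "H"]),
            elements=np.array(["O", "N", "H"]),
            residue_indices=np.array([1, 5, 5]),
            residue_names=np.array(["ALA", "ALA", "ALA"]),
            chain_ids=np.array(["A"] * 3),
            coordinates=np.vstack([o, d, h]),
        )
        assert frame_polar_pairs(frame) == {(1, 5)}

    def test_distant_donor_acceptor_not_reported(self):
        frame = StructureFrame(
            atom_names=np.array(["O", "N"]),
            elements=np.array(["O", "N"]),
            residue_indices=np.array([1, 5]),
            residue_names=np.array(["ALA", "ALA"]),
            chain_ids=np.array(["A", "A"]),
            coordinates=np.array([[0.0, 0, 0], [4.5, 0, 0]]),
        )
        assert frame_polar_pairs(frame) == set()

    def test_planted_hbond_found_exactly(self):
        rng = np.random.default_rng(5)
        # 20 well-separated residues, then one planted serine-to-carbonyl bond
        frame = random_frame(20, rng, box_side=200.0)
        og = frame.select(residue_name="SER", atom_name="OG")
        o = frame.select(atom_name="O")
        if len(og) == 0:
            pytest.skip("no serine drawn")  # deterministic rng: never happens
        donor, acceptor = int(og[0]), int(o[-1])
        if frame.residue_indices[donor] == frame.residue_indices[acceptor]:
            acceptor = int(o[0])
        frame.coordinates[acceptor] = frame.coordinates[donor] + [3.0, 0, 0]
        expect = (min(frame.residue_indices[donor], frame.residue_indices[acceptor]),
                  max(frame.residue_indices[donor], frame.residue_indices[acceptor]))
        found = frame_polar_pairs(frame)
        assert expect in found
        assert found == brute_force_polar(frame)

    def test_no_sequence_exclusion_in_polar_channel(self, helix12):
        pairs = frame_polar_pairs(helix12)
        assert {(i, i + 4) for i in range(1, 9)} <= pairs


class TestFrameInteractions:
    def test_union_semantics(self, helix12):
        union = frame_interactions(helix12)
        assert union == frame_contact_pairs(helix12) | frame_polar_pairs(helix12)

    def test_empty_frame(self):
        frame = StructureFrame(
            atom_names=np.array([], dtype="U8"), elements=np.array([], dtype="U4"),
            residue_indices=np.array([], dtype=int),
            residue_names=np.array([], dtype="U8"),
            chain_ids=np.array([], dtype="U4"), coordinates=np.zeros((0, 3)),
        )
        assert frame_interactions(frame) == set()

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        frame = random_frame(int(rng.integers(10, 31)), rng)
        assert frame_interactions(frame) == brute_force_interactions(frame)

    def test_pairs_canonical(self):
        rng = np.random.default_rng(2)
        frame = random_frame(15, rng)
        assert all(a < b for a, b in frame_interactions(frame))


class TestFrequencies:
    def test_half_frequency(self):
        sets = [[{(1, 9)} if t < 50 else set() for t in range(100)]]
        table = table_from_frame_sets("c", sets)
        assert table.frequency((1, 9)) == 0.5

    def test_absent_pair_implicit_zero(self):
        table = table_from_frame_sets("c", [[set(), set()]])
        assert table.frequency((3, 12)) == 0.0
        assert (3, 12) not in table.pairs()

    def test_planted_probability_recovered(self):
        model = PlantedInteractionModel(
            n_residues=12, pair_probabilities={"c": {(1, 8): 0.7}},
            n_frames=2000, n_replicas=1, seed=42)
        ens, _ = make_interaction_trajectory(model)
        table = ensemble_frequencies(ens["c"])
        se = np.sqrt(0.7 * 0.3 / 2000)
        assert abs(table.frequency((1, 8)) - 0.7) < 3 * se

    def test_replica_and_frame_order_invariance(self):
        rng = np.random.default_rng(0)
        sets = [[{(1, 9)} if rng.random() < 0.4 else set() for _ in range(60)]
                for _ in range(3)]
        t1 = table_from_frame_sets("c", sets)
        t2 = table_from_frame_sets("c", [list(reversed(s)) for s in reversed(sets)])
        assert t1.frequency((1, 9)) == pytest.approx(t2.frequency((1, 9)))

    def test_weighted_mean_consistency(self):
        sets = [[{(1, 9)}] * 10, [set()] * 30]
        table = table_from_frame_sets("c", sets)
        assert table.frequency((1, 9)) == pytest.approx(10 / 40)

    def test_round_trip_tsv(self, tmp_path):
        sets = [[{(1, 9), (2, 11)}, {(1, 9)}], [{(2, 11)}, set()]]
        table = table_from_frame_sets("c", sets)
        p = tmp_path / "freq.tsv"
        write_frequency_table(table, p)
        back = read_frequency_table(p)
        assert back.condition == "c"
        assert back.pairs() == table.pairs()
        for pair in table.pairs():
            assert back.frequency(pair) == pytest.approx(table.frequency(pair))


class TestDifferential:
    def test_identical_tables_no_edges(self):
        sets = [[{(1, 9)}] * 10 + [set()] * 10 for _ in range(2)]
        t = table_from_frame_sets("a", sets)
        assert differential_pairs(t, t) == []

    def test_planted_difference_detected(self):
        model = PlantedInteractionModel(
            n_residues=20, pair_probabilities={"a": {(1, 11): 0.9}, "b": {(1, 11): 0.4}},
            persistence=0.0, n_frames=1000, n_replicas=3, seed=1)
        tabs = simulate_frequency_tables(model)
        edges = differential_pairs(tabs["a"], tabs["b"])
        assert [e.pair for e in edges] == [(1, 11)]
        e = edges[0]
        assert e.direction == "higher_in_a"
        assert e.delta == pytest.approx(e.freq_a - e.freq_b)
        assert 0 <= e.q_value <= 1

    def test_single_replica_requires_bootstrap(self):
        model = PlantedInteractionModel(
            n_residues=20, pair_probabilities={"a": {(1, 11): 0.9}, "b": {(1, 11): 0.2}},
            n_frames=400, n_replicas=1, seed=2)
        tabs = simulate_frequency_tables(model)
        with pytest.raises(ValueError, match="replica"):
            differential_pairs(tabs["a"], tabs["b"], method="replica_t")
        edges = differential_pairs(tabs["a"], tabs["b"], method="block_bootstrap",
                                   seed=0, n_boot=400)
        assert [e.pair for e in edges] == [(1, 11)]

    def test_bootstrap_null_retains_nothing_obvious(self):
        model = PlantedInteractionModel(
            n_residues=20, pair_probabilities={"a": {(1, 11): 0.5}, "b": {(1, 11): 0.5}},
            persistence=0.9, n_frames=800, n_replicas=1, seed=3)
        tabs = simulate_frequency_tables(model)
        edges = differential_pairs(tabs["a"], tabs["b"], method="block_bootstrap",
                                   block_length=20, seed=0, n_boot=400)
        assert edges == []


class TestMinMaxRange:
    def test_threshold_inclusive(self):
        t1 = table_from_frame_sets("a", [[{(1, 9)}] * 2 + [set()] * 8])   # 0.2
        t2 = table_from_frame_sets("b", [[{(1, 9)}] * 6 + [set()] * 4])   # 0.6
        t3 = table_from_frame_sets("c", [[{(1, 9)}] * 5 + [set()] * 5])   # 0.5
        assert minmax_range_filter([t1, t2, t3], threshold=0.3) == [(1, 9)]
        assert minmax_range_filter([t3, t2], threshold=0.3) == []  # range 0.1

    def test_planted_ranges_match_oracle(self):
        rng = np.random.default_rng(8)
        freqs = {(i, i + 10): rng.uniform(0, 1, size=3) for i in range(1, 11)}
        tables = []
        for c in range(3):
            n = 50
            sets = [[{p for p, f in freqs.items() if t < round(f[c] * n)}
                     for t in range(n)]]
            tables.append(table_from_frame_sets(f"c{c}", sets))
        got = minmax_range_filter(tables, threshold=0.3)
        expect = sorted(
            p for p, f in freqs.items()
            if max(round(x * 50) / 50 for x in f) - min(round(x * 50) / 50 for x in f)
            >= 0.3
        )
        assert got == expect

    def test_anchor_restriction(self):
        t1 = table_from_frame_sets("a", [[{(1, 9), (20, 30)}] * 9 + [set()]])
        t2 = table_from_frame_sets("b", [[set()] * 9 + [{(1, 9), (20, 30)}]])
        frame = two_carbon = StructureFrame(
            atom_names=np.array(["CA"] * 4), elements=np.array(["C"] * 4),
            residue_indices=np.array([1, 9, 20, 30]),
            residue_names=np.array(["ALA"] * 4), chain_ids=np.array(["A"] * 4),
            coordinates=np.array([[0.0, 0, 0], [2, 0, 0], [50, 0, 0], [52, 0, 0]]),
        )
        got = minmax_range_filter([t1, t2], threshold=0.3, anchor_residues={1},
                                  anchor_distance=3.0, frames=[frame])
        assert got == [(1, 9)]


@settings(max_examples=30, derandomize=True)
@given(st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
def test_frequency_table_rejects_out_of_range(f1, f2):
    # any in-range pair of frequencies is accepted; construction checks bounds
    from mdain.interactions import InteractionFrequencyTable
    t = InteractionFrequencyTable(condition="x", n_frames=[10, 10],
                                  per_replica={(1, 9): np.array([f1, f2])})
    assert 0.0 <= t.frequency((1, 9)) <= 1.0
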