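import networkx as nx
import numpy as np
import pytest
from scipy.spatial.distance import cdist

from allores.errors import ContractError
from allores.nanoenv import (
    NanoenvConfig,
    build_contact_graph,
    compute_descriptor_table,
    distance_to_cg,
    electrostatic_potential,
    graph_bottleneck,
    graph_eccentricity,
    hbond_energies,
    hydrophobicity_env,
    kabsch_sander_energies,
    kabsch_sander_pairs,
    sponge_fraction,
)
from allores.labeling import label_residues, records_to_frame
from allores.structures import Atom, Residue, Structure, strip_group

from conftest import structure_from_points
from oracles import betweenness_oracle, eccentricity_oracle, random_graph


def _nx_from_adj(adj):
    g = nx.Graph()
    g.add_nodes_from(range(len(adj)))
    g.add_edges_from(zip(*np.nonzero(np.triu(adj))))
    return g


def _single_res(res_name, coord=(0, 0, 0), seq=1, atom="CA"):
    return Residue("A", seq, "", res_name, [Atom(seq, atom, "C", np.asarray(coord, float), 1.7)])


class TestDistanceToCg:
    def test_single_residue_chain_zero(self):
        res = _single_res("ALA")
        assert distance_to_cg(res, res.atoms) == 0.0

    def test_symmetric_pair(self):
        a = _single_res("ALA", (4, 0, 0), 1)
        b = _single_res("ALA", (-4, 0, 0), 2)
        atoms = a.atoms + b.atoms
        assert distance_to_cg(a, atoms) == pytest.approx(4.0)
        assert distance_to_cg(b, atoms) == pytest.approx(4.0)

    def test_helix_matches_direct_arithmetic(self, helix20):
        chain = helix20.chains["A"]
        atoms = [a for r in chain for a in r.atoms]
        res = chain[0]
        all_coords = np.asarray([a.coord for a in atoms if a.is_heavy])
        res_coords = np.asarray([a.coord for a in res.atoms if a.is_heavy])
        expected = np.linalg.norm(res_coords.mean(0) - all_coords.mean(0))
        assert distance_to_cg(res, atoms) == pytest.approx(expected, abs=1e-6)


class TestContactGraph:
    def test_close_pair_one_edge(self):
        chain = [_single_res("ALA", (0, 0, 0), 1), _single_res("ALA", (3, 0, 0), 2)]
        g = build_contact_graph(chain, cutoff=5.0)
        assert g.number_of_edges() == 1

    def test_far_pair_no_edge(self):
        chain = [_single_res("ALA", (0, 0, 0), 1), _single_res("ALA", (30, 0, 0), 2)]
        assert build_contact_graph(chain, cutoff=5.0).number_of_edges() == 0

    def test_helix_matches_brute_force(self, helix20):
        chain = helix20.chains["A"][:10]
        g = build_contact_graph(chain, cutoff=5.0, structure_id=helix20.id)
        expected = set()
        for i in range(10):
            for j in range(i + 1, 10):
                d = cdist(chain[i].heavy_coords(), chain[j].heavy_coords()).min()
                if d <= 5.0:
                    expected.add(
                        frozenset(
                            {chain[i].identity(helix20.id), chain[j].identity(helix20.id)}
                        )
                    )
        assert {frozenset(e) for e in g.edges} == expected

    def test_empty_raises(self):
        with pytest.raises(ContractError):
            build_contact_graph([])


class TestGraphDescriptors:
    def test_path_graph_end_and_middle(self):
        g = nx.path_graph(5)
        assert graph_eccentricity(g, 0) == 4
        assert graph_eccentricity(g, 2) == 2

    def test_path_abc_bottleneck(self):
        g = nx.path_graph(3)
        assert graph_bottleneck(g, 1) == pytest.approx(1.0)
        assert graph_bottleneck(g, 0) == 0.0

    def test_unknown_node_raises(self):
        g = nx.path_graph(3)
        with pytest.raises(KeyError):
            graph_eccentricity(g, 99)
        with pytest.raises(KeyError):
            graph_bottleneck(g, 99)

    @pytest.mark.parametrize("seed", range(10))
    def test_eccentricity_matches_oracle(self, seed):
        adj = random_graph(12, 0.3, seed)
        g = _nx_from_adj(adj)
        for v in range(12):
            assert graph_eccentricity(g, v) == eccentricity_oracle(adj, v)

    @pytest.mark.parametrize("seed", range(10))
    def test_betweenness_matches_oracle(self, seed):
        adj = random_graph(8, 0.4, seed)
        g = _nx_from_adj(adj)
        for v in range(8):
            assert graph_bottleneck(g, v) == pytest.approx(
                betweenness_oracle(adj, v), abs=1e-9
            )


class TestSponge:
    def test_isolated_atom_nearly_all_void(self):
        s = structure_from_points([(0, 0, 0)])
        assert sponge_fraction(s, s.chains["A"][0]) > 0.99

    def test_dense_lattice_packing(self):
        # overlapping atoms on a 1.5 Å lattice fill the ball
        pts = [
            (1.5 * i, 1.5 * j, 1.5 * k)
            for i in range(-7, 8)
            for j in range(-7, 8)
            for k in range(-7, 8)
        ]
        s = structure_from_points(pts)
        centre = s.chains["A"][len(pts) // 2]
        assert sponge_fraction(s, centre) < 0.35

    def test_deleting_atom_never_decreases(self, helix20):
        res = helix20.chains["A"][10]
        full = sponge_fraction(helix20, res)
        shorter = Structure(id=helix20.id, chains={"A": helix20.chains["A"][:-3]})
        assert sponge_fraction(shorter, res) >= full

    def test_invalid_geometry_raises(self, helix20):
        with pytest.raises(ContractError):
            sponge_fraction(helix20, helix20.chains["A"][0], radius=1.0, grid=2.0)


class TestHydrophobicity:
    def test_isolated_ile(self):
        chain = [_single_res("ILE")]
        assert hydrophobicity_env(chain, chain[0]) == pytest.approx(4.5)

    def test_ile_arg_cancel(self):
        chain = [_single_res("ILE", (0, 0, 0), 1), _single_res("ARG", (3, 0, 0), 2)]
        assert hydrophobicity_env(chain, chain[0]) == pytest.approx(0.0)

    def test_helix_matches_neighbourhood_mean(self, helix20):
        from allores._data import kyte_doolittle
        from allores.structures import min_heavy_distance

        chain = helix20.chains["A"]
        res = chain[8]
        table = kyte_doolittle()
        vals = [
            table[o.res_name]
            for o in chain
            if o is res or min_heavy_distance(res, o) <= 6.5
        ]
        assert hydrophobicity_env(chain, res) == pytest.approx(np.mean(vals))


class TestElectrostatics:
    def test_no_charges_zero(self):
        # CA-only residues carry no charge sites (not even termini)
        s = structure_from_points([(0, 0, 0), (5, 0, 0)])
        assert electrostatic_potential(s, s.chains["A"][0]) == 0.0

    def test_symmetric_opposite_charges_cancel(self):
        ref = _single_res("ALA", (0, 0, 0), 1)
        lys = Residue("A", 2, "", "LYS", [Atom(2, "NZ", "N", [5, 0, 0], 1.55)])
        asp = Residue("A", 3, "", "ASP", [Atom(3, "CG", "C", [-5, 0, 0], 1.7)])
        s = Structure(id="Q", chains={"A": [ref, lys, asp]})
        assert electrostatic_potential(s, ref) == pytest.approx(0.0, abs=1e-12)

    def test_single_plus_charge_at_5A(self):
        ref = _single_res("ALA", (0, 0, 0), 1)
        lys = Residue("A", 2, "", "LYS", [Atom(2, "NZ", "N", [5, 0, 0], 1.55)])
        s = Structure(id="Q", chains={"A": [ref, lys]})
        assert electrostatic_potential(s, ref) == pytest.approx(332.0636 / 100.0)

    def test_distance_floor_at_2A(self):
        ref = _single_res("ALA", (0, 0, 0), 1)
        lys = Residue("A", 2, "", "LYS", [Atom(2, "NZ", "N", [0.5, 0, 0], 1.55)])
        s = Structure(id="Q", chains={"A": [ref, lys]})
        assert electrostatic_potential(s, ref) == pytest.approx(332.0636 / 16.0)

    def test_self_charges_excluded(self):
        lys = Residue(
            "A", 1, "", "LYS",
            [Atom(1, "CA", "C", [0, 0, 0], 1.7), Atom(2, "NZ", "N", [3, 0, 0], 1.55)],
        )
        s = Structure(id="Q", chains={"A": [lys]})
        # only the terminal charges on N (absent) and C (absent) could act
        assert electrostatic_potential(s, lys) == 0.0


class TestHbonds:
    def test_isolated_extended_dipeptide_no_bonds(self):
        def backbone(seq, x0):
            return Residue(
                "A", seq, "", "ALA",
                [
                    Atom(seq * 10, "N", "N", [x0, 0, 0], 1.55),
                    Atom(seq * 10 + 1, "CA", "C", [x0 + 1.4, 0.5, 0], 1.7),
                    Atom(seq * 10 + 2, "C", "C", [x0 + 2.6, -0.3, 0], 1.7),
                    Atom(seq * 10 + 3, "O", "O", [x0 + 2.7, -1.5, 0], 1.52),
                ],
            )

        chain = [backbone(1, 0.0), backbone(2, 3.8)]
        assert hbond_energies(chain, chain[0]) == (0.0, 0.0)
        assert hbond_energies(chain, chain[1]) == (0.0, 0.0)

    def test_mid_helix_residue_donates(self, helix20):
        chain = helix20.chains["A"]
        donor, acceptor = hbond_energies(chain, chain[10])
        assert donor < -0.5
        assert acceptor < -0.5

    def test_helix_bonds_are_i_to_i_minus_4(self, helix20):
        pairs = kabsch_sander_pairs(helix20.chains["A"])
        assert pairs, "ideal helix must form backbone H-bonds"
        assert all(i - j == 4 for i, j in pairs)

    def test_donor_acceptor_bookkeeping_symmetry(self, helix20):
        chain = helix20.chains["A"]
        pairs = kabsch_sander_pairs(chain)
        energies = kabsch_sander_energies(chain)
        for (i, j), e in pairs.items():
            assert energies[i][0] <= e or energies[i][0] == pytest.approx(e)
            assert energies[j][1] <= e or energies[j][1] == pytest.approx(e)
        # each best donor energy is realized by an actual pair
        for i, (donor, _) in energies.items():
            if donor < 0:
                assert any(k == i and e == donor for (k, _), e in pairs.items())


@pytest.fixture(scope="module")
def table_inputs(holo_case):
    holo, _, _ = holo_case
    records = label_residues(holo, n_points=240)
    labels = records_to_frame(holo, records)
    apo = strip_group(holo, holo.ligand_keys()[0])
    return apo, labels


@pytest.fixture(scope="module")
def table(table_inputs):
    apo, labels = table_inputs
    return compute_descriptor_table([apo], labels, NanoenvConfig(n_points=240))


class TestDescriptorTable:
    def test_full_rectangle_no_missing(self, table):
        assert len(table.frame) == 20
        core = {
            "relative_asa", "distance_to_cg", "sponge", "hydrophobicity_env",
            "electrostatic_potential", "donor_energy", "acceptor_energy",
            "eccentricity", "bottleneck",
        }
        assert core <= set(table.frame.columns)
        assert not table.frame.isna().any().any()
        assert not any(c.endswith("_missing") for c in table.descriptor_columns)

    def test_all_finite_and_bounded(self, table):
        values = table.frame[table.descriptor_columns]
        assert np.isfinite(values.to_numpy()).all()
        assert values["sponge"].between(0, 1).all()
        assert values["relative_asa"].between(0, 1.2).all()

    def test_order_invariance(self, table_inputs, table):
        apo, labels = table_inputs
        shuffled = labels.sample(frac=1.0, random_state=5).reset_index(drop=True)
        other = compute_descriptor_table([apo], shuffled, NanoenvConfig(n_points=240))
        a = table.frame.sort_values("identity").reset_index(drop=True)
        b = other.frame.sort_values("identity").reset_index(drop=True)
        assert a.equals(b)

    def test_rerun_byte_identical_tsv(self, table_inputs, tmp_path):
        apo, labels = table_inputs
        paths = []
        for name in ("a.tsv", "b.tsv"):
            t = compute_descriptor_table([apo], labels, NanoenvConfig(n_points=240))
            t.to_tsv(tmp_path / name)
            paths.append(tmp_path / name)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_rigid_motion_invariance(self, table_inputs, table):
        apo, labels = table_inputs
        # rotate 40° about z then translate
        theta = np.radians(40.0)
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        shift = np.array([11.0, -4.0, 7.0])

        def move(res):
            return Residue(
                res.chain_id, res.res_seq, res.icode, res.res_name,
                [
                    Atom(a.serial, a.name, a.element, rot @ a.coord + shift,
                         a.vdw_radius, a.occupancy, a.altloc, a.is_hetero)
                    for a in res.atoms
                ],
            )

        moved = Structure(
            id=apo.id, chains={"A": [move(r) for r in apo.chains["A"]]}
        )
        base = compute_descriptor_table([apo], labels, NanoenvConfig(n_points=960))
        other = compute_descriptor_table([moved], labels, NanoenvConfig(n_points=960))
        a = base.frame.set_index("identity")
        b = other.frame.set_index("identity")
        for col in base.descriptor_columns:
            # sampled descriptors (fixed sphere/grid lattices) carry a small
            # orientation-dependent discretization error
            tol = 0.02 if col in ("sponge", "relative_asa") else 1e-6
            assert np.abs(a[col] - b[col]).max() <= tol, col

    def test_one_hot_option(self, table_inputs):
        apo, labels = table_inputs
        t = compute_descriptor_table(
            [apo], labels, NanoenvConfig(n_points=240, residue_one_hot=True)
        )
        assert t.frame["is_ALA"].sum() == 20

    def test_provenance_snapshot(self, table):
        assert table.provenance["config"]["n_points"] == 240
        assert "vdw_radii" in table.provenance

    def test_unmatched_labels_raise(self, table_inputs):
        apo, labels = table_inputs
        bad = labels.copy()
        bad.loc[0, "identity"] = "GHOST_A_1_ALA"
        with pytest.raises(ContractError):
            compute_descriptor_table([apo], bad, NanoenvConfig(n_points=240))

    def test_tsv_round_trip(self, table, tmp_path):
        from allores.nanoenv import DescriptorTable

        table.to_tsv(tmp_path / "t.tsv")
        again = DescriptorTable.from_tsv(tmp_path / "t.tsv")
        assert list(again.frame.columns) == list(table.frame.columns)
        assert again.provenance == table.provenance
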