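"""Graph construction from SMILES and PDB, pair tables, and the cache."""

import numpy as np
import pytest

from bsdti import molio
from bsdti.molio import (DrugGraph, MolParseError, PairDataset,
                         build_drug_graph, build_protein_graph,
                         load_graph_cache, read_pairs, save_graph_cache)


class TestDrugGraph:
    @pytest.mark.parametrize("smiles,n_nodes,n_edges", [
        ("C", 1, 0),                 # methane: single heavy atom
        ("CCO", 3, 2),               # ethanol
        ("c1ccccc1", 6, 6),          # benzene
        ("CC(=O)Oc1ccccc1C(=O)O", 13, 13),   # aspirin
    ])
    def test_heavy_atom_and_bond_counts(self, smiles, n_nodes, n_edges):
        g = build_drug_graph(smiles)
        assert g.n_nodes == n_nodes
        assert g.n_edges == n_edges

    def test_benzene_flags_aromatic_and_ring(self):
        g = build_drug_graph("c1ccccc1")
        assert (g.nodes[:, 7] == 1).all()          # aromatic
        assert (g.nodes[:, 8] == 1).all()          # in ring
        assert (g.edge_feats[:, 0] == 3).all()     # aromatic bond type
        assert (g.nodes[:, 0] == 6).all()          # carbon

    def test_ethanol_features(self):
        g = build_drug_graph("CCO")
        assert list(g.nodes[:, 0]) == [6, 6, 8]
        assert list(g.nodes[:, 2]) == [1, 2, 1]    # degrees
        assert (g.edge_feats[:, 0] == 0).all()     # single bonds

    def test_unparseable_smiles_raises_with_input_named(self):
        with pytest.raises(MolParseError, match="not-a-molecule"):
            build_drug_graph("not-a-molecule")

    def test_deterministic_construction(self):
        a = build_drug_graph("CC(=O)Oc1ccccc1C(=O)O")
        b = build_drug_graph("CC(=O)Oc1ccccc1C(=O)O")
        np.testing.assert_array_equal(a.nodes, b.nodes)
        np.testing.assert_array_equal(a.edges, b.edges)
        np.testing.assert_array_equal(a.edge_feats, b.edge_feats)

    def test_vocabulary_ranges_enforced(self):
        with pytest.raises(ValueError, match="out of vocabulary"):
            DrugGraph(np.full((2, 9), 500), np.array([[0, 1]]),
                      np.zeros((1, 4)))

    def test_edge_endpoints_validated(self):
        nodes = build_drug_graph("CC").nodes
        with pytest.raises(ValueError, match="endpoint"):
            DrugGraph(nodes, np.array([[0, 5]]), np.zeros((1, 4)))


class TestProteinGraph:
    def test_three_residue_chain_contact_edges(self, pdb_3res):
        g = build_protein_graph(pdb_3res, contact_cutoff=8.0)
        assert g.n_nodes == 3
        # 3.8, 3.8 and 7.6 A all under the 8 A cutoff
        assert set(map(tuple, g.edges)) == {(0, 1), (1, 2), (0, 2)}

    def test_tight_cutoff_drops_long_contact(self, pdb_3res):
        g = build_protein_graph(pdb_3res, contact_cutoff=4.0)
        assert set(map(tuple, g.edges)) == {(0, 1), (1, 2)}

    def test_single_residue(self, pdb_1res):
        g = build_protein_graph(pdb_1res)
        assert g.n_nodes == 1 and g.n_edges == 0
        assert g.residues[0] == molio.RESIDUE_TYPES.index("TRP")

    def test_contact_edges_monotone_in_cutoff(self, pdb_3res):
        prev = set()
        for cutoff in (2.0, 4.0, 6.0, 8.0, 12.0):
            g = build_protein_graph(pdb_3res, contact_cutoff=cutoff)
            edges = set(map(tuple, g.edges))
            assert prev <= edges
            prev = edges

    def test_chains_concatenated_without_cross_chain_adjacency(self,
                                                               pdb_2chain):
        g = build_protein_graph(pdb_2chain, contact_cutoff=6.0)
        assert g.n_nodes == 4
        edges = set(map(tuple, g.edges))
        assert (1, 2) not in edges        # no adjacency across the break
        assert (0, 2) in edges            # but contacts may cross chains
        assert g.chain_ids == ["A", "A", "B", "B"]

    def test_missing_ca_keeps_node_skips_contacts(self, pdb_no_ca):
        g = build_protein_graph(pdb_no_ca, contact_cutoff=8.0)
        assert g.n_nodes == 3
        edges = set(map(tuple, g.edges))
        assert (0, 2) in edges            # contact between the CA-bearing two
        assert (0, 1) in edges and (1, 2) in edges   # chain adjacency kept
        assert np.isnan(g.coords[1]).all()

    def test_no_residues_raises(self):
        with pytest.raises(MolParseError):
            build_protein_graph("HETATM    1  O   HOH A   1       "
                                "0.000   0.000   0.000  1.00  0.00\nEND\n")

    def test_pocket_annotation_as_indices(self, pdb_3res):
        g = build_protein_graph(pdb_3res, pocket_residues=[1])
        np.testing.assert_array_equal(g.pocket_labels, [0, 1, 0])


class TestCacheRoundTrip:
    def test_graphs_survive_serialization(self, tmp_path, pdb_3res):
        drug = build_drug_graph("CC(=O)Oc1ccccc1C(=O)O")
        prot = build_protein_graph(pdb_3res, pocket_residues=[2])
        path = tmp_path / "cache.json"
        save_graph_cache(path, drugs={"d1": drug}, proteins={"p1": prot})
        drugs, prots = load_graph_cache(path)
        d2, p2 = drugs["d1"], prots["p1"]
        np.testing.assert_array_equal(drug.nodes, d2.nodes)
        np.testing.assert_array_equal(drug.edges, d2.edges)
        np.testing.assert_array_equal(drug.edge_feats, d2.edge_feats)
        np.testing.assert_array_equal(prot.residues, p2.residues)
        np.testing.assert_array_equal(prot.edges, p2.edges)
        np.testing.assert_array_equal(prot.pocket_labels, p2.pocket_labels)
        np.testing.assert_allclose(prot.coords, p2.coords, atol=1e-3)


class TestReadPairs:
    def _write_sources(self, tmp_path, pdb_3res):
        (tmp_path / "drugs.csv").write_text(
            "drug_id,smiles\nd1,CCO\nd2,c1ccccc1\n")
        pdb_dir = tmp_path / "pdbs"
        pdb_dir.mkdir()
        (pdb_dir / "p1.pdb").write_text(pdb_3res)
        return tmp_path / "drugs.csv", pdb_dir

    def test_well_formed_table(self, tmp_path, pdb_3res):
        drugs, pdbs = self._write_sources(tmp_path, pdb_3res)
        pairs = tmp_path / "pairs.csv"
        pairs.write_text("drug_id,protein_id,label\nd1,p1,1\nd2,p1,0\n")
        ds = read_pairs(pairs, drugs, pdbs)
        assert len(ds) == 2
        np.testing.assert_array_equal(ds.labels, [1, 0])

    def test_non_binary_label_names_row(self, tmp_path, pdb_3res):
        drugs, pdbs = self._write_sources(tmp_path, pdb_3res)
        pairs = tmp_path / "pairs.csv"
        pairs.write_text("drug_id,protein_id,label\nd1,p1,1\nd2,p1,2\n")
        with pytest.raises(ValueError, match="row 2"):
            read_pairs(pairs, drugs, pdbs)

    def test_unknown_protein_id_listed(self, tmp_path, pdb_3res):
        drugs, pdbs = self._write_sources(tmp_path, pdb_3res)
        pairs = tmp_path / "pairs.csv"
        pairs.write_text("drug_id,protein_id,label\nd1,missing,1\n")
        with pytest.raises(KeyError, match="missing"):
            read_pairs(pairs, drugs, pdbs)

    def test_dataset_rejects_unresolvable_ids_directly(self):
        g = build_drug_graph("C")
        with pytest.raises(KeyError):
            PairDataset([("d1", "p1", 1)], {"d1": g}, {})
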