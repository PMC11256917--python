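"""Molecular graph I/O.

Drugs are parsed from SMILES into atom-level graphs with categorical node and
bond attributes; proteins are parsed from PDB text into residue-level graphs
whose edges combine chain adjacency with C-alpha contact pairs.  Pair datasets
tie the two together with binary interaction labels.

All categorical attributes are stored as small integer indices into fixed
vocabularies (below); out-of-vocabulary values map to the final "other" slot.
Node indices are 0-based throughout and distances are in Angstrom.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("bsdti")

# --------------------------------------------------------------------------
# vocabularies
# --------------------------------------------------------------------------

#: atom attribute vocabulary sizes, in storage order:
#: element (atomic number, 1..100, 0 = other), chirality, degree,
#: formal charge (offset by +6), attached-H count, radical electrons,
#: hybridization, aromatic flag, ring-membership flag
ATOM_VOCAB_SIZES = (101, 4, 12, 13, 10, 6, 7, 2, 2)
ATOM_FIELDS = ("element", "chirality", "degree", "formal_charge",
               "num_h", "radical", "hybridization", "aromatic", "in_ring")

#: bond attribute vocabulary sizes: type, direction, stereochemistry,
#: conjugation flag
BOND_VOCAB_SIZES = (5, 4, 7, 2)
BOND_FIELDS = ("bond_type", "direction", "stereo", "conjugated")

#: canonical amino acids in alphabetical three-letter order; index 20 = unknown
RESIDUE_TYPES = ("ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY",
                 "HIS", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER",
                 "THR", "TRP", "TYR", "VAL")
N_RESIDUE_TYPES = len(RESIDUE_TYPES) + 1
_RES_INDEX = {name: i for i, name in enumerate(RESIDUE_TYPES)}
UNKNOWN_RESIDUE = len(RESIDUE_TYPES)


class MolParseError(ValueError):
    """Raised when a molecule or structure cannot be parsed."""


# --------------------------------------------------------------------------
# graph containers
# --------------------------------------------------------------------------

@dataclass
class DrugGraph:
    """Atom/bond graph of a small molecule.

    ``nodes`` is (N, 9) int — one categorical index per atom attribute in
    ``ATOM_FIELDS`` order.  ``edges`` is (E, 2) int with each bond stored once
    (message passing expands to both directions); ``edge_feats`` is (E, 4) int
    in ``BOND_FIELDS`` order.
    """

    nodes: np.ndarray
    edges: np.ndarray
    edge_feats: np.ndarray

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=np.int64).reshape(-1, 9)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.edge_feats = np.asarray(self.edge_feats,
                                     dtype=np.int64).reshape(-1, 4)
        self.validate()

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def validate(self) -> None:
        if self.n_nodes == 0:
            raise MolParseError("drug graph has no atoms")
        if self.n_edges:
            if self.edges.min() < 0 or self.edges.max() >= self.n_nodes:
                raise ValueError("edge endpoint out of range")
        for j, size in enumerate(ATOM_VOCAB_SIZES):
            col = self.nodes[:, j]
            if col.min() < 0 or col.max() >= size:
                raise ValueError(f"atom attribute {ATOM_FIELDS[j]} "
                                 f"out of vocabulary range")
        for j, size in enumerate(BOND_VOCAB_SIZES):
            if self.n_edges and (self.edge_feats[:, j].min() < 0 or
                                 self.edge_feats[:, j].max() >= size):
                raise ValueError(f"bond attribute {BOND_FIELDS[j]} "
                                 f"out of vocabulary range")

    def adjacency(self, dtype=np.float64) -> np.ndarray:
        """Dense symmetric {0,1} adjacency (both bond directions)."""
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=dtype)
        if self.n_edges:
            a[self.edges[:, 0], self.edges[:, 1]] = 1.0
            a[self.edges[:, 1], self.edges[:, 0]] = 1.0
        return a

    def to_json(self) -> dict:
        return {"kind": "drug",
                "nodes": self.nodes.tolist(),
                "edges": self.edges.tolist(),
                "edge_feats": self.edge_feats.tolist()}

    @classmethod
    def from_json(cls, obj: dict) -> "DrugGraph":
        return cls(np.array(obj["nodes"]).reshape(-1, 9),
                   np.array(obj["edges"]).reshape(-1, 2),
                   np.array(obj["edge_feats"]).reshape(-1, 4))


@dataclass
class ProteinGraph:
    """Residue-level protein graph.

    ``residues`` is (N,) int indexing :data:`RESIDUE_TYPES` (20 = unknown),
    in chain order.  ``edges`` combine sequence-adjacent pairs with C-alpha
    contact pairs.  ``pocket_labels`` is an optional binary per-residue
    annotation of the known binding pocket; it is carried through for
    interpretability evaluation and never enters the model.
    """

    residues: np.ndarray
    edges: np.ndarray
    pocket_labels: np.ndarray | None = None
    coords: np.ndarray | None = None
    resnames: list[str] = field(default_factory=list)
    chain_ids: list[str] = field(default_factory=list)
    res_seq_ids: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.residues = np.asarray(self.residues, dtype=np.int64).reshape(-1)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.pocket_labels is not None:
            self.pocket_labels = np.asarray(self.pocket_labels,
                                            dtype=np.int64).reshape(-1)
        if self.coords is not None:
            self.coords = np.asarray(self.coords,
                                     dtype=np.float64).reshape(-1, 3)
        self.validate()

    @property
    def n_nodes(self) -> int:
        return self.residues.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def validate(self) -> None:
        if self.n_nodes == 0:
            raise MolParseError("protein graph has no residues")
        if self.residues.min() < 0 or self.residues.max() >= N_RESIDUE_TYPES:
            raise ValueError("residue type index out of range")
        if self.n_edges and (self.edges.min() < 0 or
                             self.edges.max() >= self.n_nodes):
            raise ValueError("edge endpoint out of range")
        if (self.pocket_labels is not None and
                len(self.pocket_labels) != self.n_nodes):
            raise ValueError("pocket_labels length != node count")
        if self.coords is not None and len(self.coords) != self.n_nodes:
            raise ValueError("coords length != node count")

    def adjacency(self, dtype=np.float64) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=dtype)
        if self.n_edges:
            a[self.edges[:, 0], self.edges[:, 1]] = 1.0
            a[self.edges[:, 1], self.edges[:, 0]] = 1.0
        return a

    def to_json(self) -> dict:
        obj = {"kind": "protein",
               "residues": self.residues.tolist(),
               "edges": self.edges.tolist(),
               "resnames": list(self.resnames),
               "chain_ids": list(self.chain_ids),
               "res_seq_ids": [int(i) for i in self.res_seq_ids]}
        if self.pocket_labels is not None:
            obj["pocket_labels"] = self.pocket_labels.tolist()
        if self.coords is not None:
            obj["coords"] = np.round(self.coords, 4).tolist()
        return obj

    @classmethod
    def from_json(cls, obj: dict) -> "ProteinGraph":
        return cls(np.array(obj["residues"]),
                   np.array(obj["edges"]).reshape(-1, 2),
                   pocket_labels=(np.array(obj["pocket_labels"])
                                  if "pocket_labels" in obj else None),
                   coords=(np.array(obj["coords"])
                           if "coords" in obj else None),
                   resnames=obj.get("resnames", []),
                   chain_ids=obj.get("chain_ids", []),
                   res_seq_ids=obj.get("res_seq_ids", []))


# --------------------------------------------------------------------------
# drug graph construction
# --------------------------------------------------------------------------

def _index(value, mapping: dict, other: int) -> int:
    return mapping.get(value, other)


def build_drug_graph(smiles: str) -> DrugGraph:
    """Parse a SMILES string into a :class:`DrugGraph`.

    One node per heavy atom (hydrogens stay implicit), one edge record per
    bond.  Atom ordering is the parser's input-order atom ordering, which is
    deterministic for a given SMILES string.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MolParseError(f"unparseable SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise MolParseError(f"SMILES describes an empty molecule: {smiles!r}")

    chi = {Chem.ChiralType.CHI_UNSPECIFIED: 0,
           Chem.ChiralType.CHI_TETRAHEDRAL_CW: 1,
           Chem.ChiralType.CHI_TETRAHEDRAL_CCW: 2}
    hyb = {Chem.HybridizationType.SP: 0, Chem.HybridizationType.SP2: 1,
           Chem.HybridizationType.SP3: 2, Chem.HybridizationType.SP3D: 3,
           Chem.HybridizationType.SP3D2: 4}
    btype = {Chem.BondType.SINGLE: 0, Chem.BondType.DOUBLE: 1,
             Chem.BondType.TRIPLE: 2, Chem.BondType.AROMATIC: 3}
    bdir = {Chem.BondDir.NONE: 0, Chem.BondDir.ENDUPRIGHT: 1,
            Chem.BondDir.ENDDOWNRIGHT: 2}
    bster = {Chem.BondStereo.STEREONONE: 0, Chem.BondStereo.STEREOANY: 1,
             Chem.BondStereo.STEREOZ: 2, Chem.BondStereo.STEREOE: 3,
             Chem.BondStereo.STEREOCIS: 4, Chem.BondStereo.STEREOTRANS: 5}

    nodes = np.empty((mol.GetNumAtoms(), 9), dtype=np.int64)
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        z = atom.GetAtomicNum()
        charge = atom.GetFormalCharge()
        nodes[i] = (
            z if 1 <= z <= 100 else 0,
            _index(atom.GetChiralTag(), chi, 3),
            min(atom.GetDegree(), 11),
            int(np.clip(charge, -6, 6)) + 6,
            min(atom.GetTotalNumHs(), 9),
            min(atom.GetNumRadicalElectrons(), 5),
            _index(atom.GetHybridization(), hyb, 5),
            int(atom.GetIsAromatic()),
            int(atom.IsInRing()),
        )

    edges = np.empty((mol.GetNumBonds(), 2), dtype=np.int64)
    efeat = np.empty((mol.GetNumBonds(), 4), dtype=np.int64)
    for j, bond in enumerate(mol.GetBonds()):
        edges[j] = (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
        efeat[j] = (_index(bond.GetBondType(), btype, 4),
                    _index(bond.GetBondDir(), bdir, 3),
                    _index(bond.GetStereo(), bster, 6),
                    int(bond.GetIsConjugated()))
    return DrugGraph(nodes, edges, efeat)


# --------------------------------------------------------------------------
# protein graph construction
# --------------------------------------------------------------------------

def build_protein_graph(pdb_source, contact_cutoff: float = 8.0,
                        pocket_residues=None) -> ProteinGraph:
    """Build a residue graph from PDB text or a PDB file path.

    Nodes are the polymer residues of the first model, all chains
    concatenated in file order.  Edges are the union of within-chain
    sequence-adjacent pairs and pairs whose C-alpha distance is strictly
    below ``contact_cutoff`` (Angstrom); contacts may cross chains.
    Residues without a C-alpha atom keep their node but contribute no
    contact edges (a warning is logged).

    ``pocket_residues`` may be an iterable of 0-based node indices or a
    full binary vector; it populates ``pocket_labels``.
    """
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be positive")
    from io import StringIO

    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    if isinstance(pdb_source, (str, Path)) and "\n" not in str(pdb_source):
        text = Path(pdb_source).read_text()
    else:
        text = str(pdb_source)

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("protein", StringIO(text))
    models = list(structure)
    if not models:
        raise MolParseError("PDB source contains no models")

    res_types, resnames, chain_ids, seq_ids, coords = [], [], [], [], []
    starts_chain: list[bool] = []  # True where node i opens a new chain
    for chain in models[0]:
        first_in_chain = True
        for res in chain:
            if res.id[0] != " ":
                continue  # skip waters / hetero groups
            name = res.get_resname().strip().upper()
            res_types.append(_RES_INDEX.get(name, UNKNOWN_RESIDUE))
            resnames.append(name)
            chain_ids.append(chain.id)
            seq_ids.append(res.id[1])
            if "CA" in res:
                coords.append(np.array(res["CA"].get_coord(), dtype=float))
            else:
                coords.append(None)
                log.warning("residue %s%s has no C-alpha; contact edges "
                            "skipped for it", name, res.id[1])
            starts_chain.append(first_in_chain)
            first_in_chain = False
    if not res_types:
        raise MolParseError("no parsable polymer residues in PDB source")

    n = len(res_types)
    edge_set: set[tuple[int, int]] = set()
    for i in range(n - 1):
        if not starts_chain[i + 1]:  # no adjacency across a chain break
            edge_set.add((i, i + 1))

    have_ca = [i for i, c in enumerate(coords) if c is not None]
    if len(have_ca) >= 2:
        from scipy.spatial import cKDTree

        pts = np.stack([coords[i] for i in have_ca])
        tree = cKDTree(pts)
        for a, b in tree.query_pairs(r=contact_cutoff):
            if np.linalg.norm(pts[a] - pts[b]) < contact_cutoff:
                i, j = sorted((have_ca[a], have_ca[b]))
                edge_set.add((i, j))

    coord_arr = np.stack([c if c is not None else np.full(3, np.nan)
                          for c in coords])
    labels = None
    if pocket_residues is not None:
        pocket_residues = np.asarray(list(pocket_residues), dtype=np.int64)
        if pocket_residues.shape == (n,) and set(
                np.unique(pocket_residues)) <= {0, 1}:
            labels = pocket_residues
        else:
            labels = np.zeros(n, dtype=np.int64)
            labels[pocket_residues] = 1

    edges = (np.array(sorted(edge_set), dtype=np.int64).reshape(-1, 2)
             if edge_set else np.zeros((0, 2), dtype=np.int64))
    return ProteinGraph(np.array(res_types), edges, pocket_labels=labels,
                        coords=coord_arr, resnames=resnames,
                        chain_ids=chain_ids, res_seq_ids=seq_ids)


# --------------------------------------------------------------------------
# graph cache
# --------------------------------------------------------------------------

CACHE_FORMAT = "bsdti-graph-cache-v1"


def save_graph_cache(path, drugs: dict | None = None,
                     proteins: dict | None = None) -> None:
    """Write graphs to a JSON cache file (format tag ``bsdti-graph-cache-v1``:
    top-level ``drugs`` and ``proteins`` maps of id -> graph object)."""
    obj = {"format": CACHE_FORMAT,
           "drugs": {k: g.to_json() for k, g in (drugs or {}).items()},
           "proteins": {k: g.to_json() for k, g in (proteins or {}).items()}}
    Path(path).write_text(json.dumps(obj))


def load_graph_cache(path) -> tuple[dict, dict]:
    obj = json.loads(Path(path).read_text())
    if obj.get("format") != CACHE_FORMAT:
        raise ValueError(f"{path}: not a {CACHE_FORMAT} file")
    drugs = {k: DrugGraph.from_json(v) for k, v in obj["drugs"].items()}
    proteins = {k: ProteinGraph.from_json(v)
                for k, v in obj["proteins"].items()}
    return drugs, proteins


# --------------------------------------------------------------------------
# pair datasets
# --------------------------------------------------------------------------

@dataclass
class PairDataset:
    """Labelled (drug, protein) pairs with resolved graphs."""

    records: list[tuple[str, str, int]]
    drugs: dict[str, DrugGraph]
    proteins: dict[str, ProteinGraph]

    def __post_init__(self):
        missing_d = sorted({d for d, _, _ in self.records} - set(self.drugs))
        missing_p = sorted({p for _, p, _ in self.records}
                           - set(self.proteins))
        if missing_d or missing_p:
            raise KeyError("unresolvable ids in pair list: "
                           f"drugs={missing_d} proteins={missing_p}")
        bad = [r for r in self.records if r[2] not in (0, 1)]
        if bad:
            raise ValueError(f"non-binary labels in records: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([y for _, _, y in self.records], dtype=np.int64)

    def subset(self, indices) -> "PairDataset":
        recs = [self.records[i] for i in indices]
        return PairDataset(recs, self.drugs, self.proteins)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records,
                            columns=["drug_id", "protein_id", "label"])


def _load_drug_source(source) -> dict[str, DrugGraph]:
    if isinstance(source, dict):
        return source
    source = Path(source)
    if source.suffix == ".json":
        drugs, _ = load_graph_cache(source)
        return drugs
    df = pd.read_csv(source, sep=None, engine="python")
    need = {"drug_id", "smiles"}
    if not need <= set(df.columns):
        raise ValueError(f"{source}: drug table must have columns {need}")
    return {str(r.drug_id): build_drug_graph(str(r.smiles))
            for r in df.itertuples()}


def _load_protein_source(source, contact_cutoff: float
                         ) -> dict[str, ProteinGraph]:
    if isinstance(source, dict):
        return source
    source = Path(source)
    if source.suffix == ".json":
        _, proteins = load_graph_cache(source)
        return proteins
    if not source.is_dir():
        raise ValueError(f"{source}: protein source must be a directory of "
                         "<id>.pdb files or a graph-cache .json")
    return {p.stem: build_protein_graph(p, contact_cutoff)
            for p in sorted(source.glob("*.pdb"))}


def read_pairs(path, drug_source, protein_source,
               contact_cutoff: float = 8.0) -> PairDataset:
    """Read a delimited pair table (header ``drug_id,protein_id,label``) and
    resolve every id against the drug and protein sources.

    Graphs are constructed once per unique id.  Malformed rows are rejected
    with their (1-based, header-exclusive) row numbers; unknown ids raise a
    :class:`KeyError` listing them.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    need = ["drug_id", "protein_id", "label"]
    if not set(need) <= set(df.columns):
        raise ValueError(f"{path}: pair table needs columns {need}, "
                         f"found {list(df.columns)}")
    bad_rows = []
    records = []
    for pos, row in enumerate(df.itertuples(), start=1):
        d, p, y = row.drug_id, row.protein_id, row.label
        if pd.isna(d) or pd.isna(p) or pd.isna(y):
            bad_rows.append((pos, "missing field"))
            continue
        try:
            y = int(y)
        except (TypeError, ValueError):
            bad_rows.append((pos, f"non-integer label {y!r}"))
            continue
        if y not in (0, 1):
            bad_rows.append((pos, f"non-binary label {y!r}"))
            continue
        records.append((str(d), str(p), y))
    if bad_rows:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:10])
        raise ValueError(f"{path}: malformed rows — {detail}")

    drugs = _load_drug_source(drug_source)
    proteins = _load_protein_source(protein_source, contact_cutoff)
    used_d = {d for d, _, _ in records}
    used_p = {p for _, p, _ in records}
    return PairDataset(records,
                       {k: v for k, v in drugs.items() if k in used_d},
                       {k: v for k, v in proteins.items() if k in used_p})
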