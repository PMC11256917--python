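"""Synthetic drug/protein graph generator with a planted interaction rule.

The generator emulates the two graph kinds the predictor consumes — small
atom-graphs with categorical features and larger residue-graphs with chain +
contact edges — and plants a motif-based ground truth: every drug and protein
may carry one motif from a small paired library, and a pair interacts
(label 1) exactly when drug and protein carry motifs from the same library
entry.  Because the label depends on the *combination* of the two motifs,
marginal features of either molecule alone carry no signal; a model must
relate substructures across the pair, which is precisely the mechanism under
test.  Planted protein residues are recorded as the ground-truth binding site
(``pocket_labels``) for interpretability evaluation.

Synthetic drugs are feature-valid graphs, not chemically valid molecules:
categorical attributes respect the vocabularies in :mod:`bsdti.molio` but no
valence model is enforced.  Protein hosts are compact self-avoiding-ish
C-alpha walks, so contact edges (distance < cutoff) produce the short-range
plus long-range connectivity of folded chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .molio import (DrugGraph, PairDataset, ProteinGraph, save_graph_cache)

# motif library: (drug element path, protein residue-index run).
# Elements boron/silicon vs selenium/phosphorus and residue runs TRP/CYS vs
# HIS/MET are disjoint from the host alphabets below, so motifs are
# unambiguous once planted.
DEFAULT_MOTIFS = (
    ((5, 14, 5, 14), (17, 4, 17, 4, 17, 4, 17, 4, 17, 4, 17, 4)),
    ((34, 15, 34, 15), (8, 12, 8, 12, 8, 12, 8, 12, 8, 12, 8, 12)),
)
# host alphabets exclude every motif symbol
HOST_ELEMENTS = (6, 6, 6, 6, 7, 8)           # mostly carbon, some N/O
HOST_RESIDUES = tuple(i for i in range(20) if i not in {17, 4, 8, 12})


@dataclass
class SynthSpec:
    """Study conditions for one synthetic dataset."""

    n_drugs: int = 80
    n_proteins: int = 60
    n_pairs: int = 2000
    drug_size: tuple[int, int] = (10, 24)
    protein_length: tuple[int, int] = (48, 72)
    motifs: tuple = DEFAULT_MOTIFS
    motif_fraction: float = 0.8       # molecules carrying any motif
    label_noise: float = 0.05
    contact_cutoff: float = 8.0
    ca_spacing: float = 3.8           # Angstrom between consecutive residues
    plant_motifs: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        for d_motif, p_motif in self.motifs:
            if len(d_motif) >= self.drug_size[0]:
                raise ValueError("drug motif must be smaller than the "
                                 "smallest host drug")
            if len(p_motif) >= self.protein_length[0]:
                raise ValueError("protein motif must be smaller than the "
                                 "shortest host protein")


@dataclass
class SynthDataset:
    """A generated dataset plus its ground truth."""

    dataset: PairDataset
    sites: pd.DataFrame                 # positive pair -> planted residues
    drug_motifs: dict[str, int]         # -1 = no motif
    protein_motifs: dict[str, int]
    drug_pharmacophores: dict[str, list[int]] = field(default_factory=dict)
    protein_sites: dict[str, list[int]] = field(default_factory=dict)

    def write(self, out_dir) -> None:
        """Emit pairs.csv, graphs.json (cache) and sites.csv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.dataset.to_frame().to_csv(out / "pairs.csv", index=False)
        save_graph_cache(out / "graphs.json",
                         drugs=self.dataset.drugs,
                         proteins=self.dataset.proteins)
        self.sites.to_csv(out / "sites.csv", index=False)


# --------------------------------------------------------------------------
# single-graph generators
# --------------------------------------------------------------------------

def make_drug(spec: SynthSpec, rng: np.random.Generator,
              motif_id: int | None = None
              ) -> tuple[DrugGraph, list[int]]:
    """Random connected atom-graph, optionally with a planted motif path.

    Returns the graph and the planted node ids (empty when no motif)."""
    n = int(rng.integers(spec.drug_size[0], spec.drug_size[1] + 1))
    motif = spec.motifs[motif_id][0] if motif_id is not None else ()
    if len(motif) >= n:
        raise ValueError("motif larger than host drug")
    n_host = n - len(motif)

    # random tree over the host, plus a few shortcut edges
    edges = [(int(rng.integers(0, i)), i) for i in range(1, n_host)]
    for _ in range(max(1, n_host // 5)):
        u, v = rng.integers(0, n_host, size=2)
        if u != v and (min(u, v), max(u, v)) not in edges:
            edges.append((int(min(u, v)), int(max(u, v))))
    elements = rng.choice(HOST_ELEMENTS, size=n).astype(np.int64)

    planted: list[int] = []
    if motif:
        attach = int(rng.integers(0, n_host))
        prev = attach
        for j, elem in enumerate(motif):
            idx = n_host + j
            elements[idx] = elem
            edges.append((prev, idx))
            prev = idx
            planted.append(idx)

    edges_arr = np.array(sorted(set(edges)), dtype=np.int64)
    degree = np.zeros(n, dtype=np.int64)
    for u, v in edges_arr:
        degree[u] += 1
        degree[v] += 1

    nodes = np.zeros((n, 9), dtype=np.int64)
    nodes[:, 0] = elements
    nodes[:, 2] = np.minimum(degree, 11)
    nodes[:, 3] = 6                                   # neutral formal charge
    nodes[:, 4] = rng.integers(0, 4, size=n)          # attached H count
    nodes[:, 6] = 2                                   # sp3
    efeat = np.zeros((len(edges_arr), 4), dtype=np.int64)
    return DrugGraph(nodes, edges_arr, efeat), planted


def _compact_walk(n: int, spacing: float, rng: np.random.Generator
                  ) -> np.ndarray:
    """C-alpha trace: fixed-step 3D walk loosely confined near the origin.

    Confinement strength is calibrated so an 8 A contact graph has a mean
    degree near 10 with a realistic share of long-range (sequence-distant)
    contacts — matching folded single-domain chains rather than a collapsed
    ball, which would over-connect the graph and let message passing mix
    every residue with every other."""
    pos = np.zeros((n, 3))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    for i in range(1, n):
        pull = -pos[i - 1]
        norm = np.linalg.norm(pull)
        if norm > 1e-9:
            pull = pull / norm * min(1.0, norm / 20.0)
        step = 0.45 * direction + rng.normal(size=3) + 0.25 * pull
        step /= np.linalg.norm(step)
        pos[i] = pos[i - 1] + spacing * step
        direction = step
    return pos


def make_protein(spec: SynthSpec, rng: np.random.Generator,
                 motif_id: int | None = None
                 ) -> tuple[ProteinGraph, list[int]]:
    """Random residue-graph (chain + contact edges from synthetic C-alpha
    coordinates), optionally with a contiguous planted motif run whose nodes
    become ``pocket_labels``."""
    n = int(rng.integers(spec.protein_length[0], spec.protein_length[1] + 1))
    motif = spec.motifs[motif_id][1] if motif_id is not None else ()
    if len(motif) >= n:
        raise ValueError("motif larger than host protein")

    residues = rng.choice(HOST_RESIDUES, size=n).astype(np.int64)
    labels = np.zeros(n, dtype=np.int64)
    planted: list[int] = []
    if motif:
        start = int(rng.integers(0, n - len(motif) + 1))
        residues[start:start + len(motif)] = motif
        labels[start:start + len(motif)] = 1
        planted = list(range(start, start + len(motif)))

    coords = _compact_walk(n, spec.ca_spacing, rng)
    edge_set = {(i, i + 1) for i in range(n - 1)}
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    for a, b in tree.query_pairs(r=spec.contact_cutoff):
        if np.linalg.norm(coords[a] - coords[b]) < spec.contact_cutoff:
            edge_set.add((min(a, b), max(a, b)))
    edges = np.array(sorted(edge_set), dtype=np.int64)
    return ProteinGraph(residues, edges, pocket_labels=labels, coords=coords,
                        resnames=["UNK"] * n, chain_ids=["A"] * n,
                        res_seq_ids=list(range(1, n + 1))), planted


# --------------------------------------------------------------------------
# dataset generator
# --------------------------------------------------------------------------

def _motif_assignment(n: int, n_motifs: int, fraction: float,
                      rng: np.random.Generator) -> list[int]:
    """Deterministic counts: `fraction` of molecules carry a motif, split
    evenly across the library; the rest carry none (-1)."""
    n_with = int(round(n * fraction))
    per = n_with // n_motifs
    ids = []
    for m in range(n_motifs):
        ids += [m] * per
    ids += [m % n_motifs for m in range(n_with - len(ids))]
    ids += [-1] * (n - len(ids))
    rng.shuffle(ids)
    return [int(i) for i in ids]


def make_pairs(spec: SynthSpec) -> SynthDataset:
    """Generate the full dataset: graphs, a balanced pair table, and the
    ground-truth site table.

    With ``label_noise == 0`` exactly ``n_pairs // 2`` pairs are positive
    (motif-matched); negatives mix mismatched-motif and motif-free pairs.
    Each label is then flipped independently with probability
    ``label_noise``.  Everything derives from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_motifs = len(spec.motifs)

    d_motifs = (_motif_assignment(spec.n_drugs, n_motifs,
                                  spec.motif_fraction, rng)
                if spec.plant_motifs else [-1] * spec.n_drugs)
    p_motifs = (_motif_assignment(spec.n_proteins, n_motifs,
                                  spec.motif_fraction, rng)
                if spec.plant_motifs else [-1] * spec.n_proteins)

    drugs, proteins = {}, {}
    drug_ph, prot_site = {}, {}
    for i, m in enumerate(d_motifs):
        did = f"D{i:04d}"
        g, planted = make_drug(spec, rng, m if m >= 0 else None)
        drugs[did], drug_ph[did] = g, planted
    for j, m in enumerate(p_motifs):
        pid = f"P{j:04d}"
        g, planted = make_protein(spec, rng, m if m >= 0 else None)
        proteins[pid], prot_site[pid] = g, planted

    drug_ids = sorted(drugs)
    prot_ids = sorted(proteins)
    dm = {k: m for k, m in zip(drug_ids, d_motifs)}
    pm = {k: m for k, m in zip(prot_ids, p_motifs)}

    matched = [(d, p) for d in drug_ids for p in prot_ids
               if dm[d] >= 0 and dm[d] == pm[p]]
    unmatched = [(d, p) for d in drug_ids for p in prot_ids
                 if not (dm[d] >= 0 and dm[d] == pm[p])]
    n_pos = spec.n_pairs // 2
    n_neg = spec.n_pairs - n_pos
    if spec.plant_motifs:
        if len(matched) < n_pos or len(unmatched) < n_neg:
            raise ValueError(
                f"cannot draw {n_pos} positives / {n_neg} negatives from "
                f"{len(matched)} matched and {len(unmatched)} unmatched "
                "combinations; enlarge n_drugs/n_proteins")
        pos_idx = rng.choice(len(matched), size=n_pos, replace=False)
        neg_idx = rng.choice(len(unmatched), size=n_neg, replace=False)
        chosen = ([(matched[i][0], matched[i][1], 1) for i in pos_idx] +
                  [(unmatched[i][0], unmatched[i][1], 0) for i in neg_idx])
    else:
        all_pairs = [(d, p) for d in drug_ids for p in prot_ids]
        idx = rng.choice(len(all_pairs), size=spec.n_pairs, replace=False)
        labels = np.zeros(spec.n_pairs, dtype=int)
        labels[:n_pos] = 1
        rng.shuffle(labels)
        chosen = [(all_pairs[i][0], all_pairs[i][1], int(y))
                  for i, y in zip(idx, labels)]
    rng.shuffle(chosen)

    flips = rng.random(len(chosen)) < spec.label_noise
    records = [(d, p, int(y ^ f)) for (d, p, y), f in zip(chosen, flips)]

    site_rows = [
        {"drug_id": d, "protein_id": p,
         "site_nodes": ";".join(map(str, prot_site[p])),
         "pharmacophore_nodes": ";".join(map(str, drug_ph[d]))}
        for (d, p, y) in chosen if y == 1 and prot_site[p]
    ]
    sites = pd.DataFrame(site_rows, columns=["drug_id", "protein_id",
                                             "site_nodes",
                                             "pharmacophore_nodes"])
    return SynthDataset(PairDataset(records, drugs, proteins), sites,
                        dm, pm, drug_ph, prot_site)
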