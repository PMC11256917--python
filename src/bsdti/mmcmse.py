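"""Macro-micro Cross Molecular Substructure Extraction (MMCMSE).

The drug (micro-molecule) is tokenized once at a fixed scale; the protein
(macro-molecule) is tokenized at a cascade of strictly decreasing scales by
repeated differentiable pooling, and at every scale a cross-attention
selector elects the top-K% protein tokens most relevant to the drug tokens.
The elected tokens of all scales, stacked vertically, form the protein's
multiscale representation handed to the interaction decoder; the per-scale
stage vectors feed the complementary loss.

Scales larger than the current graph are clamped to it, so short proteins
(and tiny drugs) remain well defined; message passing runs only once, before
the first pooling step — later scales are pure pooling refinements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._tensor import Tensor
from .cass import CASS, SelectionResult, n_elected
from .molio import ATOM_VOCAB_SIZES, N_RESIDUE_TYPES
from .msgn import MSGN, TokenSet


def effective_scales(scales: list[int], n_nodes: int) -> tuple[int, ...]:
    """Clamp each scale to the running cluster count: scale_i :=
    min(scale_i, previous count), starting from the node count."""
    eff = []
    current = n_nodes
    for s in scales:
        current = min(s, current)
        eff.append(current)
    return tuple(eff)


def validate_scales(scales) -> list[int]:
    scales = [int(s) for s in scales]
    if not scales:
        raise ValueError("at least one protein scale is required")
    if any(s < 1 for s in scales):
        raise ValueError("scales must be positive")
    if any(b >= a for a, b in zip(scales, scales[1:])):
        raise ValueError(f"protein scales must be strictly decreasing, "
                         f"got {scales}")
    return scales


@dataclass
class MultiScaleTokens:
    """Per-scale elections plus the concatenated protein representation."""

    per_scale: list[SelectionResult]
    concat_tokens: np.ndarray            # (sum K_i, d)
    stage_vectors: list[np.ndarray]      # one (d,) vector per scale
    drug_vector: np.ndarray              # v_d, column-sum of drug tokens
    assignment: list[np.ndarray] = field(default_factory=list)
    scale_sizes: list[int] = field(default_factory=list)
    source_graph_size: int = 0

    def validate(self) -> None:
        total = sum(len(r.selected_idx) for r in self.per_scale)
        if self.concat_tokens.shape[0] != total:
            raise ValueError("concat row count != sum of elected counts")
        for r in self.per_scale:
            r.validate()

    def token_partition(self, scale: int) -> list[np.ndarray]:
        """Node-id pre-image of every cluster at the given scale index."""
        if not 0 <= scale < len(self.scale_sizes):
            raise ValueError(f"scale {scale} out of range "
                             f"[0, {len(self.scale_sizes)})")
        owner = np.argmax(self.assignment[0], axis=-1)
        for s in self.assignment[1:scale + 1]:
            owner = np.argmax(s, axis=-1)[owner]
        return [np.flatnonzero(owner == t)
                for t in range(self.scale_sizes[scale])]


class MMCMSE(_nn.Module):
    """Embeddings + MSGNs + pooling cascade + per-scale selectors."""

    def __init__(self, hidden_dim: int, gat_layers: int, drug_tokens: int,
                 scales: list[int], rng: np.random.Generator, dtype=None):
        self.scales = validate_scales(scales)
        self.drug_tokens = drug_tokens
        self.atom_embeds = [_nn.Embedding(n, hidden_dim, rng, dtype)
                            for n in ATOM_VOCAB_SIZES]
        self.res_embed = _nn.Embedding(N_RESIDUE_TYPES, hidden_dim, rng,
                                       dtype)
        self.drug_msgn = MSGN(hidden_dim, gat_layers, drug_tokens, rng,
                              dtype=dtype)
        self.prot_msgn = MSGN(hidden_dim, gat_layers, self.scales[0], rng,
                              dtype=dtype)
        self.prot_pools = [_nn.DiffPoolLayer(hidden_dim, s, rng, dtype)
                           for s in self.scales[1:]]
        self.selectors = [CASS(hidden_dim, rng, dtype)
                          for _ in self.scales]

    # ------------------------------------------------------------ embeddings
    def embed_drug_nodes(self, idx: np.ndarray, mask: np.ndarray) -> Tensor:
        """Sum of the nine categorical atom-attribute embeddings."""
        h = self.atom_embeds[0](idx[..., 0])
        for f in range(1, len(self.atom_embeds)):
            h = h + self.atom_embeds[f](idx[..., f])
        return h * Tensor(mask[..., None])

    def embed_protein_nodes(self, idx: np.ndarray,
                            mask: np.ndarray) -> Tensor:
        return self.res_embed(idx) * Tensor(mask[..., None])

    # --------------------------------------------------------- batched paths
    def drug_forward(self, idx, adj, mask, n_tokens: int | None = None):
        """Returns (tokens (B,Td,d), v_d (B,d), S, aux)."""
        h = self.embed_drug_nodes(idx, mask)
        _, tokens, _, s, aux = self.drug_msgn(h, adj, mask,
                                              n_tokens=n_tokens)
        return tokens, tokens.sum(axis=-2), s, aux

    def protein_forward(self, idx, adj, mask, drug_tokens: Tensor,
                        k_percent: float, eff_scales=None,
                        selection: str = "topk", rng=None,
                        single_scale: bool = False):
        """Multiscale extraction + per-scale election over a batch.

        Returns a dict with the concatenated elected tokens, per-scale stage
        vectors/scores/indices, soft assignments and auxiliary pooling
        losses.  ``eff_scales`` must be uniform across the batch (the batch
        builder groups by it); ``single_scale`` stops after the first scale
        (MMCMSE-ablation mode).
        """
        eff = list(eff_scales if eff_scales is not None
                   else effective_scales(self.scales, idx.shape[-1]))
        if single_scale:
            eff = eff[:1]
        h = self.embed_protein_nodes(idx, mask)
        _, tokens, pooled_adj, s0, aux0 = self.prot_msgn(
            h, adj, mask, n_tokens=eff[0])
        assignments = [s0]
        aux_losses = [aux0]
        scale_tokens = [tokens]
        for i, eff_c in enumerate(eff[1:]):
            tokens, pooled_adj, s_i, aux_i = self.prot_pools[i](
                tokens, pooled_adj, n_clusters=eff_c)
            assignments.append(s_i)
            aux_losses.append(aux_i)
            scale_tokens.append(tokens)

        elected, stages, scores, indices = [], [], [], []
        for i, toks in enumerate(scale_tokens):
            st, stage, sc, idx_sel = self.selectors[i].forward(
                toks, drug_tokens, k_percent, selection=selection, rng=rng)
            elected.append(st)
            stages.append(stage)
            scores.append(sc)
            indices.append(idx_sel)
        from ._tensor import concat

        return {"concat_tokens": concat(elected, axis=-2),
                "stages": stages, "scores": scores, "indices": indices,
                "assignments": assignments, "aux": aux_losses,
                "eff_scales": eff, "scale_tokens": scale_tokens}

    # ----------------------------------------------------- single-graph API
    def extract_drug(self, drug_graph) -> TokenSet:
        """Fixed-scale drug tokenization; TokenSet carries the assignment."""
        idx = drug_graph.nodes[None]
        adj = drug_graph.adjacency()[None]
        mask = np.ones((1, drug_graph.n_nodes))
        tokens, v_d, s, _ = self.drug_forward(idx, adj, mask)
        ts = TokenSet(tokens.data[0], [s.data[0]],
                      source_graph_size=drug_graph.n_nodes)
        return ts

    def extract_protein_multiscale(self, protein_graph, drug_tokens,
                                   k_percent: float = 30.0
                                   ) -> MultiScaleTokens:
        """Multiscale extraction for one protein against one drug token set.

        ``drug_tokens`` may be a TokenSet or a (Td, d) array.
        """
        toks = (drug_tokens.tokens if isinstance(drug_tokens, TokenSet)
                else np.asarray(drug_tokens))
        idx = protein_graph.residues[None]
        adj = protein_graph.adjacency()[None]
        mask = np.ones((1, protein_graph.n_nodes))
        out = self.protein_forward(idx, adj, mask, Tensor(toks[None]),
                                   k_percent)
        per_scale = []
        for sc, sel_idx, toks_i, stage in zip(out["scores"], out["indices"],
                                              out["scale_tokens"],
                                              out["stages"]):
            sel = sel_idx[0]
            per_scale.append(SelectionResult(
                scores=sc.data[0], selected_idx=sel,
                selected_tokens=toks_i.data[0][sel],
                stage_vector=toks_i.data[0][sel].sum(axis=0)))
        return MultiScaleTokens(
            per_scale=per_scale,
            concat_tokens=out["concat_tokens"].data[0],
            stage_vectors=[s.data[0] for s in out["stages"]],
            drug_vector=toks.sum(axis=0),
            assignment=[s.data[0] for s in out["assignments"]],
            scale_sizes=list(out["eff_scales"]),
            source_graph_size=protein_graph.n_nodes)


def elected_counts(scales, k_percent: float, n_nodes: int | None = None
                   ) -> list[int]:
    """Per-scale election counts ceil(k% * scale); with ``n_nodes`` given,
    scales are first clamped to the graph."""
    scales = validate_scales(scales)
    eff = (effective_scales(scales, n_nodes)
           if n_nodes is not None else tuple(scales))
    return [n_elected(c, k_percent) for c in eff]
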