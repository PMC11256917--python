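"""Molecular Substructure Graph Network (MSGN).

A stack of residually connected graph-attention layers updates node features;
a differentiable-pooling step then compresses the graph into a fixed number
of substructure tokens.  The soft assignment matrices are kept so every token
can later be traced back to the original nodes (hard backtracking by argmax).

Two surfaces are provided: :class:`MSGN` (a parameterized module used inside
the trained model) and thin functional wrappers (``gat_stack``,
``diffpool_step``, ``msgn_forward``) that build a freshly seeded module and
apply it once — convenient for inspecting the mechanics on a single graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._tensor import Tensor

log = logging.getLogger("bsdti")


@dataclass
class PooledGraph:
    """Coarsened graph: weighted adjacency over clusters + token features."""

    adjacency: np.ndarray
    features: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[-1]


@dataclass
class TokenSet:
    """Substructure tokens plus the assignment history that produced them.

    ``tokens`` is (T, d); ``assignment`` is the list of soft node->cluster
    matrices applied so far (first maps original nodes, later entries map
    clusters of the previous step).  Hard backtracking composes row-argmax
    over the chain, ties resolved to the lowest cluster index (NumPy argmax).
    """

    tokens: np.ndarray
    assignment: list[np.ndarray] = field(default_factory=list)
    source_graph_size: int = 0

    @property
    def n_tokens(self) -> int:
        return self.tokens.shape[0]

    def validate(self) -> None:
        for s in self.assignment:
            rowsum = s.sum(axis=-1)
            if not np.allclose(rowsum, 1.0, atol=1e-5):
                raise ValueError("assignment rows must sum to 1")
            if (s < -1e-12).any():
                raise ValueError("assignment entries must be non-negative")

    def hard_assignment(self) -> np.ndarray:
        """(source_graph_size,) index of the token owning each node."""
        if not self.assignment:
            return np.arange(self.source_graph_size)
        owner = np.argmax(self.assignment[0], axis=-1)
        for s in self.assignment[1:]:
            owner = np.argmax(s, axis=-1)[owner]
        return owner

    def token_members(self) -> list[np.ndarray]:
        """Node-id partition: one array of original node ids per token."""
        owner = self.hard_assignment()
        return [np.flatnonzero(owner == t) for t in range(self.n_tokens)]


class MSGN(_nn.Module):
    """GAT message passing followed by one DiffPool tokenization step."""

    def __init__(self, hidden_dim: int, n_layers: int, n_tokens: int,
                 rng: np.random.Generator, in_dim: int | None = None,
                 dtype=None):
        self.gat = _nn.GATStack(n_layers, hidden_dim, rng, in_dim=in_dim,
                                dtype=dtype)
        self.pool = _nn.DiffPoolLayer(hidden_dim, n_tokens, rng, dtype=dtype)
        self.n_tokens = n_tokens

    def __call__(self, h: Tensor, adj: np.ndarray,
                 node_mask: np.ndarray | None = None,
                 n_tokens: int | None = None):
        """Returns (updated node features, tokens, pooled adj, S, aux)."""
        h = self.gat(h, adj, node_mask)
        n = h.shape[-2]
        eff = min(n_tokens or self.n_tokens, n)
        if eff < (n_tokens or self.n_tokens):
            log.warning("graph has %d nodes < %d tokens; clamping",
                        n, n_tokens or self.n_tokens)
        tokens, pooled_adj, s, aux = self.pool(h, adj, node_mask,
                                               n_clusters=eff)
        return h, tokens, pooled_adj, s, aux


# --------------------------------------------------------------------------
# functional wrappers (single graph, numpy in / numpy out)
# --------------------------------------------------------------------------

def _as_batch(features: np.ndarray) -> Tensor:
    return Tensor(np.asarray(features, dtype=np.float64)[None])


def gat_stack(graph, features: np.ndarray, n_layers: int,
              hidden_dim: int | None = None, seed: int = 0) -> np.ndarray:
    """Apply a freshly initialized residual GAT stack to one graph.

    ``features`` is (N, d_in); if ``hidden_dim`` differs from d_in the first
    layer projects into the hidden dimension before residuals apply.
    Returns the (N, hidden) updated feature matrix.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.shape[0] != graph.n_nodes:
        raise ValueError("feature row count must equal node count")
    in_dim = features.shape[1]
    hidden_dim = hidden_dim or in_dim
    rng = np.random.default_rng(seed)
    stack = _nn.GATStack(n_layers, hidden_dim, rng,
                         in_dim=in_dim if in_dim != hidden_dim else None)
    out = stack(_as_batch(features), graph.adjacency()[None])
    return out.data[0]


def diffpool_step(graph, features: np.ndarray, n_clusters: int,
                  seed: int = 0,
                  token_set: TokenSet | None = None
                  ) -> tuple[PooledGraph, TokenSet]:
    """One differentiable-pooling step on a single graph.

    Produces ``min(n_clusters, N)`` tokens as assignment-weighted sums of the
    node features and the coarsened adjacency ``S^T A S``; the soft
    assignment is appended to the (possibly supplied) :class:`TokenSet`.
    """
    if graph.n_nodes == 0:
        raise ValueError("cannot pool an empty graph")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    features = np.asarray(features, dtype=np.float64)
    rng = np.random.default_rng(seed)
    pool = _nn.DiffPoolLayer(features.shape[1], n_clusters, rng)
    tokens, pooled_adj, s, _ = pool(_as_batch(features),
                                    graph.adjacency()[None])
    ts = token_set or TokenSet(tokens.data[0], [],
                               source_graph_size=graph.n_nodes)
    ts.tokens = tokens.data[0]
    ts.assignment = list(ts.assignment) + [s.data[0]]
    return PooledGraph(pooled_adj.data[0], tokens.data[0]), ts


def msgn_forward(graph, features: np.ndarray, n_tokens: int = 8,
                 n_layers: int = 3, seed: int = 0
                 ) -> tuple[PooledGraph, TokenSet]:
    """Full MSGN pass on one graph: GAT stack then DiffPool tokenization."""
    features = np.asarray(features, dtype=np.float64)
    rng = np.random.default_rng(seed)
    msgn = MSGN(features.shape[1], n_layers, n_tokens, rng)
    _, tokens, pooled_adj, s, _ = msgn(_as_batch(features),
                                       graph.adjacency()[None])
    ts = TokenSet(tokens.data[0], [s.data[0]],
                  source_graph_size=graph.n_nodes)
    return PooledGraph(pooled_adj.data[0], tokens.data[0]), ts
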