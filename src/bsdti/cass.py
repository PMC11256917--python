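"""Cross-Attention Substructure Selector (CASS).

Main-graph tokens (protein substructures) are scored against reference-graph
tokens (drug substructures): scaled-dot-product cross attention attends each
main token over the reference set, the attended context modulates the main
tokens element-wise, a small feed-forward network maps each modulated token
to a scalar, and a softmax across tokens yields a relevance distribution.
The top ``k%`` of tokens by relevance are elected (ceil, at least one; ties
broken toward the lower index) and summed into a stage representation used by
the complementary loss.

Hard election is not differentiable; the module keeps a straight-through
correction in the computation graph so the score network still receives
gradient: forward values are exactly the unweighted elected tokens, while the
backward pass sees them scaled by their (softmax) relevance scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from ._tensor import Tensor

SCORE_ATOL = 1e-5


@dataclass
class SelectionResult:
    """Outcome of one top-K%% election over a token set."""

    scores: np.ndarray          # (T,) softmax relevance, sums to 1
    selected_idx: np.ndarray    # ascending indices of the elected tokens
    selected_tokens: np.ndarray  # (K, d) elected rows of the token matrix
    stage_vector: np.ndarray    # (d,) column-sum of the elected rows

    def validate(self) -> None:
        if not np.isclose(self.scores.sum(), 1.0, atol=SCORE_ATOL):
            raise ValueError("scores must sum to 1")
        if (self.scores < -1e-12).any():
            raise ValueError("scores must be non-negative")
        if len(self.selected_idx) == 0:
            raise ValueError("at least one token must be elected")
        if not np.all(np.diff(self.selected_idx) > 0):
            raise ValueError("selected_idx must be sorted ascending")
        if not np.allclose(self.stage_vector,
                           self.selected_tokens.sum(axis=0)):
            raise ValueError("stage_vector must equal the column-sum of the "
                             "selected tokens")


def n_elected(n_tokens: int, k_percent: float) -> int:
    """ceil(k% of T), never below one token."""
    if not 0 < k_percent <= 100:
        raise ValueError("k must lie in (0, 100]")
    return max(1, int(np.ceil(k_percent / 100.0 * n_tokens)))


def top_k_select(tokens: np.ndarray, scores: np.ndarray,
                 k_percent: float) -> SelectionResult:
    """Elect the ceil(k%)-highest-scoring tokens (pure NumPy, no parameters).

    Ties are broken toward the lower token index; the elected indices are
    returned sorted ascending and the stage vector is their unweighted
    column-sum.
    """
    tokens = np.asarray(tokens)
    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    if scores.shape[0] != tokens.shape[0]:
        raise ValueError("scores length must equal token count")
    k_sel = n_elected(len(scores), k_percent)
    order = np.argsort(-scores, kind="stable")   # stable => lower index wins
    sel = np.sort(order[:k_sel])
    chosen = tokens[sel]
    return SelectionResult(scores=scores, selected_idx=sel,
                           selected_tokens=chosen,
                           stage_vector=chosen.sum(axis=0))


class CASS(_nn.Module):
    """Parameterized selector over batched token sets.

    ``forward`` operates on (B, T, d) main tokens and (B, R, d) reference
    tokens; election counts are uniform across the batch because T is.
    """

    def __init__(self, dim: int, rng: np.random.Generator, dtype=None):
        self.Wq = _nn.Linear(dim, dim, rng, dtype=dtype)
        self.Wk = _nn.Linear(dim, dim, rng, dtype=dtype)
        self.Wv = _nn.Linear(dim, dim, rng, dtype=dtype)
        self.ffd = _nn.FeedForward(dim, dim, rng, out_dim=1, dtype=dtype)
        self.dim = dim

    def modulate(self, main: Tensor, ref: Tensor) -> Tensor:
        """Cross attention (queries = main, keys/values = reference) followed
        by element-wise modulation of the main tokens by the context."""
        if ref.shape[-2] == 0:
            raise ValueError("reference token set is empty")
        q = self.Wq(main)
        k = self.Wk(ref)
        v = self.Wv(ref)
        logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dim))
        attn = logits.softmax(axis=-1)
        context = attn @ v
        return main * context

    def score(self, modulated: Tensor) -> Tensor:
        """Per-token scalar through the selection network, softmax across
        tokens; rows sum to one."""
        raw = self.ffd(modulated)                        # (B, T, 1)
        return raw.reshape(raw.shape[:-1]).softmax(axis=-1)

    def forward(self, main: Tensor, ref: Tensor, k_percent: float,
                selection: str = "topk",
                rng: np.random.Generator | None = None):
        """Full election. Returns (selected_tokens_st, stage_vector, scores,
        selected_idx).

        ``selection='random'`` replaces score-based election with a uniform
        random draw (ablation mode); determinism then comes from ``rng``.
        """
        scores = self.score(self.modulate(main, ref))    # (B, T)
        b, t = scores.shape
        k_sel = n_elected(t, k_percent)
        if selection == "random":
            if rng is None:
                raise ValueError("random selection needs an rng")
            idx = np.stack([np.sort(rng.choice(t, size=k_sel, replace=False))
                            for _ in range(b)])
        elif selection == "topk":
            order = np.argsort(-scores.data, axis=-1, kind="stable")
            idx = np.sort(order[:, :k_sel], axis=-1)
        else:
            raise ValueError(f"unknown selection mode {selection!r}")

        chosen = main.take_rows(idx)                     # (B, K, d)
        s_sel = scores[np.arange(b)[:, None], idx]       # (B, K)
        # straight-through: forward values are exactly the elected tokens,
        # but the backward pass sees them scaled by their relevance
        st = chosen * (1.0 + s_sel.reshape(b, k_sel, 1)
                       - Tensor(s_sel.data.reshape(b, k_sel, 1)))
        # the stage vector additionally retains the softmax-weighted sum
        # over *all* tokens in the graph (value-neutral), so every token's
        # relevance score receives gradient — without this, only the
        # initially elected set would ever learn and election could not
        # discover better tokens
        weighted_all = (scores.reshape(b, t, 1) * main).sum(axis=-2)
        stage = st.sum(axis=-2) + (weighted_all - weighted_all.detach())
        return st, stage, scores, idx


# --------------------------------------------------------------------------
# functional wrappers (single token sets, numpy in / numpy out)
# --------------------------------------------------------------------------

def _seeded(dim: int, seed: int) -> CASS:
    return CASS(dim, np.random.default_rng(seed))


def cross_attention_weights(main_tokens: np.ndarray, ref_tokens: np.ndarray,
                            seed: int = 0) -> np.ndarray:
    """Modulated main tokens from a freshly seeded selector (single set)."""
    main = np.asarray(main_tokens, dtype=np.float64)
    ref = np.asarray(ref_tokens, dtype=np.float64)
    mod = _seeded(main.shape[1], seed).modulate(Tensor(main[None]),
                                                Tensor(ref[None]))
    return mod.data[0]


def score_tokens(modulated_tokens: np.ndarray, seed: int = 0) -> np.ndarray:
    """Relevance distribution over tokens from a freshly seeded selection
    network (softmax across tokens; sums to one)."""
    mod = np.asarray(modulated_tokens, dtype=np.float64)
    if mod.shape[0] == 0:
        raise ValueError("empty token set")
    return _seeded(mod.shape[1], seed).score(Tensor(mod[None])).data[0]


def cass_forward(main_tokens: np.ndarray, ref_tokens: np.ndarray,
                 k_percent: float, seed: int = 0) -> SelectionResult:
    """Modulate -> score -> elect on a single pair of token sets."""
    main = np.asarray(main_tokens, dtype=np.float64)
    ref = np.asarray(ref_tokens, dtype=np.float64)
    mod = _seeded(main.shape[1], seed)
    scores = mod.score(mod.modulate(Tensor(main[None]),
                                    Tensor(ref[None]))).data[0]
    return top_k_select(main, scores, k_percent)
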