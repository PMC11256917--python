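"""Multi-molecular-size Interaction Decoding (MMSID).

Drug tokens act as the query set of a (non-causal, position-free)
transformer decoder whose memory is the multiscale protein token stack.
The decoder output ``F`` is softmax-normalized over all of its entries to a
weight matrix ``w``, modulated element-wise (``F' = w * F``), flattened
row-major and passed through a one-hidden-layer MLP to the interaction
logit/probability.  Tokens are unordered sets, so no positional encodings
are added; permuting the protein tokens permutes nothing observable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from ._tensor import Tensor


@dataclass
class InteractionFeature:
    """Decoder output and the derived prediction quantities."""

    F: np.ndarray          # (Td, dec_dim) decoder output
    w: np.ndarray          # softmax weights, same shape, sums to 1
    F_prime: np.ndarray    # w * F
    f: np.ndarray          # row-major flattened F_prime
    y_hat: float           # interaction probability

    def validate(self) -> None:
        if not np.isclose(self.w.sum(), 1.0, atol=1e-5):
            raise ValueError("weights must sum to 1")
        if (self.w <= 0).any():
            raise ValueError("softmax weights must be positive")
        if self.f.shape[0] != self.F.size:
            raise ValueError("flattened length must equal F entry count")
        if not 0.0 <= self.y_hat <= 1.0:
            raise ValueError("probability out of [0, 1]")


def weight_flatten_t(F: Tensor, axis: str = "global") -> Tensor:
    """Softmax-weight the decoder output and flatten (batched Tensor path).

    ``axis='global'`` normalizes over all entries of each sample's F jointly;
    ``axis='row'`` normalizes each token row separately.
    """
    b, t, d = F.shape
    if axis == "global":
        w = F.reshape(b, t * d).softmax(axis=-1).reshape(b, t, d)
    elif axis == "row":
        w = F.softmax(axis=-1)
    else:
        raise ValueError("axis must be 'global' or 'row'")
    return (w * F).reshape(b, t * d)


class MMSID(_nn.Module):
    """Input projections + decoder stack + weighting + MLP head."""

    def __init__(self, token_dim: int, dec_dim: int, heads: int,
                 n_layers: int, drug_tokens: int,
                 rng: np.random.Generator, head_hidden: int = 256,
                 softmax_axis: str = "global", dtype=None):
        self.proj_drug = _nn.Linear(token_dim, dec_dim, rng, dtype=dtype)
        self.proj_prot = _nn.Linear(token_dim, dec_dim, rng, dtype=dtype)
        self.layers = [_nn.TransformerDecoderLayer(dec_dim, heads, dec_dim,
                                                   rng, dtype=dtype)
                       for _ in range(n_layers)]
        self.head = _nn.FeedForward(drug_tokens * dec_dim, head_hidden, rng,
                                    out_dim=1, dtype=dtype)
        self.dec_dim = dec_dim
        self.drug_tokens = drug_tokens
        self.softmax_axis = softmax_axis

    def decode(self, drug_tokens: Tensor, protein_tokens: Tensor,
               memory_mask: np.ndarray | None = None) -> Tensor:
        """Decoder output F, one row per drug token."""
        if drug_tokens.shape[-2] == 0 or protein_tokens.shape[-2] == 0:
            raise ValueError("decoder requires non-empty token sets")
        x = self.proj_drug(drug_tokens)
        memory = self.proj_prot(protein_tokens)
        for layer in self.layers:
            x = layer(x, memory, memory_mask)
        return x

    def forward(self, drug_tokens: Tensor, protein_tokens: Tensor,
                memory_mask: np.ndarray | None = None) -> Tensor:
        """Interaction logit per sample (B,)."""
        F = self.decode(drug_tokens, protein_tokens, memory_mask)
        f = weight_flatten_t(F, self.softmax_axis)       # (B, Td_eff*dec)
        b, flat = f.shape
        want = self.drug_tokens * self.dec_dim
        if flat < want:                                  # clamped tiny drug
            pad = Tensor(np.zeros((b, want - flat), dtype=f.data.dtype))
            from ._tensor import concat
            f = concat([f, pad], axis=-1)
        logit = self.head(f)
        return logit.reshape(b)

    def analyze(self, drug_tokens: np.ndarray, protein_tokens: np.ndarray
                ) -> InteractionFeature:
        """Single-pair pass returning all intermediates."""
        dt = Tensor(np.asarray(drug_tokens)[None])
        pt = Tensor(np.asarray(protein_tokens)[None])
        F = self.decode(dt, pt).data[0]
        w = _softmax_entries(F, self.softmax_axis)
        F_prime = w * F
        f = F_prime.reshape(-1)
        logit = self.forward(dt, pt).data[0]
        return InteractionFeature(F=F, w=w, F_prime=F_prime, f=f,
                                  y_hat=float(1.0 / (1.0 + np.exp(-logit))))


def _softmax_entries(F: np.ndarray, axis: str = "global") -> np.ndarray:
    if axis == "global":
        z = F - F.max()
        e = np.exp(z)
        return e / e.sum()
    z = F - F.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# --------------------------------------------------------------------------
# functional wrappers (single pair, numpy in / numpy out)
# --------------------------------------------------------------------------

def decode(drug_tokens: np.ndarray, protein_tokens: np.ndarray,
           dec_dim: int = 256, heads: int = 8, n_layers: int = 3,
           seed: int = 0) -> np.ndarray:
    """Decoder output F from a freshly seeded decoder (single pair)."""
    dt = np.asarray(drug_tokens, dtype=np.float64)
    pt = np.asarray(protein_tokens, dtype=np.float64)
    rng = np.random.default_rng(seed)
    mod = MMSID(dt.shape[1], dec_dim, heads, n_layers, dt.shape[0], rng)
    return mod.decode(Tensor(dt[None]), Tensor(pt[None])).data[0]


def weight_flatten(F: np.ndarray, axis: str = "global") -> np.ndarray:
    """w = softmax over F's entries; returns flatten(w * F) row-major."""
    F = np.asarray(F, dtype=np.float64)
    if not np.all(np.isfinite(F)):
        raise ValueError("F must be finite")
    return (_softmax_entries(F, axis) * F).reshape(-1)


def predict_head(f: np.ndarray, hidden: int = 256, seed: int = 0,
                 weights=None) -> float:
    """One-hidden-layer MLP + sigmoid on a flattened interaction feature.

    ``weights`` may supply explicit ``(W1, b1, W2, b2)`` arrays; otherwise a
    seeded Glorot initialization is used.
    """
    f = np.asarray(f, dtype=np.float64).reshape(-1)
    if weights is not None:
        W1, b1, W2, b2 = [np.asarray(w, dtype=np.float64) for w in weights]
        if W1.shape[0] != f.shape[0]:
            raise ValueError("feature length mismatch with supplied weights")
        h = np.maximum(f @ W1 + b1, 0.0)
        logit = float(np.asarray(h @ W2 + b2).reshape(-1)[0])
    else:
        rng = np.random.default_rng(seed)
        head = _nn.FeedForward(f.shape[0], hidden, rng, out_dim=1)
        logit = float(head(Tensor(f[None])).data[0, 0])
    return float(1.0 / (1.0 + np.exp(-logit)))
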