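"""Neural-network layers and the Adam optimizer, built on :mod:`bsdti._tensor`.

Layers hold their parameters as named :class:`~bsdti._tensor.Tensor` objects;
``Module.parameters()`` walks the attribute tree so the optimizer and the
(de)serialization code see one flat name->tensor mapping.  Initialization is
Glorot-uniform from a caller-supplied ``numpy.random.Generator`` so every model
build is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor

DEFAULT_DTYPE = np.float64


def glorot(rng: np.random.Generator, shape, dtype=None) -> Tensor:
    dtype = dtype or DEFAULT_DTYPE
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape).astype(dtype),
                  requires_grad=True)


def zeros(shape, dtype=None) -> Tensor:
    return Tensor(np.zeros(shape, dtype=dtype or DEFAULT_DTYPE),
                  requires_grad=True)


class Module:
    """Base class: parameter discovery by attribute walk."""

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                out[key] = val
            elif isinstance(val, Module):
                out.update(val.parameters(prefix=key + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.update(item.parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{key}.{i}"] = item
        return out

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True, dtype=None):
        self.W = glorot(rng, (in_dim, out_dim), dtype)
        self.b = zeros((out_dim,), dtype) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y + self.b if self.b is not None else y


class Embedding(Module):
    """Lookup table initialized at small scale (uniform +-0.05).

    Node features are *summed* — over attribute tables and again over soft
    clusters during pooling — so per-entry scale must be well below Glorot's
    to keep token magnitudes (and the squared-distance complementary loss
    built on them) O(1) at initialization.
    """

    def __init__(self, n: int, dim: int, rng: np.random.Generator, dtype=None,
                 scale: float = 0.15):
        self.table = Tensor(
            rng.uniform(-scale, scale, size=(n, dim)).astype(
                dtype or DEFAULT_DTYPE), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.table[np.asarray(idx)]


class LayerNorm(Module):
    def __init__(self, dim: int, dtype=None, eps: float = 1e-5):
        self.g = Tensor(np.ones(dim, dtype=dtype or DEFAULT_DTYPE),
                        requires_grad=True)
        self.b = zeros((dim,), dtype)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.g + self.b


class FeedForward(Module):
    """Two-layer ReLU MLP, the transformer position-wise block."""

    def __init__(self, dim: int, hidden: int, rng, out_dim=None, dtype=None):
        self.fc1 = Linear(dim, hidden, rng, dtype=dtype)
        self.fc2 = Linear(hidden, out_dim or dim, rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


NEG_INF = -1e9


def make_attn_mask(adj: np.ndarray,
                   node_mask: np.ndarray | None = None) -> np.ndarray:
    """Additive attention mask: 0 where attention is permitted (edges plus
    self-loops), a large negative constant elsewhere.  Padded nodes keep only
    their self-loop so their softmax stays defined (and their output is later
    zeroed by the node mask)."""
    n = adj.shape[-1]
    eye = np.eye(n, dtype=adj.dtype)
    allowed = np.clip(adj + eye, 0.0, 1.0)
    if node_mask is not None:
        allowed = allowed * node_mask[..., None, :] * node_mask[..., :, None]
        allowed = np.clip(allowed + eye, 0.0, 1.0)
    return np.asarray(NEG_INF * (1.0 - allowed), dtype=adj.dtype)


def gat_attention(e_src: Tensor, e_dst: Tensor, attn_mask: np.ndarray,
                  slope: float = 0.2) -> Tensor:
    """Fused attention coefficients softmax_j(LeakyReLU(e_i + e_j) + mask).

    This sits in the model's inner loop over (B, N, N) logit arrays, so the
    elementwise chain is collapsed into one forward and one backward pass
    instead of op-by-op tape entries.
    """
    z = e_src.data + np.swapaxes(e_dst.data, -1, -2)      # (B,N,N)
    pos = z > 0
    m = np.where(pos, z, slope * z) + attn_mask
    m -= m.max(axis=-1, keepdims=True)
    np.exp(m, out=m)
    m /= m.sum(axis=-1, keepdims=True)
    alpha = m
    out = Tensor(alpha, e_src.requires_grad or e_dst.requires_grad)
    if out.requires_grad:
        out._parents = (e_src, e_dst)

        def bw(g):
            tmp = g * alpha
            dz = tmp - alpha * tmp.sum(axis=-1, keepdims=True)
            np.multiply(dz, np.where(pos, 1.0, slope).astype(dz.dtype),
                        out=dz)
            if e_src.requires_grad:
                e_src._accum(dz.sum(axis=-1, keepdims=True))
            if e_dst.requires_grad:
                e_dst._accum(dz.sum(axis=-2)[..., None])
        out._backward = bw
    return out


class GATLayer(Module):
    """Single-head graph attention over a dense masked adjacency.

    ``adj`` is a {0,1} float array of shape (B, N, N) giving permitted
    attention pairs (self-loops are added internally); padded nodes must have
    all-zero rows/columns.
    """

    def __init__(self, dim: int, rng, dtype=None, slope: float = 0.2):
        self.W = glorot(rng, (dim, dim), dtype)
        self.a_src = glorot(rng, (dim, 1), dtype)
        self.a_dst = glorot(rng, (dim, 1), dtype)
        self.b = zeros((dim,), dtype)
        self.slope = slope

    def __call__(self, h: Tensor, adj: np.ndarray,
                 node_mask: np.ndarray | None = None,
                 attn_mask: np.ndarray | None = None) -> Tensor:
        # h: (B,N,D); adj: (B,N,N)
        if attn_mask is None:
            attn_mask = make_attn_mask(adj, node_mask)
        hw = h @ self.W                                   # (B,N,D)
        e_src = hw @ self.a_src                           # (B,N,1)
        e_dst = hw @ self.a_dst                           # (B,N,1)
        alpha = gat_attention(e_src, e_dst, attn_mask, self.slope)
        out = alpha @ hw + self.b
        if node_mask is not None:
            out = out * Tensor(node_mask[..., None])
        return out


class GATStack(Module):
    """`n_layers` graph-attention layers, each wrapped in a residual add.

    With every layer's weights set to zero the stack is the identity map on
    its input features, which is the intended behaviour of the residual
    formulation for very small molecules.
    """

    def __init__(self, n_layers: int, dim: int, rng, in_dim: int | None = None,
                 dtype=None):
        if n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        self.in_proj = (Linear(in_dim, dim, rng, dtype=dtype)
                        if in_dim is not None and in_dim != dim else None)
        self.layers = [GATLayer(dim, rng, dtype) for _ in range(n_layers)]

    def __call__(self, h: Tensor, adj: np.ndarray,
                 node_mask: np.ndarray | None = None) -> Tensor:
        if self.in_proj is not None:
            h = self.in_proj(h)
        attn_mask = make_attn_mask(adj, node_mask)
        for layer in self.layers:
            h = layer(h, adj, node_mask, attn_mask=attn_mask) + h
        return h


class DiffPoolLayer(Module):
    """Differentiable pooling: learned soft assignment of nodes to clusters.

    The assignment matrix ``S`` (B,N,C) is a row-softmax of a linear map of
    the node features; tokens are ``S^T X`` and the coarsened adjacency is
    ``S^T A S``.  When the graph is smaller than the configured cluster count
    the assignment is clamped to the node count by slicing the logit columns,
    so tiny inputs remain well-defined.
    """

    def __init__(self, dim: int, n_clusters: int, rng, dtype=None):
        if n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        self.n_clusters = n_clusters
        self.assign = Linear(dim, n_clusters, rng, dtype=dtype)

    def __call__(self, h: Tensor, adj, node_mask=None, n_clusters=None):
        """Returns (tokens, pooled_adj, S_soft ndarray, aux_losses)."""
        n = h.shape[-2]
        if n == 0:
            raise ValueError("cannot pool an empty graph")
        c = min(n_clusters or self.n_clusters, n)
        logits = h @ self.assign.W[:, :c] + self.assign.b[:c]
        s = logits.softmax(axis=-1)                       # (B,N,C)
        if node_mask is not None:
            s = s * Tensor(node_mask[..., None])
        st = s.swapaxes(-1, -2)                           # (B,C,N)
        tokens = st @ h                                   # (B,C,D)
        adj_t = adj if isinstance(adj, Tensor) else Tensor(adj)
        pooled_adj = st @ adj_t @ s                       # (B,C,C)
        # auxiliary link-prediction + assignment-entropy terms
        recon = s @ st
        diff = recon - adj_t
        denom = float(np.prod(diff.shape[-2:]))
        link_loss = (diff * diff).sum(axis=(-2, -1)) * (1.0 / denom)
        ent = -(s * (s + 1e-12).log()).sum(axis=-1)
        if node_mask is not None:
            ent = ent * Tensor(node_mask)
            nn = np.maximum(node_mask.sum(axis=-1), 1.0)
            ent_loss = ent.sum(axis=-1) / Tensor(nn)
        else:
            ent_loss = ent.mean(axis=-1)
        return tokens, pooled_adj, s, (link_loss.mean(), ent_loss.mean())


class MultiheadAttention(Module):
    def __init__(self, dim: int, heads: int, rng, dtype=None):
        if dim % heads:
            raise ValueError("dim must divide heads")
        self.heads = heads
        self.dim = dim
        self.Wq = Linear(dim, dim, rng, dtype=dtype)
        self.Wk = Linear(dim, dim, rng, dtype=dtype)
        self.Wv = Linear(dim, dim, rng, dtype=dtype)
        self.Wo = Linear(dim, dim, rng, dtype=dtype)

    def _split(self, x: Tensor) -> Tensor:
        b, n, _ = x.shape
        return x.reshape(b, n, self.heads, self.dim // self.heads
                         ).swapaxes(1, 2)                 # (B,H,N,hd)

    def __call__(self, q: Tensor, k: Tensor, v: Tensor,
                 key_mask: np.ndarray | None = None) -> Tensor:
        b, nq, _ = q.shape
        qh, kh, vh = self._split(self.Wq(q)), self._split(self.Wk(k)), \
            self._split(self.Wv(v))
        scale = 1.0 / np.sqrt(self.dim // self.heads)
        logits = (qh @ kh.swapaxes(-1, -2)) * scale       # (B,H,Nq,Nk)
        if key_mask is not None:
            logits = logits + Tensor(
                NEG_INF * (1.0 - key_mask)[:, None, None, :])
        attn = logits.softmax(axis=-1)
        out = (attn @ vh).swapaxes(1, 2).reshape(b, nq, self.dim)
        return self.Wo(out)


class TransformerDecoderLayer(Module):
    """Post-norm decoder layer: self-attention over the query set, cross
    attention to the memory set, position-wise feed-forward.  No causal mask —
    substructure tokens are unordered."""

    def __init__(self, dim: int, heads: int, ffn_dim: int, rng, dtype=None):
        self.self_attn = MultiheadAttention(dim, heads, rng, dtype)
        self.cross_attn = MultiheadAttention(dim, heads, rng, dtype)
        self.ffn = FeedForward(dim, ffn_dim, rng, dtype=dtype)
        self.ln1 = LayerNorm(dim, dtype)
        self.ln2 = LayerNorm(dim, dtype)
        self.ln3 = LayerNorm(dim, dtype)

    def __call__(self, x: Tensor, memory: Tensor,
                 memory_mask: np.ndarray | None = None) -> Tensor:
        x = self.ln1(x + self.self_attn(x, x, x))
        x = self.ln2(x + self.cross_attn(x, memory, memory, memory_mask))
        return self.ln3(x + self.ffn(x))


class Adam:
    """Adam with an optional multiplicative per-epoch learning-rate decay."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.base_lr = lr
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def set_epoch(self, epoch: int, decay: float = 0.10) -> None:
        """lr_e = lr0 * (1 - decay)^epoch."""
        self.lr = self.base_lr * (1.0 - decay) ** epoch

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
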