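"""End-to-end model assembly, training loop and ablation switches.

The full model chains the extraction stage (drug tokens at a fixed scale,
protein tokens at a cascade of scales with per-scale top-K% election) into
the transformer-decoder interaction head, and trains it with Adam under an
exponential learning-rate schedule (lr_e = lr0 * (1 - decay)^e), batch-level
shuffling, and early stopping on validation AUROC.  Everything downstream of
the config seed is deterministic on one machine.

Batches group pairs whose clamped token-count signature matches (drugs
smaller than the token count, proteins shorter than a pooling scale), pad
node dimensions inside the group, and mask padded nodes out of attention and
pooling, so scores are invariant to how the pair list is partitioned.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn, objective
from ._tensor import Tensor, concat
from .mmcmse import MMCMSE, effective_scales
from .molio import PairDataset

log = logging.getLogger("bsdti")

ABLATION_FLAGS = ("no_cass", "no_cl", "cl_all_time", "no_mmsid",
                  "no_topk", "no_mmcmse")


@dataclass
class ModelConfig:
    """All model and optimization hyperparameters."""

    gat_layers: int = 3
    hidden_dim: int = 80
    drug_tokens: int = 8
    protein_scales: tuple = (1024, 512, 256, 128)
    top_k_percent: float = 30.0
    decoder_layers: int = 3
    decoder_heads: int = 8
    decoder_hidden: int = 256
    head_hidden: int = 256
    cl_weight: float = 0.01
    cl_mode: str = "positives_only"
    scale_reduction: str = "mean"
    aux_pool_weight: float = 1e-3
    softmax_axis: str = "global"
    lr: float = 0.001
    lr_decay_per_epoch: float = 0.10
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    dtype: str = "float64"
    ablation: str | None = None

    def __post_init__(self):
        for name in ("gat_layers", "hidden_dim", "drug_tokens",
                     "decoder_layers", "decoder_heads", "decoder_hidden",
                     "head_hidden", "batch_size", "max_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.top_k_percent <= 100:
            raise ValueError("top_k_percent must lie in (0, 100]")
        self.protein_scales = tuple(int(s) for s in self.protein_scales)
        if self.ablation is not None and self.ablation not in ABLATION_FLAGS:
            raise ValueError(f"unknown ablation flag {self.ablation!r}; "
                             f"known: {ABLATION_FLAGS}")

    # effective settings after applying the ablation flag
    @property
    def k_effective(self) -> float:
        return 100.0 if self.ablation == "no_topk" else self.top_k_percent

    @property
    def cl_weight_effective(self) -> float:
        return 0.0 if self.ablation == "no_cl" else self.cl_weight

    @property
    def cl_mode_effective(self) -> str:
        return "all_pairs" if self.ablation == "cl_all_time" \
            else self.cl_mode

    @property
    def selection_mode(self) -> str:
        return "random" if self.ablation == "no_cass" else "topk"

    @property
    def single_scale(self) -> bool:
        return self.ablation == "no_mmcmse"

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    def to_yaml(self, path) -> None:
        import yaml

        obj = asdict(self)
        obj["protein_scales"] = list(self.protein_scales)
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        import yaml

        obj = yaml.safe_load(Path(path).read_text())
        return cls(**obj)


@dataclass
class Batch:
    drug_idx: np.ndarray      # (B, Nd, 9)
    drug_adj: np.ndarray      # (B, Nd, Nd)
    drug_mask: np.ndarray     # (B, Nd)
    prot_idx: np.ndarray      # (B, Np)
    prot_adj: np.ndarray
    prot_mask: np.ndarray
    y: np.ndarray             # (B,)
    positions: np.ndarray     # original indices into the pair list
    drug_tokens_eff: int
    eff_scales: tuple


def _pair_signature(cfg: ModelConfig, drug_g, prot_g):
    td = min(cfg.drug_tokens, drug_g.n_nodes)
    eff = effective_scales(list(cfg.protein_scales), prot_g.n_nodes)
    if cfg.single_scale:
        eff = eff[:1]
    return td, tuple(eff)


def build_batches(dataset: PairDataset, indices, batch_size: int,
                  cfg: ModelConfig) -> list[Batch]:
    """Group pairs by token-count signature, then chunk and pad."""
    groups: dict[tuple, list[int]] = {}
    for i in indices:
        d_id, p_id, _ = dataset.records[i]
        key = _pair_signature(cfg, dataset.drugs[d_id],
                              dataset.proteins[p_id])
        groups.setdefault(key, []).append(i)

    dt = cfg.np_dtype
    batches = []
    for (td, eff), members in groups.items():
        for lo in range(0, len(members), batch_size):
            chunk = members[lo:lo + batch_size]
            dgs = [dataset.drugs[dataset.records[i][0]] for i in chunk]
            pgs = [dataset.proteins[dataset.records[i][1]] for i in chunk]
            nd = max(g.n_nodes for g in dgs)
            npr = max(g.n_nodes for g in pgs)
            b = len(chunk)
            batch = Batch(
                drug_idx=np.zeros((b, nd, 9), dtype=np.int64),
                drug_adj=np.zeros((b, nd, nd), dtype=dt),
                drug_mask=np.zeros((b, nd), dtype=dt),
                prot_idx=np.zeros((b, npr), dtype=np.int64),
                prot_adj=np.zeros((b, npr, npr), dtype=dt),
                prot_mask=np.zeros((b, npr), dtype=dt),
                y=np.array([dataset.records[i][2] for i in chunk],
                           dtype=dt),
                positions=np.array(chunk, dtype=np.int64),
                drug_tokens_eff=td, eff_scales=eff)
            for j, (dg, pg) in enumerate(zip(dgs, pgs)):
                batch.drug_idx[j, :dg.n_nodes] = dg.nodes
                batch.drug_adj[j, :dg.n_nodes, :dg.n_nodes] = \
                    dg.adjacency(dt)
                batch.drug_mask[j, :dg.n_nodes] = 1.0
                batch.prot_idx[j, :pg.n_nodes] = pg.residues
                batch.prot_adj[j, :pg.n_nodes, :pg.n_nodes] = \
                    pg.adjacency(dt)
                batch.prot_mask[j, :pg.n_nodes] = 1.0
            batches.append(batch)
    return batches


class DTIModel(_nn.Module):
    """Full assembly: extraction stage + interaction decoder + loss."""

    def __init__(self, config: ModelConfig):
        self.cfg = config
        rng = np.random.default_rng(config.seed)
        dt = config.np_dtype
        self.extractor = MMCMSE(config.hidden_dim, config.gat_layers,
                                config.drug_tokens,
                                list(config.protein_scales), rng, dtype=dt)
        if config.ablation == "no_mmsid":
            # decoder replaced by mean-pooled drug/protein features
            self.pool_head = _nn.FeedForward(2 * config.hidden_dim,
                                             config.head_hidden, rng,
                                             out_dim=1, dtype=dt)
            self.decoder = None
        else:
            from .mmsid import MMSID

            self.decoder = MMSID(config.hidden_dim, config.decoder_hidden,
                                 config.decoder_heads, config.decoder_layers,
                                 config.drug_tokens, rng,
                                 head_hidden=config.head_hidden,
                                 softmax_axis=config.softmax_axis, dtype=dt)
        self._sel_rng = np.random.default_rng(config.seed + 7919)

    # ------------------------------------------------------------- forward
    def forward_batch(self, batch: Batch) -> dict:
        cfg = self.cfg
        d_tokens, v_d, _, d_aux = self.extractor.drug_forward(
            batch.drug_idx, batch.drug_adj, batch.drug_mask,
            n_tokens=batch.drug_tokens_eff)
        prot = self.extractor.protein_forward(
            batch.prot_idx, batch.prot_adj, batch.prot_mask, d_tokens,
            cfg.k_effective, eff_scales=batch.eff_scales,
            selection=cfg.selection_mode, rng=self._sel_rng,
            single_scale=cfg.single_scale)
        if self.decoder is None:
            f = concat([d_tokens.mean(axis=-2),
                        prot["concat_tokens"].mean(axis=-2)], axis=-1)
            logits = self.pool_head(f).reshape(len(batch.y))
        else:
            logits = self.decoder.forward(d_tokens, prot["concat_tokens"])
        aux_terms = [d_aux[0] + d_aux[1]] + [a[0] + a[1]
                                             for a in prot["aux"]]
        return {"logits": logits, "v_d": v_d, "stages": prot["stages"],
                "aux": aux_terms, "indices": prot["indices"],
                "scores": prot["scores"],
                "assignments": prot["assignments"]}

    def loss(self, out: dict, y: np.ndarray) -> Tensor:
        cfg = self.cfg
        loss_cfg = objective.LossConfig(
            cl_weight=cfg.cl_weight_effective,
            cl_mode=cfg.cl_mode_effective,
            scale_reduction=cfg.scale_reduction)
        total = objective.total_loss(out["logits"], y, out["v_d"],
                                     out["stages"], loss_cfg)
        if cfg.aux_pool_weight > 0:
            aux = out["aux"][0]
            for a in out["aux"][1:]:
                aux = aux + a
            total = total + cfg.aux_pool_weight * aux
        return total

    # ------------------------------------------------------------- training
    def fit(self, train_set: PairDataset, val_set: PairDataset
            ) -> pd.DataFrame:
        cfg = self.cfg
        if len(train_set) == 0 or len(val_set) == 0:
            raise ValueError("train and validation sets must be non-empty")
        vl = val_set.labels
        if vl.min() == vl.max():
            raise ValueError("validation set needs both classes")

        params = self.parameters()
        opt = _nn.Adam(params, lr=cfg.lr)
        shuffle_rng = np.random.default_rng(cfg.seed + 1)
        history = []
        # early-stopping key: val AUROC, ties broken by lower val BCE (so
        # saturated-AUROC runs keep tracking the best-calibrated epoch)
        best_key, best_state, best_epoch = (-np.inf, -np.inf), None, -1
        for epoch in range(cfg.max_epochs):
            opt.set_epoch(epoch, cfg.lr_decay_per_epoch)
            order = shuffle_rng.permutation(len(train_set))
            batches = build_batches(train_set, order, cfg.batch_size, cfg)
            epoch_losses = []
            logits_all = np.empty(len(train_set))
            y_all = np.empty(len(train_set))
            for batch in batches:
                out = self.forward_batch(batch)
                loss = self.loss(out, batch.y)
                value = float(loss.data)
                if not np.isfinite(value):
                    raise RuntimeError(
                        f"training diverged: non-finite loss {value} at "
                        f"epoch {epoch} (lr={opt.lr:.2e})")
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(value)
                logits_all[batch.positions] = out["logits"].data
                y_all[batch.positions] = batch.y
            train_loss = float(np.mean(epoch_losses))
            train_m = objective.metrics(y_all.astype(int),
                                        1 / (1 + np.exp(-logits_all)))
            val_scores = self.predict(val_set)["probability"].to_numpy()
            val_m = objective.metrics(vl, val_scores)
            p = np.clip(val_scores, 1e-12, 1 - 1e-12)
            val_bce = float(-np.mean(vl * np.log(p) +
                                     (1 - vl) * np.log(1 - p)))
            history.append({"epoch": epoch, "lr": opt.lr,
                            "train_loss": train_loss,
                            "train_auroc": train_m["auroc"],
                            "val_auroc": val_m["auroc"],
                            "val_auprc": val_m["auprc"],
                            "val_bce": val_bce})
            log.info("epoch %d lr %.2e loss %.4f train AUROC %.4f "
                     "val AUROC %.4f", epoch, opt.lr, train_loss,
                     train_m["auroc"], val_m["auroc"])
            key = (val_m["auroc"], -val_bce)
            if key > best_key:
                best_key = key
                best_state = self.state_dict()
                best_epoch = epoch
            elif epoch - best_epoch >= cfg.patience:
                log.info("early stop at epoch %d (best %d)", epoch,
                         best_epoch)
                break
        if best_state is not None:
            self.load_state_dict(best_state)
        hist = pd.DataFrame(history)
        hist.attrs["best_epoch"] = best_epoch
        return hist

    def evaluate_loss(self, dataset: PairDataset) -> float:
        """Dataset-level training loss of the current weights (size-weighted
        over signature groups, equivalent to one full batch per group)."""
        total = 0.0
        for batch in build_batches(dataset, range(len(dataset)),
                                   len(dataset), self.cfg):
            out = self.forward_batch(batch)
            total += float(self.loss(out, batch.y).data) * len(batch.y)
        return total / max(len(dataset), 1)

    # ------------------------------------------------------------ inference
    def predict(self, dataset: PairDataset,
                threshold: float = 0.5) -> pd.DataFrame:
        """Per-pair probability and binary call at the threshold."""
        cols = ["drug_id", "protein_id", "label", "probability",
                "prediction"]
        if len(dataset) == 0:
            return pd.DataFrame(columns=cols)
        probs = np.empty(len(dataset))
        for batch in build_batches(dataset, range(len(dataset)),
                                   self.cfg.batch_size, self.cfg):
            out = self.forward_batch(batch)
            probs[batch.positions] = 1 / (1 + np.exp(-out["logits"].data))
        df = dataset.to_frame()
        df["probability"] = probs
        df["prediction"] = (probs >= threshold).astype(int)
        return df

    def analyze_pair(self, drug_graph, protein_graph) -> dict:
        """Single-pair pass keeping every interpretable intermediate."""
        tokens = self.extractor.extract_drug(drug_graph)
        mst = self.extractor.extract_protein_multiscale(
            protein_graph, tokens, self.cfg.k_effective)
        result = {"drug_tokens": tokens, "multiscale": mst}
        if self.decoder is not None:
            feat = self.decoder.analyze(tokens.tokens, mst.concat_tokens)
            result["interaction"] = feat
            result["probability"] = feat.y_hat
        else:
            f = np.concatenate([tokens.tokens.mean(axis=0),
                                mst.concat_tokens.mean(axis=0)])
            logit = float(self.pool_head(Tensor(f[None])).data[0, 0])
            result["probability"] = float(1 / (1 + np.exp(-logit)))
        return result

    # ---------------------------------------------------------- persistence
    def save(self, run_dir) -> None:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        self.cfg.to_yaml(run_dir / "config.yaml")
        state = self.state_dict()
        np.savez(run_dir / "weights.npz", **state)
        (run_dir / "manifest.json").write_text(json.dumps(
            {"format": "bsdti-model-v1",
             "n_parameters": int(sum(v.size for v in state.values()))}))

    @classmethod
    def load(cls, run_dir) -> "DTIModel":
        run_dir = Path(run_dir)
        cfg = ModelConfig.from_yaml(run_dir / "config.yaml")
        model = cls(cfg)
        with np.load(run_dir / "weights.npz") as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
        return model


# --------------------------------------------------------------------------
# module-level operations
# --------------------------------------------------------------------------

def train(config: ModelConfig, train_set: PairDataset,
          val_set: PairDataset) -> tuple[DTIModel, pd.DataFrame]:
    """Build a model from the config and fit it; returns (model, history)."""
    model = DTIModel(config)
    history = model.fit(train_set, val_set)
    return model, history


def predict(model: DTIModel, pairs: PairDataset,
            threshold: float = 0.5) -> pd.DataFrame:
    return model.predict(pairs, threshold=threshold)


def ablate(config: ModelConfig, flag: str) -> DTIModel:
    """Assemble a model variant with one component switched off."""
    if flag not in ABLATION_FLAGS:
        raise ValueError(f"unknown ablation flag {flag!r}; "
                         f"known: {ABLATION_FLAGS}")
    return DTIModel(replace(config, ablation=flag))


def train_val_split(dataset: PairDataset, val_fraction: float, seed: int,
                    stratify: bool = False
                    ) -> tuple[PairDataset, PairDataset]:
    """Deterministic shuffled split of a pair dataset.

    With ``stratify`` the held-out fraction is drawn per class, so small
    validation splits keep both labels whenever the data has them."""
    rng = np.random.default_rng(seed)
    if stratify:
        labels = dataset.labels
        val_idx = []
        for cls in np.unique(labels):
            members = rng.permutation(np.flatnonzero(labels == cls))
            n_val = max(1, int(round(val_fraction * len(members))))
            val_idx.extend(members[:n_val].tolist())
        val_mask = np.zeros(len(dataset), dtype=bool)
        val_mask[val_idx] = True
        return (dataset.subset(np.flatnonzero(~val_mask)),
                dataset.subset(np.sort(val_idx)))
    order = rng.permutation(len(dataset))
    n_val = max(1, int(round(val_fraction * len(dataset))))
    return dataset.subset(order[n_val:]), dataset.subset(order[:n_val])
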