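"""Training losses and evaluation metrics.

The total loss is binary cross-entropy plus a weighted *complementary loss*:
the squared Euclidean distance between the drug stage vector and the protein
stage vector, applied only to interacting (label 1) pairs — similar elected
substructures are pulled together where binding occurs, while non-binding
pairs are left unconstrained.  With multiscale protein stage vectors the
penalty is computed per scale and reduced (mean by default) across scales.

Threshold and rank metrics (AUROC, AUPRC, MCC, F1) delegate to scikit-learn;
ROC enrichment — TPR at a fixed small FPR divided by that FPR, the early
recognition statistic of virtual screening — is computed here from the
step-interpolated empirical ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, as_tensor

RE_FRACTIONS = (0.005, 0.01, 0.02, 0.05)


@dataclass
class LossConfig:
    cl_weight: float = 0.01
    cl_mode: str = "positives_only"       # or "all_pairs"
    scale_reduction: str = "mean"         # over protein scales: mean | sum

    def __post_init__(self):
        if self.cl_weight < 0:
            raise ValueError("cl_weight must be non-negative")
        if self.cl_mode not in ("positives_only", "all_pairs"):
            raise ValueError(f"unknown cl_mode {self.cl_mode!r}")
        if self.scale_reduction not in ("mean", "sum"):
            raise ValueError("scale_reduction must be 'mean' or 'sum'")


def _cl_single(v_d: Tensor, v_p: Tensor, y: np.ndarray, mode: str) -> Tensor:
    diff = v_d - v_p
    sq = (diff * diff).sum(axis=-1)            # (B,)
    if mode == "positives_only":
        sq = sq * Tensor(np.asarray(y, dtype=sq.data.dtype))
    return sq.sum()


def complementary_loss(v_d, v_p, y, mode: str = "positives_only",
                       scale_reduction: str = "mean"):
    """CL = sum_i y_i * ||v_d,i - v_p,i||^2 over the batch.

    ``v_p`` may be a single (B, d) array/Tensor or a list of them (one per
    protein scale), in which case the per-scale sums are reduced by
    ``scale_reduction``.  Accepts Tensors (differentiable) or arrays; the
    return type follows the inputs.
    """
    v_d_t = as_tensor(v_d)
    y = np.asarray(y)
    if isinstance(v_p, (list, tuple)):
        parts = [_cl_single(v_d_t, as_tensor(p), y, mode) for p in v_p]
        total = parts[0]
        for p in parts[1:]:
            total = total + p
        if scale_reduction == "mean":
            total = total * (1.0 / len(parts))
    else:
        vp_t = as_tensor(v_p)
        if vp_t.shape != v_d_t.shape:
            raise ValueError(f"shape mismatch: {v_d_t.shape} vs "
                             f"{vp_t.shape}")
        total = _cl_single(v_d_t, vp_t, y, mode)
    if isinstance(v_d, Tensor) or (isinstance(v_p, (list, tuple)) and
                                   any(isinstance(p, Tensor) for p in v_p)) \
            or isinstance(v_p, Tensor):
        return total
    return float(total.data)


def bce_with_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy on logits."""
    x = as_tensor(logits)
    yt = Tensor(np.asarray(y, dtype=x.data.dtype))
    absx = x.relu() + (-x).relu()
    per = x.relu() - x * yt + (1.0 + (-absx).exp()).log()
    return per.mean()


def total_loss(logits, y, v_d, v_p, config: LossConfig | None = None):
    """L = BCE + w * CL / batch_size.

    The complementary term is the batch *sum* of squared distances (its
    natural definition); dividing by the batch size here keeps the
    recommended weight w = 0.01 meaningful at any batch size.
    """
    config = config or LossConfig()
    y = np.asarray(y)
    b = bce_with_logits(logits, y)
    if config.cl_weight == 0.0:
        return b
    cl = complementary_loss(v_d, v_p, y, mode=config.cl_mode,
                            scale_reduction=config.scale_reduction)
    cl = as_tensor(cl)
    return b + (config.cl_weight / max(len(y), 1)) * cl


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def roc_enrichment(y_true, y_score, fractions=RE_FRACTIONS) -> dict:
    """RE_x = TPR(FPR = x) / x on the step-interpolated empirical ROC.

    At each requested FPR fraction the TPR of the last ROC step with
    FPR <= x is used.  Requires both classes present.
    """
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return {f"re_{100 * x:g}%": float("nan") for x in fractions}
    order = np.argsort(-y_score, kind="stable")
    yt = y_true[order]
    scores = y_score[order]
    tp = np.cumsum(yt == 1)
    fp = np.cumsum(yt == 0)
    # keep only the last index of each tied-score block
    last = np.r_[scores[1:] != scores[:-1], True]
    tpr = np.r_[0.0, tp[last] / n_pos]
    fpr = np.r_[0.0, fp[last] / n_neg]
    out = {}
    for x in fractions:
        idx = np.searchsorted(fpr, x, side="right") - 1
        out[f"re_{100 * x:g}%"] = float(tpr[idx] / x)
    return out


def metrics(y_true, y_score, threshold: float = 0.5,
            re_fractions=RE_FRACTIONS) -> dict:
    """AUROC, AUPRC, MCC, F1 (at the threshold) and ROC enrichment.

    Rank metrics are reported as NaN (undefined), not zero, when only one
    class is present.
    """
    from sklearn.metrics import (average_precision_score, f1_score,
                                 matthews_corrcoef, roc_auc_score)

    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=float)
    y_pred = (y_score >= threshold).astype(int)
    single_class = len(np.unique(y_true)) < 2
    out = {
        "auroc": (float("nan") if single_class
                  else float(roc_auc_score(y_true, y_score))),
        "auprc": (float("nan") if single_class
                  else float(average_precision_score(y_true, y_score))),
        "mcc": float(matthews_corrcoef(y_true, y_pred)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
    }
    out.update(roc_enrichment(y_true, y_score, re_fractions))
    return out
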