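"""Classification losses for class-imbalanced learning, with analytic gradients.

The centrepiece is the **double-balanced (DB) loss**, which reweights the
squared log-probability of the true class by both the size-balance factor
``alpha`` (effective-sample-size imbalance) and the class prior ``pp``
(sample-difficulty imbalance):

    printed variant :  (1 + alpha_y * pp_y) * (log p_y)^2
    derived variant :  (1 + alpha_y) * pp_y * (log p_y)^2

The two variants reflect two readings of how the difficulty weight composes
with the size-balanced cross-entropy; both are exposed and share one property
suite.  Comparison losses (plain, weighted and class-balanced cross-entropy,
focal loss) are provided on the same interface, together with exact gradients
with respect to logits so a classifier can be trained without an autodiff
framework.

All losses use the natural logarithm and clamp probabilities at ``eps``
before any log, since ``(log p)^2`` diverges quadratically at ``p = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .balance import WeightTable

__all__ = [
    "LossConfig",
    "softmax",
    "cross_entropy",
    "weighted_cross_entropy",
    "focal_loss",
    "class_balanced_ce",
    "difficulty_weight",
    "db_loss",
    "batch_loss",
    "grad_wrt_logits",
    "batch_grad_logits",
    "weight_curve",
    "default_wce_weights",
]

LOSS_KINDS = ("ce", "wce", "focal", "cb", "db")
DB_VARIANTS = ("printed", "derived")


@dataclass(frozen=True)
class LossConfig:
    """Selects a loss family and its hyperparameters.

    ``kind``       one of ce | wce | focal | cb | db
    ``gamma``      focal modulation exponent (>= 0)
    ``variant``    DB parenthesization, "printed" or "derived"
    ``eps``        probability clamp floor applied before any log
    ``reduction``  batch reduction: mean | sum | none
    """

    kind: str = "ce"
    gamma: float = 2.0
    variant: str = "printed"
    eps: float = 1e-12
    reduction: str = "mean"

    def __post_init__(self) -> None:
        if self.kind not in LOSS_KINDS:
            raise ValueError(f"unknown loss kind {self.kind!r}; choose from {LOSS_KINDS}")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.variant not in DB_VARIANTS:
            raise ValueError(f"unknown DB variant {self.variant!r}; choose from {DB_VARIANTS}")
        if not 0.0 < self.eps <= 1e-6:
            raise ValueError("eps must lie in (0, 1e-6]")
        if self.reduction not in ("mean", "sum", "none"):
            raise ValueError("reduction must be mean, sum or none")


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis (max-subtraction)."""
    z = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("logits must be finite")
    z = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def _clamp(p: np.ndarray | float, eps: float) -> np.ndarray | float:
    return np.maximum(p, eps)


def _p_true(probs: np.ndarray, y: int) -> float:
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a single probability vector")
    if not 0 <= int(y) < p.shape[0]:
        raise ValueError(f"label index {y} out of range for k={p.shape[0]}")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("probabilities must be non-negative and sum to 1")
    return float(p[int(y)])


def cross_entropy(probs: np.ndarray, y: int, eps: float = 1e-12) -> float:
    """Cross-entropy of the true class: ``-log p_y`` (natural log)."""
    return -float(np.log(_clamp(_p_true(probs, y), eps)))


def weighted_cross_entropy(
    probs: np.ndarray, y: int, class_weights: np.ndarray, eps: float = 1e-12
) -> float:
    """``w_y * (-log p_y)`` with positive per-class weights."""
    w = np.asarray(class_weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("class weights must be positive")
    return float(w[int(y)]) * cross_entropy(probs, y, eps)


def default_wce_weights(table: WeightTable) -> np.ndarray:
    """Inverse-class-frequency weights rescaled to mean 1.

    The normalized inverse frequency (the rho=1 prior) is rescaled so the
    average weight is one, keeping the loss magnitude comparable to plain
    cross-entropy.
    """
    n = table.counts.as_array()
    pp = (1.0 / n) / (1.0 / n).sum()
    return pp / pp.mean()


def focal_loss(probs: np.ndarray, y: int, gamma: float = 2.0, eps: float = 1e-12) -> float:
    """``(1 - p_y)^gamma * (-log p_y)`` — down-weights easy samples."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    p = _p_true(probs, y)
    return (1.0 - p) ** gamma * cross_entropy(probs, y, eps)


def class_balanced_ce(
    probs: np.ndarray, y: int, counts, beta: float, eps: float = 1e-12
) -> float:
    """Cross-entropy weighted by the inverse effective sample size.

    The weight is ``e_y = (1 - beta) / (1 - beta^{n_y})``; at beta = 0 it is
    exactly 1 and the loss reduces to plain cross-entropy.
    """
    from .balance import effective_sample_sizes

    e = 1.0 / effective_sample_sizes(counts, beta)
    return float(e[int(y)]) * cross_entropy(probs, y, eps)


def difficulty_weight(prior_y: float, p_true: float, eps: float = 1e-12) -> float:
    """Prior-weighted distance ``-pp_y * log p_y`` between prior and prediction.

    Large when the model assigns low probability to the true class of a
    sample (a hard sample), zero when the prediction is certain and correct.
    """
    return -float(prior_y) * float(np.log(_clamp(p_true, eps)))


def _db_scale(table: WeightTable, y: np.ndarray | int, variant: str) -> np.ndarray | float:
    a = table.alpha[y]
    w = table.prior[y]
    if variant == "printed":
        return 1.0 + a * w
    if variant == "derived":
        return (1.0 + a) * w
    raise ValueError(f"unknown DB variant {variant!r}")


def db_loss(
    probs: np.ndarray,
    y: int,
    table: WeightTable,
    variant: str = "printed",
    eps: float = 1e-12,
) -> float:
    """Double-balanced loss of one sample.

    ``(1 + alpha_y * pp_y) * (log p_y)^2`` ("printed") or
    ``(1 + alpha_y) * pp_y * (log p_y)^2`` ("derived").  Non-negative, zero
    iff the true class gets probability one, and larger for rarer classes at
    any fixed prediction.
    """
    p = np.asarray(probs, dtype=float)
    if p.shape[-1] != table.k:
        raise ValueError(
            f"probability vector has k={p.shape[-1]} but weight table has k={table.k}"
        )
    log_p = np.log(_clamp(_p_true(probs, y), eps))
    return float(_db_scale(table, int(y), variant)) * float(log_p**2)


def _per_sample_losses(
    cfg: LossConfig, P: np.ndarray, y: np.ndarray, table: WeightTable | None
) -> np.ndarray:
    """Vectorized per-sample loss values for an n x k probability matrix."""
    pt = np.clip(P[np.arange(P.shape[0]), y], None, None)
    pc = _clamp(pt, cfg.eps)
    log_p = np.log(pc)
    if cfg.kind == "ce":
        return -log_p
    if cfg.kind == "focal":
        return (1.0 - pt) ** cfg.gamma * (-log_p)
    if table is None:
        raise ValueError(f"loss kind {cfg.kind!r} requires a WeightTable")
    if cfg.kind == "wce":
        return default_wce_weights(table)[y] * (-log_p)
    if cfg.kind == "cb":
        return table.inverse_effective[y] * (-log_p)
    if cfg.kind == "db":
        return _db_scale(table, y, cfg.variant) * log_p**2
    raise ValueError(f"unknown loss kind {cfg.kind!r}")


def batch_loss(
    cfg: LossConfig,
    prob_matrix: np.ndarray,
    labels: np.ndarray,
    table: WeightTable | None = None,
):
    """Apply the configured loss row-wise; reduce per ``cfg.reduction``."""
    P = np.atleast_2d(np.asarray(prob_matrix, dtype=float))
    y = np.asarray(labels, dtype=int).ravel()
    if P.shape[0] != y.shape[0]:
        raise ValueError("prob_matrix rows and labels must match")
    if np.any(y < 0) or np.any(y >= P.shape[1]):
        raise ValueError("label index out of range")
    if np.any(P < 0) or np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-6:
        raise ValueError("rows of prob_matrix must be probability vectors")
    values = _per_sample_losses(cfg, P, y, table)
    if cfg.reduction == "mean":
        return float(values.mean())
    if cfg.reduction == "sum":
        return float(values.sum())
    return values


def _dloss_dp(
    cfg: LossConfig, pt: np.ndarray, y: np.ndarray, table: WeightTable | None
) -> np.ndarray:
    """d(loss)/d(p_true) evaluated at the clamped true-class probability."""
    pc = _clamp(pt, cfg.eps)
    if cfg.kind == "ce":
        return -1.0 / pc
    if cfg.kind == "focal":
        g = cfg.gamma
        m = np.maximum(1.0 - pt, 0.0)
        out = -(m**g) / pc
        if g > 0:  # modulation term vanishes as p_true -> 1 for every gamma > 0
            hard = m > 0
            out[hard] += g * m[hard] ** (g - 1.0) * np.log(pc[hard])
        return out
    if table is None:
        raise ValueError(f"loss kind {cfg.kind!r} requires a WeightTable")
    if cfg.kind == "wce":
        return -default_wce_weights(table)[y] / pc
    if cfg.kind == "cb":
        return -table.inverse_effective[y] / pc
    if cfg.kind == "db":
        return _db_scale(table, y, cfg.variant) * 2.0 * np.log(pc) / pc
    raise ValueError(f"unknown loss kind {cfg.kind!r}")


def batch_grad_logits(
    cfg: LossConfig,
    logits: np.ndarray,
    labels: np.ndarray,
    table: WeightTable | None = None,
) -> np.ndarray:
    """Gradient of the per-sample loss w.r.t. logits, one row per sample.

    The losses depend on the logits only through the softmax probability of
    the true class, so the chain rule through the softmax Jacobian gives
    ``d loss / d z_j = dL/dp * p_y * (1[j = y] - p_j)``.  For plain
    cross-entropy this collapses to the classical ``p - onehot(y)``.
    """
    Z = np.atleast_2d(np.asarray(logits, dtype=float))
    y = np.asarray(labels, dtype=int).ravel()
    P = softmax(Z)
    pt = P[np.arange(P.shape[0]), y]
    dLdp = _dloss_dp(cfg, pt, y, table)
    onehot = np.zeros_like(P)
    onehot[np.arange(P.shape[0]), y] = 1.0
    return (dLdp * pt)[:, None] * (onehot - P)


def grad_wrt_logits(
    cfg: LossConfig,
    logits: np.ndarray,
    y: int,
    table: WeightTable | None = None,
) -> np.ndarray:
    """Analytic gradient for a single sample (see :func:`batch_grad_logits`)."""
    z = np.asarray(logits, dtype=float)
    if z.ndim != 1:
        raise ValueError("expected a single logit vector")
    return batch_grad_logits(cfg, z[None, :], np.array([int(y)]), table)[0]


def weight_curve(
    table: WeightTable,
    class_index: int,
    p_grid: np.ndarray,
    variant: str = "printed",
    eps: float = 1e-12,
) -> np.ndarray:
    """Effective multiplier on cross-entropy, ``W(p) = DB(p) / (-log p)``.

    For the printed variant ``W(p) = (1 + alpha pp) * (-log p)``: strictly
    decreasing in p (easy samples are suppressed) and, for unequal counts,
    ordered opposite to the class counts at every p.
    """
    p = np.asarray(p_grid, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("p grid must lie strictly inside (0, 1)")
    scale = float(_db_scale(table, int(class_index), variant))
    return scale * (-np.log(_clamp(p, eps)))
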