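"""Multi-objective training: binary cross-entropy for the serious/non-serious
task plus a diversity (multi-label) cross-entropy for the seven seriousness
classes, combined as ``loss_total = loss_association + alpha * loss_severity``
and minimized with Adam.

Class labels exist only for serious pairs, so by default
(``severity_mask_mode="serious_only"``) non-serious samples contribute to the
association loss only.  Predictions are clipped to [eps, 1-eps] before logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .model import GCAPModel, PairFeatures
from .nn import Adam

EPS = 1e-7


@dataclass(frozen=True)
class TrainingConfig:
    alpha: float = 1.0
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    severity_mask_mode: str = "serious_only"  # or "all"
    severity_literal: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.severity_mask_mode not in ("serious_only", "all"):
            raise ValueError("severity_mask_mode must be 'serious_only' or 'all'")


@dataclass
class LossBreakdown:
    loss_association: float
    loss_severity: float
    loss_total: float
    n: int


def _clip(pred: Tensor) -> Tensor:
    return ad.clamp(pred, EPS, 1.0 - EPS)


def loss_association(y_pred: Tensor, y_true: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over the batch (the association task)."""
    y_true = np.asarray(y_true, dtype=np.float64).reshape(-1)
    if y_true.size == 0:
        raise ValueError("empty batch")
    p = _clip(ad.reshape(y_pred, (y_true.size,)))
    t = Tensor(y_true)
    ll = t * ad.log(p) + (1.0 - t) * ad.log(1.0 - p)
    return -ad.mean(ll)


def loss_severity(
    class_pred: Tensor,
    class_true: np.ndarray,
    mask: np.ndarray | None = None,
    literal: bool = False,
) -> Tensor:
    """Multi-label cross-entropy over (class, sample) pairs.

    Default normalization is the mean of elementwise binary cross-entropy
    over all included pairs.  ``literal=True`` instead applies the
    per-class 1/(C * N_c) prefactor (N_c = positives of class c in the
    included samples) and sums over classes — kept for comparison; it is
    undefined for a class with no positives, in which case that class term
    uses the included sample count.
    """
    class_true = np.asarray(class_true, dtype=np.float64)
    if mask is None:
        mask = np.ones(class_true.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        return Tensor(0.0)
    sel = np.where(mask)[0]
    p = _clip(ad.gather_rows(class_pred, sel))
    t = Tensor(class_true[sel])
    ll = t * ad.log(p) + (1.0 - t) * ad.log(1.0 - p)
    if not literal:
        return -ad.mean(ad.reshape(ll, (ll.data.size,)))
    C = class_true.shape[1]
    n_c = class_true[sel].sum(axis=0)
    n_c = np.where(n_c > 0, n_c, len(sel))
    weights = 1.0 / (C * n_c)
    return -ad.sum_(ad.sum_(ll, axis=0) * Tensor(weights))


def loss_total(assoc: Tensor, severity: Tensor, alpha: float) -> Tensor:
    return assoc + alpha * severity


@dataclass
class TrainResult:
    model: GCAPModel
    history: list[LossBreakdown] = field(default_factory=list)
    best_state: list[np.ndarray] | None = None
    best_loss: float = float("inf")


def compute_losses(
    model: GCAPModel,
    batch: list[PairFeatures],
    y_serious: np.ndarray,
    y_classes: np.ndarray,
    config: TrainingConfig,
) -> tuple[Tensor, LossBreakdown]:
    assoc_pred, class_pred, _ = model.forward_batch(batch)
    l_assoc = loss_association(assoc_pred, y_serious)
    mask = (
        np.asarray(y_serious, dtype=bool)
        if config.severity_mask_mode == "serious_only"
        else None
    )
    l_sev = loss_severity(class_pred, y_classes, mask=mask, literal=config.severity_literal)
    total = loss_total(l_assoc, l_sev, config.alpha)
    return total, LossBreakdown(
        loss_association=float(l_assoc.data),
        loss_severity=float(l_sev.data),
        loss_total=float(total.data),
        n=len(batch),
    )


def train(
    model: GCAPModel,
    features: list[PairFeatures],
    y_serious: np.ndarray,
    y_classes: np.ndarray,
    config: TrainingConfig,
    validation: tuple[list[PairFeatures], np.ndarray, np.ndarray] | None = None,
    verbose: bool = False,
) -> TrainResult:
    """Adam loop over shuffled mini-batches; deterministic given the seed.

    Keeps the state with the best (validation if given, else training) total
    loss.  Aborts with a diagnostic if the loss becomes non-finite.
    """
    rng = np.random.default_rng(config.seed)
    y_serious = np.asarray(y_serious, dtype=np.float64)
    y_classes = np.asarray(y_classes, dtype=np.float64)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    result = TrainResult(model=model)
    n = len(features)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_assoc = epoch_sev = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = [features[i] for i in idx]
            total, parts = compute_losses(
                model, batch, y_serious[idx], y_classes[idx], config
            )
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={float(total.data)}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_assoc += parts.loss_association * len(idx)
            epoch_sev += parts.loss_severity * len(idx)
        breakdown = LossBreakdown(
            loss_association=epoch_assoc / n,
            loss_severity=epoch_sev / n,
            loss_total=(epoch_assoc + config.alpha * epoch_sev) / n,
            n=n,
        )
        result.history.append(breakdown)
        if validation is not None:
            v_feats, v_ser, v_cls = validation
            v_total, _ = compute_losses(model, v_feats, v_ser, v_cls, config)
            score = float(v_total.data)
        else:
            score = breakdown.loss_total
        if score < result.best_loss:
            result.best_loss = score
            result.best_state = model.state_dict()
        if verbose and (epoch % 10 == 0 or epoch == config.epochs - 1):
            print(
                f"epoch {epoch:4d}  assoc {breakdown.loss_association:.4f}  "
                f"severity {breakdown.loss_severity:.4f}  total {breakdown.loss_total:.4f}"
            )
    return result
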