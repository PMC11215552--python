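"""Base-model training and patient personalization.

The base model is fit jointly on cell-line synergy records, each carrying the
sensitivity labels of its two drugs in that cell line where available, by
mini-batch Adam on the joint loss; the snapshot with the best validation
metric is returned (early stopping on patience).

Personalization fine-tunes a trained model on patients' single-drug response
labels only — there are no patient synergy labels — with the synergy head
(SAN) frozen.  Strategy 1 fine-tunes once on all patients pooled; Strategy 2
fine-tunes an independent model per patient, each starting from the same
pre-trained weights.  Training is bitwise reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .model import (
    ArchitectureConfig,
    Batch,
    Layer,
    LossConfig,
    ModelParameters,
    PredictionResult,
    loss_and_grads,
    predict,
    sensitivity_loss_and_grads,
    total_loss,
)
from .nn import Adam, clip_global_norm
from .records import (
    ExpressionProfile,
    SensitivityRecord,
    SynergyRecord,
    ValidationError,
)

__all__ = [
    "TrainingConfig",
    "PatientContext",
    "TrainingDivergedError",
    "build_training_batch",
    "train_base",
    "finetune_all_patients",
    "finetune_per_patient",
    "predict_synergy_for_patient",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-3
    finetune_learning_rate: float = 1e-4  # conservative: 0.1x the base rate
    max_epochs: int = 200
    patience: int = 10
    batch_size: int = 128
    seed: int = 0
    finetune_train_ddn: bool = True
    selection_metric: str = "val_total_loss"  # or "val_mse"
    augment: bool = True  # present each pair in both orders
    finetune_max_epochs: int = 50  # fixed budget; patient panels are too
    # small to spare a validation split for early stopping
    grad_clip: float = 5.0
    weight_decay: float = 0.0  # decoupled L2, base training only
    lr_decay: float = 1.0  # per-epoch multiplicative decay of the base rate
    finetune_batch_size: Optional[int] = None  # defaults to batch_size; patient
    # label sets are small, so a smaller batch gives adaptation more steps

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.finetune_learning_rate <= 0:
            raise ValidationError("learning rates must be positive")
        if self.max_epochs <= 0 or self.batch_size <= 0:
            raise ValidationError("max_epochs and batch_size must be positive")
        if not (0.0 < self.lr_decay <= 1.0):
            raise ValidationError("lr_decay must be in (0, 1]")
        if not (0 <= self.patience <= self.max_epochs):
            raise ValidationError("need 0 <= patience <= max_epochs")
        if self.finetune_max_epochs < 0:
            raise ValidationError("finetune_max_epochs must be >= 0")
        if self.finetune_batch_size is not None and self.finetune_batch_size <= 0:
            raise ValidationError("finetune_batch_size must be positive")
        if self.selection_metric not in ("val_total_loss", "val_mse"):
            raise ValidationError(f"unknown selection metric {self.selection_metric!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PatientContext:
    """One patient: expression profile plus their single-drug response labels."""

    patient_id: str
    expression: ExpressionProfile
    sensitivity_labels: list[SensitivityRecord]

    def __post_init__(self) -> None:
        for r in self.sensitivity_labels:
            if r.label not in (0, 1):
                raise ValidationError(
                    f"patient {self.patient_id}: sensitivity record for "
                    f"{r.drug_id} lacks a binary label"
                )


# ---------------------------------------------------------------------------
# batch assembly


def build_training_batch(
    records: Sequence[SynergyRecord],
    sensitivity_index: dict[tuple[str, str], int],
    drugs: dict[str, np.ndarray],
    contexts: dict[str, np.ndarray],
    augment: bool = True,
) -> Batch:
    """Assemble tensors for the joint task from synergy records.

    Each record contributes (d_i, d_j, c, y) plus the sensitivity labels of
    its two drugs in its context where the index has them; absent labels are
    masked out of the classification term.  With ``augment`` each pair is
    emitted in both drug orders, which is how order-robustness is taught to
    the concatenation-based synergy head.
    """
    if not records:
        raise ValidationError("cannot build a batch from zero records")
    d_i, d_j, c, y, s_i, m_i, s_j, m_j = [], [], [], [], [], [], [], []
    for r in records:
        for did in (r.drug_i, r.drug_j):
            if did not in drugs:
                raise ValidationError(f"no feature vector for drug {did!r}")
        if r.context_id not in contexts:
            raise ValidationError(f"no expression profile for context {r.context_id!r}")
        li = sensitivity_index.get((r.drug_i, r.context_id))
        lj = sensitivity_index.get((r.drug_j, r.context_id))
        orders = [(r.drug_i, r.drug_j, li, lj)]
        if augment:
            orders.append((r.drug_j, r.drug_i, lj, li))
        for a, b, la, lb in orders:
            d_i.append(drugs[a])
            d_j.append(drugs[b])
            c.append(contexts[r.context_id])
            y.append(r.bliss)
            s_i.append(0 if la is None else la)
            m_i.append(la is not None)
            s_j.append(0 if lb is None else lb)
            m_j.append(lb is not None)
    return Batch(
        np.asarray(d_i, float),
        np.asarray(d_j, float),
        np.asarray(c, float),
        np.asarray(y, float),
        np.asarray(s_i, float),
        np.asarray(m_i, bool),
        np.asarray(s_j, float),
        np.asarray(m_j, bool),
    )


def _observed_labels(batch: Batch) -> np.ndarray:
    return np.concatenate([batch.s_i[batch.m_i], batch.s_j[batch.m_j]])


# ---------------------------------------------------------------------------
# base training


def train_base(
    train_records: Sequence[SynergyRecord],
    val_records: Sequence[SynergyRecord],
    drugs: dict[str, np.ndarray],
    contexts: dict[str, np.ndarray],
    sensitivity_index: dict[tuple[str, str], int],
    arch_cfg: ArchitectureConfig,
    loss_cfg: LossConfig = LossConfig(),
    train_cfg: TrainingConfig = TrainingConfig(),
) -> tuple[ModelParameters, dict]:
    """Fit the joint model and return the best-on-validation snapshot.

    The returned log records per-epoch training loss and validation metric,
    the selected epoch and the resolved loss weights.
    """
    if not train_records or not val_records:
        raise ValidationError("train and validation record lists must be nonempty")

    train_batch = build_training_batch(
        train_records, sensitivity_index, drugs, contexts, augment=train_cfg.augment
    )
    val_batch = build_training_batch(
        val_records, sensitivity_index, drugs, contexts, augment=False
    )
    loss_cfg = loss_cfg.resolved(_observed_labels(train_batch))

    params = ModelParameters.initialize(arch_cfg, seed=train_cfg.seed)
    rng = np.random.default_rng(train_cfg.seed)
    opt = Adam(
        params.flat_arrays(),
        lr=train_cfg.learning_rate,
        weight_decay=train_cfg.weight_decay,
    )

    def val_metric() -> float:
        if train_cfg.selection_metric == "val_mse":
            res = predict(val_batch.d_i, val_batch.d_j, val_batch.c, params)
            return float(np.mean((val_batch.y - res.y_hat) ** 2))
        return total_loss(val_batch, params, loss_cfg)

    n = len(train_batch)
    best = np.inf
    best_params = params.copy()
    best_epoch = -1
    since_improve = 0
    log = {
        "train_loss": [],
        "val_metric": [],
        "selection_metric": train_cfg.selection_metric,
        "loss_config": {
            "lambda_task": loss_cfg.lambda_task,
            "lambda_sensitive": loss_cfg.lambda_sensitive,
            "lambda_resistant": loss_cfg.lambda_resistant,
        },
    }

    for epoch in range(train_cfg.max_epochs):
        opt.lr = train_cfg.learning_rate * train_cfg.lr_decay**epoch
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_cfg.batch_size):
            mini = train_batch.take(order[start : start + train_cfg.batch_size])
            loss, grads = loss_and_grads(mini, params, loss_cfg, mode="train", rng=rng)
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            flat = _flatten_grads(grads, ("den", "ddn", "san"))
            clip_global_norm(flat, train_cfg.grad_clip)
            opt.step(flat)
            losses.append(loss)
        vm = val_metric()
        if not np.isfinite(vm):
            raise TrainingDivergedError(epoch)
        log["train_loss"].append(float(np.mean(losses)))
        log["val_metric"].append(float(vm))
        if vm < best:
            best = vm
            best_params = params.copy()
            best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve > train_cfg.patience:
                break

    log["best_epoch"] = best_epoch
    log["epochs_run"] = len(log["train_loss"])
    log["best_val_metric"] = float(best)
    return best_params, log


def _flatten_grads(grads: dict[str, list[Layer]], parts: Sequence[str]) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for name in parts:
        for layer in grads[name]:
            out.extend([layer.W, layer.b])
    return out


# ---------------------------------------------------------------------------
# fine-tuning


def _patient_rows(
    patients: Sequence[PatientContext], drugs: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d_rows, c_rows, labels = [], [], []
    for p in patients:
        for r in p.sensitivity_labels:
            if r.drug_id not in drugs:
                raise ValidationError(
                    f"patient {p.patient_id}: no feature vector for drug {r.drug_id!r}"
                )
            d_rows.append(drugs[r.drug_id])
            c_rows.append(p.expression.values)
            labels.append(r.label)
    if not labels:
        raise ValidationError("fine-tuning requires at least one sensitivity label")
    return (
        np.asarray(d_rows, float),
        np.asarray(c_rows, float),
        np.asarray(labels, float),
    )


def _finetune(
    base: ModelParameters,
    d: np.ndarray,
    c: np.ndarray,
    labels: np.ndarray,
    loss_cfg: LossConfig,
    train_cfg: TrainingConfig,
) -> ModelParameters:
    """Optimize the classification term only, with SAN structurally frozen.

    The synergy head's parameters are never handed to the optimizer and take
    no gradient, so freezing cannot drift; zero fine-tune epochs returns a
    bitwise copy of the base parameters.
    """
    params = base.copy()
    if train_cfg.finetune_max_epochs == 0:
        return params
    loss_cfg = loss_cfg.resolved(labels)
    trainable_parts = ("den", "ddn") if train_cfg.finetune_train_ddn else ("den",)
    opt = Adam(params.flat_arrays(trainable_parts), lr=train_cfg.finetune_learning_rate)
    rng = np.random.default_rng(train_cfg.seed)
    n = len(labels)
    batch = train_cfg.finetune_batch_size or train_cfg.batch_size
    for epoch in range(train_cfg.finetune_max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            loss, grads = sensitivity_loss_and_grads(
                d[idx], c[idx], labels[idx], params, loss_cfg, mode="train", rng=rng
            )
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            flat = _flatten_grads(grads, trainable_parts)
            clip_global_norm(flat, train_cfg.grad_clip)
            opt.step(flat)
    return params


def finetune_all_patients(
    base: ModelParameters,
    patients: Sequence[PatientContext],
    drugs: dict[str, np.ndarray],
    loss_cfg: LossConfig = LossConfig(),
    train_cfg: TrainingConfig = TrainingConfig(),
) -> ModelParameters:
    """Strategy 1: one fine-tuned model from all patients' labels pooled."""
    d, c, labels = _patient_rows(patients, drugs)
    return _finetune(base, d, c, labels, loss_cfg, train_cfg)


def finetune_per_patient(
    base: ModelParameters,
    patients: Sequence[PatientContext],
    drugs: dict[str, np.ndarray],
    loss_cfg: LossConfig = LossConfig(),
    train_cfg: TrainingConfig = TrainingConfig(),
) -> dict[str, ModelParameters]:
    """Strategy 2: an independent fine-tuned model per patient.

    Every patient's run starts from the same pre-trained weights and the same
    seed, so two patients with identical data yield identical models.
    """
    out = {}
    for p in patients:
        d, c, labels = _patient_rows([p], drugs)
        out[p.patient_id] = _finetune(base, d, c, labels, loss_cfg, train_cfg)
    return out


def predict_synergy_for_patient(
    params: ModelParameters,
    patient: PatientContext,
    pairs: Sequence[tuple[str, str]],
    drugs: dict[str, np.ndarray],
) -> PredictionResult:
    """Symmetric synergy/sensitivity predictions for drug pairs in a patient.

    The patient's expression must already be aligned to the model's gene list
    and quantile-normalized onto the training reference.
    """
    if not pairs:
        raise ValidationError("no drug pairs to predict")
    for i, j in pairs:
        for did in (i, j):
            if did not in drugs:
                raise ValidationError(f"unknown drug {did!r}")
    d_i = np.asarray([drugs[i] for i, _ in pairs], float)
    d_j = np.asarray([drugs[j] for _, j in pairs], float)
    c = np.tile(patient.expression.values, (len(pairs), 1))
    return predict(d_i, d_j, c, params)
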