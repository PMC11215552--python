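"""High-level modelling interface: a model object fitted to data, returning a
results object that carries the estimates and everything derived from them.

:class:`PDSPModel` bundles the training inputs (synergy records, drug
features, context expression, sensitivity labels) with the architecture and
loss configuration; :meth:`PDSPModel.fit` runs the training loop and returns
a :class:`PDSPResults` whose methods cover prediction, evaluation,
personalization (fine-tuning) and checkpointing, plus a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import io as pio
from .metrics import classification_metrics, regression_metrics, threshold_metrics
from .model import (
    ArchitectureConfig,
    LossConfig,
    ModelParameters,
    PredictionResult,
    predict,
)
from .records import SynergyRecord, ValidationError
from .train import (
    PatientContext,
    TrainingConfig,
    finetune_all_patients,
    finetune_per_patient,
    predict_synergy_for_patient,
    train_base,
)

__all__ = ["PDSPModel", "PDSPResults", "PersonalizedResults"]


class PDSPModel:
    """Joint synergy-regression / sensitivity-classification model.

    Parameters
    ----------
    train_records, val_records
        Canonicalized, replicate-averaged synergy records (the validation
        records drive snapshot selection and early stopping).
    drugs
        drug_id -> chemical feature vector; all vectors one length.
    contexts
        context_id -> expression vector, already aligned and normalized.
    sensitivity_index
        (drug_id, context_id) -> binary label; pairs not present are masked
        out of the classification loss.
    arch, loss
        Architecture and loss-weight configuration; dimensions default to
        those of the supplied feature tables.
    """

    def __init__(
        self,
        train_records: Sequence[SynergyRecord],
        val_records: Sequence[SynergyRecord],
        drugs: dict[str, np.ndarray],
        contexts: dict[str, np.ndarray],
        sensitivity_index: Optional[dict[tuple[str, str], int]] = None,
        arch: Optional[ArchitectureConfig] = None,
        loss: LossConfig = LossConfig(),
    ):
        if not drugs or not contexts:
            raise ValidationError("drug and context feature tables must be nonempty")
        d_drug = {len(v) for v in drugs.values()}
        d_expr = {len(v) for v in contexts.values()}
        if len(d_drug) != 1 or len(d_expr) != 1:
            raise ValidationError("inconsistent feature vector lengths")
        if arch is None:
            arch = ArchitectureConfig(d_drug=d_drug.pop(), d_expr=d_expr.pop())
        elif arch.d_drug != d_drug.pop() or arch.d_expr != d_expr.pop():
            raise ValidationError("architecture dims do not match feature tables")
        self.train_records = list(train_records)
        self.val_records = list(val_records)
        self.drugs = drugs
        self.contexts = contexts
        self.sensitivity_index = sensitivity_index or {}
        self.arch = arch
        self.loss = loss

    def fit(self, train_cfg: TrainingConfig = TrainingConfig()) -> "PDSPResults":
        """Train and return the best-on-validation snapshot with its log."""
        params, log = train_base(
            self.train_records,
            self.val_records,
            self.drugs,
            self.contexts,
            self.sensitivity_index,
            self.arch,
            self.loss,
            train_cfg,
        )
        return PDSPResults(self, params, log, train_cfg)


@dataclass
class PDSPResults:
    """A fitted model: parameters, training log, and derived quantities."""

    model: PDSPModel
    params: ModelParameters
    log: dict
    train_cfg: TrainingConfig

    # -- prediction --------------------------------------------------------
    def predict_records(
        self, records: Sequence[SynergyRecord], params: Optional[ModelParameters] = None
    ) -> PredictionResult:
        p = params or self.params
        drugs, contexts = self.model.drugs, self.model.contexts
        d_i = np.asarray([drugs[r.drug_i] for r in records])
        d_j = np.asarray([drugs[r.drug_j] for r in records])
        c = np.asarray([contexts[r.context_id] for r in records])
        return predict(d_i, d_j, c, p)

    # -- evaluation --------------------------------------------------------
    def evaluate_regression(
        self,
        records: Sequence[SynergyRecord],
        truth: Optional[dict[tuple[str, str, str], float]] = None,
    ) -> dict[str, float]:
        """Regression metrics on records; ``truth`` substitutes noiseless
        reference values for the recorded (noisy) scores when supplied."""
        res = self.predict_records(records)
        if truth is None:
            y = np.asarray([r.bliss for r in records])
        else:
            y = np.asarray([truth[(r.drug_i, r.drug_j, r.context_id)] for r in records])
        return regression_metrics(y, res.y_hat)

    def evaluate_classification(
        self,
        records: Sequence[SynergyRecord],
        truth: Optional[dict[tuple[str, str, str], float]] = None,
    ) -> dict[str, float]:
        res = self.predict_records(records)
        if truth is None:
            y = np.asarray([r.bliss for r in records])
        else:
            y = np.asarray([truth[(r.drug_i, r.drug_j, r.context_id)] for r in records])
        return classification_metrics((y > 0).astype(int), res.y_hat)

    # -- personalization ---------------------------------------------------
    def finetune(
        self,
        patients: Sequence[PatientContext],
        strategy: str = "per-patient",
        train_cfg: Optional[TrainingConfig] = None,
    ) -> "PersonalizedResults":
        """Personalize on patients' single-drug labels; the synergy head stays
        frozen.  ``strategy`` is ``"all"`` (one pooled model) or
        ``"per-patient"`` (one model per patient)."""
        cfg = train_cfg or self.train_cfg
        if strategy == "all":
            tuned = finetune_all_patients(
                self.params, patients, self.model.drugs, self.model.loss, cfg
            )
            per_patient = {p.patient_id: tuned for p in patients}
        elif strategy == "per-patient":
            per_patient = finetune_per_patient(
                self.params, patients, self.model.drugs, self.model.loss, cfg
            )
        else:
            raise ValidationError(f"unknown strategy {strategy!r}")
        return PersonalizedResults(self, strategy, list(patients), per_patient)

    # -- persistence / reporting -------------------------------------------
    def save(self, path) -> None:
        pio.save_checkpoint(self.params, path)

    def summary(self) -> str:
        a = self.params.config_snapshot
        lc = self.log.get("loss_config", {})
        lines = [
            "PDSP joint synergy/sensitivity model",
            "=" * 52,
            f"architecture   DEN {a.d_drug}+{a.d_expr} -> {list(a.den_hidden)} -> m={a.latent_dim}",
            f"               DDN {a.latent_dim} -> {list(a.ddn_hidden)} -> 1 (logit)",
            f"               SAN {2 * a.latent_dim} -> {list(a.san_hidden)} -> 1 (Bliss)",
            f"dropout        {a.dropout_rate}",
            f"loss           L_reg + {lc.get('lambda_task', '?')} * (wBCE_i + wBCE_j), "
            f"class weights ({lc.get('lambda_sensitive', '?'):.3g}, {lc.get('lambda_resistant', '?'):.3g})"
            if lc
            else "loss           (unresolved)",
            f"training       {self.log['epochs_run']} epochs run, "
            f"best epoch {self.log['best_epoch']} "
            f"({self.log['selection_metric']} = {self.log['best_val_metric']:.4f})",
            f"records        train {len(self.model.train_records)}, "
            f"val {len(self.model.val_records)}",
        ]
        return "\n".join(lines)


@dataclass
class PersonalizedResults:
    """Fine-tuned per-patient (or pooled) models and their evaluations."""

    base: PDSPResults
    strategy: str
    patients: list[PatientContext]
    params_by_patient: dict[str, ModelParameters]

    def params_for(self, patient_id: str) -> ModelParameters:
        return self.params_by_patient[patient_id]

    def predict_for_patient(
        self, patient_id: str, pairs: Sequence[tuple[str, str]]
    ) -> PredictionResult:
        patient = next(p for p in self.patients if p.patient_id == patient_id)
        return predict_synergy_for_patient(
            self.params_by_patient[patient_id], patient, pairs, self.base.model.drugs
        )

    def evaluate_panel(
        self, panel: Sequence[SynergyRecord]
    ) -> dict[str, float]:
        """Pooled thresholded classification metrics over a patient synergy
        panel, each patient scored with their own model."""
        y_true, y_score = [], []
        for p in self.patients:
            mine = [r for r in panel if r.context_id == p.patient_id]
            if not mine:
                continue
            res = self.predict_for_patient(p.patient_id, [(r.drug_i, r.drug_j) for r in mine])
            y_true.extend(int(r.bliss > 0) for r in mine)
            y_score.extend(np.atleast_1d(res.y_hat))
        cm, thr = threshold_metrics(np.asarray(y_true), np.asarray(y_score))
        return {**thr, "tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn}
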