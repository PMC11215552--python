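"""End-to-end synthetic benchmark: simulate, preprocess, split, train,
personalize and evaluate in one call.

This wires the package's stages together in the order a study would run
them: generate a planted world, average replicates, quantile-normalize all
expression onto the cell-line reference, split synergy records
leave-pair-out 60/20/20, fit the base model, fine-tune per patient (and
pooled), then score cell-line test regression and patient synergy
classification.  The desk-scale architecture used here is a smaller funnel
than the package default, sized to the synthetic world's 64-dimensional
features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .api import PDSPModel, PDSPResults, PersonalizedResults
from .metrics import threshold_metrics
from .model import ArchitectureConfig, LossConfig, ModelParameters
from .preprocess import (
    average_replicates,
    binarize_sensitivity_records,
    quantile_normalize_to_reference,
)
from .records import ExpressionProfile, SynergyRecord, sensitivity_index
from .splitting import leave_pair_out_split
from .synth import SyntheticWorld, WorldConfig, generate_world
from .train import PatientContext, TrainingConfig, predict_synergy_for_patient

__all__ = [
    "desk_scale_arch",
    "desk_scale_training",
    "prepare_world",
    "run_synthetic_benchmark",
    "evaluate_patient_panel",
]


def desk_scale_arch(d_drug: int = 64, d_expr: int = 64) -> ArchitectureConfig:
    """Architecture sized for the synthetic world's 64-dim features."""
    return ArchitectureConfig(
        d_drug=d_drug,
        d_expr=d_expr,
        latent_dim=32,
        den_hidden=(128, 64),
        ddn_hidden=(32, 16),
        san_hidden=(64, 32),
        dropout_rate=0.2,
    )


def desk_scale_training(seed: int = 0) -> TrainingConfig:
    return TrainingConfig(
        learning_rate=1e-3,
        finetune_learning_rate=3e-4,
        max_epochs=300,
        patience=40,
        batch_size=128,
        finetune_batch_size=32,
        seed=seed,
        selection_metric="val_mse",
    )


@dataclass
class PreparedWorld:
    """A synthetic world after preprocessing, ready for model fitting."""

    world: SyntheticWorld
    synergy: list[SynergyRecord]  # replicate-averaged
    drugs: dict[str, np.ndarray]
    contexts: dict[str, np.ndarray]  # quantile-normalized cell lines
    sens_index: dict[tuple[str, str], int]
    patients: list[PatientContext]  # expression quantile-normalized


def prepare_world(world: SyntheticWorld) -> PreparedWorld:
    """Replicate-average, binarize sensitivity and quantile-normalize.

    The cell-line matrix is its own quantile reference; patient profiles are
    mapped onto the same reference, the asymmetric normalization that avoids
    fitting quantiles on a handful of patient samples.
    """
    averaged = average_replicates(world.synergy_records)
    reference = world.cell_expression
    cells_qn = quantile_normalize_to_reference(world.cell_expression, reference)
    patients_qn = quantile_normalize_to_reference(world.patient_expression, reference)

    labelled = binarize_sensitivity_records(world.cell_sensitivity)
    sens_idx = sensitivity_index(labelled)

    drugs = {d: world.drug_features[k] for k, d in enumerate(world.drug_ids)}
    patients = []
    by_patient: dict[str, list] = {}
    for r in world.patient_sensitivity:
        by_patient.setdefault(r.context_id, []).append(r)
    for pid in world.patient_expression.sample_ids:
        patients.append(
            PatientContext(
                pid,
                ExpressionProfile(pid, "patient", patients_qn.column(pid)),
                by_patient.get(pid, []),
            )
        )
    return PreparedWorld(
        world=world,
        synergy=averaged,
        drugs=drugs,
        contexts=cells_qn.as_dict(),
        sens_index=sens_idx,
        patients=patients,
    )


def evaluate_patient_panel(
    params_by_patient: dict[str, ModelParameters],
    patients: list[PatientContext],
    panel: list[SynergyRecord],
    drugs: dict[str, np.ndarray],
) -> dict[str, float]:
    """Thresholded synergy classification over a patient panel.

    Each patient's pairs are scored with that patient's model (pass the same
    parameters for every patient to evaluate a non-personalized model); a
    predicted Bliss score > 0 is a synergistic call.  Also reports
    per-patient balanced accuracy.
    """
    y_true, y_score = [], []
    per_patient_bacc = {}
    for p in patients:
        mine = [r for r in panel if r.context_id == p.patient_id]
        if not mine:
            continue
        res = predict_synergy_for_patient(
            params_by_patient[p.patient_id], p, [(r.drug_i, r.drug_j) for r in mine], drugs
        )
        t = [int(r.bliss > 0) for r in mine]
        s = list(np.atleast_1d(res.y_hat))
        _, thr = threshold_metrics(np.asarray(t), np.asarray(s))
        per_patient_bacc[p.patient_id] = thr["bacc"]
        y_true.extend(t)
        y_score.extend(s)
    cm, thr = threshold_metrics(np.asarray(y_true), np.asarray(y_score))
    return {
        **thr,
        "tp": cm.tp,
        "tn": cm.tn,
        "fp": cm.fp,
        "fn": cm.fn,
        "per_patient_bacc": per_patient_bacc,
    }


def run_synthetic_benchmark(
    seed: int = 0,
    world_cfg: Optional[WorldConfig] = None,
    arch: Optional[ArchitectureConfig] = None,
    loss: LossConfig = LossConfig(),
    train_cfg: Optional[TrainingConfig] = None,
    strategies: tuple[str, ...] = ("all", "per-patient"),
) -> dict:
    """Run the whole study on one seeded synthetic world.

    Returns the fitted results plus cell-line test metrics (against both the
    observed noisy scores and the noiseless planted truth) and patient-panel
    classification metrics for the base and fine-tuned models.
    """
    wcfg = world_cfg or WorldConfig(seed=seed)
    if wcfg.seed != seed:
        wcfg = WorldConfig(**{**wcfg.to_dict(), "seed": seed})
    world = generate_world(wcfg)
    prep = prepare_world(world)

    split = leave_pair_out_split(prep.synergy, (0.6, 0.2, 0.2), seed=seed)
    arch = arch or desk_scale_arch(wcfg.d_drug, wcfg.d_expr)
    tcfg = train_cfg or desk_scale_training(seed)

    model = PDSPModel(
        split.train,
        split.validation,
        prep.drugs,
        prep.contexts,
        prep.sens_index,
        arch=arch,
        loss=loss,
    )
    results = model.fit(tcfg)

    out: dict = {
        "seed": seed,
        "world": world,
        "prepared": prep,
        "split": split,
        "results": results,
        "cellline_test_observed": results.evaluate_regression(split.test),
        "cellline_test_truth": results.evaluate_regression(
            split.test, truth=world.synergy_truth
        ),
        "cellline_val_observed": results.evaluate_regression(split.validation),
    }

    base_by_patient = {p.patient_id: results.params for p in prep.patients}
    out["patient_base"] = evaluate_patient_panel(
        base_by_patient, prep.patients, world.patient_synergy, prep.drugs
    )
    if "all" in strategies:
        st1 = results.finetune(prep.patients, strategy="all")
        out["st1"] = st1
        out["patient_st1"] = evaluate_patient_panel(
            st1.params_by_patient, prep.patients, world.patient_synergy, prep.drugs
        )
    if "per-patient" in strategies:
        st2 = results.finetune(prep.patients, strategy="per-patient")
        out["st2"] = st2
        out["patient_st2"] = evaluate_patient_panel(
            st2.params_by_patient, prep.patients, world.patient_synergy, prep.drugs
        )
    return out
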