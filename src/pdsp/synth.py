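"""Synthetic benchmark generator with a planted latent structure.

The generator emits the four observable tables the pipeline consumes (drug
descriptors, expression matrices for cell lines and patients, synergy
records, sensitivity records) from a known ground truth:

* each drug has a latent vector ``u_i = P d_i`` and each context a latent
  ``v_k = Q c_k`` (linear projections of the observable features);
* single-drug sensitivity is ``1[<u_i, v_k> + noise > 0]``;
* pair synergy is ``<u_i * u_j, R v_k> + beta (<u_i, v_k> + <u_j, v_k>)``
  plus noise — symmetric in the drugs by construction.

Because sensitivity and synergy share the same latents, a patient's
single-drug responses carry information about that patient's synergy
landscape; this is precisely the premise that makes fine-tuning on
single-drug labels useful for synergy prediction, and it is what the
transfer tests exercise.  Patients are cell-line-like expression vectors
plus a controllable mean shift along a random per-patient direction,
emulating the cohort/platform domain shift between cell lines and patient
samples.

Feature marginals are standard normal and projections have unit-norm rows;
the generator makes no attempt at realistic descriptor marginals or
expression covariance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as pio
from .records import (
    Domain,
    ExpressionMatrix,
    SensitivityRecord,
    SynergyRecord,
    ValidationError,
    canonicalize_pair,
)

__all__ = ["WorldConfig", "SyntheticWorld", "generate_world", "export_world", "planted_oracle"]


@dataclass(frozen=True)
class WorldConfig:
    """Desk-scale defaults: many drugs, few contexts, a tiny patient panel.

    ``noise_sd_synergy=None`` calibrates the synergy noise so the planted
    signal explains ~``target_r2`` of the observed variance.  The default
    world trains in minutes on one CPU.
    """

    n_drugs: int = 300
    n_cell_lines: int = 20
    n_patients: int = 3
    d_drug: int = 64
    d_expr: int = 64
    latent_dim: int = 8
    n_pair_records: int = 5000
    sens_labels_per_patient: int = 200
    n_patient_pairs: int = 40  # evaluation panel per patient
    noise_sd_synergy: Optional[float] = None
    noise_sd_sens: float = 0.5
    patient_shift: float = 2.0
    beta: float = 0.5
    replicate_fraction: float = 0.1
    target_r2: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_drugs, self.n_cell_lines, self.n_patients, self.d_drug,
            self.d_expr, self.latent_dim, self.n_pair_records,
            self.sens_labels_per_patient, self.n_patient_pairs,
        )
        if any(c <= 0 for c in counts):
            raise ValidationError("all world counts must be positive")
        if self.latent_dim > min(self.d_drug, self.d_expr):
            raise ValidationError("latent_dim must not exceed min(d_drug, d_expr)")
        for name in ("noise_sd_sens", "patient_shift", "replicate_fraction"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.noise_sd_synergy is not None and self.noise_sd_synergy < 0:
            raise ValidationError("noise_sd_synergy must be >= 0")
        if not (0 < self.target_r2 <= 1):
            raise ValidationError("target_r2 must be in (0, 1]")
        if self.n_drugs < 2:
            raise ValidationError("need at least two drugs to form pairs")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticWorld:
    cfg: WorldConfig
    drug_ids: list[str]
    drug_features: np.ndarray  # (n_drugs, d_drug)
    gene_ids: list[str]
    cell_expression: ExpressionMatrix
    patient_expression: ExpressionMatrix
    synergy_records: list[SynergyRecord]  # observed, with replicates
    synergy_truth: dict[tuple[str, str, str], float]  # noiseless values
    cell_sensitivity: list[SensitivityRecord]  # ln_ic50 form
    patient_sensitivity: list[SensitivityRecord]  # binary-label form
    patient_synergy: list[SynergyRecord]  # noiseless evaluation panel
    planted: dict  # P, Q, R, beta
    noise_sd_synergy: float

    @property
    def drug_index(self) -> dict[str, int]:
        return {d: k for k, d in enumerate(self.drug_ids)}

    def context_latent(self, context_id: str) -> np.ndarray:
        Q = self.planted["Q"]
        if context_id in self.cell_expression.sample_ids:
            return Q @ self.cell_expression.column(context_id)
        if context_id in self.patient_expression.sample_ids:
            return Q @ self.patient_expression.column(context_id)
        raise ValidationError(f"unknown context {context_id!r}")

    def drug_latent(self, drug_id: str) -> np.ndarray:
        try:
            return self.planted["P"] @ self.drug_features[self.drug_index[drug_id]]
        except KeyError:
            raise ValidationError(f"unknown drug {drug_id!r}") from None


def _unit_rows(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    M = rng.normal(size=shape)
    return M / np.linalg.norm(M, axis=1, keepdims=True)


def _noiseless_synergy(u_i, u_j, v, w, beta) -> float:
    return float((u_i * u_j) @ w + beta * (u_i @ v + u_j @ v))


def generate_world(cfg: WorldConfig = WorldConfig()) -> SyntheticWorld:
    """Draw a complete synthetic world, deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)

    drug_ids = [f"D{k:04d}" for k in range(cfg.n_drugs)]
    drug_features = rng.normal(size=(cfg.n_drugs, cfg.d_drug))
    gene_ids = [f"G{k:04d}" for k in range(cfg.d_expr)]
    cell_ids = [f"CL{k:02d}" for k in range(cfg.n_cell_lines)]
    cell_values = rng.normal(size=(cfg.d_expr, cfg.n_cell_lines))

    patient_ids = [f"PT{k}" for k in range(1, cfg.n_patients + 1)]
    # a patient is a cell-line-like vector plus a directional mean shift
    patient_base = rng.normal(size=(cfg.d_expr, cfg.n_patients))
    directions = _unit_rows(rng, (cfg.n_patients, cfg.d_expr)).T
    patient_values = patient_base + cfg.patient_shift * directions

    P = _unit_rows(rng, (cfg.latent_dim, cfg.d_drug))
    Q = _unit_rows(rng, (cfg.latent_dim, cfg.d_expr))
    R = _unit_rows(rng, (cfg.latent_dim, cfg.latent_dim))

    U = drug_features @ P.T  # (n_drugs, latent)
    V_cell = (Q @ cell_values).T  # (n_cells, latent)
    W_cell = (R @ V_cell.T).T
    V_pat = (Q @ patient_values).T
    W_pat = (R @ V_pat.T).T

    # unique (pair, cell line) triples
    triples: list[tuple[int, int, int]] = []
    seen: set[tuple[int, int, int]] = set()
    max_unique = cfg.n_drugs * (cfg.n_drugs - 1) // 2 * cfg.n_cell_lines
    if cfg.n_pair_records > max_unique:
        raise ValidationError(
            f"n_pair_records={cfg.n_pair_records} exceeds the "
            f"{max_unique} possible (pair, cell line) triples"
        )
    while len(triples) < cfg.n_pair_records:
        i, j = sorted(rng.choice(cfg.n_drugs, size=2, replace=False))
        k = int(rng.integers(cfg.n_cell_lines))
        key = (int(i), int(j), k)
        if key not in seen:
            seen.add(key)
            triples.append(key)

    truth_vals = np.array(
        [_noiseless_synergy(U[i], U[j], V_cell[k], W_cell[k], cfg.beta) for i, j, k in triples]
    )
    if cfg.noise_sd_synergy is None:
        noise_sd = float(np.std(truth_vals) * np.sqrt(1.0 / cfg.target_r2 - 1.0))
    else:
        noise_sd = float(cfg.noise_sd_synergy)

    synergy_records: list[SynergyRecord] = []
    synergy_truth: dict[tuple[str, str, str], float] = {}
    for (i, j, k), y0 in zip(triples, truth_vals):
        ids = (drug_ids[i], drug_ids[j], cell_ids[k])
        synergy_truth[ids] = float(y0)
        n_rep = 2 if rng.random() < cfg.replicate_fraction else 1
        for _ in range(n_rep):
            synergy_records.append(
                SynergyRecord(*ids, float(y0 + rng.normal(0.0, noise_sd)))
            )

    # full drug x cell-line sensitivity panel, exported on the ln IC50 scale:
    # sensitive (ln IC50 < -2) exactly when the noisy planted logit is positive
    cell_sensitivity = []
    logits = U @ V_cell.T + rng.normal(0.0, cfg.noise_sd_sens, size=(cfg.n_drugs, cfg.n_cell_lines))
    for a, did in enumerate(drug_ids):
        for b, cid in enumerate(cell_ids):
            cell_sensitivity.append(
                SensitivityRecord(did, cid, ln_ic50=float(-2.0 - logits[a, b]))
            )

    patient_sensitivity = []
    for t, pid in enumerate(patient_ids):
        chosen = rng.choice(cfg.n_drugs, size=min(cfg.sens_labels_per_patient, cfg.n_drugs), replace=False)
        for a in chosen:
            logit = float(U[a] @ V_pat[t] + rng.normal(0.0, cfg.noise_sd_sens))
            patient_sensitivity.append(
                SensitivityRecord(drug_ids[a], pid, label=int(logit > 0))
            )

    patient_synergy = []
    for t, pid in enumerate(patient_ids):
        panel: set[tuple[int, int]] = set()
        while len(panel) < cfg.n_patient_pairs:
            i, j = sorted(rng.choice(cfg.n_drugs, size=2, replace=False))
            panel.add((int(i), int(j)))
        for i, j in sorted(panel):
            y0 = _noiseless_synergy(U[i], U[j], V_pat[t], W_pat[t], cfg.beta)
            patient_synergy.append(SynergyRecord(drug_ids[i], drug_ids[j], pid, y0))

    return SyntheticWorld(
        cfg=cfg,
        drug_ids=drug_ids,
        drug_features=drug_features,
        gene_ids=gene_ids,
        cell_expression=ExpressionMatrix(gene_ids, cell_ids, cell_values, Domain.cell_line),
        patient_expression=ExpressionMatrix(gene_ids, patient_ids, patient_values, Domain.patient),
        synergy_records=synergy_records,
        synergy_truth=synergy_truth,
        cell_sensitivity=cell_sensitivity,
        patient_sensitivity=patient_sensitivity,
        patient_synergy=patient_synergy,
        planted={"P": P, "Q": Q, "R": R, "beta": cfg.beta},
        noise_sd_synergy=noise_sd,
    )


def planted_oracle(
    world: SyntheticWorld, drug_i: str, drug_j: str, context: str
) -> dict[str, float]:
    """Noiseless planted values for a pair in a context.

    Returns the synergy score and the two sensitivity logits; exactly
    symmetric under drug exchange.
    """
    a, b = canonicalize_pair(drug_i, drug_j)
    u_i, u_j = world.drug_latent(a), world.drug_latent(b)
    v = world.context_latent(context)
    w = world.planted["R"] @ v
    y0 = _noiseless_synergy(u_i, u_j, v, w, world.planted["beta"])
    out = {a: float(u_i @ v), b: float(u_j @ v)}
    return {
        "synergy": y0,
        "sensitivity_logit_i": out[drug_i],
        "sensitivity_logit_j": out[drug_j],
    }


def export_world(world: SyntheticWorld, out_dir) -> dict[str, Path]:
    """Write the world's observable tables plus a ground-truth manifest.

    Observable tables use the package's standard TSV formats and round-trip
    exactly through the readers; the truth manifest (planted parameters and
    noiseless values) is a separate JSON file, not part of the observable
    set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "drug_features": out / "drug_features.tsv",
        "expression_cell_lines": out / "expression_cell_lines.tsv",
        "expression_patients": out / "expression_patients.tsv",
        "synergy": out / "synergy.tsv",
        "sensitivity_cell_lines": out / "sensitivity_cell_lines.tsv",
        "sensitivity_patients": out / "sensitivity_patients.tsv",
    }
    from .records import DrugProfile

    pio.write_drug_features(
        [DrugProfile(d, world.drug_features[k]) for k, d in enumerate(world.drug_ids)],
        paths["drug_features"],
    )
    pio.write_expression_matrix(world.cell_expression, paths["expression_cell_lines"])
    pio.write_expression_matrix(world.patient_expression, paths["expression_patients"])
    pio.write_synergy_table(world.synergy_records, paths["synergy"])
    pio.write_sensitivity_table(world.cell_sensitivity, paths["sensitivity_cell_lines"])
    pio.write_sensitivity_table(world.patient_sensitivity, paths["sensitivity_patients"])

    manifest = {
        "config": world.cfg.to_dict(),
        "noise_sd_synergy": world.noise_sd_synergy,
        "planted": {k: np.asarray(v).tolist() for k, v in world.planted.items()},
        "synergy_truth": [
            {"drug_i": i, "drug_j": j, "context": k, "bliss": y}
            for (i, j, k), y in world.synergy_truth.items()
        ],
        "patient_synergy": [
            {"drug_i": r.drug_i, "drug_j": r.drug_j, "context": r.context_id, "bliss": r.bliss}
            for r in world.patient_synergy
        ],
    }
    manifest_path = out / "truth_manifest.json"
    manifest_path.write_text(json.dumps(manifest))
    return {**paths, "truth_manifest": manifest_path}
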