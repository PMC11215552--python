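"""Training loop contracts, fine-tuning freeze semantics, and the model API."""

import numpy as np
import pytest

from pdsp import io as pio
from pdsp.api import PDSPModel
from pdsp.model import ArchitectureConfig, LossConfig
from pdsp.pipeline import prepare_world
from pdsp.records import ExpressionProfile, SensitivityRecord, SynergyRecord, ValidationError
from pdsp.splitting import leave_pair_out_split
from pdsp.synth import WorldConfig, generate_world
from pdsp.train import (
    PatientContext,
    TrainingConfig,
    build_training_batch,
    finetune_all_patients,
    finetune_per_patient,
    predict_synergy_for_patient,
    train_base,
)

SMALL_ARCH = ArchitectureConfig(
    d_drug=8, d_expr=8, latent_dim=4,
    den_hidden=(16,), ddn_hidden=(8,), san_hidden=(16,), dropout_rate=0.1,
)

WORLD = dict(
    n_drugs=20, n_cell_lines=5, n_patients=2, d_drug=8, d_expr=8,
    latent_dim=3, n_pair_records=120, sens_labels_per_patient=15, n_patient_pairs=6,
)


@pytest.fixture(scope="module")
def small_world():
    world = generate_world(WorldConfig(**WORLD, seed=21))
    prep = prepare_world(world)
    split = leave_pair_out_split(prep.synergy, (0.6, 0.2, 0.2), seed=21)
    return world, prep, split


def _quick_cfg(seed=0, **kw):
    base = dict(
        learning_rate=1e-3, max_epochs=5, patience=5, batch_size=32,
        seed=seed, finetune_max_epochs=3, selection_metric="val_total_loss",
    )
    base.update(kw)
    base["patience"] = min(base["patience"], base["max_epochs"])
    return TrainingConfig(**base)


class TestBuildTrainingBatch:
    def test_missing_label_is_masked(self):
        drugs = {"A": np.zeros(2), "B": np.ones(2)}
        contexts = {"k": np.ones(2)}
        records = [SynergyRecord("A", "B", "k", 1.0)]
        batch = build_training_batch(records, {("A", "k"): 1}, drugs, contexts, augment=False)
        assert batch.m_i.tolist() == [True] and batch.m_j.tolist() == [False]
        assert batch.s_i.tolist() == [1.0]

    def test_augmentation_doubles_and_swaps(self):
        drugs = {"A": np.zeros(2), "B": np.ones(2)}
        contexts = {"k": np.ones(2)}
        records = [SynergyRecord("A", "B", "k", 1.0)]
        batch = build_training_batch(records, {("A", "k"): 1}, drugs, contexts, augment=True)
        assert len(batch) == 2
        np.testing.assert_array_equal(batch.d_i[1], drugs["B"])
        assert batch.m_j.tolist() == [False, True]

    def test_empty_records_rejected(self):
        with pytest.raises(ValidationError):
            build_training_batch([], {}, {}, {}, augment=False)

    def test_missing_feature_vector_named(self):
        records = [SynergyRecord("A", "B", "k", 1.0)]
        with pytest.raises(ValidationError, match="'B'"):
            build_training_batch(records, {}, {"A": np.zeros(2)}, {"k": np.zeros(2)})


class TestTrainBase:
    def test_loss_descends_on_average(self, small_world):
        _, prep, split = small_world
        drops = 0
        for seed in (1, 2, 3):
            _, log = train_base(
                split.train, split.validation, prep.drugs, prep.contexts,
                prep.sens_index, SMALL_ARCH, LossConfig(), _quick_cfg(seed, max_epochs=2),
            )
            drops += log["train_loss"][1] < log["train_loss"][0]
        assert drops >= 2  # descent sanity over 3 seeds

    def test_same_seed_bitwise_identical(self, small_world):
        _, prep, split = small_world
        args = (split.train, split.validation, prep.drugs, prep.contexts,
                prep.sens_index, SMALL_ARCH, LossConfig())
        p1, _ = train_base(*args, _quick_cfg(7, max_epochs=3))
        p2, _ = train_base(*args, _quick_cfg(7, max_epochs=3))
        for part in ("den", "ddn", "san"):
            assert p1.equal(p2, part)

    def test_patience_zero_stops_at_first_non_improvement(self, small_world):
        _, prep, split = small_world
        # a huge learning rate makes the validation metric blow past the
        # first epoch's value immediately
        params, log = train_base(
            split.train, split.validation, prep.drugs, prep.contexts,
            prep.sens_index, SMALL_ARCH, LossConfig(),
            _quick_cfg(3, learning_rate=5.0, max_epochs=10, patience=0),
        )
        if log["epochs_run"] < 10:  # early stop triggered
            assert log["best_epoch"] == int(np.argmin(log["val_metric"]))
            assert log["epochs_run"] == log["best_epoch"] + 2

    def test_empty_inputs_rejected(self, small_world):
        _, prep, split = small_world
        with pytest.raises(ValidationError):
            train_base([], split.validation, prep.drugs, prep.contexts,
                       prep.sens_index, SMALL_ARCH, LossConfig(), _quick_cfg())


@pytest.fixture(scope="module")
def trained(small_world):
    _, prep, split = small_world
    params, log = train_base(
        split.train, split.validation, prep.drugs, prep.contexts,
        prep.sens_index, SMALL_ARCH, LossConfig(), _quick_cfg(5, max_epochs=4),
    )
    return params, log


class TestFinetune:
    def test_san_frozen_bitwise(self, small_world, trained):
        _, prep, _ = small_world
        base, _ = trained
        tuned = finetune_all_patients(base, prep.patients, prep.drugs,
                                      LossConfig(), _quick_cfg(1))
        assert tuned.checksum("san") == base.checksum("san")
        assert not tuned.equal(base, "den")  # encoder actually moved

    def test_zero_epochs_is_identity(self, small_world, trained):
        _, prep, _ = small_world
        base, _ = trained
        tuned = finetune_all_patients(
            base, prep.patients, prep.drugs, LossConfig(),
            _quick_cfg(1, finetune_max_epochs=0),
        )
        for part in ("den", "ddn", "san"):
            assert tuned.equal(base, part)

    def test_ddn_freeze_flag(self, small_world, trained):
        _, prep, _ = small_world
        base, _ = trained
        tuned = finetune_all_patients(
            base, prep.patients, prep.drugs, LossConfig(),
            _quick_cfg(1, finetune_train_ddn=False),
        )
        assert tuned.equal(base, "ddn") and tuned.checksum("san") == base.checksum("san")
        assert not tuned.equal(base, "den")

    def test_per_patient_yields_distinct_models(self, small_world, trained):
        _, prep, _ = small_world
        base, _ = trained
        tuned = finetune_per_patient(base, prep.patients, prep.drugs,
                                     LossConfig(), _quick_cfg(1))
        assert set(tuned) == {p.patient_id for p in prep.patients}
        pids = list(tuned)
        assert not tuned[pids[0]].equal(tuned[pids[1]], "den")
        for p in tuned.values():
            assert p.checksum("san") == base.checksum("san")

    def test_identical_patients_get_identical_models(self, small_world, trained):
        _, prep, _ = small_world
        base, _ = trained
        p = prep.patients[0]
        clone = PatientContext("copy", ExpressionProfile("copy", "patient",
                               p.expression.values), p.sensitivity_labels)
        tuned = finetune_per_patient(base, [p, clone], prep.drugs,
                                     LossConfig(), _quick_cfg(1))
        assert tuned[p.patient_id].equal(tuned["copy"], "den")

    def test_single_patient_strategies_coincide(self, small_world, trained):
        _, prep, _ = small_world
        base, _ = trained
        p = prep.patients[0]
        st1 = finetune_all_patients(base, [p], prep.drugs, LossConfig(), _quick_cfg(1))
        st2 = finetune_per_patient(base, [p], prep.drugs, LossConfig(), _quick_cfg(1))
        for part in ("den", "ddn", "san"):
            assert st1.equal(st2[p.patient_id], part)

    def test_no_labels_rejected(self, small_world, trained):
        _, prep, _ = small_world
        base, _ = trained
        empty = PatientContext("p0", prep.patients[0].expression, [])
        with pytest.raises(ValidationError):
            finetune_all_patients(base, [empty], prep.drugs, LossConfig(), _quick_cfg(1))


class TestPredictForPatient:
    def test_delegates_to_symmetric_predict(self, small_world, trained):
        world, prep, _ = small_world
        base, _ = trained
        patient = prep.patients[0]
        pairs = [(r.drug_i, r.drug_j) for r in world.patient_synergy
                 if r.context_id == patient.patient_id]
        fwd = predict_synergy_for_patient(base, patient, pairs, prep.drugs)
        rev = predict_synergy_for_patient(base, patient, [(b, a) for a, b in pairs], prep.drugs)
        np.testing.assert_array_equal(fwd.y_hat, rev.y_hat)

    def test_unknown_drug_rejected(self, small_world, trained):
        _, prep, _ = small_world
        base, _ = trained
        with pytest.raises(ValidationError, match="unknown drug"):
            predict_synergy_for_patient(base, prep.patients[0], [("nope", "D0001")], prep.drugs)


class TestModelAPI:
    def test_fit_predict_evaluate_roundtrip(self, small_world, tmp_path):
        world, prep, split = small_world
        model = PDSPModel(split.train, split.validation, prep.drugs, prep.contexts,
                          prep.sens_index, arch=SMALL_ARCH)
        res = model.fit(_quick_cfg(2, max_epochs=3))
        metrics = res.evaluate_regression(split.test)
        assert set(metrics) == {"mse", "pearson", "spearman"}
        assert "epochs run" in res.summary() or "epochs" in res.summary()

        path = tmp_path / "ckpt.npz"
        res.save(path)
        loaded = pio.load_checkpoint(path)
        for part in ("den", "ddn", "san"):
            assert loaded.equal(res.params, part)

    def test_finetune_interface(self, small_world):
        world, prep, split = small_world
        model = PDSPModel(split.train, split.validation, prep.drugs, prep.contexts,
                          prep.sens_index, arch=SMALL_ARCH)
        res = model.fit(_quick_cfg(2, max_epochs=2))
        pers = res.finetune(prep.patients, strategy="per-patient", train_cfg=_quick_cfg(2))
        panel = pers.evaluate_panel(world.patient_synergy)
        assert {"bacc", "precision", "tp", "tn", "fp", "fn"} <= set(panel)

    def test_dimension_mismatch_rejected(self, small_world):
        _, prep, split = small_world
        bad = ArchitectureConfig(d_drug=5, d_expr=8, latent_dim=2,
                                 den_hidden=(4,), ddn_hidden=(4,), san_hidden=(4,))
        with pytest.raises(ValidationError):
            PDSPModel(split.train, split.validation, prep.drugs, prep.contexts,
                      prep.sens_index, arch=bad)
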