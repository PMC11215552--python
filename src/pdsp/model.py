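"""Multi-task synergy/sensitivity network and its joint loss.

The architecture has three sub-networks:

* **DEN** (drug encoder): maps the concatenation of one drug's chemical
  features with the context's expression profile to a conditional latent
  vector ``h`` of dimension ``m``.  One weight set serves both drug
  positions, so the two drugs of a pair receive identical treatment.
* **DDN** (drug decoder): maps ``h`` to a single-drug sensitivity logit;
  again one weight set for both positions.
* **SAN** (synergy aggregation): maps ``concat(h1, h2)`` to the predicted
  Bliss synergy score.

The training loss is ``L = L_reg + lambda * L_cls`` where ``L_reg`` is the
mean squared error on Bliss scores and ``L_cls`` is a class-weighted binary
cross-entropy summed over the two drug positions, with per-position masks for
pairs whose sensitivity label is unknown.

Concatenation makes the raw SAN score order-dependent, so :func:`predict`
averages the two concatenation orders, which is exactly symmetric in floating
point; training additionally presents each pair in both orders (see
:mod:`pdsp.train`).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .nn import (
    Adam,
    Layer,
    init_mlp,
    mlp_backward,
    mlp_forward,
    sigmoid,
    softplus,
)
from .records import ValidationError

_BCE_EPS = 1e-7


@dataclass(frozen=True)
class ArchitectureConfig:
    """Layer widths and dropout for the three sub-networks.

    ``den_hidden``/``ddn_hidden``/``san_hidden`` are the hidden widths before
    the final linear layer of each network; the encoder's output width is
    ``latent_dim``.  The defaults follow the wide-to-narrow funnel customary
    for descriptor+expression inputs and are configuration, not constants —
    the synthetic-scale configs used in the tests are much smaller.
    """

    d_drug: int
    d_expr: int
    latent_dim: int = 256
    den_hidden: tuple[int, ...] = (1024, 512)
    ddn_hidden: tuple[int, ...] = (128, 64)
    san_hidden: tuple[int, ...] = (512, 256)
    dropout_rate: float = 0.2

    def __post_init__(self) -> None:
        dims = (
            self.d_drug,
            self.d_expr,
            self.latent_dim,
            *self.den_hidden,
            *self.ddn_hidden,
            *self.san_hidden,
        )
        if any(int(d) <= 0 for d in dims):
            raise ValidationError("all architecture dimensions must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        d = dict(d)
        for key in ("den_hidden", "ddn_hidden", "san_hidden"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class LossConfig:
    """Weights of the joint loss.

    ``lambda_task`` multiplies the classification term.  ``lambda_sensitive``
    and ``lambda_resistant`` weight the positive and negative classes inside
    the cross-entropy; leave them ``None`` to derive inverse class
    frequencies (renormalized to mean 1) from the training labels at fit
    time, the standard imbalance correction.
    """

    lambda_task: float = 10.0
    lambda_sensitive: Optional[float] = None
    lambda_resistant: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lambda_task < 0:
            raise ValidationError("lambda_task must be >= 0")
        for v in (self.lambda_sensitive, self.lambda_resistant):
            if v is not None and v < 0:
                raise ValidationError("class weights must be >= 0")

    def resolved(self, labels: Optional[np.ndarray] = None) -> "LossConfig":
        """Fill in class weights, from label frequencies if available."""
        l1, l2 = self.lambda_sensitive, self.lambda_resistant
        if l1 is not None and l2 is not None:
            return self
        if labels is None or len(labels) == 0:
            return LossConfig(self.lambda_task, l1 or 1.0, l2 or 1.0)
        labels = np.asarray(labels)
        p1 = float(np.mean(labels == 1))
        p0 = 1.0 - p1
        if p1 == 0.0 or p0 == 0.0:  # one class absent: no reweighting possible
            return LossConfig(self.lambda_task, 1.0, 1.0)
        w1, w0 = 1.0 / p1, 1.0 / p0
        mean = 0.5 * (w1 + w0)
        return LossConfig(self.lambda_task, w1 / mean, w0 / mean)


@dataclass
class PredictionResult:
    """Symmetrized synergy score and the two sensitivity probabilities."""

    y_hat: np.ndarray
    s_hat_i: np.ndarray
    s_hat_j: np.ndarray


class ModelParameters:
    """The three sub-network parameter sets, with shared-encoder semantics.

    There is exactly one ``den`` layer stack and one ``ddn`` layer stack —
    both drug positions run through the same objects, so weight sharing is
    structural rather than enforced by synchronization.
    """

    def __init__(
        self,
        den: list[Layer],
        ddn: list[Layer],
        san: list[Layer],
        config_snapshot: ArchitectureConfig,
    ):
        self.den = den
        self.ddn = ddn
        self.san = san
        self.config_snapshot = config_snapshot

    # -- construction -----------------------------------------------------
    @classmethod
    def initialize(cls, cfg: ArchitectureConfig, seed: int = 0) -> "ModelParameters":
        rng = np.random.default_rng(seed)
        den = init_mlp([cfg.d_drug + cfg.d_expr, *cfg.den_hidden, cfg.latent_dim], rng)
        ddn = init_mlp([cfg.latent_dim, *cfg.ddn_hidden, 1], rng)
        san = init_mlp([2 * cfg.latent_dim, *cfg.san_hidden, 1], rng)
        return cls(den, ddn, san, cfg)

    @classmethod
    def zeros(cls, cfg: ArchitectureConfig) -> "ModelParameters":
        p = cls.initialize(cfg, seed=0)
        for arr in p.flat_arrays():
            arr[...] = 0.0
        return p

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            [l.copy() for l in self.den],
            [l.copy() for l in self.ddn],
            [l.copy() for l in self.san],
            self.config_snapshot,
        )

    # -- introspection -----------------------------------------------------
    def parts(self) -> dict[str, list[Layer]]:
        return {"den": self.den, "ddn": self.ddn, "san": self.san}

    def flat_arrays(self, parts: Sequence[str] = ("den", "ddn", "san")) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for name in parts:
            for layer in self.parts()[name]:
                out.extend([layer.W, layer.b])
        return out

    def checksum(self, part: str) -> str:
        h = hashlib.sha256()
        for layer in self.parts()[part]:
            h.update(np.ascontiguousarray(layer.W).tobytes())
            h.update(np.ascontiguousarray(layer.b).tobytes())
        return h.hexdigest()

    def equal(self, other: "ModelParameters", part: str) -> bool:
        a, b = self.parts()[part], other.parts()[part]
        return len(a) == len(b) and all(
            np.array_equal(x.W, y.W) and np.array_equal(x.b, y.b)
            for x, y in zip(a, b)
        )

    # -- serialization -----------------------------------------------------
    def to_arrays(self) -> tuple[dict[str, np.ndarray], dict]:
        arrays = {}
        for name, layers in self.parts().items():
            for k, layer in enumerate(layers):
                arrays[f"{name}_{k}_W"] = layer.W
                arrays[f"{name}_{k}_b"] = layer.b
        meta = {
            "config": self.config_snapshot.to_dict(),
            "n_layers": {name: len(ls) for name, ls in self.parts().items()},
        }
        return arrays, meta

    @classmethod
    def from_arrays(cls, arrays: dict[str, np.ndarray], meta: dict) -> "ModelParameters":
        cfg = ArchitectureConfig.from_dict(meta["config"])
        stacks = {}
        for name in ("den", "ddn", "san"):
            n = meta["n_layers"][name]
            stacks[name] = [
                Layer(arrays[f"{name}_{k}_W"].copy(), arrays[f"{name}_{k}_b"].copy())
                for k in range(n)
            ]
        return cls(stacks["den"], stacks["ddn"], stacks["san"], cfg)


# ---------------------------------------------------------------------------
# forward passes


def _as_batch(x: np.ndarray, width: int, what: str) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.ndim != 2 or x.shape[1] != width:
        raise ValidationError(
            f"{what}: expected width {width}, got shape {x.shape}"
        )
    return x, single


def _den_dropout(params: ModelParameters) -> list[bool]:
    # dropout after every encoder layer, including the final linear one
    return [True] * len(params.den)


def _head_dropout(layers: Sequence[Layer]) -> list[bool]:
    # dropout after hidden layers only; the final linear output is left alone
    return [True] * (len(layers) - 1) + [False]


def den_forward(
    d: np.ndarray,
    c: np.ndarray,
    params: ModelParameters,
    mode: str = "eval",
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Encode (drug features, context expression) into the latent vector h."""
    cfg = params.config_snapshot
    d2, single_d = _as_batch(d, cfg.d_drug, "drug features")
    c2, single_c = _as_batch(c, cfg.d_expr, "context expression")
    if d2.shape[0] != c2.shape[0]:
        raise ValidationError("drug and context batches differ in length")
    x = np.concatenate([d2, c2], axis=1)
    h, _ = mlp_forward(
        x, params.den, _den_dropout(params), cfg.dropout_rate, mode == "train", rng
    )
    return h[0] if (single_d and single_c) else h


def ddn_forward(
    h: np.ndarray,
    params: ModelParameters,
    mode: str = "eval",
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Decode a latent vector to a single-drug sensitivity logit."""
    cfg = params.config_snapshot
    h2, single = _as_batch(h, cfg.latent_dim, "latent vector")
    z, _ = mlp_forward(
        h2, params.ddn, _head_dropout(params.ddn), cfg.dropout_rate, mode == "train", rng
    )
    z = z[:, 0]
    return float(z[0]) if single else z


def san_forward(
    h1: np.ndarray,
    h2: np.ndarray,
    params: ModelParameters,
    mode: str = "eval",
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Score the concatenation of two latent vectors as a Bliss prediction.

    Raw output depends on concatenation order; :func:`predict` symmetrizes.
    """
    cfg = params.config_snapshot
    a, single1 = _as_batch(h1, cfg.latent_dim, "latent vector h1")
    b, single2 = _as_batch(h2, cfg.latent_dim, "latent vector h2")
    if a.shape[0] != b.shape[0]:
        raise ValidationError("latent batches differ in length")
    y, _ = mlp_forward(
        np.concatenate([a, b], axis=1),
        params.san,
        _head_dropout(params.san),
        cfg.dropout_rate,
        mode == "train",
        rng,
    )
    y = y[:, 0]
    return float(y[0]) if (single1 and single2) else y


def predict(
    d_i: np.ndarray,
    d_j: np.ndarray,
    c: np.ndarray,
    params: ModelParameters,
    mode: str = "eval",
) -> PredictionResult:
    """Order-invariant prediction for one pair (or a batch of pairs).

    ``y_hat`` averages the two concatenation orders of the synergy head, so
    swapping the drugs swaps the sensitivity outputs and leaves the synergy
    score bit-identical.
    """
    h_i = den_forward(d_i, c, params, mode)
    h_j = den_forward(d_j, c, params, mode)
    y = 0.5 * (
        np.asarray(san_forward(h_i, h_j, params, mode))
        + np.asarray(san_forward(h_j, h_i, params, mode))
    )
    s_i = sigmoid(np.asarray(ddn_forward(h_i, params, mode), dtype=float))
    s_j = sigmoid(np.asarray(ddn_forward(h_j, params, mode), dtype=float))
    return PredictionResult(y, s_i, s_j)


# ---------------------------------------------------------------------------
# losses


def regression_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean squared error over Bliss scores."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValidationError(
            f"regression_loss: need equal, nonempty vectors, got {y.shape} vs {y_hat.shape}"
        )
    return float(np.mean((y - y_hat) ** 2))


def weighted_bce(
    labels: np.ndarray,
    probs: np.ndarray,
    lambda_sensitive: float,
    lambda_resistant: float,
) -> float:
    """Class-weighted binary cross-entropy over probabilities.

    ``-(1/N) * sum[ l1 * s * log(p) + l2 * (1-s) * log(1-p) ]`` with
    probabilities clipped away from {0, 1} by 1e-7.
    """
    labels = np.asarray(labels, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if labels.shape != probs.shape or labels.size == 0:
        raise ValidationError("weighted_bce: need equal, nonempty vectors")
    if np.any((probs < 0.0) | (probs > 1.0)):
        raise ValidationError("weighted_bce: probability outside [0, 1]")
    p = np.clip(probs, _BCE_EPS, 1.0 - _BCE_EPS)
    terms = lambda_sensitive * labels * np.log(p) + lambda_resistant * (
        1.0 - labels
    ) * np.log(1.0 - p)
    return float(-np.mean(terms))


def _wbce_from_logits_masked(
    labels: np.ndarray, logits: np.ndarray, mask: np.ndarray, l1: float, l2: float
) -> tuple[float, np.ndarray]:
    """Stable masked wBCE from logits; returns (loss, dloss/dlogits).

    Masked entries contribute nothing and N counts only unmasked entries;
    with every entry masked the term (and its gradient) is zero.
    """
    n = int(mask.sum())
    if n == 0:
        return 0.0, np.zeros_like(logits)
    s = labels
    per = l1 * s * softplus(-logits) + l2 * (1.0 - s) * softplus(logits)
    loss = float(np.sum(per * mask) / n)
    sig = sigmoid(logits)
    grad = (l1 * s * (sig - 1.0) + l2 * (1.0 - s) * sig) * mask / n
    return loss, grad


@dataclass
class Batch:
    """Vectorized training batch with per-position sensitivity masks."""

    d_i: np.ndarray  # (n, d_drug)
    d_j: np.ndarray  # (n, d_drug)
    c: np.ndarray  # (n, d_expr)
    y: np.ndarray  # (n,)
    s_i: np.ndarray  # (n,) binary, meaningful where m_i
    m_i: np.ndarray  # (n,) bool mask: position-i label present
    s_j: np.ndarray
    m_j: np.ndarray

    def __len__(self) -> int:
        return len(self.y)

    def take(self, idx: np.ndarray) -> "Batch":
        return Batch(
            self.d_i[idx], self.d_j[idx], self.c[idx], self.y[idx],
            self.s_i[idx], self.m_i[idx], self.s_j[idx], self.m_j[idx],
        )


def _forward_joint(
    batch: Batch,
    params: ModelParameters,
    mode: str,
    rng: Optional[np.random.Generator],
):
    cfg = params.config_snapshot
    train = mode == "train"
    x_i = np.concatenate([batch.d_i, batch.c], axis=1)
    x_j = np.concatenate([batch.d_j, batch.c], axis=1)
    dd = _den_dropout(params)
    h_i, cache_i = mlp_forward(x_i, params.den, dd, cfg.dropout_rate, train, rng)
    h_j, cache_j = mlp_forward(x_j, params.den, dd, cfg.dropout_rate, train, rng)
    hd = _head_dropout(params.san)
    y_hat, cache_s = mlp_forward(
        np.concatenate([h_i, h_j], axis=1), params.san, hd, cfg.dropout_rate, train, rng
    )
    hdd = _head_dropout(params.ddn)
    z_i, cache_di = mlp_forward(h_i, params.ddn, hdd, cfg.dropout_rate, train, rng)
    z_j, cache_dj = mlp_forward(h_j, params.ddn, hdd, cfg.dropout_rate, train, rng)
    return (
        h_i, h_j, y_hat[:, 0], z_i[:, 0], z_j[:, 0],
        (cache_i, cache_j, cache_s, cache_di, cache_dj),
    )


def total_loss(batch: Batch, params: ModelParameters, loss_cfg: LossConfig) -> float:
    """Joint loss ``L_reg + lambda * (wBCE_i + wBCE_j)`` in eval mode."""
    if len(batch) == 0:
        raise ValidationError("total_loss: empty batch")
    cfg = loss_cfg.resolved()
    _, _, y_hat, z_i, z_j, _ = _forward_joint(batch, params, "eval", None)
    l_reg = float(np.mean((batch.y - y_hat) ** 2))
    bce_i, _ = _wbce_from_logits_masked(
        batch.s_i, z_i, batch.m_i.astype(float), cfg.lambda_sensitive, cfg.lambda_resistant
    )
    bce_j, _ = _wbce_from_logits_masked(
        batch.s_j, z_j, batch.m_j.astype(float), cfg.lambda_sensitive, cfg.lambda_resistant
    )
    return l_reg + cfg.lambda_task * (bce_i + bce_j)


def loss_and_grads(
    batch: Batch,
    params: ModelParameters,
    loss_cfg: LossConfig,
    mode: str = "train",
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, dict[str, list[Layer]]]:
    """Joint loss and analytic gradients for every sub-network.

    Both drug positions run through the single shared encoder/decoder stacks,
    so their gradient contributions are summed into one parameter set each.
    """
    if len(batch) == 0:
        raise ValidationError("loss_and_grads: empty batch")
    cfg = loss_cfg.resolved()
    n = len(batch)
    m = params.config_snapshot.latent_dim

    h_i, h_j, y_hat, z_i, z_j, caches = _forward_joint(batch, params, mode, rng)
    cache_i, cache_j, cache_s, cache_di, cache_dj = caches

    l_reg = float(np.mean((batch.y - y_hat) ** 2))
    bce_i, gz_i = _wbce_from_logits_masked(
        batch.s_i, z_i, batch.m_i.astype(float), cfg.lambda_sensitive, cfg.lambda_resistant
    )
    bce_j, gz_j = _wbce_from_logits_masked(
        batch.s_j, z_j, batch.m_j.astype(float), cfg.lambda_sensitive, cfg.lambda_resistant
    )
    loss = l_reg + cfg.lambda_task * (bce_i + bce_j)

    # synergy head
    gy = (2.0 / n) * (y_hat - batch.y)
    g_concat, g_san = mlp_backward(gy[:, None], params.san, cache_s)
    gh_i = g_concat[:, :m].copy()
    gh_j = g_concat[:, m:].copy()

    # sensitivity heads (shared DDN: sum both positions' gradients)
    gin_di, g_ddn_i = mlp_backward(
        cfg.lambda_task * gz_i[:, None], params.ddn, cache_di
    )
    gin_dj, g_ddn_j = mlp_backward(
        cfg.lambda_task * gz_j[:, None], params.ddn, cache_dj
    )
    gh_i += gin_di
    gh_j += gin_dj
    g_ddn = [
        Layer(a.W + b.W, a.b + b.b) for a, b in zip(g_ddn_i, g_ddn_j)
    ]

    # shared encoder: sum both positions' gradients
    _, g_den_i = mlp_backward(gh_i, params.den, cache_i)
    _, g_den_j = mlp_backward(gh_j, params.den, cache_j)
    g_den = [Layer(a.W + b.W, a.b + b.b) for a, b in zip(g_den_i, g_den_j)]

    return loss, {"den": g_den, "ddn": g_ddn, "san": g_san}


def sensitivity_loss_and_grads(
    d: np.ndarray,
    c: np.ndarray,
    labels: np.ndarray,
    params: ModelParameters,
    loss_cfg: LossConfig,
    mode: str = "train",
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, dict[str, list[Layer]]]:
    """wBCE loss and gradients through DEN -> DDN for single-drug examples.

    This is the fine-tuning objective: no synergy term exists for patient
    data, and the synergy head takes no gradient at all.
    """
    cfg = loss_cfg.resolved(labels)
    acfg = params.config_snapshot
    train = mode == "train"
    n = len(labels)
    if n == 0:
        raise ValidationError("sensitivity fine-tuning: empty batch")
    x = np.concatenate([np.asarray(d, float), np.asarray(c, float)], axis=1)
    h, cache_e = mlp_forward(
        x, params.den, _den_dropout(params), acfg.dropout_rate, train, rng
    )
    z, cache_d = mlp_forward(
        h, params.ddn, _head_dropout(params.ddn), acfg.dropout_rate, train, rng
    )
    z = z[:, 0]
    loss, gz = _wbce_from_logits_masked(
        np.asarray(labels, float), z, np.ones(n), cfg.lambda_sensitive, cfg.lambda_resistant
    )
    gh, g_ddn = mlp_backward(gz[:, None], params.ddn, cache_d)
    _, g_den = mlp_backward(gh, params.den, cache_e)
    return loss, {"den": g_den, "ddn": g_ddn}
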