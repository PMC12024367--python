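"""Contrastive pre-training of the encoder.

The objective is a pairwise margin loss over the latent vectors of a
mini-batch: same-class pairs contribute their squared Euclidean distance,
different-class pairs a hinge that is active while they sit closer than the
margin (0.5 by default).  Two hinge variants are provided:

* ``hinge_on_distance`` (default): max(0, eps - D_ij)^2 — the canonical
  margin-contrastive form;
* ``hinge_on_squared_distance``: max(0, eps - D_ij^2) — a literal reading of
  the ambiguous ``||.||2`` notation.

Pairs are aggregated by *mean* so the loss scale is comparable across batch
sizes, which is what makes a batch-size sweep meaningful.  Optimization uses
a from-scratch Adam with a step-decay learning-rate schedule (halving every
60 epochs by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .data_model import Cohort
from .encoder import EncoderConfig, EncoderParams, backward, forward

__all__ = [
    "TrainConfig",
    "TrainState",
    "Standardizer",
    "pairwise_distance_matrix",
    "contrastive_loss",
    "contrastive_loss_grad",
    "lr_at_epoch",
    "train",
    "AdamOptimizer",
]

_VARIANTS = ("hinge_on_distance", "hinge_on_squared_distance")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Defaults: margin 0.5, Adam at 1e-3 halved every 60 epochs, 240 epochs.
    The default batch size is 100 (the value a batch-size sweep selects);
    300 is the alternative preset.
    """

    batch_size: int = 100
    margin: float = 0.5
    learning_rate: float = 1e-3
    lr_step: int = 60
    lr_gamma: float = 0.5
    epochs: int = 240
    loss_variant: str = "hinge_on_distance"
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if not (0 < self.lr_gamma <= 1):
            raise ValueError("lr_gamma must be in (0, 1]")
        if self.epochs < 1 or self.batch_size < 2 or self.lr_step < 1:
            raise ValueError("epochs >= 1, batch_size >= 2, lr_step >= 1 required")
        if self.loss_variant not in _VARIANTS:
            raise ValueError(f"loss_variant must be one of {_VARIANTS}")


@dataclass
class Standardizer:
    """Per-feature z-scoring fitted on the training partition only."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)  # constant columns pass through
        return cls(mean=X.mean(axis=0), scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


@dataclass
class TrainState:
    """Outcome of a training run."""

    params: EncoderParams
    epoch: int
    current_lr: float
    loss_history: list[float]
    val_loss_history: list[float] = field(default_factory=list)
    chem_scaler: Standardizer | None = None
    train_config: TrainConfig | None = None

    def log_frame(self):
        """Per-epoch log as a DataFrame (epoch, lr, train_loss, val_loss)."""
        import pandas as pd

        cfg = self.train_config
        epochs = len(self.loss_history)
        lrs = [lr_at_epoch(cfg, e) if cfg else np.nan for e in range(epochs)]
        val = self.val_loss_history or [np.nan] * epochs
        return pd.DataFrame(
            {"epoch": np.arange(epochs), "lr": lrs,
             "train_loss": self.loss_history, "val_loss": val}
        )


# ---------------------------------------------------------------------------
# loss primitives
# ---------------------------------------------------------------------------


def pairwise_distance_matrix(X) -> np.ndarray:
    """Symmetric batch x batch matrix of Euclidean row distances."""
    from .encoder import LatentMatrix

    if isinstance(X, LatentMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    if not np.all(np.isfinite(X)):
        raise FloatingPointError("non-finite rows in latent matrix")
    diff = X[:, None, :] - X[None, :, :]
    M = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(M, 0.0)
    return (M + M.T) / 2.0  # enforce exact symmetry against rounding


def _pair_terms(X, y, margin, variant):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if n < 2:
        raise ValueError("contrastive loss needs at least two samples")
    if y.shape != (n,):
        raise ValueError("labels do not match batch size")
    same = y[:, None] == y[None, :]
    if same.all():
        warnings.warn("single-class batch: no negative pairs in contrastive "
                      "loss", stacklevel=3)
    D = pairwise_distance_matrix(X)
    iu, ju = np.triu_indices(n, k=1)
    d = D[iu, ju]
    s = same[iu, ju]
    if variant == "hinge_on_distance":
        hinge = np.maximum(0.0, margin - d)
        terms = np.where(s, d**2, hinge**2)
    else:
        terms = np.where(s, d**2, np.maximum(0.0, margin - d**2))
    return terms, d, s, iu, ju


def contrastive_loss(X, y, margin: float = 0.5,
                     variant: str = "hinge_on_distance") -> float:
    """Mean pairwise contrastive loss over all unordered pairs of the batch."""
    from .encoder import LatentMatrix

    if isinstance(X, LatentMatrix):
        X = X.values
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    terms, *_ = _pair_terms(X, y, margin, variant)
    return float(terms.mean())


def contrastive_loss_grad(X, y, margin: float = 0.5,
                          variant: str = "hinge_on_distance"):
    """Loss value and its gradient with respect to the latent rows.

    The hinge term's distance gradient involves 1/D; at coincident
    different-class points (D = 0) the subgradient 0 is used.
    """
    X = np.asarray(X, dtype=float)
    terms, d, s, iu, ju = _pair_terms(X, y, margin, variant)
    n = X.shape[0]
    n_pairs = len(terms)
    diff = X[iu] - X[ju]  # (n_pairs, p)
    if variant == "hinge_on_distance":
        hinge = np.maximum(0.0, margin - d)
        with np.errstate(divide="ignore", invalid="ignore"):
            coef_neg = np.where(d > 1e-12, -2.0 * hinge / d, 0.0)
    else:
        coef_neg = np.where(d**2 < margin, -2.0, 0.0)
    coef = np.where(s, 2.0, coef_neg) / n_pairs  # d(term)/d(diff) factor
    g = coef[:, None] * diff
    grad = np.zeros_like(X)
    np.add.at(grad, iu, g)
    np.add.at(grad, ju, -g)
    return float(terms.mean()), grad


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Step-decay schedule: lr * gamma^floor(epoch / step)."""
    if not (0 <= epoch < config.epochs):
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    return config.learning_rate * config.lr_gamma ** (epoch // config.lr_step)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class AdamOptimizer:
    """Adaptive-moment estimation over a dict of named parameter arrays."""

    def __init__(self, keys, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: None for k in keys}
        self.v = {k: None for k in keys}

    def step(self, arrays: dict[str, np.ndarray],
             grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for k in self.m:
            g = grads[k]
            if self.m[k] is None:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            arrays[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _modality_inputs(modality_set, X_f, X_c):
    if modality_set == "both":
        return {"ftir": X_f, "chem": X_c}
    if modality_set == "ftir_only":
        return {"ftir": X_f}
    if modality_set == "chem_only":
        return {"chem": X_c}
    raise ValueError(f"unknown modality_set {modality_set!r}")


def train(
    cohort: Cohort,
    enc_config: EncoderConfig,
    train_config: TrainConfig,
    modality_set: str = "both",
) -> TrainState:
    """Contrastively pre-train an encoder on the cohort's training partition.

    Per epoch the training samples are shuffled and iterated in mini-batches
    (a trailing partial batch is kept when it holds at least two samples);
    each batch takes one Adam step at the scheduled learning rate.  The
    validation partition is encoded in eval mode each epoch and its loss
    logged; it never contributes gradients.  There is no early stopping.

    Initialization is controlled by ``enc_config.seed``, shuffling by
    ``train_config.seed``; the run is deterministic given both.
    """
    if cohort.split is None:
        raise ValueError("cohort has no split; call grouped_split first")
    tr = cohort.partition("train")
    va = cohort.partition("val")
    Xf_tr, Xc_tr, y_tr = tr.features()
    if len(set(y_tr.tolist())) < 2:
        raise ValueError("training partition must contain both classes")
    scaler = Standardizer.fit(Xc_tr)
    Xc_tr = scaler.transform(Xc_tr)
    have_val = len(va) >= 2
    if have_val:
        Xf_va, Xc_va, y_va = va.features()
        Xc_va = scaler.transform(Xc_va)

    params = EncoderParams.init(enc_config, modality_set)
    opt = AdamOptimizer(params.trainable_keys(), train_config.adam_beta1,
                        train_config.adam_beta2, train_config.adam_eps)
    rng = np.random.default_rng(train_config.seed)
    n = len(y_tr)
    bs = train_config.batch_size
    loss_history: list[float] = []
    val_history: list[float] = []
    for epoch in range(train_config.epochs):
        lr = lr_at_epoch(train_config, epoch)
        perm = rng.permutation(n)
        batch_losses = []
        batch_sizes = []
        for start in range(0, n, bs):
            idx = perm[start : start + bs]
            if len(idx) < 2:
                continue  # drop a trailing singleton: no pairs, no BN batch
            inputs = _modality_inputs(modality_set, Xf_tr[idx], Xc_tr[idx])
            Y, cache = forward(params, inputs, mode="train",
                               update_running=True)
            loss, dY = contrastive_loss_grad(
                Y, y_tr[idx], train_config.margin, train_config.loss_variant
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss!r}"
                )
            grads = backward(params, cache, dY)
            opt.step(params.arrays, grads, lr)
            batch_losses.append(loss)
            batch_sizes.append(len(idx))
        if not batch_losses:
            raise ValueError("training partition too small for any batch")
        loss_history.append(
            float(np.average(batch_losses, weights=batch_sizes))
        )
        if have_val:
            inputs = _modality_inputs(modality_set, Xf_va, Xc_va)
            Yv, _ = forward(params, inputs, mode="eval")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # val may be single-class
                val_history.append(
                    contrastive_loss(Yv, y_va, train_config.margin,
                                     train_config.loss_variant)
                )
    return TrainState(
        params=params,
        epoch=train_config.epochs,
        current_lr=lr_at_epoch(train_config, train_config.epochs - 1),
        loss_history=loss_history,
        val_loss_history=val_history,
        chem_scaler=scaler,
        train_config=train_config,
    )
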