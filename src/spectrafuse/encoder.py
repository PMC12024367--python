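"""Multi-modality spectral transformer encoder (forward and backward pass).

The encoder maps a pair (FTIR absorbance vector, biochemical indicator
vector) to a compact latent vector.  Per attention head, each modality is
encoded by three fully connected layers into query/key/value vectors (no
LayerNorm: the modalities keep their own physical scales and are instead
batch-normalized after the affine maps).  The per-modality Q, K, V vectors
are concatenated and a dual-path attention step runs over the concatenated
coordinates, treating each latent coordinate as a token of dimension 1:

    A = row_softmax(q k^T / sqrt(d_k)),   output = A v        (per sample)

so that the diagonal blocks of A carry intra-modal interactions and the
off-diagonal blocks inter-modal ones.  Head outputs are averaged and a final
per-feature batch normalization produces the latent vector of width
``d1 + d2`` (default 32 + 8 = 40).

Everything here is plain numpy with hand-written reverse-mode gradients;
:func:`backward` is validated against finite differences in the test suite.
In ``eval`` mode all batch norms use running statistics, so the encoding of a
sample is independent of the batch it shares.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "EncoderConfig",
    "EncoderParams",
    "LatentMatrix",
    "RunningStats",
    "batch_normalize",
    "dual_path_attention",
    "encode",
    "unimodal_encode",
    "forward",
    "backward",
]

_CHECKPOINT_VERSION = 1
_ROLES = ("q", "k", "v")


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters.

    ``d1``/``d2`` are the per-modality latent widths (32 for FTIR, 8 for the
    biochemical panel by default); ``d_k`` is the attention temperature, 1
    under the token-dimension-1 reading.  ``seed`` controls weight
    initialization and is recorded so repeated-initialization protocols are
    reproducible.
    """

    d_ftir: int = 1801
    d_chem: int = 36
    d1: int = 32
    d2: int = 8
    n_heads: int = 4
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1
    d_k: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d1 < 1 or self.d2 < 1 or self.n_heads < 1:
            raise ValueError("d1, d2 and n_heads must be >= 1")
        if self.bn_eps <= 0 or self.d_k <= 0:
            raise ValueError("bn_eps and d_k must be positive")

    def modalities(self, modality_set: str) -> list[tuple[str, int, int]]:
        """(name, input width, latent width) triplets active in a mode."""
        table = {
            "both": [("ftir", self.d_ftir, self.d1), ("chem", self.d_chem, self.d2)],
            "ftir_only": [("ftir", self.d_ftir, self.d1)],
            "chem_only": [("chem", self.d_chem, self.d2)],
        }
        if modality_set not in table:
            raise ValueError(f"unknown modality_set {modality_set!r}")
        return table[modality_set]

    def latent_width(self, modality_set: str) -> int:
        return sum(d_out for _, _, d_out in self.modalities(modality_set))


@dataclass
class RunningStats:
    """Exponential-moving-average statistics for one batch-norm layer."""

    mean: np.ndarray
    var: np.ndarray


@dataclass
class LatentMatrix:
    """Batch of encoded latent vectors, rows aligned with ``sample_ids``."""

    values: np.ndarray
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("latent values must be a 2-D matrix")
        if self.sample_ids is not None and len(self.sample_ids) != len(self.values):
            raise ValueError("sample_ids length does not match row count")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


class EncoderParams:
    """All learned arrays of the encoder, keyed by a flat naming scheme.

    Keys are ``head{h}.{modality}.{q|k|v}.{W|b|gamma|beta|mean|var}`` plus
    ``out.{gamma|beta|mean|var}`` for the final normalization.  ``mean`` and
    ``var`` entries are running statistics, not trainable.
    """

    def __init__(self, config: EncoderConfig, modality_set: str,
                 arrays: dict[str, np.ndarray]):
        self.config = config
        self.modality_set = modality_set
        self.arrays = arrays
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def init(cls, config: EncoderConfig, modality_set: str = "both",
             seed: int | None = None) -> "EncoderParams":
        """Seeded uniform fan-in initialization (U(-1/sqrt(fan_in), +))."""
        rng = np.random.default_rng(config.seed if seed is None else seed)
        arrays: dict[str, np.ndarray] = {}
        for h in range(config.n_heads):
            for mod, d_in, d_out in config.modalities(modality_set):
                a = 1.0 / np.sqrt(d_in)
                for role in _ROLES:
                    p = f"head{h}.{mod}.{role}"
                    arrays[f"{p}.W"] = rng.uniform(-a, a, size=(d_in, d_out))
                    arrays[f"{p}.b"] = rng.uniform(-a, a, size=d_out)
                    arrays[f"{p}.gamma"] = np.ones(d_out)
                    arrays[f"{p}.beta"] = np.zeros(d_out)
                    arrays[f"{p}.mean"] = np.zeros(d_out)
                    arrays[f"{p}.var"] = np.ones(d_out)
        width = config.latent_width(modality_set)
        arrays["out.gamma"] = np.ones(width)
        arrays["out.beta"] = np.zeros(width)
        arrays["out.mean"] = np.zeros(width)
        arrays["out.var"] = np.ones(width)
        return cls(config, modality_set, arrays)

    def _expected_shapes(self) -> dict[str, tuple[int, ...]]:
        shapes: dict[str, tuple[int, ...]] = {}
        cfg = self.config
        for h in range(cfg.n_heads):
            for mod, d_in, d_out in cfg.modalities(self.modality_set):
                for role in _ROLES:
                    p = f"head{h}.{mod}.{role}"
                    shapes[f"{p}.W"] = (d_in, d_out)
                    for leaf in ("b", "gamma", "beta", "mean", "var"):
                        shapes[f"{p}.{leaf}"] = (d_out,)
        width = cfg.latent_width(self.modality_set)
        for leaf in ("gamma", "beta", "mean", "var"):
            shapes[f"out.{leaf}"] = (width,)
        return shapes

    def _validate(self) -> None:
        expected = self._expected_shapes()
        if set(self.arrays) != set(expected):
            missing = sorted(set(expected) - set(self.arrays))
            extra = sorted(set(self.arrays) - set(expected))
            raise ValueError(f"parameter keys mismatch: missing={missing}, "
                             f"extra={extra}")
        for key, shp in expected.items():
            if self.arrays[key].shape != shp:
                raise ValueError(
                    f"{key}: expected shape {shp}, got {self.arrays[key].shape}"
                )
        for key in self.arrays:
            if key.endswith(".var") and np.any(self.arrays[key] < 0):
                raise ValueError(f"{key}: running variance must be >= 0")

    # -- views -------------------------------------------------------------

    @property
    def latent_width(self) -> int:
        return self.config.latent_width(self.modality_set)

    def trainable_keys(self) -> list[str]:
        return [k for k in self.arrays
                if not (k.endswith(".mean") or k.endswith(".var"))]

    def copy(self) -> "EncoderParams":
        return EncoderParams(self.config, self.modality_set,
                             {k: v.copy() for k, v in self.arrays.items()})

    # -- checkpoint io -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = {
            "version": _CHECKPOINT_VERSION,
            "modality_set": self.modality_set,
            "config": asdict(self.config),
        }
        np.savez(Path(path), __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.arrays)

    @classmethod
    def load(cls, path: str | Path) -> "EncoderParams":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("version") != _CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version: {meta}")
            arrays = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(EncoderConfig(**meta["config"]), meta["modality_set"], arrays)


# ---------------------------------------------------------------------------
# batch normalization primitives
# ---------------------------------------------------------------------------


def _bn_train(Z, gamma, beta, eps):
    m = Z.shape[0]
    if m < 2:
        raise ValueError("batch normalization in train mode needs batch size >= 2")
    mu = Z.mean(axis=0)
    var = Z.var(axis=0)  # biased: divide by m, matching the 1/m definition
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (Z - mu) * inv
    return gamma * xhat + beta, (xhat, inv, mu, var)


def _bn_eval(Z, gamma, beta, mean, var, eps):
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (Z - mean) * inv
    return gamma * xhat + beta, (xhat, inv)


def _bn_train_backward(dout, cache, gamma):
    xhat, inv, _, _ = cache
    m = dout.shape[0]
    dgamma = (dout * xhat).sum(axis=0)
    dbeta = dout.sum(axis=0)
    dxhat = dout * gamma
    dZ = (inv / m) * (
        m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
    )
    return dZ, dgamma, dbeta


def batch_normalize(
    X: np.ndarray,
    gamma: np.ndarray,
    beta: np.ndarray,
    eps: float = 1e-5,
    mode: str = "train",
    running_stats: RunningStats | None = None,
    momentum: float = 0.1,
) -> np.ndarray:
    """Standalone batch-norm operation.

    ``train`` mode normalizes by the batch mean and biased batch variance and,
    if ``running_stats`` is supplied, updates it in place by exponential
    moving average.  ``eval`` mode normalizes by the running statistics and
    never updates them.
    """
    X = np.asarray(X, dtype=float)
    if mode == "train":
        out, cache = _bn_train(X, gamma, beta, eps)
        if running_stats is not None:
            _, _, mu, var = cache
            running_stats.mean = (1 - momentum) * running_stats.mean + momentum * mu
            running_stats.var = (1 - momentum) * running_stats.var + momentum * var
        return out
    if mode == "eval":
        if running_stats is None:
            raise ValueError("eval mode requires running statistics")
        out, _ = _bn_eval(X, gamma, beta, running_stats.mean,
                          running_stats.var, eps)
        return out
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# dual-path attention over latent coordinates
# ---------------------------------------------------------------------------


def _softmax_last(S: np.ndarray) -> np.ndarray:
    S = S - S.max(axis=-1, keepdims=True)
    E = np.exp(S)
    return E / E.sum(axis=-1, keepdims=True)


def _attention_forward(Q, K, V, d_k):
    """Batched per-sample attention over T coordinate-tokens of dimension 1.

    Q, K, V: (n, T).  Returns output (n, T) and the (n, T, T) row-stochastic
    attention tensor.
    """
    S = Q[:, :, None] * K[:, None, :] / np.sqrt(d_k)
    A = _softmax_last(S)
    out = np.einsum("ntl,nl->nt", A, V)
    return out, A


def _attention_backward(dout, Q, K, V, A, d_k):
    dA = dout[:, :, None] * V[:, None, :]
    dV = np.einsum("njl,nj->nl", A, dout)
    dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
    scale = 1.0 / np.sqrt(d_k)
    dQ = np.einsum("njl,nl->nj", dS, K) * scale
    dK = np.einsum("njl,nj->nl", dS, Q) * scale
    return dQ, dK, dV


def dual_path_attention(Q, K, V, d_k: float = 1.0) -> np.ndarray:
    """Attention over the concatenated latent coordinates of one sample.

    Accepts a single length-T vector triplet or an (n, T) batch; the diagonal
    blocks of the softmax matrix realise intra-modal attention, the
    off-diagonal blocks inter-modal attention.  Rows of the attention matrix
    sum to one, so a constant value vector is returned unchanged.
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if not (Q.shape == K.shape == V.shape):
        raise ValueError(f"Q, K, V shapes differ: {Q.shape}, {K.shape}, {V.shape}")
    single = Q.ndim == 1
    if single:
        Q, K, V = Q[None, :], K[None, :], V[None, :]
    out, _ = _attention_forward(Q, K, V, d_k)
    return out[0] if single else out


def attention_matrix(q, k, d_k: float = 1.0) -> np.ndarray:
    """The (T, T) row-stochastic attention matrix for one sample."""
    q = np.asarray(q, dtype=float)[None, :]
    k = np.asarray(k, dtype=float)[None, :]
    _, A = _attention_forward(q, k, q, d_k)
    return A[0]


# ---------------------------------------------------------------------------
# full forward / backward
# ---------------------------------------------------------------------------


def forward(
    params: EncoderParams,
    inputs: dict[str, np.ndarray],
    mode: str = "eval",
    update_running: bool = False,
):
    """Run the encoder on a batch.

    ``inputs`` maps modality name to an (n, d_in) matrix; only the modalities
    active in ``params.modality_set`` are read.  Returns ``(Y, cache)`` where
    ``Y`` is (n, latent_width) and ``cache`` holds every intermediate needed
    by :func:`backward` (train mode only).
    """
    cfg = params.config
    mods = cfg.modalities(params.modality_set)
    arrs = params.arrays
    n = None
    X_by_mod = {}
    for mod, d_in, _ in mods:
        if mod not in inputs or inputs[mod] is None:
            raise ValueError(f"modality {mod!r} required but not supplied")
        X = np.asarray(inputs[mod], dtype=float)
        if X.ndim != 2 or X.shape[1] != d_in:
            raise ValueError(
                f"{mod}: expected (n, {d_in}) input, got {X.shape}"
            )
        if n is None:
            n = X.shape[0]
        elif X.shape[0] != n:
            raise ValueError("modalities disagree on batch size")
        X_by_mod[mod] = X
    if mode not in ("train", "eval"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "train" and n < 2:
        raise ValueError("train-mode encoding needs batch size >= 2")

    mom, eps = cfg.bn_momentum, cfg.bn_eps
    cache = {"inputs": X_by_mod, "heads": [], "mode": mode}
    head_outputs = []
    for h in range(cfg.n_heads):
        role_vecs = {}
        role_caches = {}
        for role in _ROLES:
            segs, seg_caches = [], []
            for mod, _, _ in mods:
                p = f"head{h}.{mod}.{role}"
                Z = X_by_mod[mod] @ arrs[f"{p}.W"] + arrs[f"{p}.b"]
                if mode == "train":
                    out, bn_cache = _bn_train(Z, arrs[f"{p}.gamma"],
                                              arrs[f"{p}.beta"], eps)
                    if update_running:
                        _, _, mu, var = bn_cache
                        arrs[f"{p}.mean"] = (1 - mom) * arrs[f"{p}.mean"] + mom * mu
                        arrs[f"{p}.var"] = (1 - mom) * arrs[f"{p}.var"] + mom * var
                else:
                    out, bn_cache = _bn_eval(Z, arrs[f"{p}.gamma"],
                                             arrs[f"{p}.beta"],
                                             arrs[f"{p}.mean"],
                                             arrs[f"{p}.var"], eps)
                segs.append(out)
                seg_caches.append((p, bn_cache))
            role_vecs[role] = np.concatenate(segs, axis=1)
            role_caches[role] = seg_caches
        out_h, A = _attention_forward(role_vecs["q"], role_vecs["k"],
                                      role_vecs["v"], cfg.d_k)
        head_outputs.append(out_h)
        cache["heads"].append({"roles": role_vecs, "role_caches": role_caches,
                               "A": A})
    H = np.mean(head_outputs, axis=0)
    if mode == "train":
        Y, out_cache = _bn_train(H, arrs["out.gamma"], arrs["out.beta"], eps)
        if update_running:
            _, _, mu, var = out_cache
            arrs["out.mean"] = (1 - mom) * arrs["out.mean"] + mom * mu
            arrs["out.var"] = (1 - mom) * arrs["out.var"] + mom * var
    else:
        Y, out_cache = _bn_eval(H, arrs["out.gamma"], arrs["out.beta"],
                                arrs["out.mean"], arrs["out.var"], eps)
    cache["out_cache"] = out_cache
    cache["H"] = H
    return Y, cache


def backward(params: EncoderParams, cache, dY: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. every trainable array.

    ``cache`` must come from a train-mode :func:`forward` call on the same
    parameters.
    """
    if cache["mode"] != "train":
        raise ValueError("backward requires a train-mode forward cache")
    cfg = params.config
    mods = cfg.modalities(params.modality_set)
    arrs = params.arrays
    grads = {k: np.zeros_like(arrs[k]) for k in params.trainable_keys()}

    dH, dg, db = _bn_train_backward(dY, cache["out_cache"], arrs["out.gamma"])
    grads["out.gamma"] += dg
    grads["out.beta"] += db

    n_heads = cfg.n_heads
    for h in range(n_heads):
        hc = cache["heads"][h]
        dout_h = dH / n_heads
        dQ, dK, dV = _attention_backward(
            dout_h, hc["roles"]["q"], hc["roles"]["k"], hc["roles"]["v"],
            hc["A"], cfg.d_k
        )
        for role, dcat in zip(_ROLES, (dQ, dK, dV)):
            col = 0
            for (p, bn_cache), (mod, _, d_out) in zip(
                hc["role_caches"][role], mods
            ):
                dseg = dcat[:, col : col + d_out]
                col += d_out
                dZ, dgamma, dbeta = _bn_train_backward(
                    dseg, bn_cache, arrs[f"{p}.gamma"]
                )
                grads[f"{p}.gamma"] += dgamma
                grads[f"{p}.beta"] += dbeta
                X = cache["inputs"][mod]
                grads[f"{p}.W"] += X.T @ dZ
                grads[f"{p}.b"] += dZ.sum(axis=0)
    return grads


# ---------------------------------------------------------------------------
# public encoding entry points
# ---------------------------------------------------------------------------


def _check_finite(Y: np.ndarray, context: str) -> None:
    if not np.all(np.isfinite(Y)):
        bad = np.argwhere(~np.isfinite(Y))
        raise FloatingPointError(
            f"{context}: non-finite latent values at (row, col) "
            f"{bad[:5].tolist()} (showing up to 5 of {len(bad)})"
        )


def encode(
    X_ftir: np.ndarray | None,
    X_chem: np.ndarray | None,
    params: EncoderParams,
    mode: str = "eval",
    sample_ids: tuple[str, ...] | None = None,
    update_running: bool = False,
) -> LatentMatrix:
    """Encode a batch into latent vectors.

    Biochemical inputs are expected already standardized (per-indicator
    z-scores using training-set statistics); spectra are used as-is after
    replicate averaging.  In ``eval`` mode the result for a sample does not
    depend on its batch companions.
    """
    inputs = {"ftir": X_ftir, "chem": X_chem}
    Y, _ = forward(params, inputs, mode=mode, update_running=update_running)
    _check_finite(Y, "encode")
    return LatentMatrix(values=Y, sample_ids=sample_ids)


def unimodal_encode(
    X: np.ndarray,
    modality: str,
    params: EncoderParams,
    mode: str = "eval",
    sample_ids: tuple[str, ...] | None = None,
) -> LatentMatrix:
    """Encode a single modality through its own attention path.

    ``params`` must have been initialized (and trained) with the matching
    ``{modality}_only`` set; attention then runs over that modality's
    coordinates only and the latent width is d1 (FTIR) or d2 (chem).
    """
    if modality not in ("ftir", "chem"):
        raise ValueError(f"unknown modality {modality!r}")
    expected = f"{modality}_only"
    if params.modality_set != expected:
        raise ValueError(
            f"params were built for modality_set={params.modality_set!r}; "
            f"unimodal encoding of {modality!r} needs {expected!r}"
        )
    Y, _ = forward(params, {modality: X}, mode=mode)
    _check_finite(Y, "unimodal_encode")
    return LatentMatrix(values=Y, sample_ids=sample_ids)
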