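"""Evaluation protocol: modality ablation, batch-size sweep, visual exports.

The ablation repeats the whole pipeline over ``n_splits`` subject-level
splits at ratios 7:0.5:2.5 and ``n_inits`` encoder initializations per split
(default 10 x 5 = 50 trials per modality arm), for the fused ``both`` arm and
the two unimodal arms.  Every trial freezes the trained encoder, fits LDA on
the training latents and scores the held-out test latents; metrics are
aggregated as mean +- sd over trials.  Unimodal arms route through the same
encoder machinery by default (``unimodal_path="encoded"``); a ``"raw"`` path
feeding the untransformed features straight to LDA is also provided.

An AML-vs-healthy-only control is a cohort filter
(``cohort.filter_groups({"aml", "healthy"})``), not a separate pipeline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import (
    MetricReport,
    aggregate_metrics,
    compute_metrics,
    confusion_from_labels,
    fit_lda,
    pca_embed,
    predict,
)
from .data_model import Cohort, grouped_split
from .encoder import EncoderConfig, LatentMatrix, encode, unimodal_encode
from .trainer import TrainConfig, TrainState, train

__all__ = [
    "AblationPlan",
    "SweepPlan",
    "AblationResult",
    "SweepResult",
    "derive_seeds",
    "run_trial",
    "run_ablation",
    "batch_size_sweep",
    "save_trial_latents",
    "export_visualizations",
]

MODALITY_SETS = ("both", "ftir_only", "chem_only")
_PARTS = ("train", "val", "test")


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """n reproducible sub-seeds (< 2^31) from one base seed."""
    state = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


@dataclass(frozen=True)
class AblationPlan:
    """Repeated-split, repeated-init evaluation plan (default 50 trials)."""

    modality_sets: tuple[str, ...] = MODALITY_SETS
    n_splits: int = 10
    n_inits: int = 5
    ratios: tuple[float, float, float] = (0.7, 0.05, 0.25)
    base_seed: int = 0
    unimodal_path: str = "encoded"

    def __post_init__(self) -> None:
        if self.n_splits < 1 or self.n_inits < 1:
            raise ValueError("n_splits and n_inits must be >= 1")
        for m in self.modality_sets:
            if m not in MODALITY_SETS:
                raise ValueError(f"unknown modality set {m!r}")
        if self.unimodal_path not in ("encoded", "raw"):
            raise ValueError("unimodal_path must be 'encoded' or 'raw'")

    @property
    def n_trials(self) -> int:
        return self.n_splits * self.n_inits


@dataclass(frozen=True)
class SweepPlan:
    """Batch sizes to sweep (strictly increasing), at reduced trial count."""

    batch_sizes: tuple[int, ...]
    modality_set: str = "both"
    n_splits: int = 2
    n_inits: int = 1
    ratios: tuple[float, float, float] = (0.7, 0.05, 0.25)
    base_seed: int = 0

    def __post_init__(self) -> None:
        bs = self.batch_sizes
        if not bs or any(b2 <= b1 for b1, b2 in zip(bs, bs[1:])):
            raise ValueError("batch_sizes must be non-empty, strictly increasing")

    @classmethod
    def default_for(cls, n_train_samples: int, **kw) -> "SweepPlan":
        """Increments of 50 up to the training-sample count."""
        top = (n_train_samples // 50) * 50
        if top < 50:
            raise ValueError("too few training samples for a 50-step sweep")
        return cls(batch_sizes=tuple(range(50, top + 1, 50)), **kw)


@dataclass
class AblationResult:
    per_trial: pd.DataFrame
    reports: dict[str, MetricReport]
    failures: list[dict] = field(default_factory=list)


@dataclass
class SweepResult:
    table: pd.DataFrame
    selected_batch_size: int


# ---------------------------------------------------------------------------
# single trial
# ---------------------------------------------------------------------------


def _encode_partition(
    part: Cohort, state: TrainState, modality_set: str
) -> tuple[LatentMatrix, np.ndarray]:
    X_f, X_c, y = part.features()
    X_c = state.chem_scaler.transform(X_c)
    ids = tuple(s.sample_id for s in part.samples)
    if modality_set == "both":
        lat = encode(X_f, X_c, state.params, mode="eval", sample_ids=ids)
    elif modality_set == "ftir_only":
        lat = unimodal_encode(X_f, "ftir", state.params, sample_ids=ids)
    else:
        lat = unimodal_encode(X_c, "chem", state.params, sample_ids=ids)
    return lat, y


def _raw_features(part: Cohort, scaler, modality_set: str):
    X_f, X_c, y = part.features()
    X_c = scaler.transform(X_c)
    if modality_set == "ftir_only":
        return X_f, y
    if modality_set == "chem_only":
        return X_c, y
    return np.hstack([X_f, X_c]), y


def _assert_no_leakage(split_cohort: Cohort) -> None:
    split = split_cohort.split
    parts = {p: {s for s, v in split.items() if v == p} for p in _PARTS}
    if (parts["train"] & parts["test"]) or (parts["train"] & parts["val"]) \
            or (parts["val"] & parts["test"]):
        raise AssertionError("subject leakage across split partitions")


def run_trial(
    split_cohort: Cohort,
    modality_set: str,
    enc_config: EncoderConfig,
    train_config: TrainConfig,
    unimodal_path: str = "encoded",
    shrinkage: float | str = "auto",
) -> tuple[MetricReport, dict, TrainState | None]:
    """Train (or bypass, on the raw path), fit LDA, score the test split."""
    _assert_no_leakage(split_cohort)
    if modality_set != "both" and unimodal_path == "raw":
        from .trainer import Standardizer

        tr = split_cohort.partition("train")
        te = split_cohort.partition("test")
        scaler = Standardizer.fit(tr.features()[1])
        X_tr, y_tr = _raw_features(tr, scaler, modality_set)
        X_te, y_te = _raw_features(te, scaler, modality_set)
        state = None
    else:
        state = train(split_cohort, enc_config, train_config, modality_set)
        lat_tr, y_tr = _encode_partition(
            split_cohort.partition("train"), state, modality_set
        )
        lat_te, y_te = _encode_partition(
            split_cohort.partition("test"), state, modality_set
        )
        X_tr, X_te = lat_tr, lat_te
    lda = fit_lda(X_tr, y_tr, shrinkage=shrinkage)
    counts = confusion_from_labels(y_te, predict(lda, X_te))
    report = compute_metrics(counts)
    counts_dict = {"TP": counts.TP, "TN": counts.TN,
                   "FP": counts.FP, "FN": counts.FN}
    return report, counts_dict, state


# ---------------------------------------------------------------------------
# ablation protocol
# ---------------------------------------------------------------------------


def run_ablation(
    cohort: Cohort,
    plan: AblationPlan,
    enc_config: EncoderConfig,
    train_config: TrainConfig,
) -> AblationResult:
    """Run the full repeated-split, repeated-init modality ablation.

    All modality arms see the identical sequence of splits and trial seeds,
    so arm comparisons are paired.  Individual trial failures are recorded
    and skipped; more than 20% failures aborts the run.
    """
    labels = cohort.subject_labels()
    for cls in (0, 1):
        if sum(1 for v in labels.values() if v == cls) < 3:
            raise ValueError("need at least 3 subjects per class")
    seeds = derive_seeds(plan.base_seed, plan.n_splits * (1 + plan.n_inits))
    split_seeds = seeds[: plan.n_splits]
    trial_seeds = seeds[plan.n_splits :]
    rows = []
    failures: list[dict] = []
    attempted = 0
    for si, split_seed in enumerate(split_seeds):
        split_cohort = grouped_split(cohort, plan.ratios, seed=split_seed)
        for ii in range(plan.n_inits):
            trial_seed = trial_seeds[si * plan.n_inits + ii]
            e_cfg = dataclasses.replace(enc_config, seed=trial_seed)
            t_cfg = dataclasses.replace(train_config, seed=trial_seed)
            for mset in plan.modality_sets:
                attempted += 1
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        report, counts, _ = run_trial(
                            split_cohort, mset, e_cfg, t_cfg,
                            unimodal_path=plan.unimodal_path,
                        )
                except Exception as exc:  # recorded, run continues
                    failures.append(
                        {"split": si, "init": ii, "modality_set": mset,
                         "error": f"{type(exc).__name__}: {exc}"}
                    )
                    continue
                rows.append(
                    {"modality_set": mset, "split": si, "init": ii,
                     "split_seed": split_seed, "trial_seed": trial_seed,
                     **counts,
                     "accuracy": report.accuracy,
                     "sensitivity": report.sensitivity,
                     "specificity": report.specificity}
                )
    if attempted and len(failures) > 0.2 * attempted:
        raise RuntimeError(
            f"{len(failures)}/{attempted} trials failed; first: {failures[0]}"
        )
    per_trial = pd.DataFrame(rows)
    reports = {}
    for mset in plan.modality_sets:
        sub = per_trial[per_trial["modality_set"] == mset]
        trial_reports = [
            MetricReport(accuracy=r.accuracy, sensitivity=r.sensitivity,
                         specificity=r.specificity)
            for r in sub.itertuples()
        ]
        if trial_reports:
            reports[mset] = aggregate_metrics(trial_reports)
    return AblationResult(per_trial=per_trial, reports=reports,
                          failures=failures)


def batch_size_sweep(
    cohort: Cohort,
    plan: SweepPlan,
    enc_config: EncoderConfig,
    train_config: TrainConfig,
) -> SweepResult:
    """Mean test accuracy as a function of contrastive batch size.

    Each size runs the ablation protocol (single modality arm) at the plan's
    reduced trial count; the selected size is the accuracy argmax, ties going
    to the smaller size.
    """
    rows = []
    for bs in plan.batch_sizes:
        t_cfg = dataclasses.replace(train_config, batch_size=bs)
        a_plan = AblationPlan(
            modality_sets=(plan.modality_set,),
            n_splits=plan.n_splits,
            n_inits=plan.n_inits,
            ratios=plan.ratios,
            base_seed=plan.base_seed,
        )
        result = run_ablation(cohort, a_plan, enc_config, t_cfg)
        rep = result.reports[plan.modality_set]
        rows.append({"batch_size": bs, "mean_accuracy": rep.accuracy,
                     "sd_accuracy": rep.accuracy_sd,
                     "n_trials": rep.n_trials})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["mean_accuracy"].idxmax(), "batch_size"])
    # idxmax takes the first maximum; batch_sizes are increasing, so ties
    # already resolve to the smaller size
    return SweepResult(table=table, selected_batch_size=best)


# ---------------------------------------------------------------------------
# latent separation diagnostics
# ---------------------------------------------------------------------------


def separation_ratio(X, y) -> float:
    """Mean cross-class / mean within-class pairwise Euclidean distance.

    Values well above 1 indicate class-separated embeddings; raw clinical
    feature spaces typically sit near 1.
    """
    from .trainer import pairwise_distance_matrix

    X = X.values if isinstance(X, LatentMatrix) else np.asarray(X, float)
    y = np.asarray(y)
    D = pairwise_distance_matrix(X)
    iu, ju = np.triu_indices(len(y), k=1)
    same = y[iu] == y[ju]
    if same.all() or not same.any():
        raise ValueError("need both within- and cross-class pairs")
    d = D[iu, ju]
    return float(d[~same].mean() / d[same].mean())


def separation_benchmark(
    cohort: Cohort,
    enc_config: EncoderConfig,
    train_config: TrainConfig,
    seeds: list[int],
    partition: str = "val",
) -> pd.DataFrame:
    """Per seed: split, pre-train, and compare encoded vs. raw separation.

    The raw reference is the concatenation of the spectrum with the
    z-scored panel, i.e. exactly what the encoder consumes.  Returns one row
    per seed with ``ratio_encoded``, ``ratio_raw`` and ``improved``.
    """
    rows = []
    for seed in seeds:
        split_cohort = grouped_split(cohort, seed=seed)
        e_cfg = dataclasses.replace(enc_config, seed=seed)
        t_cfg = dataclasses.replace(train_config, seed=seed)
        state = train(split_cohort, e_cfg, t_cfg, "both")
        part = split_cohort.partition(partition)
        lat, y = _encode_partition(part, state, "both")
        X_raw, _ = _raw_features(part, state.chem_scaler, "both")
        r_enc = separation_ratio(lat, y)
        r_raw = separation_ratio(X_raw, y)
        rows.append({"seed": seed, "ratio_encoded": r_enc,
                     "ratio_raw": r_raw, "improved": r_enc > r_raw})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# visualization exports
# ---------------------------------------------------------------------------


def save_trial_latents(
    split_cohort: Cohort,
    state: TrainState,
    run_dir: str | Path,
    modality_set: str = "both",
) -> None:
    """Persist encoded latents and raw features per partition as CSVs."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    for part_name in _PARTS:
        part = split_cohort.partition(part_name)
        if not part.samples:
            continue
        lat, y = _encode_partition(part, state, modality_set)
        ids = [s.sample_id for s in part.samples]
        enc_df = pd.DataFrame(lat.values,
                              columns=[f"z{j}" for j in range(lat.n_features)])
        enc_df.insert(0, "sample_id", ids)
        enc_df.insert(1, "label", y)
        enc_df.to_csv(run_dir / f"latents_{part_name}.csv", index=False)
        X_raw, _ = _raw_features(part, state.chem_scaler, modality_set)
        raw_df = pd.DataFrame(X_raw,
                              columns=[f"x{j}" for j in range(X_raw.shape[1])])
        raw_df.insert(0, "sample_id", ids)
        raw_df.insert(1, "label", y)
        raw_df.to_csv(run_dir / f"raw_{part_name}.csv", index=False)


def export_visualizations(run_dir: str | Path) -> list[Path]:
    """Six 2-D PCA scatter plots (encoded and raw x train/val/test).

    Reads the latent/raw CSVs written by :func:`save_trial_latents`; a
    missing file raises an error naming the absent artifact.  Returns the
    written image paths; each plot's projection is also saved as a CSV with
    the same sample ordering as the source file.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    written = []
    for kind in ("latents", "raw"):
        for part in _PARTS:
            src = run_dir / f"{kind}_{part}.csv"
            if not src.exists():
                raise FileNotFoundError(f"missing saved artifact: {src}")
            df = pd.read_csv(src)
            X = df.drop(columns=["sample_id", "label"]).to_numpy(float)
            Z = pca_embed(X, n_components=2)
            out_df = pd.DataFrame(
                {"sample_id": df["sample_id"], "label": df["label"],
                 "pc1": Z[:, 0], "pc2": Z[:, 1]}
            )
            out_df.to_csv(run_dir / f"pca_{kind}_{part}.csv", index=False)
            fig, ax = plt.subplots(figsize=(4, 4))
            for lab, color, name in ((0, "tab:blue", "negative"),
                                     (1, "tab:red", "AML")):
                m = df["label"] == lab
                ax.scatter(Z[m, 0], Z[m, 1], s=14, c=color, label=name,
                           alpha=0.8)
            title = "encoded" if kind == "latents" else "raw"
            ax.set_title(f"{title} / {part}")
            ax.set_xlabel("PC1")
            ax.set_ylabel("PC2")
            ax.legend(frameon=False, fontsize=8)
            fig.tight_layout()
            path = run_dir / f"pca_{kind}_{part}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
    return written


def write_run_manifest(run_dir: str | Path, **entries) -> Path:
    """Write a replay manifest (config hash, seeds, package version)."""
    from . import __version__

    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    payload = {"spectrafuse_version": __version__, **entries}
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()
    payload["config_hash"] = digest
    path = run_dir / "manifest.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
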