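"""High-level Model/Results surface for the screening pipeline.

:class:`AmlScreeningModel` is built from a :class:`~.data_model.Cohort` and
its :meth:`~AmlScreeningModel.fit` runs the full two-stage procedure —
contrastive pre-training of the encoder followed by LDA on the frozen
latents — returning an :class:`AmlScreeningResults` with the test-set
metrics, confusion counts, training curves and a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import (
    ConfusionCounts,
    LdaModel,
    MetricReport,
    compute_metrics,
    confusion_from_labels,
    fit_lda,
    pca_embed,
    predict,
)
from .data_model import Cohort, grouped_split, read_cohort
from .encoder import EncoderConfig, LatentMatrix
from .experiments import _encode_partition, _raw_features
from .trainer import TrainConfig, TrainState, train

__all__ = ["AmlScreeningModel", "AmlScreeningResults"]


class AmlScreeningModel:
    """Two-stage AML screening model over paired FTIR + biochemistry data.

    Parameters
    ----------
    cohort : Cohort
        Paired samples with binary labels; a subject-level split is created
        at fit time if the cohort does not already carry one.
    encoder_config, train_config : optional
        Architecture and optimization settings; input widths are inferred
        from the cohort when ``encoder_config`` is omitted.
    modality_set : {"both", "ftir_only", "chem_only"}
        Which modalities the encoder consumes.
    """

    def __init__(
        self,
        cohort: Cohort,
        encoder_config: EncoderConfig | None = None,
        train_config: TrainConfig | None = None,
        modality_set: str = "both",
    ):
        if not cohort.samples:
            raise ValueError("cohort is empty")
        X_f, X_c, _ = cohort.features()
        if encoder_config is None:
            encoder_config = EncoderConfig(d_ftir=X_f.shape[1],
                                           d_chem=X_c.shape[1])
        else:
            if encoder_config.d_ftir != X_f.shape[1] or \
                    encoder_config.d_chem != X_c.shape[1]:
                raise ValueError(
                    f"encoder config expects ({encoder_config.d_ftir}, "
                    f"{encoder_config.d_chem}) inputs; cohort provides "
                    f"({X_f.shape[1]}, {X_c.shape[1]})"
                )
        self.cohort = cohort
        self.encoder_config = encoder_config
        self.train_config = train_config or TrainConfig()
        self.modality_set = modality_set

    @classmethod
    def from_csv(cls, directory: str | Path, **kwargs) -> "AmlScreeningModel":
        """Build from a spectra/panels/manifest CSV directory."""
        return cls(read_cohort(directory), **kwargs)

    def fit(
        self,
        split_seed: int = 0,
        ratios: tuple[float, float, float] = (0.7, 0.05, 0.25),
        shrinkage: float | str = "auto",
    ) -> "AmlScreeningResults":
        """Split (if needed), pre-train the encoder, fit and score the LDA."""
        cohort = self.cohort
        if cohort.split is None:
            cohort = grouped_split(cohort, ratios, seed=split_seed)
        state = train(cohort, self.encoder_config, self.train_config,
                      self.modality_set)
        lat_tr, y_tr = _encode_partition(cohort.partition("train"), state,
                                         self.modality_set)
        lda = fit_lda(lat_tr, y_tr, shrinkage=shrinkage)
        lat_te, y_te = _encode_partition(cohort.partition("test"), state,
                                         self.modality_set)
        counts = confusion_from_labels(y_te, predict(lda, lat_te))
        return AmlScreeningResults(
            model=self,
            split_cohort=cohort,
            train_state=state,
            lda=lda,
            confusion=counts,
            metrics=compute_metrics(counts),
        )


@dataclass
class AmlScreeningResults:
    """Fitted pipeline: encoder state, discriminant, and test-set scores."""

    model: AmlScreeningModel
    split_cohort: Cohort
    train_state: TrainState
    lda: LdaModel
    confusion: ConfusionCounts
    metrics: MetricReport
    _latent_cache: dict = field(default_factory=dict, repr=False)

    @property
    def loss_history(self) -> list[float]:
        return self.train_state.loss_history

    @property
    def val_loss_history(self) -> list[float]:
        return self.train_state.val_loss_history

    def latents(self, partition: str = "test") -> LatentMatrix:
        """Eval-mode latent vectors for one split partition (cached)."""
        if partition not in self._latent_cache:
            lat, y = _encode_partition(
                self.split_cohort.partition(partition), self.train_state,
                self.model.modality_set,
            )
            self._latent_cache[partition] = (lat, y)
        return self._latent_cache[partition][0]

    def predict(self, X_ftir: np.ndarray, X_chem: np.ndarray) -> np.ndarray:
        """Screen new samples: encode with the frozen encoder, score with LDA.

        ``X_chem`` is standardized with the training-set statistics stored in
        the fitted state.
        """
        from .encoder import encode, unimodal_encode

        mset = self.model.modality_set
        state = self.train_state
        if mset == "both":
            lat = encode(X_ftir, state.chem_scaler.transform(X_chem),
                         state.params)
        elif mset == "ftir_only":
            lat = unimodal_encode(X_ftir, "ftir", state.params)
        else:
            lat = unimodal_encode(state.chem_scaler.transform(X_chem),
                                  "chem", state.params)
        return predict(self.lda, lat)

    def pca_embedding(self, partition: str = "train",
                      source: str = "encoded") -> np.ndarray:
        """2-D PCA projection of encoded latents or raw inputs."""
        part = self.split_cohort.partition(partition)
        if source == "encoded":
            X = self.latents(partition).values
        elif source == "raw":
            X, _ = _raw_features(part, self.train_state.chem_scaler,
                                 self.model.modality_set)
        else:
            raise ValueError("source must be 'encoded' or 'raw'")
        return pca_embed(X, n_components=2)

    def summary(self) -> str:
        """Plain-text report in the spirit of a statsmodels results table."""
        m = self.model
        cohort = self.split_cohort
        counts = {p: len(cohort.partition(p)) for p in ("train", "val", "test")}
        c = self.confusion
        met = self.metrics

        def fmt(v):
            return "   n/a" if v is None else f"{v:6.3f}"

        lines = [
            "        AML screening: contrastive encoder + LDA",
            "=" * 58,
            f"modality set:      {m.modality_set:<12}  latent width: "
            f"{self.train_state.params.latent_width}",
            f"samples (tr/va/te): {counts['train']}/{counts['val']}/"
            f"{counts['test']}    subjects: {len(cohort.subject_ids())}",
            f"epochs: {len(self.loss_history):<6} final train loss: "
            f"{self.loss_history[-1]:.5f}  final lr: "
            f"{self.train_state.current_lr:.2e}",
            "-" * 58,
            "test confusion      predicted +   predicted -",
            f"  actual +           {c.TP:8d}    {c.FN:10d}",
            f"  actual -           {c.FP:8d}    {c.TN:10d}",
            "-" * 58,
            f"accuracy:    {fmt(met.accuracy)}",
            f"sensitivity: {fmt(met.sensitivity)}",
            f"specificity: {fmt(met.specificity)}",
            "=" * 58,
        ]
        return "\n".join(lines)
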