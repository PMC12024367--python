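"""Synthetic serum cohort generator: paired FTIR spectra and biochemistry.

No clinical data are distributed with this package, so every downstream stage
is exercised on a statistically controlled stand-in cohort.  The generator
emulates the structure of a serum-screening study:

* a default cohort of 36 AML subjects, 24 other-disease subjects
  (hyperuricemia / gout / rheumatoid arthritis) and 24 healthy subjects;
* spectra built from Gaussian vibrational bands (amide I/II, CH stretch,
  carbohydrate region, ...) whose amplitudes differ multiplicatively between
  the positive and negative class, plus a random low-order polynomial
  baseline and white replicate noise, averaged over >=5 replicates;
* a 36-indicator biochemical panel with large class shifts in albumin,
  total protein and lactate dehydrogenase and near-null shifts in potassium
  and uric acid, with the other-disease subgroup carrying its own small
  shifts (urate elevation, inflammation markers) so the negative class is
  heterogeneous.

Absorbance is NOT clipped at zero: white noise and baseline excursions may
produce slightly negative values, exactly as baseline-subtracted instrument
output can.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .data_model import (
    BiochemPanel,
    Cohort,
    LabeledSample,
    SpectrumRecord,
    WavenumberGrid,
    write_manifest,
    write_panels_table,
    write_spectra_table,
)

__all__ = [
    "BandSpec",
    "IndicatorSpec",
    "CohortConfig",
    "default_config",
    "default_bands",
    "default_indicators",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band.

    ``class_effect`` multiplies the amplitude for positive-class subjects;
    values below 1 model bands that are weaker in disease.
    """

    center: float
    width: float
    amplitude: float
    class_effect: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be non-negative")
        if self.class_effect <= 0:
            raise ValueError("class_effect must be positive")


@dataclass(frozen=True)
class IndicatorSpec:
    """One biochemical indicator's population model.

    ``class_shift`` (and ``other_shift`` for the non-leukemia disease
    subgroup) are signed multiples of ``neg_sd`` added to the healthy mean.
    ``distribution`` is ``normal`` or ``lognormal``; the lognormal option is
    parameterised so that its mean and sd match the requested moments.
    """

    name: str
    neg_mean: float
    neg_sd: float
    class_shift: float = 0.0
    other_shift: float = 0.0
    distribution: str = "normal"

    def __post_init__(self) -> None:
        if self.neg_sd <= 0:
            raise ValueError(f"{self.name}: neg_sd must be positive")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError(f"{self.name}: unknown distribution")


def default_bands(water_band: bool = False) -> list[BandSpec]:
    """Serum mid-IR band set for the stand-in spectra.

    Amplitudes are in absorbance units roughly matching dried-serum ATR
    spectra; the protein amide I/II bands dominate.  The broad ~3350 cm^-1
    O-H stretch is only injected when ``water_band`` is set (lyophilised serum
    largely lacks it).
    """
    bands = [
        BandSpec(center=1050.0, width=40.0, amplitude=0.12, class_effect=1.18),  # carbohydrate C-O
        BandSpec(center=1240.0, width=30.0, amplitude=0.08, class_effect=1.05),  # amide III / PO2-
        BandSpec(center=1400.0, width=25.0, amplitude=0.10, class_effect=0.97),
        BandSpec(center=1540.0, width=25.0, amplitude=0.55, class_effect=0.92),  # amide II
        BandSpec(center=1650.0, width=25.0, amplitude=0.80, class_effect=1.12),  # amide I
        BandSpec(center=2870.0, width=20.0, amplitude=0.06, class_effect=1.02),  # CH2 sym
        BandSpec(center=2930.0, width=22.0, amplitude=0.10, class_effect=1.08),  # CH2 asym
        BandSpec(center=2960.0, width=15.0, amplitude=0.07, class_effect=1.04),  # CH3
        BandSpec(center=3290.0, width=60.0, amplitude=0.25, class_effect=1.03),  # amide A N-H
    ]
    if water_band:
        bands.append(BandSpec(center=3350.0, width=200.0, amplitude=0.60))
    return bands


def default_indicators() -> list[IndicatorSpec]:
    """A 36-indicator clinical chemistry panel with class-dependent shifts.

    Means and dispersions are plausible adult reference values in the listed
    units.  The class structure mirrors what the screening setting describes:
    albumin, total protein and LDH carry large class effects
    (|shift| >= 1.5 sd) while the remaining indicators vary little, with
    potassium and uric acid near-null (|shift| <= 0.2 sd).  The other-disease
    subgroup elevates urate (hyperuricemia/gout) and inflammation-adjacent
    markers (rheumatoid arthritis), so the negative class is heterogeneous.
    """
    I = IndicatorSpec
    return [
        I("albumin_g_l", 45.0, 4.0, class_shift=-2.0),
        I("total_protein_g_l", 72.0, 5.0, class_shift=-1.6),
        I("ldh_u_l", 180.0, 40.0, class_shift=2.5, distribution="lognormal"),
        I("potassium_mmol_l", 4.2, 0.35, class_shift=0.1),
        I("uric_acid_umol_l", 320.0, 60.0, class_shift=0.15, other_shift=1.5,
          distribution="lognormal"),
        I("sodium_mmol_l", 140.0, 2.5, class_shift=-0.2),
        I("chloride_mmol_l", 103.0, 2.5, class_shift=-0.1),
        I("calcium_mmol_l", 2.35, 0.10, class_shift=-0.3),
        I("phosphate_mmol_l", 1.15, 0.15, class_shift=0.2),
        I("magnesium_mmol_l", 0.85, 0.08, class_shift=0.1),
        I("glucose_mmol_l", 5.2, 0.6, class_shift=0.2, distribution="lognormal"),
        I("urea_mmol_l", 5.5, 1.2, class_shift=0.3, distribution="lognormal"),
        I("creatinine_umol_l", 75.0, 14.0, class_shift=0.2, other_shift=0.4,
          distribution="lognormal"),
        I("alt_u_l", 22.0, 9.0, class_shift=0.3, distribution="lognormal"),
        I("ast_u_l", 24.0, 8.0, class_shift=0.4, distribution="lognormal"),
        I("alp_u_l", 70.0, 18.0, class_shift=0.3, distribution="lognormal"),
        I("ggt_u_l", 28.0, 14.0, class_shift=0.3, distribution="lognormal"),
        I("total_bilirubin_umol_l", 10.0, 3.5, class_shift=0.2,
          distribution="lognormal"),
        I("direct_bilirubin_umol_l", 3.0, 1.2, class_shift=0.2,
          distribution="lognormal"),
        I("globulin_g_l", 28.0, 4.0, class_shift=0.4),
        I("albumin_globulin_ratio", 1.6, 0.25, class_shift=-0.5),
        I("total_cholesterol_mmol_l", 4.8, 0.9, class_shift=-0.3),
        I("triglycerides_mmol_l", 1.3, 0.5, class_shift=0.3,
          distribution="lognormal"),
        I("hdl_mmol_l", 1.4, 0.3, class_shift=-0.3),
        I("ldl_mmol_l", 2.8, 0.7, class_shift=-0.2),
        I("crp_mg_l", 2.0, 1.5, class_shift=0.5, other_shift=0.8,
          distribution="lognormal"),
        I("ferritin_ug_l", 120.0, 60.0, class_shift=0.5,
          distribution="lognormal"),
        I("beta2_microglobulin_mg_l", 1.8, 0.4, class_shift=0.5,
          distribution="lognormal"),
        I("haptoglobin_g_l", 1.1, 0.3, class_shift=0.4),
        I("transferrin_g_l", 2.6, 0.35, class_shift=-0.4),
        I("iron_umol_l", 18.0, 5.0, class_shift=-0.3),
        I("bicarbonate_mmol_l", 25.0, 2.0, class_shift=-0.2),
        I("amylase_u_l", 60.0, 18.0, class_shift=0.0, distribution="lognormal"),
        I("lipase_u_l", 35.0, 12.0, class_shift=0.0, distribution="lognormal"),
        I("ck_u_l", 95.0, 35.0, class_shift=-0.1, distribution="lognormal"),
        I("cystatin_c_mg_l", 0.9, 0.15, class_shift=0.2, other_shift=0.3),
    ]


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort, reproducible from ``seed``."""

    n_positive_subjects: int = 36
    n_other_subjects: int = 24
    n_healthy_subjects: int = 24
    samples_per_subject: tuple[int, int] = (1, 3)
    replicates_per_sample: int = 5
    grid: WavenumberGrid = field(default_factory=WavenumberGrid)
    bands: list[BandSpec] = field(default_factory=default_bands)
    indicators: list[IndicatorSpec] = field(default_factory=default_indicators)
    #: subject-level relative variation of band amplitudes / indicator means
    subject_sd: float = 0.05
    #: white-noise sd per replicate, absorbance units
    noise_sd: float = 0.01
    #: amplitude scale of the random quadratic baseline, absorbance units
    baseline_drift: float = 0.02
    water_band: bool = False
    keep_replicates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_positive_subjects", "n_other_subjects",
                     "n_healthy_subjects", "replicates_per_sample"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.samples_per_subject
        if not (1 <= lo <= hi):
            raise ValueError("samples_per_subject must be an increasing range >= 1")
        names = [ind.name for ind in self.indicators]
        if len(names) != len(set(names)):
            raise ValueError("indicator names must be unique")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["grid"] = {"start": self.grid.start, "stop": self.grid.stop,
                     "step": self.grid.step}
        d["samples_per_subject"] = list(self.samples_per_subject)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["grid"] = WavenumberGrid(**d["grid"])
        d["samples_per_subject"] = tuple(d["samples_per_subject"])
        d["bands"] = [BandSpec(**b) for b in d["bands"]]
        d["indicators"] = [IndicatorSpec(**i) for i in d["indicators"]]
        return cls(**d)


def default_config(seed: int = 0, water_band: bool = False) -> CohortConfig:
    """The study-condition cohort: 36/24/24 subjects, 1801-point grid."""
    return CohortConfig(seed=seed, water_band=water_band,
                        bands=default_bands(water_band=water_band))


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _draw_indicator(
    spec: IndicatorSpec, group: str, subject_z: float, rng: np.random.Generator
) -> float:
    shift = {"aml": spec.class_shift, "other": spec.other_shift,
             "healthy": 0.0}[group]
    mean = spec.neg_mean + shift * spec.neg_sd
    z = subject_z + rng.standard_normal()
    if spec.distribution == "normal":
        return mean + z * spec.neg_sd
    if mean <= 0:
        raise ValueError(f"{spec.name}: lognormal needs a positive mean")
    mu, sigma = _lognormal_params(mean, spec.neg_sd)
    return float(np.exp(mu + sigma * z))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full cohort; bit-identical for identical configs.

    Per subject: multiplicative band factors ~ N(1, subject_sd) and a panel
    offset ~ N(0, subject_sd) in sd units, both shared across that subject's
    samples.  Per sample: a quadratic baseline with N(0, baseline_drift)
    coefficients, plus N(0, noise_sd) white noise per replicate; replicates
    are averaged into the sample spectrum.
    """
    rng = np.random.default_rng(config.seed)
    wn = config.grid.values()
    # precompute unit band shapes on the grid
    shapes = np.stack(
        [np.exp(-0.5 * ((wn - b.center) / b.width) ** 2) for b in config.bands]
    )
    base_amp = np.array([b.amplitude for b in config.bands])
    effect = np.array([b.class_effect for b in config.bands])
    x01 = np.linspace(-1.0, 1.0, config.grid.n_points)
    poly = np.stack([np.ones_like(x01), x01, x01**2])

    plan = (
        [("aml", i) for i in range(config.n_positive_subjects)]
        + [("other", i) for i in range(config.n_other_subjects)]
        + [("healthy", i) for i in range(config.n_healthy_subjects)]
    )
    lo, hi = config.samples_per_subject
    samples: list[LabeledSample] = []
    raw_reps: list[SpectrumRecord] = []
    names = tuple(ind.name for ind in config.indicators)
    for group, idx in plan:
        subject_id = f"{group}{idx:03d}"
        label = int(group == "aml")
        band_factors = 1.0 + config.subject_sd * rng.standard_normal(len(config.bands))
        panel_z = config.subject_sd * rng.standard_normal(len(config.indicators))
        amps = base_amp * band_factors
        if label:
            amps = amps * effect
        n_samples = int(rng.integers(lo, hi + 1))
        for s in range(n_samples):
            sample_id = f"{subject_id}_s{s}"
            clean = amps @ shapes
            coeffs = config.baseline_drift * rng.standard_normal(3)
            clean = clean + coeffs @ poly
            reps = clean + config.noise_sd * rng.standard_normal(
                (config.replicates_per_sample, config.grid.n_points)
            )
            if config.keep_replicates:
                for r in range(config.replicates_per_sample):
                    raw_reps.append(
                        SpectrumRecord(sample_id, subject_id, reps[r],
                                       config.grid, replicate_index=r)
                    )
            spectrum = SpectrumRecord(
                sample_id, subject_id, reps.mean(axis=0), config.grid
            )
            values = np.array(
                [
                    _draw_indicator(ind, group, panel_z[k], rng)
                    for k, ind in enumerate(config.indicators)
                ]
            )
            panel = BiochemPanel(sample_id, subject_id, values, names)
            samples.append(
                LabeledSample(spectrum=spectrum, panel=panel, label=label,
                              subject_id=subject_id, group=group)
            )
    return Cohort(samples=samples, replicates=raw_reps)


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Emit spectra.csv / panels.csv / manifest.csv into ``directory``.

    If the cohort retained raw replicates, the replicate-level spectra (with a
    ``replicate`` column) are written; otherwise the averaged per-sample
    spectra are.
    """
    if not cohort.samples:
        raise ValueError("cohort is empty")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "spectra": directory / "spectra.csv",
        "panels": directory / "panels.csv",
        "manifest": directory / "manifest.csv",
    }
    spectra = cohort.replicates if cohort.replicates else [
        s.spectrum for s in cohort.samples
    ]
    write_spectra_table(spectra, paths["spectra"])
    write_panels_table([s.panel for s in cohort.samples], paths["panels"])
    write_manifest(cohort.subject_groups(), paths["manifest"])
    return paths
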