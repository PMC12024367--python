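"""Domain types and tabular I/O for paired serum FTIR / biochemistry cohorts.

The unit of analysis is a *sample* (one serum draw), identified by
``sample_id`` and owned by a *subject* (``subject_id``).  A subject may
contribute several samples taken at different time points, which is why every
train/validation/test split in this package is performed at the subject level:
no individual may appear on both sides of a split.

File dialect (fixed, comma-delimited UTF-8):

* spectra:  ``sample_id, subject_id[, replicate], <wavenumber columns>``
  with wavenumber headers as decimal strings on a uniform grid;
* panels:   ``sample_id, subject_id, <indicator columns>``;
* manifest: ``subject_id, class`` with class in ``{aml, other, healthy}``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberGrid",
    "SpectrumRecord",
    "BiochemPanel",
    "LabeledSample",
    "Cohort",
    "SpectraFormatError",
    "SplitError",
    "POSITIVE_GROUP",
    "GROUPS",
    "read_spectra_table",
    "read_panels_table",
    "read_manifest",
    "write_spectra_table",
    "write_panels_table",
    "write_manifest",
    "average_replicates",
    "harmonize_grid",
    "grouped_split",
]

#: Subject classes recognised in the manifest; ``aml`` is the positive
#: screening class, the other two are pooled into the negative class.
GROUPS = ("aml", "other", "healthy")
POSITIVE_GROUP = "aml"

_PARTITIONS = ("train", "val", "test")

# relative tolerance for declaring a wavenumber axis uniform
_GRID_RTOL = 1e-6


class SpectraFormatError(ValueError):
    """Raised when a spectra table violates the declared grid or dialect."""


class SplitError(ValueError):
    """Raised when a subject-level split cannot keep both classes everywhere."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform wavenumber axis in cm^-1, ``start`` to ``stop`` inclusive.

    The default instrument setting is 400-4000 cm^-1 at 2 cm^-1 resolution,
    which gives 1801 points.
    """

    start: float = 400.0
    stop: float = 4000.0
    step: float = 2.0

    def __post_init__(self) -> None:
        if not (self.step > 0):
            raise ValueError(f"step must be positive, got {self.step}")
        if not (self.start < self.stop):
            raise ValueError(
                f"start must be below stop, got [{self.start}, {self.stop}]"
            )

    @property
    def n_points(self) -> int:
        return int(math.floor((self.stop - self.start) / self.step)) + 1

    def values(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)

    @classmethod
    def from_values(cls, wavenumbers: Sequence[float]) -> "WavenumberGrid":
        """Infer a uniform grid from an explicit axis, validating spacing."""
        wn = np.asarray(wavenumbers, dtype=float)
        if wn.ndim != 1 or wn.size < 2:
            raise SpectraFormatError("need at least two wavenumber columns")
        steps = np.diff(wn)
        step = float(steps[0])
        if step <= 0 or not np.allclose(steps, step, rtol=_GRID_RTOL, atol=0.0):
            raise SpectraFormatError(
                "wavenumber headers are not uniformly increasing: "
                f"steps range [{steps.min():g}, {steps.max():g}]"
            )
        return cls(start=float(wn[0]), stop=float(wn[-1]), step=step)

    def matches(self, wavenumbers: Sequence[float]) -> bool:
        wn = np.asarray(wavenumbers, dtype=float)
        return wn.size == self.n_points and bool(
            np.allclose(wn, self.values(), rtol=_GRID_RTOL, atol=1e-9)
        )


@dataclass
class SpectrumRecord:
    """One absorbance spectrum on a declared grid.

    ``replicate_index`` is set while the record is a raw instrument replicate
    and ``None`` once replicates have been averaged.
    """

    sample_id: str
    subject_id: str
    absorbance: np.ndarray
    grid: WavenumberGrid
    replicate_index: int | None = None

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != (self.grid.n_points,):
            raise SpectraFormatError(
                f"sample {self.sample_id!r}: absorbance length "
                f"{self.absorbance.shape} does not match grid "
                f"({self.grid.n_points} points)"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError(f"sample {self.sample_id!r}: non-finite absorbance")


@dataclass
class BiochemPanel:
    """One sample's clinical biochemistry panel (heterogeneous units)."""

    sample_id: str
    subject_id: str
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(set(self.names)):
            raise ValueError("indicator names must be unique")
        if self.values.shape != (len(self.names),):
            raise ValueError(
                f"sample {self.sample_id!r}: {self.values.size} values for "
                f"{len(self.names)} indicator names"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"sample {self.sample_id!r}: non-finite indicator")


@dataclass
class LabeledSample:
    """Paired (replicate-averaged spectrum, panel) with a binary label.

    ``label`` is 1 for the positive screening class (AML) and 0 for the pooled
    negative class; ``group`` keeps the finer-grained origin
    (``aml``/``other``/``healthy``) so control analyses can filter on it.
    """

    spectrum: SpectrumRecord
    panel: BiochemPanel
    label: int
    subject_id: str
    group: str = "other"

    def __post_init__(self) -> None:
        if self.spectrum.sample_id != self.panel.sample_id:
            raise ValueError(
                f"spectrum/panel sample ids differ: "
                f"{self.spectrum.sample_id!r} vs {self.panel.sample_id!r}"
            )
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def sample_id(self) -> str:
        return self.spectrum.sample_id


@dataclass
class Cohort:
    """Aligned collection of labeled samples plus an optional subject split."""

    samples: list[LabeledSample]
    split: dict[str, str] | None = None
    #: raw replicate-level spectra retained by the generator, if any
    replicates: list[SpectrumRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.split is not None:
            known = self.subject_ids()
            for sid, part in self.split.items():
                if part not in _PARTITIONS:
                    raise ValueError(f"unknown partition {part!r}")
                if sid not in known:
                    raise ValueError(f"split names unknown subject {sid!r}")

    def __len__(self) -> int:
        return len(self.samples)

    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.subject_id, None)
        return list(seen)

    def subject_labels(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.samples:
            prev = out.setdefault(s.subject_id, s.label)
            if prev != s.label:
                raise ValueError(
                    f"subject {s.subject_id!r} carries inconsistent labels"
                )
        return out

    def subject_groups(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for s in self.samples:
            out.setdefault(s.subject_id, s.group)
        return out

    def features(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Stacked (X_ftir, X_chem, y) matrices in sample order."""
        X_f = np.stack([s.spectrum.absorbance for s in self.samples])
        X_c = np.stack([s.panel.values for s in self.samples])
        y = np.array([s.label for s in self.samples], dtype=int)
        return X_f, X_c, y

    def partition(self, name: str) -> "Cohort":
        """Sub-cohort of samples whose subject is assigned to ``name``."""
        if self.split is None:
            raise ValueError("cohort has no split; call grouped_split first")
        if name not in _PARTITIONS:
            raise ValueError(f"unknown partition {name!r}")
        keep = [s for s in self.samples if self.split.get(s.subject_id) == name]
        return Cohort(samples=keep)

    def filter_groups(self, groups: Iterable[str]) -> "Cohort":
        """Keep only samples whose subject class is in ``groups``.

        Used for the AML-vs-healthy-only negative control.  Any existing split
        is restricted to the surviving subjects.
        """
        keep_groups = set(groups)
        unknown = keep_groups - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups {sorted(unknown)}")
        keep = [s for s in self.samples if s.group in keep_groups]
        split = None
        if self.split is not None:
            subjects = {s.subject_id for s in keep}
            split = {k: v for k, v in self.split.items() if k in subjects}
        return Cohort(samples=keep, split=split)


# ---------------------------------------------------------------------------
# tabular readers / writers
# ---------------------------------------------------------------------------

_ID_COLS = ("sample_id", "subject_id")


def _numeric_block(df: pd.DataFrame, cols: Sequence[str], path: Path) -> np.ndarray:
    """Parse a block of columns as floats, naming the offending cell on error."""
    try:
        return df[list(cols)].to_numpy(dtype=float)
    except (TypeError, ValueError):
        for col in cols:
            parsed = pd.to_numeric(df[col], errors="coerce")
            bad = parsed.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SpectraFormatError(
                    f"{path}: non-numeric value {df[col].iloc[row]!r} in "
                    f"column {col!r}, data row {row}"
                ) from None
        raise


def read_spectra_table(
    path: str | Path, grid: WavenumberGrid | None = None
) -> list[SpectrumRecord]:
    """Read a wide spectra CSV into :class:`SpectrumRecord` objects.

    If ``grid`` is omitted it is inferred from the wavenumber headers, which
    must be uniformly spaced; if given, the headers must match it exactly.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={c: str for c in (*_ID_COLS, "replicate")},
                     float_precision="round_trip")
    for col in _ID_COLS:
        if col not in df.columns:
            raise SpectraFormatError(f"{path}: missing id column {col!r}")
    has_rep = "replicate" in df.columns
    wn_cols = [c for c in df.columns if c not in (*_ID_COLS, "replicate")]
    try:
        wn = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric wavenumber header: {exc}")
    inferred = WavenumberGrid.from_values(wn)
    if grid is None:
        grid = inferred
    elif not grid.matches(wn):
        raise SpectraFormatError(
            f"{path}: wavenumber headers ({inferred.start:g}..{inferred.stop:g} "
            f"step {inferred.step:g}) do not match declared grid "
            f"({grid.start:g}..{grid.stop:g} step {grid.step:g})"
        )
    if df.empty:
        return []
    values = _numeric_block(df, wn_cols, path)
    records = []
    for i in range(len(df)):
        rep = int(df["replicate"].iloc[i]) if has_rep else None
        records.append(
            SpectrumRecord(
                sample_id=str(df["sample_id"].iloc[i]),
                subject_id=str(df["subject_id"].iloc[i]),
                absorbance=values[i],
                grid=grid,
                replicate_index=rep,
            )
        )
    return records


def write_spectra_table(records: Sequence[SpectrumRecord], path: str | Path) -> None:
    path = Path(path)
    if not records:
        raise ValueError("no spectra to write")
    grid = records[0].grid
    has_rep = any(r.replicate_index is not None for r in records)
    cols: dict[str, object] = {
        "sample_id": [r.sample_id for r in records],
        "subject_id": [r.subject_id for r in records],
    }
    if has_rep:
        cols["replicate"] = [r.replicate_index for r in records]
    wn = grid.values()
    mat = np.stack([r.absorbance for r in records])
    df = pd.DataFrame(cols)
    spec = pd.DataFrame(mat, columns=[f"{v:g}" for v in wn])
    pd.concat([df, spec], axis=1).to_csv(path, index=False)


def read_panels_table(path: str | Path) -> list[BiochemPanel]:
    path = Path(path)
    df = pd.read_csv(path, dtype={c: str for c in _ID_COLS},
                     float_precision="round_trip")
    for col in _ID_COLS:
        if col not in df.columns:
            raise SpectraFormatError(f"{path}: missing id column {col!r}")
    names = tuple(c for c in df.columns if c not in _ID_COLS)
    if df.empty:
        return []
    values = _numeric_block(df, names, path)
    return [
        BiochemPanel(
            sample_id=str(df["sample_id"].iloc[i]),
            subject_id=str(df["subject_id"].iloc[i]),
            values=values[i],
            names=names,
        )
        for i in range(len(df))
    ]


def write_panels_table(panels: Sequence[BiochemPanel], path: str | Path) -> None:
    if not panels:
        raise ValueError("no panels to write")
    names = panels[0].names
    df = pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in panels],
            "subject_id": [p.subject_id for p in panels],
        }
    )
    vals = pd.DataFrame(np.stack([p.values for p in panels]), columns=list(names))
    pd.concat([df, vals], axis=1).to_csv(Path(path), index=False)


def read_manifest(path: str | Path) -> dict[str, str]:
    """Read ``subject_id -> class`` from a manifest CSV."""
    df = pd.read_csv(Path(path), dtype=str)
    for col in ("subject_id", "class"):
        if col not in df.columns:
            raise SpectraFormatError(f"{path}: missing manifest column {col!r}")
    out: dict[str, str] = {}
    for sid, cls in zip(df["subject_id"], df["class"]):
        if cls not in GROUPS:
            raise SpectraFormatError(f"{path}: unknown class {cls!r}")
        out[str(sid)] = str(cls)
    return out


def write_manifest(groups: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"subject_id": list(groups), "class": [groups[k] for k in groups]}
    ).to_csv(Path(path), index=False)


def assemble_cohort(
    spectra: Sequence[SpectrumRecord],
    panels: Sequence[BiochemPanel],
    manifest: Mapping[str, str],
) -> Cohort:
    """Join averaged spectra, panels and the subject manifest into a cohort."""
    averaged = average_replicates(list(spectra))
    panel_by_id = {p.sample_id: p for p in panels}
    samples = []
    for rec in averaged:
        if rec.sample_id not in panel_by_id:
            raise ValueError(f"sample {rec.sample_id!r} has no biochemical panel")
        group = manifest.get(rec.subject_id)
        if group is None:
            raise ValueError(f"subject {rec.subject_id!r} missing from manifest")
        samples.append(
            LabeledSample(
                spectrum=rec,
                panel=panel_by_id[rec.sample_id],
                label=int(group == POSITIVE_GROUP),
                subject_id=rec.subject_id,
                group=group,
            )
        )
    return Cohort(samples=samples)


def read_cohort(directory: str | Path) -> Cohort:
    """Read the three-file cohort layout produced by ``write_cohort``."""
    directory = Path(directory)
    spectra = read_spectra_table(directory / "spectra.csv")
    panels = read_panels_table(directory / "panels.csv")
    manifest = read_manifest(directory / "manifest.csv")
    return assemble_cohort(spectra, panels, manifest)


# ---------------------------------------------------------------------------
# replicate averaging and grid harmonization
# ---------------------------------------------------------------------------


def average_replicates(records: Sequence[SpectrumRecord]) -> list[SpectrumRecord]:
    """Collapse instrument replicates to one mean spectrum per sample.

    Groups by ``sample_id`` (order of first appearance preserved); the
    returned records carry no replicate index.  Averaging an already averaged
    list is a no-op.
    """
    groups: dict[str, list[SpectrumRecord]] = {}
    for rec in records:
        groups.setdefault(rec.sample_id, []).append(rec)
    out = []
    for sample_id, grp in groups.items():
        grid = grp[0].grid
        for rec in grp[1:]:
            if rec.grid != grid:
                raise SpectraFormatError(
                    f"sample {sample_id!r}: replicates on differing grids"
                )
        mean = np.mean([r.absorbance for r in grp], axis=0)
        out.append(
            SpectrumRecord(
                sample_id=sample_id,
                subject_id=grp[0].subject_id,
                absorbance=mean,
                grid=grid,
                replicate_index=None,
            )
        )
    return out


def harmonize_grid(record: SpectrumRecord, target: WavenumberGrid) -> SpectrumRecord:
    """Resample a spectrum onto ``target`` by linear interpolation.

    Extrapolation is refused: the target range must lie within the source
    range.
    """
    src = record.grid
    if target.start < src.start - 1e-9 or target.stop > src.stop + 1e-9:
        raise ValueError(
            f"target range [{target.start:g}, {target.stop:g}] extends beyond "
            f"source range [{src.start:g}, {src.stop:g}]; refusing to extrapolate"
        )
    new = np.interp(target.values(), src.values(), record.absorbance)
    return replace(record, absorbance=new, grid=target)


# ---------------------------------------------------------------------------
# subject-level splitting
# ---------------------------------------------------------------------------


def _apportion(n: int, ratios: np.ndarray) -> list[int]:
    """Largest-remainder apportionment of n units into len(ratios) parts.

    Ties in fractional remainder are broken in partition order
    (train before val before test).
    """
    exact = ratios * n
    floors = np.floor(exact).astype(int)
    leftover = n - int(floors.sum())
    order = sorted(range(len(ratios)), key=lambda i: (-(exact[i] - floors[i]), i))
    for i in order[:leftover]:
        floors[i] += 1
    return floors.tolist()


def grouped_split(
    cohort: Cohort,
    ratios: tuple[float, float, float] = (0.7, 0.05, 0.25),
    seed: int = 0,
) -> Cohort:
    """Assign subjects (not samples) to train/val/test, stratified by class.

    Subjects are permuted by a seeded RNG and partitioned independently within
    the positive and negative subject pools, so small validation/test sets
    still contain both classes.  Counts follow largest-remainder rounding per
    pool.  Returns a new cohort sharing the sample list, with ``split`` set.
    """
    r = np.asarray(ratios, dtype=float)
    if r.shape != (3,) or np.any(r <= 0):
        raise ValueError("ratios must be three positive numbers")
    r = r / r.sum()
    labels = cohort.subject_labels()
    if len(labels) < 3:
        raise SplitError("need at least 3 subjects to split")
    rng = np.random.default_rng(seed)
    split: dict[str, str] = {}
    for cls in (1, 0):
        pool = [sid for sid in cohort.subject_ids() if labels[sid] == cls]
        if not pool:
            raise SplitError(f"no subjects with label {cls}")
        pool = [pool[i] for i in rng.permutation(len(pool))]
        counts = _apportion(len(pool), r)
        if min(counts) == 0:
            raise SplitError(
                f"class {cls} pool of {len(pool)} subjects leaves an empty "
                f"partition at ratios {tuple(r)}; use a larger cohort or "
                "different ratios"
            )
        idx = 0
        for part, k in zip(_PARTITIONS, counts):
            for sid in pool[idx : idx + k]:
                split[sid] = part
            idx += k
    return Cohort(samples=cohort.samples, split=split, replicates=cohort.replicates)
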