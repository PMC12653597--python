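"""Cohort loading, marker-panel construction and missingness filtering.

A cohort pairs longitudinal chest-radiograph references with routine blood
measurements for silicosis patients, labelled simple silicosis (SS = 0) or
progressive massive fibrosis (PMF = 1).  The blood side of each sample is a
21-marker candidate panel: leukocyte and platelet counts, the five-part
differential as absolute counts and percentages, six derived systemic
inflammation indices (NLR, PLR, LMR, SII, SIRI, AISI), and three enzymes
(ALP, LDH, ACE).  Markers with cohort-wide missingness at or above a
threshold (default 20%) are excluded before modelling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MEASURED_MARKERS",
    "DERIVED_MARKERS",
    "PANEL_MARKERS",
    "LABEL_MAP",
    "CellCounts",
    "InflammationIndices",
    "MarkerPanel",
    "Sample",
    "Cohort",
    "compute_inflammation_indices",
    "build_marker_panel",
    "filter_markers_by_missingness",
    "load_cohort",
    "write_manifest",
]

#: Measured quantities expected as manifest columns (missing cells allowed).
MEASURED_MARKERS: tuple[str, ...] = (
    "leukocytes",
    "platelets",
    "neutrophils_abs",
    "eosinophils_abs",
    "basophils_abs",
    "monocytes_abs",
    "lymphocytes_abs",
    "neutrophils_pct",
    "eosinophils_pct",
    "basophils_pct",
    "monocytes_pct",
    "lymphocytes_pct",
    "alp",
    "ldh",
    "ace",
)

#: Ratios derived from the absolute counts (standard clinical definitions).
DERIVED_MARKERS: tuple[str, ...] = ("nlr", "plr", "lmr", "sii", "siri", "aisi")

#: Fixed candidate-panel ordering shared by every sample of a cohort.
PANEL_MARKERS: tuple[str, ...] = (
    "leukocytes",
    "platelets",
    "neutrophils_abs",
    "eosinophils_abs",
    "basophils_abs",
    "monocytes_abs",
    "lymphocytes_abs",
    "neutrophils_pct",
    "eosinophils_pct",
    "basophils_pct",
    "monocytes_pct",
    "lymphocytes_pct",
    "nlr",
    "plr",
    "lmr",
    "sii",
    "siri",
    "aisi",
    "alp",
    "ldh",
    "ace",
)

PERCENT_MARKERS = frozenset(m for m in MEASURED_MARKERS if m.endswith("_pct"))

LABEL_MAP = {"SS": 0, "PMF": 1, "0": 0, "1": 1}


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class CellCounts:
    """Blood cell counts for one sample.

    Absolute counts are in 1e9 cells/L, percentages in percent of WBC.
    Missing values are represented as NaN (never silently zero).
    """

    leukocytes: float = math.nan
    platelets: float = math.nan
    neutrophils_abs: float = math.nan
    eosinophils_abs: float = math.nan
    basophils_abs: float = math.nan
    monocytes_abs: float = math.nan
    lymphocytes_abs: float = math.nan
    neutrophils_pct: float = math.nan
    eosinophils_pct: float = math.nan
    basophils_pct: float = math.nan
    monocytes_pct: float = math.nan
    lymphocytes_pct: float = math.nan

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if _is_missing(v):
                continue
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
            if name in PERCENT_MARKERS and v > 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")


@dataclass(frozen=True)
class InflammationIndices:
    """Derived systemic inflammation indices (dimensionless ratios).

    An index is NaN whenever an ingredient is missing or a denominator is
    zero; it is never infinite.
    """

    nlr: float
    plr: float
    lmr: float
    sii: float
    siri: float
    aisi: float


def _ratio(numerator_parts: Sequence[float], denominator: float) -> float:
    parts = list(numerator_parts) + [denominator]
    if any(_is_missing(p) for p in parts) or denominator == 0:
        return math.nan
    return math.prod(numerator_parts) / denominator


def compute_inflammation_indices(counts: CellCounts) -> InflammationIndices:
    """Compute NLR, PLR, LMR, SII, SIRI and AISI from absolute counts.

    NLR = N/L, PLR = P/L, LMR = L/M, SII = N*P/L, SIRI = N*M/L,
    AISI = N*M*P/L, with N, L, M the absolute neutrophil, lymphocyte and
    monocyte counts and P the platelet count.  Zero or missing denominators
    yield NaN.
    """
    n = counts.neutrophils_abs
    l = counts.lymphocytes_abs
    m = counts.monocytes_abs
    p = counts.platelets
    return InflammationIndices(
        nlr=_ratio([n], l),
        plr=_ratio([p], l),
        lmr=_ratio([l], m),
        sii=_ratio([n, p], l),
        siri=_ratio([n, m], l),
        aisi=_ratio([n, m, p], l),
    )


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered biomarker vector with an explicit missingness mask."""

    marker_names: tuple[str, ...]
    values: np.ndarray  # float array, NaN where missing

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.marker_names) != self.values.shape[0]:
            raise ValueError("marker_names and values must have equal length")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class Sample:
    """One paired (radiograph, blood panel) observation of a patient."""

    patient_id: str
    sample_index: int
    image_ref: str | None
    raw: dict[str, float]  # measured quantities, NaN where missing
    panel: MarkerPanel | None
    label: int

    def __post_init__(self):
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 (SS) or 1 (PMF), got {self.label}")


@dataclass
class Cohort:
    """A patient-grouped collection of samples; the unit of all splitting."""

    samples: list[Sample]

    def __post_init__(self):
        seen: set[tuple[str, int]] = set()
        for s in self.samples:
            key = (s.patient_id, s.sample_index)
            if key in seen:
                raise ValueError(f"duplicate (patient_id, sample_index): {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def patients(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            out.setdefault(s.patient_id, []).append(i)
        return out

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    @property
    def patient_ids(self) -> np.ndarray:
        return np.array([s.patient_id for s in self.samples], dtype=object)

    @property
    def marker_names(self) -> tuple[str, ...]:
        if not self.samples or self.samples[0].panel is None:
            raise ValueError("marker panels not built")
        return self.samples[0].panel.marker_names

    def panel_matrix(self) -> np.ndarray:
        """n_samples x n_markers matrix with NaN for missing values."""
        names = self.marker_names
        for s in self.samples:
            if s.panel is None or s.panel.marker_names != names:
                raise ValueError("inconsistent marker panels across samples")
        return np.vstack([s.panel.values for s in self.samples])

    def class_counts(self) -> tuple[int, int]:
        y = self.labels
        return int((y == 0).sum()), int((y == 1).sum())


def _panel_from_raw(raw: Mapping[str, float]) -> MarkerPanel:
    counts = CellCounts(**{k: raw.get(k, math.nan) for k in CellCounts.__dataclass_fields__})
    idx = compute_inflammation_indices(counts)
    values = []
    for name in PANEL_MARKERS:
        if name in DERIVED_MARKERS:
            values.append(getattr(idx, name))
        else:
            v = raw.get(name, math.nan)
            values.append(math.nan if _is_missing(v) else float(v))
    return MarkerPanel(PANEL_MARKERS, np.array(values))


def build_marker_panel(cohort: Cohort) -> Cohort:
    """(Re)build every sample's 21-marker candidate panel from raw values.

    The panel order is fixed (:data:`PANEL_MARKERS`) and identical across
    samples; derived ratios propagate missingness from their ingredients.
    """
    samples = [replace(s, panel=_panel_from_raw(s.raw)) for s in cohort.samples]
    return Cohort(samples)


def filter_markers_by_missingness(
    cohort: Cohort, threshold: float = 0.20
) -> tuple[Cohort, list[str]]:
    """Drop markers whose cohort-wide missing fraction is >= ``threshold``.

    The boundary is inclusive: a marker missing in exactly 20% of samples is
    removed at the default threshold.  Remaining order is preserved.
    Returns the filtered cohort and the removed marker names.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    matrix = cohort.panel_matrix()
    names = cohort.marker_names
    frac = np.isnan(matrix).mean(axis=0)
    keep = frac < threshold
    removed = [n for n, k in zip(names, keep) if not k]
    if not keep.any():
        raise ValueError("all markers exceed the missingness threshold; no biomarker modality left")
    kept_names = tuple(n for n, k in zip(names, keep) if k)
    samples = [
        replace(s, panel=MarkerPanel(kept_names, s.panel.values[keep]))
        for s in cohort.samples
    ]
    return Cohort(samples), removed


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------

_BASE_COLUMNS = ("patient_id", "sample_index", "label", "image_path")


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def load_cohort(
    manifest_path: str | Path,
    image_root: str | Path | None = None,
    delimiter: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> Cohort:
    """Load and validate a cohort manifest (delimited text, header row).

    Required columns: ``patient_id``, ``label`` and the 15 measured marker
    columns (:data:`MEASURED_MARKERS`); ``sample_index`` and ``image_path``
    are optional (indices default to per-patient row order).  Labels may be
    the strings SS/PMF (case-insensitive) or 0/1.  Derived-ratio columns, if
    present, are ignored and recomputed.  Column names can be remapped via
    ``column_map`` (canonical name -> manifest name).

    Unresolvable image paths produce a warning and an absent flag so the
    biomarker modality can still run; unknown labels or duplicate
    (patient_id, sample_index) pairs are rejected with the row number.
    """
    manifest_path = Path(manifest_path)
    sep = delimiter or _sniff_delimiter(manifest_path)
    df = pd.read_csv(manifest_path, sep=sep)
    colmap = dict(column_map or {})
    def col(name: str) -> str:
        return colmap.get(name, name)

    for required in ("patient_id", "label", *MEASURED_MARKERS):
        if col(required) not in df.columns:
            raise ValueError(f"manifest is missing required column {col(required)!r}")

    per_patient_counter: dict[str, int] = {}
    samples: list[Sample] = []
    for row_no, (_, row) in enumerate(df.iterrows(), start=2):  # 1-based + header
        pid = str(row[col("patient_id")])
        raw_label = row[col("label")]
        key = str(raw_label).strip().upper()
        if key not in LABEL_MAP:
            raise ValueError(f"row {row_no}: unknown label {raw_label!r} (expected SS/PMF or 0/1)")
        label = LABEL_MAP[key]

        if col("sample_index") in df.columns and not pd.isna(row[col("sample_index")]):
            sample_index = int(row[col("sample_index")])
        else:
            sample_index = per_patient_counter.get(pid, 0)
        per_patient_counter[pid] = sample_index + 1

        image_ref: str | None = None
        if col("image_path") in df.columns and not pd.isna(row[col("image_path")]):
            image_ref = str(row[col("image_path")])
            if image_root is not None:
                resolved = Path(image_root) / image_ref
                if not resolved.exists():
                    warnings.warn(
                        f"row {row_no}: image {resolved} not found; flagged absent",
                        stacklevel=2,
                    )
                    image_ref = None

        raw: dict[str, float] = {}
        for m in MEASURED_MARKERS:
            v = row[col(m)]
            raw[m] = math.nan if pd.isna(v) else float(v)
        try:
            samples.append(
                Sample(
                    patient_id=pid,
                    sample_index=sample_index,
                    image_ref=image_ref,
                    raw=raw,
                    panel=None,
                    label=label,
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {row_no}: {exc}") from exc

    return build_marker_panel(Cohort(samples))


def write_manifest(cohort: Cohort, path: str | Path, delimiter: str = ",") -> None:
    """Serialize a cohort to the manifest format :func:`load_cohort` reads."""
    rows = []
    for s in cohort.samples:
        row = {
            "patient_id": s.patient_id,
            "sample_index": s.sample_index,
            "label": "SS" if s.label == 0 else "PMF",
            "image_path": s.image_ref if s.image_ref is not None else "",
        }
        for m in MEASURED_MARKERS:
            v = s.raw.get(m, math.nan)
            row[m] = "" if _is_missing(v) else v
        rows.append(row)
    pd.DataFrame(rows, columns=list(_BASE_COLUMNS) + list(MEASURED_MARKERS)).to_csv(
        path, sep=delimiter, index=False
    )
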