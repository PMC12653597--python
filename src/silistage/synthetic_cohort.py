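"""Synthetic silicosis cohorts with tunable per-modality discriminability.

The study data this package is built for (94 engineered-stone silicosis
patients, 341 longitudinal paired radiograph/blood samples, 187 SS and 154
PMF) are not publicly deposited, so every stage of the pipeline is
exercised on generated cohorts that emulate that shape:

* patients carry 1-10 longitudinal samples (truncated geometric, mean
  ~3.6, so 94 patients yield ~341 samples);
* an SS patient may progress to PMF mid-series (PMF never reverts),
  producing the mixed-label patients that stress stratified grouping;
* blood counts are log-normal around clinically plausible medians, with
  PMF shifting neutrophils, monocytes and platelets up and lymphocytes
  down — raising NLR/SII/SIRI/AISI with disease stage — scaled by
  ``biomarker_effect``; a per-patient random inflammation effect induces
  within-patient correlation;
* image features are Gaussian with a class-mean shift of size
  ``image_effect`` along a planted unit direction, plus a per-patient
  offset; they stand in for frozen-backbone embeddings;
* ALP/LDH/ACE missingness defaults put those three markers at or above the
  20% exclusion threshold.

Labels, image features and biomarkers are conditionally independent given
the planted class/severity, so with orthogonal per-modality signals a
decision-level ensemble is guaranteed an expected gain over either
modality alone — which is what makes fusion claims testable here.

Marker medians are synthetic conventions (round plausible values), not
estimates of any real cohort; no radiographic texture or real hematology
covariance is simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .cohort_io import Cohort, Sample, build_marker_panel

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "complementary_config",
    "generate_cohort",
    "make_reference_fixture",
    "generate_fixture_images",
]

#: Log-space medians for the measured counts (SS class), synthetic conventions.
_SS_MEDIANS = {
    "neutrophils_abs": 4.2,   # 1e9/L
    "lymphocytes_abs": 2.0,
    "monocytes_abs": 0.5,
    "eosinophils_abs": 0.2,
    "basophils_abs": 0.05,
    "platelets": 250.0,
    "alp": 80.0,              # U/L
    "ldh": 180.0,
    "ace": 40.0,
}

_SIGMA_LOG = 0.25

#: Direction of the PMF shift per marker, in units of biomarker_effect * sigma.
_PMF_SHIFT = {
    "neutrophils_abs": 1.0,
    "platelets": 0.5,
    "monocytes_abs": 0.5,
    "lymphocytes_abs": -1.0,
}

#: Sign with which the per-patient inflammation effect enters each marker.
_PATIENT_SIGN = {
    "neutrophils_abs": 1.0,
    "platelets": 1.0,
    "monocytes_abs": 1.0,
    "lymphocytes_abs": -1.0,
}

_DIFFERENTIAL = (
    "neutrophils_abs",
    "eosinophils_abs",
    "basophils_abs",
    "monocytes_abs",
    "lymphocytes_abs",
)


@dataclass
class SimulationConfig:
    """Shape, effect-size and missingness knobs of the synthetic cohort.

    Defaults reproduce the emulated study shape in expectation: 94 patients
    with truncated-geometric series lengths (p = 0.26, range 1-10, mean
    ~3.66 -> ~344 samples) and an initial PMF probability of 0.42 which,
    together with a 0.15 mid-series SS->PMF progression chance, puts the
    expected PMF sample fraction at ~0.45 (154/341).  Effects are
    standardized mean shifts; ``patient_sd`` scales the per-patient random
    effect in both modalities.
    """

    n_patients: int = 94
    samples_geometric_p: float = 0.26
    max_samples_per_patient: int = 10
    initial_pmf_prob: float = 0.42
    progression_prob: float = 0.15
    image_effect: float = 1.0
    biomarker_effect: float = 0.6
    patient_sd: float = 0.3
    feature_dim: int = 64
    baseline_missing: float = 0.02
    enzyme_missing: dict[str, float] = field(
        default_factory=lambda: {"alp": 0.25, "ldh": 0.25, "ace": 0.30}
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        for name in ("samples_geometric_p", "initial_pmf_prob", "progression_prob",
                     "baseline_missing"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.image_effect, self.biomarker_effect, self.patient_sd) < 0:
            raise ValueError("effects and patient_sd must be nonnegative")
        if self.initial_pmf_prob > 0 and self.n_patients * self.initial_pmf_prob < 1e-9:
            raise ValueError("infeasible class balance")


@dataclass
class GroundTruth:
    """Planted generative state stored alongside every synthetic cohort."""

    features: np.ndarray                 # n_samples x feature_dim
    signal_direction: np.ndarray         # unit vector of the image class shift
    severities: np.ndarray               # per-sample latent severity
    patient_effects: dict[str, float]    # per-patient inflammation random effect
    config: SimulationConfig


def _missing_prob(cfg: SimulationConfig, marker: str) -> float:
    return cfg.enzyme_missing.get(marker, cfg.baseline_missing)


def _materialize(
    patients: list[tuple[str, list[int]]],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    impose_missingness: bool = True,
) -> tuple[list[Sample], GroundTruth]:
    """Draw raw markers and image features for fixed per-patient label series."""
    u = rng.standard_normal(cfg.feature_dim)
    u /= np.linalg.norm(u)

    samples: list[Sample] = []
    feats: list[np.ndarray] = []
    sevs: list[float] = []
    patient_effects: dict[str, float] = {}
    for pid, label_series in patients:
        a_p = float(rng.standard_normal())  # inflammation random effect (unit scale)
        v_p = rng.standard_normal(cfg.feature_dim) * cfg.patient_sd
        patient_effects[pid] = a_p
        for k, label in enumerate(label_series):
            raw: dict[str, float] = {}
            for m in ("neutrophils_abs", "lymphocytes_abs", "monocytes_abs",
                      "eosinophils_abs", "basophils_abs", "platelets"):
                z = (
                    cfg.biomarker_effect * _PMF_SHIFT.get(m, 0.0) * label
                    + cfg.patient_sd * _PATIENT_SIGN.get(m, 0.0) * a_p
                    + rng.standard_normal()
                )
                raw[m] = _SS_MEDIANS[m] * math.exp(_SIGMA_LOG * z)
            wbc = sum(raw[m] for m in _DIFFERENTIAL)
            raw["leukocytes"] = wbc
            for m in _DIFFERENTIAL:
                raw[m.replace("_abs", "_pct")] = raw[m] / wbc * 100.0
            for m in ("alp", "ldh", "ace"):
                raw[m] = _SS_MEDIANS[m] * math.exp(0.3 * rng.standard_normal())
            if impose_missingness:
                for m in list(raw):
                    if rng.random() < _missing_prob(cfg, m):
                        raw[m] = math.nan

            sev = label + 0.5 * a_p * cfg.patient_sd + 0.2 * rng.standard_normal()
            f = (
                cfg.image_effect * label * u
                + v_p
                + rng.standard_normal(cfg.feature_dim)
            )
            samples.append(
                Sample(
                    patient_id=pid,
                    sample_index=k,
                    image_ref=None,
                    raw=raw,
                    panel=None,
                    label=int(label),
                )
            )
            feats.append(f)
            sevs.append(sev)

    gt = GroundTruth(
        features=np.vstack(feats),
        signal_direction=u,
        severities=np.array(sevs),
        patient_effects=patient_effects,
        config=cfg,
    )
    return samples, gt


def _draw_label_series(cfg: SimulationConfig, rng: np.random.Generator, n_samples: int):
    if rng.random() < cfg.initial_pmf_prob:
        return [1] * n_samples
    series = [0] * n_samples
    if n_samples >= 2 and rng.random() < cfg.progression_prob:
        t = int(rng.integers(1, n_samples))  # conversion point; PMF never reverts
        for k in range(t, n_samples):
            series[k] = 1
    return series


def generate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a stochastic cohort with the emulated study shape and its ground truth."""
    rng = np.random.default_rng(config.seed)
    patients: list[tuple[str, list[int]]] = []
    for i in range(config.n_patients):
        n = int(rng.geometric(config.samples_geometric_p))
        n = min(max(n, 1), config.max_samples_per_patient)
        patients.append((f"P{i:04d}", _draw_label_series(config, rng, n)))
    if config.initial_pmf_prob > 0 and not any(1 in s for _, s in patients):
        # tiny cohorts may draw zero PMF patients; force one for validity
        patients[0] = (patients[0][0], [1] * len(patients[0][1]))
    samples, gt = _materialize(patients, config, rng)
    return build_marker_panel(Cohort(samples)), gt


def make_reference_fixture(
    seed: int = 0,
    image_effect: float = 1.0,
    biomarker_effect: float = 0.6,
    feature_dim: int = 64,
) -> tuple[Cohort, GroundTruth]:
    """Deterministic fixture with the exact reference study shape.

    Exactly 94 patients and 341 samples (59 patients with 4 samples, 35
    with 3), 187 SS / 154 PMF: patients 0-37 are PMF throughout (152
    samples), patient 38 progresses SS->PMF halfway (2 + 2), the rest stay
    SS.  ALP, LDH and ACE are missing deterministically in >= 20% of
    samples (every 4th/4th/5th sample respectively); other markers are
    fully observed.
    """
    cfg = SimulationConfig(
        image_effect=image_effect,
        biomarker_effect=biomarker_effect,
        feature_dim=feature_dim,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    patients: list[tuple[str, list[int]]] = []
    for i in range(94):
        n = 4 if i < 59 else 3
        if i < 38:
            series = [1] * n
        elif i == 38:
            series = [0, 0, 1, 1]
        else:
            series = [0] * n
        patients.append((f"P{i:04d}", series))
    samples, gt = _materialize(patients, cfg, rng, impose_missingness=False)
    for i, s in enumerate(samples):
        if i % 4 == 0:
            s.raw["alp"] = math.nan
        if i % 4 == 1:
            s.raw["ldh"] = math.nan
        if i % 5 == 0:
            s.raw["ace"] = math.nan
    return build_marker_panel(Cohort(samples)), gt


def complementary_config(
    seed: int = 0,
    image_effect: float = 1.5,
    biomarker_effect: float = 0.6,
) -> SimulationConfig:
    """A medium-sized cohort with orthogonal, comparably strong modality signals.

    The image signal lives in the feature space, the biomarker signal in the
    blood panel, so their noise is independent given the class — the setting
    in which decision-level fusion is guaranteed an expected gain.  The
    default effects are calibrated so each unimodal branch reaches a
    cross-validated AUC of roughly 0.75 with this pipeline (60 patients,
    32-dim image features, patient_sd 0.2).
    """
    return SimulationConfig(
        n_patients=60,
        image_effect=image_effect,
        biomarker_effect=biomarker_effect,
        patient_sd=0.2,
        feature_dim=32,
        seed=seed,
    )


def generate_fixture_images(
    cohort: Cohort,
    out_dir: str | Path,
    seed: int = 0,
    ground_truth: GroundTruth | None = None,
    size: int = 96,
) -> list[tuple[Path, Path]]:
    """Render small grayscale images + binary lung masks for a cohort.

    Two elliptical "lung fields" on a noisy background, with intensity
    modulated by the sample's latent severity (or its label when no ground
    truth is given).  Writes ``<pid>_<k>.png`` and ``<pid>_<k>_mask.png``
    under ``out_dir`` and sets each sample's ``image_ref``.  Deterministic
    for a fixed seed.
    """
    from skimage.draw import ellipse

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written: list[tuple[Path, Path]] = []
    for i, s in enumerate(cohort.samples):
        sev = (
            float(ground_truth.severities[i]) if ground_truth is not None else float(s.label)
        )
        img = np.clip(rng.normal(40, 10, (size, size)), 0, 255)
        mask = np.zeros((size, size), dtype=bool)
        level = np.clip(110 + 60 * sev, 60, 240)
        for cx in (0.32, 0.68):
            rr, cc = ellipse(
                size * (0.5 + 0.03 * rng.standard_normal()),
                size * (cx + 0.02 * rng.standard_normal()),
                size * 0.30,
                size * 0.14,
                shape=(size, size),
            )
            img[rr, cc] = np.clip(level + rng.normal(0, 8, rr.shape), 0, 255)
            mask[rr, cc] = True
        img_path = out_dir / f"{s.patient_id}_{s.sample_index}.png"
        mask_path = out_dir / f"{s.patient_id}_{s.sample_index}_mask.png"
        Image.fromarray(img.astype(np.uint8), mode="L").save(img_path)
        Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(mask_path)
        s.image_ref = img_path.name
        written.append((img_path, mask_path))
    return written
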