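"""Fusion architectures over a uniform probabilistic-classifier contract.

Three ways of combining the imaging latent scores with the standardized
biomarker panel are provided, all using the same shallow classifier family
(SVM, random forest, or gradient-boosted decision trees):

* **early fusion** — concatenate the 15 latent image scores with the 18
  standardized biomarkers (33-dim under defaults) and train one classifier;
* **late fusion** — train one classifier per modality and average their
  PMF probabilities with weights proportional to each branch's mean AUC on
  3 patient-grouped internal sub-folds of the training set:
  ``w_image = AUC_image / (AUC_image + AUC_biomarker)`` (and symmetrically
  for the biomarker branch), thresholding the weighted probability at 0.5;
* **hybrid fusion** — combine the early-fusion probability with the
  late-fusion probability, either by simple mean (default) or with weights
  proportional to the two branches' internal sub-fold AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "DEFAULT_GRIDS",
    "QUICK_GRIDS",
    "FAMILIES",
    "ClassifierSpec",
    "FusionWeights",
    "BranchAUCs",
    "Prediction",
    "build_classifier",
    "fit_modality_model",
    "predict_pmf_probability",
    "fit_biomarker_preprocessor",
    "early_fuse",
    "compute_auc_weights",
    "late_fuse_predict",
    "hybrid_fuse_predict",
    "estimate_branch_aucs",
]

FAMILIES = ("svm", "rf", "gbdt")

#: Full hyperparameter grids per classifier family.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm": {
        "C": [0.1, 1, 10],
        "kernel": ["rbf", "linear"],
        # candidate gamma values beyond the scale heuristic are a package
        # convention (see config comments); gamma is ignored by linear kernels
        "gamma": ["scale", 0.01, 0.001],
    },
    "rf": {
        "n_estimators": [100, 200],
        "max_depth": [None, 10, 20],
        "min_samples_split": [2, 5],
        "min_samples_leaf": [1, 2],
    },
    "gbdt": {
        "n_estimators": [100, 200],
        "learning_rate": [0.01, 0.1],
        "max_depth": [4, 6, 8],
        "reg_lambda": [1, 3, 5],
    },
}

#: Reduced grids for smoke runs and large simulation sweeps.
QUICK_GRIDS: dict[str, dict[str, list]] = {
    "svm": {"C": [1, 10], "kernel": ["linear"]},
    "rf": {"n_estimators": [100], "max_depth": [None, 10]},
    "gbdt": {"n_estimators": [100], "learning_rate": [0.1], "max_depth": [4, 6]},
}


@dataclass
class ClassifierSpec:
    """A classifier family with its hyperparameter grid and base seed."""

    family: str = "svm"
    grid: dict[str, list] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.family].items()}
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")


def build_classifier(family: str, params: dict, seed: int):
    """Instantiate a probabilistic classifier of the given family."""
    params = dict(params)
    if family == "svm":
        # probability estimates via the implementation's internal calibration CV,
        # seeded from the run seed
        return SVC(probability=True, random_state=seed, **params)
    if family == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "gbdt":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            subsample=0.8,
            subsample_freq=1,
            min_child_samples=5,
            random_state=seed,
            n_jobs=1,
            verbose=-1,
            **params,
        )
    raise ValueError(f"unknown family {family!r}")


def fit_modality_model(features: np.ndarray, labels: np.ndarray, spec: ClassifierSpec,
                       tuned_params: dict, seed: int | None = None):
    """Fit one probabilistic classifier on a (features, labels) matrix."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("cannot fit a classifier on single-class labels")
    model = build_classifier(spec.family, tuned_params, spec.seed if seed is None else seed)
    with warnings.catch_warnings():
        # keep libsvm's internal Platt calibration: unlike CalibratedClassifierCV
        # it tolerates the very small per-class counts of internal sub-folds
        warnings.filterwarnings("ignore", message="The `probability` parameter")
        model.fit(np.asarray(features, dtype=float), labels)
    return model


def predict_pmf_probability(model, features: np.ndarray) -> np.ndarray:
    """Probability of the positive (PMF = 1) class for each row."""
    proba = model.predict_proba(np.asarray(features, dtype=float))
    col = int(np.flatnonzero(model.classes_ == 1)[0])
    return proba[:, col]


def fit_biomarker_preprocessor(train_values: np.ndarray) -> Pipeline:
    """Train-fold mean imputation followed by standardization.

    Residual missingness in retained markers is mean-imputed with training
    means; both the imputer and the scaler are fold-fitted, mirroring the
    image-side scalers.
    """
    pipe = Pipeline(
        [("impute", SimpleImputer(strategy="mean")), ("scale", StandardScaler())]
    )
    return pipe.fit(np.asarray(train_values, dtype=float))


# ---------------------------------------------------------------------------
# Fusion primitives
# ---------------------------------------------------------------------------


def early_fuse(latent: np.ndarray, panel_values: np.ndarray) -> np.ndarray:
    """Concatenate image latents (first) with standardized biomarkers.

    Works on single vectors or on aligned 2-D matrices; no re-scaling is
    applied after concatenation.
    """
    latent = np.asarray(latent, dtype=float)
    panel_values = np.asarray(panel_values, dtype=float)
    if latent.ndim != panel_values.ndim:
        raise ValueError("latent and panel inputs must have matching dimensionality")
    axis = 0 if latent.ndim == 1 else 1
    if latent.ndim == 2 and latent.shape[0] != panel_values.shape[0]:
        raise ValueError("latent and panel matrices must have the same number of rows")
    return np.concatenate([latent, panel_values], axis=axis)


@dataclass(frozen=True)
class FusionWeights:
    """Nonnegative per-modality weights summing to 1 (decision-level fusion)."""

    w_image: float
    w_biomarker: float

    def __post_init__(self):
        if self.w_image < 0 or self.w_biomarker < 0:
            raise ValueError("fusion weights must be nonnegative")
        if abs(self.w_image + self.w_biomarker - 1.0) > 1e-12:
            raise ValueError("fusion weights must sum to 1")


@dataclass(frozen=True)
class BranchAUCs:
    """Mean internal sub-fold AUC of the image and biomarker branches."""

    auc_image: float
    auc_biomarker: float
    n_subfolds: int = 3

    def __post_init__(self):
        if self.auc_image < 0 or self.auc_biomarker < 0:
            raise ValueError("AUCs must be nonnegative")
        if self.auc_image > 1 or self.auc_biomarker > 1:
            raise ValueError("AUCs must be at most 1")
        if self.n_subfolds < 2:
            raise ValueError("n_subfolds must be at least 2")


@dataclass(frozen=True)
class Prediction:
    """A fused PMF probability and its thresholded label."""

    probability_pmf: float
    label: int


def compute_auc_weights(branch: BranchAUCs) -> FusionWeights:
    """AUC-proportional fusion weights; equal weights when both AUCs are 0."""
    total = branch.auc_image + branch.auc_biomarker
    if total == 0:
        warnings.warn("both branch AUCs are zero; falling back to equal weights", stacklevel=2)
        return FusionWeights(0.5, 0.5)
    return FusionWeights(branch.auc_image / total, branch.auc_biomarker / total)


def late_fuse_predict(
    p_image: float,
    p_biomarker: float,
    weights: FusionWeights,
    threshold: float = 0.5,
) -> Prediction:
    """Weighted-average probability, thresholded inclusively at ``threshold``."""
    for name, p in (("p_image", p_image), ("p_biomarker", p_biomarker)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    prob = weights.w_image * p_image + weights.w_biomarker * p_biomarker
    return Prediction(float(prob), int(prob >= threshold))


def hybrid_fuse_predict(
    p_early: float,
    p_late: float,
    branch: BranchAUCs | None = None,
    scheme: str = "mean",
    threshold: float = 0.5,
) -> Prediction:
    """Combine the early-fusion and late-fusion branch probabilities.

    ``scheme='mean'`` averages the two probabilities; ``'auc_proportional'``
    weights them by the branches' internal sub-fold AUCs carried in
    ``branch`` (auc_image slot = early branch, auc_biomarker slot = late
    branch).
    """
    for name, p in (("p_early", p_early), ("p_late", p_late)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    if scheme == "mean":
        prob = 0.5 * (p_early + p_late)
    elif scheme == "auc_proportional":
        if branch is None:
            raise ValueError("auc_proportional scheme requires branch AUCs")
        w = compute_auc_weights(branch)
        prob = w.w_image * p_early + w.w_biomarker * p_late
    else:
        raise ValueError(f"unknown hybrid scheme {scheme!r}")
    return Prediction(float(prob), int(prob >= threshold))


# ---------------------------------------------------------------------------
# Internal sub-fold branch evaluation (weight estimation)
# ---------------------------------------------------------------------------


def subfold_branch_probabilities(
    image_features: np.ndarray,
    panel_values: np.ndarray,
    labels: np.ndarray,
    patient_ids: np.ndarray,
    spec: ClassifierSpec,
    params_image: dict,
    params_biomarker: dict,
    params_early: dict | None = None,
    n_subfolds: int = 3,
    seed: int = 0,
    n_components: int = 15,
):
    """Patient-grouped sub-fold out-of-fold probabilities per branch.

    For each of ``n_subfolds`` patient-grouped splits of the training
    cohort, fits the image transform, biomarker preprocessor and the
    requested classifiers on the sub-training set and predicts the held-out
    sub-fold.  Returns a list of dicts with keys ``y``, ``p_image``,
    ``p_biomarker`` and (when ``params_early`` is given) ``p_early``.
    Sub-folds whose held-out set is single-class are skipped with a warning.
    """
    from .evaluation import plan_group_folds
    from .feature_bank import fit_image_transformer

    image_features = np.asarray(image_features, dtype=float)
    panel_values = np.asarray(panel_values, dtype=float)
    labels = np.asarray(labels)
    assignments, _ = plan_group_folds(patient_ids, labels, k=n_subfolds, seed=seed)
    fold_of = np.array([assignments[p] for p in patient_ids])
    out = []
    for f in range(n_subfolds):
        tr = fold_of != f
        te = fold_of == f
        y_tr, y_te = labels[tr], labels[te]
        if np.unique(y_te).size < 2 or np.unique(y_tr).size < 2:
            warnings.warn(f"sub-fold {f} is single-class; skipped in branch AUC estimation",
                          stacklevel=2)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # n_components auto-cap on tiny sub-folds
            transformer = fit_image_transformer(image_features[tr], y_tr, n_components)
        L_tr = transformer.transform(image_features[tr])
        L_te = transformer.transform(image_features[te])
        prep = fit_biomarker_preprocessor(panel_values[tr])
        B_tr = prep.transform(panel_values[tr])
        B_te = prep.transform(panel_values[te])

        m_img = fit_modality_model(L_tr, y_tr, spec, params_image, seed=spec.seed + f)
        m_bio = fit_modality_model(B_tr, y_tr, spec, params_biomarker, seed=spec.seed + f)
        rec = {
            "y": y_te,
            "p_image": predict_pmf_probability(m_img, L_te),
            "p_biomarker": predict_pmf_probability(m_bio, B_te),
        }
        if params_early is not None:
            m_early = fit_modality_model(
                early_fuse(L_tr, B_tr), y_tr, spec, params_early, seed=spec.seed + f
            )
            rec["p_early"] = predict_pmf_probability(m_early, early_fuse(L_te, B_te))
        out.append(rec)
    if not out:
        raise ValueError(
            f"no usable sub-fold among {n_subfolds} (need >= {n_subfolds} "
            "patients per class in the training cohort)"
        )
    return out


def estimate_branch_aucs(
    image_features: np.ndarray,
    panel_values: np.ndarray,
    labels: np.ndarray,
    patient_ids: np.ndarray,
    spec: ClassifierSpec,
    params_image: dict,
    params_biomarker: dict,
    n_subfolds: int = 3,
    seed: int = 0,
    n_components: int = 15,
) -> BranchAUCs:
    """Mean held-out AUC of each unimodal branch over internal sub-folds."""
    from .evaluation import rank_auc

    records = subfold_branch_probabilities(
        image_features, panel_values, labels, patient_ids, spec,
        params_image, params_biomarker, n_subfolds=n_subfolds, seed=seed,
        n_components=n_components,
    )
    auc_img = float(np.mean([rank_auc(r["p_image"], r["y"]) for r in records]))
    auc_bio = float(np.mean([rank_auc(r["p_biomarker"], r["y"]) for r in records]))
    return BranchAUCs(auc_img, auc_bio, n_subfolds=n_subfolds)
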