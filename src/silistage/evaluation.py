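"""Patient-aware nested cross-validation, metrics and model comparison.

The outer loop is a stratified *group* 5-fold split: all samples of a
patient land in exactly one fold, and folds approximate the cohort's
sample-level SS/PMF mix via greedy assignment.  When grouping constraints
make stratification infeasible (a class with fewer patients than folds, or
a greedy plan leaving a fold single-class), a plain group K-fold fallback
is used and flagged.  Hyperparameters are tuned inside each outer training
fold with a secondary patient-grouped grid search (selection by mean inner
AUC, first-listed wins on ties), after which the winner is refitted on the
whole outer training set.

Per-fold performance uses the PMF-positive confusion matrix (accuracy,
precision, recall, F1), plus the rank-based AUC; fold metrics are
aggregated as mean with a t-based 95% confidence interval (k-1 df).
Paired model comparison uses the exact two-sided Wilcoxon signed-rank test
on per-fold AUCs from one shared fold plan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid

from .cohort_io import Cohort
from .feature_bank import fit_image_transformer
from .fusion_models import (
    BranchAUCs,
    ClassifierSpec,
    compute_auc_weights,
    early_fuse,
    fit_biomarker_preprocessor,
    fit_modality_model,
    predict_pmf_probability,
    subfold_branch_probabilities,
)

__all__ = [
    "STRATEGIES",
    "FoldPlan",
    "ConfusionCounts",
    "MetricTable",
    "ComparisonResult",
    "ExperimentResult",
    "plan_group_folds",
    "plan_folds",
    "nested_grid_search",
    "confusion_metrics",
    "rank_auc",
    "aggregate_folds",
    "wilcoxon_paired_auc",
    "run_experiment",
]

STRATEGIES = ("image_only", "biomarker_only", "early", "late", "hybrid")

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")


# ---------------------------------------------------------------------------
# Fold planning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldPlan:
    """Patient -> fold assignment; ``stratified`` is False when the fallback ran."""

    k: int
    assignments: dict[str, int]
    stratified: bool

    def fold_of_samples(self, patient_ids: np.ndarray) -> np.ndarray:
        return np.array([self.assignments[p] for p in patient_ids], dtype=int)

    def splits(self, patient_ids: np.ndarray):
        """Yield (train_indices, test_indices) per fold."""
        fold_of = self.fold_of_samples(patient_ids)
        for f in range(self.k):
            yield np.flatnonzero(fold_of != f), np.flatnonzero(fold_of == f)


def _patient_table(patient_ids: np.ndarray, labels: np.ndarray):
    """Per-patient (n_class0, n_class1) sample counts, first-appearance order."""
    order: list[str] = []
    counts: dict[str, np.ndarray] = {}
    for pid, y in zip(patient_ids, labels):
        if pid not in counts:
            counts[pid] = np.zeros(2, dtype=int)
            order.append(pid)
        counts[pid][int(y)] += 1
    return order, counts


def _plain_group_kfold(order, counts, k, rng) -> dict[str, int]:
    """Size-balanced group K-fold: big patients first into the smallest fold."""
    shuffled = list(order)
    rng.shuffle(shuffled)
    shuffled.sort(key=lambda p: -counts[p].sum())
    fold_sizes = np.zeros(k, dtype=int)
    assignments = {}
    for pid in shuffled:
        f = int(np.argmin(fold_sizes))
        assignments[pid] = f
        fold_sizes[f] += counts[pid].sum()
    return assignments


def plan_group_folds(
    patient_ids: np.ndarray, labels: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[dict[str, int], bool]:
    """Assign patients to ``k`` folds, stratifying sample-level class counts.

    Greedy assignment: patients (with their full label multiset, so
    mixed-label progressors are handled) are taken largest-first and placed
    in the fold that minimizes the deviation of per-fold class counts from
    the cohort proportions.  Falls back to a plain group K-fold (and
    returns ``stratified=False``) when any class has fewer patients than
    ``k`` or when the greedy plan leaves a fold without both classes.
    """
    patient_ids = np.asarray(patient_ids, dtype=object)
    labels = np.asarray(labels, dtype=int)
    order, counts = _patient_table(patient_ids, labels)
    if len(order) < k:
        raise ValueError(f"need at least k={k} patients, got {len(order)}")
    rng = np.random.default_rng(seed)

    # feasibility by majority label per patient
    majority = {p: int(np.argmax(counts[p])) for p in order}
    per_class_patients = np.bincount([majority[p] for p in order], minlength=2)
    if per_class_patients.min() < k:
        return _plain_group_kfold(order, counts, k, rng), False

    totals = np.zeros(2, dtype=int)
    for p in order:
        totals += counts[p]
    target = totals / k

    shuffled = list(order)
    rng.shuffle(shuffled)
    shuffled.sort(key=lambda p: -counts[p].sum())
    fold_counts = np.zeros((k, 2), dtype=int)
    assignments: dict[str, int] = {}
    for pid in shuffled:
        best, best_key = None, None
        for f in range(k):
            # change in the fold's deviation from the target class mix
            delta = (
                np.abs(fold_counts[f] + counts[pid] - target).sum()
                - np.abs(fold_counts[f] - target).sum()
            )
            key = (delta, fold_counts[f].sum(), f)
            if best_key is None or key < best_key:
                best, best_key = f, key
        assignments[pid] = best
        fold_counts[best] += counts[pid]

    if (fold_counts.sum(axis=1) == 0).any() or (fold_counts == 0).any():
        return _plain_group_kfold(order, counts, k, rng), False
    return assignments, True


def plan_folds(cohort: Cohort, k: int = 5, seed: int = 0) -> FoldPlan:
    """Build a patient-aware (stratified when feasible) fold plan for a cohort."""
    assignments, stratified = plan_group_folds(cohort.patient_ids, cohort.labels, k=k, seed=seed)
    return FoldPlan(k=k, assignments=assignments, stratified=stratified)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    """PMF-positive confusion-matrix outcomes."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """Accuracy, precision, recall and F1 from confusion counts.

    Undefined ratios (empty predicted-positive or actual-positive sets) are
    reported as 0 with a warning; F1 is 0 when precision + recall is 0.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    accuracy = (counts.tp + counts.tn) / counts.total
    if counts.tp + counts.fp == 0:
        warnings.warn("precision undefined (no predicted positives); reporting 0", stacklevel=2)
        precision = 0.0
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        warnings.warn("recall undefined (no actual positives); reporting 0", stacklevel=2)
        recall = 0.0
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return accuracy, precision, recall, f1


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC (ties count 0.5); requires both classes present."""
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("AUC requires both classes in the labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class MetricTable:
    """Per-fold metrics with mean and 95% CI (t-interval, k-1 df)."""

    per_fold: dict[str, np.ndarray]
    mean: dict[str, float] = field(default_factory=dict)
    ci_lower: dict[str, float] = field(default_factory=dict)
    ci_upper: dict[str, float] = field(default_factory=dict)
    ci_available: bool = True


def aggregate_folds(per_fold: dict[str, np.ndarray]) -> MetricTable:
    """Mean and t-based 95% CI across folds, truncated to [0, 1].

    NaN fold entries (e.g. AUC on a degenerate single-class test fold) are
    ignored.  With fewer than 2 folds only the mean is reported.
    """
    table = MetricTable(per_fold={k: np.asarray(v, dtype=float) for k, v in per_fold.items()})
    for name, vals in table.per_fold.items():
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            table.mean[name] = float("nan")
            table.ci_lower[name] = float("nan")
            table.ci_upper[name] = float("nan")
            continue
        m = float(vals.mean())
        table.mean[name] = m
        if vals.size < 2:
            table.ci_available = False
            table.ci_lower[name] = float("nan")
            table.ci_upper[name] = float("nan")
            continue
        half = stats.t.ppf(0.975, vals.size - 1) * vals.std(ddof=1) / np.sqrt(vals.size)
        table.ci_lower[name] = float(max(0.0, m - half))
        table.ci_upper[name] = float(min(1.0, m + half))
    return table


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sided Wilcoxon signed-rank comparison of paired fold AUCs."""

    model_a: str
    model_b: str
    paired_auc_diffs: np.ndarray
    p_value: float
    significant: bool  # at the 0.05 level


def _exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Exact two-sided p by the sign-flip distribution of W+ (midranks).

    Equivalent to full enumeration of the 2^n sign patterns, computed as a
    convolution over ranks.  Ranks are doubled so midranks stay integral.
    """
    ranks2 = np.round(stats.rankdata(np.abs(diffs)) * 2).astype(int)
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w_obs = float(ranks2[diffs > 0].sum())
    mu = total / 2.0
    dev = abs(w_obs - mu)
    support = np.arange(total + 1)
    return float(dist[np.abs(support - mu) >= dev - 1e-9].sum())


def wilcoxon_paired_auc(
    aucs_a: np.ndarray,
    aucs_b: np.ndarray,
    model_a: str = "A",
    model_b: str = "B",
    plan_a: FoldPlan | None = None,
    plan_b: FoldPlan | None = None,
) -> ComparisonResult:
    """Exact two-sided Wilcoxon signed-rank test on paired per-fold AUCs.

    Zero differences are dropped before ranking (classic convention).  The
    exact sign-flip distribution is used for up to 25 nonzero pairs; beyond
    that the normal approximation from scipy is used.  When fold plans are
    supplied they must be identical (pairedness guard).
    """
    if plan_a is not None and plan_b is not None and plan_a != plan_b:
        raise ValueError("paired comparison requires an identical fold plan for both models")
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equally sized AUC vectors of length >= 2")
    ok = ~(np.isnan(a) | np.isnan(b))
    if not ok.all():
        warnings.warn("dropping fold pairs with undefined AUC from the comparison",
                      stacklevel=2)
        a, b = a[ok], b[ok]
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        warnings.warn("all paired AUC differences are zero; p = 1.0", stacklevel=2)
        p = 1.0
    elif nonzero.size <= 25:
        p = min(1.0, _exact_signed_rank_p(nonzero))
    else:  # pragma: no cover - folds are few in practice
        p = float(stats.wilcoxon(a, b, zero_method="wilcox", mode="approx").pvalue)
    return ComparisonResult(model_a, model_b, diffs, p, significant=p < 0.05)


# ---------------------------------------------------------------------------
# Nested grid search
# ---------------------------------------------------------------------------


def nested_grid_search(
    features: np.ndarray,
    labels: np.ndarray,
    patient_ids: np.ndarray,
    spec: ClassifierSpec,
    inner_k: int = 3,
    seed: int = 0,
) -> dict:
    """Exhaustive patient-grouped grid search by mean inner-fold AUC.

    Ties are broken by grid order (first listed wins); the caller refits the
    winner on the full outer training set.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = list(dict.fromkeys(patient_ids))
    if len(order) < inner_k:
        raise ValueError(
            f"inner split infeasible: {len(order)} patients < inner_k={inner_k}"
        )
    assignments, _ = plan_group_folds(patient_ids, labels, k=inner_k, seed=seed)
    fold_of = np.array([assignments[p] for p in patient_ids])
    splits = []
    for f in range(inner_k):
        tr, te = np.flatnonzero(fold_of != f), np.flatnonzero(fold_of == f)
        if np.unique(labels[tr]).size == 2 and np.unique(labels[te]).size == 2:
            splits.append((tr, te))
    if not splits:
        raise ValueError("inner split infeasible: no sub-fold contains both classes")

    grid = list(ParameterGrid(spec.grid))
    best_params, best_auc = None, -np.inf
    for params in grid:
        aucs = []
        for i, (tr, te) in enumerate(splits):
            model = fit_modality_model(features[tr], labels[tr], spec, params, seed=seed + i)
            aucs.append(rank_auc(predict_pmf_probability(model, features[te]), labels[te]))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:  # strict: earlier grid entries win ties
            best_auc, best_params = mean_auc, params
    return dict(best_params)


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    """One strategy x family run: per-fold records and the aggregate table."""

    strategy: str
    family: str
    fold_plan: FoldPlan
    metrics: MetricTable
    fold_records: list[dict]

    @property
    def fold_aucs(self) -> np.ndarray:
        return self.metrics.per_fold["auc"]


def _fold_seed(seed: int, fold: int) -> int:
    return (seed * 100_003 + fold * 7_919 + 17) % (2**31)


def run_experiment(
    cohort: Cohort,
    image_features: np.ndarray,
    strategy: str,
    spec: ClassifierSpec,
    k_outer: int = 5,
    k_inner: int = 3,
    n_components: int = 15,
    n_subfolds: int = 3,
    threshold: float = 0.5,
    hybrid_scheme: str = "mean",
    seed: int = 0,
    fold_plan: FoldPlan | None = None,
) -> ExperimentResult:
    """Nested patient-aware cross-validation of one fusion strategy.

    ``image_features`` is the n_samples x D frozen-backbone feature matrix
    aligned to ``cohort.samples``.  All preprocessing (image transform,
    biomarker imputation/standardization), hyperparameter tuning and fusion
    weights are fitted inside each outer training fold.  Passing one
    ``fold_plan`` across strategies gives paired per-fold AUCs for model
    comparison.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    image_features = np.asarray(image_features, dtype=float)
    if image_features.shape[0] != len(cohort):
        raise ValueError("image_features rows must align with cohort samples")
    panel = cohort.panel_matrix()
    y = cohort.labels
    pids = cohort.patient_ids
    if fold_plan is None:
        fold_plan = plan_folds(cohort, k=k_outer, seed=seed)

    per_fold: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    fold_records: list[dict] = []
    for fold, (tr, te) in enumerate(fold_plan.splits(pids)):
        fseed = _fold_seed(seed, fold)
        y_tr, y_te = y[tr], y[te]
        if np.unique(y_tr).size < 2:
            raise ValueError(f"outer fold {fold}: training set is single-class")

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            transformer = fit_image_transformer(image_features[tr], y_tr, n_components)
        L_tr = transformer.transform(image_features[tr])
        L_te = transformer.transform(image_features[te])
        prep = fit_biomarker_preprocessor(panel[tr])
        B_tr, B_te = prep.transform(panel[tr]), prep.transform(panel[te])

        record: dict = {"fold": fold, "seed": fseed}

        def tune(X):
            return nested_grid_search(X, y_tr, pids[tr], spec, inner_k=k_inner, seed=fseed)

        if strategy == "image_only":
            params = tune(L_tr)
            model = fit_modality_model(L_tr, y_tr, spec, params, seed=fseed)
            prob = predict_pmf_probability(model, L_te)
            record["params"] = params
        elif strategy == "biomarker_only":
            params = tune(B_tr)
            model = fit_modality_model(B_tr, y_tr, spec, params, seed=fseed)
            prob = predict_pmf_probability(model, B_te)
            record["params"] = params
        elif strategy == "early":
            F_tr, F_te = early_fuse(L_tr, B_tr), early_fuse(L_te, B_te)
            params = tune(F_tr)
            model = fit_modality_model(F_tr, y_tr, spec, params, seed=fseed)
            prob = predict_pmf_probability(model, F_te)
            record["params"] = params
        else:  # late or hybrid
            params_i, params_b = tune(L_tr), tune(B_tr)
            record["params_image"], record["params_biomarker"] = params_i, params_b
            params_e = tune(early_fuse(L_tr, B_tr)) if strategy == "hybrid" else None
            subs = subfold_branch_probabilities(
                image_features[tr], panel[tr], y_tr, pids[tr], spec,
                params_i, params_b, params_early=params_e,
                n_subfolds=n_subfolds, seed=fseed, n_components=n_components,
            )
            branch = BranchAUCs(
                float(np.mean([rank_auc(r["p_image"], r["y"]) for r in subs])),
                float(np.mean([rank_auc(r["p_biomarker"], r["y"]) for r in subs])),
                n_subfolds=n_subfolds,
            )
            w = compute_auc_weights(branch)
            record["branch_aucs"] = (branch.auc_image, branch.auc_biomarker)
            record["weights"] = (w.w_image, w.w_biomarker)
            m_img = fit_modality_model(L_tr, y_tr, spec, params_i, seed=fseed)
            m_bio = fit_modality_model(B_tr, y_tr, spec, params_b, seed=fseed)
            p_late = (
                w.w_image * predict_pmf_probability(m_img, L_te)
                + w.w_biomarker * predict_pmf_probability(m_bio, B_te)
            )
            if strategy == "late":
                prob = p_late
            else:
                record["params_early"] = params_e
                m_early = fit_modality_model(
                    early_fuse(L_tr, B_tr), y_tr, spec, params_e, seed=fseed
                )
                p_early = predict_pmf_probability(m_early, early_fuse(L_te, B_te))
                if hybrid_scheme == "mean":
                    prob = 0.5 * (p_early + p_late)
                elif hybrid_scheme == "auc_proportional":
                    auc_e = float(np.mean([rank_auc(r["p_early"], r["y"]) for r in subs]))
                    p_late_sub = [
                        w.w_image * r["p_image"] + w.w_biomarker * r["p_biomarker"]
                        for r in subs
                    ]
                    auc_l = float(
                        np.mean([rank_auc(p, r["y"]) for p, r in zip(p_late_sub, subs)])
                    )
                    total = auc_e + auc_l
                    we = 0.5 if total == 0 else auc_e / total
                    record["hybrid_branch_aucs"] = (auc_e, auc_l)
                    prob = we * p_early + (1 - we) * p_late
                else:
                    raise ValueError(f"unknown hybrid scheme {hybrid_scheme!r}")

        pred = (prob >= threshold).astype(int)
        counts = ConfusionCounts.from_predictions(y_te, pred)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            acc, prec, rec, f1 = confusion_metrics(counts)
        if np.unique(y_te).size < 2:
            warnings.warn(f"outer fold {fold}: single-class test fold, AUC undefined",
                          stacklevel=2)
            auc = float("nan")
        else:
            auc = rank_auc(prob, y_te)
        for name, val in zip(METRIC_NAMES, (acc, prec, rec, f1, auc)):
            per_fold[name].append(val)
        record.update(
            counts=(counts.tp, counts.tn, counts.fp, counts.fn),
            test_indices=te,
            probabilities=prob,
            predictions=pred,
        )
        fold_records.append(record)

    metrics = aggregate_folds({k: np.array(v) for k, v in per_fold.items()})
    return ExperimentResult(strategy, spec.family, fold_plan, metrics, fold_records)
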