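"""Configuration, CLI and report generation for reproducible runs.

The ``silistage`` command exposes two verbs:

* ``simulate`` — write a synthetic cohort (manifest + optional fixture
  images/masks + ground-truth sidecar) from a YAML config;
* ``run`` — execute every (strategy x classifier family) experiment on a
  shared fold plan and write metric tables ("mean [95% CI]" cells),
  per-fold predictions, fusion-weight logs and pairwise Wilcoxon
  comparisons into a run directory, together with a verbatim config
  snapshot so every artifact is reproducible from snapshot + seed alone.

A single global seed expands deterministically into per-fold / per-model
sub-seeds via a counter-based scheme, so adding a strategy does not perturb
the randomness of the others.
"""

from __future__ import annotations

import argparse
import dataclasses
import json
import logging
import sys
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, fusion_models
from .cohort_io import Cohort, filter_markers_by_missingness, load_cohort, write_manifest
from .feature_bank import BackboneContract, RandomProjectionBackbone, extract_features
from .image_pipeline import (
    DEFAULT_MASK_SUFFIX,
    OracleMaskBackend,
    load_gray_image,
    preprocess,
)
from .synthetic_cohort import (
    GroundTruth,
    SimulationConfig,
    generate_cohort,
    generate_fixture_images,
)

logger = logging.getLogger("silistage")

__all__ = [
    "RunConfig",
    "derive_seed",
    "extract_cohort_features",
    "run",
    "simulate",
    "main",
]


def derive_seed(master: int, *tags) -> int:
    """Deterministically expand a master seed with string/int tags (< 2^31)."""
    h = zlib.crc32(repr(tags).encode())
    return int(np.random.SeedSequence([master & 0x7FFFFFFF, h]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """One experiment run: cohort source, strategies, families and parameters.

    Defaults mirror the framework's canonical settings: 5 outer folds, 3
    inner tuning folds, 3 weight-estimation sub-folds, 15 latent
    components, 20% marker-missingness exclusion, 0.5 decision threshold.
    """

    manifest: str | None = None
    image_root: str | None = None
    synthetic: dict = field(default_factory=dict)
    strategies: list[str] = field(default_factory=lambda: list(evaluation.STRATEGIES))
    families: list[str] = field(default_factory=lambda: ["svm"])
    k_outer: int = 5
    k_inner: int = 3
    n_subfolds: int = 3
    n_components: int = 15
    missingness_threshold: float = 0.20
    decision_threshold: float = 0.5
    hybrid_scheme: str = "mean"
    quick: bool = False
    seed: int = 0
    out_dir: str = "runs/latest"
    segmentation_backend: str = "oracle"
    mask_suffix: str = DEFAULT_MASK_SUFFIX
    backbone_dim: int = 64
    write_images: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"invalid config key(s): {sorted(unknown)}")
        return cls(**data)

    def snapshot(self, path: Path) -> None:
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def extract_cohort_features(
    cohort: Cohort,
    image_root: str | Path,
    backbone: BackboneContract,
    mask_suffix: str = DEFAULT_MASK_SUFFIX,
) -> np.ndarray:
    """Run preprocess + frozen-backbone extraction over every cohort image.

    Masks are looked up beside each image as ``<stem><mask_suffix><ext>``
    (the oracle backend); samples flagged image-absent raise, since the
    imaging modality cannot run without them.
    """
    image_root = Path(image_root)
    feats = []
    for s in cohort.samples:
        if s.image_ref is None:
            raise ValueError(
                f"sample ({s.patient_id}, {s.sample_index}) has no image; "
                "imaging strategies cannot run"
            )
        img_path = image_root / s.image_ref
        mask_path = img_path.with_name(img_path.stem + mask_suffix + img_path.suffix)
        image = load_gray_image(img_path)
        tensor = preprocess(image, OracleMaskBackend(mask_path), size=backbone.input_size)
        feats.append(extract_features(tensor, backbone))
    return np.vstack(feats)


def _format_table(result: evaluation.ExperimentResult) -> dict:
    cells = {}
    for m in evaluation.METRIC_NAMES:
        mean = result.metrics.mean[m]
        lo, hi = result.metrics.ci_lower[m], result.metrics.ci_upper[m]
        scale = 100.0 if m != "auc" else 1.0
        fmt = (lambda v: f"{v * scale:.2f}")
        cells[m] = f"{fmt(mean)} [{fmt(lo)}-{fmt(hi)}]"
    return cells


def _prepare_cohort(config: RunConfig) -> tuple[Cohort, np.ndarray, list[str]]:
    """Load or generate the cohort and the aligned image-feature matrix."""
    if config.manifest:
        cohort = load_cohort(config.manifest, image_root=config.image_root)
        backbone = RandomProjectionBackbone(
            output_dim=config.backbone_dim, seed=derive_seed(config.seed, "backbone")
        )
        features = extract_cohort_features(
            cohort, config.image_root or ".", backbone, mask_suffix=config.mask_suffix
        )
    else:
        sim = SimulationConfig(**{**config.synthetic, "seed": config.seed})
        cohort, gt = generate_cohort(sim)
        features = gt.features
    cohort, removed = filter_markers_by_missingness(cohort, config.missingness_threshold)
    logger.info("markers removed by missingness filter: %s", removed)
    return cohort, features, removed


def run(config: RunConfig) -> dict[tuple[str, str], evaluation.ExperimentResult]:
    """Execute all (strategy, family) experiments; write tables and comparisons."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.snapshot(out / "config.yaml")
    cohort, features, removed = _prepare_cohort(config)

    fold_plan = evaluation.plan_folds(cohort, k=config.k_outer, seed=derive_seed(config.seed, "folds"))
    (out / "fold_plan.txt").write_text(
        f"k={fold_plan.k} stratified={fold_plan.stratified}\n"
        + "".join(f"{p}\t{f}\n" for p, f in sorted(fold_plan.assignments.items()))
    )

    results: dict[tuple[str, str], evaluation.ExperimentResult] = {}
    tables = {}
    for family in config.families:
        grids = fusion_models.QUICK_GRIDS if config.quick else fusion_models.DEFAULT_GRIDS
        for strategy in config.strategies:
            spec = fusion_models.ClassifierSpec(
                family=family,
                grid={k: list(v) for k, v in grids[family].items()},
                seed=derive_seed(config.seed, "clf", family, strategy),
            )
            logger.info("running strategy=%s family=%s", strategy, family)
            res = evaluation.run_experiment(
                cohort,
                features,
                strategy,
                spec,
                k_outer=config.k_outer,
                k_inner=config.k_inner,
                n_components=config.n_components,
                n_subfolds=config.n_subfolds,
                threshold=config.decision_threshold,
                hybrid_scheme=config.hybrid_scheme,
                seed=derive_seed(config.seed, "exp", family, strategy),
                fold_plan=fold_plan,
            )
            results[(strategy, family)] = res
            tables[f"{strategy}/{family}"] = _format_table(res)

            pred_path = out / f"predictions_{strategy}_{family}.csv"
            with open(pred_path, "w") as fh:
                fh.write("fold,sample,patient_id,label,probability,prediction\n")
                for rec in res.fold_records:
                    for i, idx in enumerate(rec["test_indices"]):
                        s = cohort.samples[idx]
                        fh.write(
                            f"{rec['fold']},{idx},{s.patient_id},{s.label},"
                            f"{rec['probabilities'][i]:.6f},{rec['predictions'][i]}\n"
                        )
            for rec in res.fold_records:
                params = {k: v for k, v in rec.items()
                          if k.startswith("params") or k in ("weights", "branch_aucs")}
                logger.info("fold %d [%s/%s]: %s", rec["fold"], strategy, family, params)

    (out / "metrics.json").write_text(json.dumps(tables, indent=2))
    with open(out / "metrics.csv", "w") as fh:
        fh.write("strategy,family," + ",".join(evaluation.METRIC_NAMES) + "\n")
        for key, cells in tables.items():
            strategy, family = key.split("/")
            fh.write(f"{strategy},{family}," + ",".join(f"\"{cells[m]}\"" for m in evaluation.METRIC_NAMES) + "\n")

    with open(out / "comparisons.csv", "w") as fh:
        fh.write("family,model_a,model_b,p_value,significant\n")
        for family in config.families:
            strategies = [s for s in config.strategies]
            for i, sa in enumerate(strategies):
                for sb in strategies[i + 1 :]:
                    ra, rb = results[(sa, family)], results[(sb, family)]
                    cmp = evaluation.wilcoxon_paired_auc(
                        ra.fold_aucs, rb.fold_aucs, model_a=sa, model_b=sb,
                        plan_a=ra.fold_plan, plan_b=rb.fold_plan,
                    )
                    fh.write(f"{family},{sa},{sb},{cmp.p_value:.6g},{cmp.significant}\n")
    return results


def simulate(config: RunConfig) -> Path:
    """Generate a synthetic cohort; write manifest (+ images) + ground truth."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = SimulationConfig(**{**config.synthetic, "seed": config.seed})
    cohort, gt = generate_cohort(sim)
    if config.write_images:
        generate_fixture_images(
            cohort, out / "images", seed=derive_seed(config.seed, "images"), ground_truth=gt
        )
    write_manifest(cohort, out / "manifest.csv")
    np.savetxt(out / "ground_truth_features.csv", gt.features, delimiter=",")
    (out / "ground_truth.json").write_text(
        json.dumps(
            {
                "signal_direction": gt.signal_direction.tolist(),
                "severities": gt.severities.tolist(),
                "patient_effects": gt.patient_effects,
                "config": dataclasses.asdict(gt.config),
            }
        )
    )
    config.snapshot(out / "config.yaml")
    logger.info("wrote synthetic cohort with %d samples / %d patients to %s",
                len(cohort), cohort.n_patients, out)
    return out


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(
        prog="silistage",
        description="Multimodal (radiograph + blood biomarker) silicosis staging experiments",
    )
    sub = parser.add_subparsers(dest="verb", required=True)
    for verb in ("simulate", "run"):
        p = sub.add_parser(verb)
        p.add_argument("--config", help="YAML run configuration")
        p.add_argument("--seed", type=int, default=None)
        p.add_argument("--out", default=None)
        p.add_argument("--quick", action="store_true", help="reduced hyperparameter grids")
        if verb == "run":
            p.add_argument("--strategy", action="append", default=None)
            p.add_argument("--family", action="append", default=None)
    args = parser.parse_args(argv)

    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    try:
        config = RunConfig.from_yaml(args.config) if args.config else RunConfig()
        if args.seed is not None:
            config.seed = args.seed
        elif not args.config:
            config.seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
            logger.info("no seed given; drew seed=%d", config.seed)
        if args.out:
            config.out_dir = args.out
        if args.quick:
            config.quick = True
        if args.verb == "run":
            if args.strategy:
                config.strategies = args.strategy
            if args.family:
                config.families = args.family
            run(config)
        else:
            simulate(config)
    except (ValueError, OSError) as exc:
        logger.error("%s", exc)
        return 1
    return 0


if __name__ == "__main__":  # pragma: no cover
    sys.exit(main())
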