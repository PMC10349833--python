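"""End-to-end orchestration of the superpixel classification pipeline.

One call runs, per image: hair removal -> seeded graph-cut lesion
segmentation -> background blackening -> SLIC superpixels -> background
superpixel elimination -> geometric feature extraction; then, on the pooled
record table: stratified split -> z-score normalization fitted on train ->
training of each requested classifier with five-fold cross-validation ->
confusion-matrix metrics on the held-out records.

Outputs are plain files under the configured directory: ``features.csv``,
``split_manifest.json``, ``metrics_<model>.json`` and ``run_log.json`` (the
log carries versions, the seed and per-stage timings; all other outputs are
byte-reproducible from config + seed).  Heavy per-image stages are cached
under ``<outdir>/cache`` keyed by a content hash of their inputs, so
repeated runs skip completed work.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adapters import load_dataset_adapter
from .dataset import SplitSpec, split_dataset, zscore_fit_transform
from .features import extract_all
from .graphcut import GraphCutParams, apply_black_mask, auto_seeds, graph_cut_segment
from .islic import SlicParams, filter_background_superpixels, slic_superpixels
from .metrics import compute_metrics, confusion
from .models import MODEL_NAMES, build_spec, predict, train_model
from .preprocess import HairRemovalParams, detect_hair_mask, remove_hair
from .synthetic import SyntheticConfig, add_hair_overlay, generate_lesion_image

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "process_image", "StageError"]

CSV_COLUMNS = [
    "image_id",
    "sp_label",
    "area",
    "perimeter",
    "eccentricity",
    "orientation",
    "convex_area",
    "major_axis_length",
    "class",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and image id."""

    def __init__(self, stage: str, image_id: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed on image {image_id!r}: {cause}")
        self.stage = stage
        self.image_id = image_id


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative description of one full run; JSON round-trippable."""

    n_images_per_class: int = 10
    models: tuple[str, ...] = MODEL_NAMES
    train_fraction: float = 0.70
    cv_folds: int = 5
    overlap_threshold: float = 0.5
    seed: int = 0
    output_dir: str = "results"
    adapter: str | None = None  # None -> synthetic images
    adapter_root: str | None = None
    synthetic_overrides: dict = field(default_factory=dict)
    hair_params: HairRemovalParams = field(default_factory=HairRemovalParams)
    graphcut_params: GraphCutParams = field(default_factory=GraphCutParams)
    slic_params: SlicParams = field(default_factory=SlicParams)
    cache: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["models"] = tuple(d.get("models", MODEL_NAMES))
        for key, typ in (
            ("hair_params", HairRemovalParams),
            ("graphcut_params", GraphCutParams),
            ("slic_params", SlicParams),
        ):
            if isinstance(d.get(key), dict):
                sub = d[key]
                if "se_orientations" in sub:
                    sub["se_orientations"] = tuple(sub["se_orientations"])
                d[key] = typ(**sub)
        return cls(**d)


def _child_seed(base: int, i: int) -> int:
    return int((base * 100003 + 7919 * i + 1) % (2**31 - 1))


def _cache_key(stage: str, payload: bytes) -> str:
    return hashlib.sha1(stage.encode() + b"\0" + payload).hexdigest()


def _cached(cache_dir: Path | None, stage: str, payload: bytes, fn):
    if cache_dir is None:
        return fn()
    key = _cache_key(stage, payload)
    path = cache_dir / f"{stage}-{key}.npz"
    if path.exists():
        with np.load(path) as data:
            return data["value"]
    value = fn()
    cache_dir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, value=value)
    return value


def process_image(
    rgb_image: np.ndarray,
    image_id: str,
    class_label,
    config: PipelineConfig,
    cache_dir: Path | None = None,
) -> list[dict]:
    """Run the per-image stages and return the superpixel feature records."""

    def run(stage: str, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise StageError(stage, image_id, exc) from exc

    img_bytes = np.ascontiguousarray(rgb_image).tobytes()
    params_tag = json.dumps(
        {
            "hair": asdict(config.hair_params),
            "cut": asdict(config.graphcut_params),
            "slic": asdict(config.slic_params),
        },
        sort_keys=True,
    ).encode()

    def _preprocess():
        mask = detect_hair_mask(rgb_image, config.hair_params)
        return remove_hair(rgb_image, mask)

    clean = run(
        "preprocess",
        lambda: _cached(cache_dir, "preprocess", img_bytes + params_tag, _preprocess),
    )

    def _segment():
        fg, bg = auto_seeds(clean, config.graphcut_params)
        return graph_cut_segment(clean, fg, bg, config.graphcut_params)

    lesion = run(
        "segment",
        lambda: _cached(
            cache_dir, "segment", clean.tobytes() + params_tag, _segment
        ),
    ).astype(bool)

    masked = run("blackmask", lambda: apply_black_mask(clean, lesion))
    labels = run(
        "superpixels",
        lambda: _cached(
            cache_dir,
            "superpixels",
            masked.tobytes() + params_tag,
            lambda: slic_superpixels(masked, config.slic_params),
        ),
    )
    sp_set = run(
        "filter",
        lambda: filter_background_superpixels(
            labels, lesion, config.overlap_threshold, config.slic_params.n_superpixels
        ),
    )
    return run("features", lambda: extract_all(sp_set, image_id, class_label))


def _collect_images(config: PipelineConfig):
    """Yield (image_id, rgb_image, class_label) for the configured source."""
    if config.adapter is None:
        for cls_idx, cls in enumerate(("nevus", "melanoma")):
            for i in range(config.n_images_per_class):
                seed = _child_seed(config.seed, cls_idx * config.n_images_per_class + i)
                cfg = SyntheticConfig.for_class(
                    cls, seed=seed, **config.synthetic_overrides
                )
                img, _, label = generate_lesion_image(cfg)
                if cfg.n_hairs:
                    img = add_hair_overlay(
                        img, cfg.n_hairs, cfg.hair_width_px, seed=seed + 1
                    )
                yield f"{cls}-{i:03d}", img, label
    else:
        import imageio.v3 as iio

        pairs = load_dataset_adapter(config.adapter, config.adapter_root)
        for entry in pairs:
            path, label = entry[0], entry[1]
            yield Path(path).stem, iio.imread(path), label


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write the results bundle.

    Returns a dict with the feature table, split manifest, per-model metric
    reports and output paths.
    """
    unknown = set(config.models) - set(MODEL_NAMES)
    if unknown:
        raise ValueError(
            f"unknown model name(s) {sorted(unknown)}; valid: {list(MODEL_NAMES)}"
        )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cache_dir = outdir / "cache" if config.cache else None
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    records: list[dict] = []
    for image_id, img, label in _collect_images(config):
        logger.info("processing image %s", image_id)
        records.extend(process_image(img, image_id, label, config, cache_dir))
    timings["image_stages"] = time.perf_counter() - t0
    if not records:
        raise RuntimeError("pipeline produced no superpixel records")

    features = pd.DataFrame.from_records(records)[CSV_COLUMNS]
    features_path = outdir / "features.csv"
    features.to_csv(features_path, index=False)

    t0 = time.perf_counter()
    split = SplitSpec(train_fraction=config.train_fraction, seed=config.seed)
    train_raw, test_raw = split_dataset(features, split)
    train, test, norm_params = zscore_fit_transform(train_raw, test_raw)
    manifest = {
        "seed": config.seed,
        "train_fraction": config.train_fraction,
        "train_indices": train.index.tolist(),
        "test_indices": test.index.tolist(),
        "normalization": {k: list(v) for k, v in norm_params.items()},
    }
    manifest_path = outdir / "split_manifest.json"
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=1))
    timings["split_normalize"] = time.perf_counter() - t0

    reports: dict[str, dict] = {}
    for name in config.models:
        t0 = time.perf_counter()
        spec = build_spec(name, seed=config.seed)
        model = train_model(spec, train, cv_folds=config.cv_folds)
        y_pred = predict(model, test)
        report = compute_metrics(confusion(test["class"].to_numpy(), y_pred))
        reports[name] = {
            "model": name,
            "dataset": config.adapter or "synthetic",
            "split": config.train_fraction,
            "cv_mean_accuracy": model.cv_mean_accuracy,
            "test": {
                **report.to_dict(),
                "confusion": confusion(test["class"].to_numpy(), y_pred).to_dict(),
            },
        }
        (outdir / f"metrics_{name}.json").write_text(
            json.dumps(reports[name], sort_keys=True, indent=1)
        )
        timings[f"train_{name}"] = time.perf_counter() - t0
        logger.info(
            "%s: cv=%.3f test acc=%.3f mcc=%.3f",
            name,
            model.cv_mean_accuracy or float("nan"),
            reports[name]["test"]["accuracy"],
            reports[name]["test"]["mcc"],
        )

    run_log = {
        "config": config.to_dict(),
        "versions": _versions(),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "n_records": len(features),
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, sort_keys=True, indent=1))

    return {
        "features": features,
        "manifest": manifest,
        "metrics": reports,
        "paths": {
            "features": features_path,
            "manifest": manifest_path,
            "metrics": {n: outdir / f"metrics_{n}.json" for n in config.models},
        },
    }


def _versions() -> dict:
    import sklearn
    import scipy
    import skimage

    return {
        "dermasp": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "scikit-learn": sklearn.__version__,
        "pandas": pd.__version__,
    }
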