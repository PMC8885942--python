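"""End-to-end orchestration: load -> preprocess -> segment -> features ->
classify, plus the full simulate/train/evaluate experiment harness.

Every stage mirrors one button of a step-by-step diagnostic workflow:
input image, grayscale, preprocessing, lesion detection, classification.
``classify_image`` can dump each intermediate raster as a PNG so a run is
fully inspectable; ``run_experiment`` wires the synthetic generator to the
trainer and evaluator and emits a reproducible JSON/CSV summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio

from . import classifier as clf
from . import preprocessing as pre
from . import segmentation as seg
from .features import FEATURE_NAMES, FeatureVector, extract_features
from .synthetic import generate_dataset
from .types import LesionImage, LesionMask, ValidationError

log = logging.getLogger("dermoknn")

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "merge_config",
    "load_image",
    "process_image",
    "classify_image",
    "run_experiment",
    "CaseReport",
]

CLASS_NAMES = {0: "normal", 1: "melanoma"}

# offset added to the experiment seed to derive the held-out test stream;
# keeps train and test draws disjoint while staying below 2**31
_TEST_SEED_OFFSET = 500_009

DEFAULT_CONFIG: dict = {
    "preprocessing": {"line_length": 15, "n_angles": 8, "equalize": True},
    "segmentation": {
        "window": None,  # None -> default_window(image shape)
        "offset": 10.0,
        "polarity": "dark_foreground",
        "connectivity": 8,
        # threshold the dehaired raster: global equalization before a
        # locally adaptive threshold amplifies quantization gaps in flat
        # skin and degrades recovery on clean images
        "source": "dehaired",  # or "equalized"
    },
    "classifier": {"k": None, "k_grid": None, "standardize": True},
    "experiment": {
        "n_train_normal": 40,
        "n_train_malignant": 40,
        "n_test_normal": 50,
        "n_test_malignant": 50,
        "seed": 1,
    },
    "simulate": {"profile": None},
}


def merge_config(overrides: dict | None) -> dict:
    """Deep-merge user overrides into the defaults, rejecting unknown keys."""
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if not overrides:
        return cfg
    bad = []
    for section, values in overrides.items():
        if section not in cfg:
            bad.append(section)
            continue
        if not isinstance(values, dict):
            bad.append(section)
            continue
        for key, val in values.items():
            if key not in cfg[section]:
                bad.append(f"{section}.{key}")
            else:
                cfg[section][key] = val
    if bad:
        raise ValidationError("config", f"unknown keys: {', '.join(sorted(bad))}")
    return cfg


def load_config(path: str | Path | None) -> dict:
    """Read a YAML config file (nested sections) and merge with defaults."""
    if path is None:
        return merge_config(None)
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError("config", "config file must hold a mapping")
    return merge_config(data)


def load_image(path: str | Path) -> LesionImage:
    """Decode a PNG/JPEG/TIFF file to an 8-bit RGB :class:`LesionImage`."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read image file {path}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:  # grayscale file: replicate to 3 channels
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return LesionImage(arr, stage_tag="raw", source_id=str(path))


@dataclass
class CaseReport:
    """Everything one classification run produced, stage by stage."""

    source: str
    label: int
    class_name: str
    vote_fraction: float
    features: dict
    stage_paths: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "source": self.source,
                "label": self.label,
                "class_name": self.class_name,
                "vote_fraction": self.vote_fraction,
                "features": self.features,
                "stage_paths": self.stage_paths,
            },
            indent=1,
            sort_keys=True,
        )


def process_image(raw: LesionImage, config: dict | None = None):
    """Run preprocessing, segmentation and feature extraction on one image.

    Returns ``(gray, preprocessed, mask, feature_vector)``.
    """
    cfg = merge_config(config)
    pcfg, scfg = cfg["preprocessing"], cfg["segmentation"]
    gray = pre.to_grayscale(raw)
    log.debug("grayscale %s -> shape %s", raw.source_id, gray.shape)
    dehaired = pre.remove_hair(gray, line_length=pcfg["line_length"],
                               n_angles=pcfg["n_angles"])
    equalized = (
        pre.equalize_histogram(dehaired) if pcfg["equalize"] else dehaired
    )
    preprocessed = LesionImage(equalized, stage_tag="preprocessed",
                               source_id=raw.source_id)
    seg_source = dehaired if scfg["source"] == "dehaired" else equalized
    mask = seg.segment(
        seg_source,
        window=scfg["window"],
        offset=scfg["offset"],
        polarity=scfg["polarity"],
        connectivity=scfg["connectivity"],
    )
    log.debug("segmented %s: %d foreground px", raw.source_id,
              mask.foreground_count)
    fv = extract_features(raw, preprocessed.pixels, gray.pixels, mask)
    return gray, preprocessed, mask, fv


def classify_image(path: str | Path, model: clf.TrainedModel,
                   config: dict | None = None,
                   out_dir: str | Path | None = None) -> CaseReport:
    """Classify one image file end to end.

    With ``out_dir`` set, every intermediate raster (gray, preprocessed,
    mask, overlay) is written as a PNG and its path recorded in the
    report.
    """
    raw = load_image(path)
    cfg = merge_config(config)
    gray, preprocessed, mask, fv = process_image(raw, cfg)
    label, frac, _ = clf.predict(model, fv.to_array())

    stage_paths = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = Path(path).stem
        stages = {
            "gray": gray.pixels,
            "preprocessed": preprocessed.pixels,
            "mask": (mask.pixels * np.uint8(255)),
            "overlay": _overlay(raw.pixels, mask),
        }
        for name, arr in stages.items():
            p = out / f"{stem}_{name}.png"
            iio.imwrite(p, arr)
            stage_paths[name] = str(p)

    return CaseReport(
        source=str(path),
        label=int(label),
        class_name=CLASS_NAMES[int(label)],
        vote_fraction=frac,
        features=fv.to_dict(),
        stage_paths=stage_paths,
    )


def _overlay(rgb: np.ndarray, mask: LesionMask) -> np.ndarray:
    """Raw image with the mask boundary painted green."""
    from scipy import ndimage as ndi

    m = mask.pixels
    boundary = m & ~ndi.binary_erosion(m)
    out = rgb.copy()
    out[boundary] = (0, 255, 0)
    return out


def _feature_table(items, cfg) -> tuple[np.ndarray, np.ndarray]:
    rows, labels = [], []
    for img, _mask, label, _spec in items:
        _, _, _, fv = process_image(img, cfg)
        rows.append(fv.to_array())
        labels.append(label)
    return np.asarray(rows), np.asarray(labels, dtype=int)


def run_experiment(config: dict | None = None, seed: int | None = None,
                   out_dir: str | Path | None = None) -> dict:
    """Full simulate -> train (with k selection) -> evaluate experiment.

    Training and test sets are generated from disjoint seed streams
    derived from the experiment seed.  Returns (and optionally writes, as
    JSON and CSV) a summary with accuracy, sensitivity, specificity, the
    chosen k and the accuracy-vs-k curve.  Identical config + seed gives
    a byte-identical summary.
    """
    cfg = merge_config(config)
    ecfg = cfg["experiment"]
    if seed is None:
        seed = int(ecfg["seed"])
    profile = cfg["simulate"]["profile"]

    log.info("generating %d+%d training and %d+%d test images (seed %d)",
             ecfg["n_train_normal"], ecfg["n_train_malignant"],
             ecfg["n_test_normal"], ecfg["n_test_malignant"], seed)
    train = generate_dataset(ecfg["n_train_normal"], ecfg["n_train_malignant"],
                             profile=profile, seed=seed)
    test = generate_dataset(ecfg["n_test_normal"], ecfg["n_test_malignant"],
                            profile=profile, seed=seed + _TEST_SEED_OFFSET)

    x_train, y_train = _feature_table(train, cfg)
    x_test, y_test = _feature_table(test, cfg)

    ccfg = cfg["classifier"]
    model = clf.fit(x_train, y_train, k=ccfg["k"], k_grid=ccfg["k_grid"],
                    standardize=ccfg["standardize"])
    if ccfg["k"] is None:
        _, curve = clf.select_k(x_train, y_train, ccfg["k_grid"],
                                standardize=ccfg["standardize"])
    else:
        curve = []
    accuracy, sensitivity, specificity, cm = clf.evaluate(model, x_test, y_test)

    summary = {
        "seed": int(seed),
        "n_train": int(len(train)),
        "n_test": int(len(test)),
        "k": int(model.k),
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "confusion_matrix": cm.tolist(),
        "accuracy_curve": [[int(k), float(a)] for k, a in curve],
    }
    log.info("experiment done: accuracy=%.3f sens=%.3f spec=%.3f k=%d",
             accuracy, sensitivity, specificity, model.k)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True)
        )
        flat = {k: v for k, v in summary.items()
                if k not in ("confusion_matrix", "accuracy_curve")}
        pd.DataFrame([flat]).to_csv(out / "summary.csv", index=False)
        clf.save_model(model, out / "model.json")
    return summary


def features_to_frame(feature_rows, labels=None, files=None) -> pd.DataFrame:
    """Tabulate feature vectors with the frozen header."""
    arr = np.atleast_2d(np.asarray(
        [fv.to_array() if isinstance(fv, FeatureVector) else fv
         for fv in feature_rows], dtype=float))
    df = pd.DataFrame(arr, columns=list(FEATURE_NAMES))
    if files is not None:
        df.insert(0, "file", list(files))
    if labels is not None:
        df["label"] = list(labels)
    return df
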