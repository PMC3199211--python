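"""Reading and writing images, masks and fitted models.

Images are PNG/TIFF, 8- or 16-bit, converted to [0,1] floats on read.
Binary masks are single-channel PNGs with 0 = background and 255 = lesion.
Fitted models serialize to versioned JSON files with a documented field
order, so runs are reproducible and models portable across machines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .crf import WeightVector
from .features import RasterImage
from .pp import (
    ClassConditionalSet,
    LabelField,
    LabelSet,
    LdaProjection,
    PPModel,
    PriorDistribution,
)
from .training import TrainingTrace

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "save_pp_model",
    "load_pp_model",
    "save_weights",
    "load_weights",
]

PP_MODEL_FORMAT = "dermcrf-pp-model/1"
WEIGHTS_FORMAT = "dermcrf-crf-weights/1"


def read_image(path: str | Path) -> RasterImage:
    """Read a PNG/TIFF image as sRGB floats in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float64) / 65535.0
    else:
        arr = np.clip(arr.astype(np.float64), 0.0, 1.0)
    return RasterImage(arr, "sRGB")


def write_image(path: str | Path, img: RasterImage) -> None:
    """Write an sRGB image as 8-bit PNG/TIFF."""
    if img.color_space != "sRGB":
        raise ValueError("only sRGB images can be written")
    arr = np.round(np.clip(img.pixels, 0, 1) * 255.0).astype(np.uint8)
    Image.fromarray(arr).save(path)


def write_mask(path: str | Path, field: LabelField, positive_label: int = 1) -> None:
    """Write a binary label field as a 0/255 single-channel PNG."""
    arr = np.where(field.as_image() == positive_label, 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def read_mask(path: str | Path, positive_label: int = 1) -> LabelField:
    """Read a 0/255 mask PNG back into a binary label field."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    labels = np.where(arr >= 128, positive_label, 0)
    return LabelField(labels.ravel(), arr.shape[0], arr.shape[1])


def save_pp_model(path: str | Path, model: PPModel) -> None:
    """Serialize a fitted per-pixel model to versioned JSON.

    Field order: format, labels, Q, mu_global, means, covariances, prior.
    """
    doc = {
        "format": PP_MODEL_FORMAT,
        "labels": list(model.labels.labels),
        "Q": model.projection.Q.tolist(),
        "mu_global": model.projection.mu_global.tolist(),
        "means": model.conditionals.means.tolist(),
        "covariances": model.conditionals.covariances.tolist(),
        "prior": model.prior.p.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_pp_model(path: str | Path) -> PPModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != PP_MODEL_FORMAT:
        raise ValueError(f"unrecognized model format {doc.get('format')!r}")
    return PPModel(
        labels=LabelSet(tuple(doc["labels"])),
        projection=LdaProjection(
            Q=np.array(doc["Q"]), mu_global=np.array(doc["mu_global"])
        ),
        conditionals=ClassConditionalSet(
            means=np.array(doc["means"]),
            covariances=np.array(doc["covariances"]),
        ),
        prior=PriorDistribution(np.array(doc["prior"])),
    )


def save_weights(
    path: str | Path, w: WeightVector, trace: TrainingTrace | None = None
) -> None:
    """Serialize CRF weights (and optionally the training trace CSV).

    The trace, when given, is written next to the weights file with the
    suffix ``.trace.csv``.
    """
    doc = {
        "format": WEIGHTS_FORMAT,
        "w": w.w.tolist(),
        "edge_indices": list(w.edge_indices),
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1))
    if trace is not None:
        trace.to_dataframe().to_csv(path.with_suffix(".trace.csv"))


def load_weights(path: str | Path) -> WeightVector:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != WEIGHTS_FORMAT:
        raise ValueError(f"unrecognized weights format {doc.get('format')!r}")
    return WeightVector(np.array(doc["w"]), tuple(doc["edge_indices"]))
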