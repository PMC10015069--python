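"""Count-by-integration and the MAE/RMSE counting metrics.

The predicted count of an image is the sum of all values of its predicted
density map; because ground-truth maps carry one unit of mass per annotated
mosquito (and downsampling is mass-preserving), the same integral on a
ground-truth map recovers the annotation count.  Accuracy is summarized by
the mean absolute error, MAE = (1/N) sum |Y_i - Y_i^GT|, and robustness by
the root-mean-square error, RMSE = sqrt((1/N) sum |Y_i - Y_i^GT|^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

from .annotations_io import AnnotatedImage
from .density import DensityMap

__all__ = ["EvalResult", "count_from_density", "counting_errors", "evaluate"]


class DensityPredictor(Protocol):
    def predict_density(self, image: np.ndarray) -> DensityMap: ...


@dataclass
class EvalResult:
    """Per-image predicted vs true counts with aggregate MAE and RMSE."""

    per_image: list[tuple[str, float, float]]  # (image_id, predicted, true)
    mae: float
    rmse: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_image,
                            columns=["image_id", "pred_count", "true_count"])


def count_from_density(dmap: DensityMap | np.ndarray) -> float:
    """Object count as the integral (sum) of the density map."""
    values = dmap.values if isinstance(dmap, DensityMap) else np.asarray(dmap)
    if (values < 0).any():
        warnings.warn(
            "density map contains negative values (model without final "
            "ReLU?); summing as-is", RuntimeWarning, stacklevel=2)
    return float(values.sum())


def counting_errors(pred: Sequence[float], true: Sequence[float]
                    ) -> tuple[float, float]:
    """(MAE, RMSE) over paired per-image counts."""
    pred = np.asarray(pred, dtype=np.float64)
    true = np.asarray(true, dtype=np.float64)
    if pred.shape != true.shape:
        raise ValueError("pred and true counts differ in length")
    if pred.size == 0:
        raise ValueError("no images to evaluate")
    err = np.abs(pred - true)
    return float(err.mean()), float(np.sqrt(np.mean(err ** 2)))


def evaluate(predictor: DensityPredictor | Callable[[np.ndarray], DensityMap],
             images: Iterable[AnnotatedImage]) -> EvalResult:
    """Run the predictor on each full image, integrate the predicted map,
    and compare with the annotation count."""
    predict = predictor.predict_density if hasattr(predictor, "predict_density") \
        else predictor
    per_image: list[tuple[str, float, float]] = []
    for img in images:
        pred_count = count_from_density(predict(img.image))
        per_image.append((img.image_id, pred_count, float(img.count)))
    if not per_image:
        raise ValueError("no images to evaluate")
    mae, rmse = counting_errors([p for _, p, _ in per_image],
                                [t for _, _, t in per_image])
    return EvalResult(per_image=per_image, mae=mae, rmse=rmse)
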