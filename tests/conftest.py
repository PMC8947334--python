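"""Shared fixtures: phantom cases and lightweight oracle predictors."""

from __future__ import annotations

import numpy as np
import pytest

import thrombseg as ts
from thrombseg import nn


@pytest.fixture(scope="session")
def default_case() -> ts.PhantomCase:
    """One deterministic phantom with the default spec."""
    return ts.generate_case(ts.PhantomSpec(), seed=123)


@pytest.fixture(scope="session")
def zero_jitter_case() -> ts.PhantomCase:
    from dataclasses import replace

    return ts.generate_case(
        replace(ts.PhantomSpec(), detection_jitter_mm=0.0), seed=5
    )


def random_blob_mask(rng: np.random.Generator, shape=(12, 12, 12),
                     p: float = 0.15) -> np.ndarray:
    """Random non-empty boolean mask (thresholded smoothed noise)."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=1.5)
    mask = field > np.quantile(field, 1 - p)
    if not mask.any():
        mask[tuple(rng.integers(0, s) for s in shape)] = True
    return mask


class IntensityOracleModel:
    """Hand-crafted stand-in for a trained network.

    Thresholds the preprocessed intensities directly: a voxel is thrombus
    when NCCT is hyperdense and CTA lacks contrast.  Quacks like a
    :class:`~thrombseg.nets.SegNet` (``cfg`` + ``forward``) so the pipeline
    can run end-to-end without any training.
    """

    def __init__(self) -> None:
        self.cfg = ts.NetConfig(variant="unet2ch", depth=1, base_width=1)

    def forward(self, ncct: np.ndarray, cta: np.ndarray | None = None) -> nn.Tensor:
        from scipy import ndimage

        hyperdense = np.asarray(ncct) > 0.42  # ~42 HU on the (0, 100) window
        no_contrast = np.asarray(cta) < 0.45  # ~112 HU on the (0, 250) window
        cand = hyperdense & no_contrast
        # isolated noise voxels have few positive neighbours; tube voxels many
        neighbours = ndimage.convolve(cand.astype(np.int8), np.ones((3, 3, 3)),
                                      mode="constant") - cand
        keep = cand & (neighbours >= 3)
        logits = np.where(keep, 10.0, -10.0)
        return nn.Tensor(logits[None])


@pytest.fixture(scope="session")
def oracle_model() -> IntensityOracleModel:
    return IntensityOracleModel()


def gt_clipped_predictor(gt: np.ndarray):
    """Stub predictor returning the ground truth restricted to the box."""

    def predict(box: ts.BoundingBox) -> np.ndarray:
        return box.extract(gt)

    return predict
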