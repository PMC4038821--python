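"""Nuclear area and integrated optical density (IOD) from delineated nuclei.

IOD sums the deconvolved hematoxylin optical density over a nucleus mask and
serves as a DNA-content proxy: the synthetic renderer makes hematoxylin
density stoichiometric to DNA content, so recovery is directly testable.
Per tumor, a fixed number of nuclei (15 by default) are measured and
summarised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from prolifmark.errors import InvalidParameterError
from prolifmark.ihc_counting import color_deconvolve
from prolifmark.synthetic_imaging import StainVectors, SyntheticField

__all__ = [
    "NucleusMeasurement",
    "nucleus_iod",
    "tumor_iod",
    "sample_nuclei_masks",
]

DEFAULT_NUCLEI_PER_TUMOR = 15


@dataclass(frozen=True)
class NucleusMeasurement:
    """Area (px^2) and hematoxylin IOD (summed OD, arbitrary units) of one nucleus."""

    nucleus_id: int
    area_px2: int
    iod: float


def nucleus_iod(
    rgb: np.ndarray,
    mask: np.ndarray,
    vectors: StainVectors | None = None,
    background_intensity=(245.0, 245.0, 245.0),
    nucleus_id: int = 0,
) -> NucleusMeasurement:
    """Measure one delineated nucleus.

    ``iod`` is the sum of the deconvolved hematoxylin channel (floored at 0)
    over the mask pixels; ``area`` is the mask pixel count.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != np.asarray(rgb).shape[:2]:
        raise InvalidParameterError("mask shape must match the raster")
    area = int(mask.sum())
    if area == 0:
        raise InvalidParameterError("nucleus mask is empty")
    hema, _, _ = color_deconvolve(rgb, vectors or StainVectors(), background_intensity)
    return NucleusMeasurement(nucleus_id=nucleus_id, area_px2=area,
                              iod=float(hema[mask].sum()))


def tumor_iod(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    vectors: StainVectors | None = None,
    background_intensity=(245.0, 245.0, 245.0),
    expected_n: int = DEFAULT_NUCLEI_PER_TUMOR,
    aggregator: Callable[[np.ndarray], float] = np.mean,
) -> float:
    """Per-tumor nuclear IOD: aggregate of per-nucleus IODs.

    ``pairs`` holds (rgb field, nucleus mask) tuples, one per delineated
    nucleus; fields may repeat when several nuclei come from one image. A
    count other than ``expected_n`` warns but proceeds. The mean is the
    default aggregator (median via ``aggregator=np.median``); it is
    permutation-invariant by construction.
    """
    pairs = list(pairs)
    if not pairs:
        raise InvalidParameterError("no nuclei supplied")
    if len(pairs) != expected_n:
        warnings.warn(
            f"expected {expected_n} delineated nuclei, got {len(pairs)}; proceeding",
            stacklevel=2,
        )
    iods = [
        nucleus_iod(rgb, mask, vectors, background_intensity, nucleus_id=i).iod
        for i, (rgb, mask) in enumerate(pairs)
    ]
    return float(aggregator(np.asarray(iods)))


def sample_nuclei_masks(field: SyntheticField, n: int,
                        rng: np.random.Generator) -> list[np.ndarray]:
    """Select ``n`` distinct ground-truth nucleus masks uniformly at random.

    Stands in for manual pen-tablet delineation: each returned boolean mask
    is one nucleus's region of the field's label mask.
    """
    labels = [r.label for r in field.records]
    if n > len(labels):
        raise InvalidParameterError(
            f"field has {len(labels)} nuclei, cannot sample {n}"
        )
    chosen = rng.choice(np.asarray(labels), size=n, replace=False)
    return [field.labels == lab for lab in chosen]
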