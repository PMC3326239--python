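"""Common estimator interface for all segmenters.

Every segmentation method is a scikit-learn style estimator: constructor
arguments are hyperparameters (visible to ``get_params``/``set_params`` and
clonable), ``fit`` consumes one :class:`ImageVolume` plus optional per-image
context (seed point, search region, background ROI) and exposes the result
as fitted attributes — at minimum ``mask_`` (a :class:`BinaryMask`).
``fit_predict`` returns the mask directly.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .regions import default_seed_point
from .volume import BinaryMask, ImageVolume

__all__ = ["BaseSegmenter"]


class BaseSegmenter(BaseEstimator):
    """Base class: input validation and the fit/fit_predict contract."""

    #: set by subclasses that cannot run without a background ROI
    _requires_background = False

    def fit(
        self,
        img: ImageVolume,
        y=None,
        *,
        seed_point=None,
        search_region: BinaryMask | None = None,
        background_mask: BinaryMask | None = None,
    ):
        if not isinstance(img, ImageVolume):
            raise TypeError("fit expects an ImageVolume")
        region = None
        if search_region is not None:
            if search_region.shape != img.shape:
                raise ValueError("search_region shape mismatch")
            region = search_region.values
        bkg = None
        if background_mask is not None:
            if background_mask.shape != img.shape:
                raise ValueError("background_mask shape mismatch")
            bkg = background_mask.values
        if self._requires_background and bkg is None:
            raise ValueError(
                f"{type(self).__name__} requires a background_mask"
            )
        if seed_point is None:
            seed_point = default_seed_point(img, region)
        else:
            seed_point = tuple(int(round(c)) for c in seed_point)
            if any(s < 0 or s >= n for s, n in zip(seed_point, img.shape)):
                raise ValueError(f"seed_point {seed_point} outside the image")
        self._fit(img, seed_point, region, bkg)
        return self

    def fit_predict(self, img: ImageVolume, y=None, **kwargs) -> BinaryMask:
        return self.fit(img, **kwargs).mask_

    # subclasses implement
    def _fit(self, img, seed_point, region, bkg):  # pragma: no cover - abstract
        raise NotImplementedError
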