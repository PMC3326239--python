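"""The five adaptive SUV-thresholding segmenters.

* ``PercentMaxThreshold`` — fixed percentage (default 40%) of SUV_max.
* ``BiehlThreshold`` — volume-adaptive: %T = 59.1 - 18.5 * log10(V [cm^3]).
* ``BlackThreshold`` — uptake-adaptive: T = 0.307 * mean target SUV + 0.588.
* ``NestleThreshold`` — T = beta * I_mean(70% isocontour) + I_bkg, beta=0.15.
* ``SchaeferThreshold`` — contrast-oriented:
  T / SUV_max = (a * SUV_mean(70%) + b * BKG) / SUV_max with size-dependent
  coefficients (a = b = 0.50 for equivalent diameter >= 3 cm, a = 0.67,
  b = 0.60 below).

Biehl and Black define the threshold through statistics of the thresholded
region itself; that circular dependence is resolved by Picard fixed-point
iteration started from the 40% SUV_max mask, with a period-2 oscillation
guard (midpoint threshold, ``converged_ = False``).  The published
coefficients are scanner-dependent and exposed as estimator parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import BaseSegmenter
from .regions import (
    EmptyMaskError,
    isocontour_mean,
    mask_from_threshold,
    suv_max,
)
from .volume import BinaryMask, ImageVolume

__all__ = [
    "ThresholdResult",
    "biehl_percent_threshold",
    "black_threshold",
    "nestle_threshold",
    "schaefer_fraction",
    "PercentMaxThreshold",
    "BiehlThreshold",
    "BlackThreshold",
    "NestleThreshold",
    "SchaeferThreshold",
    "segment_pct_max",
    "segment_biehl",
    "segment_black",
    "segment_nestle",
    "segment_schaefer",
]


# ---------------------------------------------------------------------------
# The published threshold formulas (pure functions)


def biehl_percent_threshold(
    volume_cm3: float, intercept: float = 59.1, slope: float = 18.5
) -> float:
    """Volume-adaptive percent threshold: %T = 59.1 - 18.5 log10(V)."""
    if volume_cm3 <= 0:
        raise ValueError("volume must be positive")
    return intercept - slope * np.log10(volume_cm3)


def black_threshold(
    mean_target_suv: float, gain: float = 0.307, offset: float = 0.588
) -> float:
    """Uptake-adaptive threshold: T = 0.307 * mean target SUV + 0.588 (SUV)."""
    return gain * mean_target_suv + offset


def nestle_threshold(i_mean: float, i_bkg: float, beta: float = 0.15) -> float:
    """T = beta * I_mean + I_bkg with I_mean from the 70% isocontour."""
    return beta * i_mean + i_bkg


def schaefer_fraction(
    suv_mean_70: float, bkg: float, suv_max_val: float, a: float, b: float
) -> float:
    """Fraction of SUV_max: (a * SUV_mean(70%) + b * BKG) / SUV_max."""
    if suv_max_val <= 0:
        raise ValueError("SUV_max must be positive")
    return (a * suv_mean_70 + b * bkg) / suv_max_val


@dataclass
class ThresholdResult:
    """Final threshold, mask and fixed-point diagnostics of one run."""

    mask: BinaryMask
    threshold: float
    fixed_point_iterations: int = 0
    converged: bool = True


def _check_flat(img: ImageVolume, region) -> float:
    vals = img.values if region is None else img.values[region]
    if vals.size == 0:
        raise ValueError("empty search region")
    if vals.max() == vals.min():
        raise ValueError("flat image: thresholding is degenerate")
    return float(vals.max())


class _ThresholdSegmenter(BaseSegmenter):
    """Shared fitted attributes for the thresholding family."""

    def _finish(self, img, result: ThresholdResult):
        self.mask_ = result.mask
        self.threshold_ = result.threshold
        self.n_iter_ = result.fixed_point_iterations
        self.converged_ = result.converged
        self.result_ = result


class PercentMaxThreshold(_ThresholdSegmenter):
    """Threshold at ``fraction`` (default 0.40) of SUV_max."""

    def __init__(self, fraction: float = 0.40):
        self.fraction = fraction

    def _fit(self, img, seed_point, region, bkg):
        if not (0.0 < self.fraction < 1.0):
            raise ValueError("fraction must be in (0, 1)")
        mx = _check_flat(img, region)
        t = self.fraction * mx
        self._finish(img, ThresholdResult(mask_from_threshold(img, t, seed_point, region), t))


def _fixed_point(img, seed_point, region, t0, update, tol, max_iter):
    """Damped Picard iteration threshold <-> region statistic.

    ``update(mask)`` maps the current mask to the next threshold.  Stops
    when |dT| < tol; a period-2 cycle returns the midpoint threshold with
    converged=False.
    """
    t = t0
    mask = mask_from_threshold(img, t, seed_point, region)
    history = [t]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if mask.is_empty():
            break
        t_new = update(mask)
        if abs(t_new - t) < tol:
            t = t_new
            mask = mask_from_threshold(img, t, seed_point, region)
            converged = True
            break
        if len(history) >= 2 and abs(t_new - history[-2]) < tol:
            t = 0.5 * (t + t_new)  # period-2 oscillation: take the midpoint
            mask = mask_from_threshold(img, t, seed_point, region)
            converged = False
            break
        t = t_new
        history.append(t)
        mask = mask_from_threshold(img, t, seed_point, region)
    return ThresholdResult(mask, t, it, converged)


class BiehlThreshold(_ThresholdSegmenter):
    """Volume-adaptive log-linear threshold, solved as a fixed point.

    ``mode="single_pass"`` applies the formula once to the 40% SUV_max
    initial mask instead of iterating (the published description leaves the
    choice open).
    """

    def __init__(
        self,
        intercept: float = 59.1,
        slope: float = 18.5,
        init_fraction: float = 0.40,
        mode: str = "fixed_point",
        max_iter: int = 50,
        tol_fraction: float = 0.001,
    ):
        self.intercept = intercept
        self.slope = slope
        self.init_fraction = init_fraction
        self.mode = mode
        self.max_iter = max_iter
        self.tol_fraction = tol_fraction

    def _fit(self, img, seed_point, region, bkg):
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        mx = _check_flat(img, region)

        def update(mask: BinaryMask) -> float:
            pct = biehl_percent_threshold(mask.volume_cm3, self.intercept, self.slope)
            return np.clip(pct, 1.0, 99.0) / 100.0 * mx

        t0 = self.init_fraction * mx
        if self.mode == "single_pass":
            mask0 = mask_from_threshold(img, t0, seed_point, region)
            t = update(mask0)
            res = ThresholdResult(mask_from_threshold(img, t, seed_point, region), t, 1, True)
        else:
            res = _fixed_point(
                img, seed_point, region, t0, update, self.tol_fraction * mx, self.max_iter
            )
        self._finish(img, res)


class BlackThreshold(_ThresholdSegmenter):
    """Mean-uptake-adaptive threshold, solved as a fixed point."""

    def __init__(
        self,
        gain: float = 0.307,
        offset: float = 0.588,
        init_fraction: float = 0.40,
        mode: str = "fixed_point",
        max_iter: int = 50,
        tol_fraction: float = 0.001,
    ):
        self.gain = gain
        self.offset = offset
        self.init_fraction = init_fraction
        self.mode = mode
        self.max_iter = max_iter
        self.tol_fraction = tol_fraction

    def _fit(self, img, seed_point, region, bkg):
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        mx = _check_flat(img, region)

        def update(mask: BinaryMask) -> float:
            mean_suv = float(img.values[mask.values].mean())
            return black_threshold(mean_suv, self.gain, self.offset)

        t0 = self.init_fraction * mx
        if self.mode == "single_pass":
            mask0 = mask_from_threshold(img, t0, seed_point, region)
            t = update(mask0)
            res = ThresholdResult(mask_from_threshold(img, t, seed_point, region), t, 1, True)
        else:
            res = _fixed_point(
                img, seed_point, region, t0, update, self.tol_fraction * mx, self.max_iter
            )
        self._finish(img, res)


class NestleThreshold(_ThresholdSegmenter):
    """T = beta * I_mean(70% isocontour) + I_bkg; single pass.

    I_mean is defined from the 70% isocontour, not from the output mask,
    so no fixed point arises.  Requires a background ROI.
    """

    _requires_background = True

    def __init__(self, beta: float = 0.15, iso_fraction: float = 0.70):
        self.beta = beta
        self.iso_fraction = iso_fraction

    def _fit(self, img, seed_point, region, bkg):
        if not (0.0 < self.iso_fraction < 1.0):
            raise ValueError("iso_fraction must be in (0, 1)")
        _check_flat(img, region)
        i_mean = isocontour_mean(img, self.iso_fraction, seed_point, region)
        i_bkg = float(img.values[bkg].mean())
        t = nestle_threshold(i_mean, i_bkg, self.beta)
        self.i_mean_ = i_mean
        self.i_bkg_ = i_bkg
        self._finish(img, ThresholdResult(mask_from_threshold(img, t, seed_point, region), t, 1, True))


def _equivalent_diameter_cm(mask: BinaryMask) -> float:
    v_mm3 = mask.volume_cm3 * 1000.0
    return 2.0 * (3.0 * v_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0) / 10.0


class SchaeferThreshold(_ThresholdSegmenter):
    """Contrast-oriented threshold with size-dependent coefficients.

    The size class (equivalent-sphere diameter vs ``size_cut_cm``) is first
    estimated from the 40% SUV_max mask and re-estimated once from the
    resulting mask (two passes at most).  A fraction >= 1 yields the empty-
    mask signal.
    """

    _requires_background = True

    def __init__(
        self,
        a_large: float = 0.50,
        b_large: float = 0.50,
        a_small: float = 0.67,
        b_small: float = 0.60,
        size_cut_cm: float = 3.0,
        iso_fraction: float = 0.70,
        init_fraction: float = 0.40,
    ):
        self.a_large = a_large
        self.b_large = b_large
        self.a_small = a_small
        self.b_small = b_small
        self.size_cut_cm = size_cut_cm
        self.iso_fraction = iso_fraction
        self.init_fraction = init_fraction

    def _coeffs(self, large: bool):
        return (self.a_large, self.b_large) if large else (self.a_small, self.b_small)

    def _fit(self, img, seed_point, region, bkg):
        for c in (self.a_large, self.b_large, self.a_small, self.b_small):
            if c <= 0:
                raise ValueError("Schaefer coefficients must be positive")
        mx = _check_flat(img, region)
        mean70 = isocontour_mean(img, self.iso_fraction, seed_point, region)
        bkg_mean = float(img.values[bkg].mean())
        init = mask_from_threshold(img, self.init_fraction * mx, seed_point, region)
        large = _equivalent_diameter_cm(init) >= self.size_cut_cm
        mask, t, frac = init, self.init_fraction * mx, None
        passes = 0
        for passes in range(1, 3):
            a, b = self._coeffs(large)
            frac = schaefer_fraction(mean70, bkg_mean, mx, a, b)
            if frac >= 1.0:
                mask = BinaryMask(np.zeros(img.shape, dtype=bool), img.spacing)
                t = frac * mx
                break
            t = frac * mx
            mask = mask_from_threshold(img, t, seed_point, region)
            new_large = _equivalent_diameter_cm(mask) >= self.size_cut_cm
            if new_large == large:
                break
            large = new_large
        self.fraction_ = frac
        self.size_class_large_ = large
        self.suv_mean_70_ = mean70
        self.bkg_ = bkg_mean
        self._finish(img, ThresholdResult(mask, t, passes, True))


# ---------------------------------------------------------------------------
# Functional wrappers


def segment_pct_max(img, fraction=0.40, seed_point=None, **kw) -> ThresholdResult:
    est = PercentMaxThreshold(fraction).fit(img, seed_point=seed_point, **kw)
    return est.result_


def segment_biehl(img, seed_point=None, **kw) -> ThresholdResult:
    params = {k: kw.pop(k) for k in list(kw) if k in BiehlThreshold().get_params()}
    return BiehlThreshold(**params).fit(img, seed_point=seed_point, **kw).result_


def segment_black(img, seed_point=None, **kw) -> ThresholdResult:
    params = {k: kw.pop(k) for k in list(kw) if k in BlackThreshold().get_params()}
    return BlackThreshold(**params).fit(img, seed_point=seed_point, **kw).result_


def segment_nestle(img, seed_point=None, **kw) -> ThresholdResult:
    params = {k: kw.pop(k) for k in list(kw) if k in NestleThreshold().get_params()}
    return NestleThreshold(**params).fit(img, seed_point=seed_point, **kw).result_


def segment_schaefer(img, seed_point=None, **kw) -> ThresholdResult:
    params = {k: kw.pop(k) for k in list(kw) if k in SchaeferThreshold().get_params()}
    return SchaeferThreshold(**params).fit(img, seed_point=seed_point, **kw).result_
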