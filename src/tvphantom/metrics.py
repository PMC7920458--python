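"""Quantitative image-quality analysis: ROI statistics, CNR, COV and the
replicated four-arm study.

CNR (contrast-to-noise ratio) between a target ROI "A" and a background
ROI "B":

    CNR = (H_A - H_B) / sqrt(sigma_A^2 + sigma_B^2)

COV (coefficient of variation) within a nominally uniform ROI:

    COV = sigma_A / H_A

where H and sigma are the ROI mean and sample standard deviation. Higher
CNR means better detectability; lower COV means less residual noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MetricUndefinedError
from .filters import WindowSpec, median_filter, wiener_filter
from .image import Image
from .phantom import (
    BIAS_SEED_OFFSET,
    AcquisitionProfile,
    NoiseSpec,
    PhantomSpec,
    add_gaussian_noise,
    apply_bias_field,
    apply_system_blur,
    render_phantom,
)
from .tv import TVParams, denoise_tv

logger = logging.getLogger(__name__)

ARM_NAMES = ("noise", "wiener", "median", "tv")

#: Stable column order of the tidy metrics table.
METRIC_COLUMNS = ("profile", "arm", "replicate", "cnr", "cov")


@dataclass(frozen=True)
class RoiSpec:
    """Circular region of interest.

    A pixel belongs to the ROI iff its centre (integer row/col coordinates)
    lies within ``radius_px`` of the ROI centre, inclusive — a deterministic
    membership rule, so pixel counts are platform-independent.
    """

    center_row: float
    center_col: float
    radius_px: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ConfigurationError(f"radius_px must be > 0, got {self.radius_px}")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        # the image extends half a pixel beyond the outermost pixel centres
        if (self.center_row - self.radius_px < -0.5
                or self.center_row + self.radius_px > shape[0] - 0.5
                or self.center_col - self.radius_px < -0.5
                or self.center_col + self.radius_px > shape[1] - 0.5):
            raise ConfigurationError(
                f"ROI {self.label or '?'} (centre ({self.center_row}, "
                f"{self.center_col}), radius {self.radius_px}) is not fully "
                f"inside image of shape {shape}"
            )
        rr = np.arange(shape[0])[:, np.newaxis] - self.center_row
        cc = np.arange(shape[1])[np.newaxis, :] - self.center_col
        return rr * rr + cc * cc <= self.radius_px**2


@dataclass(frozen=True)
class RoiStats:
    """Mean H, sample standard deviation sigma, and pixel count of an ROI."""

    mean: float
    sd: float
    n_pixels: int


def roi_stats(img: Image, roi: RoiSpec) -> RoiStats:
    """Mean and sample (n-1 denominator) standard deviation over ROI pixels."""
    values = img.values[roi.mask(img.shape)]
    if values.size < 2:
        raise ConfigurationError(
            f"ROI {roi.label or '?'} covers {values.size} pixel(s); "
            "need >= 2 for a standard deviation"
        )
    return RoiStats(mean=float(values.mean()),
                    sd=float(values.std(ddof=1)),
                    n_pixels=int(values.size))


def cnr(img: Image, roi_a: RoiSpec, roi_b: RoiSpec) -> float:
    """Contrast-to-noise ratio (H_A - H_B) / sqrt(sd_A^2 + sd_B^2).

    The sign is preserved (no absolute value) so inverted-contrast
    configurations are detectable. The two ROIs must be disjoint.
    """
    mask_a = roi_a.mask(img.shape)
    mask_b = roi_b.mask(img.shape)
    if np.any(mask_a & mask_b):
        raise ConfigurationError("CNR requires disjoint ROIs")
    a = roi_stats(img, roi_a)
    b = roi_stats(img, roi_b)
    denom = math.hypot(a.sd, b.sd)
    if denom == 0:
        raise MetricUndefinedError(
            "CNR undefined: both ROI standard deviations are zero"
        )
    return (a.mean - b.mean) / denom


def cov(img: Image, roi_a: RoiSpec) -> float:
    """Coefficient of variation sigma_A / H_A within one ROI."""
    a = roi_stats(img, roi_a)
    if a.mean == 0:
        raise MetricUndefinedError("COV undefined: ROI mean is zero")
    return a.sd / a.mean


# ---------------------------------------------------------------------------
# replicated study


@dataclass
class MetricsTable:
    """Per-replicate CNR/COV records with per-(profile, arm) aggregates.

    ``rows`` is tidy (one row per profile/arm/replicate);
    ``aggregates`` holds replicate mean and sample sd per profile/arm and is
    always recomputable from ``rows`` exactly.
    """

    rows: pd.DataFrame
    n_replicates: int

    @property
    def aggregates(self) -> pd.DataFrame:
        return aggregate_metrics(self.rows)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")

    def summary_dict(self) -> dict:
        agg = self.aggregates.reset_index()
        return {
            f"{r.profile}/{r.arm}": {
                "cnr_mean": r.cnr_mean, "cnr_sd": r.cnr_sd,
                "cov_mean": r.cov_mean, "cov_sd": r.cov_sd,
                "n": int(r.n),
            }
            for r in agg.itertuples()
        }


def aggregate_metrics(rows: pd.DataFrame) -> pd.DataFrame:
    """Replicate mean and sample sd of CNR/COV per (profile, arm)."""
    g = rows.groupby(["profile", "arm"], sort=False)
    agg = g.agg(
        cnr_mean=("cnr", "mean"),
        cnr_sd=("cnr", lambda s: s.std(ddof=1)),
        cov_mean=("cov", "mean"),
        cov_sd=("cov", lambda s: s.std(ddof=1)),
        n=("cnr", "size"),
    )
    return agg


def _make_arm_runners(
    arms: Mapping[str, object],
) -> dict[str, Callable[[Image], Image]]:
    """Map arm names to image -> image callables, validating the names."""
    runners: dict[str, Callable[[Image], Image]] = {}
    for name, cfg in arms.items():
        if name == "noise":
            runners[name] = lambda im: im
        elif name == "wiener":
            if isinstance(cfg, tuple):
                win, nv = cfg
            else:
                win, nv = (cfg or WindowSpec()), None
            runners[name] = lambda im, w=win, v=nv: wiener_filter(im, w, v)
        elif name == "median":
            win = cfg or WindowSpec()
            runners[name] = lambda im, w=win: median_filter(im, w)
        elif name == "tv":
            params = cfg or TVParams()
            runners[name] = lambda im, p=params: denoise_tv(im, p).image
        else:
            raise ConfigurationError(
                f"unknown arm {name!r}: expected one of {ARM_NAMES}"
            )
    return runners


def default_arms(tv: TVParams | None = None,
                 wiener_window: WindowSpec | None = None,
                 wiener_noise_variance: float | None = None,
                 median_window: WindowSpec | None = None) -> dict[str, object]:
    """The study's four arms: unfiltered noise, Wiener, median, TV."""
    return {
        "noise": None,
        "wiener": (wiener_window or WindowSpec(), wiener_noise_variance),
        "median": median_window or WindowSpec(),
        "tv": tv or TVParams(),
    }


def replicate_study(
    phantom: PhantomSpec,
    profiles: list[AcquisitionProfile],
    noise: NoiseSpec,
    arms: Mapping[str, object],
    rois: tuple[RoiSpec, RoiSpec],
    n_replicates: int = 10,
) -> MetricsTable:
    """Run the replicated four-arm study and tabulate CNR/COV.

    For each profile the clean phantom is rendered once, blurred with the
    profile PSF and multiplied by the profile's bias field (seeded from the
    base seed); then for each replicate fresh Gaussian noise is added with
    seed ``noise.seed + replicate`` and every arm's filter is applied and
    scored on the fixed ROI pair. A failing cell is logged and recorded with
    NaN metrics rather than silently dropped.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    roi_a, roi_b = rois
    runners = _make_arm_runners(arms)
    clean = render_phantom(phantom)
    records: list[dict] = []
    for profile in profiles:
        blurred = apply_system_blur(clean, profile.psf_fwhm_mm)
        biased = apply_bias_field(blurred, profile,
                                  seed=noise.seed + BIAS_SEED_OFFSET)
        for rep in range(n_replicates):
            rep_noise = NoiseSpec(variance=noise.variance, mean=noise.mean,
                                  seed=noise.seed + rep)
            noisy = add_gaussian_noise(biased, rep_noise)
            for arm_name, run in runners.items():
                rec = {"profile": profile.name, "arm": arm_name,
                       "replicate": rep, "cnr": np.nan, "cov": np.nan}
                try:
                    filtered = run(noisy)
                    rec["cnr"] = cnr(filtered, roi_a, roi_b)
                    rec["cov"] = cov(filtered, roi_a)
                except Exception:  # noqa: BLE001 - cell marked missing, run continues
                    logger.exception(
                        "metrics failed for profile=%s arm=%s replicate=%d",
                        profile.name, arm_name, rep,
                    )
                records.append(rec)
    rows = pd.DataFrame.from_records(records, columns=list(METRIC_COLUMNS))
    return MetricsTable(rows=rows, n_replicates=n_replicates)
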