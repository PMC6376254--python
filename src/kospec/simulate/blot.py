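"""Synthetic western-blot renderer with closed-form ground truth.

Blots are rendered as float images: each band is a Gaussian in the vertical
(migration) axis, uniform across the lane width, placed at the row implied by
log-linear ladder calibration of its molecular weight.  A smooth polynomial
background and additive Gaussian (optionally Poisson) noise are layered on
top.  The per-band ground-truth area of the lane *profile* has the closed
form ``amplitude * sigma_px * sqrt(2*pi)``, which is what the densitometry
oracle tests integrate against.

Row 0 is the top of the gel (highest molecular weight).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import sqrt, tau
from typing import Sequence

import numpy as np
import pandas as pd

from ..densitometry import LadderCalibration, calibrate_ladder

CONTROL = "control"
KO = "ko"


class BlotSpecError(ValueError):
    """Invalid blot specification."""


@dataclass(frozen=True)
class BandSpec:
    """One band: molecular weight, profile amplitude, vertical Gaussian spread."""

    mw_kda: float
    amplitude: float
    sigma_px: float

    def __post_init__(self) -> None:
        if self.mw_kda <= 0:
            raise BlotSpecError("band molecular weight must be positive")
        if self.amplitude < 0:
            raise BlotSpecError("band amplitude must be >= 0")
        if self.sigma_px <= 0:
            raise BlotSpecError("band sigma_px must be > 0")

    @property
    def true_area(self) -> float:
        """Closed-form integrated profile area: amplitude * sigma * sqrt(2*pi)."""
        return self.amplitude * self.sigma_px * sqrt(tau)


@dataclass(frozen=True)
class LaneSpec:
    """An ordered lane: experimental condition plus its bands."""

    condition: str
    bands: tuple[BandSpec, ...]
    lane_id: str = ""

    def __post_init__(self) -> None:
        if self.condition not in (CONTROL, KO):
            raise BlotSpecError(f"condition must be {CONTROL!r} or {KO!r}")
        object.__setattr__(self, "bands", tuple(self.bands))


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian sd plus optional Poisson shot-noise scaling.

    ``poisson_scale`` is the expected photon/grain count per intensity unit;
    0 disables shot noise.
    """

    gaussian_sd: float = 0.0
    poisson_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0 or self.poisson_scale < 0:
            raise BlotSpecError("noise parameters must be >= 0")


@dataclass(frozen=True)
class BlotSpec:
    """Full description of a synthetic blot; ``seed`` fixes the rendering."""

    lanes: tuple[LaneSpec, ...]
    ladder: tuple[tuple[float, float], ...]  # (mw_kda, row) anchors
    shape: tuple[int, int] = (360, 130)
    lane_centers: tuple[int, ...] = (40, 90)
    lane_width_px: int = 20
    background_coeffs: tuple[tuple[float, ...], ...] = ((0.0,),)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lanes", tuple(self.lanes))
        object.__setattr__(self, "ladder", tuple(tuple(a) for a in self.ladder))
        object.__setattr__(self, "lane_centers", tuple(int(c) for c in self.lane_centers))
        if len(self.lanes) != len(self.lane_centers):
            raise BlotSpecError("one x-center required per lane")
        centers = np.asarray(self.lane_centers)
        if np.any(np.diff(centers) <= 0):
            raise BlotSpecError("lane x-centers must be strictly increasing")
        if np.any(np.diff(centers) < self.lane_width_px):
            raise BlotSpecError("lanes overlap at the stated width")
        half = self.lane_width_px // 2
        if centers.size and (centers[0] - half < 0 or
                             centers[-1] - half + self.lane_width_px > self.shape[1]):
            raise BlotSpecError("lane sampling bands exceed image width")
        ladder = sorted(self.ladder, key=lambda a: a[1])  # by row
        mws = [a[0] for a in ladder]
        if len(mws) < 2:
            raise BlotSpecError("ladder needs at least 2 anchor bands")
        if any(m2 >= m1 for m1, m2 in zip(mws, mws[1:])):
            raise BlotSpecError("ladder MW must strictly decrease with row (top = high MW)")

    def calibration(self) -> LadderCalibration:
        """Log-linear row<->MW calibration implied by the ladder anchors."""
        return calibrate_ladder([(row, mw) for mw, row in self.ladder])


def _background(shape: tuple[int, int], coeffs: Sequence[Sequence[float]]) -> np.ndarray:
    c = np.atleast_2d(np.asarray(coeffs, dtype=float))
    if not np.any(c):
        return np.zeros(shape)
    h, w = shape
    yn = np.linspace(0.0, 1.0, h)[:, None]
    xn = np.linspace(0.0, 1.0, w)[None, :]
    return np.polynomial.polynomial.polyval2d(
        np.broadcast_to(yn, shape), np.broadcast_to(xn, shape), c
    )


def render_blot(spec: BlotSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a blot image and its ground-truth band table.

    Returns a float image of ``spec.shape`` and a DataFrame with one row per
    (lane, band): lane_id, condition, mw_kda, row (sub-pixel band center),
    amplitude, sigma_px and the closed-form true_area.  A band whose MW falls
    outside the ladder-calibratable range is rejected.
    """
    cal = spec.calibration()
    mw_lo, mw_hi = cal.mw_range
    h, w = spec.shape
    image = _background((h, w), spec.background_coeffs)
    rows_axis = np.arange(h, dtype=float)
    half = spec.lane_width_px // 2

    records = []
    for i, (lane, center) in enumerate(zip(spec.lanes, spec.lane_centers)):
        lane_id = lane.lane_id or f"lane{i}"
        x0 = center - half
        x1 = x0 + spec.lane_width_px
        profile = np.zeros(h)
        for j, band in enumerate(lane.bands):
            if not (mw_lo <= band.mw_kda <= mw_hi):
                raise BlotSpecError(
                    f"band {band.mw_kda} kDa in lane {lane_id!r} is outside the "
                    f"ladder range [{mw_lo:g}, {mw_hi:g}] kDa"
                )
            row0 = float(cal.row_of(band.mw_kda))
            profile += band.amplitude * np.exp(-0.5 * ((rows_axis - row0) / band.sigma_px) ** 2)
            records.append(
                dict(
                    lane_id=lane_id,
                    condition=lane.condition,
                    band=j,
                    mw_kda=band.mw_kda,
                    row=row0,
                    amplitude=band.amplitude,
                    sigma_px=band.sigma_px,
                    true_area=band.true_area,
                )
            )
        image[:, x0:x1] += profile[:, None]

    rng = np.random.default_rng(spec.seed)
    if spec.noise.poisson_scale > 0:
        image = rng.poisson(np.clip(image, 0, None) * spec.noise.poisson_scale) / (
            spec.noise.poisson_scale
        )
    if spec.noise.gaussian_sd > 0:
        image = image + rng.normal(0.0, spec.noise.gaussian_sd, size=image.shape)

    truth = pd.DataFrame.from_records(
        records,
        columns=[
            "lane_id", "condition", "band", "mw_kda", "row",
            "amplitude", "sigma_px", "true_area",
        ],
    )
    return image.astype(float), truth


def replicate_blots(
    spec: BlotSpec, seeds: Sequence[int]
) -> list[tuple[np.ndarray, pd.DataFrame]]:
    """Render the same blot under independent noise realizations.

    All replicates share the spec (hence identical true areas) and differ only
    in the noise seed.  Requires >= 2 distinct seeds.
    """
    seeds = list(seeds)
    if len(seeds) < 2:
        raise BlotSpecError("replicate_blots needs at least 2 seeds")
    if len(set(seeds)) != len(seeds):
        raise BlotSpecError("replicate seeds must be distinct")
    return [render_blot(replace(spec, seed=int(s))) for s in seeds]
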