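"""Synthetic immunofluorescence fields with ground-truth puncta.

Emulates the three conditions of a knockout-validation immunostaining
experiment: wild-type (WT) cells with punctate vesicular staining
concentrated in a perinuclear annulus, knockout (KO) cells, and a
secondary-antibody-only background control.  Cells are disks on a jittered
grid with disk nuclei; puncta are small Gaussian spots placed either in the
perinuclear annulus (a ring of ``annulus_px`` around the nucleus) or in the
remaining cytoplasm, with a minimum separation so that vesicles stay
resolvable.  The renderer draws exactly what the field spec states: a
non-specific antibody is emulated by giving the KO field the same puncta and
diffuse parameters as the WT field.  A secondary-only field with any primary
signal (puncta or diffuse) is rejected as contradictory.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, floor, sqrt

import numpy as np
import pandas as pd

WT = "WT"
KO = "KO"
SECONDARY_ONLY = "secondary_only"
_CONDITIONS = (WT, KO, SECONDARY_ONLY)


class IFSpecError(ValueError):
    """Invalid immunofluorescence field specification."""


@dataclass(frozen=True)
class IFFieldSpec:
    """Parameters of one synthetic field; ``seed`` fixes image and puncta."""

    condition: str
    n_cells: int = 5
    puncta_per_cell: int = 50
    perinuclear_fraction: float = 0.7
    punctum_amplitude: float = 120.0
    punctum_sigma_px: float = 2.0
    diffuse_level: float = 15.0
    background_level: float = 8.0
    noise_sd: float = 0.0
    cell_radius_px: int = 55
    nucleus_radius_px: int = 18
    annulus_px: int = 15
    min_separation_px: float = 5.0
    edge_margin_px: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in _CONDITIONS:
            raise IFSpecError(f"condition must be one of {_CONDITIONS}")
        if not 0.0 <= self.perinuclear_fraction <= 1.0:
            raise IFSpecError("perinuclear_fraction must be in [0, 1]")
        if self.condition == SECONDARY_ONLY and (
            self.puncta_per_cell > 0 or self.diffuse_level > 0
        ):
            raise IFSpecError(
                "secondary_only field cannot carry primary-antibody signal "
                "(puncta_per_cell and diffuse_level must be 0)"
            )
        if self.n_cells < 1:
            raise IFSpecError("n_cells must be >= 1")
        if self.nucleus_radius_px + self.annulus_px >= self.cell_radius_px:
            raise IFSpecError("annulus must fit inside the cell radius")
        if min(self.punctum_amplitude, self.punctum_sigma_px) <= 0:
            raise IFSpecError("punctum amplitude and sigma must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        pitch = 2 * self.cell_radius_px + 14
        rows = max(1, floor(sqrt(self.n_cells)))
        cols = ceil(self.n_cells / rows)
        return (rows * pitch, cols * pitch)


@dataclass(frozen=True)
class IFField:
    """Rendered field: image, masks, and the ground-truth puncta table."""

    image: np.ndarray
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    puncta: pd.DataFrame
    spec: IFFieldSpec


def _cell_centers(spec: IFFieldSpec, rng: np.random.Generator) -> np.ndarray:
    pitch = 2 * spec.cell_radius_px + 14
    rows = max(1, floor(sqrt(spec.n_cells)))
    cols = ceil(spec.n_cells / rows)
    centers = []
    for k in range(spec.n_cells):
        r, c = divmod(k, cols)
        jitter = rng.uniform(-4, 4, size=2)
        centers.append(
            [(r + 0.5) * pitch + jitter[0], (c + 0.5) * pitch + jitter[1]]
        )
    return np.asarray(centers)


def _sample_ring(
    rng: np.random.Generator, center: np.ndarray, r0: float, r1: float, n: int,
    min_sep: float, accepted: list[np.ndarray],
) -> list[np.ndarray]:
    """Area-uniform points in a ring, rejecting those closer than min_sep."""
    out: list[np.ndarray] = []
    attempts = 0
    while len(out) < n and attempts < 200 * max(n, 1):
        attempts += 1
        r = sqrt(rng.uniform(r0 * r0, r1 * r1))
        theta = rng.uniform(0.0, 2.0 * np.pi)
        p = center + r * np.array([np.cos(theta), np.sin(theta)])
        if accepted or out:
            pts = np.asarray(accepted + out)
            if np.min(np.hypot(*(pts - p).T)) < min_sep:
                continue
        out.append(p)
    if len(out) < n:
        raise IFSpecError(
            "could not place puncta at the requested density and separation"
        )
    return out


def render_if_field(spec: IFFieldSpec) -> IFField:
    """Render one field with its cell/nucleus masks and ground-truth puncta.

    The puncta table has columns row, col, cell, perinuclear (bool) and
    amplitude; it is empty for fields with ``puncta_per_cell == 0``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w]
    centers = _cell_centers(spec, rng)

    cell_mask = np.zeros((h, w), dtype=bool)
    nucleus_mask = np.zeros((h, w), dtype=bool)
    for cy, cx in centers:
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        cell_mask |= d2 <= spec.cell_radius_px**2
        nucleus_mask |= d2 <= spec.nucleus_radius_px**2

    image = np.full((h, w), float(spec.background_level))
    if spec.diffuse_level > 0:
        image[cell_mask] += spec.diffuse_level

    records = []
    r_nuc = float(spec.nucleus_radius_px)
    r_ann = r_nuc + spec.annulus_px
    r_out = float(spec.cell_radius_px - spec.edge_margin_px)
    for ci, center in enumerate(centers):
        n = spec.puncta_per_cell
        if n == 0:
            continue
        n_peri = int(round(spec.perinuclear_fraction * n))
        placed: list[np.ndarray] = []
        peri = _sample_ring(rng, center, r_nuc + 1, r_ann, n_peri,
                            spec.min_separation_px, placed)
        placed += peri
        outer = _sample_ring(rng, center, r_ann, r_out, n - n_peri,
                             spec.min_separation_px, placed)
        for p, is_peri in [(q, True) for q in peri] + [(q, False) for q in outer]:
            records.append(
                dict(row=p[0], col=p[1], cell=ci, perinuclear=is_peri,
                     amplitude=spec.punctum_amplitude)
            )

    sig = spec.punctum_sigma_px
    halfwin = int(ceil(4 * sig))
    for rec in records:
        r0, c0 = rec["row"], rec["col"]
        ra, rb = max(0, int(r0) - halfwin), min(h, int(r0) + halfwin + 1)
        ca, cb = max(0, int(c0) - halfwin), min(w, int(c0) + halfwin + 1)
        ys = np.arange(ra, rb)[:, None]
        xs = np.arange(ca, cb)[None, :]
        image[ra:rb, ca:cb] += rec["amplitude"] * np.exp(
            -0.5 * ((ys - r0) ** 2 + (xs - c0) ** 2) / sig**2
        )

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)

    puncta = pd.DataFrame.from_records(
        records, columns=["row", "col", "cell", "perinuclear", "amplitude"]
    )
    return IFField(image=image.astype(float), cell_mask=cell_mask,
                   nucleus_mask=nucleus_mask, puncta=puncta, spec=spec)
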