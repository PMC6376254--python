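"""Quantitative scoring of knockout-validation immunofluorescence.

Replaces the visual two-criterion assessment of antibody stainings with
numeric surrogates:

* "typical localization pattern" — enough detected puncta per cell, a large
  enough share of the above-background signal inside those puncta, and a
  punctum density in the perinuclear annulus clearly above the rest of the
  cytoplasm;
* "loss of signal in KO" — the knockout field's mean intensity falls back to
  the secondary-only background, measured by
  ``(mean_KO - mean_sec) / (mean_WT - mean_sec)``.

Puncta are found with a scale-normalized Laplacian-of-Gaussian blob detector
whose contrast threshold is set relative to the robust spread of the
background response, so that rescaling the stain intensity does not change
the detections.  Cell and nucleus masks are inputs; no segmentation is done
here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.morphology import dilation, disk, erosion

FLAG_NO_PUNCTA = "no puncta"
FLAG_CAPPED = "outer density zero (ratio capped)"
FLAG_WT_AT_BACKGROUND = "WT signal indistinguishable from background"

#: reported in place of an infinite perinuclear enrichment
ENRICHMENT_CAP = 100.0


@dataclass(frozen=True)
class IFThresholds:
    """Score thresholds; defaults separate the synthetic phenotype panel."""

    min_puncta_per_cell: float = 10.0
    min_signal_fraction: float = 0.3
    min_perinuclear_enrichment: float = 2.0
    max_ko_loss_ratio: float = 0.25
    detect_k: float = 5.0  # LoG contrast threshold in robust-sigma units


@dataclass(frozen=True)
class IFScore:
    """Numeric metrics plus the two binary criteria for one antibody."""

    antibody_id: str
    n_puncta_per_cell: float
    puncta_signal_fraction: float
    perinuclear_enrichment: float
    ko_loss_ratio: float
    pattern_positive: bool
    ko_loss_positive: bool
    flags: tuple[str, ...] = ()


def detect_puncta(
    image: np.ndarray,
    cell_mask: np.ndarray,
    scale_px: float = 2.0,
    *,
    k: float = 5.0,
) -> pd.DataFrame:
    """Laplacian-of-Gaussian punctum detection inside a cell mask.

    Local maxima of the scale-normalized (-LoG) response above
    ``k`` robust sigmas of the response's spread within the mask.  The mask
    is eroded by ~2 scales so intensity steps at the cell boundary are not
    reported as puncta.  Returns a DataFrame (row, col, response, intensity)
    where intensity is the background-subtracted integral over a disk of
    radius ``3 * scale_px`` around the punctum.
    """
    img = np.asarray(image, dtype=float)
    mask = np.asarray(cell_mask, dtype=bool)
    if not mask.any():
        raise ValueError("cell mask is empty")
    response = -ndimage.gaussian_laplace(img, sigma=scale_px) * scale_px**2

    inner = erosion(mask, disk(int(np.ceil(2 * scale_px)) + 2))
    vals = response[mask]
    med = float(np.median(vals))
    sigma = 1.4826 * float(np.median(np.abs(vals - med)))
    threshold = med + max(k * sigma, 1e-9)

    labels = inner.astype(np.uint8)
    coords = peak_local_max(
        response,
        min_distance=max(1, int(round(scale_px))),
        threshold_abs=threshold,
        labels=labels,
        exclude_border=False,
    )

    bg = float(np.median(img[mask]))
    radius = 3.0 * scale_px
    records = []
    h, w = img.shape
    for r, c in coords:
        ra, rb = max(0, int(r - radius)), min(h, int(r + radius) + 1)
        ca, cb = max(0, int(c - radius)), min(w, int(c + radius) + 1)
        yy, xx = np.mgrid[ra:rb, ca:cb]
        in_disk = (yy - r) ** 2 + (xx - c) ** 2 <= radius**2
        intensity = float(np.clip(img[ra:rb, ca:cb] - bg, 0, None)[in_disk].sum())
        records.append(dict(row=int(r), col=int(c),
                            response=float(response[r, c]), intensity=intensity))
    return pd.DataFrame.from_records(records, columns=["row", "col", "response", "intensity"])


@dataclass(frozen=True)
class EnrichmentResult:
    """Perinuclear punctum-density ratio with a degeneracy flag."""

    ratio: float
    flag: str | None = None


def perinuclear_enrichment(
    puncta: pd.DataFrame,
    nucleus_mask: np.ndarray,
    cell_mask: np.ndarray,
    annulus_px: int = 15,
) -> EnrichmentResult:
    """Punctum density in the perinuclear annulus vs the remaining cytoplasm.

    The annulus is the nucleus mask dilated by ``annulus_px`` (clipped to the
    cell), minus the nucleus itself.  With no puncta the ratio is undefined
    (NaN, flagged); with all puncta in the annulus the ratio is reported as
    the capped flag value :data:`ENRICHMENT_CAP`.
    """
    nucleus = np.asarray(nucleus_mask, dtype=bool)
    cell = np.asarray(cell_mask, dtype=bool)
    if not nucleus.any():
        raise ValueError("nucleus mask is empty")
    if annulus_px <= 0:
        raise ValueError("annulus_px must be > 0")
    annulus = dilation(nucleus, disk(annulus_px)) & cell & ~nucleus
    outside = cell & ~nucleus & ~annulus
    area_ann = int(annulus.sum())
    area_out = int(outside.sum())
    if area_ann == 0 or area_out == 0:
        raise ValueError("annulus or outer cytoplasm has zero area")

    if len(puncta) == 0:
        return EnrichmentResult(ratio=float("nan"), flag=FLAG_NO_PUNCTA)
    rows = puncta["row"].to_numpy(dtype=int)
    cols = puncta["col"].to_numpy(dtype=int)
    n_ann = int(annulus[rows, cols].sum())
    n_out = int(outside[rows, cols].sum())
    if n_out == 0:
        return EnrichmentResult(ratio=ENRICHMENT_CAP, flag=FLAG_CAPPED)
    return EnrichmentResult(ratio=(n_ann / area_ann) / (n_out / area_out))


@dataclass(frozen=True)
class KOLossResult:
    """Background-referenced KO/WT intensity ratio with a degeneracy flag."""

    ratio: float
    flag: str | None = None


def ko_loss_ratio(
    wt_image: np.ndarray,
    ko_image: np.ndarray,
    sec_only_image: np.ndarray,
    wt_mask: np.ndarray,
    ko_mask: np.ndarray,
    sec_only_mask: np.ndarray,
) -> KOLossResult:
    """(mean_KO - mean_sec) / (mean_WT - mean_sec) over the cell masks.

    Near 0 the KO field is at the secondary-only background (signal lost);
    near 1 there is no loss.  The ratio is clamped below at 0 and undefined
    (flagged) when the WT mean does not exceed the background.  Adding a
    common constant offset to all three images leaves the ratio unchanged.
    """
    means = []
    for img, mask in ((wt_image, wt_mask), (ko_image, ko_mask),
                      (sec_only_image, sec_only_mask)):
        m = np.asarray(mask, dtype=bool)
        if not m.any():
            raise ValueError("empty cell mask")
        means.append(float(np.asarray(img, dtype=float)[m].mean()))
    mean_wt, mean_ko, mean_sec = means
    if mean_wt <= mean_sec:
        return KOLossResult(ratio=float("nan"), flag=FLAG_WT_AT_BACKGROUND)
    return KOLossResult(ratio=max(0.0, (mean_ko - mean_sec) / (mean_wt - mean_sec)))


def _n_cells(nucleus_mask: np.ndarray) -> int:
    _, n = ndimage.label(np.asarray(nucleus_mask, dtype=bool))
    return max(int(n), 1)


def score_antibody_if(
    wt,
    ko,
    sec_only,
    *,
    antibody_id: str = "",
    scale_px: float = 2.0,
    annulus_px: int = 15,
    thresholds: IFThresholds | None = None,
) -> IFScore:
    """Score one antibody from matched WT / KO / secondary-only fields.

    Each argument provides ``image``, ``cell_mask`` and ``nucleus_mask``
    attributes (e.g. a rendered synthetic field).  The pattern criterion is
    positive when puncta per cell, the punctum signal fraction and the
    perinuclear enrichment all clear their thresholds; the KO-loss criterion
    is positive when the background-referenced KO ratio is at most the
    configured maximum.  Degenerate metrics (flagged NaN) fail their
    criterion and propagate their flags.
    """
    thr = thresholds or IFThresholds()
    puncta = detect_puncta(wt.image, wt.cell_mask, scale_px, k=thr.detect_k)
    n_per_cell = len(puncta) / _n_cells(wt.nucleus_mask)

    img = np.asarray(wt.image, dtype=float)
    mask = np.asarray(wt.cell_mask, dtype=bool)
    bg = float(np.median(img[mask]))
    total_signal = float(np.clip(img - bg, 0, None)[mask].sum())
    punctum_signal = float(puncta["intensity"].sum()) if len(puncta) else 0.0
    signal_fraction = punctum_signal / total_signal if total_signal > 0 else 0.0
    signal_fraction = min(signal_fraction, 1.0)

    enrich = perinuclear_enrichment(puncta, wt.nucleus_mask, wt.cell_mask, annulus_px)
    loss = ko_loss_ratio(wt.image, ko.image, sec_only.image,
                         wt.cell_mask, ko.cell_mask, sec_only.cell_mask)

    flags = tuple(f for f in (enrich.flag, loss.flag) if f)
    pattern_positive = (
        n_per_cell >= thr.min_puncta_per_cell
        and signal_fraction >= thr.min_signal_fraction
        and np.isfinite(enrich.ratio)
        and enrich.ratio >= thr.min_perinuclear_enrichment
    )
    ko_loss_positive = bool(
        np.isfinite(loss.ratio) and loss.ratio <= thr.max_ko_loss_ratio
    )
    return IFScore(
        antibody_id=antibody_id,
        n_puncta_per_cell=float(n_per_cell),
        puncta_signal_fraction=float(signal_fraction),
        perinuclear_enrichment=float(enrich.ratio),
        ko_loss_ratio=float(loss.ratio),
        pattern_positive=bool(pattern_positive),
        ko_loss_positive=ko_loss_positive,
        flags=flags,
    )
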