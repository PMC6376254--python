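"""Ready-made synthetic antibody panels used by the demo, tests and docs.

The western-blot side parametrizes each antibody by the pair of ground-truth
signal fractions (f_c, f_k): the specific ~25 kDa band's share of the total
peak area in the control and KO lane respectively, so that the true
specificity index is f_c - f_k.  Band amplitudes are solved from the
fractions at a fixed total control area; the specific band runs at 25 kDa
(sigma 4 px) and a single non-specific band at 50 kDa (sigma 6 px) carries
the remaining area in both lanes.  Noise is scaled so that the *smallest*
rendered band sits at the requested SNR (amplitude / Gaussian sd), i.e.
every real band is detectable at the stated difficulty.

The immunofluorescence side provides the 2x2 antibody phenotypes
{punctate, diffuse} x {KO-lost, KO-retained} against a shared
secondary-only background control.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt, tau

import numpy as np

from .blot import CONTROL, KO, BandSpec, BlotSpec, LaneSpec, NoiseSpec
from .iffield import SECONDARY_ONLY, WT, IFFieldSpec
from .iffield import KO as IF_KO

# SeeBlue-Plus2-style prestained ladder, placed exactly log-linearly so the
# calibration round-trips the anchors.
_LADDER_MWS = (98.0, 62.0, 49.0, 38.0, 28.0, 17.0, 14.0)
_ROW_TOP, _ROW_SLOPE = 40.0, 331.4  # row = top + slope * log10(98 / mw)

TARGET_MW_KDA = 25.0
NONSPECIFIC_MW_KDA = 50.0
SPECIFIC_SIGMA_PX = 4.0
NONSPECIFIC_SIGMA_PX = 6.0
TOTAL_CONTROL_AREA = 2400.0
DEFAULT_BACKGROUND = ((8.0, 3.0), (4.0, 0.0))


def standard_ladder() -> tuple[tuple[float, float], ...]:
    """(mw, row) anchors of the default prestained ladder."""
    return tuple(
        (mw, _ROW_TOP + _ROW_SLOPE * np.log10(_LADDER_MWS[0] / mw))
        for mw in _LADDER_MWS
    )


def _derived_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([int(seed), *key]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class AntibodyBlot:
    """One antibody's control/KO blot spec with its ground-truth fractions."""

    antibody_id: str
    spec: BlotSpec
    fraction_control: float
    fraction_ko: float

    @property
    def true_index(self) -> float:
        return self.fraction_control - self.fraction_ko


def blot_spec_from_fractions(
    f_c: float,
    f_k: float,
    *,
    snr: float | None = 20.0,
    seed: int = 0,
    total_area: float = TOTAL_CONTROL_AREA,
    background: tuple[tuple[float, ...], ...] = DEFAULT_BACKGROUND,
) -> BlotSpec:
    """Two-lane (control, KO) blot realizing target signal fractions.

    ``f_c`` in (0, 1] and ``f_k`` in [0, 1) are the specific band's share of
    total peak area in each lane.  ``snr=None`` renders noiselessly.
    """
    if not 0.0 < f_c <= 1.0:
        raise ValueError("f_c must be in (0, 1]")
    if not 0.0 <= f_k < 1.0:
        raise ValueError("f_k must be in [0, 1)")
    area_spec_c = f_c * total_area
    area_ns = (1.0 - f_c) * total_area
    area_spec_k = f_k / (1.0 - f_k) * area_ns
    amp_spec_c = area_spec_c / (SPECIFIC_SIGMA_PX * sqrt(tau))
    amp_spec_k = area_spec_k / (SPECIFIC_SIGMA_PX * sqrt(tau))
    amp_ns = area_ns / (NONSPECIFIC_SIGMA_PX * sqrt(tau))

    ns_band = BandSpec(NONSPECIFIC_MW_KDA, amp_ns, NONSPECIFIC_SIGMA_PX)
    control_bands = [BandSpec(TARGET_MW_KDA, amp_spec_c, SPECIFIC_SIGMA_PX)]
    ko_bands = []
    if amp_ns > 0:
        control_bands.append(ns_band)
        ko_bands.append(ns_band)
    if amp_spec_k > 0:
        ko_bands.insert(0, BandSpec(TARGET_MW_KDA, amp_spec_k, SPECIFIC_SIGMA_PX))

    amps = [b.amplitude for b in control_bands + ko_bands if b.amplitude > 0]
    sd = 0.0 if snr is None else min(amps) / float(snr)
    return BlotSpec(
        lanes=(
            LaneSpec(CONTROL, tuple(control_bands), "control"),
            LaneSpec(KO, tuple(ko_bands), "ko"),
        ),
        ladder=standard_ladder(),
        noise=NoiseSpec(gaussian_sd=sd),
        background_coeffs=background,
        seed=seed,
    )


# (f_c, f_k) for the 8-antibody demo panel; true indices 0.90 down to 0.20.
PANEL_FRACTIONS: tuple[tuple[str, float, float], ...] = (
    ("mAb-1", 0.90, 0.00),
    ("mAb-2", 0.82, 0.02),
    ("mAb-3", 0.74, 0.04),
    ("mAb-4", 0.66, 0.06),
    ("pAb-1", 0.58, 0.08),
    ("pAb-2", 0.50, 0.10),
    ("pAb-3", 0.42, 0.12),
    ("pAb-4", 0.34, 0.14),
)


def make_wb_panel(seed: int = 0, snr: float | None = 20.0) -> list[AntibodyBlot]:
    """The 8-antibody knockout-validation western-blot panel."""
    panel = []
    for i, (ab_id, f_c, f_k) in enumerate(PANEL_FRACTIONS):
        spec = blot_spec_from_fractions(
            f_c, f_k, snr=snr, seed=_derived_seed(seed, 1, i)
        )
        panel.append(AntibodyBlot(ab_id, spec, f_c, f_k))
    return panel


# --- immunofluorescence panel ---------------------------------------------

IF_KINDS = ("punctate_lost", "diffuse_lost", "punctate_retained", "diffuse_retained")
#: expected (pattern_positive, ko_loss_positive) per phenotype
EXPECTED_IF_SCORES = {
    "punctate_lost": (True, True),
    "diffuse_lost": (False, True),
    "punctate_retained": (True, False),
    "diffuse_retained": (False, False),
}


def make_if_antibody(
    kind: str, seed: int = 0, *, noise_sd: float = 12.0
) -> dict[str, IFFieldSpec]:
    """WT/KO/secondary-only field specs for one antibody phenotype.

    Punctate phenotypes stain 50 vesicles per cell, 70 % of them in the
    perinuclear annulus, over a modest diffuse cytoplasmic level; diffuse
    phenotypes show cytoplasmic signal only.  "Retained" phenotypes repeat
    the WT staining in the KO field (a non-specific antibody); "lost"
    phenotypes leave the KO field at camera background, like the
    secondary-only control.
    """
    if kind not in IF_KINDS:
        raise ValueError(f"kind must be one of {IF_KINDS}")
    punctate = kind.startswith("punctate")
    retained = kind.endswith("retained")
    stain = dict(
        puncta_per_cell=50 if punctate else 0,
        perinuclear_fraction=0.7,
        diffuse_level=15.0 if punctate else 40.0,
    )
    blank = dict(puncta_per_cell=0, perinuclear_fraction=0.0, diffuse_level=0.0)
    k = IF_KINDS.index(kind)
    return {
        WT: IFFieldSpec(condition=WT, noise_sd=noise_sd,
                        seed=_derived_seed(seed, 2, k, 0), **stain),
        IF_KO: IFFieldSpec(condition=IF_KO, noise_sd=noise_sd,
                           seed=_derived_seed(seed, 2, k, 1),
                           **(stain if retained else blank)),
        SECONDARY_ONLY: IFFieldSpec(condition=SECONDARY_ONLY, noise_sd=noise_sd,
                                    seed=_derived_seed(seed, 2, k, 2), **blank),
    }


def make_if_panel(seed: int = 0, *, noise_sd: float = 12.0):
    """The 2x2 phenotype panel: kind -> {condition -> IFFieldSpec}."""
    return {kind: make_if_antibody(kind, seed, noise_sd=noise_sd) for kind in IF_KINDS}
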