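"""End-to-end quantification: image -> lane peaks -> specificity report.

These functions tie the densitometry primitives together in the order an
analyst would apply them: extract the fixed-width lane profile, detect peak
regions, drop a valley-anchored baseline under them, integrate the corrected
areas, calibrate molecular weights, then identify the band of interest
against the knockout lane and compute the specificity index.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import densitometry as dm
from .if_scoring import IFScore, IFThresholds, score_antibody_if
from .simulate.blot import CONTROL, KO, BlotSpec, render_blot
from .specificity import (
    LaneQuantification,
    RankEntry,
    SpecificityResult,
    identify_band_of_interest,
    rank_antibodies,
    specificity_index,
    undefined_result,
)


@dataclass(frozen=True)
class WBThresholds:
    """Knobs of the blot quantification; defaults are the documented ones."""

    min_prominence: float = 0.05
    mw_tolerance: float = 0.2
    min_reduction: float | None = 0.5
    width_px: int = 20
    invert: bool = False


@dataclass(frozen=True)
class LaneAnalysis:
    """Profile, baseline and quantified peaks of one lane."""

    profile: dm.LaneProfile
    baseline: dm.Baseline
    quantification: LaneQuantification


def quantify_lane(
    image: np.ndarray,
    x_center: int,
    calibration: dm.LadderCalibration,
    *,
    lane_id: str = "lane",
    condition: str = CONTROL,
    thresholds: WBThresholds | None = None,
) -> LaneAnalysis:
    """Full densitometry of one lane: profile, baseline, integrated peaks."""
    thr = thresholds or WBThresholds()
    profile = dm.extract_lane_profile(
        image, x_center, thr.width_px, invert=thr.invert,
        lane_id=lane_id, condition=condition,
    )
    rough = dm.detect_peaks(profile, None, thr.min_prominence)
    baseline = dm.estimate_baseline(profile, [p.region for p in rough])
    peaks = tuple(
        replace(
            p,
            area=dm.integrate_peak(profile, baseline, p),
            mw_kda=float(calibration.mw_of(p.apex)),
        )
        for p in rough
    )
    quant = LaneQuantification(lane_id=lane_id, condition=condition, peaks=peaks)
    return LaneAnalysis(profile=profile, baseline=baseline, quantification=quant)


@dataclass(frozen=True)
class AntibodyBlotAnalysis:
    """Both lanes plus the specificity result for one antibody."""

    antibody_id: str
    control: LaneAnalysis
    ko: LaneAnalysis
    result: SpecificityResult


def analyze_antibody_image(
    image: np.ndarray,
    *,
    control_x: int,
    ko_x: int,
    calibration: dm.LadderCalibration,
    target_mw: float,
    antibody_id: str = "",
    thresholds: WBThresholds | None = None,
) -> AntibodyBlotAnalysis:
    """Quantify a control/KO lane pair and compute the specificity index.

    When no band of interest can be defined (no peak at the target size, or
    nothing disappears in KO) the result carries the flags and an undefined
    index instead of raising.
    """
    thr = thresholds or WBThresholds()
    ctrl = quantify_lane(image, control_x, calibration,
                         lane_id=f"{antibody_id}:control", condition=CONTROL,
                         thresholds=thr)
    ko = quantify_lane(image, ko_x, calibration,
                       lane_id=f"{antibody_id}:ko", condition=KO, thresholds=thr)
    c_q, k_q = identify_band_of_interest(
        ctrl.quantification, ko.quantification, target_mw,
        mw_tolerance=thr.mw_tolerance, min_reduction=thr.min_reduction,
    )
    if c_q.peak_of_interest is None:
        result = undefined_result(antibody_id, c_q.flags + k_q.flags)
    else:
        result = specificity_index(c_q, k_q, antibody_id)
    return AntibodyBlotAnalysis(
        antibody_id=antibody_id,
        control=replace(ctrl, quantification=c_q),
        ko=replace(ko, quantification=k_q),
        result=result,
    )


def analyze_antibody_blot(
    spec: BlotSpec,
    target_mw: float,
    *,
    antibody_id: str = "",
    thresholds: WBThresholds | None = None,
) -> AntibodyBlotAnalysis:
    """Render a two-lane synthetic blot spec and analyze it."""
    if len(spec.lanes) != 2:
        raise ValueError("expected a two-lane (control, KO) blot spec")
    image, _ = render_blot(spec)
    by_cond = {lane.condition: x for lane, x in zip(spec.lanes, spec.lane_centers)}
    return analyze_antibody_image(
        image,
        control_x=by_cond[CONTROL],
        ko_x=by_cond[KO],
        calibration=spec.calibration(),
        target_mw=target_mw,
        antibody_id=antibody_id,
        thresholds=thresholds,
    )


def peak_table(analyses: list[AntibodyBlotAnalysis]) -> pd.DataFrame:
    """Long-format per-lane peak table (one row per detected peak)."""
    rows = []
    for a in analyses:
        for lane in (a.control, a.ko):
            q = lane.quantification
            for p in q.peaks:
                rows.append(
                    dict(
                        antibody_id=a.antibody_id,
                        lane_id=q.lane_id,
                        condition=q.condition,
                        apex_row=p.apex,
                        mw_kda=round(p.mw_kda, 2),
                        start=p.start,
                        end=p.end,
                        area=round(p.area, 4),
                        is_peak_of_interest=(p == q.peak_of_interest),
                    )
                )
    return pd.DataFrame.from_records(
        rows,
        columns=["antibody_id", "lane_id", "condition", "apex_row", "mw_kda",
                 "start", "end", "area", "is_peak_of_interest"],
    )


def specificity_table(entries: list[RankEntry]) -> pd.DataFrame:
    """Ranked specificity report (one row per antibody)."""
    rows = []
    for e in entries:
        r = e.result
        rows.append(
            dict(
                rank=e.rank,
                antibody_id=r.antibody_id,
                fraction_control=None if r.fraction_control is None else round(r.fraction_control, 4),
                fraction_ko=None if r.fraction_ko is None else round(r.fraction_ko, 4),
                index=None if r.index is None else round(r.index, 4),
                tied=e.tied,
                flags="; ".join(r.flags),
            )
        )
    return pd.DataFrame.from_records(
        rows, columns=["rank", "antibody_id", "fraction_control", "fraction_ko",
                       "index", "tied", "flags"],
    )


def rank_panel(
    panel,
    target_mw: float,
    *,
    thresholds: WBThresholds | None = None,
) -> tuple[list[AntibodyBlotAnalysis], list[RankEntry]]:
    """Analyze and rank a list of :class:`~kospec.simulate.AntibodyBlot`."""
    analyses = [
        analyze_antibody_blot(ab.spec, target_mw, antibody_id=ab.antibody_id,
                              thresholds=thresholds)
        for ab in panel
    ]
    ranking = rank_antibodies([a.result for a in analyses])
    return analyses, ranking


def replicate_rankings(
    panel,
    target_mw: float,
    seeds: list[int],
    *,
    thresholds: WBThresholds | None = None,
) -> list[tuple[str, ...]]:
    """Antibody order (by id) obtained in each noise replicate.

    Every antibody's blot is re-rendered under each replicate's noise seed
    (seeds must be distinct), then quantified and ranked; the per-replicate
    orders support the rank-stability check.
    """
    if len(seeds) < 2 or len(set(seeds)) != len(seeds):
        raise ValueError("need at least 2 distinct replicate seeds")
    orders: list[tuple[str, ...]] = []
    for s in seeds:
        results = []
        for i, ab in enumerate(panel):
            spec = replace(ab.spec, seed=int(np.random.SeedSequence(
                [int(s), 7, i]).generate_state(1)[0] % (2**31)))
            a = analyze_antibody_blot(spec, target_mw, antibody_id=ab.antibody_id,
                                      thresholds=thresholds)
            results.append(a.result)
        entries = rank_antibodies(results)
        orders.append(tuple(e.result.antibody_id for e in entries))
    return orders


def score_if_panel(
    panel: dict[str, dict],
    *,
    thresholds: IFThresholds | None = None,
    scale_px: float = 2.0,
    annulus_px: int = 15,
) -> dict[str, IFScore]:
    """Render and score a {kind -> {condition -> IFFieldSpec}} panel."""
    from .simulate.iffield import KO as IF_KO
    from .simulate.iffield import SECONDARY_ONLY, WT, render_if_field

    scores = {}
    for kind, specs in panel.items():
        fields = {cond: render_if_field(spec) for cond, spec in specs.items()}
        scores[kind] = score_antibody_if(
            fields[WT], fields[IF_KO], fields[SECONDARY_ONLY],
            antibody_id=kind, scale_px=scale_px, annulus_px=annulus_px,
            thresholds=thresholds,
        )
    return scores


def if_score_table(scores: dict[str, IFScore]) -> pd.DataFrame:
    """+/- score table alongside the underlying numeric metrics."""
    rows = []
    for kind, s in scores.items():
        rows.append(
            dict(
                antibody_id=s.antibody_id or kind,
                pattern="+" if s.pattern_positive else "-",
                ko_loss="+" if s.ko_loss_positive else "-",
                n_puncta_per_cell=round(s.n_puncta_per_cell, 2),
                puncta_signal_fraction=round(s.puncta_signal_fraction, 4),
                perinuclear_enrichment=round(s.perinuclear_enrichment, 3),
                ko_loss_ratio=round(s.ko_loss_ratio, 4),
                flags="; ".join(s.flags),
            )
        )
    return pd.DataFrame.from_records(
        rows, columns=["antibody_id", "pattern", "ko_loss", "n_puncta_per_cell",
                       "puncta_signal_fraction", "perinuclear_enrichment",
                       "ko_loss_ratio", "flags"],
    )
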