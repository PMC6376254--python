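"""Western-blot specificity index from knockout-control lane pairs.

The band of interest is the peak at the expected molecular weight whose
intensity disappears or diminishes in the knockout (KO) lane relative to the
control lane.  The specificity index of an antibody is then

    index = {Area(peak of interest) / Area(all peaks)}_control
          - {Area(peak of interest) / Area(all peaks)}_KO

which rewards a strong specific band relative to the non-specific background
bands in the same lane, and penalizes residual signal at the target size in
the KO lane.  When the KO lane has no matching peak the KO term is 0 by
construction.  The index is bounded in [-1, 1]; a perfectly specific
antibody (single band, fully lost in KO) scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .densitometry import Peak

FLAG_NO_BAND = "no band at target size"
FLAG_NO_DISAPPEARING_BAND = "no disappearing band"
FLAG_EMPTY_KO_LANE = "empty KO lane"


class SpecificityError(ValueError):
    """Invalid lane quantification for index computation."""


class AmbiguousBandError(SpecificityError):
    """Several peaks qualify as band of interest after tie-breaking."""


@dataclass(frozen=True)
class LaneQuantification:
    """All detected peaks of one lane plus the identified peak of interest."""

    lane_id: str
    condition: str
    peaks: tuple[Peak, ...]
    peak_of_interest: Peak | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        object.__setattr__(self, "flags", tuple(self.flags))
        if self.peak_of_interest is not None and self.peak_of_interest not in self.peaks:
            raise SpecificityError("peak_of_interest must be one of the lane's peaks")

    @property
    def area_all(self) -> float:
        """Area(all peaks): the sum of every peak's corrected area."""
        return float(sum(p.area for p in self.peaks))


@dataclass(frozen=True)
class SpecificityResult:
    """Per-antibody control/KO signal fractions and their difference."""

    antibody_id: str
    fraction_control: float | None
    fraction_ko: float | None
    index: float | None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "flags", tuple(self.flags))
        if self.index is not None:
            if not -1.0 <= self.index <= 1.0:
                raise SpecificityError("index must lie in [-1, 1]")


def _in_window(mw: float, target_mw: float, tol: float) -> bool:
    return abs(mw - target_mw) <= tol * target_mw


def identify_band_of_interest(
    control: LaneQuantification,
    ko: LaneQuantification,
    target_mw: float,
    *,
    mw_tolerance: float = 0.2,
    min_reduction: float | None = 0.5,
) -> tuple[LaneQuantification, LaneQuantification]:
    """Select the target-size band that disappears or diminishes in KO.

    A control peak qualifies when its calibrated MW lies within
    ``target_mw * (1 +/- mw_tolerance)`` and its matched KO peak (closest MW
    inside the same window) is absent or has lost at least ``min_reduction``
    of the control area.  ``min_reduction=None`` disables the loss gate and
    matches purely by molecular weight (useful when the band identity is
    already known).  Ties between equally close candidates raise
    :class:`AmbiguousBandError`; lanes with no candidate or no qualifying
    candidate are returned flagged, with no peak of interest set.
    """
    candidates = [p for p in control.peaks if _in_window(p.mw_kda, target_mw, mw_tolerance)]
    if not candidates:
        return (
            replace(control, peak_of_interest=None,
                    flags=control.flags + (FLAG_NO_BAND,)),
            replace(ko, peak_of_interest=None),
        )

    ko_window = [p for p in ko.peaks if _in_window(p.mw_kda, target_mw, mw_tolerance)]

    def ko_match(peak: Peak) -> Peak | None:
        if not ko_window:
            return None
        return min(ko_window, key=lambda q: abs(q.mw_kda - peak.mw_kda))

    if min_reduction is None:
        qualifying = [(p, ko_match(p)) for p in candidates]
    else:
        qualifying = []
        for p in candidates:
            m = ko_match(p)
            if m is None or m.area <= (1.0 - min_reduction) * p.area:
                qualifying.append((p, m))

    if not qualifying:
        return (
            replace(control, peak_of_interest=None,
                    flags=control.flags + (FLAG_NO_DISAPPEARING_BAND,)),
            replace(ko, peak_of_interest=None),
        )

    dists = [abs(p.mw_kda - target_mw) for p, _ in qualifying]
    best = min(dists)
    winners = [pair for pair, d in zip(qualifying, dists) if d <= best + 1e-9]
    if len(winners) > 1:
        listing = ", ".join(f"{p.mw_kda:.1f} kDa (area {p.area:.1f})" for p, _ in winners)
        raise AmbiguousBandError(
            f"multiple candidate bands equally close to {target_mw:g} kDa: {listing}"
        )
    poi, ko_poi = winners[0]
    return (
        replace(control, peak_of_interest=poi),
        replace(ko, peak_of_interest=ko_poi),
    )


def specificity_index(
    control: LaneQuantification,
    ko: LaneQuantification,
    antibody_id: str = "",
) -> SpecificityResult:
    """Compute the specificity index from an identified lane pair.

    Requires the control peak of interest to be set and the control lane to
    contain signal.  A KO lane without a matched peak contributes 0 to the
    index; a KO lane with no peaks at all additionally carries the
    "empty KO lane" flag.
    """
    if control.peak_of_interest is None:
        raise SpecificityError(
            "control peak_of_interest is not set; run identify_band_of_interest first"
        )
    if control.area_all <= 0:
        raise SpecificityError(f"empty control lane {control.lane_id!r} (zero total area)")

    flags = control.flags + ko.flags
    f_c = control.peak_of_interest.area / control.area_all
    if ko.peak_of_interest is None:
        f_k = 0.0
        if not ko.peaks:
            flags = flags + (FLAG_EMPTY_KO_LANE,)
    else:
        if ko.area_all <= 0:
            raise SpecificityError(f"empty KO lane {ko.lane_id!r} (zero total area)")
        f_k = ko.peak_of_interest.area / ko.area_all
    f_c = min(max(f_c, 0.0), 1.0)
    f_k = min(max(f_k, 0.0), 1.0)
    return SpecificityResult(
        antibody_id=antibody_id,
        fraction_control=f_c,
        fraction_ko=f_k,
        index=f_c - f_k,
        flags=flags,
    )


def undefined_result(antibody_id: str, flags: tuple[str, ...]) -> SpecificityResult:
    """Placeholder for an antibody whose band of interest could not be defined."""
    return SpecificityResult(
        antibody_id=antibody_id, fraction_control=None, fraction_ko=None,
        index=None, flags=flags,
    )


@dataclass(frozen=True)
class RankEntry:
    """One row of the antibody ranking."""

    rank: int
    result: SpecificityResult
    tied: bool = False


def rank_antibodies(results: list[SpecificityResult]) -> list[RankEntry]:
    """Rank antibodies by descending index.

    Sorting is stable (ties keep input order and are marked ``tied``);
    antibodies with an undefined index are listed last, carrying their flags.
    """
    if not results:
        raise SpecificityError("cannot rank an empty result list")
    defined = [r for r in results if r.index is not None]
    undefined = [r for r in results if r.index is None]
    ordered = sorted(defined, key=lambda r: -r.index)
    entries: list[RankEntry] = []
    for i, r in enumerate(ordered):
        tied = (i > 0 and ordered[i - 1].index == r.index) or (
            i + 1 < len(ordered) and ordered[i + 1].index == r.index
        )
        entries.append(RankEntry(rank=i + 1, result=r, tied=tied))
    for j, r in enumerate(undefined):
        entries.append(RankEntry(rank=len(ordered) + j + 1, result=r, tied=False))
    return entries
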