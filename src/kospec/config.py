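"""Run configuration: YAML layout/threshold schema and provenance copies.

Schema (all keys optional unless marked; see ``example_config``)::

    seed: 1                     # required for simulation modes
    outdir: results/
    blot:
      image: blot.tif           # required by quantify-blot
      target_mw: 25.0           # required
      layout:                   # required: lane geometry + ladder
        width_px: 20
        ladder: [{mw: 98, row: 40}, ...]
        lanes:
          - {antibody: mAb-1, control_x: 40, ko_x: 90}
      thresholds:
        min_prominence: 0.05
        mw_tolerance: 0.2
        min_reduction: 0.5      # null disables the disappear/diminish gate
        invert: false
    if:
      antibodies:
        - id: Ab-1
          wt: {image: wt.tif, cell_mask: ..., nucleus_mask: ...}
          ko: {image: ko.tif, cell_mask: ..., nucleus_mask: ...}
          secondary_only: {image: sec.tif, cell_mask: ..., nucleus_mask: ...}
      thresholds:
        min_puncta_per_cell: 10
        min_signal_fraction: 0.3
        min_perinuclear_enrichment: 2.0
        max_ko_loss_ratio: 0.25
      scale_px: 2.0
      annulus_px: 15

Every run writes ``resolved_config.yaml`` (the configuration actually used,
thresholds included) into its output directory for reproducibility.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Any

import yaml

from .if_scoring import IFThresholds
from .pipeline import WBThresholds


class ConfigError(ValueError):
    """Missing or out-of-range configuration values."""


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} is not a mapping")
    return cfg


def wb_thresholds(cfg: dict[str, Any]) -> WBThresholds:
    t = (cfg.get("blot") or {}).get("thresholds") or {}
    thr = WBThresholds(
        min_prominence=float(t.get("min_prominence", 0.05)),
        mw_tolerance=float(t.get("mw_tolerance", 0.2)),
        min_reduction=(None if t.get("min_reduction", 0.5) is None
                       else float(t.get("min_reduction", 0.5))),
        width_px=int(t.get("width_px", 20)),
        invert=bool(t.get("invert", False)),
    )
    if not 0.0 < thr.min_prominence <= 1.0:
        raise ConfigError("min_prominence must be in (0, 1]")
    if not 0.0 <= thr.mw_tolerance < 1.0:
        raise ConfigError("mw_tolerance must be in [0, 1)")
    if thr.min_reduction is not None and not 0.0 <= thr.min_reduction <= 1.0:
        raise ConfigError("min_reduction must be in [0, 1] or null")
    return thr


def if_thresholds(cfg: dict[str, Any]) -> IFThresholds:
    t = (cfg.get("if") or {}).get("thresholds") or {}
    thr = IFThresholds(
        min_puncta_per_cell=float(t.get("min_puncta_per_cell", 10.0)),
        min_signal_fraction=float(t.get("min_signal_fraction", 0.3)),
        min_perinuclear_enrichment=float(t.get("min_perinuclear_enrichment", 2.0)),
        max_ko_loss_ratio=float(t.get("max_ko_loss_ratio", 0.25)),
        detect_k=float(t.get("detect_k", 5.0)),
    )
    if thr.min_puncta_per_cell < 0 or thr.detect_k <= 0:
        raise ConfigError("IF thresholds out of range")
    if not 0.0 <= thr.min_signal_fraction <= 1.0:
        raise ConfigError("min_signal_fraction must be in [0, 1]")
    return thr


def blot_layout(cfg: dict[str, Any]) -> dict[str, Any]:
    """Validate and return the blot layout block (before any image read)."""
    blot = cfg.get("blot") or {}
    layout = blot.get("layout")
    if not layout:
        raise ConfigError("missing blot.layout (lanes + ladder)")
    if not layout.get("ladder") or len(layout["ladder"]) < 2:
        raise ConfigError("blot.layout.ladder needs >= 2 anchors")
    if not layout.get("lanes"):
        raise ConfigError("blot.layout.lanes is empty")
    if "target_mw" not in blot:
        raise ConfigError("missing blot.target_mw")
    return layout


def write_resolved_config(outdir: str | Path, cfg: dict[str, Any],
                          *, wb: WBThresholds | None = None,
                          if_thr: IFThresholds | None = None) -> Path:
    """Dump the configuration actually used (provenance artifact)."""
    resolved = dict(cfg)
    if wb is not None:
        resolved.setdefault("blot", {})["thresholds_resolved"] = asdict(wb)
    if if_thr is not None:
        resolved.setdefault("if", {})["thresholds_resolved"] = asdict(if_thr)
    out = Path(outdir) / "resolved_config.yaml"
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
    return out
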