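"""End-to-end orchestration: simulate/load → segment → morphometry →
markers → actin, emitting tidy per-spheroid tables.

Each input stack holds exactly one spheroid (matching one-aggregate-
per-well culture).  A batch run processes every input independently:
failure of one stack is logged and does not abort the rest, and the exit
status of the CLI reflects any failure.  Identical config + seed produces
byte-identical CSV output.

Group statistics are descriptive only (n, shape-class proportions,
mean ± sd); inferential testing is left to external tools, with the tidy
CSV as the interchange surface.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .actin import DegenerateDecompositionError, RingDecomposition, actin_ratio
from .morphometry import MorphometryResult, measure
from .nuclei import (MarkerQuantification, NucleusSet, call_positive,
                     detect_nuclei, quantify_marker, sample_intensities)
from .segmentation import SegmentationParams, segment_spheroid
from .stack import ChannelStack, read_ome_tiff
from .synthetic import SyntheticSpec, simulate

logger = logging.getLogger("spheromet")

__all__ = ["RunConfig", "SpheroidReport", "run_pipeline", "condition_summary"]

#: fixed, versioned column set of the tidy per-spheroid CSV (marker
#: percent columns are appended per configured marker channel)
CSV_SCHEMA_VERSION = "1"
BASE_COLUMNS = [
    "id", "condition", "status",
    "volume_um3", "surface_um2", "sphericity",
    "axis_a", "axis_b", "axis_c", "elongation_ratio", "protrusions",
    "shape_class", "n_nuclei",
    "area_whole_px", "area_inner_px", "area_outer_px",
    "mean_inner", "mean_outer", "ratio_periphery_to_centre",
    "config_hash", "seed", "schema_version",
]


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    inputs: List[str] = field(default_factory=list)  # OME-TIFF paths
    simulate: List[dict] = field(default_factory=list)  # SyntheticSpec dicts
    conditions: Optional[List[str]] = None  # group label per input
    nuclear_channel: str = "dapi"
    actin_channel: str = "factin"
    marker_channels: List[str] = field(default_factory=list)
    segmentation: dict = field(default_factory=dict)
    morphometry: dict = field(default_factory=dict)
    nuclei: dict = field(default_factory=dict)
    actin: dict = field(default_factory=dict)
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    _SEG_DEFAULTS = {"sigma": 3.0, "sigma_um_3d": 4.0, "n_classes": 2,
                     "min_object_size": 10_000, "min_object_size_3d": None}
    _MORPH_DEFAULTS = {"psi_deform": 0.7, "elong_min": 2.0,
                       "opening_radius_um": None}
    _NUC_DEFAULTS = {"nucleus_radius_um": 4.0, "threshold_rel": 0.1,
                     "sampling_radius_um": 4.0, "method": "otsu",
                     "manual_thresholds": {}}
    _ACTIN_DEFAULTS = {"scale_factor": 0.75}

    def __post_init__(self) -> None:
        self.segmentation = {**self._SEG_DEFAULTS, **self.segmentation}
        self.morphometry = {**self._MORPH_DEFAULTS, **self.morphometry}
        self.nuclei = {**self._NUC_DEFAULTS, **self.nuclei}
        self.actin = {**self._ACTIN_DEFAULTS, **self.actin}
        n_items = len(self.inputs) + len(self.simulate)
        if self.conditions is not None and len(self.conditions) != n_items:
            raise ValueError("conditions must have one label per input")

    def to_dict(self) -> dict:
        return {
            "inputs": list(self.inputs),
            "simulate": [dict(s) for s in self.simulate],
            "conditions": list(self.conditions) if self.conditions else None,
            "nuclear_channel": self.nuclear_channel,
            "actin_channel": self.actin_channel,
            "marker_channels": list(self.marker_channels),
            "segmentation": dict(self.segmentation),
            "morphometry": dict(self.morphometry),
            "nuclei": dict(self.nuclei),
            "actin": dict(self.actin),
            "out_dir": self.out_dir,
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"malformed config {path}: expected a mapping")
        known = set(cls.__dataclass_fields__) - {"_SEG_DEFAULTS"}
        unknown = set(data) - {k for k in known if not k.startswith("_")}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location
        and log verbosity excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        canon = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class SpheroidReport:
    """All readouts of one spheroid plus run provenance."""

    spheroid_id: str
    condition: Optional[str]
    morphometry: Optional[MorphometryResult]
    markers: List[MarkerQuantification]
    ring: Optional[RingDecomposition]
    n_nuclei: int
    provenance: dict

    def to_row(self, marker_channels: Sequence[str]) -> dict:
        row: dict = {"id": self.spheroid_id, "condition": self.condition,
                     "status": "ok"}
        if self.morphometry is not None:
            row.update(self.morphometry.to_row())
        row["n_nuclei"] = self.n_nuclei
        by_channel = {m.channel: m for m in self.markers}
        for ch in marker_channels:
            q = by_channel.get(ch)
            row[f"percent_positive_{ch}"] = (
                q.percent_positive if q is not None else None)
        if self.ring is not None:
            row.update(self.ring.to_row())
        row.update(self.provenance)
        return row


def _analyze_stack(stack: ChannelStack, config: RunConfig,
                   spheroid_id: str, condition: Optional[str]) -> SpheroidReport:
    """Run every analysis stage on one stack."""
    seg3d = SegmentationParams(mode="3d", **{k: v for k, v in
                                             config.segmentation.items()})
    mask3d = segment_spheroid(stack, channel=config.nuclear_channel,
                              params=seg3d)
    morpho = measure(mask3d.data, mask3d.spacing, **config.morphometry)

    nuc_cfg = config.nuclei
    nuclei = detect_nuclei(stack, mask3d.data, channel=config.nuclear_channel,
                           nucleus_radius_um=nuc_cfg["nucleus_radius_um"],
                           threshold_rel=nuc_cfg["threshold_rel"])
    markers: List[MarkerQuantification] = []
    for ch in config.marker_channels:
        means = sample_intensities(nuclei, stack, ch,
                                   sampling_radius_um=nuc_cfg["sampling_radius_um"])
        manual = nuc_cfg["manual_thresholds"].get(ch)
        method = "manual" if manual is not None else nuc_cfg["method"]
        flags, thr = call_positive(means, method=method, manual_threshold=manual)
        nuclei.flags[ch] = flags
        nuclei.thresholds[ch] = thr
        nuclei.threshold_method[ch] = method
        markers.append(quantify_marker(nuclei, ch))

    seg2d = SegmentationParams(mode="2d", **{k: v for k, v in
                                             config.segmentation.items()})
    try:
        ring = actin_ratio(stack, nuclear_channel=config.nuclear_channel,
                           actin_channel=config.actin_channel,
                           seg_params=seg2d,
                           scale_factor=config.actin["scale_factor"])
    except DegenerateDecompositionError:
        logger.warning("%s: degenerate ring decomposition", spheroid_id)
        ring = None

    return SpheroidReport(
        spheroid_id=spheroid_id,
        condition=condition,
        morphometry=morpho,
        markers=markers,
        ring=ring,
        n_nuclei=len(nuclei),
        provenance={"config_hash": config.config_hash(), "seed": config.seed,
                    "schema_version": CSV_SCHEMA_VERSION,
                    "version": __version__},
    )


def run_pipeline(config: RunConfig,
                 write_outputs: bool = True) -> Tuple[List[SpheroidReport],
                                                      pd.DataFrame, int]:
    """Process every input; returns (reports, tidy table, n_failures).

    Simulated inputs without an explicit ``rng_seed`` receive
    ``config.seed + index`` so the whole batch is reproducible from one
    seed.  The fully resolved config is written next to the results.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    items: List[Tuple[str, object, Optional[str]]] = []
    conditions = config.conditions or [None] * (len(config.inputs) +
                                                len(config.simulate))
    for i, path in enumerate(config.inputs):
        items.append((f"input_{i:03d}", Path(path), conditions[i]))
    for j, spec_dict in enumerate(config.simulate):
        d = dict(spec_dict)
        d.setdefault("rng_seed", config.seed + j)
        items.append((f"sim_{j:03d}", SyntheticSpec.from_dict(d),
                      conditions[len(config.inputs) + j]))

    reports: List[SpheroidReport] = []
    rows: List[dict] = []
    n_failures = 0
    for spheroid_id, source, condition in items:
        try:
            if isinstance(source, Path):
                stack = read_ome_tiff(source)
            else:
                stack, _ = simulate(source)
            report = _analyze_stack(stack, config, spheroid_id, condition)
            reports.append(report)
            rows.append(report.to_row(config.marker_channels))
            logger.info("%s: ok", spheroid_id)
        except Exception as exc:  # noqa: BLE001 — batch isolation
            n_failures += 1
            logger.error("%s: failed (%s)", spheroid_id, exc)
            rows.append({"id": spheroid_id, "condition": condition,
                         "status": f"failed: {exc}",
                         "config_hash": config.config_hash(),
                         "seed": config.seed,
                         "schema_version": CSV_SCHEMA_VERSION})

    marker_cols = [f"percent_positive_{ch}" for ch in config.marker_channels]
    columns = BASE_COLUMNS[:13] + marker_cols + BASE_COLUMNS[13:]
    df = pd.DataFrame(rows)
    for col in columns:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[[c for c in columns if c in df.columns]]

    if write_outputs:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "spheroids.csv", index=False, float_format="%.6g")
        config.to_yaml(out / "config_resolved.yaml")
        (out / "provenance.json").write_text(json.dumps(
            {"version": __version__, "config_hash": config.config_hash(),
             "seed": config.seed, "n_inputs": len(items),
             "n_failures": n_failures, "schema_version": CSV_SCHEMA_VERSION},
            indent=1))
    return reports, df, n_failures


def condition_summary(df: pd.DataFrame, grouping: str = "condition") -> pd.DataFrame:
    """Descriptive per-group summary of a tidy spheroid table.

    Per group: n, shape-class proportions (percent of spheroids), and
    mean ± sd of every percent-positive column and of the actin
    periphery/centre ratio.  The sd of a single-spheroid group is missing
    (NaN), never 0.
    """
    if grouping not in df.columns:
        raise ValueError(f"grouping column {grouping!r} not in table")
    ok = df[df["status"] == "ok"]
    if ok.empty:
        raise ValueError("no successful spheroids to summarise")
    records = []
    value_cols = [c for c in df.columns if c.startswith("percent_positive_")]
    value_cols += ["ratio_periphery_to_centre", "sphericity"]
    for group, sub in ok.groupby(grouping, dropna=False):
        rec: dict = {grouping: group, "n": len(sub)}
        for cls in ("spherical", "budded", "elongated"):
            rec[f"prop_{cls}"] = 100.0 * float((sub["shape_class"] == cls).mean())
        for col in value_cols:
            vals = pd.to_numeric(sub[col], errors="coerce").dropna()
            rec[f"{col}_mean"] = vals.mean() if len(vals) else float("nan")
            rec[f"{col}_sd"] = vals.std(ddof=1) if len(vals) > 1 else float("nan")
        records.append(rec)
    return pd.DataFrame(records)
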