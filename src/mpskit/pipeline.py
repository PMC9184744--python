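"""End-to-end workflows and the reproducible run pipeline.

The workflow functions tie the modules together (extract segments, project,
bin, correlate, average); :func:`run_pipeline` executes a selection of stages
from a single structured configuration, writes delimited/JSON outputs, and
records a manifest (config hash, seed, package versions) sufficient to
reproduce the run bit-identically on the same platform.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coip as coip_mod
from . import io as locio
from . import neurite as neurite_mod
from . import periodicity as per
from .errors import ConfigurationError
from .simulate import (
    CoIPSimConfig,
    MPSSimConfig,
    NeuriteSceneConfig,
    simulate_mps_localizations,
    simulate_neurite_scene,
    simulate_spectral_counts,
    simulate_two_color_localizations,
    simulate_uniform_control,
)

logger = logging.getLogger(__name__)

_STAGES = ("mps", "control", "two_color", "coip", "scene")


# ---------------------------------------------------------------------------
# workflow functions
# ---------------------------------------------------------------------------


def segment_profiles(
    table: pd.DataFrame,
    rois: list[locio.SegmentROI],
    bin_size: float = per.DEFAULT_BIN_SIZE,
    channel: int | None = None,
) -> list[per.Profile1D]:
    """Extract each ROI, project onto its axis, and bin into a 1D profile."""
    profiles = []
    for roi in rois:
        seg = locio.extract_segment(table, roi)
        if channel is not None:
            seg = seg[seg["channel"] == channel]
        # extract_segment already yields segment-local coordinates: the axial
        # position is local x
        positions = seg["x_nm"].to_numpy(float) if len(seg) else np.empty(0)
        profiles.append(
            per.bin_profile(positions, bin_size, range=(0.0, roi.length), segment_label=roi.label)
        )
    return profiles


def averaged_autocorrelation(
    table: pd.DataFrame,
    rois: list[locio.SegmentROI],
    bin_size: float = per.DEFAULT_BIN_SIZE,
    max_lag: float = 600.0,
    channel: int | None = None,
) -> per.CorrelationCurve:
    """Average per-segment autocorrelation curves over all ROIs."""
    profiles = segment_profiles(table, rois, bin_size, channel)
    curves = [per.autocorrelation(p, max_lag) for p in profiles]
    return per.average_curves(curves)


def averaged_cross_correlation(
    table: pd.DataFrame,
    rois: list[locio.SegmentROI],
    bin_size: float = per.DEFAULT_BIN_SIZE,
    max_lag: float = 600.0,
    channels: tuple[int, int] = (1, 2),
) -> per.CorrelationCurve:
    """Average per-segment two-channel cross-correlation curves over all ROIs."""
    profiles_a = segment_profiles(table, rois, bin_size, channels[0])
    profiles_b = segment_profiles(table, rois, bin_size, channels[1])
    curves = [
        per.cross_correlation(a, b, max_lag) for a, b in zip(profiles_a, profiles_b)
    ]
    return per.average_curves(curves)


def two_color_phase_shift(
    table: pd.DataFrame,
    rois: list[locio.SegmentROI],
    bin_size: float = per.DEFAULT_BIN_SIZE,
    max_lag: float = 600.0,
) -> dict:
    """Phase shift (degrees) between two channels from the averaged cross-correlation.

    The period is estimated from the channel-1 averaged autocorrelation; the
    phase shift is 360 times the first positive-lag cross-correlation maximum
    divided by that period.
    """
    auto = averaged_autocorrelation(table, rois, bin_size, max_lag, channel=1)
    result = per.periodicity_metrics(auto)
    period = result.period
    cross = averaged_cross_correlation(table, rois, bin_size, max_lag)
    positive = cross.lags > 0
    # first positive-lag local maximum: search below the period so the in-phase
    # repeat at ~1 period is not picked over the first extremum
    window = positive & (cross.lags <= period)
    lags = cross.lags[window]
    vals = cross.values[window]
    # local maxima; fall back to global max of the window
    local = [
        k
        for k in range(1, len(vals) - 1)
        if vals[k] >= vals[k - 1] and vals[k] >= vals[k + 1]
    ]
    k = local[0] if local else int(np.argmax(vals))
    extremum_lag = float(lags[k])
    return {
        "period_nm": period,
        "extremum_lag_nm": extremum_lag,
        "phase_shift_deg": 360.0 * extremum_lag / period,
        "autocorrelation": auto,
        "cross_correlation": cross,
    }


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Declarative run description: which stages, from what inputs, to where.

    Each requested stage needs a section that either sets ``simulate: true``
    (with optional generator-parameter overrides) or names input files
    (``localizations``/``rois`` for periodicity stages, ``counts`` for co-IP,
    mask/puncta paths for the scene stage).
    """

    analyses: list[str] = field(default_factory=lambda: list(_STAGES))
    seed: int = 0
    bin_size: float = per.DEFAULT_BIN_SIZE
    max_lag: float = 600.0
    coloc_radius: float = neurite_mod.DEFAULT_COLOC_RADIUS
    out_dir: str = "mps_run"
    mps: dict | None = None
    control: dict | None = None
    two_color: dict | None = None
    coip: dict | None = None
    scene: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for stage in self.analyses:
            if stage not in _STAGES:
                raise ConfigurationError(f"unknown analysis stage {stage!r}")
            section = getattr(self, stage)
            if section is None:
                raise ConfigurationError(
                    f"analysis {stage!r} requested but its config section is missing"
                )
            if not section.get("simulate", False):
                needed = {
                    "mps": ("localizations", "rois"),
                    "control": ("localizations", "rois"),
                    "two_color": ("localizations", "rois"),
                    "coip": ("counts",),
                    "scene": ("axon_mask", "dendrite_mask", "pre_puncta", "post_puncta"),
                }[stage]
                missing = [k for k in needed if k not in section]
                if missing:
                    raise ConfigurationError(
                        f"analysis {stage!r} needs simulate: true or inputs {missing}"
                    )


def _sim_config(section: dict, cls, seed: int, **extra):
    overrides = {
        k: v for k, v in section.items() if k in cls.__dataclass_fields__ and k != "seed"
    }
    return cls(seed=seed, **{**extra, **overrides})


def _curve_frame(curve: per.CorrelationCurve) -> pd.DataFrame:
    return pd.DataFrame({"lag_nm": curve.lags, "value": curve.values})


def _load_loc_inputs(section: dict, seed: int, kind: str):
    if section.get("simulate", False):
        if kind == "two_color":
            cfg = _sim_config(section, MPSSimConfig, seed, n_channels=2)
            table, rois, _ = simulate_two_color_localizations(cfg)
        elif kind == "control":
            cfg = _sim_config(section, MPSSimConfig, seed)
            table, rois = simulate_uniform_control(cfg)
        else:
            cfg = _sim_config(section, MPSSimConfig, seed)
            table, rois, _ = simulate_mps_localizations(cfg)
        return table, rois
    table = locio.read_localizations(section["localizations"], section.get("dialect"))
    rois = locio.read_rois(section["rois"])
    return table, rois


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages and write a report bundle to ``config.out_dir``.

    Returns the report dict (also written as ``report.json``); raises on the
    first failing stage with the stage named in the log.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    for stage in config.analyses:
        logger.info("run_pipeline: stage %s", stage)
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        section = getattr(config, stage)
        try:
            if stage in ("mps", "control"):
                table, rois = _load_loc_inputs(section, config.seed, stage)
                curve = averaged_autocorrelation(table, rois, config.bin_size, config.max_lag)
                metrics = per.periodicity_metrics(curve)
                _curve_frame(curve).to_csv(stage_dir / "autocorrelation.csv", index=False)
                locio.write_localizations(table, stage_dir / "localizations.csv")
                locio.write_rois(rois, stage_dir / "rois.csv")
                report[stage] = {
                    "amplitude": metrics.amplitude,
                    "period_nm": metrics.period,
                    "n_segments": curve.n_segments_averaged,
                }
            elif stage == "two_color":
                table, rois = _load_loc_inputs(section, config.seed, stage)
                shift = two_color_phase_shift(table, rois, config.bin_size, config.max_lag)
                _curve_frame(shift["cross_correlation"]).to_csv(
                    stage_dir / "cross_correlation.csv", index=False
                )
                report[stage] = {
                    "period_nm": shift["period_nm"],
                    "extremum_lag_nm": shift["extremum_lag_nm"],
                    "phase_shift_deg": shift["phase_shift_deg"],
                }
            elif stage == "coip":
                if section.get("simulate", False):
                    cfg = _sim_config(section, CoIPSimConfig, config.seed)
                    counts, _ = simulate_spectral_counts(cfg)
                    baits = list(cfg.bait_names[: cfg.n_baits])
                else:
                    counts = pd.read_csv(section["counts"], keep_default_na=False)
                    baits = list(section.get("baits") or sorted(
                        set(counts["sample"]) - {section.get("control_sample", "IgG")}
                    ))
                control_name = section.get("control_sample", "IgG")
                control = coip_mod.compute_dnsaf(counts, control_name)
                lists = []
                for bait in baits:
                    d = coip_mod.compute_dnsaf(counts, bait)
                    d.to_csv(stage_dir / f"dnsaf_{bait}.csv", index=False)
                    lists.append(coip_mod.fold_change_filter(d, control))
                intersection, venn = coip_mod.intersect_candidates(lists)
                pd.Series(list(intersection)).to_csv(
                    stage_dir / "candidates_intersection.csv", index=False, header=["protein_id"]
                )
                with open(stage_dir / "venn.json", "w") as fh:
                    json.dump({"-".join(map(str, k)): v for k, v in venn.items()}, fh, indent=1)
                report[stage] = {
                    "n_candidates_per_bait": [len(l) for l in lists],
                    "n_intersection": len(intersection),
                }
            elif stage == "scene":
                if section.get("simulate", False):
                    cfg = _sim_config(section, NeuriteSceneConfig, config.seed)
                    axon, dendrite, pre, post, _ = simulate_neurite_scene(cfg)
                else:
                    axon = locio.read_mask(section["axon_mask"])
                    dendrite = locio.read_mask(section["dendrite_mask"])
                    pre_df = pd.read_csv(section["pre_puncta"])
                    post_df = pd.read_csv(section["post_puncta"])
                    from .simulate import PunctaSet

                    pre = PunctaSet(pre_df[["x_nm", "y_nm"]].to_numpy(), "pre")
                    post = PunctaSet(post_df[["x_nm", "y_nm"]].to_numpy(), "post")
                locio.write_mask(axon, stage_dir / "axon_mask.tif")
                locio.write_mask(dendrite, stage_dir / "dendrite_mask.tif")
                width = neurite_mod.mean_fiber_width(axon)
                bundling = neurite_mod.dendrite_bundling_fraction(axon, dendrite)
                synapses = neurite_mod.synapse_density(pre, post, dendrite, config.coloc_radius)
                report[stage] = {
                    "mean_axon_width_nm": width.mean_width,
                    "dendrite_bundling_fraction": bundling,
                    "synapse_density_per_um2": synapses.density_per_um2,
                    "n_synapses": synapses.n_matched,
                }
        except Exception:
            logger.exception("run_pipeline: stage %s failed", stage)
            raise

    manifest = _manifest(config)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def _manifest(config: RunConfig) -> dict:
    import importlib.metadata

    canonical = yaml.safe_dump(asdict(config), sort_keys=True)
    versions = {}
    for pkg in ("mpskit", "numpy", "scipy", "pandas", "scikit-image"):
        try:
            versions[pkg] = importlib.metadata.version(pkg)
        except importlib.metadata.PackageNotFoundError:  # pragma: no cover
            versions[pkg] = "unknown"
    return {
        "config": asdict(config),
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": config.seed,
        "versions": versions,
    }


def demo_config(seed: int = 0, out_dir: str = "mps_demo") -> RunConfig:
    """Full default demo: synthetic MPS + control + two-color + co-IP + scene."""
    return RunConfig(
        analyses=list(_STAGES),
        seed=seed,
        out_dir=out_dir,
        mps={"simulate": True},
        control={"simulate": True},
        two_color={"simulate": True, "n_channels": 2, "channel_phase_offset": 0.5},
        coip={"simulate": True},
        scene={"simulate": True},
    )
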