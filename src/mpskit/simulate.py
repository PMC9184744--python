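"""Synthetic data generators for every pipeline stage.

Three families of inputs are emulated, each with the statistical structure the
downstream analyses assume:

* **MPS localizations** — single-molecule localization tables from axon
  segments carrying rings spaced ``d`` (~190 nm) apart, with finite labeling
  (Poisson localizations per ring), ring-placement jitter, localization
  precision, Gaussian lateral spread, and a uniform axial background; optional
  second color with a configurable phase offset, and a uniform (ring-free)
  negative control.
* **Co-IP spectral counts** — bait-vs-IgG spectral-count tables over a protein
  panel with true interactors enriched in the bait pulldowns and a fraction of
  counts assigned to peptides shared between protein pairs, mirroring the
  three-bait / IgG-control design.
* **Neurite scenes** — binary axon/dendrite masks built from smooth random
  paths dilated to physical widths, with pre/post synaptic puncta pairs on
  dendrites plus unpaired background puncta.

Every generator returns a ground-truth record so recovery can be tested, and
derives all randomness from named substreams of one integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from skimage.morphology import dilation, disk

from ._rng import substream
from .errors import ConfigurationError
from .io import SegmentROI

DEFAULT_BAIT_NAMES = ("betaII-spectrin", "alphaII-spectrin", "alpha-adducin")
CONTROL_SAMPLE = "IgG"


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MPSSimConfig:
    """Geometry and noise of simulated MPS axon segments (all lengths in nm)."""

    n_segments: int = 50
    segment_length: float = 2000.0
    ring_spacing: float = 190.0
    ring_axial_sd: float = 15.0
    locs_per_ring: float = 30.0
    loc_precision: float = 10.0
    background_fraction: float = 0.2
    lateral_sd: float = 30.0
    orientation: float | None = None  # radians; None -> uniform per segment
    phase: float | None = None  # nm in [0, ring_spacing); None -> uniform per segment
    n_channels: int = 1
    channel_phase_offset: float = 0.5  # fraction of ring_spacing
    seed: int = 0

    def validate(self) -> None:
        if not self.ring_spacing > 0:
            raise ConfigurationError("ring_spacing must be > 0")
        if not self.segment_length >= 2 * self.ring_spacing:
            raise ConfigurationError("segment_length must be >= 2 * ring_spacing")
        if not (0 <= self.background_fraction < 1):
            raise ConfigurationError("background_fraction must be in [0, 1)")
        for name in ("loc_precision", "ring_axial_sd", "lateral_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not self.locs_per_ring > 0:
            raise ConfigurationError("locs_per_ring must be > 0")
        if self.n_segments < 1:
            raise ConfigurationError("n_segments must be >= 1")
        if self.n_channels not in (1, 2):
            raise ConfigurationError("n_channels must be 1 or 2")
        if not (0 <= self.channel_phase_offset < 1):
            raise ConfigurationError("channel_phase_offset must be in [0, 1)")
        if self.phase is not None and not (0 <= self.phase < self.ring_spacing):
            raise ConfigurationError("phase must be in [0, ring_spacing)")


@dataclass(frozen=True)
class CoIPSimConfig:
    """Bait-vs-IgG spectral-count simulation over a protein panel."""

    n_proteins: int = 30
    protein_lengths: tuple[int, ...] | None = None  # residues; None -> drawn 200-1500
    n_true_interactors: int = 8
    bait_enrichment: float = 10.0
    baseline_count: float = 20.0
    shared_peptide_fraction: float = 0.2
    n_baits: int = 3
    n_replicates: int = 2
    bait_names: tuple[str, ...] = DEFAULT_BAIT_NAMES
    seed: int = 0

    def validate(self) -> None:
        if self.n_true_interactors > self.n_proteins:
            raise ConfigurationError("n_true_interactors must be <= n_proteins")
        if not self.bait_enrichment > 1:
            raise ConfigurationError("bait_enrichment must be > 1")
        if self.protein_lengths is not None:
            if len(self.protein_lengths) != self.n_proteins:
                raise ConfigurationError("protein_lengths must have n_proteins entries")
            if any(length <= 0 for length in self.protein_lengths):
                raise ConfigurationError("protein_lengths must all be > 0")
        if not (0 <= self.shared_peptide_fraction < 1):
            raise ConfigurationError("shared_peptide_fraction must be in [0, 1)")
        if not self.baseline_count > 0:
            raise ConfigurationError("baseline_count must be > 0")
        if self.n_baits < 1 or self.n_baits > len(self.bait_names):
            raise ConfigurationError("n_baits must be in [1, len(bait_names)]")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")


@dataclass(frozen=True)
class NeuriteSceneConfig:
    """Synthetic neurite field: masks plus synaptic puncta (pixel grid, nm units)."""

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 133.0  # nm
    n_axons: int = 6
    n_dendrites: int = 4
    axon_width: float = 800.0  # nm
    dendrite_width: float = 1200.0  # nm
    bundling_probability: float = 0.5
    n_synapse_pairs: int = 20
    pair_offset_sd: float = 50.0  # nm, per coordinate
    n_orphan_puncta: int = 10
    path_wiggle: float = 0.6  # per-step sd of the path's vertical random walk, px
    seed: int = 0

    def validate(self) -> None:
        if not self.pixel_size > 0:
            raise ConfigurationError("pixel_size must be > 0")
        for name in ("axon_width", "dendrite_width"):
            w = getattr(self, name)
            if not w > 0:
                raise ConfigurationError(f"{name} must be > 0")
            if w / self.pixel_size >= min(self.image_shape):
                raise ConfigurationError(f"{name} exceeds the image extent")
        if not (0 <= self.bundling_probability <= 1):
            raise ConfigurationError("bundling_probability must be in [0, 1]")
        for name in ("n_axons", "n_dendrites", "n_synapse_pairs", "n_orphan_puncta"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.pair_offset_sd < 0:
            raise ConfigurationError("pair_offset_sd must be >= 0")


@dataclass
class GroundTruth:
    """Generator-side record of the true parameters behind a synthetic dataset."""

    period: float | None = None
    phases: np.ndarray | None = None  # nm, per segment
    orientations: np.ndarray | None = None  # radians, per segment
    channel_phase_offset: float | None = None
    interactor_labels: dict[str, bool] | None = None
    axon_width: float | None = None
    dendrite_width: float | None = None
    bundled_axons: list[bool] | None = None
    bundled_targets: list[int | None] | None = None  # dendrite index followed, per axon
    bundling_fraction: float | None = None
    synapse_pairs: int | None = None


@dataclass
class MaskImage:
    """Binary 2D mask with a physical pixel size (nm); pixel centers at (i+0.5)*pixel_size."""

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ConfigurationError("MaskImage data must be a non-empty 2D grid")
        if not self.pixel_size > 0:
            raise ConfigurationError("pixel_size must be > 0")


@dataclass
class PunctaSet:
    """Point markers (nm coordinates, x then y) for one synaptic channel."""

    points: np.ndarray
    channel: str

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# MPS localization simulation
# ---------------------------------------------------------------------------


def _segment_origins(config: MPSSimConfig) -> np.ndarray:
    """Lay segment origins on a coarse grid so rotated segments never overlap."""
    pitch = 2.0 * config.segment_length + 1000.0
    per_row = int(math.ceil(math.sqrt(config.n_segments)))
    idx = np.arange(config.n_segments)
    return np.stack([(idx % per_row) * pitch, (idx // per_row) * pitch], axis=1)


def _n_rings(config: MPSSimConfig) -> int:
    return int(math.floor(config.segment_length / config.ring_spacing)) + 1


def _segment_geometry(config: MPSSimConfig):
    """Per-segment orientation and ring phase from dedicated substreams."""
    rng_geom = substream(config.seed, "mps", "geometry")
    n = config.n_segments
    if config.orientation is None:
        orientations = rng_geom.uniform(0, 2 * np.pi, size=n)
    else:
        orientations = np.full(n, float(config.orientation))
    if config.phase is None:
        phases = rng_geom.uniform(0, config.ring_spacing, size=n)
    else:
        phases = np.full(n, float(config.phase))
    return orientations, phases


def _emit_channel(
    rng: np.random.Generator,
    config: MPSSimConfig,
    phase: float,
    channel_offset_nm: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Axial/lateral coordinates of one channel's localizations for one segment."""
    centers = phase + channel_offset_nm + np.arange(_n_rings(config)) * config.ring_spacing
    counts = rng.poisson(config.locs_per_ring, size=centers.size)
    axial = np.repeat(centers, counts)
    axial = axial + rng.normal(0, config.ring_axial_sd, size=axial.size)
    axial = axial + rng.normal(0, config.loc_precision, size=axial.size)
    bf = config.background_fraction
    mean_bg = centers.size * config.locs_per_ring * bf / (1 - bf) if bf > 0 else 0.0
    n_bg = rng.poisson(mean_bg) if mean_bg > 0 else 0
    axial = np.concatenate([axial, rng.uniform(0, config.segment_length, size=n_bg)])
    lateral = rng.normal(0, config.lateral_sd, size=axial.size) if config.lateral_sd > 0 else np.zeros(axial.size)
    return axial, lateral


def _assemble(
    config: MPSSimConfig,
    per_segment_channels: list[list[tuple[np.ndarray, np.ndarray]]],
    orientations: np.ndarray,
) -> tuple[pd.DataFrame, list[SegmentROI]]:
    """Place per-segment local coordinates into the global frame and build ROIs."""
    origins = _segment_origins(config)
    half_width = 4 * config.lateral_sd + 50.0
    rows = []
    rois = []
    for i in range(config.n_segments):
        theta = orientations[i]
        u = np.array([math.cos(theta), math.sin(theta)])
        nvec = np.array([-u[1], u[0]])
        a = origins[i]
        for channel_index, (axial, lateral) in enumerate(per_segment_channels[i], start=1):
            xy = a + np.outer(axial, u) + np.outer(lateral, nvec)
            rows.append(
                pd.DataFrame(
                    {
                        "x_nm": xy[:, 0],
                        "y_nm": xy[:, 1],
                        "channel": channel_index,
                        "frame": i,
                    }
                )
            )
        b = a + config.segment_length * u
        rois.append(
            SegmentROI((float(a[0]), float(a[1])), (float(b[0]), float(b[1])), half_width, f"seg{i:03d}")
        )
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["x_nm", "y_nm", "channel", "frame"]
    )
    return table, rois


def simulate_mps_localizations(
    config: MPSSimConfig,
) -> tuple[pd.DataFrame, list[SegmentROI], GroundTruth]:
    """Simulate single-color localization data from periodic axon segments.

    Each segment carries rings at ``phase + k * ring_spacing`` for
    ``k = 0..floor(segment_length / ring_spacing)``; each ring emits
    ``Poisson(locs_per_ring)`` localizations jittered axially by the ring
    placement sd then the localization precision, and laterally by
    ``lateral_sd``. A uniform axial background is added so the configured
    fraction of a segment's localizations is background (in expectation).
    """
    config.validate()
    orientations, phases = _segment_geometry(config)
    per_segment = []
    for i in range(config.n_segments):
        rng = substream(config.seed, "mps", "locs", i)
        per_segment.append([_emit_channel(rng, config, phases[i], 0.0)])
    table, rois = _assemble(config, per_segment, orientations)
    truth = GroundTruth(
        period=config.ring_spacing,
        phases=phases,
        orientations=orientations,
    )
    return table, rois, truth


def simulate_two_color_localizations(
    config: MPSSimConfig,
) -> tuple[pd.DataFrame, list[SegmentROI], GroundTruth]:
    """Two-color variant: channel-2 rings offset by ``channel_phase_offset`` periods.

    An offset of 0.5 places channel-2 rings midway between channel-1 rings —
    the anti-phase (180-degree) geometry of actin-ring versus spectrin-center
    labels.
    """
    config.validate()
    if config.n_channels != 2:
        raise ConfigurationError("n_channels must be 2 for two-color simulation")
    offset_nm = config.channel_phase_offset * config.ring_spacing
    orientations, phases = _segment_geometry(config)
    per_segment = []
    for i in range(config.n_segments):
        rng = substream(config.seed, "mps", "locs", i)
        per_segment.append(
            [
                _emit_channel(rng, config, phases[i], 0.0),
                _emit_channel(rng, config, phases[i], offset_nm),
            ]
        )
    table, rois = _assemble(config, per_segment, orientations)
    truth = GroundTruth(
        period=config.ring_spacing,
        phases=phases,
        orientations=orientations,
        channel_phase_offset=config.channel_phase_offset,
    )
    return table, rois, truth


def simulate_uniform_control(
    config: MPSSimConfig,
) -> tuple[pd.DataFrame, list[SegmentROI]]:
    """Ring-free negative control: uniform axial positions, same count statistics."""
    config.validate()
    orientations, _ = _segment_geometry(config)
    mean_total = _n_rings(config) * config.locs_per_ring / (1 - config.background_fraction)
    per_segment = []
    for i in range(config.n_segments):
        rng = substream(config.seed, "mps", "locs", i)
        n = rng.poisson(mean_total)
        axial = rng.uniform(0, config.segment_length, size=n)
        lateral = rng.normal(0, config.lateral_sd, size=n) if config.lateral_sd > 0 else np.zeros(n)
        per_segment.append([(axial, lateral)])
    table, rois = _assemble(config, per_segment, orientations)
    return table, rois


# ---------------------------------------------------------------------------
# co-IP spectral-count simulation
# ---------------------------------------------------------------------------


def simulate_spectral_counts(config: CoIPSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a long-format bait-vs-IgG spectral-count table.

    Counts are Poisson with mean ``baseline_count`` everywhere except true
    interactors in bait pulldowns, whose mean is multiplied by
    ``bait_enrichment``. Proteins are randomly paired, and for paired proteins
    a binomial ``shared_peptide_fraction`` of each observation's spectra is
    assigned to a peptide shared by the pair; the remainder stays unique.

    Returns the table (columns: protein_id, length, sample, replicate,
    peptide_id, peptide_type, count, sharers) and a ground truth carrying the
    interactor labels.
    """
    config.validate()
    rng_panel = substream(config.seed, "coip", "panel")
    protein_ids = [f"P{i:04d}" for i in range(config.n_proteins)]
    if config.protein_lengths is None:
        lengths = rng_panel.integers(200, 1500, size=config.n_proteins)
    else:
        lengths = np.asarray(config.protein_lengths, dtype=int)
    interactors = set(
        rng_panel.choice(config.n_proteins, size=config.n_true_interactors, replace=False).tolist()
    )

    # random disjoint pairing for shared peptides
    partner = {}
    if config.shared_peptide_fraction > 0:
        order = rng_panel.permutation(config.n_proteins)
        for j in range(0, config.n_proteins - 1, 2):
            partner[order[j]] = order[j + 1]
            partner[order[j + 1]] = order[j]

    samples = list(config.bait_names[: config.n_baits]) + [CONTROL_SAMPLE]
    rng_counts = substream(config.seed, "coip", "counts")
    rows = []
    for sample in samples:
        for rep in range(1, config.n_replicates + 1):
            totals = np.empty(config.n_proteins, dtype=int)
            shared_part = np.zeros(config.n_proteins, dtype=int)
            for i in range(config.n_proteins):
                mean = config.baseline_count
                if sample != CONTROL_SAMPLE and i in interactors:
                    mean *= config.bait_enrichment
                totals[i] = rng_counts.poisson(mean)
                if i in partner and totals[i] > 0:
                    shared_part[i] = rng_counts.binomial(
                        totals[i], config.shared_peptide_fraction
                    )
            for i, pid in enumerate(protein_ids):
                rows.append(
                    (
                        pid,
                        int(lengths[i]),
                        sample,
                        rep,
                        f"pep_u_{pid}",
                        "unique",
                        int(totals[i] - shared_part[i]),
                        "",
                    )
                )
            # one shared peptide per pair: its observed total pools both members'
            # indistinguishable spectra; the row is repeated under each sharer
            emitted_pairs = set()
            for i in range(config.n_proteins):
                if i not in partner:
                    continue
                j = partner[i]
                pair = tuple(sorted((i, j)))
                if pair in emitted_pairs:
                    continue
                emitted_pairs.add(pair)
                sspc = int(shared_part[pair[0]] + shared_part[pair[1]])
                if sspc == 0:
                    continue
                sharer_ids = ";".join(sorted((protein_ids[pair[0]], protein_ids[pair[1]])))
                for k in pair:
                    rows.append(
                        (
                            protein_ids[k],
                            int(lengths[k]),
                            sample,
                            rep,
                            f"pep_s_{pair[0]:04d}_{pair[1]:04d}",
                            "shared",
                            sspc,
                            sharer_ids,
                        )
                    )
    table = pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "length",
            "sample",
            "replicate",
            "peptide_id",
            "peptide_type",
            "count",
            "sharers",
        ],
    )
    truth = GroundTruth(
        interactor_labels={pid: (i in interactors) for i, pid in enumerate(protein_ids)}
    )
    return table, truth


# ---------------------------------------------------------------------------
# neurite scene simulation
# ---------------------------------------------------------------------------


def _smooth_path(rng: np.random.Generator, shape: tuple[int, int], wiggle: float) -> np.ndarray:
    """Row index per column of a smooth, mostly horizontal path across the image."""
    h, w = shape
    y0 = rng.uniform(0.15 * h, 0.85 * h)
    steps = rng.normal(0, wiggle, size=w)
    y = y0 + np.cumsum(steps)
    y = uniform_filter1d(y, size=max(5, w // 16), mode="nearest")
    return np.clip(y, 1, h - 2)


def _rasterize_path(path_y: np.ndarray, shape: tuple[int, int], radius_px: int) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    cols = np.arange(shape[1])
    rows = np.clip(np.round(path_y).astype(int), 0, shape[0] - 1)
    mask[rows, cols] = True
    if radius_px > 0:
        mask = dilation(mask, disk(radius_px))
    return mask


def simulate_neurite_scene(
    config: NeuriteSceneConfig,
) -> tuple[MaskImage, MaskImage, PunctaSet, PunctaSet, GroundTruth]:
    """Simulate axon/dendrite masks and pre/post synaptic puncta.

    Dendrites and axons are smooth random paths dilated to their physical
    widths. With probability ``bundling_probability`` an axon is laid along a
    randomly chosen dendrite path (small sub-pixel offset) — a fasciculated
    pair; otherwise it takes an independent course. Synapse pairs are placed on
    dendrite paths with a Gaussian pre/post offset; orphan puncta are uniform
    over the image.
    """
    config.validate()
    shape = tuple(config.image_shape)
    rng_paths = substream(config.seed, "scene", "paths")
    rng_puncta = substream(config.seed, "scene", "puncta")

    # radius such that the rasterized ribbon (2r + 1 px) best matches the width
    dend_radius = max(0, int(round((config.dendrite_width / config.pixel_size - 1) / 2)))
    axon_radius = max(0, int(round((config.axon_width / config.pixel_size - 1) / 2)))

    dendrite_paths = [_smooth_path(rng_paths, shape, config.path_wiggle) for _ in range(config.n_dendrites)]
    dendrite_mask = np.zeros(shape, dtype=bool)
    for p in dendrite_paths:
        dendrite_mask |= _rasterize_path(p, shape, dend_radius)

    axon_mask = np.zeros(shape, dtype=bool)
    bundled = []
    targets: list[int | None] = []
    for _ in range(config.n_axons):
        is_bundled = bool(dendrite_paths) and rng_paths.uniform() < config.bundling_probability
        if is_bundled:
            target = int(rng_paths.integers(len(dendrite_paths)))
            path = np.clip(dendrite_paths[target] + rng_paths.normal(0, 0.5), 1, shape[0] - 2)
        else:
            target = None
            path = _smooth_path(rng_paths, shape, config.path_wiggle)
        axon_mask |= _rasterize_path(path, shape, axon_radius)
        bundled.append(is_bundled)
        targets.append(target)

    # synapse pairs sit on dendrite paths; coordinates in nm (x, y)
    pre_pts, post_pts = [], []
    for _ in range(config.n_synapse_pairs):
        p = dendrite_paths[rng_puncta.integers(len(dendrite_paths))] if dendrite_paths else None
        if p is None:
            break
        col = rng_puncta.integers(shape[1])
        center = np.array([(col + 0.5), (p[col] + 0.5)]) * config.pixel_size
        pre_pts.append(center + rng_puncta.normal(0, config.pair_offset_sd, size=2))
        post_pts.append(center + rng_puncta.normal(0, config.pair_offset_sd, size=2))
    extent = np.array([shape[1], shape[0]]) * config.pixel_size
    for _ in range(config.n_orphan_puncta):
        pre_pts.append(rng_puncta.uniform(0, 1, size=2) * extent)
    for _ in range(config.n_orphan_puncta):
        post_pts.append(rng_puncta.uniform(0, 1, size=2) * extent)

    pre = PunctaSet(np.array(pre_pts).reshape(-1, 2), "pre")
    post = PunctaSet(np.array(post_pts).reshape(-1, 2), "post")

    truth = GroundTruth(
        # record the *rasterized* widths (dilation radius quantizes to whole px)
        axon_width=(2 * axon_radius + 1) * config.pixel_size,
        dendrite_width=(2 * dend_radius + 1) * config.pixel_size,
        bundled_axons=bundled,
        bundled_targets=targets,
        bundling_fraction=(sum(bundled) / len(bundled)) if bundled else None,
        synapse_pairs=min(config.n_synapse_pairs, len(pre_pts)),
    )
    truth.synapse_pairs = config.n_synapse_pairs if dendrite_paths else 0
    return (
        MaskImage(axon_mask, config.pixel_size),
        MaskImage(dendrite_mask, config.pixel_size),
        pre,
        post,
        truth,
    )
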