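# Methods

## Scope and model

The package quantifies the one-dimensional periodicity of the membrane-
associated periodic skeleton (MPS) from single-molecule localization data,
filters co-immunoprecipitation spectral counts for candidate interactors, and
measures neurite-interaction phenotypes from binary images. All periodicity
statistics are 1D: segments are treated as straight, localizations are
projected onto the segment axis, and the ring's wrap around the axon
circumference is not modeled — after projection it only widens the axial
profile, which the simulation captures directly through axial jitter.

## Synthetic data

The generator is the package's stand-in for raw STORM localization tables,
co-IP count tables, and fluorescence image fields. What it emulates, per
family:

**MPS localizations.** Each of `n_segments` straight segments of length `L`
(default 2000 nm) carries rings at `phase + k·d`, `k = 0..⌊L/d⌋`, with
`d = 190 nm` and the phase drawn uniformly per segment (fixable for tests).
Each ring emits `Poisson(locs_per_ring)` localizations (default 30), jittered
axially by the ring-placement spread (`σ_ring = 15 nm`) and then the
localization precision (`σ_loc = 10 nm`), and laterally by a Gaussian
(`lateral_sd = 30 nm`). A uniform axial background is added so that the
configured fraction of a segment's localizations (default 20%) is background
in expectation. Segments are placed at per-segment random orientations on a
coarse global grid (pitch `2L + 1 µm`) so rotated segments never overlap; the
ROI half-width is `4·lateral_sd + 50 nm`, wide enough to capture essentially
all signal. Only `d` and `L` come from measured biology; density, precision
and background are not published for the original data, so the defaults were
chosen once as values typical of antibody-labeled STORM of cytoskeletal
targets — dense enough that the periodic signal is clearly detectable, noisy
enough that per-segment curves fluctuate visibly. The two-color variant
places channel-2 rings at `phase + (k + offset)·d`; `offset = 0.5` is the
anti-phase geometry of ring-bound labels versus the spectrin-tetramer center.
The uniform control keeps the count statistics but drops the rings.

What the generator does **not** reproduce: blinking/multiple returns per
fluorophore, localization-precision heterogeneity, curved axons, drift, and
ratiometric color crosstalk. Passing recovery tests therefore show the
statistics are implemented correctly and are sensitive at realistic noise
levels — not that real images of a given protein will reach any particular
amplitude.

**Spectral counts.** A panel of `n_proteins` (default 30, lengths drawn
200–1500 aa) is observed in three bait pulldowns plus an IgG control, two
replicates each. Counts are `Poisson(baseline)` (default 20) except true
interactors in bait samples, whose mean is multiplied by `bait_enrichment`
(default 10). Proteins are randomly paired; a binomial fraction (default 20%)
of each paired protein's spectra goes to a peptide shared by the pair, whose
observed total pools both members' spectra — the situation dNSAF exists to
correct. Run-to-run variation beyond Poisson noise (the dominant failure mode
of real label-free co-IP/MS) is not modeled.

**Neurite scenes.** Axons and dendrites are smoothed random-walk paths across
a 512² grid of 133-nm pixels, dilated to their physical widths (defaults 800
and 1200 nm; the dilation radius quantizes the width to an odd pixel count,
and the ground truth records the rasterized value). With probability
`bundling_probability` an axon follows a randomly chosen dendrite path
(sub-pixel offset) — a fasciculated pair. Synapse pairs sit on dendrite paths
with independent Gaussian pre/post offsets (default sd 50 nm per coordinate);
orphan puncta are uniform. Real images additionally contain crossing-induced
apparent contacts, intensity variation and segmentation error, which the
binary scenes sidestep.

All randomness derives from one integer seed through named CRC32-keyed
substreams (`SeedSequence(seed, spawn_key)`), so adding a parameter or stage
never shifts another stage's draws, and identical configs reproduce outputs
bit-identically.

## Numerical choices

- **Binning**: 10 nm. Unstated in the source analyses; 10 nm resolves the
  ~95-nm valley with ~9 bins per half period and is at the localization-
  precision scale, so finer bins only add shot noise. Lag grids are bin
  multiples, so the reported period/valley lags are quantized to 10 nm.
- **Correlation estimator**: mean-subtracted, overlap-normalized
  ("unbiased") sums, normalized by the profile variance so g(0) = 1 exactly
  and a sampled cosine returns a cosine. No wraparound. Per-segment values
  can exceed 1 slightly at large lags where the overlap is short; this is a
  property of the unbiased estimator, not an error. Zero-variance profiles
  yield an all-zero curve flagged degenerate rather than an exception, and
  degenerate curves are excluded (with a logged count) from averages.
- **Cross-correlation sign convention**: the value at lag *l* compares
  `a_i` with `b_{i+l}`; a channel shifted forward in position peaks at a
  positive lag, and `cc(a, b)(l) = cc(b, a)(−l)`.
- **Peak/valley search**: closed windows, defaults 140–240 nm (peak) and
  50–140 / 240–330 nm (valleys), overridable; ties break toward the smaller
  lag. The amplitude is computed on the *averaged* curve; condition
  comparisons then run over per-replicate averaged-curve amplitudes,
  mirroring the replicate structure of the original experiments.
- **Phase**: first-harmonic projection at a fixed period; the returned angle
  is the crest position scaled to [0, 2π). Closed-form and deterministic, at
  the cost of ignoring higher harmonics (irrelevant at these noise levels).
  Phase-aligned averaging circularly shifts profiles (linear interpolation,
  modulo the period) over the largest whole number of periods all profiles
  share.
- **t-test**: classical pooled-variance two-sample t, two-sided. Both-groups-
  constant input is answered with t = ±∞, p = 0 (or t = 0, p = 1 when equal)
  instead of dividing by zero. No multiple-testing correction, matching how
  such per-comparison p-values are conventionally reported; callers can
  Bonferroni-correct externally.
- **dNSAF**: formula as stated in the README; if every sharer of a peptide
  has zero unique counts its total is split equally. Replicates are scored
  independently and dNSAF averaged per sample before fold change (the
  combination rule is not fixed by convention; per-replicate filtering is
  available via `combine="none"`). Zero-in-control proteins detected in the
  bait are kept with an infinite fold change — absence from the IgG control
  is the strongest specificity evidence, and the filter removes only
  FC ≤ 1.
- **Fiber width**: medial-axis skeleton with width `2·EDT − 1` pixels at
  each skeleton pixel. The distance transform measures to the nearest
  *background pixel center*, half a pixel beyond the boundary on each side;
  the −1 correction makes a straight ribbon of w pixels read exactly w (and a
  1-px line read 1), where the uncorrected 2·EDT would read w+1.
- **Bundling**: dendrite skeleton against the axon mask dilated by 1 px —
  robust to single-pixel registration error, deterministic.
- **Synapse matching**: greedy one-to-one matching by ascending distance
  within the 266-nm radius. Greedy prevents double counting and is
  deterministic; tests compare its matched count against an optimal
  linear-sum assignment and agree at realistic puncta densities.
- **Otsu**: scikit-image's 256-bin histogram implementation; foreground is
  strictly above the threshold; constant images raise.

## Problem sizes

Defaults are the analysis conditions throughout: 50 segments of 2 µm for
periodicity runs (~20,000 localizations), 30-protein panels for co-IP, 512²
scenes for neurite metrics. The test suite and the acceptance script run
these full default sizes; a complete run of either takes seconds.

## Known limitations

- Straight-segment geometry only; curved neurites must be pre-cut into ~2-µm
  straight pieces (as the ROI format assumes).
- The period estimate is extremum-based on a 10-nm grid, not a sub-bin fit;
  precision is one bin.
- dNSAF shared-peptide groups support arbitrary sharer sets in the analysis,
  but the generator only produces pairwise sharing.
- The bundling fraction conflates fasciculation with incidental crossings,
  exactly as the image-level definition does; the simulation quantifies this
  (crossing background ≈ 0.1–0.3 depending on density).
- `z` coordinates are carried through I/O but ignored by the 1D statistics.
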