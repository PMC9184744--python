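# mpskit

Quantitative analysis of the neuronal **membrane-associated periodic skeleton
(MPS)** — the submembrane lattice of actin rings connected by spectrin
tetramers that repeats every ~190 nm along axons — plus the two companion
analyses used to study its interactome and functions: dNSAF-based co-IP
candidate filtering and image-level neurite-interaction metrics. A synthetic
data generator with ground truth stands in for raw super-resolution and mass
spectrometry data, so every stage is testable end to end.

Intended users: microscopists and computational biologists quantifying
periodicity in single-molecule localization (STORM/PALM) data, and anyone who
needs a reproducible, oracle-tested implementation of these statistics.

## The statistics

**Periodicity.** Localizations in an axon segment (~2 µm) are projected onto
the segment's longitudinal axis and binned at 10 nm into a profile *c*. The
normalized autocorrelation

    g(l) = ⟨(c_i − c̄)(c_{i+l} − c̄)⟩ / s²,   g(0) = 1

is averaged over 20–80 segments. The **amplitude** — g at the first peak
(~190 nm) minus the mean of the two first valleys (~95 and ~285 nm) —
measures the degree of periodicity; the first-peak lag is the **period**.
Two-color data are compared via the cross-correlation of the two channel
profiles: a first extremum at half the period means anti-phase (180°)
patterns, e.g. actin-ring components versus the spectrin-tetramer center.
Segments can also be phase-aligned (first-harmonic phase of the reference
channel) and averaged, revealing where a partner protein sits within the
repeat. Conditions are compared by two-sided unpaired Student's t-test over
biological replicates (mean ± s.e.m.).

**Co-IP filtering.** Spectral counts are scored by dNSAF: shared-peptide
counts are distributed among sharers in proportion to unique counts
(dSpC_k = uSpC_k + Σ_p sSpC_p·uSpC_k/Σ_j uSpC_j), length-normalized, and
rescaled so each sample sums to 1. Proteins are kept when the bait:IgG dNSAF
fold change is strictly > 1; per-bait lists are combined by intersection
(common to all baits) or annotated pooling (union restricted to, e.g.,
transmembrane proteins).

**Neurite metrics.** Otsu-thresholded masks are measured for mean fiber width
(medial-axis skeleton × Euclidean distance transform), dendrite bundling
fraction (share of the dendrite skeleton under the axon mask), and synapse
density (one-to-one pre/post puncta matches within 266 nm — two camera
pixels — per µm² of dendrite).

## Worked example

```bash
python examples/periodicity_demo.py
```

prints

```
periodic:  period = 190 nm (true 190), amplitude = 1.07, valleys at 90 / 280 nm
control:   amplitude = 0.026 (no rings -> flat curve)
t-test:    periodic 1.08 +/- 0.005 vs control 0.029 +/- 0.002 (s.e.m., n=3), t = 188.4, p = 4.8e-09
```

The simulated rings are spaced 190 nm; the averaged autocorrelation of 50
noisy segments (30 localizations/ring, 10 nm localization precision, 20%
uniform background) peaks at exactly that spacing, with valleys near the
half-period, while the ring-free control is flat. The t-test line is the
replicate-level condition comparison used to call a perturbation disruptive.

Other examples, one per capability: `two_color_phase.py` (180° phase
readout and aligned averaging), `coip_filtering.py` (dNSAF → fold change →
three-bait intersection, exact recovery of the simulated interactor set),
`neurite_metrics.py` (width / bundling / synapse density on a synthetic
scene), `pipeline_demo.py` (all stages from one config, with a
reproducibility manifest). The same pipeline is scriptable from the shell:
`mps demo --seed 1 --out out/`, `mps periodicity --loc locs.csv --roi rois.csv`.

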