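# taumap

Analysis pipeline for three quantitative questions about how the general
transcription factor TFIIIC recognizes RNA polymerase III type II (tRNA
gene) promoters:

1. **Cryo-EM single-particle pair mapping.** TFIIIC has two lobes, τA and
   τB, which bind the gene-internal A-box and B-box and are refined as
   *independent* cryo-EM particle populations. `taumap` pairs τA and τB
   particles per micrograph by an iterative nearest-neighbor search (the
   closest A–B pair is matched first and removed), builds the
   inter-particle distance distribution, compares it against a
   randomized-coordinate null that preserves per-micrograph particle
   counts, and computes each pair's relative orientation
   R<sub>r</sub> = R<sub>B</sub> · R<sub>A</sub><sup>−1</sup> from the
   RELION Euler angles (rot, tilt, psi; intrinsic ZYZ, so
   R = R<sub>z</sub>(γ) R<sub>y</sub>(β) R<sub>z</sub>(α)), reported as the
   Euler triplet Δαβγ.
2. **smFRET dwell-time kinetics.** TFIIIC-bound dwells from two-channel
   (donor/acceptor) TIRF traces are segmented by thresholding, and dwell
   durations are fitted by maximum likelihood to single- or
   double-exponential mixtures (EM, with right-censoring survival terms
   and optional left-truncation correction at the 200 ms frame time);
   model choice is by BIC, medians carry percentile-bootstrap intervals,
   and FRET-efficiency distributions are summarized by Gaussian mixtures.
3. **tRNA promoter motif analysis.** Non-template strand gene sequences
   are annotated with A-box/B-box intervals in gene-internal coordinates
   (+1 = transcription start, no position 0); upstream "pseudo"-A-boxes
   are found by strict wildcard matching of the degenerate consensus
   `TNGNNNANNNG` with a <30 nt proximity filter to the A-box, and
   linker-length and GC statistics are computed per gene set.

No raw particle or single-molecule data are redistributed; a first-class
synthetic-data module (`taumap.synthetic_data`) generates micrograph
fields with planted pair geometry, dwell sets and traces from stated
kinetic models, and tRNA-like gene sets, all deterministically seeded, so
every stage of the pipeline is testable end to end.  The printed tRNA-His
promoter sequences (85-bp and 120-bp constructs with wild-type and
mutated A-boxes) are packaged as annotated fixtures.

## Worked example

```python
import taumap as tm

# synthetic micrograph fields: 100 micrographs, 20 tauA/tauB pairs each,
# planted at 168 A separation (sd 10 A) with relative orientation
# (15, 128, -103) degrees under 15-degree angular noise, plus 10
# unpaired background particles per type per micrograph
cfg = tm.FieldSimConfig(seed=1)
tableA, tableB, truth = tm.gen_particle_fields(cfg)

pairs = tm.pair_particles(tableA, tableB).pairs
dist = tm.distance_distribution(pairs, bin_width=8.0)
pop = tm.orientation_population(pairs, max_distance=200.0, bin_width=10.0)
print(len(pairs), dist.mode, pop.mode)
```

prints

```
3000 164.0 (15.0, 125.0, -105.0)
```

i.e. 3000 pairs were matched, the modal distance bin is [160, 168) Å —
one 8 Å bin from the planted 168 Å separation — and the joint
orientation mode (15, 125, −105) is the 10°-bin center containing the
planted (15, 128, −103).

```python
# dwell kinetics: two-component mixture of the A/B promoter construct
dw = tm.gen_dwells(tm.DwellSimConfig(
    n_dwells=10_000, lifetimes=(1.2, 49.0), weights=(0.615, 0.385),
    frame_time=None, seed=3))
fit = tm.fit_exp_mixture(dw, k=2)
print([round(t, 2) for t in fit.lifetimes], [round(w, 3) for w in fit.weights])
```

prints

```
[1.21, 48.84] [0.617, 0.383]
```

recovering the planted lifetimes (1.2 s and 49 s) and amplitudes
(61.5%/38.5%) of the two binding modes.

```python
# promoter arithmetic on the packaged tRNA-His gene
gene = tm.annotate_trnahis()["120bp_WT"]
print(tm.linker_length(gene))                       # 32 (A/B-box distance, nt)
hits = tm.scan_upstream([gene]).matches
print(hits[0].matched, hits[0].distance_to_a_box)   # TTGAAAAGTCG 6
```

The A-box/B-box linker is 32 nt, and the pseudo-A-box (`TTGAAAAGTCG`,
ending at the +1 G) sits 6 nt upstream of the real A-box.

A thin CLI wraps the same library calls, e.g.
`taumap simulate particles --seed 1 --out sim/`,
`taumap map-pairs --star-a sim/tauA.star --star-b sim/tauB.star --out pairs.tsv`,
`taumap fit-dwells --dwells dwells.tsv --k auto`.

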