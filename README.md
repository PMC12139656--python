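# escore

Multifrequency echosounder backscatter classification for mesopelagic
surveys: a semi-supervised ellipsoid-score ("Escore") classifier on
dB-difference triplets, together with echo-integration, acoustic summary
metrics and forward scattering models for biological interpretation.

## Who this is for

Fisheries and bioacoustics researchers working with calibrated, gridded
volume backscattering strength `Sv` (dB re 1 m⁻¹) from split-beam
echosounders at several narrowband frequencies (here 18, 38, 70, 120 and
200 kHz).  In open-ocean settings mesopelagic organisms form diffuse layers
rather than discrete schools, trawl validation is sparse, and the frequency
response of the backscatter — how `Sv` changes from 18 to 120 kHz — is the
main handle for telling zooplankton, swimbladdered fish, and gas-bearing
siphonophores apart.

## The method

1. **Echo-integration.** Raw `Sv` grids are averaged in the linear domain
   (`sv = 10^(Sv/10)`) onto elementary sampling distance units (ESDUs,
   default 3 pings × 1.5 m) with a −100 dB threshold, a 15 m surface
   exclusion, and per-frequency maximum depths.
2. **dB-differencing.** Every cell is reduced to the triplet
   ΔSv = (Sv₁₈−Sv₃₈, Sv₇₀−Sv₃₈, Sv₁₂₀−Sv₃₈) — translation-invariant in
   overall level, sensitive only to spectral shape.
3. **Semi-supervised training.** Rectangular regions of interest (ROIs) are
   drawn on RGB composite echograms around visually coherent layers.  The
   cells of each ROI are refined by K-means and one cluster — the
   *echo-type* — is retained.  The library of echo-type mean triplets is
   clustered hierarchically (Ward linkage) into *echo-classes*; the class
   count is chosen by a majority vote of cluster-validity indices
   (silhouette, Calinski–Harabasz, Davies–Bouldin, Dunn, gap statistic), and
   the labelling is validated by a random forest's out-of-bag error.
4. **Ellipsoid scoring.** Each class *k* is an axis-aligned ellipsoid with
   centroid μ_k and per-axis SDs σ_k.  A cell *i* scores

       Escore(i, k) = Σ_{j=1..3} ((ΔSv_ij − μ_kj) / σ_kj)²

   a sum of squared z-scores, χ²(3)-distributed under the class's Gaussian
   model.  The cell takes the class of minimum score unless that minimum is
   ≥ the *ellipsoid threshold* (default 25, chosen by a sensitivity sweep of
   well-/mis-/not-classified percentages), in which case it stays
   unclassified.
5. **Interpretation.** Forward scattering models (DWBA bent cylinder,
   randomly oriented fluid bent cylinder, high-pass dense fluid sphere,
   damped resonant gas bubble, hybrid gas + body) predict TS(f) for
   candidate organisms; their ΔSv triplets are classified with the same
   scoring rule to suggest what each echo-class represents.  Summary metrics
   (total s_A, diel-vertical-migration strength `1 − sA_night/sA_day` over
   200 m–max depth, depth-category NASC, eddy kinetic energy `½(u²+v²)`)
   support ecological comparisons between oceanographic structures.

## Worked example

The synthetic-scene generator plants four scattering layers with distinct
ΔSv signatures (one 18-kHz-dominant, three 38-kHz-peaked with different
high-frequency slopes), 0.5 dB cell noise and along-track drift, and emits
training ROIs with truth labels:

```python
from escore import synthdata, pipeline

spec = synthdata.reference_scene(seed=0)
eset, truth, rois = synthdata.generate_scene(spec)
result = pipeline.run_train(eset, rois)

print("echo-types in library:", len(result.library))
print("index votes:", result.selection.chosen_k_by_index)
print("selected number of echo-classes:", result.selection.winning_k)
print("random-forest OOB correct rate: %.1f%%" % result.rf_report.overall_correct_pct)
for i, cid in enumerate(result.model.class_ids):
    mu = ", ".join(f"{v:6.2f}" for v in result.model.mu[i])
    print(f"echo-class {cid}: centroid ΔSv = ({mu}) dB, "
          f"dominant {result.model.dominant_khz[cid]:g} kHz")

classified, per_class, _ = pipeline.run_classify(eset, result.model)
n_eval = (classified.labels != 0).sum()
n_un = (classified.labels == -1).sum()
print(f"classified grid: {n_eval} cells, {100*n_un/n_eval:.1f}% unclassified at threshold 25")
```

prints

```
echo-types in library: 208
index votes: {'silhouette': 4, 'calinski_harabasz': 4, 'davies_bouldin': 4, 'dunn': 3, 'gap': 4}
selected number of echo-classes: 4
random-forest OOB correct rate: 100.0%
echo-class 1: centroid ΔSv = (-14.05,  -9.07, -12.92) dB, dominant 38 kHz
echo-class 2: centroid ΔSv = ( -9.07,  -0.97,  -1.93) dB, dominant 38 kHz
echo-class 3: centroid ΔSv = ( -2.99,  -2.58,  -0.66) dB, dominant 38 kHz
echo-class 4: centroid ΔSv = (  6.00,  -6.98, -13.16) dB, dominant 18 kHz
classified grid: 104208 cells, 43.4% unclassified at threshold 25
```

Four of five validity indices vote for four classes; the fitted centroids
recover the planted ΔSv means to within ~0.2 dB (class numbering is by
ascending ΔSv₁₈₋₃₈, so the 18-kHz-dominant layer lands in class 4 here);
the unclassified share is dominated by flat-spectrum background water, which
no class ellipsoid claims.  Over 98% of in-layer cells receive their true
class at the default threshold.

The same workflow is available from the shell:

```bash
escore synth --seed 0 --out-dir scene/
escore train --sv 18=scene/sv_18khz.csv --sv 38=scene/sv_38khz.csv \
             --sv 70=scene/sv_70khz.csv --sv 120=scene/sv_120khz.csv \
             --rois scene/rois.csv --seed 0 --out-dir run/
escore classify --sv 18=scene/sv_18khz.csv --sv 38=scene/sv_38khz.csv \
                --sv 70=scene/sv_70khz.csv --sv 120=scene/sv_120khz.csv \
                --model run/model.json --out-dir run/
```

Other subcommands: `integrate`, `deltasv`, `rgb`, `sweep`, `metrics`,
`scatter` (see `escore --help`).

## Layout

```
src/escore/echogrid.py    Sv containers, CSV dialect, echo-integration, NASC, solar periods
src/escore/multifreq.py   ΔSv differencing, RGB composites
src/escore/training.py    ROIs, echo-types, library clustering, validation
src/escore/scoring.py     ellipsoid fitting, Escore, cell classification, sweeps
src/escore/scattering.py  sound speed and forward scattering models
src/escore/metrics.py     total sA, DVM strength, depth-category NASC, EKE
src/escore/synthdata.py   synthetic scene generator with planted truth
src/escore/pipeline.py    end-to-end orchestration
src/escore/cli.py         command-line interface
docs/methods.md           model assumptions, parameter choices, limitations
```
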