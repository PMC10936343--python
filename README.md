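# phasorflim

Fit-free phasor analysis of time-domain FLIM (fluorescence lifetime
imaging microscopy) image stacks: a headless library plus CLI for
researchers who want reproducible, scriptable phasor pipelines — per-pixel
lifetime contrast without exponential fitting — on TIFF decay stacks or on
fully synthetic data with known ground truth.

## What it computes

Each pixel of a time-domain FLIM acquisition is a photon-arrival histogram
I(t_k) over one laser period. Its **phasor** at harmonic n of the
repetition rate f (ω = 2πnf) is

    g = Σ I(t_k) cos(ω t_k) / Σ I(t_k),   s = Σ I(t_k) sin(ω t_k) / Σ I(t_k).

Single-exponential decays of lifetime τ fall on the universal semicircle,
g = 1/(1+(ωτ)²), s = ωτ/(1+(ωτ)²); mixtures fall inside it, at the
intensity-weighted average of their components. The package provides:

* **Phasor transform** of multi-page TIFF stacks (one temporal bin per page);
* **Calibration** against a standard of known lifetime (fluorescein
  4.04 ns, SHG 0 ns, ...): phase offset φ_meas − φ_theory and modulation
  factor m_theory/m_meas, applied per pixel;
* **Lifetime maps** τ_φ = tan(φ)/ω and τ_M = sqrt(1/m² − 1)/ω;
* **Distance and fraction maps** relative to molecular species points
  (e.g. distance from free NADH at 0.4 ns for metabolic contrast);
* **Reversible 3×3 median filtering** of g/s, intensity and contrast
  thresholds, cursor (reciprocity) selection, ROI statistics;
* **Export**: 32-bit float TIFF maps (NaN = masked), CSV summaries,
  provenance logs, phasor-plot and map figures;
* **Batch processing** of many stacks with one shared parameter set;
* A **synthetic generator** (exact bin-integral decays, Poisson noise,
  invertible instrument distortion) so everything is testable without
  instrument data.

See `docs/methods.md` for the model, conventions, and limitations.

## Worked example

Simulate a calibration standard and a 2 ns sample, then run the full
pipeline (all of this works identically on real TIFF stacks via
`read_flim_stack` or the CLI):

```python
import phasorflim as pf
from phasorflim.cli import run_analysis

params = pf.default_params()          # 80 MHz, 56 bins, harmonic 1

# Rhodamine-B-like 1.74 ns reference, Poisson noise, 5000 photons/pixel
ref = pf.make_reference_stack(1.74, params, shape=(8, 8),
                              poisson_noise=True, seed=99)
calib = pf.compute_calibration(ref, 1.74, params)

stack = pf.simulate_stack(
    pf.GroundTruth(components=((2.0, 1.0),), photons_per_pixel=500.0, seed=21),
    (32, 32), params,
)
result = run_analysis(
    stack, params, calib, min_intensity=100.0, median_passes=3,
    distance_species=pf.species_from_lifetime("free NADH", 0.4, params),
)
print(result.masked_means())
```

Output:

```
SummaryStats(mean_g=0.4983878122302157, mean_s=0.49958330256576344,
             mean_taup_ns=1.9945855184527417, mean_taum_ns=1.9974935219940888,
             mean_distance=0.5549866376123183, n_pixels=1024)
```

The calibrated phasor cloud sits at (0.498, 0.500) — on the universal
semicircle, as a single-exponential decay must — and both lifetime
estimates recover the programmed 2 ns within 0.3%. The mean distance from
the free-NADH point (0.961, 0.193) is 0.555 phasor units, the kind of
contrast used to map bound/free NADH shifts. All 1024 pixels passed the
intensity threshold.

The same pipeline from a shell:

```sh
phasorflim calibrate reference.tif --tau-ref 1.74 --freq-mhz 80 --bins 56 --out cal.json
phasorflim analyze sample.tif --calibration cal.json --median-passes 3 \
    --species-tau 0.4 --outdir results/
phasorflim batch --config run.yaml        # many stacks, one summary.csv
```

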