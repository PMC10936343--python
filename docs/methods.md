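# Methods

## The phasor representation of time-domain FLIM

A time-domain FLIM acquisition records, for every pixel (i, j), a histogram
I_{i,j}(t_k) of photon arrival times over one laser period T = 1/f, split
into N temporal bins of width Δt. The fit-free phasor approach maps each
histogram to a single point

    g = Σ_k I(t_k) cos(ω t_k) / Σ_k I(t_k)
    s = Σ_k I(t_k) sin(ω t_k) / Σ_k I(t_k)

with ω = 2πnf evaluated at an integer harmonic n of the repetition rate
(f is converted to GHz so that all times and lifetimes are in ns). An ideal
single-exponential decay of lifetime τ has

    g = 1 / (1 + (ωτ)²),   s = ωτ / (1 + (ωτ)²),

which lies on the universal semicircle of radius ½ centered at (½, 0):
τ = 0 at (1, 0), τ → ∞ at (0, 0). Mixtures of non-interacting species fall
inside the circle, at the intensity-weighted average of the component
phasors — the linearity that all downstream contrast maps exploit.

**Bin-time convention.** We take t_k = k·Δt (left bin edge). The choice of
a constant time offset only rotates every phasor by a fixed angle and is
absorbed exactly by the phase calibration; the left-edge convention makes an
instantaneous decay (all counts in bin 0) land exactly at (1, 0) before any
calibration, which gives the pipeline a clean exact anchor.

**Periodic re-excitation.** When τ is comparable to T, the steady-state
decay is the wrapped sum Σ_j exp(−(t + jT)/τ) = exp(−t/τ)/(1 − e^{−T/τ})
on [0, T): a scalar multiple of the single-period exponential. Scalars
cancel in the normalized transform, so wrap-around needs no special
handling anywhere.

## Calibration

The instrument response (detector transit-time spread, electronics delays)
shifts the measured phase and shrinks the measured modulation. A reference
standard of known single-exponential lifetime τ_ref is measured, its
aggregate phasor is expressed in polar form (φ_meas, m_meas), and the
correction

    phase_offset  = φ_meas − φ_theory(τ_ref)
    modulation_factor = m_theory(τ_ref) / m_meas

is stored and applied per pixel as φ′ = φ − phase_offset,
m′ = m·modulation_factor. In Cartesian coordinates this is a rotation plus
isotropic scaling — a linear map — so it commutes with intensity-weighted
averaging and preserves mixture linearity exactly.

**Aggregation rule.** The reference's aggregate phasor is the transform of
the global summed decay of all admitted pixels, which equals the
intensity-weighted mean of per-pixel phasors. For Poisson counts this is
the minimum-variance aggregate.

**Reference choice.** The affine correction removes the τ-independent part
of the discrete-binning error (the half-bin phase advance and sinc
modulation shrink of the N-point transform) but not the τ-dependent
aliasing residual, which grows as τ shrinks relative to Δt. Calibration
practice therefore dictates choosing a standard in the lifetime range of
the sample; the recovery tests follow this protocol, selecting the nearest
of the common single-exponential standards (Rose Bengal 0.52 ns,
Rhodamine B 1.74 ns, Coumarin 6 2.5 ns, fluorescein 4.04 ns; SHG from
starch or crystals provides a 0 ns impulse reference). At 56 bins and
80 MHz the worst-case noiseless residual under this protocol is +0.6% on
the phase lifetime at τ = 0.4 ns; a single 4.04 ns reference would leave
+2.4% there.

**Harmonic consistency.** A calibration is valid only at the harmonic it
was computed at; the `CalibrationTransform` carries its harmonic and
`apply_calibration` enforces the match. Double calibration is refused.

## Lifetime maps

After calibration, each pixel's polar phasor inverts to two estimates:

    τ_φ = tan(φ)/ω        (phase lifetime, TauP)
    τ_M = sqrt(1/m² − 1)/ω (modulation lifetime, TauM)

They coincide exactly on the semicircle and diverge for multi-exponential
pixels (τ_φ ≤ τ_M inside the circle). Photon noise can push pixels outside
the physical region, where the estimators are undefined. Policy: φ outside
[0, π/2) → τ_φ = NaN (φ = 0 exactly gives τ_φ = 0); m > 1 → τ_M = NaN;
m = 0 → both NaN. NaN propagates through all downstream maps and is
excluded per-statistic from summaries.

## Filtering

Intensity thresholds and contrast-range thresholds (on TauP, TauM or
distance) are inclusive at both bounds, which keeps masks monotone: a wider
range never removes a pixel. Masks AND together and carry an ordered
provenance trail that is written into the analysis log.

The spatial filter is a 3×3 median applied to g and s (never to the
intensity), optionally repeated; it tightens the phasor cloud without the
edge blur of a mean filter. Edges use reflect padding; NaN neighbors are
excluded from each window and a NaN pixel stays NaN. Medians are not
invertible, so "reversible" is implemented by retaining the pristine
coordinates on the field and restoring them bit-exactly with
`revert_filters`. We filter the calibrated field (filtering and the
rotation/scaling calibration commute only approximately, so the order is
fixed and recorded in provenance).

## Species, distance, and fraction maps

A molecular species is a fixed point in phasor space: placed on the
semicircle from a known single lifetime (free NADH 0.4 ns, SHG 0 ns), or
explicitly anywhere in the unit square for multi-exponential species. Two
contrasts derive from species locations:

* **Distance** d_B = ||(g, s) − (g_B, s_B)||, the Euclidean phasor distance
  from species B. It is a metric (non-negative, zero iff coincident,
  1-Lipschitz in the coordinates) and is the contrast used for, e.g.,
  distance-from-free-NADH metabolic mapping.

* **Fraction** f_A of species A in a two-component A/B system. On the model
  (pixels on the AB segment) this is d_B normalized by the A–B separation.
  We compute it as the signed scalar projection of (phasor − B) onto the
  unit B→A direction: identical on the segment, but linear in (g, s)
  everywhere. The distinction matters under noise — the unsigned distance
  ratio is a norm and is strictly positively biased at the endpoints
  f_A ∈ {0, 1}, whereas the projection is unbiased at every fraction. Off
  the segment the raw projection can leave [0, 1]; an optional clip bounds
  it. Fractions are intensity-weighted, not quantum-yield-weighted, so they
  are relative photon fractions, not concentration fractions.

Cursor selection implements reciprocity: a closed disk in phasor space
selects the image pixels whose phasors fall inside it. The cursor is
circular; its radius is in phasor units.

## Synthetic data generator

The generator emulates the acquisition regime the package targets:
80 MHz repetition rate, 56 bins covering one full period, and photon
budgets of a few hundred per pixel (defaults: 500).

* **Expected histograms** are exact bin integrals of the exponential,
  exp(−t_k/τ) − exp(−t_{k+1}/τ), matching how TCSPC bins accumulate
  counts. For the phasor this is equivalent to geometric sampling, which is
  why the closed form (1 − r)/(1 − r·e^{i2πn/N}) with r = e^{−Δt/τ} is an
  exact oracle for the transform of noiseless stacks.
* **Noise** is per-pixel Poisson around the expected histogram, drawn from
  a single seeded generator so a fixed seed reproduces a stack bit-exactly.
* **Instrument distortion** is modeled as a pure phase offset plus
  modulation gain at the analysis harmonic — exactly the model the
  calibration inverts, making calibration identifiable and the
  distort-then-calibrate composition tests exact. The distorted expected
  histogram is solved as a mixture of the true decay histogram (weight
  maximized by bisection), a uniform filler, and a two-adjacent-bin spike
  pair whose transform hits the rotated/scaled target phasor exactly while
  keeping every bin non-negative. This is a phasor-domain emulation, not a
  physical IRF convolution: it is exact at the analysis harmonic and makes
  no claim at other harmonics.

**What passing tests do and do not show.** The generator reproduces the
phasor-relevant statistics of real acquisitions (decay shapes, Poisson
noise, an invertible instrument response) but not detector afterpulsing,
dark counts, pile-up, non-uniform IRFs across the field of view, or decay
truncation in time-gated systems. Recovery results on synthetic data
therefore validate the mathematics and the pipeline, not the behavior of
any particular instrument.

## Numerical choices and problem sizes

* Zero-intensity pixels are NaN from the transform onward; an all-zero
  stack warns.
* The acquisition-parameter container warns (but proceeds) when
  N·Δt deviates from 1/f by more than 0.1%.
* Float-typed TIFF input is accepted when non-negative and integral within
  1e-6 (some exporters store counts as float); synthetic noiseless stacks
  are in-memory objects and are not round-tripped through integer TIFFs.
* Exported maps are 32-bit float single-page TIFFs with NaN for
  masked/undefined pixels — readable by ImageJ-style tools; no claim of
  byte compatibility with any other package's saved matrices.
* Statistical tests use 32×32 images at 500 photons/pixel with 20 fixed
  seeds (fraction recovery) or one fixed seed per lifetime (lifetime
  recovery); these sizes give standard errors well below the tolerances
  being asserted while keeping the suite fast.
* The Poisson-noise lifetime-recovery check runs the standard preprocessing
  (3 median-filter passes) before mapping lifetimes: without spatial
  filtering, truncating m > 1 pixels at short lifetimes biases the τ_M
  median by construction.

## Known limitations

* No vendor formats (.sdt/.ptu/.fbd); input is TIFF-stack only.
* No IRF deconvolution: the calibration model is a per-harmonic affine
  correction, which is the standard phasor practice but cannot correct
  harmonic-dependent IRF structure beyond the harmonic in use.
* No correction for time-gated truncation or gate shape.
* Species placement is the user's responsibility; nothing auto-locates a
  bound-NADH endpoint.
* The distance/fraction contrasts are computed from the possibly
  median-filtered field, matching the display pipeline order; compute them
  on a reverted field if unfiltered contrasts are needed.
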