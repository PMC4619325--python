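# Methods

This note records the models, conventions and numerical choices behind
`lcqc`, and what the synthetic campaigns do and do not demonstrate.

## Masses, adducts and the isotopolog ratio

Monoisotopic masses are sums of most-abundant-isotope masses over the
elemental composition, anchored at ¹²C = 12 exactly (¹H 1.0078250319,
¹⁴N 14.0030740052, ¹⁶O 15.9949146221, plus Na, Mg, Si, P, S, Cl, K, Ca, Fe,
Se, Br, I, F at comparable precision). The table is embedded: these constants
are stable and a runtime dependency buys nothing.

Ion species carry an explicit (mass delta, charge); the m/z is
(M + Δ)/|z|. Charged adducts are electron-mass correct — [M+H]⁺ adds the
proton mass 1.00727646 Da, not the hydrogen-atom mass. The ~0.0005 Da
difference matters at high resolution: for jasmonic acid it is the
difference between 211.1329 and 211.1334 at four decimals, and the test
suite guards against the off-by-electron variant. Built-in species are
[M+H]⁺, [M+Na]⁺, [M+NH₄]⁺, [M+K]⁺, [M−H]⁻, [M+Cl]⁻; anything else can be
supplied as a user-defined (label, Δ, z).

The relative isotopolog abundance (RIA) is defined here as
intensity(M+1)/intensity(M), i.e. the first carbon isotopic peak over the
monoisotopic peak, ≈ n_C · a(¹³C)/a(¹²C) with IUPAC abundances
0.0107/0.9893. Two caveats are deliberate:

* The convention is M+1/M. Prose descriptions of this ratio sometimes invert
  the isotope labels; the orientation used here is the one under which the
  ratio grows linearly with carbon number (ratio ≈ 0.0108 per carbon),
  which is what makes it useful for carbon-count estimation.
* The computation is carbon-only. N, O and S also contribute to M+1 (and
  instruments may not resolve the fine structure), so the theoretical value
  is biased low for heteroatom-rich formulas. The measured ratio is an
  empirical area ratio and carries no such assumption.

The M+1 companion trace is extracted at target m/z + 1.00336 Da (¹³C−¹²C)
with the same ppm window and integrated over the same peak boundaries as the
monoisotopic trace.

## EIC extraction

For a target m/z t and window ±p ppm, each scan contributes the summed
intensity of all centroids with |m/z − t|/t × 10⁶ ≤ p (closed interval on
both edges), located by binary search in the sorted per-scan centroid
arrays. The per-scan matched m/z is the intensity-weighted mean of the
matched centroids. The implementation is required (and tested) to be
bit-identical to a brute-force linear filter; binary search is an
optimisation, never an approximation.

The default window is ±10 ppm — wider than the outermost default tolerance
limit (±8 ppm, red). This is intentional: a window narrower than the red
limit clips the centroids of strongly drifted files, so their area and
measured m/z are silently truncated exactly when they most need to be
flagged. Screening windows should always exceed the largest deviation one
intends to detect.

## Peak detection and integration

Peak picking uses the continuous wavelet transform with the Ricker
(Mexican-hat) wavelet, the approach established for MS peak detection:

* scales 2–32 scan units, 10 geometric steps (covers peaks of a few seconds
  up to ~1 min FWHM at 1 Hz scan rates);
* local CWT maxima per scale linked into ridge lines top-down (matching
  window scale/4, up to 2 missed scales per ridge);
* candidate peaks = ridges of length ≥ 3 with SNR ≥ 3, where SNR is the
  peak's best CWT coefficient over the 95th percentile of |CWT| at the
  smallest scale in a ±5·scale neighbourhood;
* the apex is refined as the maximum of a lightly smoothed trace
  (Gaussian, σ = scale/4) near the ridge position — the raw maximum of a
  flat-topped noisy peak jitters by a scan or two, the smoothed maximum is
  unbiased for symmetric peaks;
* among candidates whose apex lies within the ±t_R tolerance window, the
  one nearest the expected retention time wins; ties go to the higher apex.
  "No candidate" is a regular result (the feature is reported missing), not
  an error.

Peak boundaries are the nearest flanking local minima of the smoothed trace
(σ = scale/2), capped at apex ± 3·scale scan spacings so noisy baselines
cannot stretch the integration window indefinitely. The area is the
trapezoidal integral of the raw (not smoothed) intensity between the
boundaries, in counts·seconds. Whether to integrate raw-trace or
wavelet-domain boundaries was an open choice; raw-trace minima were chosen
because the integral should reflect the recorded signal, with smoothing used
only to locate stable boundary positions.

The measured m/z of a feature is the intensity-weighted mean of per-scan
matched m/z values across the scans inside the peak boundaries — weighting
by intensity makes the estimate track the scans that carry actual signal.

## References and zones

Retention time and m/z are compared against fixed references from the
target list (expected t_R, theoretical m/z) by default; both can instead be
compared against the data-based mean of found values, per sequence or
globally. Feature area has no theoretical value, so its reference is always
data-based: by default the arithmetic mean of found areas of the same
feature within the same measurement sequence. Consequences worth knowing:

* under data-based references the mean bias within a scope is zero by
  construction — the screen shows *relative* instability, not absolute
  recovery;
* not-found features are excluded from reference means (a zero would drag
  the reference down and mis-flag the files that worked) and rendered
  missing/red;
* the per-sequence scope means a between-sequence sensitivity step does not
  turn every cell red — it is visible in the per-sequence summary means and
  in the area-vs-order plot instead. Choose the global scope to flag it at
  cell level.

Zone classification is inclusive at each limit (|d| ≤ g is green, etc.) and
monotone in |d|. Default limits: mass accuracy (3, 5, 8) ppm — the standard
scheme for sub-ppm-capable instruments; retention time (6, 12, 30) s and
area bias (20, 30, 50) % as repository defaults, all overridable in the
config. Summary statistics use the sample standard deviation (n−1), the QC
convention for small n.

## The synthetic campaign generator

The generator exists so that the whole chain — file parsing, extraction,
detection, classification, reporting — is testable against known ground
truth without any instrument data. A campaign spec defines sequences (file
counts per sample-type category), target compounds (formula, ion, t_R, peak
σ, apex intensity) and injectable defects. Per run:

* scans on a fixed grid (default 1 s, the typical full-scan rate);
* each feature contributes a Gaussian peak (default σ = 5 s; an optional
  exponential tail is available for robustness checks) plus its M+1
  companion at the theoretical carbon RIA;
* centroid m/z = theoretical m/z × (1 + (shift + jitter)/10⁶), with the
  injected per-file shift (linear or piecewise over the sequence) and
  Gaussian jitter of σ = 0.5 ppm, a typical scan-to-scan spread for
  well-calibrated Orbitrap-class data;
* intensities carry a per-file lognormal scale (σ = 3 %, ordinary injection
  repeatability for a QC standard in solvent) and 2 % per-centroid noise;
* a noise floor of Poisson-count uniform-m/z centroids with exponential
  intensities exercises SNR filtering;
* defects: per-sequence sensitivity factor, linear t_R drift (s/file),
  per-file ppm shift.

The default campaign is two sequences of a standard mix of eight reference
compounds (monoisotopic masses 154.0266–464.0955 Da, t_R 6.3–32.1 min) with
twelve QC-standard injections per sequence plus blanks, matrix QCs and
samples; the defect scenario adds a 2× sensitivity step and a −5 → +5 ppm
linear drift in the second sequence — the classic between-sequence offset
and within-sequence drift pattern a QC screen must surface.

Everything is keyed on (seed, sequence, file), so single runs can be
regenerated independently and identical seeds produce byte-identical mzXML
(the writer emits no timestamps and uses fixed formatting).

What the generator does **not** model: chromatographic tailing/fronting by
default, ion suppression and matrix effects, correlated drift between
compounds beyond the shared per-file shift, resolution-dependent merging of
isotopolog fine structure, profile-mode data. Passing the recovery tests
therefore shows the screen recovers injected defects of the modelled kinds
at realistic noise levels; it does not certify behaviour on pathological
real-world chromatography.

## Test conditions and sizes

Fixture sizes were chosen to exercise every code path at desk scale: unit
campaigns use 2 compounds over a 220 s gradient window; the end-to-end
defect checks run the full eight-compound, 2 × 12-injection scenario
(~2000 scans/file, 24 files). Synthetic-peak batches use 50–100 seeded
draws. Peak SNR for these fixtures follows the chromatographic convention
S/N = 2H/h with h the peak-to-peak (≈5σ) baseline noise, so "SNR 20" means
noise σ = amplitude/50. At that level the trapezoidal area estimator's own
statistical noise over a ~7σ integration window is well below the 5 %
recovery tolerance; at per-scan σ = amplitude/20 it would not be, for any
integrator.

## Known limitations

* mzXML only (centroided, MS¹); mzML/vendor formats are out of scope.
* Targeted screening only — no untargeted feature finding, no deconvolution
  of co-eluting isomers sharing an m/z window.
* No drift *correction*: the screen measures and flags; correcting t_R or
  mass-axis drift is a separate processing step.
* The carbon-only theoretical RIA under-predicts M+1 for N/O/S-rich
  formulas (see above).
* A profile-mode file is detected only heuristically (median per-scan peak
  count), with a warning rather than a hard error.
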