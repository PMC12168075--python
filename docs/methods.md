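# Methods

## Mass and fragment chemistry

Residues are defined in a plain-text table (token, nucleoside formula,
neutral-base formula); every entry must leave the ribose remainder
C5H8O4 after base subtraction, which guards the table against typos.
An oligonucleotide with 5′-OH/3′-OH termini is the sum of its nucleoside
compositions plus one HPO3 − H2O increment per internal phosphodiester;
terminal phosphates add HPO3 (cyclic: HPO3 − H2O). Monoisotopic masses
use fixed IUPAC constants (C 12, H 1.0078250319, N 14.0030740052,
O 15.9949146221, P 30.97376151); all twelve packaged reference RNAs
reproduce their printed masses within 1 mDa. Average (chemical) masses
are deliberately not implemented.

Backbone fragments are derived from elemental compositions of the
intact sub-mers with end-group adjustments (a = B − H2O, b = B,
c = B + HPO3 − H2O, d = B + HPO3; y = Y, z = Y − H2O, w = Y + HPO3,
x = Y + HPO3 − H2O), so the pair-conservation laws
a+w = b+x = c+y = d+z = M hold by construction, not by floating-point
accident. Charging is modeled as pure deprotonation (−z·1.00727646 per
charge); no electron-mass refinement. Base loss is a single neutral BH
loss; because positional isomers of the same lost base are isobaric,
base-loss variants are enumerated and bookkept per *lost base code*,
one variant per distinct base among the covered residues. A fragment's
charge range is capped by its phosphate count (minimum one charge).
Internal (doubly cleaved) fragments are not enumerated.

## Isotope patterns

Patterns are aggregated isotopologue envelopes: per-element neutron-
count distributions (abundances from the NIST table in pyteomics)
convolved by binary-exponentiation polynomial powers, truncated at
99.9% cumulative abundance, peaks spaced 1.0033548 Da (the 13C−12C
difference). Sub-mDa fine structure within an aggregated peak is below
this centroid model, which is consistent with how the simulator renders
peaks and how the matcher looks for them. The "RNA averagine" used for
composition-free deisotoping is the mean residue of an equimolar
A/C/G/U nucleotide (C9.5 H11.75 N3.75 O7 P per 321.3 Da), scaled and
hydrogen-adjusted to the target mass; on the 8-mer fixture its envelope
agrees with the exact pattern to better than 0.05 absolute.

## The synthetic spectrum generator

The generator is first-class, tested code; it defines the conditions
under which the statistics are validated.

* Cleavage: each of `n_ions` precursors survives (default 35%,
  matching a run that dissociates ~65% of ions) or cleaves at one site
  drawn from normalized propensities. A site 5′ of guanosine carries
  `g_preference` γ (default 2.75, which puts 60% of cleavage events at
  G-sites on the 18-mer topology — the headline operating point);
  modified guanosines scale γ by factors encoding the measured effects
  (c³G 1/10, m²G and inosine 1/3, m²₂G 1/20, c¹G/c⁷G 1). Per-site
  overrides are available for sensitivity tests.
* Channels: a fraction of events (default 0) forms a/w instead of c/y;
  a base-loss fraction (default 0.1) converts one pair member (chosen
  with probability proportional to its length, position uniform within
  it) into its −BH variant. Precursor survivors lose bases at the same
  rate.
* Charge partitioning: the 5′ fragment draws z ~ Binomial(n, i/N) —
  charge roughly proportional to length, approximating Coulombically
  driven charge spreading in extended anions — clamped so neither
  member exceeds its phosphate capacity; the complement takes n − z.
  Zero-charge fragments are invisible. No quantitative partitioning law
  is established experimentally; the binomial is a documented stand-in,
  and `CleavagePropensityModel.expected_site_shares` computes the
  analytic signal shares it implies (including the visibility weight
  2 − P(z₅=0) − P(z₃=0) per site), which is what simulation-based tests
  compare against.
* Rendering: every visible species becomes its exact isotope envelope
  scaled by ion count; log-normal intensity noise (default CV 0.1),
  Gaussian m/z error (default 1 ppm), and uniform chemical-noise peaks
  (default 50, exponential intensities at 1% of the base peak) emulate
  FT-ICR behaviour. Everything is reproducible from one seed, and a
  ground-truth record (per-site channel counts, per-fragment charge
  counts) accompanies every spectrum.

What the generator does *not* emulate: secondary fragmentation of
fragments, profile-mode data, ion-optics transmission bias, detector
saturation, a collision-energy → propensity mapping (energy is a label
only), and real charge-partitioning physics. Passing tests therefore
demonstrate the internal consistency of simulator, assignment and
statistics at realistic scales — not instrument fidelity.

## Assignment

Vendor deisotoping (SNAP-style) is proprietary; the matcher here is a
transparent rule: locate peaks at mz + k·1.0033548/z, accept a
candidate when ≥ 2 consecutive isotopologues (configurable) fall within
the ppm tolerance (default 3) and the matched intensities have cosine
≥ 0.9 against the theoretical envelope. The matched run may start at
k > 0 (up to the envelope apex) for heavy species whose monoisotopic
peak is missing; the observed monoisotopic m/z is then extrapolated
back. A peak claimed by more than one accepted candidate flags every
involved assignment ambiguous; ambiguous assignments are excluded from
statistics rather than intensity-split. Internal recalibration fits a
linear observed→theoretical m/z model on calibrant assignments
(requires ≥ 2 calibrants spanning a non-degenerate range) and reports
before/after residuals.

## Statistics

* Site yields: base-loss variants are pooled into their parent
  fragment before normalization; only c/y signal enters the
  denominator. Yields sum to 100% per run by construction.
* The G-site definition includes modified guanosines but not inosine
  (which lacks the exocyclic amino group); both choices are flags,
  since inosine-substituted runs are analyzed with inosine sites
  marked separately.
* Yields are abundance-weighted across charge states (an explicit,
  switchable convention — pooling by count is not offered because the
  simulator's ground truth is count-based only up to visibility).
* The fold-change correlation normalizes each run to its total c/y
  signal before ratioing; this is required to compare separately
  acquired spectra but means a large suppression at one site inflates
  all other normalized yields, so the recovered fold change for a
  configured 10× suppression is analytically ~9 on the 18-mer. Tests
  compare against the analytic expectation, not the raw factor.
* Dissociation yield counts cleavage *events*: per site the larger of
  the two pooled complementary pair members estimates the event signal
  (the longer fragment is almost always visible; summing both would
  double-count every event and overstate dissociation). Precursor and
  precursor base-loss species count as undissociated.
* Reported percentages are conventionally rounded to the nearest
  integer for display; full precision is kept internally.

## Hydrolysis

Products h_i-j retain residues i..j of the parent; single-cut products
are enumerated as h_1-k (cyclic and linear 3′-phosphate forms, pooled
on assignment since cyclic phosphates hydrolyze further at high pH) and
h_(k+1)-N (5′-OH). Site yields divide by all assigned product plus
intact abundance — the whole species population — a convention that
reduces to the CAD site-yield definition when intact signal is zero.
Multiple-cut products are excluded (their assignment is typically
ambiguous). Kinetics follow competing exponentials: the yield of site k
is (k_k/k_tot)(1 − e^(−k_tot·t)); `rate_estimate` fits all sites
jointly by bounded least squares (initialized from the last time
point), with asymptotic standard errors from the Jacobian and a warning
flag for grossly non-monotone trajectories. On 20-seed ensembles
(10⁴ molecules, 5 time points spanning roughly one total half-life) the
median relative rate error is ~2%, well inside the 15% design bound.

## Problem sizes and numerics

Simulation-based tests use 2×10⁴–10⁶ ions per spectrum and 10⁴–2×10⁵
molecules per hydrolysis aliquot — sizes at which multinomial sampling
error is a fraction of every tolerance tested while a full suite run
stays interactive. Statistical assertions are pinned to fixed seeds;
tolerances are set from the analytic sampling error (≥ 3–4 σ), not
tuned. Degenerate inputs fail loudly: empty sequences, unknown residue
tokens (reported with offset), charges exceeding the phosphodiester
count, empty candidate lists, degenerate calibrant spans, zero c/y
signal, fewer than three time points.
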