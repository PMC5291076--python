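# Methods

This note records the models, conventions and numerical choices behind
`lilbidms`, in the order the pipeline runs.

## Mass model

All masses are **neutral, average-isotopic, in kDa**. LILBID time-of-flight
spectra of protein/nanodisc ions resolve features at the ~0.01 kDa scale,
so isotopologue structure is invisible and average masses are the right
currency. Proton loss in anionic detection (a few Da) is likewise below
display precision and ignored; species are reported at neutral mass, and
masses are displayed rounded to 0.01 kDa while full precision is kept
internally.

Peptide masses are the sum of free amino-acid masses minus one water
(18.015 Da) per peptide bond. Free amino-acid and lipid masses are both
derived from molecular formulas using a single fixed atomic-weight table
(IUPAC 2021 abridged standard atomic weights: H 1.008, C 12.011, N 14.007,
O 15.999, P 30.974, S 32.06), so every derived mass in the package is
mutually consistent. This table agrees with the standard proteomics
residue-mass tables to ≤ 0.0005 Da per residue.

Complex masses are strictly additive: `M(n,m,k) = n·M_target +
m·M_scaffold + k·M_lipid`, with no adduct or desolvation corrections.

### Isotope labeling

Cell-free expression with an algal ¹⁵N/²H amino-acid mix labels sixteen
amino acids with ¹⁵N plus ²H at non-exchangeable positions; the four
supplemented separately are Asn, Gln, Trp (¹⁵N only) and Cys (unlabeled).
"Non-exchangeable" is implemented as **carbon-bound hydrogens per residue**:
amide, hydroxyl, thiol and amine protons re-exchange in aqueous buffer and
contribute no shift. The per-residue (N count, C-bound H count) table was
built once from the residue structural formulas. Mass increments are
0.99703 Da per ¹⁵N and 1.00628 Da per retained ²H.

## Species enumeration and ambiguity

A sample is one target, one scaffold, one lipid, with constraints
`n_max` (target copies), `m_max` (scaffold copies, default 2 — a disc
carries two scaffold copies; overridable for aggregation studies), `k_max`
(lipid adducts) and `z_max` (charge, default 4). Enumeration produces every
`(n, m, k)` with `n + m ≥ 1`, ordered by mass then stoichiometry so exports
are diffable.

Two species are *ambiguous* when their signals lie within a tolerance,
default **0.10 kDa**: a 0.07 kDa gap is experimentally unresolvable while a
2.7 kDa gap is clearly resolved, so the default sits at the instrument's
effective resolving scale; it is configurable everywhere it is used.
Ambiguity is computed per charge state in mass-per-charge space;
coincidences between different charge states of different species (e.g.
the 2− state of a tetramer on the 1− state of a dimer — exact whenever one
mass is an integer multiple of another) are reported with a `cross_charge`
flag rather than mixed silently into the neutral-mass clashes.

`evaluate_modification` compares an original and a modified sample that
differ only in component masses (labeled target, swapped scaffold). For
each originally ambiguous pair it reports the new separation and a
resolved/unresolved flag. A uniform label shift δ per target copy moves a
pair of species with target copy numbers n₁, n₂ by exactly |n₁ − n₂|·δ,
which is why labeling resolves clashes between species of unequal copy
number and cannot resolve clashes between species of equal copy number.

## Forward model (synthetic spectra)

The simulator emulates what the instrument reports, directly in
mass-per-charge space — it models no droplet hydrodynamics or flight-time
physics. A scenario fixes the sample, per-species particle counts, the
laser energy (nominal range 9.5–23 mJ), instrument peak width, charge-state
weights, adduct-ladder mean, droplet count, noise amplitude, and a
mandatory seed; there is no hidden global randomness.

**Dissociation.** Laser energy strips complexes before detection: each
particle of species `(n,m,k)` loses each scaffold copy with probability
`p_scaffold(E)`, each target subunit with `p_subunit(E)` and each lipid
with `p_lipid(E)`, drawn independently per copy. Probabilities are logistic
in E (configurable midpoint/slope/maximum per class) with defaults keeping
`p_subunit < p_scaffold ≤ p_lipid` over the whole range — lipids shed
first, scaffolds leave the disc before the target complex breaks up.
Released scaffolds and subunits reappear as free monomers, so total protein
copy number is conserved. Only ordinal facts (more dissociation at higher
energy, scaffold first) are experimentally grounded; the logistic form and
its parameters are modeling choices.

**Rendering.** Each surviving species contributes Gaussian peaks of width
`σ_inst` (default 0.05 kDa; 0.2 kDa used for lipid-ladder studies) at
`(M + j·M_lipid)/z`, summed over adduct count `j` and charge `z`. Charge
weights default to (0.7, 0.15, 0.1, 0.05) for z = 1..4 — predominantly
singly charged anions. The grid is uniform, default 0.005 kDa. Additive
white Gaussian noise with σ = `noise_amplitude · max_signal / √n_droplets`
(default amplitude 0.5, 1200 droplets ≈ 1.4 % of the maximum) emulates
droplet averaging; negative ordinates are clipped.

**Adduct ladder.** The attached-lipid number of these spectra is defined
*operationally*: envelope FWHM minus bare-protein FWHM, divided by the
lipid mass. The default ladder therefore plants a discrete-Gaussian count
distribution with mean λ and σ = λ/2.3548, whose half-max span in count
space is exactly λ — the FWHM counter then recovers the planted number by
construction. A truncated Poisson(λ) option is provided for comparison,
with the caveat that its half-max span is ≈ 2.3548·√λ counts, so the FWHM
counter applied to a Poisson ladder reports that smaller number, not λ.
Whether a real disc's broad low-energy envelope reflects the lipid-count
distribution or detector broadening cannot be separated here; both knobs
(`lambda_adducts`, `sigma_inst_kda`) are exposed.

What the generator does **not** emulate: baseline drift, detector
saturation, peak asymmetry, charge stripping during flight, chemical noise
from buffer adducts. Passing recovery tests on simulated spectra therefore
validates the bookkeeping and the estimators, not instrument-specific
artifact handling.

## Spectrum processing

Normalization scales the maximum intensity to 1. Peak detection uses
prominence (default 2 % of maximum) and apex-separation (default 0.5 kDa)
filters on local maxima; candidates closer than the separation to a taller
candidate are merged into it and the survivor is flagged. Defaults were
chosen on simulator fixtures and are configurable and logged.

FWHM is measured with linearly interpolated half-maximum crossings, taking
the **outermost** crossings within the peak's prominence window. For a
single smooth peak this is the ordinary FWHM; for a partially resolved
adduct comb it is the envelope width a spectroscopist would read, which is
what the lipid-counting formula needs. When a tooth riding on an envelope
never crosses the absolute half maximum inside its window, detection falls
back to the prominence-referenced half width (the scipy convention). A
half maximum not crossed inside the window is an error naming the side.

Integrals are trapezoidal over the prominence-base window (the integration
limits are otherwise undefined for overlapping peaks). Lipid counts round
to the nearest integer, ties away from zero; the real-valued estimate is
retained alongside. Lipid counting is done on 1− peaks in neutral-mass
space only. A separate resolved-ladder counter (consecutive adduct teeth at
`base + j·M_lipid`) is provided for spectra where individual attachments
are visible.

## Assignment and statistics

Peaks are matched against every species' charge ladder within a tolerance;
candidates are ordered by absolute mass error, then fewest protein copies.
An ambiguous peak (several candidates) is never dropped or force-assigned:
it propagates as its own "ambiguous" class through the distributions, so
reported fractions never launder uncertain assignments.

Oligomer distributions group species by `(n, m)` — lipid adducts ignored —
normalize per-peak integrals to the total assigned area within each
replicate, and report mean ± sample SD (n−1; SD = 0 for a single
replicate). Replicates with zero assigned area are excluded with a warning
and counted. Overlap between adjacent peaks is partitioned at the
prominence-base boundaries.

The laser-energy series report flags violations of the expected trends
(scaffold-containing fraction non-increasing, scaffold-free non-decreasing
with energy). Because dissociation is sampled per particle, monotonicity
holds in expectation only; the check accepts an explicit slack (0 by
default) and always lists violations rather than suppressing them.
Condition comparison calls the highest target copy number whose summed
fraction exceeds a presence threshold, default 2 % — a stand-in for the
by-eye presence call, logged in every report.

## Fixtures

The registry ships printed construct masses (theoretical vs experimental,
labeled vs unlabeled, never conflated) and the nanodisc characterization
table, each value with a provenance string. One construct's labeled
theoretical mass is printed inconsistently in the source (22.83 vs 22.57
kDa); both values are stored with provenance and no adjudication. Lipid
monomer masses are not printed anywhere; they are computed from molecular
formulas (free-acid forms; the cardiolipin is the tetramyristoyl species)
with the fixed atomic-weight table and are derived values, not
transcription. Table rows recovered from a typographically garbled region
are marked low-confidence.

## Problem sizes

Simulated checks use 1000–3000 particles per species on grids of 2–5·10⁴
points, 1–3 replicates, chosen so the full suite and the acceptance script
run in seconds while keeping Monte-Carlo scatter well inside the stated
tolerances (the attached-lipid recovery, for instance, is reproducible to
±1 lipid across seeds at 1000 particles).

## Known limitations

- Charge states are forward-predicted, never inferred from envelope
  spacing; there is no charge deconvolution.
- Absolute solution concentrations are out of scope; only intensity
  fractions are reported.
- Lipid mixtures are enumerated as a total adduct count unless component
  masses differ by more than the tolerance.
- The dissociation model conserves protein copies but discards shed
  lipids; lipid-transfer between species is not modeled.
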