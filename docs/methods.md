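# Methods

This note documents the models, conventions and numerical choices
behind `massdiv`, in the order data flows through the package.

## Formula arithmetic (`massdiv.formulas`)

Formulas are neutral CHNOSP compositions in Hill notation.  Masses use
IUPAC monoisotopic values to ≥ 6 decimals (C 12 exactly, H 1.00782503207,
N 14.0030740048, O 15.9949146196, S 31.97207100, P 30.97376163);
deprotonation subtracts the proton mass 1.00727646688 Da, which already
accounts for the electron retained by the anion.

Unsaturation uses DBE = 1 + C − H/2 + (N+P)/2 with trivalent N and P;
an even-electron neutral molecule therefore has integer DBE, which is
enforced by the plausibility screen (H must share parity with N+P).
Aromaticity uses the modified aromaticity index
AImod = (1 + C − O/2 − S − (N+P+H)/2) / (C − O/2 − N − S − P), clamped
to 0 whenever numerator or denominator is non-positive — half the
oxygen is treated as carbonyl-like and does not count against
aromaticity.

Compound classes are evaluated in a fixed order: saturated (DBE = 0)
first, then aromatic (AImod > 0.666), polyphenol (0.5 < AImod ≤ 0.666),
highly unsaturated (AImod < 0.5 and H/C < 1.5), and unsaturated for
everything else (including H/C > 2 with DBE > 0).  The commonly quoted
aromatic threshold "AImod > 0.5" overlaps the polyphenol band
0.5–0.666; this package resolves the overlap the way the index's
authors do — aromatic means AImod > 0.666 — and evaluates saturation
first so that DBE = 0 always wins.  Classes are subdivided oxygen-rich
(O/C > 0.5) versus oxygen-poor (O/C ≤ 0.5, boundary inclusive on the
poor side); nitrogen-containing unsaturated formulas are flagged
"with N" instead of the oxygen split, reading the truncated published
definition as "1.5 ≤ H/C ≤ 2 and N ≥ 1".  Heteroatomic groups are CHO,
CHON, CHOS, CHOP, with any co-occurrence of N/S/P collapsed to
"others"; oxygen-free formulas fold into the same families by their
N/S/P content rather than erroring, so classification stays total.

## Peak processing (`massdiv.spectra`)

The method-detection-limit rule keeps a peak iff intensity ≥
mdl_factor × noise_level, default factor 2.5.  The noise level is
user- or instrument-supplied; when absent it is estimated as the median
intensity of the lowest decile of peaks — a deliberate stand-in for
instrument noise floors, adequate when low-intensity noise dominates
that decile (true of the synthetic model and of typical FT-ICR peak
exports).

Mass alignment is deterministic greedy single-linkage on the pooled
sorted mass list: a gap > tol_ppm relative to the left neighbour starts
a new feature; the consensus mass is the intensity-weighted mean of
member masses, and if one spectrum contributes twice to a feature the
most intense peak wins (logged).  Default tolerance 0.5 ppm —
deliberately conservative against the < 0.1 ppm calibration of the
instruments this targets, so that replicate peaks always merge while
distinct formulas (≥ 1 ppm apart in any sane library) never do.

Duplicate consensus keeps a feature for a sample only when detected in
every replicate of that sample, with the sample intensity the mean over
replicates; features surviving in no sample are dropped.  Samples with
a single replicate are an error unless explicitly allowed.
Contaminant removal is supported as a user-supplied exclusion mass
list; no built-in catalogue is shipped.

## Formula attribution (`massdiv.assignment`)

Candidate enumeration is an exhaustive pruned sweep of the bounded
CHNOSP grid (defaults C ≤ 60, H ≤ 120, N ≤ 4, O ≤ 40, S ≤ 2, P ≤ 2 —
wide enough for sulfated terpenoids and CHONP/CHOSP compositions)
within ± tol_ppm of the neutral mass, filtered by the plausibility
rule 0.3 ≤ H/C ≤ 2.5, O/C ≤ 1.5, N ≤ 4, S ≤ 2, P ≤ 2, integer DBE ≥ 0,
H ≥ 1.  The default assignment tolerance is 0.2 ppm, twice the
instrument-calibration figure.  An independent test oracle enumerates
the same space as one flat numpy grid; the two must agree exactly.

Isotope verification: the expected ¹³C₁ relative intensity is
C × 0.010816.  A candidate is vetoed if an M+1 peak exists but its
ratio deviates fractionally by more than ratio_tol (default 0.3,
reflecting typical FT-ICR isotope-ratio scatter), or if no M+1 peak
exists although the expectation lies above the detection threshold;
with an undetectable expectation the candidate passes by default.
This veto does the heavy lifting against isobaric interlopers: within
a ±0.2 ppm window above ~500 Da, competing CHNOSP candidates typically
differ by 5–20 carbons, so their predicted isotopologue ratios are
grossly incompatible with the observed one.

Selection is deterministic: longest CH₂-homologous series (series are
connected components of the CH₂-difference graph over all surviving
candidates), then smallest |error_ppm|, then fewest heteroatoms
(N+S+P), then Hill string.  Series-first is a choice — the published
criteria (N/S/P rule, isotopes, series) carry no stated precedence —
made because natural mixtures are rich in CH₂ series while random
isobaric interlopers are not.  A formula claimed by several features is
kept only at its best-matching feature; everything else is logged as
unassigned with a reason code, never fatally.

## Profiles and composition (`massdiv.profiles`)

Profiles normalize assigned intensities to sum to one per sample.
Composition percentages are offered on both a count basis (fraction of
the number of formulas — the default, matching how such results are
usually quoted) and an intensity basis (relative abundance), for both
heteroatomic and compound-class groupings; both always sum to 100.
Weighted descriptors X_w = Σ Iᵢ Xᵢ use the normalized intensities, so
equal weights reduce to plain means and every X_w is bounded by the
per-formula extrema.  Presence of a formula in a sample means
"assigned after duplicate consensus", regardless of magnitude.
Shared/exclusive sets are plain set algebra over profiles; the
polyphenol search is the shared set intersected with the polyphenol
class — no separate operator.

## Diversity statistics (`massdiv.diversity`)

Bray–Curtis is computed over the union formula universe
(missing = 0) via scipy's pairwise distances; it is symmetric, zero on
the diagonal and bounded in [0,1], but not a metric (triangle
violations are possible and deliberately not asserted).

PCoA double-centers the squared dissimilarities
(B = −½ J D² J) and eigendecomposes; coordinates are eigenvectors
scaled by √λ for positive eigenvalues only, and explained percentages
are taken over the positive-eigenvalue total.  Negative eigenvalues
(possible for non-Euclidean input) are simply dropped — no
Lingoes/Cailliez correction — because the downstream use is a 2-axis
ordination where the correction only rescales.  On Euclidean-embeddable
input the embedding reproduces the distances to 1e-8, which the tests
assert, and the implementation is cross-checked against scikit-bio's
PCoA.

Vector fitting regresses each centered metadata vector on the first
k axes (default 2, the plotted pair); r² is the explained variance
fraction and the direction cosines orient the arrow.  Significance is
permutational: the vector is shuffled over samples n_perm times
(default 10,000) with a seeded generator and
p = (#{r²_perm ≥ r²_obs} + 1)/(n_perm + 1), so the smallest attainable
p is 1/(n_perm+1), p-values are reproducible given the seed, and they
are invariant to affine rescaling of the vector.  Constant vectors are
flagged and excluded.  Ordination runs on replicate-level profiles by
default — replicates enter as separate points, restricted to the
features the consensus rule accepted for their sample — since that is
how such ordinations are usually plotted; sample-level profiles are a
flag away because published descriptions of the replicate structure
are often ambiguous.

## Annotation (`massdiv.annotation`)

The offline fixture database (35 formulas, JSON, packaged) is keyed by
canonical Hill string and validated with pydantic; entries carry the
curated isomer order, which the fixture ranking policy preserves.
"Most common isomer" has no operational definition in the literature
this serves, so the live ranking policy uses a popularity proxy —
descending annotation/literature count, ties by ascending database
identifier — and provenance is reported per backend without merging
PubChem and MetaboLights results.  Live queries require an explicit
online flag; the HTTP transport is injectable, all tests replay
recorded responses, and failures are typed (offline, backend
unavailable, malformed payload) so an empty result list is always a
genuine empty result.

## Synthetic ground truth (`massdiv.synthetic`)

The generator emulates the acquisition this package targets:
negative-mode singly charged ions, 100–1000 Da window, Gaussian mass
error with sd 0.05 ppm (half the stated < 0.1 ppm calibration bound),
lognormal intensities (median 1e6 arbitrary units, log-sd 1.0 — a
realistic ~3 decades of dynamic range), deterministic ¹³C₁
isotopologues, and Poisson(150) noise peaks per measurement, uniform
in m/z with log-uniform intensity between 0.2× and 4× the noise level
(1000).  The noise ceiling intentionally sits *above* the 2.5× MDL
threshold so that a noise fraction survives the MDL filter and must be
purged by duplicate consensus — noise is redrawn independently per
replicate, signal is redrawn in intensity and mass error but not in
identity.

Formula libraries are built as CH₂-homologous families (geometric
length, mean 3) whose members pass the valence screen, with sampling
weights over N/S/P counts and a minimum pairwise gap of 1 ppm so the
library itself contains no unresolvable near-isobars; carbon counts
6–35 put most masses in the realistic 150–600 Da range.  The study
simulator splits the library into a shared pool plus per-group
exclusive pools (20 % of the library each by default), draws the first
group's exclusives nitrogen-enriched and the others CHO-dominated
(mirroring the distinct heteroatomic chemistries of a red and a brown
alga), modulates expected intensities per solvent (lognormal, log-sd
0.5), and generates metadata as value = base + effect·1[group B] +
Gaussian noise.  All randomness flows from one SeedSequence spawned in
a documented fixed order, so studies are bit-reproducible.

What passing tests on this generator do **not** show: robustness to
adducts, multimers, multiply charged ions, isotope fine structure
beyond ¹³C₁, mass-calibration drift, or chemistry whose true formulas
fall outside the CHNOSP bounds — none of which the generator emulates.

## Problem sizes and tolerances

The validation suite runs the study at its design scale — 2 groups ×
5 solvents × 2 replicates with 500 true formulas — and asserts ≥ 99 %
per-sample formula recovery and ≥ 99 % noise elimination against the
ledger.  The enumeration oracle is checked on 1,000 random masses at
0.2 and 1.0 ppm (exact agreement required).  The permutation test's
type-I error is calibrated with 200 null vectors at 1,000 permutations
(accepted band 0.02–0.08 at α = 0.05).  Mass assertions use 1e-5 Da
for literature-rounded reference values and 1e-9 Da for internal
additivity; PCoA reconstruction uses 1e-8.  End-to-end determinism is
asserted byte-for-byte on the CLI pipeline, whose manifests contain no
timestamps for exactly that reason.
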