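# Methods

## Mass arithmetic

Monoisotopic masses (lightest stable isotope, IUPAC 2021, ≥ 6 decimals) are
hard-coded in a single constants table (`chem.MONOISOTOPIC_MASS`; H, C, N, O,
S, Na, Cu, Mg, P). All ion m/z values include the electron mass
(0.000549 Da): at the 3 ppm working tolerance this term is not negligible,
and the Cu(CH₃CN)₂⁺ lock-mass value 144.9821 — used as a regression guard —
is only reproduced when it is kept.

Lipid species formulas are assembled as *backbone + Σ free fatty acids − one
H₂O per esterified position*, with fatty acids CₙH₂ₙ₋₂dO₂. The class
backbones are not printed in the comparative-lipidomics literature for these
strains, so each was reconstructed from the standard structure; the YAML
config ships the reference SMILES next to each formula and the test suite
recomputes every formula from the SMILES with RDKit. The DGCC backbone
(C₁₀H₂₁NO₆, reconstructed as the carboxy-hydroxymethyl-choline ether of
glycerol) is the least certain of the set and is flagged in the config;
a species whose reconstructed mass disagrees with an authenticated standard
should be corrected there, not silently accepted. Pigments are named
compounds with fixed formulas, not chain families; uriolide and micromonal
are catalog stubs without pinned formulas (supplying one enables matching).
Ceramide is modeled as sphingosine (d18:1) plus one amide-linked chain; the
amide follows the same −H₂O arithmetic as an ester.

## Annotation engine

Candidates are enumerated exhaustively over the template chain space
(per-chain carbons 12–24 including odd chains, double bonds 0–6; both
[M+H]⁺ and [M+Na]⁺) plus the pigment catalog, at a precursor tolerance of
3 ppm. Fragments are matched at max(10 ppm, 0.005 Da) — MS² is acquired at
roughly a quarter of the MS¹ resolution, so the MS¹ tolerance would be too
tight. Candidate ranking is (number of matched diagnostic/acyl fragments,
regiochemistry resolved before unresolved, smaller |precursor ppm error|);
remaining ties are kept as co-annotations, never dropped.

Regiochemistry: both acyl-loss fragments must be found and the
larger/smaller intensity ratio must reach 1.2, else the status is
*ambiguous* and chains are reported unordered. The literature rule states
only "higher peak intensity"; the 1.2 margin is a documented default that
prevents noise-driven flips, and the decision depends only on the intensity
ratio, so it is invariant under uniform intensity scaling. `annotate()`
reports chains in the evidence-supported sn order with status *assigned*;
`assign_regiochemistry()` additionally distinguishes *swapped* relative to
a caller-supplied chain order.

Betaine handling: DGTS and DGTA are mass-isomeric, so composition alone
cannot separate them. Confirmation requires the 59.0735 Da trimethylamine
neutral loss; the class is then decided by the strain's lineage label
(green → DGTS, brown → DGTA), and the annotation records that the prior was
used. Without the loss or a label the class stays undetermined. The 87 Da
DGTS loss is catalogued as non-required evidence (it is not reliably
observed on this instrument class). The 80 Da epoxycarotenoid loss is
matched as a nominal window (±0.5 Da) because the lost fragment's exact
composition is not established; the prasinoxanthin dehydration requirement
(≥ 2 successive water losses) and the fucoxanthin rule (≥ 2 of 3 diagnostic
ions) are config parameters rather than hard-coded chemistry. Spectral
library lookup (e.g. GNPS) is deliberately replaced by this local rule
engine for offline reproducibility; there is no network access.

## Feature pipeline

Grouping reproduces the stated tolerances (0.1 min, 3 ppm, 2–18 min window,
2×10⁶ floor) with a documented greedy scheme, since the vendor algorithm is
proprietary: features are processed in descending area (ties broken by m/z,
RT, sample id, making the result independent of run order); each feature
joins the nearest existing group within both tolerances of its
intensity-weighted centroid or seeds a new group; a run contributing several
members to a group is represented by its most intense one. Boundary
conventions are inclusive (a feature at RT 2.0 or a group peaking exactly at
2×10⁶ is kept). Blank hiding removes groups whose max algal area is less
than 5× the max blank area (ratio unstated in the source workflow; 5 is a
common metabolomics default, exposed in config). Gap filling is zero-fill
with a per-cell provenance flag, not re-integration — raw chromatograms are
out of scope, and the downstream statistics are rank-based, which tolerates
the zero convention. The top-10 major-metabolite ranking uses strain-mean
areas over replicates (per-replicate ranking would be an alternative; the
mean is the stabler choice) with deterministic tie-breaking (area desc,
m/z asc, RT asc).

Two feature counts are reported (grouped, and after filters) because
published workflows are ambiguous about which convention a "detected ion"
count refers to; both are in `report.json`.

## Chemotaxonomy statistics

Metabolomic distance is 1 − ρ (Spearman with midranks) between strain-mean
abundance profiles of the blank-hidden, gap-filled matrix; a constant
profile raises an error naming the strain. HCA is complete linkage on that
matrix (one leaf per strain). PCA is SVD of the centered, unit-variance
scaled replicate-level matrix; zero-variance features are dropped with a
warning, explained fractions are eigenvalue shares, and the sign convention
(largest-|loading| entry positive) fixes score orientation. Patristic
distances are path sums of branch lengths (depth(i) + depth(j) −
2·depth(MRCA)); missing branch lengths are an error.

The Mantel test uses the Pearson correlation of the strictly-upper-triangle
distance vectors (the convention of the classical R implementations of this
test), one-sided greater, 999 permutations by default, null built by jointly
permuting rows and columns of the second matrix, and
p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1) with the observed statistic
included — so p ≥ 1/(n_perm + 1), and the smallest reportable value at 999
permutations is 0.001. An exhaustive mode enumerates all n! permutations for
small n and is used in tests against a naive oracle. All tolerances,
permutation counts and seeds flow from a single CLI seed via deterministic
sub-streams, so identical configs reproduce byte-identical outputs.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions: 300 ancestral
metabolites, gain and loss rates of 5 events per unit branch length
(whole-metabolome Poisson event counts — per-metabolite hazards at this
magnitude would extinguish the metabolome over the fixture tree, which
contradicts the observation that major lipid classes are shared across all
strains), Brownian log-abundance variance 1 per unit branch length,
lognormal measurement CV 0.2, 3 replicates per strain, 2 blank replicates, 1
QC (parsed and rendered but not used for drift correction). Ancestral
abundances are lognormal (median 5×10⁷, natural-log sd 1.5) so that areas
span orders of magnitude while ~98% clear the 2×10⁶ floor. Feature
identities (m/z 250–1200, RT 2.2–17.8 min) are placed pairwise separable
under the grouping tolerances, and rendering jitter stays within half of
them, so grouping recovers the true metabolite count exactly — a property
the tests assert.

Bacterial contamination is modeled as additive alien features drawn from a
shared pool (the simplest mechanism that reproduces the clustering artifact
seen when two cultures cannot be axenized): contaminated strains carry a
common prefix of a 300-feature pool at lognormal abundances (median 10⁷)
with small per-strain wobble. The mapping from a ~1:1 cell ratio to a
feature fraction is not measurable from published data, so it is a free
simulation parameter; the designed scenario uses fraction 0.5 for the two
mixotrophic strains and places bacterial abundances below the algal top-10
range, so the artifact corrupts the whole-metabolome clustering but not the
major-metabolite chemotaxonomy. Clade markers (high-abundance metabolites
forced present exactly in their clade, emulating e.g. prasinoxanthin in the
Mamiellales) anchor the top-10 matrix.

What passing these tests shows: the statistics recover a Brownian/Poisson
evolutionary signal from noisy, contaminated, blank-contaminated feature
tables at realistic scale. What they do not show: performance on real
chromatography (no peak shapes, RT warping beyond jitter, isotope envelopes,
in-source fragments, or matrix effects), nor that real metabolome evolution
is Brownian.

## Problem sizes and numerical choices

The simulation-based acceptance properties use 100 studies of 12 taxa at the
default parameters (and 30 paired seeds per point of the CV grid
{0.1, 0.5, 1.0}), which the statistics resolve comfortably; the type-I
calibration uses 1000 null simulations at 999 permutations, checked against
the exact binomial 99% interval. Grouping uses float64 throughout;
zero-area features are guarded with a 10⁻¹² weight floor in centroid
updates; Mantel permutation comparisons use a 10⁻¹² slack so the identity
permutation always counts. The fixture tree's branch lengths are invented
(the real 18S branch lengths are not published as numbers) but mirror the
published topology and depth ordering; all simulation results are reported
relative to this tree, not to the real one.

## Known limitations

* The DGCC backbone and the unverified pigment entries await confirmation
  against authenticated standards.
* Negative-mode adducts, multiple charging, isotope-pattern scoring and
  chlorophyll fragmentation are out of scope.
* Gap filling is zero-fill; quantitative (non-rank) downstream analyses
  would need re-integration.
* The annotation engine resolves DGTS/DGTA only through the lineage prior;
  a strain of unknown lineage yields an undetermined betaine class by
  design.
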