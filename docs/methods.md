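# Methods

## B-factor normalization and flexible-region detection

Per-residue flexibility is read from the Cα temperature factors of a single
chain. Raw values are z-scored, `B' = (B − ⟨B⟩)/σ(B)`, so profiles from
different crystals are comparable; the result has mean 0 and standard
deviation 1 by construction (verified to 1e-9 in the tests, and invariant
under any affine rescaling `aB + b, a > 0` of the input).

**Standard-deviation convention.** The population form (divide by N) is the
default and is recorded in the profile metadata; the sample form (N−1) is a
documented switch. For chains of crystallographic size the difference is far
below any decision threshold, but declaring it keeps profiles bit-for-bit
reproducible.

**Detection thresholds.** A flexible region is a maximal run of at least
`min_run` consecutive residues with `B' ≥ threshold`. Defaults are
`threshold = 1.0` (one standard deviation above the chain mean) and
`min_run = 3` (a one- or two-residue spike is noise, three consecutive
flagged residues describe a mobile segment). There is no community-standard
cutoff for "high flexibility"; both values are exposed on the CLI and in the
API, and the synthetic generator plants bumps far enough above threshold
that conclusions do not hinge on the exact value.

**Parsing rules.** Author residue numbering is authoritative; insertion
codes order after their base number, and two residues are "consecutive" when
adjacent in the chain with numbers differing by at most one (so inserted
residues do not break a run). For alternate locations the highest-occupancy
CA wins, ties going to the alphabetically first altloc. Waters and
CA-less heteroatoms are dropped; amino-acid-like heterogroups that do carry
a CA (MSE and friends) are kept with one-letter code `X` and a warning,
since excluding them would silently shift the profile. Multi-chain files
are normalized per chain — each chain gets its own ⟨B⟩ and σ(B).

## Consensus from a homolog alignment

The consensus at a column is the plurality residue among non-gap characters;
ties break deterministically by one-letter alphabetical order. Conservation
is quantified by the plurality frequency (used for filtering) and by Shannon
entropy of the column (reported, not filtered on, since a frequency floor is
easier to reason about than an entropy cutoff). All-gap columns are flagged
degenerate. Columns with more than 50 % gaps are excluded from mutation
proposal by default: a mostly-gapped column usually reflects an insertion
private to a few homologs, not transferable consensus information.

The structure's sequence must already be a row of the alignment; the package
maps its k-th non-gap character to its column and adds a user-supplied
offset to convert sequence positions to structure numbering. Building the
alignment itself is out of scope — use any aligner and pass the result in.

## Mutation proposal

A candidate is emitted at every position that (i) lies in a flexible region,
(ii) maps to a column whose consensus differs from the wild-type residue,
and (iii) passes the frequency (≥ 0.5) and gap (≤ 0.5) filters. Gapped query
positions are skipped with a warning. Proposed cysteines are flagged
(`introduces-cysteine`, a disulfide/oxidation risk) but not suppressed —
that is a judgement call for the experimentalist. The ranking score
`0.5·min(B'/3, 1) + 0.5·consensus_freq` caps the flexibility term at
`B' = 3` (beyond three standard deviations, "more flexible" is no longer
more informative) and exists purely to order the output; no candidate is
ever dropped because of its score.

## Kinetics

The Lineweaver–Burk fit is unweighted OLS of `1/v` on `1/[S]`. The
double-reciprocal transform is the classical procedure for this assay
family, and is kept as the default for comparability, but it over-weights
the smallest rates; the nonlinear least-squares fit of the hyperbola
(initialized from the linear estimate) is provided as the recommended
cross-check, and on 2 % multiplicative noise the two agree to well within
the noise (median Km discrepancy ≈ 2 %).

Turnover numbers are deliberately accepted as input. Published kcat values
are often on a lab-specific basis (active-site titration, subunit vs
holoenzyme mass) and cannot be reconstructed from Vmax alone; when no kcat
is supplied the package derives `kcat = Vmax·M/60` (Vmax in U/mg, M in kDa,
giving /s) and labels the result `derived`, never silently mixing the two
conventions. Catalytic efficiency is `kcat/Km` in /s/mM; fold changes are
plain mutant/wild-type ratios reported to two decimals.

## Thermal inactivation

Residual activity is modelled as first-order decay,
`residual(t) = A0·exp(−kt)`, fit by OLS of `ln(residual)` on time
(non-positive residuals are excluded; at least three positive points are
required). The half-life is `ln 2 / k` identically. The alternative
`nearest-timepoint` method returns the sampled time whose residual is
closest to 50 % (ties to the earlier time); it exists to reproduce
half-lives read directly off published time courses, where the sampling
grid, not a fit, sets the precision. Residual activities above 100 % are
kept with a warning rather than truncated — renormalizing would hide assay
drift.

## Ensemble post-processing

Ensembles are multi-MODEL PDB files (one MODEL per frame, identical atom
order); no binary trajectory formats are read. Coordinates are held in nm
internally; PDB Å are converted on input.

Superposition uses the closed-form least-squares rotation (SVD of the
covariance of the centered point sets) with the determinant guard that
replaces an improper rotation by the best proper one. The default fitting
selection is all Cα atoms against the first frame; fewer than three or
collinear selected atoms raise rather than return a spurious fit.

RMSF is `sqrt(⟨|r_i(t) − ⟨r_i⟩|²⟩)` per selected atom, reported per residue.
Superposition is the caller's explicit step: for ensembles generated without
global motion it is legitimately skipped, and the fit itself absorbs a small
share of the fluctuation (six rigid-body degrees of freedom out of 3A
coordinates), which is visible when comparing against the closed-form
expectation below.

Hydrogen-bond occupancy is the percentage of frames in which the
donor–acceptor heavy-atom distance is ≤ 0.35 nm, with a D–H⋯A angle test
(≥ 120°) applied only when a hydrogen is named and an angle cutoff set —
crystallographic and coarse ensembles usually carry no hydrogens. Both
cutoffs follow common practice for geometric H-bond criteria and are
config-exposed; occupancy is monotone in the distance cutoff and invariant
to frame order.

## Synthetic generators and what passing tests mean

Each generator is seeded, uses one private RNG, and writes a truth manifest;
downstream tests read ground truth only from the manifest.

* The structure generator plants its flexibility bump on a baseline built
  from a plateau (z between roughly 0.3 and 0.7 baseline units) plus
  scattered deep "rigid-core" dips near −2. The dips carry enough variance
  that no plateau residue can reach `B' = 1`, so the planted window is
  provably the only detectable region — the detection tests are exact, not
  statistical. Geometry is a straight line; nothing downstream of B-factor
  extraction reads it.
* The alignment generator draws columns independently: consensus residue
  with the requested probability, otherwise uniform over the remaining 19,
  with gaps at the requested rate outside the query row. Defaults (92
  sequences, 70 % plurality, 10 % gaps) make consensus recovery essentially
  certain. Real alignments are phylogenetically correlated; nothing here
  tests robustness to clade structure.
* Kinetics/decay generators evaluate the exact models on the standard
  designs (8 doubling dilutions from 10 mM; the 50 °C grid to 120 min and
  the 60 °C grid to 90 min) with multiplicative Gaussian noise of stated CV
  (default 2 %).
* The ensemble generator perturbs a helical trace by per-residue isotropic
  Gaussian noise, so the true per-residue RMSF is `σ√3`; optional per-frame
  random rigid transforms exercise superposition, and an optional
  donor/acceptor pair is inside the bond cutoff in exactly
  `round(p/100·F)` frames, making occupancy recovery exact.

Passing these tests demonstrates correctness of the computations on data
matching the stated models. It does not validate the biological premise that
flexible-position consensus mutations stabilize a given enzyme, nor
reproduce quantities that depend on data not distributable with the package
(crystal B-factor tables, long MD trajectories); for those, the test suite
substitutes the closed-form and planted-truth checks above.

## Problem sizes and numerical choices

The default verification workloads are desk-scale: 1000 random profiles for
the region-scan equivalence check, 500 noisy kinetic replicates (median Km
recovery error ≈ 2.3 %, bound asserted at 10 %), 50 noisy decay replicates
against a dense grid-search oracle, a 5000-frame ensemble for the `σ√3`
check (2 % tolerance per residue), and 100–200-frame ensembles elsewhere.
The whole suite runs in a few seconds on one CPU. Fits raise informative
errors on degenerate input (zero rates, non-hyperbolic reciprocal plots,
non-decaying series, constant B-factors, collinear superposition
selections) instead of returning out-of-domain parameters.

## Design shape

The two genuinely regression-shaped operations (the Michaelis–Menten fit
and the first-order decay fit) are scikit-learn estimators with `fit`,
`predict` and fitted attributes, so they plug into sklearn pipelines and
model selection; the module-level functions wrap them. The rest of the
pipeline — parsers, consensus counting, rule-based design, ensemble
post-processing, generators — is deliberately plain functions over frozen
dataclasses: there is nothing to "fit", and the intermediate objects
(profiles, regions, maps, candidates) are the scientific record the CLI
serializes.
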