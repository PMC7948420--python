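# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `ptmforge`, in the spirit of a statistics
package's model documentation: what is computed, under which
assumptions, and what the synthetic benchmarks do and do not establish.

## Peptide chemistry

Masses are monoisotopic throughout. Residue masses and the water mass
come from pyteomics' standard table; the proton mass is 1.007276 Da.
For a peptidoform with charge z,

    M = Σ residue masses + 18.010565 + Σ modification deltas
    m/z = (M + z · 1.007276) / z

m/z values are reported to two decimals (round-half-even), matching the
convention of instrument-vendor browsers; comparisons against reported
values use a 0.005 Th tolerance, i.e. agreement at the printed
precision.

**Propionylation.** In-gel derivatization with propionic anhydride
labels free lysine ε-amines and (optionally) peptide N-termini. A
monomethylated lysine retains a free proton on the ε-amine and is still
propionylated (methyl + propionyl); di- and tri-methylation block the
site. `propionylate()` encodes exactly this rule; untagged lysines
default to me0. For the K36-containing tryptic peptide KSAPSTGGVKKPHR
this yields three propionyl groups for me0/me1 and two for me2/me3, and
the four z = 3 channels 539.97 / 544.65 / 530.64 / 535.31 Th.

**Digestion.** Cleavage rules follow the common search-engine enzyme
definitions: trypsin and chymotrypsin (F/Y/W/L/K/R) cleave C-terminal to
their residues but not before proline; LysargiNase cleaves N-terminal to
K/R; Asp-N in ammonium-bicarbonate buffer is configured to cleave
N-terminal to both D and E by default (a D-only variant is available,
since reagent specificity differs between suppliers). Products with up
to `max_missed` internal missed cleavages are emitted in deterministic
order; with zero missed cleavages they tile the protein exactly.
Coordinates are 1-based inclusive everywhere in the package.

## PSM filtering and collation

The filter admits a PSM iff FDR < 0.01 **and** ion score ≥ 30 **and**
expectation value p < 0.05 **and** every localized modification site on
it has localization probability ≥ 95 %. Boundary semantics mirror the
inequality symbols of the standard reporting convention (strict for FDR
and expectation, inclusive for score and localization). A PSM failing
any criterion contributes no sites: this is the conservative reading in
which a single dubious spectrum cannot seed a "high-confidence" site.
Manual spectral inspection cannot be algorithmized; it survives only as
an optional pass-through flag on records.

Collation deduplicates peptidoforms on (protein, sequence, modification
string) and sites on (protein, position, PTM type), aggregating the
(protease, fragmentation) pairs of all supporting PSMs as the site's
evidence set. Peptides are located in the parent protein by exact
substring match; an unlocatable peptide is an error, and the first
occurrence is used when a peptide occurs more than once (ambiguity is
negligible at tryptic peptide lengths).

## XIC integration and stoichiometry

The integrator is a documented functional stand-in for proprietary
vendor peak-integration algorithms, whose smoothing and baseline
parameters are unpublished; its contract is simply "area of the XIC
peak", and it is validated against analytic areas rather than against
any reference implementation. Choices:

* baseline = median of the lowest decile of in-window intensities;
* apex = maximum of the baseline-subtracted signal; bounds walk outward
  from the apex until the signal drops below 0.5 % of the apex (an
  explicit `rt_window` overrides detection entirely);
* area = trapezoidal integral of the baseline-subtracted signal, clipped
  at zero. An all-zero or signal-free trace yields area 0 with an
  `empty` flag rather than an error (the methyltransferase-knockout
  case).

On noise-free rectangular and Gaussian peaks the recovered area is
within 1 % of the analytic value (the 0.5 % bound cut captures 99.9 % of
a Gaussian's mass). Occupancy is strictly relative — no correction for
ionization-efficiency differences between modified and unmodified forms
— and is undefined (NaN, flagged) when both areas are zero. Isobaric
peptidoforms are resolved by nearest expected retention time with a
0.5 min tolerance; a peak equidistant between two expectations within
that tolerance is flagged ambiguous rather than assigned.

## Ordinal regression

Both models are fitted by Newton iterations with step-halving on the
exact analytic score; the Hessian is obtained by central finite
differences of the score (step 1e-5), and convergence requires an
infinity-norm score below 1e-6. Starting values are the pooled empirical
cumulative logits (cutpoints) and zero (effects). Step-halving also
enforces the strict ordering of the cutpoints. The observed-information
inverse at the optimum provides Wald standard errors, two-sided
p-values, and 95 % CIs for the common odds ratio. Divergent estimates
(|β| > 20, arising from degenerate strain distributions / complete
separation) raise a dedicated error instead of returning a sham fit.
The proportional-odds fit agrees with statsmodels' `OrderedModel` (an
independent generic-optimizer route) to 1e-4 in all parameters on fixed
data; that cross-check lives in the test suite, not in the
implementation.

Replicate-level state *fractions* are modeled as weighted multinomials
with a declared effective count per replicate (default 1000), making the
precision that drives significance an explicit, documented assumption
rather than a hidden scaling; a raw-counts mode bypasses this when true
counts exist. Consequently the package does not attempt to reproduce
any specific published p-value whose underlying effective sample size is
unrecorded — significance on real data is only meaningful relative to a
declared precision.

The adjacent-category model with per-boundary slopes is, for a K-strain
comparison, the saturated between-strain model; the proportional-odds
model is nested at the null, so the likelihood-ratio statistic is
referred to chi-square with df equal to the parameter difference (2 per
non-reference strain pair beyond the common slope). Null simulations at
the default generator settings confirm uniform p-values.

## Sequence context

* **Disorder**: a site is disordered iff its per-residue score is ≥ 0.5
  (the usual disorder-predictor convention); the threshold is
  configurable. Tallies are validated against exhaustive per-residue
  counting.
* **Domains**: 1-based inclusive intervals, endpoints in-domain.
* **Alignment**: global alignment with free end gaps (semi-global), a
  Gotoh three-state dynamic program in which a gap run costs
  `open + (L−1)·extend` internally and 0 when it touches either end of
  the alignment. Default scoring is BLOSUM62 with 12/3 penalties —
  common free-end-gap defaults, configurable, since conserved-site
  counts on real orthologs depend on scoring choices that published
  alignment-GUI workflows rarely record; such counts are therefore not
  treated as bit-reproducible quantities. Traceback ties resolve
  deterministically (diagonal, then the gap consuming the query).
  Optimality is verified against an independent suffix-recursion oracle
  on all tested pairs up to length 8 and against pure path enumeration
  up to length 5. Cross-species analysis beyond two sequences is
  realized as repeated pairwise anchoring to the yeast sequence, not a
  full multiple alignment — a documented limitation.
* **Conservation**: a phosphosite maps through the alignment column map;
  aligned-to-gap → *not aligned*; partner residue in {S, T, Y} →
  *residue conserved*; additionally listed in the partner's known
  phosphosite set → *phosphosite conserved*.

## Net-charge model

The Set2p N-terminal window (1–15) is represented by a
composition-faithful model sequence (`MAKAASASASEDEKE`): lysine 3,
phosphorylatable serines 6/8/10, the EDEKE acidic patch at 11–15, and
uncharged filler at unannotated positions, which cannot affect any
computed charge. Counting rules: +1 N-terminus, +1 per K/R, −1 per D/E,
−2 per phosphoserine (both phosphate ionizations at physiological pH),
S→A = 0, S→D = −1 (a mimetic restores only one charge), histidine 0.
The model is additive by construction: each single S→A raises the window
charge by +2 and each S→D by +1 relative to the phosphorylated wild
type, giving the ladder −7 / −6 / −5 / −4 / −1.

## Network admission

Fold changes are interpreted on the signed linear scale as supplied
(vendor exports differ; a log2 interpretation is a caller-side
transform). Motif scores are admitted strictly above 2. Physical
interaction records are admitted without a threshold at protein level;
site-less records corroborate all site-level edges of the same
regulator/substrate pair. Genetic interactions never create edges.
Conflicting quantification records from different source datasets are
kept as separate evidence lines rather than deduplicated. Every
assembled edge is guaranteed ≥ 1 non-genetic evidence line (asserted),
and regulators touching ≥ 2 enzymes are flagged multi-substrate.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of (parameters, seed); one global seed
fans out through `SeedSequence(seed, spawn_key=(k,))` with a fixed `k`
per generator, so regenerating one fixture never perturbs another.
Defaults encode the study conditions: three biological replicates per
strain; a wild-type methylation distribution of ~40/15/15/30 % (me0–me3,
encoded as the default cutpoints −0.405/0.201/0.847); planted
occupancies spanning 0.1–26 %; 5 % apex-relative Gaussian XIC noise
(each trace's noise scales with its own peak apex, as scan-to-scan
variation does; an analyte-free trace carries a 1 %-scale residual
background); PSM scores straddling all four filter thresholds with each
decoy failing exactly one criterion.

Simulated inputs are deliberately idealized: Gaussian chromatographic
peaks without tailing or co-eluting interference, exact peptide
identities without search-engine ambiguity, noise-free site positions,
and evidence tables whose noise fails rules cleanly. Recovery tests on
these fixtures therefore establish *correctness of the implemented
rules and estimators* — exact site recovery, area/occupancy accuracy
(±0.03 across the observed occupancy range), CI coverage and LR
calibration, exact network recovery — not robustness to the messier
failure modes of real LC-MS data (chimeric spectra, retention drift,
matrix effects), which no synthetic benchmark of this kind can certify.

Benchmark problem sizes — 400-residue proteins, 25–40 PSM tables,
3001-point traces, effective multinomial counts of 1000–2000, 100–200
simulation replicates — were chosen as the smallest sizes at which the
asymptotic statistical properties under test are expected to hold.

## Known limitations

* Occupancy and methylation fractions are relative, not absolute,
  stoichiometries.
* The XIC integrator is not a reimplementation of any vendor algorithm;
  on strongly tailing peaks its bounds differ from vendor output.
* The ordinal models treat replicates as exchangeable multinomials; no
  overdispersion/random-effect term is fitted.
* Alignment-based conservation depends on the chosen substitution
  matrix and penalties; defaults are sensible, not canonical.
* FDR estimation, spectrum parsing/rescoring, disorder prediction and
  motif scoring are out of scope: the package consumes their outputs.
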