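# Methods

This note documents the models, conventions and numerical choices behind
`caminer`, and what the synthetic-data generators do and do not emulate.

## Screening cascade

The cascade operates on predicted proteins plus their standard-format
annotations; it never runs assembly, gene calling, HMMER, BLAST or Phobius
itself.

**Branch assignment.** A protein enters the SCAP branch if it has at least
one domain hit whose versioned Pfam accession belongs to the configured
SCAP set (eight CA-related profiles by default). No e-value threshold is
applied at this step — the domain table's own reporting thresholds are
taken as given. Proteins without a SCAP hit enter the similarity (fnr)
branch when they have a hit at e-value ≤ 10⁻⁵⁰, inclusive. The two
branches are disjoint by construction.

**Keyword filtering.** The fnr reference is built from titles matching
"carbonic anhydrase" or "carbonic dehydratase" as case-insensitive
substrings on word boundaries, or "ca" as a whole token (tokens are maximal
alphabetic runs). The whole-token rule exists because "ca" as a plain
substring would match nearly every protein title ("calcium", "catalase",
"cadherin"); tokenization is a repo convention.

**Curation.** In order: sampling-environment filter (temperature ≥ the
configured minimum, default 90 °C, and pH > 7 when alkalinity is required),
motif scan, gene boundary check, length plausibility, SP/TM flagging,
de-duplication. A candidate is selected when it has branch evidence and
passes every check and is the representative of its identity cluster.

* *Motifs.* Patterns use uppercase literals and lowercase `x` as a wildcard
  over the 20 standard residues (the ambiguity code X does not match).
  All overlapping matches are reported, 1-based.
* *Boundaries.* First codon ∈ {ATG, GTG, TTG}, last codon ∈
  {TAA, TGA, TAG}. Contig-edge (partial) predictions fail the truncated
  side but are reported with reasons rather than dropped silently. An `N`
  in a boundary codon fails that codon when N-tolerance is enabled;
  otherwise non-ACGT characters are an error.
* *Length.* Within `[0.5, 2.0] ×` the configured family mean length
  (default 180 residues, a plausible β-CA family mean — e.g. the reference
  enzyme here is 168 residues; the window is deliberately loose since the
  published screen states no number).
* *SP/TM.* Signal-peptide or transmembrane predictions are recorded as a
  flag and a reason; the default policy is flag-only because the published
  screen "evaluated" topology without stating outright rejection. A
  `reject` policy is available.
* *Identity and de-duplication.* Pairwise identity is computed from a
  global (Needleman–Wunsch) alignment with match +1, mismatch 0, linear
  gap −1, as identical columns over the alignment length including gaps.
  The aligner is implemented in-repo; the pair is ordered lexicographically
  before alignment and the traceback prefers diagonal moves, making the
  value deterministic and symmetric. Clustering is greedy: sequences are
  visited by descending length (ties by id) and join the first
  representative at identity ≥ 90 % (inclusive), else found a new cluster.
* *Determinism.* Reports are computed on id-sorted inputs, so row order of
  any table cannot affect outcomes.

## Stopped-flow kinetics

CO₂ hydration releases one proton per turnover. In the assay the falling pH
converts phenol red to its protonated (yellow) form and the absorbance of
the deprotonated form decays.

**Buffering factor.** The conversion from absorbance rate to proton-release
(= CO₂ hydration) rate is

Q = (d[protons buffered]/dpH) / (dA/dpH),

with both derivatives evaluated analytically at the working pH: each
buffering species contributes −ln10 · C · f(1−f) (f its protonated
fraction), and the optics contribute dA/dpH = ln10 · ε·l · f_d(1−f_d) with
f_d the deprotonated indicator fraction. Units: mol L⁻¹ per absorbance
unit. `epsilon_path` folds extinction coefficient, indicator concentration
and path length into a single instrument constant (absorbance per mole
fraction deprotonated). The absolute CO₂ rates therefore depend on this
linearization convention; the implementation is validated by round-trip
against the mechanistic trace generator (which shares no code path with Q)
rather than against any particular published algebraic form.

**Rates and fitting.** Initial rates are ordinary least-squares slopes over
a configurable window (default 10–20 s, the assay protocol's convention).
The uncatalyzed slope is subtracted signed; a run where the background is
faster than the catalyzed trace is flagged as anomalous. Michaelis–Menten
constants come from nonlinear least squares with fixed initialization
(V₀ = max rate, K₀ = median substrate) so the fit is deterministic, with
standard errors from the fit covariance. Solver tolerances are set to
1e-14 because the bounded trust-region solver otherwise stalls far from
the optimum on rates of magnitude ~10⁻⁴ mol L⁻¹ s⁻¹. Substrate
concentrations are post-mixing values (1:1 mixing halves the syringe
concentration): the fitted K_M of the reference enzyme (4.9 mM) lies
inside the post-mixing range 3.4–17 mM, not the syringe range.

**Choice of rate window for round-trip tests.** With an uncatalyzed
constant of 3.5 × 10⁻² s⁻¹ most of the substrate is consumed within ~20 s,
and the Michaelis–Menten fit strongly amplifies any systematic tilt of the
rate–substrate curve (a few percent of correlated rate error can double
the apparent K_M). Round-trip tests that compare against instantaneous
model rates therefore read slopes from an early window (0–0.3 s for the
parameter round trip; 0–0.6 s for the Q validation) where the initial-rate
linearization holds; the window remains a plain argument everywhere.

## Stability

Activity is expressed in Wilbur–Anderson units, WA = (t₀ − t)/t, from the
time the indicator needs to traverse the assay pH drop without (t₀) and
with (t) enzyme. Residual activity or solubility is 100·value(t)/value(0);
values above 100 % are allowed (thermal activation is a real phenomenon in
thermophilic enzymes). These are the classical reconstructions of the
assay conventions and results carry a `reconstructed-formula` provenance
string.

The half-life estimator restricts the series to the suffix starting at its
maximum — a first-order fit cannot represent an early activation rise, so
the decay is measured from the peak — and returns the first 50 % crossing
by log-linear interpolation (exponential decay between samples). A series
that never reaches 50 % yields "undefined" (None), which is a value, not
an error. Under noise this estimator is censored: when the true half-life
coincides with the last timepoint, roughly half the noisy replicates never
cross and the median over defined estimates is biased a few percent low.
The acceptance script reports the median over defined estimates and this
bias is visible there (~22 h recovered for a 24 h truth at 5-point noise).

## Batch reactor

The closed vessel (150 mL total, 50 mL solvent, 7 bar absolute, 20:80
CO₂:N₂ by default) is analyzed with an ideal-gas mass balance under the
assumption that only CO₂ dissolves: n_abs(t) = (P₀ − P(t))·V_head/(R·T).
Water vapor is neglected by default (a constant offset is available).
Temperatures are Kelvin and pressures absolute Pa internally; the CLI
accepts °C and bar. The initial pressure is treated as absolute.

Metric conventions (the published description names the quantities but not
their estimation rules):

* *Initial absorption rate* — least-squares slope from t = 0 until the
  absorbed amount first exceeds 20 % of its final value, capped at 15 min.
* *Plateau* — earliest time from which the forward-looking 3-point rolling
  slope stays below 2 % of the initial rate for the remainder of the run.
* *Productivity* — absorbed CO₂ at the plateau divided by the plateau time
  (mmol L⁻¹ min⁻¹). If no plateau exists the series end is used and the
  result flagged.
* *Removal efficiency* — absorbed moles over the initial CO₂ inventory,
  capped at 100 % with a warning.

The forward simulator integrates dP_CO2/dt = −kLa·E·(P_CO2 − P_eq) with
inert N₂ — a pseudo-first-order approach to a fixed equilibrium partial
pressure, with the enzymatic effect as a multiplicative enhancement E of
the volumetric mass-transfer coefficient. This is the simplest model
consistent with saturating absorption curves; it exists to exercise the
inverse metrics and makes no claim of process fidelity (no carbonate
speciation, no two-film theory). Integration uses RK45 at rtol 10⁻¹⁰ and
is checked against the closed-form exponential to 10⁻⁶ relative.

## Synthetic data

Generators are bit-reproducible for a fixed seed
(`numpy.random.default_rng`).

**Screening fixtures.** Amino-acid backgrounds are uniform over the 20
standard residues; motifs are inserted at uniformly random non-overlapping
offsets. Planted positives satisfy every criterion (both motifs, valid
boundaries, length within the window, hot alkaline source sample, SCAP or
strong-similarity evidence, alternating so both branches are exercised).
Decoys cycle through six violation classes — no evidence, missing motif
(with accidental motif occurrences scrubbed), bad boundary, implausible
length, wrong environment, and a near-duplicate of a positive (truncated
by three residues and ~2 % mutated outside motif spans, so it clusters
with, and loses to, its source). With ≥ 6 decoys every criterion is
violated by at least one. Annotation tables are written directly from the
planted truth; HMMER/BLAST scoring internals are not simulated.

**Traces.** d[CO₂]/dt = −(k_u + k_cat·E/(K_M + S))·S is integrated (RK45,
rtol 10⁻¹⁰), released protons are partitioned among buffer, indicator and
free H⁺ by inverting the Henderson–Hasselbalch conservation equation
(bisection, monotone in pH), and absorbance is ε·l times the deprotonated
indicator fraction — a single absorbing species at one wavelength, matching
a one-wavelength instrument. Bicarbonate back-reaction and carbonate
speciation are not modeled, which is acceptable for initial-rate work but
means late-trace equilibria are not realistic.

**Noise.** Additive gaussian, homoscedastic, everywhere (absorbance units
for traces, percentage points for decay series via a fraction-of-initial
argument, bar for pressure gauges); decay series are renormalized so the
t = 0 point reads exactly 100 %, as a real normalization would. No
instrument noise magnitudes are published for any of these assays, so the
defaults (0.002 AU, 5 points, 0 bar) are plain arguments chosen at
plausible instrument scales and are easy to override.

**What passing tests show.** Recovery results demonstrate that the
estimators are unbiased and correctly implemented under the stated noise
model at the stated design points. They do not establish performance on
real instruments (correlated drift, heteroscedastic noise, mixing
artifacts) or on real metagenomes (homologous decoys far subtler than the
planted ones, annotation errors upstream).

## Problem sizes

Stochastic checks use 100 seeds for kinetic and half-life recovery and 20
seeded fixtures (12 proteins, 4 positives) for the cascade-truth property;
these sizes put Monte-Carlo error well below the test tolerances while the
full suite runs in a few seconds.
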