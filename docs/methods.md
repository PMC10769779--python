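# Methods

## Scope and data flow

`commfba` predicts a per-sample butyrate production capacity for gut
microbial communities and compares it across a two-visit clinical cohort.
The stages are: (1) map OTU representative 16S sequences onto reference
genome 16S genes, (2) select and weight community members from relative
abundances, (3) merge the members' metabolic models into one community
model, (4) solve a parsimonious flux balance problem per sample, and
(5) run four exact nonparametric comparisons between responder and
nonresponder patients.  All inputs are plain text (model JSON, FASTA, TSV);
a synthetic generator produces complete, internally consistent inputs so the
whole chain is exercised without external data.

## OTU-to-genome mapping

Queries are aligned to every reference with exact local Smith–Waterman under
BLASTN-like scoring: match +2, mismatch −3, and affine gaps costing
5 + 2·L for a gap of length L (implemented on Biopython's
`PairwiseAligner`; Biopython's gap convention charges open+extend for the
first gap column, hence open −7 / extend −2 internally).  Percent identity
follows the BLAST convention — matched columns over all alignment columns,
gap columns included — and query coverage is the aligned query span over the
query length.  Hits need identity ≥ 97% and coverage ≥ 95%; among survivors
only hits tied (10⁻⁹) for the maximum identity are retained.  The ambiguity
code N always scores as a mismatch, including N against N — conservative
and deterministic.  Both query orientations are tried and the
higher-scoring one kept (forward preferred on ties).

Two deliberate choices where a heuristic tool leaves details open:

* **Exact alignment instead of seeded heuristics.**  At desk scale (dozens
  of references, a few hundred nucleotides) exactness is affordable and
  makes the identity/coverage quantities well defined and testable against
  an independent dynamic program.
* **Deterministic tie resolution.**  An OTU retained with several
  equal-identity hits must still feed exactly one model downstream; the
  lexicographically smallest reference id is assigned and the ambiguity is
  logged and reported (`n_tied_hits` in the mapping table).

## Community model construction

Members are the taxa with relative abundance strictly greater than 0.1% in
the sample; surviving weights are renormalized to sum to one.  Taxa whose
OTU could not be mapped to any model are dropped first, with their mass
excluded before renormalization and counted in the diagnostics.

The merge namespaces each member's internal metabolites and reactions with
`species|`, shares lumen metabolites by id, and installs one community
exchange reaction per lumen metabolite, written `metabolite → ∅` so positive
flux is outflow.  Member exchange reactions are absorbed into this boundary:
the community exchange bounds are the element-wise widest member exchange
bounds (the union of the members' media assumptions), while each member's
own transport reactions remain its interface to the lumen.  Keeping member
boundary reactions as parallel system boundaries would break conservation
and turn a shared substrate pool into one pool per member.  Lumen
metabolites no member declares an exchange for get bounds [0, 1000]: freely
secreted, never imported — secretion should not be blocked by an absent
declaration, and the medium is defined only by declared uptake bounds.

Growth is coupled as `v_biomass,i = w_i · μ` with a single community growth
variable μ.  This hard proportional coupling is the central modelling
assumption: the community grows as one unit at its observed composition, so
the member least able to grow on the shared medium limits everyone.  The
alternative (independent member objectives, SteadyCom-style balancing) is
out of scope.

## Parsimonious FBA

The LP maximizes `μ − λ·Σ|v|` with λ = 10⁻⁵ subject to mass balance,
coupling and flux bounds.  Absolute values are handled by splitting each
flux into two nonnegative variables; this keeps the stated combined
objective a single exact LP rather than the two-stage pFBA variant.  The
parsimony term selects the minimal-total-flux solution among near-optimal
growth states (verified on a model with a redundant longer pathway: the long
route carries zero flux) and perturbs μ by at most λ·Σ|v|.

Numerical choices: HiGHS (via `scipy.optimize.milp`, which is the same
solver as `linprog`'s HiGHS backend with lower per-call overhead — relevant
because cohort simulations solve ~10⁵ small LPs); basic solutions of these
small, well-scaled LPs carry mass-balance residuals far below the asserted
1e-8; μ ≤ 10⁻¹⁰ is reported as `zero_growth` and the butyrate rate is then
*undefined* (`None`/`NA`), not zero — 0/0 is not "no butyrate", and
undefined samples are excluded from the statistics and counted.  A
structure cache reuses the LP matrix for repeated member sets, patching only
the coupling coefficients; a test asserts bitwise agreement with the
uncached path.

The butyrate production rate is `r = flux(EX_but) / μ`, the community
butyrate outflow per unit of community biomass production.  Because the
community exchange is the net flow, any modelled butyrate uptake by members
is netted out of `r`.

## Cohort statistics

Response is a ≥50% drop (inclusive) of the Lichtiger score from V1 to V2,
with baseline eligibility score ≥ 4.  The four comparisons are rank-sum
tests between groups at V1 and at V2, and paired signed-rank tests between
visits within each group.  Both tests are permutation-exact on the observed
data: mid-ranks for ties, enumeration of all C(n, n_x) group assignments
(rank sum) or all 2^m sign patterns after dropping zero differences (signed
rank), with the two-sided p doubling the smaller one-sided tail, capped at
one.  The enumerations are computed by dynamic programming over doubled
mid-ranks (exact integer sums), and the test suite checks them against
independent brute-force enumeration, including ties and zeros.  Above the
enumeration caps (25 combined observations / 20 nonzero differences) the
classical normal approximation with continuity correction takes over
(`scipy.stats`), with a logged notice — at the default cohort sizes
(n = 85–93 unpaired, m = 22–63 paired) the approximate branch is the one
exercised, and its type-I calibration is itself under test.

Patients whose response label cannot be derived (no V2 score in the
metadata, e.g. a missing week-4 sample) are excluded from all four tests and
counted, so with the default generator the baseline rank-sum runs at n = 85
rather than 93.  Samples with undefined rates are likewise excluded and
counted.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated:

* **Registry** (default 20 species, 40% producers): producers obligately
  co-produce one butyrate per biomass unit (so community butyrate capacity
  is a deterministic, monotone readout of producer abundance — the cleanest
  mechanism for the interpretation that producer enrichment drives predicted
  butyrate); non-producers only grow.  Per-species glucose uptake capacities
  are uniform on [5, 15] (both the exchange bound and the species' own
  transporter), and each species gets a random 250-nt 16S stand-in.
* **Cohort** (default 69 responders / 24 nonresponders at V1; 63 / 22
  retained at V2): each patient has a latent profile θ ~ Dirichlet(1); both
  visits are independent draws ~ Dirichlet(50·θ).  Drawing the two visits
  i.i.d. around a patient latent — rather than jittering V2 off the realized
  V1 — makes the pair exchangeable under the null, which is exactly the
  symmetry the signed-rank test assumes; a V2-conditioned-on-V1 scheme has
  mean-zero but asymmetric differences and silently miscalibrates the paired
  null.  In responders, 15% absolute abundance mass is then shifted
  proportionally onto producer taxa at V2 (capped so producers stay below
  99%).  The within-patient concentration 50 gives a per-visit producer-mass
  standard deviation of roughly 0.07, i.e. visible biological noise that the
  planted 0.15 shift still dominates.
* **Clinical scores**: responders draw V1 ~ U{8..14} and
  V2 = ⌊V1·(1−u)⌋ with u ~ U[0.5, 0.9]; nonresponders use u ~ U[0, 0.4] and
  the ceiling.  Floor/ceiling are chosen per group so the generated label
  always matches the intended one (a ceiling on the responder side would
  misclassify odd baseline scores when u ≈ 0.5); no clinical realism beyond
  exercising the labelling rule is claimed.
* **OTUs**: one per species, mutated from its reference at 1% per-base
  substitution, so mapping at 97%/95% recovers the source by construction.

What the generator does *not* emulate: real 16S phylogenetic structure,
sequencing or denoising error, compositional count noise from rarefaction,
multiple OTUs per species, cross-feeding metabolic dependencies, or any
correlation between clinical scores and community composition beyond the
planted producer shift.  Passing tests therefore show the pipeline's
machinery is correct and calibrated under these conditions, not that the
biological effect exists in real cohorts.

## Problem sizes used in validation

Conservation laws are checked on 100 random communities of up to 20 species;
mapping recovery on 1000 mutated OTUs; type-I calibration on 1000 null
cohorts at full default size (the four tests' rejection rates must fall in
the binomial 99% CI around 5%); effect recovery on 50 planted cohorts
(responder signed-rank significant in ≥90% of seeds, nonresponder in ≤10%,
responder median rate rising in every seed).  The acceptance script reports
a single planted cohort's four p-values plus rejection fractions over 20
seeds, and 200 mapping trials.

## Known limitations

* Proportional coupling makes μ pessimistic (weakest-member-limited); rates
  remain well defined because butyrate output is tied to biomass shares.
* The widest-bounds community medium ignores inter-sample diet variation; no
  diet database is integrated.
* Exact tests above the enumeration caps silently (but loggedly) switch to
  the normal approximation; extremely tied data at moderate n may deserve
  the exact branch with a raised cap (`--exact-test-cap`).
* The rank-sum at baseline uses only patients with derivable labels; with
  per-sample metadata this excludes V2-dropout patients even though their
  baseline sample exists.
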