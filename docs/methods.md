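# Methods

## Problem and scope

`presnet` studies whether physicians with similar risky-prescribing
behavior are preferentially connected in a shared-patient network —
*homophily* — at the dyadic level (exponential random graph models) and at
the triadic level (attribute-restricted triangle statistics with
permutation tests). "Risky prescribing" refers to exposure of a patient to
opioids (O), benzodiazepines (B) and non-benzodiazepine sedative-hypnotics
(S), alone and in combination; concurrent receipt of all three is the
riskiest state. Because the claims data that motivate this kind of
analysis are patient-identifiable and not shareable, the package includes
a synthetic claims generator whose planted structure makes every stage of
the pipeline testable against known ground truth.

## Network construction

Encounters are claims-like rows (patient, physician, day) on a single
365-day integer calendar. A directed arc i → j carries the number of
distinct patients seen by i on some day strictly before a day on which
they saw j; same-day visits to two physicians carry no ordering
information and create no arc. Whether to require *consecutive* visits is
genuinely open; we use any strictly ordered pair of encounter days per
patient, the simplest reading (the arc weight — distinct patients rather
than ordered visit pairs — only feeds a ≥ 1 threshold, so the choice is
inconsequential downstream). The analyzed network keeps mutual dyads only
(both arcs present, each with at least one patient), binarized and
undirected; it is restricted to physicians with at least one O/B/S fill
and reduced to its largest connected component (ties broken toward the
component containing the smallest node id). Region sub-networks assign
each physician to the region of the plurality of their distinct patients
(lexicographic tie-break), keep only within-region edges, drop regions
under a minimum size (default 100 nodes), and are deliberately *not*
re-restricted to their own largest component.

Summary statistics: density, component structure, degree mean/IQR/SD on
the simple graph, global clustering 3·(triangles)/(2-stars), and average
shortest-path length over reachable pairs.

## Prescription states and transitions

Refill merging: scanning each (patient, drug) chronologically, a fill
merges into the running exposure episode when its start is at most the
episode end plus 20% of the *preceding fill's* days supply; merging is
prescriber-blind but the episode keeps its initiating physician. Intervals
are half-open in days, `[start, start + supply)`. Note the rule is not
idempotent under re-merging of rendered episodes: the buffer is defined on
the preceding fill, not the accumulated episode, so collapsing an episode
into one long pseudo-fill enlarges the buffer. We treat the fill-level
rule as normative.

Each patient's year is cut at episode starts and ends into maximal
intervals of constant class-set; the class set maps to states 1..8 in the
order ∅, O, B, S, OB, OS, BS, OBS. The tier structure (0, 1, 2, 3 drugs)
is meaningful; the within-tier order is an arbitrary convention we fix for
determinism. Every index below depends only on the per-state drug count
and on the state-8 column, so the convention is inert *except* for
same-tier class switches (e.g. O → B), which land above or below the
diagonal by that arbitrary order. Following the diagonal definition of
prescribing/deprescribing literally, a state-index increase is classified
as prescribing and a decrease as deprescribing; class switches are rare in
practice and the limitation is documented rather than papered over.

Transitions that add classes are attributed to the initiating physicians
of the newly started exposures of the *gained* classes; N co-initiating
physicians share weight 1/N. A same-day start of a drug in an already
active class changes no state and is attributed to no one.

## Deprescribing attribution

Stopping a drug triggers no claim, so deprescribing is inferred: an
exposure longer than 30 days, never resumed (post-merge) within the year,
whose end follows the patient's most recent clinical visit by at most 30
days (inclusive), is attributed to all physicians seen on that visit day,
with equal weights. Visits on the exposure's end day do not qualify (the
supply is already exhausted). When several eligible drugs end the same
day, one combined state transition is emitted and the candidates pool into
one equally weighted responsible set. Discontinuations failing the visit
rule are kept in the patient's trajectory but carry no responsibility and
enter no physician's matrix. Both 30-day thresholds are configurable for
sensitivity analysis.

## Responsibility matrices and indexes

Physician k's 8×8 matrix C(k) accumulates the weights of transitions
attributed to them, rows indexed by the origin state and columns by the
destination. With n(ω) the drug count of state ω and
w_ij = |n(i) − n(j)|:

* I_α = (P_α − D_α)/(P_α + D_α), P_α = Σ_{i<j} C_ij w_ij^α,
  D_α = Σ_{i>j} C_ij w_ij^α, α ∈ {0, 1}, with 0⁰ = 1. I_0 is the raw
  prescribe/deprescribe balance; I_1 weights by drugs changed. The index
  lies in [−1, 1]; it equals 1 iff D = 0 < P and attains −1 exactly when a
  physician has deprescribing mass only (the lower bound is strict
  whenever P > 0).
* I_OBS = (Σ_{i<8} C_i8)/(total off-diagonal mass): the share of a
  physician's transitions that move a patient into the all-three state;
  I_everOBS binarizes its numerator.
* I_presc2mr and I_depresc2mr: among same-direction mass, the fraction
  with w_ij ≥ 2. I_depresc2mr is defined as 0 on an empty denominator (a
  physician with no deprescribing has no multi-drug deprescribing); the
  other ratio indexes are undefined (NaN) on empty denominators, and such
  physicians are dropped — with a logged count — from any model using that
  attribute. Fractional co-responsibility weights flow through unrounded.

## Dyad-independent ERGMs

The ERGM Pr(A = a | X = x) ∝ exp(Σ_p η_p g_p(a, x)) is implemented for
statistics whose per-dyad contribution depends only on that dyad: edges,
nodefactor, nodecov, uniform and differential nodematch, absdiff. For
these the likelihood factorizes into independent Bernoulli-logistic terms,
so the exact MLE is a logistic regression of tie indicators on per-dyad
change statistics — no MCMC, no degeneracy. Dyad-dependent statistics are
rejected by construction; triadic structure is handled descriptively (next
section). Newton-Raphson with step halving supplies the MLE; standard
errors come from the observed information; coefficients escaping past ±30
are reported as ±∞ with undefined SE (perfect separation, e.g. an empty or
complete graph under an edges-only model). An exact all-graphs enumeration
(n ≤ 5) provides the normalizing constant for oracle tests.

For a binary attribute, the design containing edges, nodefactor and both
differential nodematch columns is rank deficient (the level-0 match column
equals edges − nodefactor + level-1 match); only uniform homophily is
identified alongside the main effect. Identifiability is checked
numerically before every fit (singular values below 1e−8 of the largest
count as zero) and failures are reported with the named collinear column
set. The exact-deficiency-one statement requires at least two nodes at
each level; with a lone minority node the match column for that level is
identically zero and the deficiency is 2.

Default model layout per prescribing index: edges + specialty main
effects (reference = most frequent specialty) + uniform specialty
homophily + the index's main effect and homophily term (match terms for
the binary ever-OBS indicator; nodecov + absdiff for continuous indexes,
where a negative absdiff coefficient indicates homophily).

## Triadic homophily and the permutation test

For node attributes x ∈ [0, 1] (continuous attributes are min–max
standardized):

* Tri1 = Σ_triangles x_i x_j x_k / #triangles — the attribute-weighted
  share of closed triangles;
* Tri2 = Σ_closed 2-stars x_i x_j x_k / Σ_all 2-stars x_i x_j x_k — an
  attribute-restricted transitivity; each triangle closes three 2-stars.

Counting is over unordered triangles and (center, unordered pair) 2-stars;
any consistent ordered convention yields the same ratios. With all x = 1,
Tri1 = 1 and Tri2 equals the global clustering coefficient. Both are
computed by dense matrix products (trace((AD_x)³)/6 and the centered
second-moment identity for 2-stars), verified against O(n³) triple
enumeration.

Significance: the attribute vector is uniformly permuted across nodes
(graph and attribute multiset fixed) and the statistic recomputed; the
p-value is the raw proportion of null draws ≥ the observed value
(one-sided "greater" by default; a (b+1)/(m+1) correction is available by
flag). The historical default of 30 permutations gives p-value granularity
1/30; validation experiments here use 99–200. This null preserves density
and attribute prevalence but not the degree distribution;
degree-preserving rewiring nulls are out of scope.

## Synthetic claims generator

Each physician has a latent risky-prescribing propensity ~ Beta(2, 5), a
specialty (primary care 35%, emergency medicine 15%, neurology 10%,
psychiatry 10%, other 30%) and a region. Each patient receives a
region-biased primary physician and 1–6 further panel physicians drawn
with weight exp(−homophily_strength · |risk difference to the primary|),
tripled within the patient's region — so patient-sharing is assortative on
the latent propensity with a planted absdiff-like form, and region
structure supports the sub-network partition. Patients visit each panel
physician 1–4 times at uniform days; every prescription fill adds a
same-day encounter with its prescriber.

Prescribing: each class is included with probability
0.15 + 2 · risky_escalation_rate · (panel mean risk), so patients of risky
panels accumulate concurrent multi-class exposure. A fill chain starts at
a uniform day with supply 30/60/90 (probabilities 0.5/0.3/0.2) and is
extended by refills (probability refill_rate per step, up to 6 fills) with
gaps drawn inside the 20% buffer, occasionally signed by a different panel
physician. Planted deprescribing: for chains longer than 30 days whose end
lies inside the year and is visible as a state change (the class actually
deactivates and no other exposure starts that day), with probability
deprescribe_rate a panel physician visits on the day before supply
exhaustion and no refill follows; the event is recorded in a ground-truth
table so attribution sensitivity can be scored. Identical configurations
(including the seed) reproduce byte-identical tables.

What the generator does *not* emulate: demographic structure, enrollment
gaps, dose/strength (no morphine-equivalent scaling), specialty-dependent
prescribing styles, and the size and sparsity of a real regional network
(synthetic cohorts of a few hundred physicians are necessarily far denser
than a statewide network of tens of thousands, and rare events such as
all-three-class prescribing are correspondingly rarer as absolute counts).
Passing tests demonstrate the correctness and calibration of the methods
under the planted mechanisms, not the real-world magnitudes of homophily.

## Numerical and validation choices

* Problem sizes: validation experiments use cohorts of 60–200 physicians,
  networks of n = 300 for parameter recovery (100 replicates), 500
  simulated datasets for permutation calibration, and exhaustive
  enumeration up to n = 5 (1024 graphs); these sizes give stable rates
  while keeping the default suite quick.
* Exact-MLE agreement is asserted to 1e−6 against a Nelder-Mead
  maximization of the enumerated likelihood; enumeration probabilities sum
  to 1 within 1e−12.
* Rank tolerance 1e−8 × largest singular value; separation threshold |η| >
  30 on the logit scale.
* Degenerate inputs: empty encounter tables give empty graphs; physicians
  with no patients stay unmapped from regions (flagged); constant
  attributes standardize to zeros with a warning; statistics with empty
  denominators are NaN unless a zero convention is stated
  (I_depresc2mr); permutation tests refuse undefined observed statistics
  and n_perm < 1.

## Known limitations

* Deprescribing attribution is a heuristic; its measured sensitivity is
  with respect to the generator's planted mechanism, which schedules
  qualifying visits by construction. Real claims will contain
  discontinuations with no qualifying visit and visits unrelated to
  deprescribing.
* Direction classification of simultaneous add-and-remove boundaries
  follows the state-index diagonal, which is convention-dependent for
  equal-drug-count switches.
* The ERGM family is restricted to dyad-independent terms by design;
  triadic dependence is measured descriptively, not modeled.
* Year boundaries are not censoring-adjusted: exposures running past day
  365 are truncated for trajectories and their discontinuations are
  unobservable.
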