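# Methods

## The measurement problem

A gland lobe is reconstructed as a rooted tree of duct segments.  The main
duct carries generation index ("level") 1 and every daughter duct is one
level deeper; terminal ducts may bear an acinus, which shares the address
of its duct.  Whether levels start at 0 or 1 is a convention; this package
fixes main duct = level 1, and every level-indexed output uses that origin.
Duct width is not modelled — it stays roughly constant along the tree while
length falls with level — so only duct length enters density and census
calculations.

Sparse induction of a multicolor reporter labels individual endbud cells.
By collection, each labelled progenitor has become a clone: same-color
cells spread over one subtree.  Everything downstream is inference on that
footprint.

## Clone grouping, common ancestors, renewal

Cells of one color within one connected occupied subtree form a clone.
The original analysis grouped cells manually; the deterministic counterpart
used here is: all same-color cells in a lobe are co-clonal by default, and
an optional *maximal-CA-depth guard* (`min_ca_level`) declares two
same-color cells co-clonal only when their joint ancestor lies at that
level or deeper — equivalently, grouping by ancestor duct at that level.
When analysing synthetic cohorts the guard is set to the induction level,
which is exactly the scale at which distinct endbuds' clones separate;
with real data the choice mirrors how conservatively the annotator would
split distant same-color groups.

The clone's **common ancestor (CA)** is the duct at the lowest level from
which every occupied duct can be reached — the deepest node whose subtree
contains the clone — and proxies the clone's endbud of origin at induction.
The implementation intersects root paths; the test suite checks it against
an exhaustive brute-force oracle on 1000 random trees.

Clones confined to a single duct (an acinus counts as part of its terminal
duct) are **non-renewing**: their founders never multiplied through a
bifurcation, so they are excluded from population statistics.  *Potency* is
the set of compartments present among a clone's counted cells, with order
1–4 (uni/bi/tri/quadripotent; "multi" pools orders 3–4).  Acinar cells
found inside ducts rather than acini ("duct-associated acinar cells") do
not contribute to forming an acinus and are excluded from the acinar call
and from the census by default (`include_duct_acinar` re-includes them).
Class proportions carry the standard error of proportion
SEP = sqrt(p(1−p)/n).

Because potency is a set union over observed cells, subsampling a clone can
only remove lineages: classified order is monotone non-increasing under
censoring, with equality when every progeny compartment is sampled.  This
is asserted as a property test.

## Subclone dispersion and model selection

A **subclone** is the subset of a clone's ductal (non-acinus) cells in one
duct; its density is cells per micron of that duct.  Profiles average
density over *occupied* ducts per level distance Δ from the CA (unoccupied
ducts contribute no zeros; the SD of a single observation is reported as
absent, not 0).  Two growth models are fitted to the profile:

- linear (OLS of mean density on Δ, by default over Δ ≤ 18), the prediction
  of *random segregation*: progenitor progeny are well mixed and partition
  binomially between daughter endbuds at each bifurcation;
- exponential (OLS on the log mean density), the prediction of *coherent*
  dispersion in which the clone keeps its position and runs down one duct
  path, doubling each level.

The preferred model is the one with the lower residual sum of squares in
density space on the common support.  The clone-size survival function
S(s) is fitted by least squares of log S on s with the terminal S = 0 point
excluded; the clone-size–subtree-size association uses Spearman rank
correlation (midpoint ranks for ties), chosen for robustness to the
heavy-tailed size distribution — the original study names no statistic for
this panel, so the choice is documented here rather than asserted as
theirs.

## Labelling-merger model

If, at induction, N endbuds receive a total of M labelling events in one
color, an endbud is labelled in that color with probability
P_c = 1 − (1 − 1/N)^M and carries exactly one event with probability
P_1 = (M/N)(1 − 1/N)^(M−1).  A labelled endbud then hosts a *merged* clone
(two or more same-color founders masquerading as one) with probability

    P_merger = 1 − P_1/P_c  ≈  1 − p/(e^p − 1)  ≈  p/2   (p = M/N « 1).

Same-color mergers are invisible, but cross-color co-labelling is not.
With k equally efficient colors, Q_1 = k·P_c(1−P_c)^(k−1) and
Q_* = 1 − (1−P_c)^k give the co-label fraction C = 1 − Q_1/Q_*, which for
k = 4 tends to 3p/2 = 3·P_merger.  Observing the fraction Ĉ of CA endbuds
bearing more than one color therefore estimates the merger rate as Ĉ/3.
The implementation returns the exact discrete forms by default with the
exponential approximations as named variants (`method="approx"`,
`"small_p"`); the exact forms carry finite-M corrections (e.g. exact
P_merger ≈ (M−1)/(2N) rather than M/(2N)), which matters when comparing
against the limits.  The Ĉ/3 inference is valid in the small-p regime only;
a warning fires when Ĉ > 0.2.  Unequal per-color efficiencies (the
observed clone proportions are roughly 10:11:3:13 for CFP:YFP:GFP:RFP) are
handled by the generalized per-color form of Q_1 and Q_*.

## Tree-walk clone simulator

The null model of clone dynamics places a single tip cell on a duct and
iterates: cells advance one level towards the endpoints; at a bifurcation
every cell duplicates and (random rule) each daughter independently picks a
branch uniformly, or (coherent rule) the doubled clone stays together and
enters one uniformly chosen branch; each traversal deposits one unit of
duct density; the walk ends when all lineages reach endpoints.  At a
k-furcation the cell still duplicates once, each daughter choosing among
the k branches; pass-through ducts move cells without duplication.

On a full binary tree of depth D a clone started at level L always ends
with exactly 2^(D−L) tip cells and deposits 2^(D−L+1) − 2 units in total —
conservation laws the suite asserts.  Random-rule ensembles produce
occupied-duct density growing linearly with level (the mean conditional on
occupancy of a critical branching process grows ∝ Δ); coherent ensembles
give exactly 2^Δ on one path.  Ensemble summaries reuse the same density
aggregation code as the measured-clone analysis, so simulated and measured
profiles are directly comparable.

**Simulation-based merger rates.**  A realization places `n_clones`
same-color clones on start ducts sampled uniformly *with replacement* at a
start level (replacement is what creates same-endbud mergers, mirroring
Poisson induction), evolves them, and joins clones whose occupied ducts
(start duct included) overlap into components.  The merger fraction is the
pooled number of multi-clone components over the pooled number of
components — the fraction of *apparent* clones that are mergers, which is
the quantity the closed form 1 − P_1/P_c describes and, on full binary
trees, an asymptotically unbiased ratio estimate of it (N = ducts at the
start level, M = n_clones).  The fraction of induced clones involved in
any merger is exposed separately (`clone_involved_fraction`); it is
systematically larger and is not what the analytic model predicts.  The
Monte-Carlo standard error of the pooled ratio comes from the delta
method.  Merger rates fall as the start level deepens, since deeper levels
offer more endbuds to choose from.

## Progenitor census

A renewing progenitor contributes, on average, a representative share of
its compartment in the subtree stemming from its clone's CA.  Writing f_u,
f_b, f_m for the fractions of uni-, bi- and multipotent clones among those
contributing to compartment c, and c_u, c_b, c_m for their mean percentage
contributions, the renewing pool for that compartment is

    N_c = 100 / (f_u·c_u + f_b·c_b + f_m·c_m),

split per type as f·N_c (rounded half-up; the total is reported both raw
and as the rounded sum).  Subtree compartment totals come from a fixed
census: 63 acinar cells per acinus (95% CI 48–79), 6 myoepithelial per
acinus (CI 5–7), 0.29 luminal and 0.25 basal cells per micron of duct
(SEM ±0.02 and ±0.04) — all configurable.  Contributions are percentages;
inputs whose non-zero values all fall below 0.1 are treated as raw
fractions and rescaled with a warning (genuine sub-0.1% contributions
would imply pools far larger than an endbud, so the heuristic cannot
misfire in-domain).  Estimates are computed per gland and aggregated as
mean ± SD, each flagged against a configurable endbud-size bound (default
117 cells).  The estimator assumes labelling is representative of endbud
composition; that caveat is carried as a flag, not corrected for.

Known estimator bias: when a clone's earliest progeny happen to enter a
single daughter branch, the inferred CA slides below the true endbud and
the measured contribution roughly doubles, biasing N_c downward by some
20–30% under the single-founder tree-walk null.  Compartments counted
against very small censuses (myoepithelial: ~6 cells per acinus) suffer an
extra downward bias because only clones with at least one observed cell
enter the average (zero-truncation).  The estimate is an order-of-magnitude
tool, and the recovery tests bound the acinar and luminal estimators to
±30% of a known synthetic pool.

## Synthetic data generator

The generator emulates the study design so that every stage has ground
truth; it is first-class, tested code.

**Tree growth.** Synchronous rounds of stochastic tip bifurcation, one
round per day of development: each active tip splits with probability 0.95
per round (certain through the first 4 levels, since measured lobes always
comprise at least ~4 generations); a tip that fails terminates with an
acinus.  Trees are grown to 12 generations with induction snapshotted at
generation 7, the average CA level of the traced cohorts; measured trees
span 4–15 generations.  Duct length follows 250 µm × 0.85^(level−1) with
10% lognormal noise — values chosen to reproduce the reported decrease of
mean duct length with level at realistic organ scale.

**Induction.** Each endbud present at the induction round draws Poisson
labelling events per color with per-color means 10, 11, 3 and 13
(CFP:YFP:GFP:RFP, the observed per-gland clone counts) spread over the N
endbuds.  Each event labels a distinct member of the endbud's renewing
pool (117 progenitors by default) whose potency state is drawn from a
mixture of 42% uni-, 37% bi-, 21% multipotent, approximating the traced
proportions; bipotent states are acinar+luminal or basal+myoepithelial,
and unipotent lineage weights skew acinar/luminal as observed.  Same-endbud
same-color event groups are recorded as ground-truth mergers; endbuds
labelled in several colors as co-labelled.  Pooled over seeds, the
co-label frequency matches the closed-form C with the Poisson (exponential)
labelling probability — an analytic cross-check in the suite.

**Clone growth and cell deposition.** Each labelled progenitor's clone
follows the random-segregation tree-walk; the founder also deposits one
unit of residence in its origin duct, so clones carry subclones at their
duct of origin as measured clones do at their CA.  Cells are then emitted
so the census model holds: a duct of length L holds round(0.29·L) luminal
and round(0.25·L) basal cells, an acinus 63 acinar and 6 myoepithelial;
the clone labels each with probability (its traversal units there)/(number
of pool progenitors feeding that compartment), capped at 1.  A progenitor
thus contributes on average exactly a representative 1/n_c share, making
pool-size recovery a well-posed test.  A 4% fraction of acinar cells is
placed inside ducts (`in_acinus=False`) to emulate duct-associated acinar
cells.  Lineage-restriction dynamics *during* growth (multi→bi→uni
transitions along the hierarchy) are not modelled — no rates are reported
for them — so a clone's potency is fixed at induction; the mixture
parameters are free and nothing here asserts them as universal.

**What passing tests do and do not show.** The generator realizes the
analysis model's own assumptions (well-mixed segregation, representative
labelling, census homogeneity).  Recovery within stated tolerances
demonstrates the chain is self-consistent and correctly implemented; it
does not validate those assumptions against real tissue, where induction
bias, spatially varying census constants and coherent cell behavior would
degrade the estimates in ways the real study could not exclude either.

## Numerical and design choices

- Exact discrete merger formulas are the default; approximations are named
  variants so both are testable.
- Polytomies are permitted in the data model; the simulator duplicates
  once per branch point regardless of arity.
- Density averages condition on occupied ducts; SD of one observation is
  absent.
- The exponential clone-size fit excludes the final S = 0 point; ties get
  midpoint ranks; a degenerate (all-equal) size set is flagged rather than
  fitted.
- All generators and simulators take a single integer seed (numpy
  Generator); identical seeds give byte-identical pipeline summaries, with
  floats written to 6 significant digits.
- Problem sizes in the shipped tests — depth-12 full binary trees, 1000
  simulator realizations, 3–4 synthetic glands per cohort — were chosen as
  the smallest sizes at which Monte-Carlo error is comfortably below the
  assertion tolerances.

## Limitations

- The merged-endbud merger fraction matches the closed form exactly only
  on trees where same-level subtrees are disjoint (true of full binary
  trees); on irregular trees ancestor–descendant start pairs add overlap
  routes.
- The census estimator's CA-collapse and zero-truncation biases (above)
  are inherent to the method, not implementation artifacts.
- No spatial geometry, mesenchyme, or signaling-perturbation phenotypes;
  perturbed-arm statistics can be emulated only by changing the potency
  mixture.
- The Ĉ/3 merger inference gives a point estimate; no uncertainty is
  propagated.
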