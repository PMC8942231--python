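# Methods

`commitgf` implements community-conditional gap filling for genome-scale
metabolic reconstructions, together with the machinery around it: merging
several automatically generated draft reconstructions of one organism into a
consensus, comparing reconstructions structurally, predicting which
metabolites can leak across membranes, and analysing the metabolite
exchanges a gap-filled community implies.  This note records the models and
procedures, the parameters that matter, and the design choices made where
the design was genuinely open.

## Model representation and flux analysis

A reconstruction is a stoichiometric network over metabolites identified by
(id, compartment) pairs; the compartment vocabulary is fixed to cytosol
(`c`) and extracellular space (`e`), with a transient `boundary`
pseudo-compartment used only for database filtering.  A periplasmic
compartment in input files is collapsed into `e` during namespace
translation.  Flux balance analysis maximizes an objective `c·v` subject to
steady state `S·v = 0` and flux bounds; all LPs are solved with HiGHS
(through `scipy.optimize.linprog`), which is deterministic for a fixed
input.  An optional second stage minimizes `Σ|v|` (linearized by splitting
`v = p − q`) while holding the objective within a relative tolerance of
1e-6; because any cancellable futile cycle strictly increases `Σ|v|`, the
one-norm-minimal flux carries no removable internal cycle.  A strict
loop-law mode (big-M MILP with direction indicators and a nullspace
potential constraint over internal reactions) is available for the
dependency screen; it is intended for small networks and is not the
default.

Numerical conventions, used package-wide: feasibility/optimality tolerance
1e-6; a reaction "carries flux" when `|v| > 1e-6`; unconstrained bounds are
±1000 mmol·gDW⁻¹·h⁻¹; biomass flux is in h⁻¹.  Media are lower-bound
magnitudes on exchange reactions (negative flux = uptake); applying a
medium closes uptake for all exchanges not in the medium and creates
exchanges for medium metabolites that lack one.

## Consensus merging

Drafts translated to a common namespace (id maps; the proton alias MNXM01
is rewritten to MNXM1 everywhere) are merged pairwise in input order after
stripping exchange, sink and biomass reactions.  Metabolites are unified by
(id, compartment).  Reactions are matched by cosine similarity of their
stoichiometric vectors over the union of keys, computed proton-insensitively,
which recognizes duplicates that are reversed (cosine −1), scaled (equal
coefficients up to a factor), or protonation variants.  The default match
threshold is `1 − 1e-9`, i.e. exact up to protons/scale/sign; it is a
parameter because looser matching is defensible but changes consensus size.
A matched pair is unified with the permissive direction union (reversible
wins), the OR of the gene rules, the union of EC numbers, and — when the
stoichiometries differ — the mass-balanced variant (checked from formulas
when available) or, failing that, the variant with the smallest
integer-like coefficients.  Every merge and conflict is recorded in the
report so the resolution can be audited.  Matching across more than two
drafts is iterative pairwise folding with sorted-id tie-breaks, which makes
the outcome reproducible; true transitive matching is not attempted.

Model quality against a curated reference is scored as sensitivity
`TP/(TP+FN)` and precision `TP/(TP+FP)` over metabolite or EC-number sets;
true negatives are unknowable for this comparison, so no other score is
defined.

## Structural distances and STATIS

Nine pairwise quantities are implemented: Jaccard distances on the sets of
metabolites, reactions, EC numbers, genes, and dead-end metabolites; a
normalized dead-end-count difference `|n_a − n_b| / max(n_a, n_b)`;
rank-correlation distances `(1 − ρ)/2` (Spearman, average ranks for ties,
missing keys counted 0) of EC-number occurrence and cofactor usage; and the
SVD distance between stoichiometric spectra (sorted singular values, the
shorter spectrum zero-padded, both scaled to unit length, Euclidean
distance).  A dead-end metabolite is one that is only ever produced or only
ever consumed, with reversible reactions counting as both.  The cofactor
list is configurable (default: ATP/ADP/AMP, NAD(P)(H), FAD(H₂), CoA, H⁺,
H₂O in MNXref ids) since usage vocabularies differ between namespaces.  The
ensemble builder computes any subset of the nine (default: all); where a
count vector is constant — e.g. no cofactors at all — the rank measure is
uninformative and contributes distance 0.

STATIS combines `k` distance matrices: each matrix is double-centered
(`−½ J D J`), Rv coefficients between the centered matrices form a k×k
similarity matrix, its dominant eigenvector (nonnegative by
Perron–Frobenius; mixed signs raise an error) scaled to sum 1 gives the
weights, and the compromise is the weighted average `Σ wᵢ Dᵢ` of the input
matrices.  The Mantel test between two distance matrices uses the Pearson
correlation of lower-triangle entries with a one-sided permutation p-value
(`n_perm` simultaneous row/column permutations of one matrix, seeded
generator, add-one correction).

## Permeability

A metabolite is classified likely membrane-permeable by an extended
Lipinski rule, all bounds inclusive: HBD ≤ 5, HBA ≤ 10, MW ≤ 500 Da,
TPSA ≤ 140 Å², RB ≤ 10, −0.4 ≤ XLogP3 ≤ 5.6.  Any missing property
classifies the metabolite as not permeable.  Missing XLogP3 values are
imputed first, by 1-nearest-neighbour regression on (MW, TPSA, HBD, RB);
predictors are z-scored with parameters fitted on the training records only
(raw-scale mode is available; scaling matters because molecular weight in
the hundreds would otherwise dominate integer counts), and distance ties
are broken by the smallest metabolite id so imputation is deterministic.
Classification runs second, on the completed table.  Transport reactions in
the gap-filling database that carry at least one permeable metabolite
receive a reduced cost.

## Gap filling

The candidate pool is the chemically balanced part of a universal reaction
database after dropping reactions that touch the `@BOUNDARY`
pseudo-compartment, reactions in generic (untranslatable) compartments, and
reactions with any |coefficient| above 20 (20 itself is retained); the
proton alias is normalized before the coefficient check and every exclusion
is counted in a report.

Category costs, per unit flux through an added candidate: transport 100,
non-transport (metabolic) 50, transport of a permeable metabolite 50,
sequence-evidenced 25 (HMM/BLAST E-value ≤ 1e-6, supplied as an input
table), reversing an existing irreversible model reaction 25 (realized as a
reversed-copy candidate), uptake of a metabolite already secreted by the
community 1, exchange 1e5.  Each candidate takes the minimum applicable
cost.  Biomass flux is confined to [1e-3, 2.81] h⁻¹ during gap filling:
the upper limit is the observed growth rate of very fast-growing bacteria
and prevents the LP from pushing biomass to the generic 1000 bound (which
would recruit more reactions), the lower limit reflects the slow growth of
soil microbes and defines "functional".  These biomass limits apply to the
gap-filling LP only and are not propagated to the returned model.

The LP maximizes `α·v_bio − Σ costᵢ·|vᵢ|` over the merged network, with
candidate fluxes split into forward/backward parts so `|vᵢ|` is linear and
the model's own reactions cost nothing.  The scalar α starts at 1 and
doubles until the solution grows at ≥ 1e-3 h⁻¹ or α exceeds 1e6 (schedule
configurable); flux-carrying candidates form the raw solution, which a
greedy pass prunes in decreasing-cost order (ties by id), removing any
reaction whose removal keeps growth feasible.  The pruned solution is
locally minimal by construction; on small candidate pools it matches the
exhaustive subset-enumeration optimum (asserted in the test suite).  When
no α achieves growth, the result names the biomass precursors that remain
unproducible even with the entire pool open.

Secretion capability is assessed post hoc: with the biomass optimum
`v_opt` fixed, temporary sink reactions (bounds [0, 1000]) are added for
every cytosolic metabolite that is permeable or participates in a model
transport reaction, and the summed sink flux is maximized subject to
`v_bio ≥ f·v_opt` with f = 0.9, i.e. a tolerated growth reduction of 10% —
unbounded altruism is not considered biologically plausible.  The summed
objective has degenerate optima (exporting a precursor ties with exporting
its product), so sinks left at zero are re-checked by individual
maximization under the same constraint; a metabolite is secretable iff its
export alone can exceed tolerance within the growth budget, which matches
the per-metabolite definition of permitted secretion.  Metabolites that
already have an uptake in the model are not reported.  Sinks never persist:
secreted metabolites are materialized as a c→e transport plus a
secretion-only exchange where no export path exists.  An alternative mode
places the sinks directly into the gap-filling objective; post hoc is the
default.

## Community-conditional orchestration

Given a community, random orderings of the members are explored (default
100; for n members with n! below that, all permutations are enumerated
once, otherwise distinct permutations are sampled without replacement from
a seeded generator).  Within one ordering, the first member is gap-filled
on its auxotrophic medium — its required nutrients are assumed to come from
the rest of the community — and every later member on the shared minimal
medium, with uptake candidates (exchange plus e→c transport, cost 1 each)
for every metabolite in the pool accumulated from the secretion analysis of
the members before it.  The minimal medium is the intersection of the
members' auxotrophic media minus a configurable list of organic/amino-acid
ids, plus a designated carbon source (glucose by default).

Orderings are scored on four criteria: total added reactions, dependence
of the first member on later secretions (the size of the intersection of
its uptake-carrying introduced imports with the union of subsequent
members' secreted sets), total permeable metabolites (summed per-member
secretable counts), and the summed biomass fluxes.  The criteria are
combined lexicographically — fewest added reactions first, then the other
three maximized in the order above — because solutions with the smallest
number of added reactions are the favoured ones; the order is configurable
since no canonical aggregation exists.  Failed orderings (a member
infeasible) are recorded and excluded from optimum selection.  The
individual baseline gap-fills every member independently on the minimal
medium with no pool discounts.  The pool grants later members uptake
candidates only, not the producer's quantitative flux capacity;
steady-state balancing across members (SteadyCom-style coupling, or a
single whole-community LP) is deliberately out of scope.

## Interaction analysis

A metabolite is *secreted* when some member actually exports it, and
*exchanged* when it is secreted by at least one member and imported by at
least one other (self-exchange does not count; minimal-medium nutrients are
excluded).  The dependency screen blocks, one at a time, the uptake of
every metabolite whose import a member gained during conditional gap
filling and records the ratio of blocked to reference growth, both states
evaluated with the same one-norm (or strict loop-law) treatment; ratios at
or above 0.99 are reported as 1 to avoid false-positive dependences, and
entries for metabolites a member never imported are left undefined.
Exchange flows can be aggregated per taxonomic family with
abundance-scaled weights, and the undirected interaction graph (pairs with
non-empty secreted-vs-imported overlap) can be scored against an external
edge list by both/either/neither fractions.

## Synthetic communities

The generator builds the study conditions for all tests and benchmarks.
Each member imports glucose and phosphate (default uptake 10
mmol·gDW⁻¹·h⁻¹), runs a member-specific linear core pathway (default
length 4) to a biomass precursor, and its biomass consumes that precursor,
phosphate, and any cross-fed nutrients.  A cross-feeding edge plants a
two-step synthesis branch in the producer and an auxotrophy in the
consumer (which keeps only the transporter), so the individually cheapest
repair is re-adding the two synthesis reactions (cost 100) while the
community-aware completion is a single cost-1 uptake — the planted
asymmetry that makes community benefit measurable rather than assumed.
Auxotrophic media contain glucose, phosphate, and incoming cross-fed
metabolites; the derived minimal medium is {glucose, phosphate}.  The
universal database holds every member reaction, the synthesis branches,
exchanges for extracellular species, and mass-balanced decoys that survive
database preparation.  The property table makes exactly the cross-fed
metabolites and glucose Lipinski-compliant, everything else failing on
size, with a seeded fraction of XLogP3 values blanked and a near-duplicate
donor row planted for each so 1-NN imputation restores a compliant value.
Everything is deterministic given the spec seed.

The knockout benchmark removes, per member, `⌈fraction·n_eligible⌉`
flux-carrying internal reactions (flux taken at the one-norm-minimal
optimum on the auxotrophic medium, so cycle-only reactions are never
counted), gap-fills the damaged community conditionally and individually,
and scores precision and recall of added-vs-removed reaction identities.
Matching is strict by id: a functionally equivalent decoy or an uptake
shortcut counts as a false positive.

What the generator does not emulate: genome-annotation noise, namespace
ambiguity beyond the proton alias, realistic pathway topology (branching,
cofactor coupling), thermodynamics, or abundance effects.  Passing tests
therefore demonstrate the correctness of the algorithms under planted
cross-feeding structure, not recovery performance on real draft
reconstructions.

## Problem sizes and limitations

The shipped tests and the acceptance script use deliberately small
instances — communities of 2-5 members with pathways of length 3-12,
candidate pools of tens of reactions, 8-12 orderings, 10-20 benchmark
replicates — chosen so exhaustive oracles (subset enumeration over ≤ 12
candidates, all permutations of small communities, power iteration for
STATIS) remain tractable and every pipeline stage is exercised end to end.
The LP formulation scales to genome-scale inputs, but the α-scan plus
greedy pruning is a heuristic: global optimality is only asserted where the
enumeration oracle can check it.  The exact α-schedule of the original
FastGapFilling algorithm is not published; the doubling schedule here is a
faithful re-creation with all knobs exposed in `WeightConfig`.
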