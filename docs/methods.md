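# Methods

`oncorestrict` implements a complete simulate–sample–filter–infer–score
pipeline for asking how well order restrictions among cancer driver
mutations can be recovered from cross-sectional data. This note documents
the models, the parameters that matter, the numerical choices, and what the
shipped test profile does and does not show.

## Restriction graphs

A restriction graph is a rooted DAG over driver genes. An edge u → v means
that mutation u must precede v; a node with two or more parents is a
*conjunction* and requires **all** parents (AND semantics; OR/XOR
dependency types are out of scope). Stored edge sets are always cover
(transitively reduced) relations; constructors reject anything else.
Genotypes never include Root, which behaves as always mutated. For a
genotype, `count_driver_status` splits the mutated drivers into j (all
parents mutated) and p (some parent missing); a genotype is *compatible*
(a down-set of the order) iff p = 0. "Relations" — the unit scored by the
performance measures — are the transitive closure of the cover relations
with Root excluded on both sides.

### The six study graphs

The benchmark refers to six true graphs, 11-A/B, 9-A/B, 7-A/B: 7, 9 and 11
drivers, A variants with at least one conjunction, B variants derived from
the A variants by deleting all but one incoming edge at each multi-parent
node. The original topologies were published only in a supplement that is
not available, so the graphs in `oncorestrict.graphs` are **documented
reconstructions**: they satisfy every printed structural constraint (node
counts, conjunction status, B-from-A derivation, maximal dependency chains
spanning two to six drivers across the collection) but cannot claim to
match the originals edge for edge. Results that depend on topology detail
(e.g. which scenarios allow perfect recovery) are therefore specific to
these reconstructions.

## Evolutionary simulation

Four clone-level birth–death–mutation models with selection coefficient
s = 0.1 throughout. Per-clone rates depend on (j, p) of the clone's
genotype; passengers are strictly neutral and contribute to neither:

| model | birth | death | per-gene mutation / unit time |
|-------|-------|-------|------------------------------|
| Bozic | 1 | (1−s)^j (1+s_h)^p | 1e-6 |
| exp | max(0, (1+s)^j (1−s_h)^p) | 1 | birth × 1e-7 |
| McF_4, McF_6 | (1+s)^j / (1+s_h)^p | log(1 + N/K), K = 2000 | 5e-7 |

Bozic and exp stop when the population exceeds 1e9 cells; the McF models
stop when some clone reaches j ≥ 4 (McF_4) or j ≥ 6 (McF_6). The
deviation-from-monotonicity parameter s_h is 0 (an out-of-order driver is
a neutral passenger) or ∞ (fitness zero). s_h = ∞ is realized by pruning:
the mutation is generated but the resulting clone is instantiated dead, so
no arithmetic with infinities occurs and every clone ever alive is
compatible with the true graph.

Each mutation event flips exactly one currently unmutated gene, chosen
uniformly; per-cell mutation rate is the per-gene rate times the number of
unmutated genes.

**Engines.** The default engine is a clone-level tau-leap whose
within-clone updates over each step use the *exact* transition law of the
linear birth–death process (survivor lineages Binomial(n, 1−α), each
surviving lineage a shifted-geometric family — the binomial–negative-
binomial kernel), so step length is not limited by per-event resolution.
Step length adapts to keep |b−d|·dt ≤ 0.25 (bounds the error in the
McF density-dependent death rate and in mutation-time placement) and about
one expected mutation per step; mutations within a step use the trapezoid
mean clone size. An exact per-event Gillespie engine is provided as a
correctness oracle; the suite checks that the two engines give
statistically indistinguishable mean final driver counts on matched small
configurations. Snapshots are recorded at every mutation event, so memory
scales with clone count, not cell count.

**Initial condition and restarts.** Runs start from 500 wild-type cells (a
package choice; the reference value is not printed). Patients in the study
are by construction individuals who developed cancer, so extinct or capped
runs are resimulated with fresh randomness, counting attempts in the
trajectory metadata; a run that reaches its end condition without ever
having acquired a driver is also retried, because the sampling window
(first driver → end) would be undefined.

## Sampling

One patient = one simulation = one observed genotype (cross-sectional
design; no multi-region sampling, no spatial structure). S.Time = `last`
samples at the end of the simulation; `unif` draws the sampling time
uniformly between the appearance of the first mutated driver and the end.
S.Type = `singleC` returns the genotype of one clone drawn with
probability proportional to abundance; `wholeT_0.5` / `wholeT_0.01` call a
gene mutated iff ≥ 50% / ≥ 1% of cells carry it (boundary inclusive —
"mutated in x% of the cells" is read as at-least). Per-subject RNG
substreams are derived from (master seed, design-point key, subject
index), so any subject is reproducible in isolation. The Drivers-Unknown
genome adds four neutral passengers per driver; the Drivers-Known arm
simulates drivers only, which is exact because passengers never feed back
on driver dynamics.

## Filtering and augmentation

S filters keep genes with marginal frequency strictly above the threshold
(1% or 5%; "larger than" is strict). J filters keep the largest gene set
whose every unordered pair is jointly mutated in at least the threshold
fraction of subjects ("at least" is inclusive); this is a maximum clique
of the qualifying-pair graph, solved exactly by clique enumeration
(candidate sets are at most a few dozen genes). Ties among maximum cliques
break by higher summed marginal frequency, then lexicographically — the
reference tie-break is unspecified. If more than 12 genes qualify, the 12
most frequent are kept. Augmentation (the "-A" method variants) appends
round-half-up(0.10 n) all-zero rows; in the Drivers-Unknown pipeline it
always runs after filtering.

## Oncogenetic trees

`OncotreeEstimator` computes marginal and pairwise joint frequencies and
returns the maximum-weight arborescence rooted at Root (Chu–Liu/Edmonds,
via networkx) with edge weight

    w(i → j) = log(p_ij / (p_i + p_j)) + log(p_ij / (p_i · p_j)),

p_Root = 1, p_Root,j = p_j. Pairs that never co-occur are excluded
(weight −∞). Exact weight ties break deterministically (higher parent
frequency, then lexicographic) via an additive perturbation at 1e-9, far
below any meaningful weight difference. Genes at frequency 0 are dropped
and recorded; genes at frequency 1 are excluded from the branching and
re-attached as childless direct children of Root, mirroring the standard
implementation's degenerate behavior — this is precisely the pathology
that augmentation removes. Edge probabilities p_ij/p_i are stored but not
used by any metric; topology is the deliverable. A brute-force enumeration
over all rooted spanning arborescences (≤ 6 genes) serves as the
optimality oracle in the tests.

## Conjunctive Bayesian networks

The CBN model places a poset on the genes: gene g becomes *enabled* when
all its poset parents have mutated and then waits Exp(λ_g). A patient is
observed at an Exp(ν = 1) sampling time, so the true-genotype distribution
is the phase-type solution π = ν e₀ᵀ(νI − Q)⁻¹ over the lattice of
down-sets, with Q carrying rate λ_g on each transition x → x ∪ {g}. An
independent per-gene flip error ε links true genotypes to observed rows:
P(y) = Σ_x π(x) ε^H(x,y) (1−ε)^(n−H). ε defaults to 0.05 and is held
fixed. The lattice is capped at 14 genes (it can reach 2^14 states); dense
linear solves are used up to 1024 states and sparse solves beyond.

Rates are fitted by L-BFGS-B on log λ (bounds e^±7, tolerance 1e-6),
initialized at the marginal odds f/(1−f) per gene, with 3 restarts for
final fits and warm-started single starts during the structure search.
Structure search is simulated annealing at temperature 1 with n² steps
from a linear poset ordered by decreasing marginal frequency (ties
lexicographic); moves add or remove a single cover relation (the result is
re-reduced transitively), candidates are enumerated in sorted order so the
chain is reproducible across processes, and the best-scoring poset visited
is returned. A forward simulation of the exponential clocks
(`sample_genotypes`) provides an independent Monte-Carlo oracle for the
lattice algebra and the generative route for recovery tests. This module
implements the published CBN model class; it is not bit-compatible with
any particular external binary, and comparisons with numbers produced by
such binaries are qualitative only.

With the default n² step budget the annealing search is deliberately
short; on small posets it occasionally returns a neighbor of the best
poset. The suite therefore checks recovery properties in expectation over
seeds, not per-seed.

## Performance measures

Diff counts directed cover edges present in exactly one of the two graphs,
over the union of node sets with Root included. PFD = FP/(TP+FP),
PND = FN/(TP+FN), FPF = FP/(FP+TN) on relations (closure, Root excluded)
over the universe of all ordered pairs of distinct non-Root genes from the
union of both gene sets — selected passengers and missed drivers both
enter the universe. 0/0 is scored 0 for PFD and FPF (no discoveries means
no false discoveries); PND's denominator is nonzero for every study graph.
Diff uses cover adjacency, not the closure.

## Experiment, ranking, MCB

The full factorial design crosses Model(4) × sh(2) × nodes(3) ×
conjunction(2) × S.Size(3) × S.Type(3) × S.Time(2) = 864 among-data-set
combinations × 20 replicates. The within-data-set roster has six method
slots (OT, OT-A, CBN, CBN-A and two slots for an external
progression-network tool that requires a proprietary MILP solver and is
exposed only as a plug-in registry); the bookkeeping identities (5184,
20736, 172800 analyses per plain+augmented family, per-cell counts 8640 /
4320 / 12960 / 720) are computed from the factor levels, never hardcoded.
Per-analysis failures are recorded as missing rows and excluded pairwise
from ranking and comparisons.

Ranking: within each cell of the remaining factors, treatment combinations
are ranked by mean score (ties → average rank); ranks are averaged over
cells and the averages ranked again. MCB (multiple comparisons with the
best): per among-data-set combination, each treatment is compared against
the best of the others with a one-sided paired Wilcoxon signed-rank test
on per-dataset blocks, at per-comparison level (1−coverage)/(m−1)
(Bonferroni), giving joint coverage ≥ 0.90 by default; zero differences
are handled by zero-splitting, and the empirically best treatment is
always retained so the confidence set is never empty. The reference MCB
variant is not fully specified; this one is isolated behind a small
interface so an alternative can be swapped in.

## Test profile and scaled-down study conditions

The study-scale defaults (1e9-cell thresholds, 1e-6/1e-7/5e-7 mutation
rates, 864 × 20 datasets) are cluster-sized. The repository's test profile
(`build_grid("test")`) is the package's single-CPU configuration and is
used by the test suite and the acceptance script:

* population threshold 5e4 (Bozic/exp) instead of 1e9;
* McF mutation rate 1e-5 (3e-5 in the deep McF_6 recovery scenario, where
  standing diversity must reach six-driver clones);
* McF_4, 7-gene graphs, S.Size 100, 3 replicates for the sweep arms;
* n = 1000 subjects for the structure-recovery regressions.

Pinned stochastic regressions measured once under these conditions and
frozen: OT achieves Diff = 0 on the reconstructed 7-B tree in 3/5 seeds
(0.6) and on 9-B in 4/5 (0.8) under McF_6 / sh=∞ / singleC / last; on
11-B recovery is never perfect (Diff ≤ 2, the six-deep chain tail stays
below observable frequency before the end condition); CBN rate recovery
has median relative error ≈ 0.08 at n = 1000 (deep, rarely observed
events recover poorly — their likelihood is nearly flat). The qualitative
sweep reproduces the study's orderings: OT/OT-A below CBN/CBN-A on mean
Diff, CBN/CBN-A below OT on PND, J5 filtering misses more relations than
S1, and uniform-time sampling selects fewer genes than last-time sampling
under every filter.

What the generator does **not** emulate: sequencing noise beyond the
detection threshold, spatial/tissue structure, deleterious passengers,
intra-patient multi-sampling, and the unknown exact topologies of the
original six graphs. Passing tests therefore demonstrate correctness of
the machinery and reproduction of the design's qualitative behavior at
reduced scale, not quantitative agreement with any external study table.

## Known limitations

* The annealing budget (n² steps) makes CBN structure search noisy on
  purpose — it reproduces the reference default rather than maximizing
  recovery.
* Whole-tumor sampling with threshold ≥ is a choice at the boundary; data
  exactly at threshold are called mutated.
* The exp model's mutation rate is read literally as b_j × 1e-7 per gene
  per unit time (a rate scaled by clone birth rate), not as a per-division
  probability.
* `Diff` compares cover adjacencies; if a reference computation included
  transitive edges in the adjacency matrices its Diff values would differ.
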