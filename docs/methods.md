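# Methods

This note documents the models implemented in `revenant`, the conventions
and numerical choices behind them, and the design of the validation
experiments, in enough detail to reproduce or audit any of it.

## Coordinates and conventions

Time is absolute and increases from the root at t = 0. A lineage occupies
the half-open interval (t_start, t_end]; `alive_at(tree, t)` is
{ℓ : t_start < t ≤ t_end}. Newick branch lengths are durations in the T and
G tiers and expected substitutions per site after S-mode scaling. Genome
positions are 0-based and circular (index arithmetic modulo the gene
count). Lineages are labelled `n1` (root), `n2`, … in order of creation.
Gene-tree tips are `<lineage>_<family>_<copy>`, which makes them joinable
to the genome tables.

## Species tree (T)

The complete tree is simulated with the exact Gillespie algorithm for a
linear birth–death process. Piecewise-constant rate functions are handled
by rejection at interval boundaries: if a proposed waiting time crosses the
next rate boundary, the clock advances to the boundary and the draw is
repeated with the new rates — exact for piecewise-constant intensities.
Stopping conditions: fixed horizon, total number of lineages ever created,
or both. Total extinction is a flagged outcome, not an error; the CLI can
retry with derived seeds (`--resample-until-survival`, bounded at 100
attempts).

Pruning keeps exactly the lineages ancestral to a survivor and splices out
degree-2 nodes by extending the surviving child's interval back to its
grandparent, so root-to-tip times are preserved exactly (no re-summation of
floats — the child keeps its absolute t_end).

The lineage-count profile mode runs free birth–death inside each time unit
and then forces uniformly chosen speciations or extinctions *at the unit
boundary* until the alive count equals the target. Two consequences are
worth knowing: forced events sit exactly on unit boundaries (zero-length
branches are possible), and the last alive lineage is never allowed to die,
because targets are ≥ 1 and a dead tree cannot be steered anywhere.

User-supplied Newick trees are read as chronograms: node times accumulate
from the root, tips at the maximum depth (tolerance 1e-9) are alive at the
present, strictly shallower tips are extinct. Non-binary nodes and missing
branch lengths are format errors.

`caterpillar_sampling_tree` builds a backbone lineage with zero-length side
tips: each tip's genome is an exact snapshot of the backbone genome at the
branching time. It exists because the engine only reports genomes at
lineage ends; snapshot tips turn one long run into a time series without
any special-casing in the engine. (At equal times the engine orders a
speciation before the extinction of the lineages it creates, which is what
makes zero-length tips legal.)

## Genomes (G, Gu, Gm, Gf)

A genome is a circular list of oriented gene copies, each copy identified
by (family, copy id) — copy ids are unique within a family across the whole
simulation, including across speciations, which assign fresh ids to both
children and record the mapping.

**Rates.** Each of D/L/I/P/T has an effective rate r_e in events per gene
per unit time (the total propensity of a genome is n·Σr_e + r_O), folding
occurrence and fixation into one intensity. Per-gene scaling is what makes
family dynamics a gene-level birth–death process, which the family-size
validation below depends on. Origination is per lineage (rate r_O), so
empty genomes can be repopulated. Gu overrides swap the whole rate set on
chosen lineages; Gm overrides D/L/T rates per family, in which case event
selection walks genes individually.

**Extensions.** The number of contiguous genes hit by one event is
geometric on {1, 2, …} with mean equal to the extension parameter,
truncated to the genome size (to size − 1 for transpositions). The
geometric law is this package's choice; only the mean is treated as
meaningful.

**Event semantics.** Duplications are tandem (copy inserted directly after
the template, fresh copy ids). Losses delete the segment (empty genomes are
legal). Inversions reverse the segment and flip orientations — applying the
same inversion twice is the identity. Transpositions excise and reinsert
outside the segment, preserving order and orientation. Transfers are
additive: the donor keeps its copy and the recipient, drawn among lineages
alive at the event time, gains fresh copies at a uniform position. With
transfer bias α > 0 the recipient is drawn with weight exp(−α·d), d being
patristic distance at the event time (2 × time since divergence); α = 0 is
uniform. A transfer with no possible recipient is discarded with a log
message. One k-gene event is logged once but carries per-copy mappings, so
each affected family sees k single-copy records.

**Global clock.** The engine runs one Gillespie clock over all alive
genomes between consecutive species-tree events, recomputing propensities
after every event; this global time ordering is what makes transfer
recipient sets correct, including donors and recipients that later go
extinct. Species-level records (SP with the copy-id mapping, EX, END with
the surviving copy lists) go into the same event log, which therefore
contains everything needed to replay any family's history.

**Intergenes (Gf).** Each gene carries one trailing intergene length
(continuous, arbitrary units; initial lengths are a flat Dirichlet draw
scaled to a configured total). Inversions and transpositions are driven by
breakpoints drawn uniformly on total intergenic length — a long intergene
is proportionally more likely to be cut — and the cut pieces are rejoined
so that total intergenic length is conserved exactly. The segment moved by
a Gf rearrangement is whatever lies between the two cuts, so the extension
parameter does not apply to I/P in Gf mode (it still governs D/L/T, whose
copied or deleted segments carry their intergenes with them; duplications
and transfers add intergenic length, losses remove it). This length-
weighted cut-and-rejoin dynamics is precisely the one whose stationary
distribution of normalized intergene sizes is the flat Dirichlet; an
implementation that picks the insertion intergene uniformly (not length-
weighted) demonstrably breaks that equilibrium, which is how the validation
below caught an early version of the transposition move.

`GeneCopy.length_nt` exists in the data model but has no consumer: sequence
length comes from the S-mode config and intergenic sequence content is out
of scope. It is retained (default 1) for schema completeness.

## Gene trees and reconciliations

Gene trees are rebuilt per family by replaying the event log in time order.
Each active copy is an open edge; duplications and transfers bifurcate it
(donor continuation + new copy), speciations bifurcate every copy present
in the parent into the two children, losses/extinctions close it with a
terminal node, and copies alive at the end become PRESENT leaves. The root
is the family's origination node (time 0 for root-genome families) and is
legitimately unary. Replay fails loudly if a copy is referenced before
anything created it.

Pruning keeps ancestors of PRESENT leaves and suppresses unary chains
(children keep their absolute times, so durations sum automatically); the
origination root is kept. A family with no survivors prunes to an explicit
empty marker and is listed in `lost_families.txt`.

RecPhyloXML documents pair the complete species tree with each gene tree.
Transfer departures are `branchingOut` on the donor side and the
recipient-side child carries `transferBack` with the destination species.
Both PRESENT and EXTINCTION nodes are `leaf` tags — extinct lineages are
tips of the *complete* species tree — so `loss` tags count exactly the L
events of the family, and duplication/branchingOut tags count exactly D and
T. The transfer bifurcation sits at the departure time in the donor
lineage; the recipient edge starts at that same time.

## Sequences (S)

Substitution models are normalized so one unit of branch length is one
expected substitution per site: HKY85 (JC69 when κ = 1 and frequencies are
equal), a GY94-style codon model over the 61 sense codons of the standard
code (single-nucleotide changes only, transitions × κ, nonsynonymous × ω),
the LG empirical amino-acid model (published exchangeabilities and
frequencies), and an equal-rates amino-acid model. All are reversible;
validity (rows sum to zero, detailed balance) is asserted at construction.

Simulation draws the root from the stationary distribution and evolves each
site independently down each edge with P = expm(ℓQ) (SciPy matrix
exponential, cached per distinct edge length, rows renormalized against
floating-point dust). Branch lengths are durations × global factor ×
per-branch factor. No indels and no across-site rate heterogeneity, so
alignments are trivial (equal-length, ungapped). By default only PRESENT
leaves are emitted; extinct tips are available behind a flag.

## Validation experiments

All statistical checks use α = 0.01. The experiment conditions live in one
place (`revenant.experiments`) and are shared by the test suite and
`scripts/acceptance.py`.

- **Waiting times.** Only at constant total propensity are inter-event
  waits Exp(R), so the experiment runs inversions/transpositions only
  (size-preserving) on a single lineage with 100 genes: R = 100·(r_I+r_P),
  10,000 waits, KS test.
- **Birth–death moment.** 10,000 replicates at λ = 1, μ = 0.5, t = 2; the
  mean survivor count is compared with e^{(λ−μ)t} at 3 standard errors.
- **Intergene equilibrium.** 300 Gf replicates, 20 genes, rearrangements
  only, branch length 60 (≈ 240 events per replicate of burn-in from an
  already-Dirichlet start); the pooled normalized marginals are tested
  against Beta(1, m−1), the marginal of the flat Dirichlet.
- **Event frequencies.** Rates 2:1:1:1:1 on two lineages with 2000 genes:
  since every gene-level rate scales with the same genome size, each
  event's conditional probability is its rate share regardless of how the
  genome grows, so observed counts are chi-squared against the plain rate
  ratios; extensions are chi-squared against Geometric(1/mean) per event
  type with a Bonferroni correction across types.
- **Family-size tails.** Both candidate laws are fit by maximum likelihood
  *truncated to the observed range* [5, max], and the Weibull shape is
  constrained to β ≥ 0.25. Both choices are essential for the comparison to
  mean anything: an untruncated power law is punished merely for predicting
  mass beyond the largest observable family, and an unconstrained truncated
  Weibull with β → 0 degenerates into a power law of arbitrary exponent, so
  the likelihood-ratio sign would otherwise be decided by the fitting
  pathologies rather than the data. The comparator was calibrated on
  synthetic Pareto, log-uniform and geometric controls. Margins below 2
  log-units, or fewer than 50 tail observations, give an explicit
  "inconclusive" verdict.

  The two regimes use different observables because the two laws live at
  different levels. Duplication-dominant (r_D = 0.3 > r_L = 0.2, six
  replicates): clade-wide family sizes on a growing birth–death species
  tree (λ = 0.2, μ = 0.05, t = 25). On a growing tree the origination
  opportunity grows exponentially, so family ages are exponentially tilted
  toward young — the classical mechanism by which exponentially growing
  families observed at exponentially distributed ages produce a genuine
  power law. (Per-genome sizes in this regime, with family ages uniform
  over a finite run, carry a soft exponential cutoff and would prefer the
  stretched exponential at any sample size — measured during development,
  not assumed.) Loss-dominant (r_D = 1.9 < r_L = 2.0, origination 20):
  per-genome sizes sampled at stationarity along one lineage via 160
  snapshot tips spaced 3 time units after a burn-in of 60 — the stationary
  per-genome size law under loss dominance is the log-series-type
  distribution whose tail is exponential-type, and the stretched
  exponential wins decisively there.
- **Bookkeeping.** On an all-event-type run: per-family D/T/L node counts
  in the gene trees equal the per-copy event-log counts exactly, and
  PRESENT leaf counts equal surviving copy counts exactly (integer
  equality, no tolerance).
- **Sequence divergence.** Two-leaf JC tree with edge length t = 0.2: the
  proportion of differing sites over 100,000 sites is compared with
  3/4·(1 − e^{−8t/3}) at 3 binomial standard errors.
- **Ghost donor.** A handcrafted event log in which lineage B donates a
  gene to A at t = 1.0 and goes extinct at t = 1.5, while A has already
  lost its own copy: the complete gene tree must show the donor path
  through B, and the pruned gene tree must retain exactly the transferred
  copy in A with no donor-side leaves.

## What the synthetic conditions do and do not show

The generator produces data under the simulator's own assumptions: constant
or piecewise-constant rates, memoryless events, additive transfers,
independent sites, no indels. Passing the battery shows the implementation
agrees with its specified stochastic processes (exact waiting-time law,
correct conditional event probabilities, exact bookkeeping) — it does not
show that real genomes evolve this way, and the family-size experiments in
particular show that *which* tail law you observe depends on the observable
(per-genome vs clade-wide) and the sampling design, not only on the
duplication/loss balance.

## Known limitations

Replacement transfers, gene fusion/fission, within-gene breakpoints, linear
chromosomes and chromosome-number changes are out of scope; transfers are
always additive. No fossilized birth–death sampling or extant-sampling
fractions. Reconciliations record simulated truth only — there is no
inference. The engine recomputes per-lineage propensities after every
event, which is exact but O(alive lineages) per event; runs in the 10^5–10^6
event range take seconds to minutes in pure Python.
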