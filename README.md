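# revenant

A multilevel evolutionary simulator that keeps its dead.

`revenant` simulates, in three chained tiers, (**T**) a species tree under a
birth–death process *including every lineage that goes extinct before the
present*, (**G**) circular genomes of oriented genes evolving along all
branches of that complete tree under six event types — originations (O),
duplications (D), losses (L), inversions (I), transpositions (P) and lateral
transfers (T) — and (**S**) nucleotide, codon or amino-acid sequences along
the resulting gene trees.

Why keep extinct lineages? Because most lateral gene transfers observed in
real data come from donors that left no sampled descendants. A simulator
that only grows the reconstructed tree silently assumes every donor
survived. Here, a lineage keeps evolving — and keeps donating genes — until
the moment it dies, so the pruned ("observable") outputs contain genes whose
true history runs through **ghost lineages** that are invisible in the
species phylogeny. Full gene-tree/species-tree reconciliations (RecPhyloXML)
record the simulated truth for benchmarking inference methods.

## Model summary

- **T mode.** Exact Gillespie simulation of a linear birth–death process:
  with *N* lineages alive and rates λ (speciation), μ (extinction), the next
  event is at an Exp(*N*(λ+μ)) wait and is a speciation with probability
  λ/(λ+μ), striking a uniformly chosen lineage. Rates may be
  piecewise-constant in time; runs stop at a fixed time or lineage count; a
  lineage-count profile mode forces exact alive counts per time unit. The
  complete tree is pruned to the reconstructed tree of survivors by removing
  extinct lineages and suppressing degree-2 nodes.
- **G mode.** One global Gillespie clock over all concurrently alive
  genomes. Each of D/L/I/P/T has an *effective rate* (events per gene per
  unit time) and an *extension* (mean number of contiguous genes affected,
  geometric); origination is per lineage. Transfers copy a segment into a
  recipient drawn among the lineages alive at that instant — uniformly, or
  biased toward close relatives by exp(−α·d) in patristic distance.
  Variants: branch-specific rates (**Gu**), family-specific rates (**Gm**),
  and explicit intergene lengths (**Gf**) whose rearrangement breakpoints
  fall uniformly on intergenic sequence.
- **Gene trees.** Rebuilt per family by replaying the event log:
  speciations, duplications and transfers bifurcate; losses and extinctions
  terminate; survivors become PRESENT leaves. Inversions and transpositions
  change gene neighbourhoods, never tree topology. Complete and pruned
  Newick trees plus RecPhyloXML reconciliations are written per family.
- **S mode.** Continuous-time Markov substitution along (scaled) gene
  trees: HKY85/JC69 nucleotide, GY94-style codon (61 sense codons, κ and
  ω=dN/dS), or LG amino acid. Branch durations × global and per-branch
  factors give expected substitutions/site; no indels.

## Worked example

Three flat `KEY VALUE` config files drive the pipeline (5-gene starting
genome, all six event types):

```
# t.conf                 # g.conf                  # s.conf
SPECIATION_RATE 1.0      MODE G                    MODEL_LEVEL NUCLEOTIDE
EXTINCTION_RATE 0.5      INITIAL_GENOME_SIZE 5     ROOT_LENGTH 60
STOP_TIME 3              DUPLICATION_RATE 0.05     SEED 7
SEED 0                   LOSS_RATE 0.05
                         INVERSION_RATE 0.05
                         TRANSPOSITION_RATE 0.05
                         TRANSFER_RATE 0.05
                         ORIGINATION_RATE 0.1
                         SEED 42
```

```
$ revenant T t.conf demo
T: 7 lineages (3 alive at the end) -> demo/T
$ revenant G g.conf demo
G: 6 families, events: D=1, END=3, EX=1, I=2, L=4, O=1, P=2, SP=3, T=2 -> demo/G
$ revenant S s.conf demo
S: 6 alignments -> demo/S
```

The T tier simulated 7 lineages of which 3 survive to the present (so the
pruned `ExtantTree.nwk` has 3 tips and `CompleteTree.nwk` keeps all 7,
including one extinct branch). The G tier evolved the 5 starting families
plus 1 origination (6 families total) and logged every event with its copy
mapping, e.g. in `demo/G/Events.tsv`:

```
time          type  lineage  recipient  start  extension  families  copy_map
0.453287936   SP    n1                                    1,2,3,4,5  1.1>2,3;...
0.4598901569  EX    n2                                    1,2,3,4,5  1.2>-;...
1.575885334   I     n4                  0      1          1
```

(lineage n2 went extinct 0.007 time units after the root speciation — its
genome is still written under `demo/G/Genomes/n2.tsv`). The S tier writes
one FASTA per family with tips named `<lineage>_<family>_<copy>`:

```
>n5_1_5
CAGCAAAAGAAGCTCGCTACGGATGAGTTCTCAAGCAGTAATCCAACGGGACTAACAAAT
```

`revenant validate <run_dir>` runs the statistical checks that apply to a
finished run (exponential waiting times, rate-proportional event counts,
family-size tails) and writes `validation.tsv`.

The same machinery is available as a library — `simulate_complete_tree`,
`evolve_genomes`, `build_all_gene_trees`, `simulate_alignment`,
`run_pipeline` — see `docs/methods.md` for the model details and design
choices.

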