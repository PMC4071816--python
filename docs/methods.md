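# Methods

## The homing-cycle model

Each intein allele (one insertion site in one host gene) evolves
independently along a species tree as a continuous-time chain over three
occupancy states of its target site:

```
ABSENT --invasion/transfer--> LARGE --hen_loss--> MINI --deletion--> ABSENT
```

`LARGE` is the canonical two-domain intein (splicing domains + homing
endonuclease); `MINI` has lost the HEN and retains only splicing
activity. Two routes enter `LARGE`: de novo invasion from an external
intein pool (rate `invasion_rate` per branch per unit time) and homing
transfer from a contemporaneous lineage. Transfer requires a LARGE donor
(the HEN is the invasion machinery) and an ABSENT recipient site (homing
needs an empty target); its rate per donor–recipient pair is
`transfer_rate · exp(−d / decay_lambda)` where `d` is the patristic
distance between the two lineages at the moment of the event. The
exponential kernel is the minimal monotone choice for the observation
that recombination succeeds more readily between close relatives; no
functional form is established empirically, so `decay_lambda` is a free
scale (default 1.0, about 40% of the height of a default 12-taxon tree).

The literal homing cycle is a verbal description, not a parameterised
model; the independent per-allele Markov chain with Poisson thinning is
the simplest generative process matching its phases. Within-population
dynamics (coexistence of invaded and free alleles inside one genome
population) are deliberately out of scope: a lineage is a point, not a
population.

### Bookkeeping and numerics

The simulation walks the tree root→tips in time slices of 1% of tree
height. Within a slice each (lineage, allele) undergoes at most one state
event (probability `1 − exp(−rate·dt)` per eligible transition), and each
donor/recipient pair can fire one transfer. Slicing avoids exact
continuous-time competing-risk machinery; at 100 slices the
discretisation bias is negligible at the simulated scale. Branches
shorter than one slice simply experience no events. Species trees are
pure-birth (Yule) trees generated in-package so that newick output is
byte-stable for a given seed.

### Sequences

Host (extein) and intein sequences evolve by a uniform-rate amino-acid
replacement process: Poisson(μ·L·dt) substitutions per slice, each to one
of the 19 other residues uniformly. The model is deliberately simple — a
stationary substitution process is all the detection stage needs, and the
constraint that matters is the rate ratio: `mu_intein ≥ mu_extein`
(inteins evolve measurably faster than their exteins; defaults 0.15
vs 0.05 substitutions/site/unit time). Splicing-critical residues are
held invariant (purifying selection on splicing function): the intein's
N-terminal nucleophile (C), its C-terminal His-Asn dipeptide, and the +1
extein nucleophile (S). Each allele has one fixed insertion site per
host gene (ectopic re-invasion is rare enough to ignore), placed at the
midpoint of a 400-aa extein. Large inteins are 450 aa; HEN loss deletes a
fixed internal 270-aa segment leaving a 180-aa mini, so the length gap
the state classifier relies on is 270 aa — comfortably above its 100-aa
cutoff. A `missing_frac` of cells (default 5%) is masked as missing data
(the host gene is withheld from the emitted FASTA), emulating incomplete
genomes.

### What the simulator does not emulate

Real data add several difficulties the generator leaves out:
insertions/deletions inside inteins and exteins (lengths here are exact,
so the length-gap classifier sees clean bimodality), substitution-rate
heterogeneity across sites and lineages, intein alleles sharing one host
protein, truncated contigs (only whole proteins or absent ones), and
annotation noise. Passing the self-tests therefore shows the pipeline's
logic is correct on data matching its assumptions, not that its
sensitivity transfers to arbitrary real genomes.

### Default rates

No quantitative transfer/loss rates exist for halobacterial inteins; the
defaults (transfer 0.4, HEN loss 0.15, deletion 0.05, invasion 0 with one
forced invasion per allele) were chosen once to make every downstream
stage exercisable — presence and absence coexist, minis and larges
coexist, and some but not all alleles stay vertically compatible — and
are not biological estimates.

## Detection

Candidates come from a global pairwise alignment (BLOSUM62, affine gaps
open 11 / extend 1 — common protein-alignment defaults, so block
boundaries are reproducible) of the host protein against an intein-free
reference ortholog. Maximal host-only runs are candidate insertions; runs
separated by ≤ 5 matched residues are bridged, because a few inserted
residues matching the ortholog by chance can split one insertion in two.
Each block must be flank-anchored (10 residues per side aligning at
≥ 50% identity — the conserved-site requirement), add 100–700 aa, and
carry the splicing motifs. Alignment boundaries can be off by a residue
or two, so termini are refined within ±3 residues to the offsets
satisfying the most motif criteria (smallest shift wins ties).

PSSM confirmation: per-allele seed alignments give log-odds matrices
(`log2` of pseudocount-smoothed column frequency over background;
background-proportional pseudocounts with weight 1.0 keep scores finite
on tiny seed sets; columns > 50% gap are dropped and recorded). A hit
must be overlapped by a scan window scoring ≥ 10 bits. Because
mini-inteins lack the entire HEN domain, a full-length matrix cannot
align to them in one ungapped window; N-terminal (100-column) and
C-terminal (50-column) splicing-region sub-matrices are scanned as well —
the splicing domains are what every intein retains. The 10-bit default
threshold was calibrated on the simulator's null (random background
proteins essentially never reach it) since no search threshold for the
original genome screen is recorded.

Iterative refinement folds passing inteins back into the seed alignments
(pairwise alignment to the column consensus; insertions relative to the
profile are discarded so the column frame is stable), rebuilds the
matrices and rescans, stopping at a fixed point or after a fixed round
budget (default 3, with a `converged` flag).

## State calling

Within one allele, sort the unique intein lengths and find the largest
adjacent gap (ties broken toward the gap at the smaller length, which
favors fewer mini calls). If it is ≥ 100 aa, cut at the gap midpoint —
the criterion states the gap, not where to cut, and the midpoint is
symmetric and order-stable. Gap-free alleles get a single state by median
length against a 300-aa floor: below typical two-domain inteins, above
splicing-only domains. Alleles observed in a single genome necessarily
use the floor rule and are flagged low-confidence. Mini calls are
verified against the alignment: the mini's gap columns must fall ≥ 80%
inside the HEN region (estimated, when not given, as the maximal column
run where ≥ 80% of large rows have residues and ≥ 80% of mini rows are
gapped). Hits whose insertion abuts a sequence end are demoted to
missing — a truncated sequence cannot be length-classified.

## Tree analyses

**Parsimony.** Presence–absence characters are mapped with unit-cost
Sankoff dynamic programming; missing leaves are pruned, not imputed
(conservative and order-independent). Polytomies are soft — the count is
the minimum over binary resolutions, consistent with treating collapsed
low-support nodes as unresolved rather than as hard multifurcations. For
a binary character this minimum has a closed form at a polytomy: each
child subtree pays its own minimum, plus one change if any child strictly
prefers the opposite state (all such children bundle under one new edge).
A trifurcating root is just an unrooted binary node and is scored hard.
An allele is vertically compatible when its character needs ≤ 1 change
(one gain, no loss); the bound is configurable.

**Monophyly.** Allele trees are unrooted, so "clade" is made precise as
"some edge bipartition separates exactly the focal leaves". On
multifurcating trees the test is split compatibility: the focal|rest
split must be compatible with every split of the tree, i.e. some
resolution contains the clade — permissive by design, matching the
practice of discounting nodes under 70% bootstrap support. For
polyphyletic sets, interrupting taxa are the non-focal leaves inside the
subtree spanned by the focal leaves; to make the report deterministic and
independent of input rooting, the tree is rooted at the lexicographically
smallest non-focal leaf and the interrupters are the non-focal leaves
under the focal MRCA. (Minimal interrupter sets are not unique — in a
discordant quartet either non-focal leaf suffices — so any consistent
convention is equally defensible.) Their majority group annotation is
reported, with ties listing all tied groups.

**Support collapsing** contracts internal edges whose child support is
below threshold (default 70); nodes without numeric support are kept.

## Result-table fixtures

The survey's printed tables are shipped as TSV transcriptions
(`inteinflow/data/`): the 24-allele catalog with novelty flags, the
per-allele topology/taxon-count table, and the non-halobacterial carrier
list with mini and within-Halobacteria flags. Headline percentages are
rounded to the nearest integer, the precision the survey reports
(20/24 → 83%). The mini/large tally of clade-interrupting taxa is
reported but not asserted: no single counting rule over the printed flags
reproduces the prose's "5 of 11" figure, so the tally is provided for
inspection. Genome-level claims (survey size, genus composition) require
the survey's supplementary genome list, which is not redistributed; the
relevant summary accepts such a table as input and is otherwise cleanly
unavailable.

## Mixed-matrix export

For Bayesian clustering, the exporter writes a NEXUS file with
`datatype=mixed`: one binary column per allele (1 = intein present, mini
and large alike; 0 = intein-free site; ? = missing) followed by one
protein partition per allele, padded with `?` for genomes absent from
that allele's alignment. The command block encodes the stated priors —
variable coding with 5 beta categories and a symmetric
Dirichlet/exponential(1.0) hyperprior for the binary partition; fixed WAG
with empirical frequencies and invariant-sites + gamma rates for the
protein partitions — and leaves MCMC run length explicitly unset. Running
the MCMC itself is out of scope; the exporter makes an external run a
one-command affair.

## Problem sizes

The shipped self-tests run the simulator at desk scale: 12 taxa × 4
alleles for end-to-end recovery, 16 taxa × 6 alleles × 30–50 replicates
for the rate sweeps, random trees of ≤ 10 leaves against the brute-force
oracles. These sizes give stable Monte-Carlo means while keeping the
whole suite in well under a minute of simulation time; the simulator
itself handles the ~120-taxon scale of a real survey.
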