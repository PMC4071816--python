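# inteinflow

Inteins are self-splicing protein parasites that sit in conserved sites of
slowly evolving host genes (exteins). Canonical ("large") inteins carry a
homing endonuclease (HEN) domain that cuts intein-free alleles at the
conserved target site and triggers repair-mediated copying of the intein —
the homing cycle: invasion → fixation → HEN degradation into a "mini"
intein → precise loss → re-invasion. Because homing rides on whatever gene
flow a population already has, the distribution and state of intein
alleles across genomes is a tracer of horizontal gene transfer, especially
in highly recombinant groups such as the halophilic archaea
(Halobacteria).

`inteinflow` is a toolkit for this kind of survey, aimed at
microbial-evolution researchers:

* **detect** — find intein insertions in host proteins by PSSM window
  scanning plus global alignment against an intein-free reference
  ortholog, with the 100–700 aa size envelope and splicing-motif filters
  (N-terminal C/S/A, C-terminal HN/HQ or N/Q, +1 extein C/S/T);
* **states** — call the symbiotic state of every genome × allele cell
  (`absent` / `mini` / `large` / `missing`): within an allele, a gap
  ≥ 100 aa in the sorted intein lengths separates minis from larges (cut
  at the gap midpoint), and mini calls are verified by requiring their
  alignment gaps to coincide with the HEN region;
* **phylo** — map presence–absence characters onto a reference phylogeny
  with minimum-change parsimony (an allele needing ≤ 1 change is
  compatible with vertical inheritance; more implies transfer), classify
  monophyly of a focal taxon set on unrooted allele trees via split
  compatibility, collapse nodes with bootstrap support < 70, and count
  cluster-shared alleles;
* **profiles** — catalog summaries, per-group tallies, per-genus density
  profiles and headline percentages, with the survey's printed result
  tables shipped as TSV transcriptions;
* **simulate** — a forward simulator of the homing cycle on a Yule
  species tree (per-allele ABSENT→LARGE→MINI→ABSENT chains, de novo
  invasion, distance-biased transfer `transfer_rate · exp(−d/λ)`, and
  sequence evolution with the intein rate elevated over the extein rate)
  that emits FASTA/newick/TSV fixtures with full ground truth, so the
  whole pipeline is testable without any downloads;
* **io / cli** — FASTA, newick and TSV round-trips, a mixed
  presence-absence + protein NEXUS exporter for Bayesian clustering, and
  an `inteinflow` command with `simulate`, `detect`, `classify`,
  `analyze`, `report`, `export-nexus` and `run` subcommands.

## Worked example

Run the full pipeline on a simulated 12-genome, 4-allele dataset:

```bash
inteinflow run --seed 42 --out demo/
```

```
state recovery: 1.000; vertical fraction: 0.750
```

The detection + classification stages recovered the simulated truth on
100% of unmasked genome × allele cells, and 3 of 4 alleles map onto the
species tree with at most one parsimony event (the fourth needed more
changes — the signature of the horizontal transfers the simulator
actually performed). `demo/` contains the emitted fixture (host-protein
FASTA, species tree, truth tables), the detected profile TSV, a run
manifest and a plain-text report.

The survey summary over the shipped allele catalog and tree-topology
tables:

```bash
inteinflow report
```

```
intein alleles: 24
invaded host genes: 13
newly reported alleles: 7
newly reported host proteins: 2
monophyletic allele trees: 83%
polyphyletic alleles: 4 ({"bacteria": 2, "Euryarchaeota": 2})
```

That is: the halobacterial survey found 24 intein alleles across 13
invaded host genes (7 alleles newly reported, 2 of them in proteins not
previously known to carry inteins); 83% of the per-allele trees show the
halobacterial sequences as a single clade, and of the 4 polyphyletic
alleles, 2 are interrupted by bacterial sequences.

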