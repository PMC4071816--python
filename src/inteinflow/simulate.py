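"""Forward simulation of the intein homing cycle on a species tree.

The generative model follows the three phases of the homing cycle:
invasion of an empty target site by a canonical (HEN-bearing, "large")
intein, degradation of the homing endonuclease yielding a mini-intein,
and precise deletion restoring the empty site.  Each allele evolves
independently along the tree as a continuous-time chain
ABSENT -> LARGE -> MINI -> ABSENT, with two entry routes into LARGE:
de novo invasion from an external intein pool, and homing transfer from a
contemporaneous lineage that carries a large intein, at a rate decaying
exponentially with the donor-recipient patristic distance (recombination
succeeds more readily between close relatives).  Transfers require a
LARGE donor (the HEN is the invasion machinery) and an ABSENT recipient
site (homing needs an empty target).

Host (extein) and intein sequences evolve under a uniform-rate amino-acid
replacement process, with the intein substitution rate elevated relative
to the extein.  Splicing-critical residues (intein N-terminal nucleophile,
C-terminal Asn, and the +1 extein nucleophile) are held invariant —
purifying selection on splicing function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .io import AMINO_ACIDS, FastaRecord, write_fasta, write_newick, write_tsv, read_tsv
from .states import AlleleProfile, State

_N_SLICES = 100  # transfer bookkeeping at time slices of 1% of tree height


@dataclass
class SimulationConfig:
    """Rates are per unit time on the simulated tree's branch-length scale.

    n_taxa: extant leaves of the species tree.
    birth_rate: Yule speciation rate (trees of height ~ log(n_taxa)).
    mu_extein / mu_intein: substitutions/site/unit-time for host and intein
        sites; mu_intein must be >= mu_extein (inteins evolve faster than
        their extein hosts).
    n_alleles: number of independent intein alleles, one host gene each.
    invasion_rate: per-branch rate of de novo LARGE intein entry from the
        external pool.
    transfer_rate: per donor-recipient pair rate of homing transfer,
        thinned by exp(-d / decay_lambda) in patristic distance d.
    hen_loss_rate / deletion_rate: LARGE->MINI and MINI->ABSENT rates.
    large_len / mini_len: intein lengths (aa); the difference is the HEN
        segment and must be >= 100 so length-gap classification applies.
    extein_len: host protein length (aa).
    missing_frac: fraction of genome x allele cells masked as missing data
        in the emitted truth (the host gene is withheld).
    root_invasion_alleles: alleles (by index) forced to LARGE at the root —
        the "invaded before the radiation" control.
    seed_invasions: when True, every allele without a root invasion gets
        exactly one forced invasion at a branch-length-uniform point, so
        presence is guaranteed and, with all rates zero, strictly vertical.
    """

    n_taxa: int = 12
    birth_rate: float = 1.0
    mu_extein: float = 0.05
    mu_intein: float = 0.15
    n_alleles: int = 4
    invasion_rate: float = 0.0
    transfer_rate: float = 0.4
    decay_lambda: float = 1.0
    hen_loss_rate: float = 0.15
    deletion_rate: float = 0.05
    large_len: int = 450
    mini_len: int = 180
    extein_len: int = 400
    missing_frac: float = 0.05
    seed: int = 0
    root_invasion_alleles: tuple[int, ...] = ()
    seed_invasions: bool = True

    def __post_init__(self):
        rates = dict(birth_rate=self.birth_rate, mu_extein=self.mu_extein,
                     mu_intein=self.mu_intein, invasion_rate=self.invasion_rate,
                     transfer_rate=self.transfer_rate, decay_lambda=self.decay_lambda,
                     hen_loss_rate=self.hen_loss_rate, deletion_rate=self.deletion_rate)
        for name, value in rates.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0 (got {value})")
        if self.mu_intein < self.mu_extein:
            raise ValueError("mu_intein must be >= mu_extein")
        if self.large_len - self.mini_len < 100:
            raise ValueError("large_len - mini_len must be >= 100")
        if not 0 <= self.missing_frac < 1:
            raise ValueError("missing_frac must lie in [0, 1)")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if any(a < 0 or a >= self.n_alleles for a in self.root_invasion_alleles):
            raise ValueError("root_invasion_alleles indices out of range")


@dataclass
class Event:
    time: float
    branch: str  # label of the child node of the branch
    allele: str
    kind: str  # invasion | transfer | hen_loss | deletion
    donor: str = ""


@dataclass
class EventLog:
    events: list[Event] = field(default_factory=list)

    def append(self, ev: Event) -> None:
        if self.events and ev.time < self.events[-1].time - 1e-12:
            raise ValueError("event times must be non-decreasing")
        self.events.append(ev)

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)


@dataclass
class SimulationTruth:
    tree: dendropy.Tree
    profile: AlleleProfile
    events: EventLog
    # (genome, allele) -> full host protein (intein spliced in when present)
    proteins: dict[tuple[str, str], str]
    # (genome, allele) -> (start, end) of the intein block, present cells only
    coordinates: dict[tuple[str, str], tuple[int, int]]
    # allele -> intein-free ancestral extein (reference ortholog)
    reference_orthologs: dict[str, str]
    # allele -> small divergent sample of the pool intein (seed alignment)
    seed_alignments: dict[str, list[str]]
    config: SimulationConfig = None


# ---------------------------------------------------------------------------
# Species tree (pure-birth)
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Simulate an ultrametric Yule (pure-birth) species tree.

    Starts from the crown split, waits Exp(k * birth_rate) with k extant
    lineages, splits a uniformly chosen lineage, and extends all lineages
    to the present once n_taxa is reached.  Leaf labels T01..Tnn;
    deterministic for a given seed.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    root.time = 0.0
    active = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append(child)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (len(active) * birth_rate))
        i = int(rng.integers(len(active)))
        parent = active.pop(i)
        parent.time = t
        for _ in range(2):
            child = dendropy.Node()
            parent.add_child(child)
            active.append(child)
    t += rng.exponential(1.0 / (len(active) * birth_rate))
    height = t
    width = max(2, len(str(n_taxa)))
    # label leaves in a stable traversal order
    counter = 0
    for node in tree.preorder_node_iter():
        if node in active:
            counter += 1
            node.taxon = taxa.new_taxon(label=f"T{counter:0{width}d}")
            node.time = height
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.time - node.parent_node.time
    tree.seed_node.edge.length = None
    return tree


# ---------------------------------------------------------------------------
# Homing simulation
# ---------------------------------------------------------------------------

def _label_nodes(tree: dendropy.Tree) -> None:
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.sim_label = node.taxon.label
        elif node.parent_node is None:
            node.sim_label = "root"
        else:
            k += 1
            node.sim_label = f"N{k}"


def _node_times(tree: dendropy.Tree) -> dict:
    times = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            times[node] = times[node.parent_node] + (node.edge.length or 0.0)
    return times


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _mutate(rng: np.random.Generator, seq: str, mu: float, dt: float,
            protected: frozenset[int]) -> str:
    """Uniform-rate replacement: Poisson(mu * L * dt) substitutions, each at
    a uniform site, to one of the 19 other residues."""
    n_sub = rng.poisson(mu * len(seq) * dt)
    if n_sub == 0:
        return seq
    chars = list(seq)
    for _ in range(n_sub):
        pos = int(rng.integers(len(chars)))
        if pos in protected:
            continue
        old = chars[pos]
        new = AMINO_ACIDS[int(rng.integers(20))]
        while new == old:
            new = AMINO_ACIDS[int(rng.integers(20))]
        chars[pos] = new
    return "".join(chars)


@dataclass
class _Lineage:
    node: object  # dendropy node at the tip of this branch
    states: list[str]  # per-allele: 'A' | 'L' | 'M'
    inteins: list[str | None]


def simulate_homing(tree: dendropy.Tree, config: SimulationConfig) -> SimulationTruth:
    """Run the homing-cycle simulation along a species tree.

    Walks the tree root->tips in time slices of 1% of tree height; within
    a slice each active lineage x allele undergoes at most one state event
    (Poisson thinning), and each LARGE donor / ABSENT recipient pair may
    trigger a transfer at rate transfer_rate * exp(-d / decay_lambda).
    Sequences co-evolve at mu_extein (extein) and mu_intein (intein).
    """
    rng = np.random.default_rng(config.seed)
    _label_nodes(tree)
    times = _node_times(tree)
    height = max(times[lf] for lf in tree.leaf_node_iter())
    dt = height / _N_SLICES
    alleles = [f"allele{i + 1:02d}" for i in range(config.n_alleles)]
    hen_len = config.large_len - config.mini_len
    hen_start = (2 * config.mini_len) // 3
    insert_pos = config.extein_len // 2

    # ancestral material per allele: extein with protected +1 residue, and
    # an external-pool large intein with canonical splicing residues
    ref_exteins, pool_inteins = {}, {}
    for a in alleles:
        ext = list(_random_protein(rng, config.extein_len))
        ext[insert_pos] = "S"  # +1 extein nucleophile
        ref_exteins[a] = "".join(ext)
        pool = list(_random_protein(rng, config.large_len))
        pool[0] = "C"
        pool[-1] = "N"
        pool[-2] = "H"
        pool_inteins[a] = "".join(pool)
    ext_protected = frozenset([insert_pos])
    large_protected = frozenset([0, config.large_len - 2, config.large_len - 1])
    mini_protected = frozenset([0, config.mini_len - 2, config.mini_len - 1])

    def protected_for(seq: str) -> frozenset[int]:
        return large_protected if len(seq) == config.large_len else mini_protected

    # seed alignments: 3 divergent copies of the pool intein (no indels)
    seed_alignments = {
        a: [_mutate(rng, pool_inteins[a], 0.08, 1.0, protected_for(pool_inteins[a]))
            for _ in range(3)]
        for a in alleles
    }

    events = EventLog()
    root = tree.seed_node
    root_states = ["A"] * config.n_alleles
    root_inteins: list[str | None] = [None] * config.n_alleles
    for ai in config.root_invasion_alleles:
        root_states[ai] = "L"
        root_inteins[ai] = pool_inteins[alleles[ai]]
        events.append(Event(0.0, "root", alleles[ai], "invasion"))

    # forced single invasions at branch-length-uniform points
    forced: dict[tuple[object, int], list[float]] = {}
    if config.seed_invasions:
        branches = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
        lengths = np.array([b.edge.length for b in branches])
        probs = lengths / lengths.sum()
        for ai in range(config.n_alleles):
            if ai in config.root_invasion_alleles:
                continue
            b = branches[int(rng.choice(len(branches), p=probs))]
            t_ev = times[b.parent_node] + rng.uniform(0, b.edge.length)
            forced.setdefault((b, ai), []).append(t_ev)

    # per-lineage extein sequences evolve with the walk as well
    lineages: dict[object, _Lineage] = {}
    exteins: dict[object, dict[str, str]] = {}
    for child in root.child_nodes():
        lineages[child] = _Lineage(node=child, states=list(root_states),
                                   inteins=list(root_inteins))
        exteins[child] = dict(ref_exteins)

    split_time_cache: dict[tuple, float] = {}

    def split_time(n1, n2) -> float:
        key = (id(n1), id(n2)) if id(n1) < id(n2) else (id(n2), id(n1))
        if key not in split_time_cache:
            anc1 = set()
            p = n1
            while p is not None:
                anc1.add(p)
                p = p.parent_node
            p = n2
            best = 0.0
            while p is not None:
                if p in anc1:
                    best = times[p]
                    break
                p = p.parent_node
            split_time_cache[key] = best
        return split_time_cache[key]

    def advance_splits(t_now: float, t_event: float) -> None:
        """Replace every lineage whose node time has passed with its children."""
        changed = True
        while changed:
            changed = False
            for node, lin in list(lineages.items()):
                if not node.is_leaf() and times[node] <= t_now + 1e-12:
                    # pending forced invasions on this branch fire before the split
                    for ai in range(config.n_alleles):
                        if (node, ai) in forced:
                            del forced[(node, ai)]
                            if lin.states[ai] == "A":
                                lin.states[ai] = "L"
                                lin.inteins[ai] = pool_inteins[alleles[ai]]
                                events.append(Event(t_event, node.sim_label,
                                                    alleles[ai], "invasion"))
                    del lineages[node]
                    ext = exteins.pop(node)
                    for child in node.child_nodes():
                        lineages[child] = _Lineage(node=child, states=list(lin.states),
                                                   inteins=list(lin.inteins))
                        exteins[child] = dict(ext)
                    changed = True

    p_hen = 1 - np.exp(-config.hen_loss_rate * dt)
    p_del = 1 - np.exp(-config.deletion_rate * dt)
    p_inv = 1 - np.exp(-config.invasion_rate * dt)

    for k in range(_N_SLICES):
        t0, t1 = k * dt, (k + 1) * dt
        t_mid = (t0 + t1) / 2
        # splits occurring within this slice
        advance_splits(t1, t0)
        active = sorted(lineages.values(), key=lambda l: l.node.sim_label)
        # state events (at most one per lineage x allele per slice)
        for lin in active:
            for ai, a in enumerate(alleles):
                key = (lin.node, ai)
                if key in forced and any(t_ev <= t1 for t_ev in forced[key]):
                    forced[key] = [t_ev for t_ev in forced[key] if t_ev > t1]
                    if not forced[key]:
                        del forced[key]
                    if lin.states[ai] == "A":
                        lin.states[ai] = "L"
                        lin.inteins[ai] = pool_inteins[a]
                        events.append(Event(t_mid, lin.node.sim_label, a, "invasion"))
                st = lin.states[ai]
                u = rng.random()
                if st == "A" and u < p_inv:
                    lin.states[ai] = "L"
                    lin.inteins[ai] = pool_inteins[a]
                    events.append(Event(t_mid, lin.node.sim_label, a, "invasion"))
                elif st == "L" and u < p_hen:
                    seq = lin.inteins[ai]
                    lin.inteins[ai] = seq[:hen_start] + seq[hen_start + hen_len:]
                    lin.states[ai] = "M"
                    events.append(Event(t_mid, lin.node.sim_label, a, "hen_loss"))
                elif st == "M" and u < p_del:
                    lin.states[ai] = "A"
                    lin.inteins[ai] = None
                    events.append(Event(t_mid, lin.node.sim_label, a, "deletion"))
        # homing transfers between contemporaneous lineages
        if config.transfer_rate > 0:
            for rec in active:
                for ai, a in enumerate(alleles):
                    if rec.states[ai] != "A":
                        continue
                    for don in active:
                        if don is rec or don.states[ai] != "L":
                            continue
                        d = 2 * (t_mid - split_time(rec.node, don.node))
                        p = 1 - np.exp(-config.transfer_rate * dt
                                       * np.exp(-d / config.decay_lambda))
                        if rng.random() < p:
                            rec.states[ai] = "L"
                            rec.inteins[ai] = don.inteins[ai]
                            events.append(Event(t_mid, rec.node.sim_label, a,
                                                "transfer", donor=don.node.sim_label))
                            break
        # sequence evolution over the slice
        for lin in active:
            ext = exteins[lin.node]
            for a in alleles:
                ext[a] = _mutate(rng, ext[a], config.mu_extein, dt, ext_protected)
            for ai, a in enumerate(alleles):
                if lin.inteins[ai] is not None:
                    seq = lin.inteins[ai]
                    lin.inteins[ai] = _mutate(rng, seq, config.mu_intein, dt,
                                              protected_for(seq))

    # assemble truth at the leaves
    leaf_lins = {lin.node.taxon.label: lin for lin in lineages.values()
                 if lin.node.is_leaf()}
    genomes = sorted(leaf_lins)
    profile = AlleleProfile(genomes=genomes, alleles=list(alleles))
    proteins: dict[tuple[str, str], str] = {}
    coordinates: dict[tuple[str, str], tuple[int, int]] = {}
    mask = rng.random((len(genomes), len(alleles))) < config.missing_frac
    for gi, g in enumerate(genomes):
        lin = leaf_lins[g]
        ext = exteins[lin.node]
        for ai, a in enumerate(alleles):
            if mask[gi, ai]:
                profile.set(g, a, State.MISSING)
                continue
            st = lin.states[ai]
            if st == "A":
                profile.set(g, a, State.ABSENT)
                proteins[(g, a)] = ext[a]
            else:
                intein = lin.inteins[ai]
                profile.set(g, a, State.LARGE if st == "L" else State.MINI,
                            length=float(len(intein)))
                host = ext[a][:insert_pos] + intein + ext[a][insert_pos:]
                proteins[(g, a)] = host
                coordinates[(g, a)] = (insert_pos, insert_pos + len(intein))
    return SimulationTruth(tree=tree, profile=profile, events=events,
                           proteins=proteins, coordinates=coordinates,
                           reference_orthologs=ref_exteins,
                           seed_alignments=seed_alignments, config=config)


def run_simulation(config: SimulationConfig) -> SimulationTruth:
    """Convenience: simulate the tree then the homing process."""
    tree = simulate_tree(config.n_taxa, config.birth_rate, config.seed)
    return simulate_homing(tree, config)


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------

def emit_fixture(truth: SimulationTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write the simulated dataset as plain-text files.

    proteins.fasta (ids ``genome|allele``; missing cells omitted),
    reference_orthologs.fasta, seeds/<allele>.fasta, tree.nwk,
    truth_profile.tsv (genome, allele, state, start, end; 0-based
    half-open) and events.tsv.  Byte-stable for a given seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "seeds").mkdir(exist_ok=True)
    paths = {}

    recs = [FastaRecord(id=f"{g}|{a}", seq=seq)
            for (g, a), seq in sorted(truth.proteins.items())]
    paths["proteins"] = out / "proteins.fasta"
    write_fasta(recs, paths["proteins"])

    paths["orthologs"] = out / "reference_orthologs.fasta"
    write_fasta([FastaRecord(id=a, seq=s)
                 for a, s in sorted(truth.reference_orthologs.items())],
                paths["orthologs"])

    for a, rows in sorted(truth.seed_alignments.items()):
        write_fasta([FastaRecord(id=f"{a}_seed{i + 1}", seq=s)
                     for i, s in enumerate(rows)], out / "seeds" / f"{a}.fasta")
    paths["seeds"] = out / "seeds"

    paths["tree"] = out / "tree.nwk"
    write_newick(truth.tree, paths["tree"])

    rows = []
    for g in truth.profile.genomes:
        for a in truth.profile.alleles:
            st = truth.profile.state(g, a)
            start, end = truth.coordinates.get((g, a), ("", ""))
            rows.append(dict(genome=g, allele=a, state=st.code, start=start, end=end))
    paths["profile"] = out / "truth_profile.tsv"
    write_tsv(rows, paths["profile"], ["genome", "allele", "state", "start", "end"])

    ev_rows = [dict(time=f"{e.time:.6f}", branch=e.branch, allele=e.allele,
                    event=e.kind, donor=e.donor) for e in truth.events]
    paths["events"] = out / "events.tsv"
    write_tsv(ev_rows, paths["events"], ["time", "branch", "allele", "event", "donor"])
    return paths


def read_truth_profile(path: str | Path) -> AlleleProfile:
    """Reconstruct the AlleleProfile from an emitted truth TSV."""
    rows = read_tsv(path)
    genomes, alleles = [], []
    for r in rows:
        if r["genome"] not in genomes:
            genomes.append(r["genome"])
        if r["allele"] not in alleles:
            alleles.append(r["allele"])
    prof = AlleleProfile(genomes=genomes, alleles=alleles)
    for r in rows:
        st = State.from_code(r["state"])
        length = float(int(r["end"]) - int(r["start"])) if st.present else None
        prof.set(r["genome"], r["allele"], st, length=length)
    return prof
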