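"""Intein detection in host proteins.

Two complementary signals are combined: (1) window scanning with a
position-specific scoring matrix (PSSM) built from a seed alignment of
known inteins of the same allele, and (2) comparison against an
intein-free reference ortholog, which localises the inserted block
exactly.  Candidate insertions must add 100-700 aa to the host protein
(the size envelope characteristic of intein invasion) and must carry the
canonical splicing residues at their termini.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import AMINO_ACIDS

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class DetectionConfig:
    """min/max_added_len: size envelope (aa) an intein adds to its host;
    pssm_score_threshold: bits required of the best scan window;
    min_block_len: shortest host-only alignment run reported as a candidate
    insertion; require_pssm: whether hits must also pass the PSSM scan."""

    min_added_len: int = 100
    max_added_len: int = 700
    pssm_score_threshold: float = 10.0
    min_block_len: int = 30
    require_pssm: bool = True
    # splicing-motif rules; configurable because degenerate variants exist
    n_terminal_residues: frozenset = frozenset("CSA")
    c_terminal_pairs: frozenset = frozenset({"HN", "HQ"})
    c_terminal_residues: frozenset = frozenset("NQ")
    plus_one_residues: frozenset = frozenset("CST")

    def __post_init__(self):
        if not 0 < self.min_added_len < self.max_added_len:
            raise ValueError("require 0 < min_added_len < max_added_len")


@dataclass
class MotifReport:
    """Splicing-domain evidence at the three diagnostic positions.

    ``plus_one_ok`` is None when the +1 extein residue is unknown; the hit
    then passes provisionally if both termini check out.
    """

    n_terminal_ok: bool
    c_terminal_ok: bool
    plus_one_ok: bool | None

    @property
    def passed(self) -> bool:
        if not (self.n_terminal_ok and self.c_terminal_ok):
            return False
        return self.plus_one_ok is not False

    @property
    def provisional(self) -> bool:
        return self.passed and self.plus_one_ok is None


@dataclass
class InteinHit:
    """One detected intein insertion (coordinates 0-based half-open)."""

    genome_id: str
    allele_id: str
    host_gene: str
    insertion_start: int
    insertion_end: int
    intein_seq: str
    motif_report: MotifReport
    pssm_score: float | None = None
    host_length: int | None = None
    anchored: bool = True

    def __post_init__(self):
        if self.insertion_end - self.insertion_start != len(self.intein_seq):
            raise ValueError("coordinates inconsistent with intein sequence length")

    @property
    def length(self) -> int:
        return len(self.intein_seq)


# ---------------------------------------------------------------------------
# PSSM
# ---------------------------------------------------------------------------

@dataclass
class PSSM:
    """Log-odds scoring matrix over the 20 amino acids (bits).

    ``scores[i, j]`` is log2 of the pseudocount-smoothed column frequency
    of residue j at position i over its background frequency.
    """

    scores: np.ndarray  # (length, 20)
    background: np.ndarray  # (20,)
    pseudocount_weight: float
    dropped_columns: list[int] = field(default_factory=list)

    def __post_init__(self):
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("PSSM scores must be finite")
        if len(self.scores) < 1:
            raise ValueError("PSSM must have at least one position")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def score_window(self, seq: str, offset: int = 0) -> float:
        idx = [_AA_INDEX[c] for c in seq[offset:offset + self.length]]
        return float(self.scores[np.arange(self.length), idx].sum())

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[j] for j in self.scores.argmax(axis=1))


def uniform_background() -> np.ndarray:
    return np.full(20, 0.05)


def build_pssm(seed_alignment: Sequence[str], pseudocount_weight: float = 1.0,
               background: np.ndarray | None = None) -> PSSM:
    """Build a PSSM from >= 2 aligned intein sequences.

    Per-column residue frequencies are mixed with the background via
    background-proportional pseudocounts (weight 1.0 by default, which
    keeps every score finite even on tiny seed sets); score =
    log2(mixed / background).  Columns with > 50% gap are dropped and
    their original indices recorded.
    """
    if len(seed_alignment) < 2:
        raise ValueError("seed alignment needs at least 2 sequences")
    widths = {len(s) for s in seed_alignment}
    if len(widths) != 1:
        raise ValueError(f"ragged seed alignment: lengths {sorted(widths)}")
    width = widths.pop()
    if width == 0:
        raise ValueError("empty seed alignment")
    bg = uniform_background() if background is None else np.asarray(background, float)
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must sum to 1")
    rows = [s.upper() for s in seed_alignment]
    bad = set("".join(rows)) - set(AMINO_ACIDS) - {"-", "?", "X"}
    if bad:
        raise ValueError(f"unknown characters in seed alignment: {sorted(bad)}")

    kept_scores, dropped = [], []
    n = len(rows)
    for c in range(width):
        col = [r[c] for r in rows]
        gaps = sum(ch in "-?" for ch in col)
        if gaps > n / 2:
            dropped.append(c)
            continue
        counts = np.zeros(20)
        for ch in col:
            if ch in _AA_INDEX:
                counts[_AA_INDEX[ch]] += 1
            elif ch == "X":  # ambiguous: spread over background
                counts += bg
        n_eff = counts.sum()
        mixed = (counts + pseudocount_weight * bg) / (n_eff + pseudocount_weight)
        if pseudocount_weight == 0:
            with np.errstate(divide="ignore"):
                kept_scores.append(np.log2(mixed / bg))
        else:
            kept_scores.append(np.log2(mixed / bg))
    if not kept_scores:
        raise ValueError("all alignment columns were majority-gap")
    scores = np.vstack(kept_scores)
    scores[~np.isfinite(scores)] = -30.0  # floor for zero-probability cells
    return PSSM(scores=scores, background=bg,
                pseudocount_weight=pseudocount_weight, dropped_columns=dropped)


@dataclass
class ScanWindow:
    start: int
    end: int
    score: float


def scan(pssm: PSSM, protein: str, threshold: float) -> list[ScanWindow]:
    """All PSSM windows scoring at least ``threshold`` bits, overlap-merged.

    Overlapping windows are merged keeping the single best-scoring window
    per overlap cluster (ties broken toward the smaller start).  A protein
    shorter than the PSSM yields an empty result.
    """
    L = pssm.length
    n = len(protein)
    if n < L:
        return []
    idx = np.array([_AA_INDEX.get(c, -1) for c in protein])
    # score all offsets; unknown residues contribute the background-average score
    col_means = pssm.scores.mean(axis=1)
    totals = np.zeros(n - L + 1)
    for i in range(L):
        sub = idx[i:i + n - L + 1]
        vals = np.where(sub >= 0, pssm.scores[i, np.clip(sub, 0, 19)], col_means[i])
        totals += vals
    hits = [ScanWindow(o, o + L, float(totals[o]))
            for o in np.nonzero(totals >= threshold)[0]]
    # merge overlap clusters, keep best
    merged: list[ScanWindow] = []
    cluster: list[ScanWindow] = []
    for w in hits:
        if cluster and w.start < cluster[-1].end:
            cluster.append(w)
        else:
            if cluster:
                merged.append(max(cluster, key=lambda x: (x.score, -x.start)))
            cluster = [w]
    if cluster:
        merged.append(max(cluster, key=lambda x: (x.score, -x.start)))
    return merged


# ---------------------------------------------------------------------------
# Ortholog comparison
# ---------------------------------------------------------------------------

@dataclass
class InsertionBlock:
    start: int
    end: int
    anchored: bool = True

    @property
    def length(self) -> int:
        return self.end - self.start


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    return aligner


_FLANK = 10
_FLANK_MIN_IDENTITY = 0.5


_BRIDGE_MAX = 5


def extract_insertion(host: str, ortholog: str,
                      min_block_len: int = 30) -> list[InsertionBlock]:
    """Locate host-only blocks by global alignment against an intein-free ortholog.

    Affine-gap global alignment (BLOSUM62, open 11 / extend 1); maximal
    runs of host-only columns are reported in host coordinates.  Runs
    separated by a short matched segment (<= 5 residues — chance matches
    of inserted residues to the ortholog) are bridged into one block;
    blocks shorter than ``min_block_len`` are then discarded.  Each
    block's 10 flanking host residues per side must align to the ortholog
    at >= 50% identity, otherwise the block is flagged unanchored.
    """
    if not host or not ortholog:
        raise ValueError("both sequences must be non-empty")
    if host == ortholog:
        return []
    aln = _make_aligner().align(host, ortholog)[0]
    host_blocks, orth_blocks = aln.aligned
    # map host position -> ortholog position within matched segments
    pos_map: dict[int, int] = {}
    for (hs, he), (os_, _oe) in zip(host_blocks, orth_blocks):
        for k in range(he - hs):
            pos_map[hs + k] = os_ + k
    runs: list[list[int]] = []
    for i in range(len(host_blocks) - 1):
        h_gap_start, h_gap_end = host_blocks[i][1], host_blocks[i + 1][0]
        o_gap = orth_blocks[i + 1][0] - orth_blocks[i][1]
        if o_gap == 0 and h_gap_end > h_gap_start:
            runs.append([int(h_gap_start), int(h_gap_end)])
    merged_runs: list[list[int]] = []
    for run in runs:
        if merged_runs and run[0] - merged_runs[-1][1] <= _BRIDGE_MAX:
            merged_runs[-1][1] = run[1]
        else:
            merged_runs.append(run)
    blocks = [InsertionBlock(s, e) for s, e in merged_runs
              if e - s >= min_block_len]
    # leading/trailing host overhangs are not insertions at conserved
    # internal sites; they are ignored (they cannot be flank-anchored)
    for b in blocks:
        b.anchored = (_flank_identity(host, ortholog, pos_map,
                                      range(b.start - _FLANK, b.start))
                      >= _FLANK_MIN_IDENTITY
                      and _flank_identity(host, ortholog, pos_map,
                                          range(b.end, b.end + _FLANK))
                      >= _FLANK_MIN_IDENTITY)
    return blocks


def _flank_identity(host: str, ortholog: str, pos_map: dict[int, int],
                    host_positions) -> float:
    pairs = [(host[p], ortholog[pos_map[p]])
             for p in host_positions if 0 <= p < len(host) and p in pos_map]
    if not pairs:
        return 0.0
    return sum(a == b for a, b in pairs) / len(pairs)


def size_filter(block_length: int, config: DetectionConfig | None = None) -> bool:
    """Keep a candidate iff it adds between min_added_len and max_added_len aa."""
    config = config or DetectionConfig()
    if block_length < 0:
        raise ValueError("block length must be non-negative")
    return config.min_added_len <= block_length <= config.max_added_len


def verify_splicing_motifs(intein_seq: str, plus_one_residue: str | None = None,
                           config: DetectionConfig | None = None) -> MotifReport:
    """Check the canonical splicing residues of a candidate intein.

    N-terminal nucleophile C/S/A; C-terminal His-Asn/Gln dipeptide (HN/HQ)
    or terminal N/Q; +1 extein nucleophile C/S/T.  An unknown +1 residue
    leaves ``plus_one_ok`` indeterminate (None) and the overall verdict
    provisional when both termini pass.
    """
    config = config or DetectionConfig()
    if not intein_seq:
        raise ValueError("empty intein sequence")
    seq = intein_seq.upper()
    n_ok = seq[0] in config.n_terminal_residues
    c_ok = (seq[-2:] in config.c_terminal_pairs) or (seq[-1] in config.c_terminal_residues)
    plus: bool | None
    if plus_one_residue is None or plus_one_residue in ("", "?", "X"):
        plus = None
    else:
        plus = plus_one_residue.upper() in config.plus_one_residues
    return MotifReport(n_terminal_ok=n_ok, c_terminal_ok=c_ok, plus_one_ok=plus)


def refine_termini(host: str, start: int, end: int,
                   config: DetectionConfig | None = None,
                   max_shift: int = 3) -> tuple[int, int]:
    """Nudge block boundaries onto the canonical splice junction.

    Alignment-derived boundaries can be off by a residue or two when
    inserted residues happen to match the ortholog near a junction.  The
    true junction is marked by the splicing motifs, so boundaries are
    shifted (by at most ``max_shift``) to the offsets satisfying the most
    motif criteria, preferring the smallest total shift.
    """
    config = config or DetectionConfig()
    best = (start, end)
    best_key = (-1, 0)
    for ds in range(-max_shift, max_shift + 1):
        for de in range(-max_shift, max_shift + 1):
            s, e = start + ds, end + de
            if s < 0 or e > len(host) or e - s < 2:
                continue
            rep = verify_splicing_motifs(
                host[s:e], host[e] if e < len(host) else None, config)
            n_ok = (int(rep.n_terminal_ok) + int(rep.c_terminal_ok)
                    + int(rep.plus_one_ok is True))
            key = (n_ok, -(abs(ds) + abs(de)))
            if key > best_key:
                best_key, best = key, (s, e)
    return best


# ---------------------------------------------------------------------------
# Detection pipeline and iterative refinement
# ---------------------------------------------------------------------------

def detect_inteins(proteins: Mapping[tuple[str, str], str],
                   orthologs: Mapping[str, str],
                   seeds: Mapping[str, Sequence[str]],
                   config: DetectionConfig | None = None) -> list[InteinHit]:
    """One detection pass over a corpus of host proteins.

    ``proteins`` maps (genome_id, allele_id) -> host protein sequence;
    ``orthologs`` maps allele_id -> intein-free reference sequence;
    ``seeds`` maps allele_id -> seed alignment rows.  A hit requires an
    anchored host-only block inside the size envelope, passing (at least
    provisionally) the splicing-motif check, and — when ``require_pssm``
    — a PSSM scan window at or above threshold overlapping the block.
    """
    config = config or DetectionConfig()
    pssms = {a: _confirmation_pssms(rows)
             for a, rows in seeds.items() if len(rows) >= 2}
    hits: list[InteinHit] = []
    for (genome, allele) in sorted(proteins):
        host = proteins[(genome, allele)]
        ortholog = orthologs.get(allele)
        if ortholog is None:
            continue
        for block in extract_insertion(host, ortholog, config.min_block_len):
            if not block.anchored:
                continue
            start, end = refine_termini(host, block.start, block.end, config)
            if not size_filter(end - start, config):
                continue
            intein = host[start:end]
            plus_one = host[end] if end < len(host) else None
            report = verify_splicing_motifs(intein, plus_one, config)
            if not report.passed:
                continue
            score = None
            for pssm in pssms.get(allele, []):
                windows = scan(pssm, host, config.pssm_score_threshold)
                overlapping = [w for w in windows
                               if w.start < end and start < w.end]
                if overlapping:
                    best = max(w.score for w in overlapping)
                    score = best if score is None else max(score, best)
            if score is None and config.require_pssm and pssms.get(allele):
                continue
            hits.append(InteinHit(
                genome_id=genome, allele_id=allele, host_gene=allele,
                insertion_start=start, insertion_end=end,
                intein_seq=intein, motif_report=report, pssm_score=score,
                host_length=len(host), anchored=block.anchored))
    return hits


_SUB_PSSM_N, _SUB_PSSM_C = 100, 50


def _confirmation_pssms(rows: Sequence[str]) -> list[PSSM]:
    """Full-length PSSM plus N-/C-terminal splicing-region sub-PSSMs.

    Mini-inteins have lost the homing-endonuclease domain, so a
    full-length matrix built from canonical seeds cannot align to them in
    one window; the terminal splicing regions, which every intein
    retains, are scanned separately.
    """
    full = build_pssm(rows)
    out = [full]
    if full.length >= _SUB_PSSM_N + _SUB_PSSM_C:
        for sub_scores in (full.scores[:_SUB_PSSM_N], full.scores[-_SUB_PSSM_C:]):
            out.append(PSSM(scores=sub_scores, background=full.background,
                            pseudocount_weight=full.pseudocount_weight))
    return out


def align_to_profile(seq: str, alignment: Sequence[str]) -> str:
    """Insert a sequence into an existing alignment's column frame.

    The sequence is pairwise-aligned to the alignment's majority-residue
    consensus; residues matched to consensus columns are placed there,
    insertions relative to the profile are discarded, and unmatched
    columns become gaps.  The alignment width is preserved.
    """
    width = len(alignment[0])
    cols = list(zip(*[s.upper() for s in alignment]))
    consensus = []
    for col in cols:
        residues = [c for c in col if c in _AA_INDEX]
        consensus.append(max(set(residues), key=residues.count) if residues else "A")
    consensus = "".join(consensus)
    aln = _make_aligner().align(seq, consensus)[0]
    seq_blocks, cons_blocks = aln.aligned
    out = ["-"] * width
    for (ss, se), (cs, _ce) in zip(seq_blocks, cons_blocks):
        for k in range(se - ss):
            out[cs + k] = seq[ss + k]
    return "".join(out)


@dataclass
class IterationResult:
    hits: list[InteinHit]
    seeds: dict[str, list[str]]
    rounds: int
    converged: bool


def iterate_detection(proteins: Mapping[tuple[str, str], str],
                      seeds: Mapping[str, Sequence[str]],
                      orthologs: Mapping[str, str],
                      config: DetectionConfig | None = None,
                      max_rounds: int = 3) -> IterationResult:
    """Iterative detection with seed enrichment.

    After each round, passing intein sequences are folded into the
    per-allele seed alignments (profile insertion), PSSMs are rebuilt and
    the corpus rescanned; stops at a fixed point (identical hit set) or
    after ``max_rounds`` rounds, in which case ``converged`` is False.
    """
    if not seeds:
        raise ValueError("at least one seed alignment is required")
    config = config or DetectionConfig()
    cur_seeds = {a: list(rows) for a, rows in seeds.items()}
    prev_keys: set | None = None
    hits: list[InteinHit] = []
    for rnd in range(1, max_rounds + 1):
        hits = detect_inteins(proteins, orthologs, cur_seeds, config)
        keys = {(h.genome_id, h.allele_id, h.insertion_start, h.insertion_end)
                for h in hits}
        if keys == prev_keys:
            return IterationResult(hits, cur_seeds, rounds=rnd, converged=True)
        prev_keys = keys
        cur_seeds = {a: list(rows) for a, rows in seeds.items()}
        for h in hits:
            if h.allele_id in cur_seeds:
                cur_seeds[h.allele_id].append(
                    align_to_profile(h.intein_seq, cur_seeds[h.allele_id]))
    return IterationResult(hits, cur_seeds, rounds=max_rounds, converged=False)
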