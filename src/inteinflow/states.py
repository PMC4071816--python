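"""Symbiotic state assignment: mini vs large inteins, and the genome x allele profile.

An intein allele is a specific insertion position in a specific host gene.
Within one allele, intein length separates the canonical two-domain form
(splicing domains + homing endonuclease, "large") from the degenerate
splicing-only form ("mini").  The classifier looks for a gap of at least
``gap_cutoff`` (default 100 aa) in the sorted length distribution and cuts
at the gap midpoint; alleles without such a gap are assigned a single state
by comparing the median length with ``fallback_floor``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


class State(enum.Enum):
    ABSENT = "A"
    MINI = "M"
    LARGE = "L"
    MISSING = "?"

    @property
    def code(self) -> str:
        return self.value

    @classmethod
    def from_code(cls, code: str) -> "State":
        for s in cls:
            if s.value == code:
                return s
        raise ValueError(f"unknown state code {code!r}")

    @property
    def present(self) -> bool:
        return self in (State.MINI, State.LARGE)


@dataclass
class StateConfig:
    """Parameters of the length-gap state classifier.

    gap_cutoff: minimum within-allele length gap (aa) that separates mini
        from large inteins.
    fallback_floor: when no qualifying gap exists, the whole allele is
        called LARGE if its median length is at least this many aa,
        otherwise MINI.
    hen_overlap_min: minimum fraction of a mini-intein's alignment gap
        columns that must fall inside the homing-endonuclease region for
        the mini call to verify.
    """

    gap_cutoff: float = 100.0
    fallback_floor: float = 300.0
    hen_overlap_min: float = 0.8

    def __post_init__(self):
        if self.gap_cutoff <= 0 or self.fallback_floor <= 0:
            raise ValueError("gap_cutoff and fallback_floor must be positive")
        if not 0 <= self.hen_overlap_min <= 1:
            raise ValueError("hen_overlap_min must lie in [0, 1]")


def assign_states(lengths: Mapping[str, float],
                  config: StateConfig | None = None) -> dict[str, State]:
    """Assign MINI/LARGE to every member of one allele from intein lengths.

    Sorts the unique lengths, finds the largest adjacent gap (ties broken
    toward the gap at the smaller length, which favors fewer mini calls),
    and thresholds at the gap midpoint when the gap reaches ``gap_cutoff``.
    Otherwise every member receives a single state decided by the median
    length against ``fallback_floor``.  The result is invariant under input
    ordering and under duplicated lengths.
    """
    config = config or StateConfig()
    if not lengths:
        raise ValueError("assign_states requires at least one length")
    for k, v in lengths.items():
        if v <= 0:
            raise ValueError(f"non-positive intein length for {k!r}: {v}")
    uniq = sorted(set(lengths.values()))
    threshold = None
    if len(uniq) > 1:
        gaps = [(uniq[i + 1] - uniq[i], i) for i in range(len(uniq) - 1)]
        best_gap, best_i = max(gaps, key=lambda t: (t[0], -t[1]))
        if best_gap >= config.gap_cutoff:
            threshold = (uniq[best_i] + uniq[best_i + 1]) / 2.0
    if threshold is not None:
        return {k: (State.MINI if v < threshold else State.LARGE)
                for k, v in lengths.items()}
    median = float(pd.Series(sorted(lengths.values())).median())
    state = State.LARGE if median >= config.fallback_floor else State.MINI
    return {k: state for k in lengths}


def is_low_confidence(lengths: Mapping[str, float],
                      config: StateConfig | None = None) -> bool:
    """True when the allele has no usable length distribution.

    Alleles observed in a single genome (one length) cannot exhibit a
    length gap; their state call falls back to the floor rule and should be
    treated as provisional.
    """
    config = config or StateConfig()
    uniq = sorted(set(lengths.values()))
    if len(uniq) < 2:
        return True
    return max(b - a for a, b in zip(uniq, uniq[1:])) < config.gap_cutoff


# ---------------------------------------------------------------------------
# HEN-gap verification
# ---------------------------------------------------------------------------

def estimate_hen_region(alignment: Mapping[str, str], mini_ids: Iterable[str],
                        large_ids: Iterable[str]) -> tuple[int, int]:
    """Estimate the HEN-domain column interval of an allele alignment.

    Returns the maximal contiguous column run where at least 80% of large
    rows carry a residue and at least 80% of mini rows are gapped — the
    signature of a deleted endonuclease domain.
    """
    mini_ids, large_ids = list(mini_ids), list(large_ids)
    if not mini_ids or not large_ids:
        raise ValueError("need both mini and large rows to estimate the HEN region")
    width = len(next(iter(alignment.values())))
    ok = []
    for c in range(width):
        large_res = sum(alignment[i][c] != "-" for i in large_ids) / len(large_ids)
        mini_gap = sum(alignment[i][c] == "-" for i in mini_ids) / len(mini_ids)
        ok.append(large_res >= 0.8 and mini_gap >= 0.8)
    best, cur_start, best_span = (0, 0), None, 0
    for c, flag in enumerate(ok + [False]):
        if flag and cur_start is None:
            cur_start = c
        elif not flag and cur_start is not None:
            if c - cur_start > best_span:
                best_span, best = c - cur_start, (cur_start, c)
            cur_start = None
    if best_span == 0:
        raise ValueError("no candidate HEN region found in alignment")
    return best


def verify_hen_gap(alignment: Mapping[str, str], mini_ids: Iterable[str],
                   hen_region: tuple[int, int] | None = None,
                   large_ids: Iterable[str] | None = None,
                   config: StateConfig | None = None) -> dict[str, bool]:
    """Check that each mini-intein's alignment gaps sit in the HEN region.

    For every mini row, computes the fraction of its gap columns that fall
    inside ``hen_region`` (estimated from the alignment when not supplied)
    and returns True when that fraction reaches ``hen_overlap_min``.
    """
    config = config or StateConfig()
    mini_ids = list(mini_ids)
    unknown = [m for m in mini_ids if m not in alignment]
    if unknown:
        raise ValueError(f"unknown mini id(s): {unknown}")
    if hen_region is None:
        if large_ids is None:
            large_ids = [k for k in alignment if k not in set(mini_ids)]
        hen_region = estimate_hen_region(alignment, mini_ids, large_ids)
    lo, hi = hen_region
    out = {}
    for m in mini_ids:
        row = alignment[m]
        gap_cols = [c for c, ch in enumerate(row) if ch == "-"]
        if not gap_cols:
            out[m] = False
            continue
        inside = sum(lo <= c < hi for c in gap_cols)
        out[m] = inside / len(gap_cols) >= config.hen_overlap_min
    return out


# ---------------------------------------------------------------------------
# AlleleProfile
# ---------------------------------------------------------------------------

@dataclass
class AlleleProfile:
    """Genome x allele matrix over {ABSENT, MINI, LARGE, MISSING}.

    Present cells (mini/large) carry an intein length; absent/missing cells
    carry none.  ``low_confidence`` lists alleles whose mini/large call
    rests on the fallback rule rather than an observed length gap.
    """

    genomes: list[str]
    alleles: list[str]
    _states: dict[tuple[str, str], State] = field(default_factory=dict)
    _lengths: dict[tuple[str, str], float] = field(default_factory=dict)
    low_confidence: set[str] = field(default_factory=set)

    def __post_init__(self):
        if len(set(self.genomes)) != len(self.genomes):
            raise ValueError("duplicate genome ids")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError("duplicate allele ids")

    def state(self, genome: str, allele: str) -> State:
        return self._states.get((genome, allele), State.MISSING)

    def length(self, genome: str, allele: str) -> float | None:
        return self._lengths.get((genome, allele))

    def set(self, genome: str, allele: str, state: State,
            length: float | None = None) -> None:
        if state.present and length is None:
            raise ValueError(f"{state.name} cell ({genome},{allele}) requires a length")
        if not state.present and length is not None:
            raise ValueError(f"{state.name} cell ({genome},{allele}) must not carry a length")
        self._states[(genome, allele)] = state
        if length is not None:
            self._lengths[(genome, allele)] = length
        else:
            self._lengths.pop((genome, allele), None)

    def presence_character(self, allele: str) -> dict[str, int]:
        """Binary presence map for one allele; MISSING genomes are dropped."""
        out = {}
        for g in self.genomes:
            s = self.state(g, allele)
            if s is State.MISSING:
                continue
            out[g] = 1 if s.present else 0
        return out

    def carried_alleles(self, genome: str) -> set[str]:
        return {a for a in self.alleles if self.state(genome, a).present}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.state(g, a).code for a in self.alleles] for g in self.genomes],
            index=self.genomes, columns=self.alleles,
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "genome"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlleleProfile":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
        prof = cls(genomes=list(df.index), alleles=list(df.columns))
        for g in prof.genomes:
            for a in prof.alleles:
                s = State.from_code(df.loc[g, a])
                # lengths are not stored in the state TSV; use a nominal
                # placeholder so present cells stay valid
                prof.set(g, a, s, length=1.0 if s.present else None)
        return prof

    def __eq__(self, other) -> bool:
        if not isinstance(other, AlleleProfile):
            return NotImplemented
        return (self.genomes == other.genomes and self.alleles == other.alleles
                and all(self.state(g, a) == other.state(g, a)
                        for g in self.genomes for a in self.alleles))


def merge_states(hits: Sequence, assignments: Mapping[str, Mapping[str, State]],
                 genomes: Sequence[str], alleles: Sequence[str],
                 ortholog_present: Mapping[tuple[str, str], bool],
                 config: StateConfig | None = None) -> AlleleProfile:
    """Combine detection hits and state assignments into an AlleleProfile.

    For each cell: the assigned MINI/LARGE state when a hit exists; ABSENT
    when the orthologous host gene is present without an insertion; MISSING
    when the host gene was not found.  Hits whose insertion abuts a
    sequence end are incomplete — their length is untrustworthy, so the
    cell is demoted to MISSING.  Duplicate hits for one cell are an error.
    """
    seen: dict[tuple[str, str], object] = {}
    dups = []
    for h in hits:
        key = (h.genome_id, h.allele_id)
        if key in seen:
            dups.append(key)
        seen[key] = h
    if dups:
        raise ValueError(f"conflicting duplicate hits for cells: {sorted(set(dups))}")

    prof = AlleleProfile(genomes=list(genomes), alleles=list(alleles))
    for (g, a), h in seen.items():
        if g not in prof.genomes or a not in prof.alleles:
            raise ValueError(f"hit ({g},{a}) outside declared genome/allele universe")
        truncated = h.insertion_start == 0 or (
            h.host_length is not None and h.insertion_end >= h.host_length
        )
        if truncated:
            prof.set(g, a, State.MISSING)
        else:
            state = assignments[a][g]
            prof.set(g, a, state, length=float(h.length))
    for g in prof.genomes:
        for a in prof.alleles:
            if (g, a) in seen:
                continue
            if ortholog_present.get((g, a), False):
                prof.set(g, a, State.ABSENT)
            else:
                prof.set(g, a, State.MISSING)
    return prof
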