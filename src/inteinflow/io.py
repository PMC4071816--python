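"""File formats: FASTA, newick, TSV tables, and the mixed-datatype NEXUS exporter.

All readers validate structure and raise :class:`ParseError` (with a line
number where available) rather than silently coercing malformed input.  All
writers are deterministic given identical inputs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("inteinflow")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = set(AMINO_ACIDS) | {"-", "?", "X", "*"}


class ParseError(ValueError):
    """Structurally invalid input file."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class FastaRecord:
    id: str
    seq: str
    description: str = ""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read a protein FASTA file.

    Residues are normalised to uppercase (with a log notice when lowercase
    input is encountered); ids and descriptions round-trip losslessly.
    An empty file yields an empty list.
    """
    path = Path(path)
    _validate_fasta_structure(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            log.info("read_fasta: lowercase residues in %r normalised to uppercase", rec.id)
            seq = seq.upper()
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(FastaRecord(id=rec.id, seq=seq, description=desc))
    return records


def _validate_fasta_structure(path: Path) -> None:
    with open(path) as fh:
        in_record = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                in_record = True
                continue
            if not in_record:
                raise ParseError("sequence data before first '>' header", line=lineno)
            bad = set(line.strip().upper()) - _VALID_RESIDUES
            if bad:
                raise ParseError(
                    f"invalid residue(s) {sorted(bad)} in sequence", line=lineno
                )


def write_fasta(records: Sequence[FastaRecord], path: str | Path) -> None:
    """Write records wrapped at 60 columns."""
    seqrecords = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqrecords, fh, "fasta")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single-tree newick file.

    Internal node labels are interpreted as bootstrap support values where
    numeric.  Unbalanced parentheses and similar structural faults raise
    :class:`ParseError`.
    """
    text = Path(path).read_text()
    return parse_newick(text)


def parse_newick(text: str) -> dendropy.Tree:
    if text.count("(") != text.count(")"):
        raise ParseError("unbalanced parentheses in newick string")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"newick parse failure: {exc}") from exc
    return tree


def _format_length(x: float) -> str:
    # shortest representation exact to 6 decimals: "1" not "1.000000"
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s else "0"


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Serialise a tree to a canonical one-line newick string.

    Branch lengths are written to at most 6 decimals with trailing zeros
    stripped, so integer-length input like ``((A:1,B:1)90:1,C:2);``
    round-trips byte-identically.
    """

    def render(node) -> str:
        if node.is_leaf():
            label = node.taxon.label if node.taxon else (node.label or "")
            label = label.replace(" ", "_")
            out = label
        else:
            out = "(" + ",".join(render(c) for c in node.child_nodes()) + ")"
            if node.label is not None:
                out += str(node.label)
        if node.edge.length is not None and node.parent_node is not None:
            out += ":" + _format_length(node.edge.length)
        return out

    return render(tree.seed_node) + ";"


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Mixed-datatype NEXUS export (presence-absence partition + per-allele
# protein alignments) for Bayesian clustering.
# ---------------------------------------------------------------------------

@dataclass
class MixedMatrix:
    """Concatenated binary presence-absence + per-allele protein partitions.

    ``binary`` maps genome -> string over {0,1,?}, one column per allele;
    ``blocks`` maps allele -> genome -> aligned protein string (padded with
    '?' for genomes absent from that allele's alignment).  ``charsets`` are
    1-based inclusive column ranges tiling the matrix.
    """

    genomes: list[str]
    alleles: list[str]
    binary: dict[str, str]
    blocks: dict[str, dict[str, str]]
    charsets: dict[str, tuple[int, int]] = field(default_factory=dict)

    def row(self, genome: str) -> str:
        return self.binary[genome] + "".join(
            self.blocks[a][genome] for a in self.alleles
        )

    @property
    def nchar(self) -> int:
        return len(self.row(self.genomes[0]))


def build_mixed_matrix(profile, alignments: Mapping[str, Mapping[str, str]]) -> MixedMatrix:
    """Assemble the mixed matrix from an AlleleProfile and per-allele alignments.

    Binary column per allele: 1 if the genome carries the intein (mini or
    large), 0 if the orthologous site is intein-free, '?' if missing data.
    Genomes absent from an allele's alignment are padded with '?'.
    """
    genomes = list(profile.genomes)
    alleles = list(profile.alleles)
    code = {"L": "1", "M": "1", "A": "0", "?": "?"}
    binary = {
        g: "".join(code[profile.state(g, a).code] for a in alleles) for g in genomes
    }
    blocks: dict[str, dict[str, str]] = {}
    charsets: dict[str, tuple[int, int]] = {"presence_absence": (1, len(alleles))}
    pos = len(alleles)
    for a in alleles:
        aln = dict(alignments.get(a, {}))
        widths = {len(s) for s in aln.values()}
        if len(widths) > 1:
            raise ValueError(f"allele {a!r}: ragged alignment row lengths {sorted(widths)}")
        width = widths.pop() if widths else 0
        unknown = set(aln) - set(genomes)
        if unknown:
            raise ValueError(f"allele {a!r}: alignment rows not in profile: {sorted(unknown)}")
        blocks[a] = {g: aln.get(g, "?" * width) for g in genomes}
        charsets[a] = (pos + 1, pos + width)
        pos += width
    return MixedMatrix(genomes=genomes, alleles=alleles, binary=binary,
                       blocks=blocks, charsets=charsets)


_MRBAYES_BLOCK = """\
begin mrbayes;
    charset presence_absence = 1-{n_bin};
{charset_lines}
    partition by_allele = {n_parts}: presence_absence{part_names};
    set partition = by_allele;
    lset applyto=(1) coding=variable nbetacat=5;
    prset applyto=(1) symdirihyperpr=exponential(1.0) ratepr=variable;
    lset applyto=({protein_parts}) rates=invgamma;
    prset applyto=({protein_parts}) aamodelpr=fixed(wag) statefreqpr=empirical;
    [ mcmc ngen=<unset> samplefreq=<unset>; run length left to the operator ]
end;
"""


def export_mixed_nexus(profile, alignments: Mapping[str, Mapping[str, str]],
                       path: str | Path) -> MixedMatrix:
    """Write the mixed presence-absence + protein NEXUS file.

    The data block uses ``datatype=mixed(standard:...,protein:...)``; the
    trailing command block encodes the clustering priors (variable coding
    with 5 beta categories and a symmetric Dirichlet/exponential(1.0)
    hyperprior on the binary partition; fixed WAG with empirical state
    frequencies and invgamma rates on the protein partitions).  MCMC run
    length is deliberately left unset.
    """
    mm = build_mixed_matrix(profile, alignments)
    n_bin = len(mm.alleles)
    nchar = mm.nchar
    name_w = max(len(g) for g in mm.genomes) + 2
    lines = ["#NEXUS", "", "begin data;",
             f"    dimensions ntax={len(mm.genomes)} nchar={nchar};",
             f"    format datatype=mixed(standard:1-{n_bin},protein:{n_bin + 1}-{nchar})"
             " gap=- missing=?;",
             "    matrix"]
    for g in mm.genomes:
        lines.append(f"    {g:<{name_w}}{mm.row(g)}")
    lines += ["    ;", "end;", ""]
    charset_lines = "\n".join(
        f"    charset {a} = {mm.charsets[a][0]}-{mm.charsets[a][1]};"
        for a in mm.alleles
    )
    part_names = "".join(", " + a for a in mm.alleles)
    protein_parts = ",".join(str(i + 2) for i in range(len(mm.alleles)))
    lines.append(_MRBAYES_BLOCK.format(
        n_bin=n_bin, charset_lines=charset_lines,
        n_parts=len(mm.alleles) + 1, part_names=part_names,
        protein_parts=protein_parts))
    Path(path).write_text("\n".join(lines))
    return mm


def read_mixed_nexus(path: str | Path) -> MixedMatrix:
    """Re-parse a file written by :func:`export_mixed_nexus` (round-trip check)."""
    text = Path(path).read_text()
    m = re.search(r"format datatype=mixed\(standard:1-(\d+),protein:\d+-(\d+)\)", text)
    if not m:
        raise ParseError("missing mixed-datatype format line")
    n_bin = int(m.group(1))
    matrix_m = re.search(r"matrix\n(.*?)\n\s*;", text, re.S)
    if not matrix_m:
        raise ParseError("missing matrix block")
    rows: dict[str, str] = {}
    genomes: list[str] = []
    for line in matrix_m.group(1).splitlines():
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"malformed matrix row: {line!r}")
        rows[parts[0]] = parts[1]
        genomes.append(parts[0])
    charsets: dict[str, tuple[int, int]] = {}
    for name, a, b in re.findall(r"charset (\S+) = (\d+)-(\d+);", text):
        charsets[name] = (int(a), int(b))
    alleles = [n for n in charsets if n != "presence_absence"]
    binary = {g: rows[g][:n_bin] for g in genomes}
    blocks = {
        a: {g: rows[g][charsets[a][0] - 1: charsets[a][1]] for g in genomes}
        for a in alleles
    }
    return MixedMatrix(genomes=genomes, alleles=alleles, binary=binary,
                       blocks=blocks, charsets=charsets)


# ---------------------------------------------------------------------------
# TSV helpers (plain, dependency-light; pandas is used at the analysis layer)
# ---------------------------------------------------------------------------

def write_tsv(rows: Sequence[Mapping[str, object]], path: str | Path,
              columns: Sequence[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in columns) + "\n")


def read_tsv(path: str | Path) -> list[dict[str, str]]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return []
    header = lines[0].split("\t")
    out = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise ParseError(
                f"expected {len(header)} columns, got {len(parts)}", line=lineno
            )
        out.append(dict(zip(header, parts)))
    return out
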