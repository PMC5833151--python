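"""Readers and writers for FASTA/GenBank sequences, CLUSTAL/FASTA/PHYLIP
alignments, and Newick trees, over files or standard streams.

All readers accept a file path, ``"-"`` or ``None`` (standard input), or any
object with a ``read()`` method. Residues are normalized to upper case on
read; record ids are kept verbatim. Readers never reorder records.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .tree_ops import PhyloTree, TreeNode

GAP = "-"
FASTA_WRAP = 60

NUC_CHARS = frozenset("ACGTURYSWKMBDHVN")
PROT_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO*")

_ALN_FORMATS = {"clustalw": "clustal", "fasta": "fasta", "phylip": "phylip-relaxed"}


class FormatError(ValueError):
    """Malformed input or unsupported format token."""


def guess_alphabet(residues: str) -> str:
    chars = set(residues.upper()) - {GAP}
    if not chars:
        return "dna"
    if chars <= NUC_CHARS:
        return "rna" if "U" in chars else "dna"
    if chars <= PROT_CHARS:
        return "protein"
    raise FormatError(f"residues outside IUPAC alphabets: "
                      f"{''.join(sorted(chars - (NUC_CHARS | PROT_CHARS)))!r}")


@dataclass
class SeqRecord:
    """One named molecular sequence (nucleotide or protein)."""

    id: str
    residues: str
    description: str = ""
    alphabet: str = "auto"

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid sequence id: {self.id!r}")
        self.residues = self.residues.upper()
        if self.alphabet == "auto":
            self.alphabet = guess_alphabet(self.residues)
        else:
            guess_alphabet(self.residues)  # validate characters

    def __len__(self):
        return len(self.residues)

    @property
    def is_nucleotide(self) -> bool:
        return self.alphabet in ("dna", "rna")


@dataclass
class Alignment:
    """Ordered set of equal-length gapped SeqRecords."""

    members: list = field(default_factory=list)

    def __post_init__(self):
        if self.members:
            ref = len(self.members[0])
            bad = next((m for m in self.members[1:] if len(m) != ref), None)
            if bad is not None:
                raise FormatError(
                    f"ragged alignment: member {bad.id!r} has length "
                    f"{len(bad)}, expected {ref}")
        ids = [m.id for m in self.members]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise FormatError("duplicate ids: " + ", ".join(sorted(dupes)))

    @property
    def length(self) -> int:
        return len(self.members[0]) if self.members else 0

    @property
    def nseq(self) -> int:
        return len(self.members)

    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    def column(self, j: int) -> str:
        return "".join(m.residues[j] for m in self.members)

    def columns(self):
        for j in range(self.length):
            yield self.column(j)

    def from_columns(self, cols: list[str]) -> "Alignment":
        """New alignment with the same members but the given columns."""
        rows = ["".join(col[i] for col in cols) for i in range(self.nseq)]
        return Alignment([
            SeqRecord(m.id, row, m.description, alphabet="auto")
            for m, row in zip(self.members, rows)
        ])


def _as_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    if source is None or source == "-":
        return sys.stdin.read()
    return Path(source).read_text()


# ---------------------------------------------------------------------------
# sequences


def read_seqs(source, format: str = "fasta") -> list[SeqRecord]:
    """Parse sequence records; FASTA headers split at the first whitespace,
    GenBank LOCUS names become ids. Empty input yields an empty list."""
    text = _as_text(source)
    if format == "fasta":
        return _read_fasta(text)
    if format == "genbank":
        try:
            parsed = list(SeqIO.parse(StringIO(text), "genbank"))
        except ValueError as exc:
            raise FormatError(f"malformed GenBank input: {exc}") from exc
        return [
            SeqRecord(rec.name, str(rec.seq), rec.description)
            for rec in parsed
        ]
    raise FormatError(f"unknown sequence format {format!r}; "
                      f"supported: fasta, genbank")


def _read_fasta(text: str) -> list[SeqRecord]:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FormatError(
                f"malformed FASTA at line {lineno}: expected '>' header")
        break
    records = []
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SeqRecord(rec.id, str(rec.seq), desc))
    return records


def write_seqs(records: list, wrap: int = FASTA_WRAP) -> str:
    """FASTA text; description omitted when empty, wrapped at ``wrap``."""
    out = []
    for rec in records:
        header = f">{rec.id} {rec.description}" if rec.description else f">{rec.id}"
        out.append(header)
        for i in range(0, len(rec.residues), wrap):
            out.append(rec.residues[i:i + wrap])
    return "\n".join(out) + "\n" if out else ""


# ---------------------------------------------------------------------------
# alignments


def read_alignment(source, format: str = "clustalw") -> Alignment:
    if format not in _ALN_FORMATS:
        raise FormatError(f"unknown alignment format {format!r}; "
                          f"supported: {', '.join(sorted(_ALN_FORMATS))}")
    text = _as_text(source)
    if format == "fasta":
        records = _read_fasta(text)
        return Alignment(records)
    try:
        aln = AlignIO.read(StringIO(text), _ALN_FORMATS[format])
    except ValueError as exc:
        raise FormatError(f"malformed {format} alignment: {exc}") from exc
    return Alignment([SeqRecord(r.id, str(r.seq)) for r in aln])


def write_alignment(aln: Alignment, format: str = "clustalw") -> str:
    if format not in _ALN_FORMATS:
        raise FormatError(f"unknown alignment format {format!r}; "
                          f"supported: {', '.join(sorted(_ALN_FORMATS))}")
    if format == "fasta":
        return write_seqs(aln.members)
    bio = MultipleSeqAlignment([
        _BioSeqRecord(Seq(m.residues), id=m.id, description="")
        for m in aln.members
    ])
    buf = StringIO()
    AlignIO.write(bio, buf, _ALN_FORMATS[format])
    return buf.getvalue()


# ---------------------------------------------------------------------------
# trees


class NewickError(FormatError):
    """Malformed Newick input, reported with a character offset."""


def parse_newick(text: str) -> PhyloTree:
    s = text.strip()
    if not s:
        raise NewickError("empty tree input")
    i = 0
    n = len(s)

    def parse_clade() -> TreeNode:
        nonlocal i
        node = TreeNode()
        if i < n and s[i] == "(":
            open_at = i
            i += 1
            while True:
                node.add_child(parse_clade())
                if i >= n:
                    raise NewickError(
                        f"unbalanced parentheses at character {open_at}")
                if s[i] == ",":
                    i += 1
                elif s[i] == ")":
                    i += 1
                    break
                else:
                    raise NewickError(
                        f"unexpected {s[i]!r} at character {i}")
        start = i
        while i < n and s[i] not in ",():;":
            i += 1
        label = s[start:i].strip()
        if label:
            node.label = label
        if i < n and s[i] == ":":
            i += 1
            start = i
            while i < n and s[i] not in ",():;":
                i += 1
            token = s[start:i].strip()
            try:
                node.length = float(token)
            except ValueError:
                raise NewickError(
                    f"invalid branch length {token!r} at character {start}")
            node.has_length = True
        return node

    root = parse_clade()
    if i < n and s[i] == ")":
        raise NewickError(f"unbalanced parentheses at character {i}")
    if i >= n or s[i] != ";":
        raise NewickError(f"expected ';' at character {i}")
    missing = [c for c in _walk(root) if c is not root and not c.has_length]
    if missing:
        print(f"newick: {len(missing)} edge(s) without length, read as 0",
              file=sys.stderr)
    return PhyloTree(root)


def _walk(node: TreeNode):
    yield node
    for child in node.children:
        yield from _walk(child)


def read_tree(source) -> PhyloTree:
    return parse_newick(_as_text(source))


def _fmt_length(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


def write_tree(tree: PhyloTree) -> str:
    def fmt(node: TreeNode, is_root: bool) -> str:
        if node.children:
            s = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
            s += node.label or ""
        else:
            s = node.label or ""
        if not is_root or node.has_length:
            s += ":" + _fmt_length(node.length)
        return s

    return fmt(tree.root, True) + ";\n"
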