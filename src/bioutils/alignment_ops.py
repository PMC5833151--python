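"""Alignment-level operations: summaries, slicing, member pick/delete,
concatenation, codon back-translation, bootstrap, and site permutations.
"""

from __future__ import annotations

import random
import sys
from dataclasses import dataclass
from itertools import combinations

from .io_formats import GAP, Alignment, SeqRecord
from .sequence_ops import translate_string


class AlignmentError(ValueError):
    pass


@dataclass
class SliceRange:
    """1-based inclusive column range; '-' leaves an end open."""

    start: int | None
    end: int | None

    @classmethod
    def parse(cls, text: str) -> "SliceRange":
        parts = [p.strip() for p in text.split(",")]
        if len(parts) != 2:
            raise AlignmentError(f"invalid slice {text!r}; expected 'start,end'")

        def one(token):
            if token == "-":
                return None
            try:
                return int(token)
            except ValueError:
                raise AlignmentError(f"invalid slice bound {token!r}")

        return cls(one(parts[0]), one(parts[1]))

    def resolve(self, length: int) -> tuple[int, int]:
        start = 1 if self.start is None else self.start
        end = length if self.end is None else self.end
        if not (1 <= start <= end <= length):
            raise AlignmentError(
                f"slice {start},{end} out of range for alignment of length {length}")
        return start, end


# ---------------------------------------------------------------------------
# summaries


def percent_identity(a: str, b: str) -> float:
    """Pairwise identity over columns with no gap in either sequence."""
    same = compared = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        compared += 1
        if x == y:
            same += 1
    if compared == 0:
        raise AlignmentError("no comparable (gap-free) columns between pair")
    return 100.0 * same / compared


def aln_summary(aln: Alignment, metric: str) -> float:
    if metric == "length":
        return aln.length
    if metric == "nseq":
        return aln.nseq
    if metric == "avg_pid":
        if aln.nseq < 2:
            raise AlignmentError("average identity needs at least 2 members")
        pids = [
            percent_identity(a.residues, b.residues)
            for a, b in combinations(aln.members, 2)
        ]
        return sum(pids) / len(pids)
    raise AlignmentError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# shape-preserving transforms


def slice_alignment(aln: Alignment, rng: SliceRange) -> Alignment:
    start, end = rng.resolve(aln.length)
    return Alignment([
        SeqRecord(m.id, m.residues[start - 1:end], m.description)
        for m in aln.members
    ])


def filter_members(aln: Alignment, ids: list[str], mode: str = "pick") -> Alignment:
    present = set(aln.ids())
    missing = [i for i in ids if i not in present]
    if missing:
        raise AlignmentError("id(s) not found: " + ", ".join(missing))
    wanted = set(ids)
    if mode == "pick":
        kept = [m for m in aln.members if m.id in wanted]
    else:
        kept = [m for m in aln.members if m.id not in wanted]
    return Alignment(kept)


def concat(alignments: list[Alignment]) -> Alignment:
    """Concatenate same-id-set alignments column-wise, in input order."""
    if not alignments:
        raise AlignmentError("nothing to concatenate")
    first = alignments[0]
    ref_ids = set(first.ids())
    for k, aln in enumerate(alignments[1:], start=2):
        other = set(aln.ids())
        if other != ref_ids:
            diff = sorted(ref_ids.symmetric_difference(other))
            raise AlignmentError(
                f"alignment {k} id set differs: " + ", ".join(diff))
    by_id = [{m.id: m.residues for m in aln.members} for aln in alignments]
    return Alignment([
        SeqRecord(m.id, "".join(d[m.id] for d in by_id), m.description)
        for m in first.members
    ])


# ---------------------------------------------------------------------------
# codon back-translation


def pep2dna(protein_aln: Alignment, cds_records: list) -> Alignment:
    """Expand each aligned amino acid to its source codon and each gap to
    '---', producing a codon-based nucleotide alignment."""
    cds_by_id = {r.id: r for r in cds_records}
    rows = []
    for member in protein_aln.members:
        cds = cds_by_id.get(member.id)
        if cds is None:
            raise AlignmentError(f"no CDS for aligned protein {member.id!r}")
        peptide = member.residues.replace(GAP, "")
        translated = translate_string(cds.residues)
        if translated.endswith("*") and not peptide.endswith("*"):
            translated = translated[:-1]  # tolerate a terminal stop codon
        if translated != peptide:
            mismatch = next(
                (i for i, (x, y) in enumerate(zip(translated, peptide), 1)
                 if x != y),
                min(len(translated), len(peptide)) + 1)
            raise AlignmentError(
                f"CDS for {member.id!r} does not translate to the aligned "
                f"protein (first mismatch at residue {mismatch})")
        codons = iter(
            cds.residues[i:i + 3] for i in range(0, 3 * len(peptide), 3))
        row = "".join(
            "---" if aa == GAP else next(codons) for aa in member.residues)
        rows.append(SeqRecord(member.id, row, member.description))
    return Alignment(rows)


# ---------------------------------------------------------------------------
# stochastic operations

DEFAULT_SEED = 42


def _rng(seed: int | None, operation: str) -> random.Random:
    if seed is None:
        seed = DEFAULT_SEED
        print(f"{operation}: using default seed {seed}", file=sys.stderr)
    return random.Random(seed)


def bootstrap(aln: Alignment, seed: int | None = None) -> Alignment:
    """Resample columns with replacement; member ids and count unchanged."""
    if aln.length < 1:
        raise AlignmentError("cannot bootstrap an empty alignment")
    rng = _rng(seed, "bootstrap")
    cols = list(aln.columns())
    drawn = [cols[rng.randrange(len(cols))] for _ in range(len(cols))]
    return aln.from_columns(drawn)


def shuffle_sites(aln: Alignment, seed: int | None = None) -> Alignment:
    """Permute column order uniformly; each column stays intact."""
    rng = _rng(seed, "shuffle-sites")
    cols = list(aln.columns())
    rng.shuffle(cols)
    return aln.from_columns(cols)


def mutate_sites(aln: Alignment, rate: float, seed: int | None = None) -> Alignment:
    """Replace each non-gap residue, independently with probability ``rate``,
    by a uniformly chosen different nucleotide."""
    if not 0.0 <= rate <= 1.0:
        raise AlignmentError(f"mutation rate {rate} outside [0, 1]")
    for m in aln.members:
        if not m.is_nucleotide:
            raise AlignmentError(
                f"mutate-sites needs a nucleotide alignment ({m.id!r} is protein)")
    rng = _rng(seed, "mutate-sites")
    bases = "ACGT"
    out = []
    for m in aln.members:
        residues = list(m.residues)
        for i, c in enumerate(residues):
            if c == GAP or rng.random() >= rate:
                continue
            choices = [b for b in bases if b != c] or list(bases)
            residues[i] = rng.choice(choices)
        out.append(SeqRecord(m.id, "".join(residues), m.description))
    return Alignment(out)
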