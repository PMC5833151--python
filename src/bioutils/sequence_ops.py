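"""Sequence-level operations: summaries, reverse-complement, pick/delete,
sub-sequences, translation, degapping, and restriction digestion.

Coordinates are 1-based and inclusive throughout.
"""

from __future__ import annotations

import re
import sys
from dataclasses import dataclass

from Bio.Data import CodonTable, IUPACData

from .io_formats import GAP, SeqRecord


class SequenceError(ValueError):
    pass


# IUPAC nucleotide complement, including ambiguity codes.
COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVN-",
    "TGCAAYRSWMKVBHDN-",
)

# Standard genetic code (translation table 1).
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

_AMBIG = {k.upper(): v.upper() for k, v in IUPACData.ambiguous_dna_values.items()}


def translate_codon(codon: str) -> str:
    """Translate one codon with the standard code; ambiguity codes yield the
    common amino acid if every resolution agrees, else 'X'."""
    codon = codon.upper().replace("U", "T")
    if codon in CODON_TO_AA:
        return CODON_TO_AA[codon]
    try:
        expansions = [_AMBIG[c] for c in codon]
    except KeyError as exc:
        raise SequenceError(f"cannot translate codon {codon!r}") from exc
    aas = {
        CODON_TO_AA[a + b + c]
        for a in expansions[0] for b in expansions[1] for c in expansions[2]
    }
    return aas.pop() if len(aas) == 1 else "X"


def translate_string(seq: str) -> str:
    """Frame +1 translation; trailing partial codon dropped."""
    if GAP in seq:
        raise SequenceError("cannot translate gapped sequence; degap first")
    return "".join(
        translate_codon(seq[i:i + 3]) for i in range(0, len(seq) - 2, 3))


def _require_nucleotide(records, operation: str):
    for rec in records:
        if not rec.is_nucleotide:
            raise SequenceError(f"{operation} undefined for protein "
                                f"(record {rec.id!r})")


# ---------------------------------------------------------------------------
# selectors


@dataclass
class Selector:
    """Declarative pick/delete criterion parsed from ``id:...``,
    ``order:...`` (1-based inclusive ranges), or ``re:...`` syntax."""

    mode: str
    payload: object

    @classmethod
    def parse(cls, text: str) -> "Selector":
        if ":" not in text:
            raise SequenceError(
                f"invalid selector {text!r}; expected id:, order:, or re: prefix")
        mode, _, body = text.partition(":")
        mode = mode.strip()
        body = body.strip()
        if mode == "id":
            ids = [t.strip() for t in body.split(",") if t.strip()]
            if not ids:
                raise SequenceError("empty id selector")
            return cls("id", ids)
        if mode == "order":
            ranges = []
            for token in body.split(","):
                token = token.strip()
                if "-" in token:
                    lo, _, hi = token.partition("-")
                    start, end = int(lo), int(hi)
                else:
                    start = end = int(token)
                if start < 1 or end < start:
                    raise SequenceError(f"invalid order range {token!r}")
                ranges.append((start, end))
            return cls("order", ranges)
        if mode == "re":
            try:
                return cls("re", re.compile(body))
            except re.error as exc:
                raise SequenceError(f"invalid regular expression: {exc}") from exc
        raise SequenceError(f"unknown selector mode {mode!r}")

    def matches(self, record: SeqRecord, position: int) -> bool:
        """``position`` is the record's 1-based order in the input."""
        if self.mode == "id":
            return record.id in self.payload
        if self.mode == "order":
            return any(lo <= position <= hi for lo, hi in self.payload)
        return self.payload.search(record.id) is not None


def filter_records(records: list, selector: Selector, mode: str = "pick") -> list:
    """Keep (pick) or remove (delete) matching records, preserving order."""
    if selector.mode == "id":
        present = {r.id for r in records}
        missing = [i for i in selector.payload if i not in present]
        if missing:
            raise SequenceError("id(s) not found: " + ", ".join(missing))
    matched = [
        rec for pos, rec in enumerate(records, start=1)
        if selector.matches(rec, pos)
    ]
    if mode == "pick":
        if not matched:
            print("pick: no records matched", file=sys.stderr)
        return matched
    matched_ids = {id(r) for r in matched}
    return [r for r in records if id(r) not in matched_ids]


# ---------------------------------------------------------------------------
# transforms


def summarize(records: list, metric: str) -> str:
    if metric == "count":
        return f"{len(records)}\n"
    if metric == "length":
        return "".join(f"{r.id}\t{len(r)}\n" for r in records)
    if metric == "composition":
        lines = []
        pooled: dict[str, int] = {}
        for rec in records:
            counts: dict[str, int] = {}
            for c in rec.residues:
                if c != GAP:
                    counts[c] = counts.get(c, 0) + 1
                    pooled[c] = pooled.get(c, 0) + 1
            total = sum(counts.values())
            for res in sorted(counts):
                lines.append(f"{rec.id}\t{res}\t{100.0 * counts[res] / total:.1f}")
        total = sum(pooled.values())
        for res in sorted(pooled):
            lines.append(f"_all_\t{res}\t{100.0 * pooled[res] / total:.1f}")
        return "".join(line + "\n" for line in lines)
    raise SequenceError(f"unknown metric {metric!r}")


def revcom(records: list) -> list:
    """Reverse-complement with the full IUPAC map; gaps stay in place."""
    _require_nucleotide(records, "reverse-complement")
    return [
        SeqRecord(r.id, r.residues.translate(COMPLEMENT)[::-1], r.description)
        for r in records
    ]


def subseq(records: list, start: int, end: int) -> list:
    """Residues from 1-based ``start`` to ``end`` inclusive."""
    if start < 1 or end < start:
        raise SequenceError(f"invalid range {start},{end}")
    out = []
    for rec in records:
        if end > len(rec):
            raise SequenceError(
                f"range end {end} beyond record {rec.id!r} (length {len(rec)})")
        desc = f"{rec.description} {start}..{end}".strip()
        out.append(SeqRecord(rec.id, rec.residues[start - 1:end], desc))
    return out


def degap(records: list) -> list:
    return [
        SeqRecord(r.id, r.residues.replace(GAP, ""), r.description,
                  alphabet=r.alphabet)
        for r in records
    ]


_FRAME_TAGS = ["_f+1", "_f+2", "_f+3", "_f-1", "_f-2", "_f-3"]


def translate(records: list, frames: int = 1) -> list:
    """Translate in 1, 3, or 6 reading frames (standard genetic code)."""
    if frames not in (1, 3, 6):
        raise SequenceError("frames must be 1, 3, or 6")
    _require_nucleotide(records, "translation")
    out = []
    for rec in records:
        seq = rec.residues
        if frames == 1:
            out.append(SeqRecord(rec.id, translate_string(seq),
                                 rec.description, alphabet="protein"))
            continue
        strands = [seq, seq.translate(COMPLEMENT)[::-1]][: 2 if frames == 6 else 1]
        for s, strand in enumerate(strands):
            for offset in range(3):
                tag = _FRAME_TAGS[3 * s + offset]
                out.append(SeqRecord(rec.id + tag,
                                     translate_string(strand[offset:]),
                                     rec.description, alphabet="protein"))
    return out


# ---------------------------------------------------------------------------
# restriction digestion

# enzyme -> (recognition site, cut offset within site, 5' side)
ENZYMES: dict[str, tuple[str, int]] = {
    "EcoRI": ("GAATTC", 1),
    "BamHI": ("GGATCC", 1),
    "HindIII": ("AAGCTT", 1),
    "NotI": ("GCGGCCGC", 2),
    "TaqI": ("TCGA", 1),
}


@dataclass
class DigestResult:
    fragments: list
    enzyme: str
    site: str
    cut_offset: int


def restrict(records: list, enzyme: str) -> list[DigestResult]:
    """Cut each sequence at every recognition site; fragments are emitted
    5'->3' with ids suffixed by fragment index."""
    if enzyme not in ENZYMES:
        raise SequenceError(
            f"unknown enzyme {enzyme!r}; available: " + ", ".join(sorted(ENZYMES)))
    _require_nucleotide(records, "restriction digestion")
    site, offset = ENZYMES[enzyme]
    results = []
    for rec in records:
        seq = rec.residues
        cuts = [
            i + offset
            for i in range(len(seq) - len(site) + 1)
            if seq[i:i + len(site)] == site
        ]
        bounds = [0] + cuts + [len(seq)]
        fragments = [
            SeqRecord(f"{rec.id}_{k}", seq[bounds[k - 1]:bounds[k]],
                      rec.description)
            for k in range(1, len(bounds))
            if bounds[k] > bounds[k - 1] or len(bounds) == 2
        ]
        results.append(DigestResult(fragments, enzyme, site, offset))
    return results
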