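"""Seeded generators for synthetic inputs: CDS sets, gapped protein
alignments, allelic samples with known diversity, and random support-labeled
trees. Identical configuration always yields byte-identical output.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .io_formats import Alignment, SeqRecord, write_seqs, write_tree
from .popgen_stats import harmonic
from .sequence_ops import CODON_TO_AA, translate_string
from .tree_ops import PhyloTree, TreeNode

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(c for c in CODON_TO_AA if c not in _STOPS)


class FixtureError(ValueError):
    pass


def _weighted_bases(gc_content: float) -> list[float]:
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    return [at, gc, gc, at]  # A C G T


# ---------------------------------------------------------------------------
# coding sequences


@dataclass
class CdsSet:
    records: list
    translations: dict

    @property
    def fasta(self) -> str:
        return write_seqs(self.records)


def make_cds_set(seed: int, n_seqs: int = 5, seq_length: int = 60,
                 gc_content: float = 0.5, id_prefix: str = "gene",
                 extra_codons_max: int = 0, include_stop: bool = False,
                 ids: list | None = None) -> CdsSet:
    """In-frame CDS records starting with ATG and free of internal stops.

    ``extra_codons_max`` > 0 gives each record a random extra number of
    codons so lengths vary; ``include_stop`` appends a terminal stop codon.
    """
    if seq_length % 3 != 0 or seq_length < 6:
        raise FixtureError("seq_length must be a multiple of 3 and >= 6")
    rng = random.Random(seed)
    weights = _weighted_bases(gc_content)

    def draw_codon() -> str:
        while True:
            codon = "".join(rng.choices(_BASES, weights=weights, k=3))
            if codon not in _STOPS:
                return codon

    if ids is not None and len(ids) != n_seqs:
        raise FixtureError("ids length must equal n_seqs")
    records, translations = [], {}
    for k in range(1, n_seqs + 1):
        n_codons = seq_length // 3 + (
            rng.randrange(extra_codons_max + 1) if extra_codons_max else 0)
        codons = ["ATG"] + [draw_codon() for _ in range(n_codons - 1)]
        if include_stop:
            codons.append(rng.choice(sorted(_STOPS)))
        seq = "".join(codons)
        rec = SeqRecord(ids[k - 1] if ids else f"{id_prefix}{k}", seq)
        records.append(rec)
        translations[rec.id] = translate_string(seq)
    return CdsSet(records, translations)


def _gap_pad(rows: list, rng: random.Random, extra: int,
             alphabet: str) -> Alignment:
    """Pad (id, seq) rows to a common width by inserting gaps at random
    positions; degapping each member recovers the original row."""
    width = max(len(s) for _, s in rows) + extra
    members = []
    for rec_id, seq in rows:
        chars = list(seq)
        for _ in range(width - len(seq)):
            chars.insert(rng.randrange(len(chars) + 1), "-")
        members.append(SeqRecord(rec_id, "".join(chars), alphabet=alphabet))
    return Alignment(members)


def make_protein_alignment(cds: CdsSet, seed: int,
                           max_extra_gaps: int = 4) -> Alignment:
    """Gapped protein alignment whose degapped rows equal the CDS
    translations (terminal stops stripped), suitable for codon
    back-translation tests."""
    rng = random.Random(seed)
    rows = [
        (rec.id, cds.translations[rec.id].rstrip("*")) for rec in cds.records
    ]
    return _gap_pad(rows, rng, rng.randrange(1, max_extra_gaps + 1), "protein")


def make_dna_alignment(cds: CdsSet, seed: int,
                       max_extra_gaps: int = 6) -> Alignment:
    """Gapped nucleotide alignment whose degapped rows equal the CDS
    records (emulates an aligned CDS set)."""
    rng = random.Random(seed)
    rows = [(rec.id, rec.residues) for rec in cds.records]
    return _gap_pad(rows, rng, rng.randrange(1, max_extra_gaps + 1), "dna")


# ---------------------------------------------------------------------------
# allelic samples


@dataclass
class AlleleSampleFixture:
    records: list
    true_s: int
    mutated_sites: list = field(default_factory=list)

    @property
    def fasta(self) -> str:
        return write_seqs(self.records)


def make_allele_sample(seed: int, n_seqs: int = 10, seq_length: int = 500,
                       theta: float = 2.0, gc_content: float = 0.5,
                       id_prefix: str = "allele") -> AlleleSampleFixture:
    """Allelic nucleotide sample with infinite-sites-style mutations.

    The number of segregating sites is Poisson with mean theta * a_n, and
    each mutation's descendant count i is drawn with probability
    proportional to 1/i, giving E[S] = theta * a_n and E[pi] = theta.
    """
    if n_seqs < 2:
        raise FixtureError("need at least 2 sequences")
    if theta <= 0:
        raise FixtureError("theta must be positive")
    rng = random.Random(seed)
    weights = _weighted_bases(gc_content)
    ancestor = rng.choices(_BASES, weights=weights, k=seq_length)
    a_n = harmonic(n_seqs)

    # Poisson draw via inversion; mean is modest at fixture scales
    mean = theta * a_n
    u = rng.random()
    k, p, cum = 0, math.exp(-mean), 0.0
    while True:
        cum += p
        if u <= cum or k > seq_length:
            break
        k += 1
        p *= mean / k
    n_mutations = min(k, seq_length)

    sites = rng.sample(range(seq_length), n_mutations)
    freq_weights = [1.0 / i for i in range(1, n_seqs)]
    rows = [list(ancestor) for _ in range(n_seqs)]
    for site in sites:
        i = rng.choices(range(1, n_seqs), weights=freq_weights, k=1)[0]
        carriers = rng.sample(range(n_seqs), i)
        derived = rng.choice([b for b in _BASES if b != ancestor[site]])
        for c in carriers:
            rows[c][site] = derived
    records = [
        SeqRecord(f"{id_prefix}{k + 1}", "".join(row))
        for k, row in enumerate(rows)
    ]
    return AlleleSampleFixture(records, len(sites), sorted(sites))


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeFixture:
    tree: PhyloTree
    total_length: float

    @property
    def newick(self) -> str:
        return write_tree(self.tree)


def make_tree(seed: int, n_leaves: int = 10, birth_rate: float = 1.0,
              support_range: tuple = (70, 100),
              leaf_names: list | None = None) -> TreeFixture:
    """Random pure-birth topology with exponential branch lengths and
    uniform integer support labels on internal nodes."""
    if n_leaves < 2:
        raise FixtureError("need at least 2 leaves")
    rng = random.Random(seed)
    if leaf_names is None:
        leaf_names = [f"L{k + 1}" for k in range(n_leaves)]
    elif len(leaf_names) != n_leaves:
        raise FixtureError("leaf_names length must equal n_leaves")

    def edge() -> float:
        return rng.expovariate(birth_rate)

    root = TreeNode()
    first = TreeNode(leaf_names[0], edge(), True)
    second = TreeNode(leaf_names[1], edge(), True)
    root.add_child(first)
    root.add_child(second)
    leaves = [first, second]
    lo, hi = support_range
    total = first.length + second.length
    for name in leaf_names[2:]:
        target = rng.choice(leaves)
        # split the chosen pendant edge with a new labeled internal node
        inner = TreeNode(str(rng.randint(int(lo), int(hi))))
        split = rng.random() * target.length
        inner.length, inner.has_length = target.length - split, True
        parent = target.parent
        parent.children[parent.children.index(target)] = inner
        inner.parent = parent
        inner.add_child(target)
        target.length = split
        new_leaf = TreeNode(name, edge(), True)
        inner.add_child(new_leaf)
        total += new_leaf.length
        leaves.append(new_leaf)
    return TreeFixture(PhyloTree(root), total)
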