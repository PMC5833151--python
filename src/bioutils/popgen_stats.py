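"""Population-genetic statistics over aligned allelic nucleotide sequences.

All statistics share one site-masking rule: a column is usable only when
every allele carries an unambiguous, non-gap nucleotide there, so every
statistic uses the same denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

from .io_formats import Alignment
from .sequence_ops import translate_codon

_CANONICAL = frozenset("ACGT")


class PopGenError(ValueError):
    pass


@dataclass
class AlleleSample:
    """An alignment of same-locus nucleotide sequences viewed as a
    population sample."""

    aln: Alignment
    usable_sites: list[int] = field(init=False)

    def __post_init__(self):
        self.usable_sites = [
            j for j in range(self.aln.length)
            if set(self.aln.column(j)) <= _CANONICAL
        ]

    @property
    def n(self) -> int:
        return self.aln.nseq

    def _require_pairs(self):
        if self.n < 2:
            raise PopGenError("statistic needs at least 2 sequences")

    def usable_columns(self) -> list[str]:
        return [self.aln.column(j) for j in self.usable_sites]


def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i."""
    return sum(1.0 / i for i in range(1, n))


def segregating_sites(sample: AlleleSample) -> int:
    """Number of usable columns with >= 2 distinct nucleotides; multi-allelic
    sites count once."""
    sample._require_pairs()
    return sum(1 for col in sample.usable_columns() if len(set(col)) > 1)


def pi(sample: AlleleSample, per_site: bool = False) -> float:
    """Average pairwise difference count over all unordered allele pairs,
    computed from per-column allele counts."""
    sample._require_pairs()
    n = sample.n
    n_pairs = comb(n, 2)
    diff_pairs = 0
    for col in sample.usable_columns():
        same = sum(comb(col.count(b), 2) for b in set(col))
        diff_pairs += n_pairs - same
    value = diff_pairs / n_pairs
    if per_site:
        if not sample.usable_sites:
            raise PopGenError("no usable sites for per-site diversity")
        value /= len(sample.usable_sites)
    return value


def watterson_theta_from_s(s: int, n: int) -> float:
    """theta_W = S / sum_{i=1}^{n-1} 1/i."""
    if n < 2:
        raise PopGenError("Watterson's theta needs at least 2 sequences")
    return s / harmonic(n)


def watterson_theta(sample: AlleleSample) -> float:
    return watterson_theta_from_s(segregating_sites(sample), sample.n)


def mismatch_distribution(sample: AlleleSample) -> dict[int, int]:
    """Histogram of pairwise difference counts; totals n(n-1)/2 pairs and
    its mean equals pi."""
    sample._require_pairs()
    cols = sample.usable_columns()
    hist: dict[int, int] = {}
    for i, j in combinations(range(sample.n), 2):
        k = sum(1 for col in cols if col[i] != col[j])
        hist[k] = hist.get(k, 0) + 1
    return dict(sorted(hist.items()))


# ---------------------------------------------------------------------------
# coding-SNP classification


@dataclass
class CodonVariant:
    position: int          # 1-based codon index
    alleles: tuple         # distinct codons observed (usable alleles only)
    effect: str            # synonymous | nonsynonymous | multi-hit


@dataclass
class SnpClassification:
    variants: list
    counts: dict

    @property
    def n_variable_codons(self) -> int:
        return len(self.variants)


def snp_coding(sample: AlleleSample) -> SnpClassification:
    """Classify each variable codon of an in-frame CDS sample as synonymous,
    nonsynonymous (single segregating position), or multi-hit (>1
    segregating position in the codon)."""
    sample._require_pairs()
    if sample.aln.length % 3 != 0:
        raise PopGenError(
            f"alignment length {sample.aln.length} is not divisible by 3")
    usable = set(sample.usable_sites)
    variants = []
    counts = {"synonymous": 0, "nonsynonymous": 0, "multi-hit": 0}
    for codon_idx in range(sample.aln.length // 3):
        sites = [3 * codon_idx, 3 * codon_idx + 1, 3 * codon_idx + 2]
        if not all(j in usable for j in sites):
            continue
        cols = [sample.aln.column(j) for j in sites]
        seg = [j for j, col in enumerate(cols) if len(set(col)) > 1]
        if not seg:
            continue
        codons = tuple(dict.fromkeys(
            cols[0][i] + cols[1][i] + cols[2][i] for i in range(sample.n)))
        if len(seg) > 1:
            effect = "multi-hit"
        else:
            aas = {translate_codon(c) for c in codons}
            effect = "synonymous" if len(aas) == 1 else "nonsynonymous"
        counts[effect] += 1
        variants.append(CodonVariant(codon_idx + 1, codons, effect))
    return SnpClassification(variants, counts)


# ---------------------------------------------------------------------------
# named-statistics bundle

_STATS = {
    "pi": lambda sample: pi(sample),
    "theta": watterson_theta,
}


def stats_bundle(sample: AlleleSample, names: list[str]) -> list[tuple[str, float]]:
    if not names:
        raise PopGenError("no statistics requested")
    unknown = [n for n in names if n not in _STATS]
    if unknown:
        raise PopGenError(
            "unknown statistic(s): " + ", ".join(unknown)
            + "; supported: " + ", ".join(sorted(_STATS)))
    return [(name, _STATS[name](sample)) for name in names]
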