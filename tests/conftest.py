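import pytest

from bioutils import fixtures as fx
from bioutils.io_formats import Alignment, SeqRecord, parse_newick


@pytest.fixture
def cds_set():
    return fx.make_cds_set(101, n_seqs=5, seq_length=60)


@pytest.fixture
def protein_alignment(cds_set):
    return fx.make_protein_alignment(cds_set, 202)


@pytest.fixture
def dna_alignment(cds_set):
    return fx.make_dna_alignment(cds_set, 303)


@pytest.fixture
def allele_fixture():
    return fx.make_allele_sample(404, n_seqs=8, seq_length=300, theta=3.0)


@pytest.fixture
def tree5():
    return parse_newick("(((A:1,B:2)90:1,C:3)80:1,(D:1,E:1)95:2);")


@pytest.fixture
def random_tree():
    return fx.make_tree(505, n_leaves=12).tree


def make_records(rows):
    return [SeqRecord(i, s) for i, s in rows]


def make_alignment(rows):
    return Alignment(make_records(rows))
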