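import pytest

from coevo.datasets import load_qbeta_annotation, load_qbeta_matrix


@pytest.fixture(scope="session")
def qbeta_matrix():
    return load_qbeta_matrix()


@pytest.fixture(scope="session")
def qbeta_annotation():
    return load_qbeta_annotation()


#: printed annotation of every site in the published table:
#: (genome_position, regions, gene_position, codon_change, aa_change, effect)
QBETA_PRINTED_ROWS = [
    (47, ["UTR"], None, None, None, "UTR"),
    (52, ["UTR"], None, None, None, "UTR"),
    (66, ["A2"], 6, "CCU→CCA", None, "synonymous"),
    (221, ["A2"], 161, "CUA→CGA", "Leu→Arg", "nonsynonymous"),
    (519, ["A2"], 459, "GAA→GAG", None, "synonymous"),
    (569, ["A2"], 509, "GGG→GAG", "Gly→Glu", "nonsynonymous"),
    (789, ["A2"], 729, "GGC→GGU", None, "synonymous"),
    (830, ["A2"], 770, "GUU→GCU", "Val→Ala", "nonsynonymous"),
    (1257, ["A2"], 1197, "ACC→ACU", None, "synonymous"),
    (1288, ["A2"], 1228, "AGU→GGU", "Ser→Gly", "nonsynonymous"),
    (1344, ["coat", "A1"], 1, "AUG→GUG", "Met→Met", "synonymous"),
    (1371, ["coat", "A1"], 28, "GGU→CGU", "Gly→Arg", "nonsynonymous"),
    (1795, ["A1"], 452, "AUU→ACU", "Ile→Thr", "nonsynonymous"),
    (2249, ["A1"], 906, "AGC→AGU", None, "synonymous"),
]


@pytest.fixture(scope="session")
def qbeta_printed_rows():
    return QBETA_PRINTED_ROWS
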