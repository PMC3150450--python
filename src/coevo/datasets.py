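"""Packaged reference data for the Qβ–*E. coli* coevolution experiment.

Ships the transcription of the published whole-population resequencing
status table (14 sites × 9 population columns, including the deposited NCBI
isolate and the ancestor), the gene-coordinate map, and a synthetic
4,217-nt reference sequence that embeds every printed codon context so
codon-level annotation can be exercised without network access to the real
deposited genome.
"""

from __future__ import annotations

from importlib import resources

from .data_model import GenomeAnnotation, MutationStatusMatrix, \
    read_genome_annotation, read_mutation_matrix

#: Qβ genome length in bases
QBETA_GENOME_LENGTH = 4217

#: final replication-generation totals per experimental line
QBETA_LINE_GENERATIONS = {"line1": 163, "line2": 165, "line3": 169, "line4": 168}

#: lines cocultured with the evolving host
QBETA_COPROPAGATION_LINES = ["line1", "line2"]
#: lines where the phage was passaged daily on fresh ancestral host
QBETA_PROPAGATION_LINES = ["line3", "line4"]


def _data_path(name: str):
    return resources.files("coevo.data").joinpath(name)


def load_qbeta_matrix() -> MutationStatusMatrix:
    """The mutation-status matrix of the coevolution experiment."""
    with resources.as_file(_data_path("qbeta_status_matrix.tsv")) as p:
        return read_mutation_matrix(p)


def load_qbeta_annotation(with_sequence: bool = True) -> GenomeAnnotation:
    """Gene map (A2, coat, A1, replicase) plus the synthetic reference.

    With ``with_sequence=False`` only coordinate math is available and codon
    annotation is unavailable.
    """
    with resources.as_file(_data_path("qbeta_genes.tsv")) as genes:
        if not with_sequence:
            return read_genome_annotation(genes)
        with resources.as_file(
                _data_path("qbeta_reference_synthetic.fasta")) as fasta:
            return read_genome_annotation(genes, fasta)
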