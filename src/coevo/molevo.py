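"""Weighted mutation-accumulation calculus and fixation-rate estimation.

A resequenced population scores each candidate site as absent (weight 0),
polymorphic (weight 0.5) or fixed (weight 1).  Mutation accumulation along a
lineage is the running sum of |Δweight| per site over successive sequenced
populations, so a site that appears, fixes and then reverts contributes on
both legs of its trajectory (e.g. absent→fixed→polymorphic→absent counts
1 + 0.5 + 0.5).  An ancestral population that is itself polymorphic at a
site starts that site at weight 0.5, so later fixation adds only 0.5.

Fixation rates divide weighted counts by the exposure (genome length ×
generations); gene-level bias is tested with the exact two-tailed binomial
after doubling half-integer weighted counts to integers; codon-level
annotation classifies substitutions as synonymous / nonsynonymous / UTR
against a reference sequence.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3
from scipy import stats as sps

from .data_model import (DataError, GenomeAnnotation, MutationStatusMatrix,
                         Status)
from .stats import binomial_two_tailed, welch_t

logger = logging.getLogger(__name__)

_WEIGHT = {Status.ABSENT: 0.0, Status.POLYMORPHIC: 0.5, Status.FIXED: 1.0}


def status_weight(status: Status) -> float:
    """Mutation weight of a site status: absent 0, polymorphic 0.5, fixed 1."""
    return _WEIGHT[Status(status)]


# ---------------------------------------------------------------------------
# Cumulative accumulation along a lineage
# ---------------------------------------------------------------------------

@dataclass
class CumulativeMutationSeries:
    """Cumulative weighted mutation counts along one lineage.

    ``cumulative[t]`` is the count at ``populations[t]``; the ancestor is
    index 0 with count 0.  ``increments[(genome_position, t)]`` records the
    |Δweight| contributed by a site over the interval ending at index t.
    """

    lineage_id: str
    populations: list[str]
    generations: list[float]
    cumulative: list[float]
    increments: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def final_count(self) -> float:
        return self.cumulative[-1]


def cumulative_mutation_series(matrix: MutationStatusMatrix,
                               lineage_id: str) -> CumulativeMutationSeries:
    """Σ|Δweight| accumulation over the ordered populations of a lineage."""
    pops = matrix.lineage_populations(lineage_id)
    cols = [matrix.population_index(p.population_id) for p in pops]
    cumulative = [0.0]
    increments: dict[tuple[int, int], float] = {}
    running = 0.0
    for t in range(1, len(cols)):
        for i, site in enumerate(matrix.sites):
            w_prev = status_weight(matrix.status[i][cols[t - 1]])
            w_now = status_weight(matrix.status[i][cols[t]])
            inc = abs(w_now - w_prev)
            if inc:
                increments[(site.genome_position, t)] = inc
                running += inc
                if t == 1 and matrix.status[i][cols[0]] is Status.POLYMORPHIC:
                    logger.info(
                        "lineage %s: site %d starts polymorphic in the "
                        "ancestor (weight 0.5); first interval adds %.1f",
                        lineage_id, site.genome_position, inc)
        cumulative.append(running)
    return CumulativeMutationSeries(
        lineage_id, [p.population_id for p in pops],
        [p.generation for p in pops], cumulative, increments)


# ---------------------------------------------------------------------------
# Fixation rates
# ---------------------------------------------------------------------------

@dataclass
class RateEstimate:
    """A fixation rate with its exposure; per-line detail when aggregated."""

    rate: float  # per base per generation
    count: float  # weighted mutations
    genome_length: float
    generations: float
    per_line: Optional[dict[str, float]] = None  # lineage -> rate
    sd: Optional[float] = None  # sample SD over lines (>= 2 lines)


def fixation_rate(count: float, genome_length: float,
                  generations: float) -> RateEstimate:
    """count / (genome length × generations), per base per generation."""
    if count < 0:
        raise DataError(f"count must be >= 0, got {count!r}")
    if not (genome_length > 0 and generations > 0):
        raise DataError("genome_length and generations must be > 0")
    return RateEstimate(count / (genome_length * generations), count,
                        genome_length, generations)


@dataclass
class RateComparison:
    group_a: RateEstimate
    group_b: RateEstimate
    ratio: Optional[float]  # mean(A) / mean(B); None when mean(B) == 0


def lineage_rates(matrix: MutationStatusMatrix,
                  genome_length: float,
                  generations: Optional[dict[str, float]] = None
                  ) -> dict[str, RateEstimate]:
    """Per-lineage fixation rate from the final cumulative weighted count.

    ``generations`` overrides the exposure per lineage; by default each
    line's final population generation number is used.
    """
    out = {}
    for lid in matrix.lineages:
        series = cumulative_mutation_series(matrix, lid)
        gens = (generations[lid] if generations is not None
                else series.generations[-1])
        out[lid] = fixation_rate(series.final_count, genome_length, gens)
    return out


def _aggregate(rates: Sequence[RateEstimate],
               lines: Sequence[str]) -> RateEstimate:
    values = [r.rate for r in rates]
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) >= 2 else None
    return RateEstimate(
        mean, sum(r.count for r in rates), rates[0].genome_length,
        math.nan, per_line=dict(zip(lines, values)), sd=sd)


def lineage_rate_summary(matrix: MutationStatusMatrix,
                         genome_length: float,
                         group_a: Sequence[str],
                         group_b: Sequence[str],
                         generations: Optional[dict[str, float]] = None
                         ) -> RateComparison:
    """Group mean ± sample SD of per-line rates, and the mean-ratio A/B."""
    if not group_a or not group_b:
        raise DataError("both groups need >= 1 lineage")
    rates = lineage_rates(matrix, genome_length, generations)
    for lid in list(group_a) + list(group_b):
        if lid not in rates:
            raise DataError(f"no lineage {lid!r} in matrix")
    agg_a = _aggregate([rates[l] for l in group_a], list(group_a))
    agg_b = _aggregate([rates[l] for l in group_b], list(group_b))
    ratio = agg_a.rate / agg_b.rate if agg_b.rate > 0 else None
    if ratio is None:
        logger.warning("group B mean rate is 0; ratio undefined")
    return RateComparison(agg_a, agg_b, ratio)


def rate_welch_t(group_a: Sequence[float],
                 group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-tailed t on per-line fixation rates."""
    return welch_t(group_a, group_b)


# ---------------------------------------------------------------------------
# Gene-level mutation bias
# ---------------------------------------------------------------------------

@dataclass
class GeneBiasResult:
    gene: str
    k_in_gene: float  # weighted count inside the gene
    n_total: float    # total weighted count
    p0: float         # gene length fraction of the genome
    p_value: Optional[float]
    tally: str

    @property
    def fraction(self) -> Optional[float]:
        return self.k_in_gene / self.n_total if self.n_total > 0 else None


def gene_bias_binomial(matrix: MutationStatusMatrix,
                       annotation: GenomeAnnotation,
                       gene_name: str,
                       lineages: Optional[Sequence[str]] = None,
                       tally: str = "cumulative",
                       integerize: str = "double") -> GeneBiasResult:
    """Exact two-tailed binomial test of mutation enrichment in one gene.

    ``tally`` selects how the weighted counts are formed over the chosen
    lineages (default: all lineages in the matrix):

    - ``"cumulative"`` (default): each line's per-site Σ|Δweight|
      increments, summed over lines — the same counting that builds the
      cumulative-accumulation curves;
    - ``"final"``: the status weights of each line's final population.

    The null fraction p0 is the gene's CDS length over the genome length.
    Weighted counts are half-integers; ``integerize="double"`` doubles both
    k and n (preserving the observed fraction) for the exact test, while
    ``"round"`` rounds to the nearest integers.
    """
    gene = annotation.gene(gene_name)
    if lineages is None:
        lineages = list(matrix.lineages)
    if tally not in ("cumulative", "final"):
        raise DataError(f"unknown tally {tally!r}")
    k = n = 0.0
    for lid in lineages:
        if tally == "cumulative":
            series = cumulative_mutation_series(matrix, lid)
            for (pos, _t), inc in series.increments.items():
                n += inc
                if gene.start <= pos <= gene.end:
                    k += inc
        else:
            final = matrix.lineage_populations(lid)[-1]
            col = matrix.population_index(final.population_id)
            for i, site in enumerate(matrix.sites):
                w = status_weight(matrix.status[i][col])
                n += w
                if gene.start <= site.genome_position <= gene.end:
                    k += w
    p0 = annotation.length_fraction(gene_name)
    if n == 0:
        logger.warning("no weighted mutations: binomial test undefined")
        return GeneBiasResult(gene_name, k, n, p0, None, tally)
    if integerize == "double":
        ki, ni = round(2 * k), round(2 * n)
    elif integerize == "round":
        ki, ni = round(k), round(n)
    else:
        raise DataError(f"unknown integerize mode {integerize!r}")
    return GeneBiasResult(gene_name, k, n, p0,
                          binomial_two_tailed(ki, ni, p0), tally)


# ---------------------------------------------------------------------------
# Codon annotation
# ---------------------------------------------------------------------------

@dataclass
class MutationAnnotation:
    genome_position: int
    region: str  # gene name or "UTR"
    gene_position: Optional[int] = None
    codon_index: Optional[int] = None
    codon_change: Optional[str] = None       # e.g. "GGG→GAG"
    amino_acid_change: Optional[str] = None  # e.g. "Gly→Glu"
    effect: str = "UTR"  # synonymous | nonsynonymous | UTR


def _aa3(codon_rna: str) -> str:
    aa = str(Seq(codon_rna).translate())
    return "Stop" if aa == "*" else seq3(aa)


def annotate_mutation(genome_position: int, ancestral_nt: str,
                      evolved_nt: str, annotation: GenomeAnnotation
                      ) -> list[MutationAnnotation]:
    """Codon-level annotation of a point substitution.

    Returns one record per overlapping gene (read-through frames share
    coordinates), or a single UTR record outside every CDS.  The ancestral
    nucleotide must match the reference; an AUG→GUG change at a gene's
    first codon is classed synonymous (the GUG start codon still initiates
    with Met).  Ambiguous ancestral calls like "G/A" match on either allele.
    """
    if annotation.reference_sequence is None:
        raise DataError("codon annotation requires a reference sequence")
    seq = annotation.reference_sequence
    ref_nt = seq[genome_position - 1]
    alleles = {a.strip().upper() for a in ancestral_nt.split("/")}
    if ref_nt not in alleles:
        raise DataError(
            f"position {genome_position}: ancestral {ancestral_nt!r} does not "
            f"match reference {ref_nt!r}")
    evolved_nt = evolved_nt.strip().upper()

    genes = annotation.genes_at(genome_position)
    if not genes:
        return [MutationAnnotation(genome_position, "UTR", effect="UTR")]
    out = []
    for gene in genes:
        gene_pos = annotation.gene_position(genome_position, gene)
        codon_index = (gene_pos + 2) // 3  # == ceil(gene_pos / 3)
        offset = (gene_pos - 1) % 3
        c_start = genome_position - offset
        old = seq[c_start - 1:c_start + 2]
        new = old[:offset] + evolved_nt + old[offset + 1:]
        if codon_index == 1 and old == "AUG" and new in ("GUG", "UUG"):
            # non-AUG start codons still initiate with formyl-Met
            aa_change = "Met→Met"
            effect = "synonymous"
        else:
            aa_old, aa_new = _aa3(old), _aa3(new)
            effect = "synonymous" if aa_old == aa_new else "nonsynonymous"
            aa_change = f"{aa_old}→{aa_new}" if effect == "nonsynonymous" else None
        out.append(MutationAnnotation(
            genome_position, gene.name, gene_pos, codon_index,
            f"{old}→{new}", aa_change, effect))
    return out


# ---------------------------------------------------------------------------
# Rate comparison against a reference process, and bottleneck size
# ---------------------------------------------------------------------------

def poisson_rate_test(observed_count: int, genome_length: float,
                      generations: float, reference_rate: float) -> float:
    """Upper-tail Poisson p: P(X >= observed) at λ = ref rate × L × G."""
    if observed_count < 0:
        raise DataError("observed_count must be >= 0")
    if not (genome_length > 0 and generations > 0 and reference_rate >= 0):
        raise DataError("exposure and reference rate must be positive")
    lam = reference_rate * genome_length * generations
    return float(sps.poisson.sf(observed_count - 1, lam))


@dataclass
class NeEstimate:
    initial_phage_count: float
    infecting_fraction: float

    @property
    def bottleneck_size(self) -> float:
        return self.initial_phage_count * self.infecting_fraction


def bottleneck_ne(initial_phage_count: float,
                  infecting_fraction: float) -> NeEstimate:
    """Per-passage bottleneck proxy for Ne: initial count × infecting fraction."""
    if not (0 < infecting_fraction <= 1):
        raise DataError("infecting_fraction must lie in (0, 1]")
    if initial_phage_count < 0:
        raise DataError("initial_phage_count must be >= 0")
    return NeEstimate(initial_phage_count, infecting_fraction)
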