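"""Domain types and file formats for phage–host serial-passage experiments.

The experimental system this package analyses is a daily serial-transfer
coculture of a lytic RNA phage and its bacterial host: each passage records
initial/final free-phage (PFU/ml) and cell (CFU/ml) densities plus the
dilution applied at transfer; hourly time courses track free phage, infected
cells, total cells or OD600 within one culture; whole-population resequencing
at chosen generations yields a site × population grid of mutation statuses
(absent / polymorphic / fixed).

All genome coordinates are 1-based inclusive.  A gene position ``p`` maps to
genome position ``start + p - 1``.  Mutation-status cells use the symbols
blank (absent), ``±`` (polymorphic) and ``+`` (fixed), with ASCII aliases
``0`` / ``0.5`` / ``1``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class CoevoError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CoevoError):
    """A file could not be parsed (missing column, unknown symbol, ...)."""


class ValidationError(CoevoError):
    """Parsed data violate a domain invariant."""


class DataError(CoevoError):
    """A computation was asked of data that cannot support it."""


class FitError(CoevoError):
    """A regression/fit could not be performed."""


class EstimationError(CoevoError):
    """A derived quantity (e.g. time to stationary) is undefined for the data."""


class IntegrationError(CoevoError):
    """Numerical integration of the coculture dynamics failed."""


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class Regime(str, enum.Enum):
    COPROPAGATION = "copropagation"
    PHAGE_ONLY = "phage_only"


class Entity(str, enum.Enum):
    FREE_PHAGE = "free_phage"
    INFECTED_CELLS = "infected_cells"
    TOTAL_CELLS = "total_cells"
    OD600 = "od600"


class Status(str, enum.Enum):
    ABSENT = "absent"
    POLYMORPHIC = "polymorphic"
    FIXED = "fixed"


#: canonical and ASCII-alias cell symbols for mutation-status matrices
STATUS_FROM_SYMBOL = {
    "": Status.ABSENT,
    "±": Status.POLYMORPHIC,
    "+": Status.FIXED,
    "0": Status.ABSENT,
    "0.5": Status.POLYMORPHIC,
    "1": Status.FIXED,
}
SYMBOL_FROM_STATUS = {
    Status.ABSENT: "",
    Status.POLYMORPHIC: "±",
    Status.FIXED: "+",
}


def _finite_nonneg(name: str, value: Optional[float], row: Optional[int] = None):
    if value is None:
        return
    where = f" (row {row})" if row is not None else ""
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite{where}, got {value!r}")
    if value < 0:
        raise ValidationError(f"{name} must be non-negative{where}, got {value!r}")


# ---------------------------------------------------------------------------
# Passage records
# ---------------------------------------------------------------------------

@dataclass
class PassageRecord:
    """One serial-transfer cycle of one lineage.

    Phage fields may be absent in host-only assays and cell fields absent in
    phage-only passages — never both.  Densities are per ml; ``duration`` is
    the incubation time in hours; ``dilution_factor`` is the fold-dilution
    (> 1) applied when this passage was seeded from the previous one.
    """

    day_index: int
    lineage_id: str
    regime: Regime
    dilution_factor: float
    duration: float
    n_i_phage: Optional[float] = None
    n_f_phage: Optional[float] = None
    n_i_cell: Optional[float] = None
    n_f_cell: Optional[float] = None

    def __post_init__(self):
        self.regime = Regime(self.regime)
        if self.day_index < 1:
            raise ValidationError(f"day_index must be >= 1, got {self.day_index}")
        if not (math.isfinite(self.dilution_factor) and self.dilution_factor > 1):
            raise ValidationError(
                f"dilution_factor must be > 1, got {self.dilution_factor!r}"
            )
        if not (math.isfinite(self.duration) and self.duration > 0):
            raise ValidationError(f"duration must be > 0, got {self.duration!r}")
        for name in ("n_i_phage", "n_f_phage", "n_i_cell", "n_f_cell"):
            _finite_nonneg(name, getattr(self, name))
        has_phage = self.n_i_phage is not None and self.n_f_phage is not None
        has_cell = self.n_i_cell is not None and self.n_f_cell is not None
        if not (has_phage or has_cell):
            raise ValidationError(
                "a passage record needs phage densities, cell densities, or both"
            )


PASSAGE_COLUMNS = [
    "day_index", "lineage_id", "regime", "n_i_phage", "n_f_phage",
    "n_i_cell", "n_f_cell", "dilution_factor", "duration_h",
]
_PASSAGE_REQUIRED = ["day_index", "lineage_id", "regime", "dilution_factor", "duration_h"]


def read_passage_log(path) -> list[PassageRecord]:
    """Read a TSV passage log; row order is preserved."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in _PASSAGE_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"passage log {path}: missing required column {col!r}")
    records = []
    for i, row in df.iterrows():
        def num(col):
            if col not in df.columns:
                return None
            raw = row[col].strip()
            if raw == "":
                return None
            try:
                return float(raw)
            except ValueError:
                raise FormatError(
                    f"passage log {path}: row {i + 2}, column {col!r}: "
                    f"cannot parse {raw!r} as a number"
                ) from None
        try:
            records.append(PassageRecord(
                day_index=int(row["day_index"]),
                lineage_id=row["lineage_id"],
                regime=Regime(row["regime"]),
                n_i_phage=num("n_i_phage"),
                n_f_phage=num("n_f_phage"),
                n_i_cell=num("n_i_cell"),
                n_f_cell=num("n_f_cell"),
                dilution_factor=num("dilution_factor"),
                duration=num("duration_h"),
            ))
        except ValidationError as exc:
            raise ValidationError(f"passage log {path}: row {i + 2}: {exc}") from None
    return records


def _fmt(value: Optional[float]) -> str:
    if value is None:
        return ""
    return repr(float(value))


def write_passage_log(records: Sequence[PassageRecord], path) -> None:
    """Write a TSV passage log; ``read_passage_log`` round-trips it."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PASSAGE_COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join([
                str(r.day_index), r.lineage_id, r.regime.value,
                _fmt(r.n_i_phage), _fmt(r.n_f_phage),
                _fmt(r.n_i_cell), _fmt(r.n_f_cell),
                _fmt(r.dilution_factor), _fmt(r.duration),
            ]) + "\n")


# ---------------------------------------------------------------------------
# Time courses
# ---------------------------------------------------------------------------

@dataclass
class TimeCourse:
    """A timestamped density (per ml) or OD series for one measured entity."""

    entity: Entity
    times: np.ndarray  # hours, strictly increasing
    values: np.ndarray  # PFU/ml, CFU/ml or OD units, >= 0

    def __post_init__(self):
        self.entity = Entity(self.entity)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValidationError("times and values must be 1-d arrays of equal length")
        if len(self.times) and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError("values must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.times)

    def window(self, t_start: float, t_end: float) -> "TimeCourse":
        """Restrict to ``t_start <= t <= t_end`` (inclusive)."""
        mask = (self.times >= t_start) & (self.times <= t_end)
        return TimeCourse(self.entity, self.times[mask], self.values[mask])

    def value_at(self, t: float, tolerance: Optional[float] = None) -> float:
        """Nearest-sample lookup; default tolerance is half the median step."""
        if len(self.times) == 0:
            raise DataError("empty time course")
        if tolerance is None:
            steps = np.diff(self.times)
            tolerance = 0.5 * float(np.median(steps)) if len(steps) else 0.0
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > tolerance + 1e-12:
            raise DataError(
                f"no sample within {tolerance:g} h of t={t:g} h for {self.entity.value}"
            )
        return float(self.values[i])


def read_timecourses(path) -> dict[Entity, TimeCourse]:
    """Read a tidy TSV of (entity, time_h, value) rows into one series per entity."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("entity", "time_h", "value"):
        if col not in df.columns:
            raise FormatError(f"time-course file {path}: missing column {col!r}")
    out: dict[Entity, TimeCourse] = {}
    for name, grp in df.groupby("entity", sort=False):
        try:
            entity = Entity(name)
        except ValueError:
            raise FormatError(f"time-course file {path}: unknown entity {name!r}") from None
        out[entity] = TimeCourse(entity, grp["time_h"].to_numpy(), grp["value"].to_numpy())
    return out


def write_timecourses(courses: Sequence[TimeCourse], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entity\ttime_h\tvalue\n")
        for tc in courses:
            for t, v in zip(tc.times, tc.values):
                fh.write(f"{tc.entity.value}\t{float(t)!r}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# Genome annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    name: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """Gene coordinates (1-based inclusive) on a small viral genome.

    Genes may overlap: a read-through protein shares its start with the
    shorter frame it extends.  ``reference_sequence``, when present, is the
    full-length nucleotide string (RNA or DNA alphabet) used for codon
    annotation.
    """

    genome_length: int
    genes: list[Gene]
    reference_sequence: Optional[str] = None

    def __post_init__(self):
        if self.genome_length < 1:
            raise ValidationError("genome_length must be positive")
        for g in self.genes:
            if not (1 <= g.start <= g.end <= self.genome_length):
                raise ValidationError(
                    f"gene {g.name}: 1 <= start <= end <= genome_length violated "
                    f"({g.start}..{g.end} on length {self.genome_length})"
                )
        if self.reference_sequence is not None:
            if len(self.reference_sequence) != self.genome_length:
                raise ValidationError(
                    f"reference sequence length {len(self.reference_sequence)} "
                    f"!= genome_length {self.genome_length}"
                )
            self.reference_sequence = self.reference_sequence.upper()

    def gene(self, name: str) -> Gene:
        for g in self.genes:
            if g.name == name:
                return g
        raise DataError(f"no gene named {name!r} in annotation")

    def genes_at(self, genome_position: int) -> list[Gene]:
        """All genes overlapping a genome position (possibly empty: UTR)."""
        if not (1 <= genome_position <= self.genome_length):
            raise ValidationError(
                f"genome position {genome_position} outside 1..{self.genome_length}"
            )
        return [g for g in self.genes if g.start <= genome_position <= g.end]

    def gene_position(self, genome_position: int, gene: Gene) -> int:
        """1-based position within ``gene`` of a genome position."""
        if not (gene.start <= genome_position <= gene.end):
            raise ValidationError(
                f"position {genome_position} not inside gene {gene.name}"
            )
        return genome_position - gene.start + 1

    def length_fraction(self, name: str) -> float:
        """Fraction of the genome occupied by a gene's CDS."""
        return self.gene(name).length / self.genome_length


def read_genome_annotation(gene_map, fasta=None) -> GenomeAnnotation:
    """Read a gene-coordinate TSV (columns name/start/end) and optional FASTA.

    The TSV may carry a ``# genome_length<TAB>N`` comment; otherwise the
    length is taken from the FASTA record, or (last resort) the maximal gene
    end.  When both the comment and a FASTA are given they must agree.
    """
    genome_length = None
    with open(gene_map, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    rows = []
    header = None
    for ln in lines:
        if ln.startswith("#"):
            parts = ln[1:].strip().split("\t")
            if parts and parts[0] == "genome_length" and len(parts) > 1:
                genome_length = int(parts[1])
            continue
        if not ln.strip():
            continue
        if header is None:
            header = ln.split("\t")
        else:
            rows.append(ln.split("\t"))
    if header is None:
        raise FormatError(f"gene map {gene_map}: no header row")
    for col in ("name", "start", "end"):
        if col not in header:
            raise FormatError(f"gene map {gene_map}: missing column {col!r}")
    ih = {c: header.index(c) for c in ("name", "start", "end")}
    genes = [Gene(r[ih["name"]], int(r[ih["start"]]), int(r[ih["end"]])) for r in rows]

    sequence = None
    if fasta is not None:
        seqs = list(SeqIO.parse(str(fasta), "fasta"))
        if len(seqs) != 1:
            raise FormatError(f"FASTA {fasta}: expected a single record, got {len(seqs)}")
        sequence = str(seqs[0].seq).upper()
        if genome_length is not None and genome_length != len(sequence):
            raise ValidationError(
                f"gene map declares genome_length {genome_length} but FASTA "
                f"record has length {len(sequence)}"
            )
        genome_length = len(sequence)
    if genome_length is None:
        genome_length = max(g.end for g in genes)
    return GenomeAnnotation(genome_length, genes, sequence)


def write_gene_map(annotation: GenomeAnnotation, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# genome_length\t{annotation.genome_length}\n")
        fh.write("name\tstart\tend\n")
        for g in annotation.genes:
            fh.write(f"{g.name}\t{g.start}\t{g.end}\n")


# ---------------------------------------------------------------------------
# Mutation-status matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Site:
    genome_position: int
    ancestral_nt: str
    evolved_nt: str


@dataclass(frozen=True)
class Population:
    population_id: str
    generation: float


@dataclass
class MutationStatusMatrix:
    """Sites × ordered populations grid of {absent, polymorphic, fixed}.

    ``lineages`` names, for each experimental line, the ordered population
    column ids belonging to it (ancestor first, generations non-decreasing).
    The ancestral column itself may be polymorphic at a site whose two
    alleles were both present in the founding stock.
    """

    sites: list[Site]
    populations: list[Population]
    status: list[list[Status]]  # site-major: status[i][j] = site i, population j
    lineages: dict[str, list[str]] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        npop = len(self.populations)
        if len(self.status) != len(self.sites):
            raise ValidationError("status grid must have one row per site")
        for row in self.status:
            if len(row) != npop:
                raise ValidationError("status grid must have one column per population")
        positions = [s.genome_position for s in self.sites]
        if len(set(positions)) != len(positions):
            raise ValidationError("every site must appear exactly once")
        ids = [p.population_id for p in self.populations]
        if len(set(ids)) != len(ids):
            raise ValidationError("population ids must be unique")
        for lid, members in self.lineages.items():
            gens = [self.population(m).generation for m in members]
            if any(b < a for a, b in zip(gens, gens[1:])):
                raise ValidationError(
                    f"lineage {lid}: populations must be ordered by "
                    f"non-decreasing generation number"
                )

    # -- lookups ------------------------------------------------------------
    def population(self, population_id: str) -> Population:
        for p in self.populations:
            if p.population_id == population_id:
                return p
        raise DataError(f"no population {population_id!r} in matrix")

    def population_index(self, population_id: str) -> int:
        for j, p in enumerate(self.populations):
            if p.population_id == population_id:
                return j
        raise DataError(f"no population {population_id!r} in matrix")

    def site_index(self, genome_position: int) -> int:
        for i, s in enumerate(self.sites):
            if s.genome_position == genome_position:
                return i
        raise DataError(f"no site at genome position {genome_position}")

    def status_of(self, genome_position: int, population_id: str) -> Status:
        return self.status[self.site_index(genome_position)][
            self.population_index(population_id)]

    def lineage_populations(self, lineage_id: str) -> list[Population]:
        if lineage_id not in self.lineages:
            raise DataError(f"no lineage {lineage_id!r} in matrix")
        return [self.population(pid) for pid in self.lineages[lineage_id]]


def read_mutation_matrix(path) -> MutationStatusMatrix:
    """Read a mutation-status TSV.

    Layout: ``#``-comment lines declare population generations
    (``# generation<TAB>id=N ...``), lineage membership
    (``# lineage<TAB>name<TAB>id1,id2,...``) and free-text notes
    (``# note<TAB>...``); then a header row
    ``genome_position  ancestral  evolved  <pop> ...`` followed by one row
    per site with blank/±/+ status cells (``0``/``0.5``/``1`` accepted).
    """
    generations: dict[str, float] = {}
    lineages: dict[str, list[str]] = {}
    notes: list[str] = []
    header = None
    data_rows: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh.read().splitlines(), start=1):
            if ln.startswith("#"):
                parts = ln[1:].strip("\n").split("\t")
                key = parts[0].strip()
                if key == "generation":
                    for item in parts[1:]:
                        pid, _, gen = item.partition("=")
                        generations[pid.strip()] = float(gen)
                elif key == "lineage" and len(parts) >= 3:
                    lineages[parts[1].strip()] = [
                        x.strip() for x in parts[2].split(",")]
                elif key == "note" and len(parts) >= 2:
                    notes.append(parts[1])
                continue
            if not ln.strip():
                continue
            if header is None:
                header = ln.split("\t")
            else:
                data_rows.append((lineno, ln.split("\t")))
    if header is None:
        raise FormatError(f"mutation matrix {path}: no header row")
    fixed_cols = ["genome_position", "ancestral", "evolved"]
    if header[:3] != fixed_cols:
        raise FormatError(
            f"mutation matrix {path}: first columns must be {fixed_cols}, "
            f"got {header[:3]}"
        )
    pop_ids = header[3:]
    if not pop_ids:
        raise FormatError(f"mutation matrix {path}: no population columns")
    populations = []
    for pid in pop_ids:
        if pid not in generations:
            raise FormatError(
                f"mutation matrix {path}: population {pid!r} has no "
                f"'# generation' declaration"
            )
        populations.append(Population(pid, generations[pid]))

    sites, status = [], []
    for lineno, cells in data_rows:
        cells = cells + [""] * (len(header) - len(cells))  # trailing blanks
        sites.append(Site(int(cells[0].replace(",", "")), cells[1], cells[2]))
        row = []
        for j, raw in enumerate(cells[3:len(header)]):
            symbol = raw.strip()
            if symbol not in STATUS_FROM_SYMBOL:
                raise FormatError(
                    f"mutation matrix {path}: line {lineno}, population "
                    f"{pop_ids[j]!r}: unknown status symbol {raw!r}"
                )
            row.append(STATUS_FROM_SYMBOL[symbol])
        status.append(row)
    return MutationStatusMatrix(sites, populations, status, lineages, notes)


def write_mutation_matrix(matrix: MutationStatusMatrix, path) -> None:
    """Write the matrix in the canonical TSV layout (round-trips exactly)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# generation\t" + "\t".join(
            f"{p.population_id}={p.generation:g}" for p in matrix.populations) + "\n")
        for lid, members in matrix.lineages.items():
            fh.write(f"# lineage\t{lid}\t{','.join(members)}\n")
        for note in matrix.notes:
            fh.write(f"# note\t{note}\n")
        fh.write("genome_position\tancestral\tevolved\t" + "\t".join(
            p.population_id for p in matrix.populations) + "\n")
        for site, row in zip(matrix.sites, matrix.status):
            fh.write("\t".join(
                [str(site.genome_position), site.ancestral_nt, site.evolved_nt]
                + [SYMBOL_FROM_STATUS[s] for s in row]) + "\n")


# ---------------------------------------------------------------------------
# Fitness assays
# ---------------------------------------------------------------------------

@dataclass
class FitnessAssayRecord:
    """One replicate of a cross-coculture fitness assay.

    Host fitness uses the OD600 at 7 h over the protocol's initial 0.03;
    phage fitness uses the larger of the 7 h and late (22–29.5 h) free-phage
    titres over the titre just after infection.
    """

    host_id: str
    phage_id: str
    replicate_id: int
    od600_initial: float = 0.03
    od600_7h: Optional[float] = None
    pfu_0h: Optional[float] = None
    pfu_7h: Optional[float] = None
    pfu_late: Optional[float] = None

    def __post_init__(self):
        if not (math.isfinite(self.od600_initial) and self.od600_initial > 0):
            raise ValidationError("od600_initial must be > 0")
        for name in ("od600_7h", "pfu_0h", "pfu_7h", "pfu_late"):
            _finite_nonneg(name, getattr(self, name))


FITNESS_COLUMNS = ["host_id", "phage_id", "replicate_id", "od600_initial",
                   "od600_7h", "pfu_0h", "pfu_7h", "pfu_late"]


def read_fitness_assays(path) -> list[FitnessAssayRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in ("host_id", "phage_id", "replicate_id"):
        if col not in df.columns:
            raise FormatError(f"fitness assay file {path}: missing column {col!r}")
    records = []
    for i, row in df.iterrows():
        def num(col, default=None):
            raw = row[col].strip() if col in df.columns else ""
            return float(raw) if raw != "" else default
        records.append(FitnessAssayRecord(
            host_id=row["host_id"], phage_id=row["phage_id"],
            replicate_id=int(row["replicate_id"]),
            od600_initial=num("od600_initial", 0.03),
            od600_7h=num("od600_7h"), pfu_0h=num("pfu_0h"),
            pfu_7h=num("pfu_7h"), pfu_late=num("pfu_late"),
        ))
    return records


def write_fitness_assays(records: Sequence[FitnessAssayRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(FITNESS_COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join([
                r.host_id, r.phage_id, str(r.replicate_id),
                _fmt(r.od600_initial), _fmt(r.od600_7h), _fmt(r.pfu_0h),
                _fmt(r.pfu_7h), _fmt(r.pfu_late)]) + "\n")
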