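"""Generation bookkeeping and fitness statistics for serial-passage lines.

Replication generations follow the doubling relation N_f/N_i = 2^g, so a
passage contributes g = log2(N_f/N_i) generations; cumulative totals are the
prefix sums over passages, with the initial density of passage d (> 1)
reconstructed as the previous final density over the dilution factor.  Host
fitness is log10(OD600 at 7 h / 0.03) and phage fitness is
log10(max(PFU at 7 h, late PFU) / PFU at 0 h), matching the cross-coculture
assay protocol.  Fitness is computed per replicate and never averaged
silently.

Note: during heavy lysis early in a coculture the cell-generation count
underestimates true divisions (dead cells are invisible to CFU); the
estimator is reproduced as defined, without correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import (DataError, FitnessAssayRecord, PassageRecord)


# ---------------------------------------------------------------------------
# Generations
# ---------------------------------------------------------------------------

def passage_generations(n_i: float, n_f: float) -> float:
    """Replication generations across one passage: log2(n_f / n_i).

    Negative when the population shrank.  Densities must be positive.
    """
    if not (n_i > 0 and n_f > 0):
        raise DataError(f"densities must be > 0, got n_i={n_i!r}, n_f={n_f!r}")
    return math.log2(n_f / n_i)


def amplification_fold(n_i: float, n_f: float) -> float:
    """Fold-amplification across one passage: n_f / n_i."""
    if not (n_i > 0 and n_f > 0):
        raise DataError(f"densities must be > 0, got n_i={n_i!r}, n_f={n_f!r}")
    return n_f / n_i


@dataclass
class GenerationSeries:
    """Per-passage and cumulative generation counts for one lineage."""

    lineage_id: str
    entity: str  # "phage" or "cells"
    days: list[int] = field(default_factory=list)
    per_passage: np.ndarray = field(default_factory=lambda: np.empty(0))
    cumulative: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def total(self) -> float:
        return float(self.cumulative[-1]) if len(self.cumulative) else 0.0


def cumulative_generations(records: Sequence[PassageRecord],
                           entity: str = "phage") -> GenerationSeries:
    """Cumulative generations over an ordered passage series.

    For day d > 1 the initial density is N_f(d-1) / dilution_factor(d); the
    first record uses its stored initial density.  ``entity`` selects the
    PFU ("phage") or CFU ("cells") fields.
    """
    if entity not in ("phage", "cells"):
        raise DataError(f"entity must be 'phage' or 'cells', got {entity!r}")
    i_attr, f_attr = (("n_i_phage", "n_f_phage") if entity == "phage"
                      else ("n_i_cell", "n_f_cell"))
    lineage = records[0].lineage_id if records else ""
    days, gs = [], []
    prev_final: Optional[float] = None
    for r in records:
        n_f = getattr(r, f_attr)
        if n_f is None:
            raise DataError(f"day {r.day_index}: missing final {entity} density")
        if prev_final is None:
            n_i = getattr(r, i_attr)
            if n_i is None:
                raise DataError(
                    f"day {r.day_index}: missing initial {entity} density")
        else:
            n_i = prev_final / r.dilution_factor
        gs.append(passage_generations(n_i, n_f))
        days.append(r.day_index)
        prev_final = n_f
    per = np.array(gs)
    return GenerationSeries(lineage, entity, days, per, np.cumsum(per))


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------

def host_fitness(od600_7h: float, od600_initial: float = 0.03) -> float:
    """Host fitness: log10(OD600 at 7 h / initial OD600)."""
    if not (od600_7h > 0 and od600_initial > 0):
        raise DataError("OD values must be > 0")
    return math.log10(od600_7h / od600_initial)


def phage_fitness(pfu_0h: float, pfu_7h: Optional[float] = None,
                  pfu_late: Optional[float] = None) -> float:
    """Phage fitness: log10(max(7 h, late) free-phage titre / 0 h titre).

    The late titre is the 22–29.5 h measurement; either post-infection value
    may be missing but not both.  May be negative if the phage declined.
    """
    if not pfu_0h > 0:
        raise DataError("pfu_0h must be > 0")
    candidates = [v for v in (pfu_7h, pfu_late) if v is not None]
    if not candidates:
        raise DataError("at least one post-infection titre (7 h or late) is needed")
    return math.log10(max(candidates) / pfu_0h)


@dataclass
class FitnessMatrix:
    """Hosts × phages grid of per-replicate fitness values.

    ``values[(host, phage)]`` is the list of replicate fitness values; a
    combination that was not assayed is simply missing (``NA`` in exports).
    """

    hosts: list[str]
    phages: list[str]
    values: dict[tuple[str, str], list[float]]

    def replicates(self, host: str, phage: str) -> list[float]:
        return self.values.get((host, phage), [])

    def to_frame(self) -> pd.DataFrame:
        """Replicate lists rendered as a hosts × phages DataFrame."""
        df = pd.DataFrame(index=self.hosts, columns=self.phages, dtype=object)
        for (h, p), vals in self.values.items():
            df.loc[h, p] = "/".join(f"{v:.2f}" for v in vals)
        return df


def build_fitness_matrix(
        records: Sequence[FitnessAssayRecord]) -> tuple[FitnessMatrix, FitnessMatrix]:
    """Assemble (host grid, phage grid) from per-replicate assay records.

    Replicates are preserved unaggregated.  A duplicated replicate_id within
    one host × phage cell is an error; a cell lacking the measurements for
    one of the two fitnesses is absent from that grid only.
    """
    hosts: list[str] = []
    phages: list[str] = []
    host_vals: dict[tuple[str, str], list[float]] = {}
    phage_vals: dict[tuple[str, str], list[float]] = {}
    seen: set[tuple[str, str, int]] = set()
    for r in records:
        key = (r.host_id, r.phage_id, r.replicate_id)
        if key in seen:
            raise DataError(
                f"duplicate replicate {r.replicate_id} for host {r.host_id!r} "
                f"× phage {r.phage_id!r}")
        seen.add(key)
        if r.host_id not in hosts:
            hosts.append(r.host_id)
        if r.phage_id not in phages:
            phages.append(r.phage_id)
        if r.od600_7h is not None:
            host_vals.setdefault((r.host_id, r.phage_id), []).append(
                host_fitness(r.od600_7h, r.od600_initial))
        if r.pfu_0h is not None and (r.pfu_7h is not None or r.pfu_late is not None):
            phage_vals.setdefault((r.host_id, r.phage_id), []).append(
                phage_fitness(r.pfu_0h, r.pfu_7h, r.pfu_late))
    return (FitnessMatrix(hosts, phages, host_vals),
            FitnessMatrix(hosts, phages, phage_vals))
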