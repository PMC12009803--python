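"""Per-sample clone diversity statistics.

Richness S, Shannon index H = -sum p_i log p_i over clone read-count
proportions, Shannon maximum (the largest H attainable at the observed
richness, log S — Pielou's denominator), and Shannon evenness
J = H / log S.  J is independent of the logarithm base; H is reported in
nats by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

from .extraction import CloneCountTable

logger = logging.getLogger("clonetrace")

CountsLike = Union[CloneCountTable, Mapping, Sequence]


@dataclass(frozen=True)
class DiversityStats:
    """Diversity summary for one sample at a read-count threshold."""

    sample_id: str
    richness_S: int
    total_reads_N: int
    shannon_H: float
    shannon_max: float
    evenness_J: float
    min_reads_threshold: int = 1
    log_base: float = math.e

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "richness_S": self.richness_S,
            "total_reads_N": self.total_reads_N,
            "shannon_H": self.shannon_H,
            "shannon_max": self.shannon_max,
            "evenness_J": self.evenness_J,
            "min_reads_threshold": self.min_reads_threshold,
            "log_base": self.log_base,
        }


def _as_counts(table: CountsLike, min_reads: int):
    if min_reads < 1:
        raise ValueError(f"min_reads must be >= 1, got {min_reads}")
    if isinstance(table, CloneCountTable):
        sample_id, values = table.sample_id, list(table.counts.values())
    elif isinstance(table, Mapping):
        sample_id, values = "sample", list(table.values())
    else:
        sample_id, values = "sample", list(table)
    counts = np.asarray(values, dtype=np.int64)
    if counts.size and counts.min() <= 0:
        raise ValueError("counts must be strictly positive")
    return sample_id, counts[counts >= min_reads]


def shannon_stats(
    table: CountsLike,
    min_reads: int = 1,
    base: float = math.e,
    max_mode: str = "observed",
    whitelist_size: int = 0,
) -> DiversityStats:
    """Compute richness, Shannon index, Shannon maximum and evenness.

    With retained counts c_i and p_i = c_i / N:  H = -sum p_i log p_i,
    shannon_max = log S with S the retained richness (``max_mode='observed'``,
    the Pielou convention) or log(whitelist_size) (``max_mode='whitelist'``),
    J = H / shannon_max.  Degenerate samples follow the conventions
    S <= 1 => J = 0 and an empty sample yields all-zero stats with a warning
    rather than an error, so batch runs survive failed samples.
    """
    if max_mode not in ("observed", "whitelist"):
        raise ValueError(f"unknown max_mode {max_mode!r}")
    if max_mode == "whitelist" and whitelist_size < 1:
        raise ValueError("max_mode='whitelist' requires whitelist_size >= 1")
    sample_id, counts = _as_counts(table, min_reads)
    S = int(counts.size)
    N = int(counts.sum())
    if S == 0:
        logger.warning("%s: no clones at min_reads=%d; returning zero stats", sample_id, min_reads)
        return DiversityStats(sample_id, 0, 0, 0.0, 0.0, 0.0, min_reads, base)
    log_scale = math.log(base)
    p = counts / N
    H = float(-(p * np.log(p)).sum()) / log_scale
    if S == 1:
        H = 0.0
    if max_mode == "observed":
        H_max = math.log(S) / log_scale
    else:
        H_max = math.log(whitelist_size) / log_scale
    J = H / H_max if H_max > 0 else 0.0
    return DiversityStats(sample_id, S, N, H, H_max, J, min_reads, base)


def count_unique(table: CountsLike, min_reads: int = 1) -> int:
    """Number of distinct clones with at least ``min_reads`` matched reads."""
    _, counts = _as_counts(table, min_reads)
    return int(counts.size)


def rank_abundance(table: CountsLike):
    """Rank-abundance curve: [(1, biggest count), (2, next), ...].

    Ties are broken by clone-key lexicographic order so the output is
    deterministic; an empty table yields an empty sequence.
    """
    if isinstance(table, CloneCountTable):
        items = table.counts.items()
    elif isinstance(table, Mapping):
        items = table.items()
    else:
        items = ((str(i), c) for i, c in enumerate(table))
    ordered = sorted(items, key=lambda kv: (-kv[1], kv[0]))
    return [(rank, count) for rank, (_, count) in enumerate(ordered, start=1)]
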