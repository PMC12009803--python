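"""Synthetic barcoding experiment with planted ground truth.

Emulates the lineage-tracing experiment end to end: random BC14/BC30
library construction, lentiviral transduction of a founder hiPSC pool at a
low rate (default 12%, the verified rate; unbarcoded cells are excluded,
standing in for puromycin selection), clonal expansion, stage-wise
bottleneck sampling along a differentiation protocol, and amplicon read
generation with i.i.d. per-base substitution errors.

Bottlenecks are modeled with a single knob per stage: clone growth
(deterministic doubling, or clone-specific stochastic growth) followed by
sampling cells without replacement (multivariate hypergeometric).  The
sampled cells serve both as the sequenced aliquot and as the population
propagated to the next stage.

Everything is deterministic under the configured seed; identical configs
produce byte-identical FASTQ output.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .extraction import BC14_LENGTH, BC30_LENGTH, BarcodeWhitelist, ReadLayout

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

#: default amplicon layout: BC14 | 4-nt spacer | BC30 (an assumption —
#: vendor kits differ; override via ReadLayout).
DEFAULT_SPACER = "TGGT"


def default_layout() -> ReadLayout:
    return ReadLayout.with_spacer(DEFAULT_SPACER)


# Stage plans mirroring the two differentiation protocols' harvest numbers
# (label, cells sampled for sequencing, doublings before the harvest).
# Protocol "iMac": precursors harvested mid-protocol, 2M of 4M mature
# macrophages sequenced.  Protocol "ST": HPC-first route — 1.5M of 3M HPCs,
# then 1.4M precursors, then the final 1M macrophages.
STAGE_PLAN_IMAC: List[Tuple[str, int, int]] = [
    ("iMacPre", 1_500_000, 1),
    ("iMac", 2_000_000, 1),
]
STAGE_PLAN_ST: List[Tuple[str, int, int]] = [
    ("iHPC", 1_500_000, 1),
    ("iMacPre", 1_400_000, 0),
    ("iMacST", 1_000_000, 0),
]
STAGE_PLANS = {"imac": STAGE_PLAN_IMAC, "st": STAGE_PLAN_ST}


@dataclass
class SimulationConfig:
    """Parameters of the simulated barcoding experiment.

    Defaults are the experiment's stated conditions: a 1.5-million-cell
    founder group, 12% transduction, and whitelist sizes emulating a
    ~10-million-combination barcode library.  ``scale`` multiplies all cell
    numbers (founder and stage harvests) for desk-scale runs; the whitelist
    is a library property and is not scaled.
    """

    seed: int
    n_bc14: int = 500
    n_bc30: int = 20_000
    n_founder_cells: int = 1_500_000
    transduction_rate: float = 0.12
    moi_model: str = "bernoulli_single"
    expansion_doublings: int = 5
    stage_plan: List[Tuple[str, int, int]] = field(
        default_factory=lambda: list(STAGE_PLAN_ST)
    )
    reads_per_cell: float = 10.0
    per_base_error: float = 0.001
    layout: ReadLayout = field(default_factory=default_layout)
    scale: float = 1.0
    growth_model: str = "deterministic"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        # 0 is allowed as a degenerate case (no cell barcoded -> empty founder)
        if not (0.0 <= self.transduction_rate < 1.0):
            raise ValueError("transduction_rate must be in [0, 1)")
        if not (0.0 <= self.per_base_error < 1.0):
            raise ValueError("per_base_error must be in [0, 1)")
        if self.moi_model not in ("bernoulli_single", "poisson"):
            raise ValueError(f"unknown moi_model {self.moi_model!r}")
        if self.growth_model not in ("deterministic", "stochastic"):
            raise ValueError(f"unknown growth_model {self.growth_model!r}")
        if self.n_bc14 < 1 or self.n_bc30 < 1:
            raise ValueError("whitelist sizes must be >= 1")
        if self.reads_per_cell < 0:
            raise ValueError("reads_per_cell must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        plan = []
        for entry in self.stage_plan:
            if len(entry) == 2:
                label, cells = entry
                doublings = 1
            else:
                label, cells, doublings = entry
            plan.append((str(label), int(cells), int(doublings)))
        self.stage_plan = plan

    def scaled(self, cells: int) -> int:
        return max(1, int(round(cells * self.scale)))

    @property
    def founder_sample_cells(self) -> int:
        return self.scaled(self.n_founder_cells)


@dataclass
class StagePopulation:
    """Per-clone cell counts at a named differentiation stage."""

    stage_label: str
    clone_cells: dict
    n_multi_integration: int = 0

    def __post_init__(self):
        if any(c <= 0 for c in self.clone_cells.values()):
            raise ValueError("clone cell counts must be strictly positive")
        self.clone_cells = {k: int(v) for k, v in self.clone_cells.items()}

    @property
    def total_cells(self) -> int:
        return sum(self.clone_cells.values())

    @property
    def richness(self) -> int:
        return len(self.clone_cells)


# ---------------------------------------------------------------------------
# Library construction
# ---------------------------------------------------------------------------

def _random_kmers(n: int, length: int, rng: np.random.Generator) -> List[str]:
    if n > 4 ** length:
        raise ValueError(f"cannot draw {n} distinct {length}-mers from 4^{length} possibilities")
    out: set = set()
    while len(out) < n:
        batch = rng.integers(0, 4, size=(n - len(out), length), dtype=np.uint8)
        for row in _BASES[batch]:
            if len(out) >= n:
                break
            out.add(row.tobytes().decode())
    return sorted(out)


def build_library(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> BarcodeWhitelist:
    """Random whitelist of pairwise-distinct BC14 and BC30 sequences."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    bc14 = _random_kmers(config.n_bc14, BC14_LENGTH, rng)
    bc30 = _random_kmers(config.n_bc30, BC30_LENGTH, rng)
    return BarcodeWhitelist(
        bc14_set=frozenset(bc14),
        bc30_set=frozenset(bc30),
        source_name=f"synthetic(n14={config.n_bc14}, n30={config.n_bc30}, seed={config.seed})",
    )


# ---------------------------------------------------------------------------
# Transduction and bottleneck stages
# ---------------------------------------------------------------------------

def _pair_keys(idx: np.ndarray, bc14: List[str], bc30: List[str]) -> List[str]:
    n30 = len(bc30)
    return [bc14[i // n30] + bc30[i % n30] for i in idx]


def simulate_transduction(
    config: SimulationConfig,
    whitelist: BarcodeWhitelist,
    rng: Optional[np.random.Generator] = None,
) -> StagePopulation:
    """Barcode the founder pool; unbarcoded cells are selected away.

    ``bernoulli_single``: each cell receives one random BC14-BC30 pair with
    probability ``transduction_rate``.  ``poisson``: integrations per cell
    are Poisson with lambda solved from P(>=1) = transduction_rate; cells
    with several integrations keep their first pair as clone identity and
    are tallied in ``n_multi_integration``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    bc14 = sorted(whitelist.bc14_set)
    bc30 = sorted(whitelist.bc30_set)
    n_pairs = len(bc14) * len(bc30)
    n_cells = config.scaled(config.n_founder_cells)
    n_barcoded = int(rng.binomial(n_cells, config.transduction_rate))
    n_multi = 0
    if config.moi_model == "poisson":
        lam = -math.log1p(-config.transduction_rate)
        m = rng.poisson(lam, size=n_barcoded)
        while True:  # resample the zero-truncated tail
            zeros = m == 0
            if not zeros.any():
                break
            m[zeros] = rng.poisson(lam, size=int(zeros.sum()))
        n_multi = int((m > 1).sum())
    idx = rng.integers(0, n_pairs, size=n_barcoded)
    keys, counts = np.unique(idx, return_counts=True)
    clone_cells = dict(zip(_pair_keys(keys, bc14, bc30), counts.tolist()))
    return StagePopulation(stage_label="founder", clone_cells=clone_cells,
                           n_multi_integration=n_multi)


def simulate_stage(
    population: StagePopulation,
    cells_sampled: int,
    growth_doublings: int = 0,
    rng: Optional[np.random.Generator] = None,
    growth_model: str = "deterministic",
    stage_label: str = "stage",
) -> StagePopulation:
    """Grow the population, then sample cells without replacement.

    Growth multiplies each clone by 2**doublings, either exactly
    (``deterministic``) or with clone-specific Poisson noise
    (``stochastic``, mean 2**doublings per cell; clones may go extinct).
    Sampling is multivariate hypergeometric over cells, the bottleneck
    proper.  Requesting more cells than the post-growth total is an error.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    keys = list(population.clone_cells.keys())
    cells = np.array([population.clone_cells[k] for k in keys], dtype=np.int64)
    factor = 2 ** growth_doublings
    if growth_model == "deterministic":
        cells = cells * factor
    elif growth_model == "stochastic":
        cells = rng.poisson(cells * float(factor)).astype(np.int64)
        alive = cells > 0
        keys = [k for k, a in zip(keys, alive) if a]
        cells = cells[alive]
    else:
        raise ValueError(f"unknown growth_model {growth_model!r}")
    total = int(cells.sum())
    if cells_sampled > total:
        raise ValueError(
            f"cannot sample {cells_sampled} cells from a population of {total}"
        )
    if cells_sampled == total:
        sampled = cells
    else:
        method = "marginals" if total > 10_000 else "count"
        sampled = rng.multivariate_hypergeometric(cells, cells_sampled, method=method)
    clone_cells = {k: int(c) for k, c in zip(keys, sampled) if c > 0}
    return StagePopulation(stage_label=stage_label, clone_cells=clone_cells,
                           n_multi_integration=population.n_multi_integration)


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

def _clone_template(key: str, layout: ReadLayout) -> str:
    b14, b30 = key[:BC14_LENGTH], key[BC14_LENGTH:]
    gap = layout.bc30_offset - (layout.bc14_offset + layout.bc14_length)
    filler = layout.spacer if layout.spacer is not None else "A" * gap
    return "A" * layout.bc14_offset + b14 + filler + b30


def generate_reads(
    population: StagePopulation,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    fastq_path=None,
):
    """Sequence a population: Poisson read depth plus substitution errors.

    Per clone, the read count is Poisson(reads_per_cell x cells); each read
    is the layout template carrying the clone's barcodes, with i.i.d.
    per-base substitutions at ``per_base_error`` and a constant dummy
    quality string (base qualities are never used downstream).

    Returns ``(reads, truth)`` where ``reads`` is a list of
    (name, sequence, quality) tuples — or ``fastq_path`` if given, with the
    records written there (gzip if the suffix is .gz) — and ``truth`` is
    the planted clone -> cell count mapping.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    layout = config.layout
    keys = sorted(population.clone_cells)
    truth = {k: population.clone_cells[k] for k in keys}
    cells = np.array([truth[k] for k in keys], dtype=np.int64)
    n_reads = rng.poisson(config.reads_per_cell * cells) if keys else np.zeros(0, dtype=np.int64)

    read_len = layout.min_read_length
    total = int(n_reads.sum())
    if total == 0:
        reads: List[Tuple[str, str, str]] = []
    else:
        templates = np.frombuffer(
            "".join(_clone_template(k, layout) for k in keys).encode(), dtype=np.uint8
        ).reshape(len(keys), read_len)
        mat = np.repeat(templates, n_reads, axis=0).copy()
        if config.per_base_error > 0:
            err = rng.random(mat.shape) < config.per_base_error
            n_err = int(err.sum())
            if n_err:
                shift = rng.integers(1, 4, size=n_err, dtype=np.uint8)
                mat[err] = _BASES[(_BASE_INDEX[mat[err]] + shift) % 4]
        qual = "I" * read_len
        origin = np.repeat(np.arange(len(keys)), n_reads)
        seqs = mat.tobytes().decode()
        reads = [
            (f"{population.stage_label}_read{i}_clone{origin[i]}",
             seqs[i * read_len:(i + 1) * read_len], qual)
            for i in range(total)
        ]

    if fastq_path is None:
        return reads, truth
    fastq_path = Path(fastq_path)
    opener = gzip.open if fastq_path.suffix == ".gz" else open
    with opener(fastq_path, "wt") as fh:
        for name, seq, q in reads:
            fh.write(f"@{name}\n{seq}\n+\n{q}\n")
    return fastq_path, truth


def run_stage_plan(
    config: SimulationConfig,
    whitelist: Optional[BarcodeWhitelist] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[StagePopulation]:
    """Full cell-level experiment: transduce, expand, sample every stage.

    Returns the sequenced populations in order: the founder aliquot first,
    then one population per stage-plan entry.  Each sequenced aliquot is
    also the population carried into the next stage (the bottleneck model).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if whitelist is None:
        whitelist = build_library(config, rng)
    pool = simulate_transduction(config, whitelist, rng)
    founder = simulate_stage(
        pool, config.founder_sample_cells, config.expansion_doublings,
        rng, config.growth_model, stage_label="hiPSC",
    )
    stages = [founder]
    current = founder
    for label, cells, doublings in config.stage_plan:
        current = simulate_stage(
            current, config.scaled(cells), doublings, rng,
            config.growth_model, stage_label=label,
        )
        stages.append(current)
    return stages
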