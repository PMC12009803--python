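"""Cross-stage lineage retention: quantifying the differentiation bottleneck.

Compares clone count tables between a founder population and later
differentiation stages: how many founder barcodes survive, how richness
and evenness change, and an unpaired t-test helper for group comparisons.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .diversity import DiversityStats, rank_abundance, shannon_stats
from .extraction import CloneCountTable


@dataclass(frozen=True)
class RetentionStats:
    """Founder-vs-stage clone set comparison.

    ``retained_fraction`` is the share of founder clones still observed at
    the stage; ``richness_ratio`` is stage richness over founder richness
    (these differ when the stage contains clones missed in the founder
    sample — founder sampling itself is incomplete, so novel-in-stage
    clones are reported, not dropped).
    """

    founder_sample: str
    stage_sample: str
    founder_richness: int
    stage_richness: int
    shared_clones: int
    retained_fraction: float
    novel_in_stage: int
    jaccard: float
    richness_ratio: float
    evenness_delta: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def retention(
    founder: CloneCountTable,
    stage: CloneCountTable,
    min_reads: int = 1,
) -> RetentionStats:
    """Set statistics between thresholded founder and stage clone sets."""
    if founder.clone_key_mode != stage.clone_key_mode:
        raise ValueError(
            f"clone_key_mode mismatch: {founder.clone_key_mode!r} vs {stage.clone_key_mode!r}"
        )
    f_set = founder.clone_keys(min_reads)
    s_set = stage.clone_keys(min_reads)
    if not f_set:
        raise ValueError(f"founder sample {founder.sample_id!r} has no clones at min_reads={min_reads}")
    shared = len(f_set & s_set)
    union = len(f_set | s_set)
    j_f = shannon_stats(founder, min_reads=min_reads).evenness_J
    j_s = shannon_stats(stage, min_reads=min_reads).evenness_J
    return RetentionStats(
        founder_sample=founder.sample_id,
        stage_sample=stage.sample_id,
        founder_richness=len(f_set),
        stage_richness=len(s_set),
        shared_clones=shared,
        retained_fraction=shared / len(f_set),
        novel_in_stage=len(s_set - f_set),
        jaccard=shared / union if union else 0.0,
        richness_ratio=len(s_set) / len(f_set),
        evenness_delta=j_s - j_f,
    )


def bottleneck_report(
    samples: Sequence[CloneCountTable],
    labels: Optional[Sequence[str]] = None,
    min_reads: int = 1,
    out_dir=None,
    plots: bool = False,
    seed: Optional[int] = None,
) -> dict:
    """Stage-by-stage bottleneck report; the first sample is the founder.

    Returns (and optionally serializes as JSON + TSV + rank-abundance plot)
    per-sample diversity statistics, founder->stage retention statistics,
    and rank-abundance curves.
    """
    if len(samples) < 2:
        raise ValueError("bottleneck_report needs >= 2 samples (founder first)")
    if labels is None:
        labels = [t.sample_id for t in samples]
    if len(labels) != len(samples):
        raise ValueError("labels and samples length mismatch")
    modes = {t.clone_key_mode for t in samples}
    if len(modes) > 1:
        raise ValueError(f"mismatched clone_key modes across samples: {sorted(modes)}")

    diversity = [shannon_stats(t, min_reads=min_reads) for t in samples]
    founder = samples[0]
    ret = [retention(founder, t, min_reads=min_reads) for t in samples[1:]]
    report = {
        "schema_version": 1,
        "min_reads": min_reads,
        "seed": seed,
        "labels": list(labels),
        "founder": labels[0],
        "diversity": [d.as_dict() for d in diversity],
        "retention": [r.as_dict() for r in ret],
        "richness_ratios": {
            lab: r.richness_ratio for lab, r in zip(labels[1:], ret)
        },
        "rank_abundance": {
            lab: rank_abundance(t) for lab, t in zip(labels, samples)
        },
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(out_dir / "diversity.tsv", "w") as fh:
            cols = ["label", "richness_S", "total_reads_N", "shannon_H",
                    "shannon_max", "evenness_J"]
            fh.write("\t".join(cols) + "\n")
            for lab, d in zip(labels, diversity):
                fh.write(f"{lab}\t{d.richness_S}\t{d.total_reads_N}"
                         f"\t{d.shannon_H:.6f}\t{d.shannon_max:.6f}\t{d.evenness_J:.6f}\n")
        with open(out_dir / "retention.tsv", "w") as fh:
            cols = ["stage", "founder_richness", "stage_richness", "shared_clones",
                    "retained_fraction", "novel_in_stage", "jaccard",
                    "richness_ratio", "evenness_delta"]
            fh.write("\t".join(cols) + "\n")
            for lab, r in zip(labels[1:], ret):
                fh.write(f"{lab}\t{r.founder_richness}\t{r.stage_richness}"
                         f"\t{r.shared_clones}\t{r.retained_fraction:.6f}"
                         f"\t{r.novel_in_stage}\t{r.jaccard:.6f}"
                         f"\t{r.richness_ratio:.6f}\t{r.evenness_delta:.6f}\n")
        if plots:
            _plot_rank_abundance(report["rank_abundance"], out_dir / "rank_abundance.png")
    return report


def _plot_rank_abundance(curves: dict, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        if not curve:
            continue
        ranks, counts = zip(*curve)
        ax.plot(ranks, counts, label=label, lw=1.2)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("clone rank")
    ax.set_ylabel("read count")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    p_value: float
    stars: str
    welch: bool


def significance_stars(p: float) -> str:
    """Star annotation at the conventional thresholds."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(values_a, values_b, welch: bool = True) -> TTestResult:
    """Two-sided unpaired t-test between two groups (Welch by default).

    Each group needs >= 2 values.  Two groups with zero variance and equal
    means yield t = 0, p = 1 by convention (rather than 0/0).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values for an unpaired t-test")
    if a.std() == 0.0 and b.std() == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, "ns", welch)
        t = math.inf if a.mean() > b.mean() else -math.inf
        return TTestResult(t, 0.0, "****", welch)
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(float(t), float(p), significance_stars(float(p)), welch)
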