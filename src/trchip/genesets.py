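"""Regulated-gene selection and Venn / partition / fold-change analytics.

Builds T3-regulated gene sets from expression tables (default: 1.5-fold
regulation at FDR < 0.05 — the fold cutoff inclusive on the log2 scale, the
FDR strictly below threshold) and computes the overlap statistics relating
TR-bound gene sets across treatments and genotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionRecord

__all__ = [
    "GeneSet",
    "VennResult",
    "select_regulated",
    "venn",
    "overlap_percent",
    "partition_by_genotype",
    "fold_change_matrix",
    "plot_fold_change_heatmap",
]


@dataclass(frozen=True)
class GeneSet:
    label: str
    gene_ids: frozenset

    def __len__(self) -> int:
        return len(self.gene_ids)

    @staticmethod
    def of(label: str, genes) -> "GeneSet":
        return GeneSet(label, frozenset(genes))


@dataclass(frozen=True)
class VennResult:
    """Exact region cardinalities of a 2- or 3-set Venn decomposition.

    ``regions`` is keyed by the sorted tuple of labels whose exclusive
    region it is, e.g. ``("A",)`` for A-only and ``("A", "B")`` for the
    exclusive A∩B region.  ``percentages`` reports, for each pair, the
    rounded integer share of the full pairwise intersection in each set.
    """

    labels: tuple
    regions: Mapping[tuple, int]
    union_size: int
    percentages: Mapping[str, int]


def select_regulated(
    records: Sequence[ExpressionRecord],
    genotype: str,
    direction: str,
    fold_cutoff: float = 1.5,
    fdr_cutoff: float = 0.05,
) -> GeneSet:
    """Genes up- or down-regulated beyond ``fold_cutoff`` at FDR < cutoff.

    Up: log2fc ≥ log2(fold_cutoff); down: log2fc ≤ −log2(fold_cutoff);
    both require fdr strictly below ``fdr_cutoff``.  Genes with absent
    values for the requested genotype are excluded.
    """
    if genotype not in ("wt", "ko"):
        raise ValueError(f"genotype must be 'wt' or 'ko', got {genotype!r}")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if fold_cutoff <= 1:
        raise ValueError(f"fold_cutoff must exceed 1, got {fold_cutoff}")
    if not (0 < fdr_cutoff <= 1):
        raise ValueError(f"fdr_cutoff must be in (0, 1], got {fdr_cutoff}")
    threshold = math.log2(fold_cutoff)
    selected = set()
    for r in records:
        log2fc = r.log2fc_wt if genotype == "wt" else r.log2fc_ko
        fdr = r.fdr_wt if genotype == "wt" else r.fdr_ko
        if log2fc is None or fdr is None:
            continue
        if fdr >= fdr_cutoff:
            continue
        if direction == "up" and log2fc >= threshold:
            selected.add(r.gene_id)
        elif direction == "down" and log2fc <= -threshold:
            selected.add(r.gene_id)
    return GeneSet.of(f"{genotype}_{direction}", selected)


def venn(sets: Sequence[GeneSet]) -> VennResult:
    """Region cardinalities for 2 or 3 gene sets by exact set algebra."""
    if len(sets) < 2:
        raise ValueError("venn requires at least 2 sets")
    if len(sets) > 3:
        raise ValueError("venn supports at most 3 sets")
    labels = tuple(s.label for s in sets)
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate set labels {labels}")
    universe = frozenset().union(*(s.gene_ids for s in sets))
    regions: dict = {}
    for gene in universe:
        membership = tuple(
            sorted(s.label for s in sets if gene in s.gene_ids)
        )
        regions[membership] = regions.get(membership, 0) + 1
    # report every possible region, including empty ones
    from itertools import combinations

    for r in range(1, len(sets) + 1):
        for combo in combinations(sorted(labels), r):
            regions.setdefault(combo, 0)
    percentages = {}
    for a, b in combinations(sets, 2):
        inter = len(a.gene_ids & b.gene_ids)
        if a.gene_ids:
            percentages[f"{a.label}∩{b.label} of {a.label}"] = overlap_percent(
                inter, len(a.gene_ids)
            )
        if b.gene_ids:
            percentages[f"{a.label}∩{b.label} of {b.label}"] = overlap_percent(
                inter, len(b.gene_ids)
            )
    return VennResult(
        labels=labels,
        regions=regions,
        union_size=len(universe),
        percentages=percentages,
    )


def overlap_percent(part: int, whole: int) -> int:
    """Integer percentage of ``part`` in ``whole``, rounded half away from 0."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    if part < 0 or part > whole:
        raise ValueError(f"part {part} outside [0, {whole}]")
    return int(math.floor(100.0 * part / whole + 0.5))


def partition_by_genotype(
    wt_bound: GeneSet, ko_bound: GeneSet
) -> dict[str, GeneSet]:
    """Disjoint partition {wt_only, common, ko_only} of WT∪KO bound genes."""
    return {
        "wt_only": GeneSet.of("wt_only", wt_bound.gene_ids - ko_bound.gene_ids),
        "common": GeneSet.of("common", wt_bound.gene_ids & ko_bound.gene_ids),
        "ko_only": GeneSet.of("ko_only", ko_bound.gene_ids - wt_bound.gene_ids),
    }


def fold_change_matrix(
    partition: Mapping[str, GeneSet],
    records: Sequence[ExpressionRecord],
) -> pd.DataFrame:
    """Log2 fold-change matrix for the heat map of genotype-partitioned genes.

    One row per partitioned gene with columns ``block``, ``log2fc_wt`` and
    ``log2fc_ko`` (NaN where unmeasured); blocks ordered wt_only, common,
    ko_only, rows within a block by descending WT log2 fold change with
    absent values last.
    """
    by_gene = {r.gene_id: r for r in records}
    rows = []
    for block in ("wt_only", "common", "ko_only"):
        if block not in partition:
            continue
        for gene in partition[block].gene_ids:
            rec = by_gene.get(gene)
            rows.append(
                {
                    "block": block,
                    "gene_id": gene,
                    "log2fc_wt": np.nan if rec is None or rec.log2fc_wt is None
                    else rec.log2fc_wt,
                    "log2fc_ko": np.nan if rec is None or rec.log2fc_ko is None
                    else rec.log2fc_ko,
                }
            )
    df = pd.DataFrame(rows, columns=["block", "gene_id", "log2fc_wt", "log2fc_ko"])
    if df.empty:
        return df
    df["_block_order"] = df["block"].map({"wt_only": 0, "common": 1, "ko_only": 2})
    df = df.sort_values(
        ["_block_order", "log2fc_wt", "gene_id"],
        ascending=[True, False, True],
        na_position="last",
    ).drop(columns="_block_order")
    return df.reset_index(drop=True)


def plot_fold_change_heatmap(matrix: pd.DataFrame, path) -> None:
    """Render the fold-change matrix as a simple diverging heat map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = matrix[["log2fc_wt", "log2fc_ko"]].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(4, 8))
    vmax = np.nanmax(np.abs(values)) if values.size else 1.0
    im = ax.imshow(values, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks([0, 1], ["WT", "TRα−/−"])
    ax.set_ylabel("genes (wt_only | common | ko_only)")
    fig.colorbar(im, label="log2 fold change (+T3 / −T3)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
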