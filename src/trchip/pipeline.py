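"""End-to-end orchestration: consensus → assign → scan → sets → enrichment.

``run_all`` reads a YAML run configuration, executes each stage in order,
writes every stage's table under the run directory and returns a
machine-readable :class:`RunReport` (also written as ``report.json``).
A missing input aborts before any stage runs; a stage failure aborts with
a message naming the stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import yaml

from . import __version__
from .assign import assign_peaks, bound_gene_set, build_windows, classify_peak_locations
from .consensus import intersect_replicates, peak_width_summary
from .enrichment import differential_enrichment, enrich
from .genesets import (
    GeneSet,
    fold_change_matrix,
    overlap_percent,
    partition_by_genotype,
    select_regulated,
    venn,
)
from .io import (
    read_expression_table,
    read_fasta,
    read_gff3_genes,
    read_gmt,
    read_peaks,
    write_tsv,
)
from .motif import HalfSiteModel, count_tres_in_peaks

__all__ = ["RunReport", "load_run_config", "run_all", "StageError"]

log = logging.getLogger("trchip")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclasses.dataclass
class RunReport:
    seed: Optional[int]
    version: str
    config: dict
    consensus_counts: dict = dataclasses.field(default_factory=dict)
    peak_location_summary: dict = dataclasses.field(default_factory=dict)
    peak_width: dict = dataclasses.field(default_factory=dict)
    bound_gene_counts: dict = dataclasses.field(default_factory=dict)
    venn: dict = dataclasses.field(default_factory=dict)
    overlap_percentages: dict = dataclasses.field(default_factory=dict)
    tre_totals: dict = dataclasses.field(default_factory=dict)
    enrichment: dict = dataclasses.field(default_factory=dict)
    differential_terms: list = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_run_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if "inputs" not in config:
        raise ValueError("run config must contain an 'inputs' section")
    return config


def _preflight(config: Mapping) -> None:
    inputs = config["inputs"]
    required = ["annotation", "peaks"]
    for key in required:
        if key not in inputs:
            raise FileNotFoundError(f"run config inputs missing {key!r}")
    paths = [inputs["annotation"]]
    for sample, reps in inputs["peaks"].items():
        paths.extend(reps.values())
    for optional in ("genome", "expression", "terms"):
        if inputs.get(optional):
            paths.append(inputs[optional])
    missing = [p for p in paths if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return out

        return inner

    return wrap


def run_all(config: Mapping, outdir) -> RunReport:
    """Execute every stage of the analysis on the configured inputs."""
    _preflight(config)
    inputs = config["inputs"]
    params = config.get("params", {})
    flank = int(params.get("flank", 5000))
    spacer = int(params.get("spacer", 4))
    fold_cutoff = float(params.get("fold_cutoff", 1.5))
    fdr_cutoff = float(params.get("fdr_cutoff", 0.05))
    enrich_fdr = float(params.get("enrichment_fdr", 0.05))
    min_width = int(params.get("consensus_min_width", 1))

    outdir = Path(outdir)
    (outdir / "consensus").mkdir(parents=True, exist_ok=True)
    (outdir / "genes").mkdir(exist_ok=True)
    report = RunReport(
        seed=config.get("seed"), version=__version__, config=dict(config)
    )

    genes = read_gff3_genes(inputs["annotation"])
    windows = build_windows(genes, flank=flank)

    @_stage("consensus")
    def stage_consensus():
        consensus = {}
        for sample in sorted(inputs["peaks"]):
            reps = {
                rep_id: read_peaks(
                    path, sample_id=sample, replicate_id=rep_id
                )
                for rep_id, path in sorted(inputs["peaks"][sample].items())
            }
            cons = intersect_replicates(
                reps, min_width=min_width, sample_id=sample
            )
            consensus[sample] = cons
            report.consensus_counts[sample] = len(cons)
            rows = []
            support_rows = []
            for c in cons:
                rows.append(
                    (
                        c.interval.chrom,
                        c.interval.start,
                        c.interval.end,
                        c.peak_id,
                        int(round(c.height)),
                        ".",
                    )
                )
                for rep_id, contributing in sorted(c.support.items()):
                    for p in contributing:
                        support_rows.append(
                            (
                                c.peak_id,
                                rep_id,
                                p.interval.chrom,
                                p.interval.start,
                                p.interval.end,
                                p.height,
                            )
                        )
            write_tsv(
                outdir / "consensus" / f"{sample}.bed",
                rows,
                header=["chrom", "start", "end", "name", "score", "strand"],
            )
            write_tsv(
                outdir / "consensus" / f"{sample}.support.tsv",
                support_rows,
                header=[
                    "consensus_id",
                    "replicate_id",
                    "chrom",
                    "start",
                    "end",
                    "height",
                ],
            )
            if cons:
                report.peak_width[sample] = peak_width_summary(cons)
        return consensus

    consensus = stage_consensus()

    @_stage("assign")
    def stage_assign():
        bound = {}
        for sample, cons in consensus.items():
            assignments = assign_peaks(cons, windows)
            genes_for_sample = bound_gene_set(assignments)
            bound[sample] = genes_for_sample
            report.bound_gene_counts[sample] = len(genes_for_sample)
            rows = [
                (
                    a.consensus_peak_id,
                    c.interval.chrom,
                    c.interval.start,
                    c.interval.end,
                    ";".join(sorted(a.gene_ids)),
                    a.category,
                )
                for a, c in zip(assignments, cons)
            ]
            write_tsv(
                outdir / "genes" / f"{sample}.assignments.tsv",
                rows,
                header=["consensus_id", "chrom", "start", "end", "gene_ids",
                        "category"],
            )
            with open(outdir / "genes" / f"{sample}.txt", "w") as fh:
                for g in sorted(genes_for_sample):
                    fh.write(g + "\n")
            labels, summary = classify_peak_locations(cons, genes, flank=flank)
            report.peak_location_summary[sample] = summary
        return bound

    bound = stage_assign()

    if inputs.get("genome"):

        @_stage("scan")
        def stage_scan():
            genome = read_fasta(inputs["genome"])
            model = HalfSiteModel(
                pattern=params.get("half_site", "RGGTCA"),
                max_mismatch=int(params.get("max_mismatch", 0)),
            )
            for sample, cons in consensus.items():
                per_peak, total = count_tres_in_peaks(
                    cons, genome, model, spacer=spacer
                )
                report.tre_totals[sample] = total
                rows = []
                for peak_id, count, hits in per_peak:
                    for h in hits:
                        rows.append(
                            (
                                h.chrom,
                                h.start,
                                h.end,
                                f"{h.half1_seq}-N{h.spacer}-{h.half2_seq}",
                                0,
                                h.strand,
                                peak_id,
                            )
                        )
                write_tsv(
                    outdir / "consensus" / f"{sample}.dr4.tsv",
                    rows,
                    header=["chrom", "start", "end", "name", "score",
                            "strand", "consensus_id"],
                )

        stage_scan()

    wt_bound = GeneSet.of(
        "wt_bound", set(bound.get("wt_minusT3", set())) | set(bound.get("wt_plusT3", set()))
    )
    ko_bound = GeneSet.of(
        "ko_bound", set(bound.get("ko_minusT3", set())) | set(bound.get("ko_plusT3", set()))
    )

    @_stage("sets")
    def stage_sets():
        if "wt_minusT3" in bound and "wt_plusT3" in bound:
            v = venn(
                [
                    GeneSet.of("wt_minusT3", bound["wt_minusT3"]),
                    GeneSet.of("wt_plusT3", bound["wt_plusT3"]),
                ]
            )
            report.venn["wt_treatment"] = {
                "regions": {"|".join(k): c for k, c in sorted(v.regions.items())},
                "union": v.union_size,
            }
        if wt_bound.gene_ids or ko_bound.gene_ids:
            v = venn([wt_bound, ko_bound])
            report.venn["genotype"] = {
                "regions": {"|".join(k): c for k, c in sorted(v.regions.items())},
                "union": v.union_size,
            }
        if not inputs.get("expression"):
            return None
        records = read_expression_table(inputs["expression"])
        up_wt = select_regulated(records, "wt", "up", fold_cutoff, fdr_cutoff)
        down_wt = select_regulated(records, "wt", "down", fold_cutoff, fdr_cutoff)
        if wt_bound.gene_ids:
            report.overlap_percentages["wt_bound_up"] = overlap_percent(
                len(wt_bound.gene_ids & up_wt.gene_ids), len(wt_bound.gene_ids)
            )
            report.overlap_percentages["wt_bound_down"] = overlap_percent(
                len(wt_bound.gene_ids & down_wt.gene_ids), len(wt_bound.gene_ids)
            )
        if up_wt.gene_ids:
            report.overlap_percentages["up_that_are_bound"] = overlap_percent(
                len(wt_bound.gene_ids & up_wt.gene_ids), len(up_wt.gene_ids)
            )
        if wt_bound.gene_ids and ko_bound.gene_ids:
            common = wt_bound.gene_ids & ko_bound.gene_ids
            report.overlap_percentages["ko_bound_also_wt"] = overlap_percent(
                len(common), len(ko_bound.gene_ids)
            )
        partition = partition_by_genotype(wt_bound, ko_bound)
        matrix = fold_change_matrix(partition, records)
        matrix.to_csv(outdir / "fold_change_matrix.tsv", sep="\t", index=False)
        return records

    stage_sets()

    if inputs.get("terms"):

        @_stage("enrich")
        def stage_enrich():
            terms = read_gmt(inputs["terms"])
            # background: annotation genes that appear in the term universe
            gmt_universe = set().union(*(t.gene_ids for t in terms))
            universe = {g.gene_id for g in genes} & gmt_universe
            background = GeneSet.of("background", universe)
            results = {}
            for label, query in (("wt", wt_bound), ("ko", ko_bound)):
                q = GeneSet.of(label, query.gene_ids & universe)
                res = enrich(q, background, terms, fdr_threshold=enrich_fdr)
                results[label] = res
                write_tsv(
                    outdir / f"enrichment_{label}.tsv",
                    [
                        (r.term_id, r.term_name, r.k, r.K, r.n, r.N,
                         r.p_value, r.fdr, r.enriched)
                        for r in res
                    ],
                    header=["term_id", "term_name", "k", "K", "n", "N",
                            "p_value", "fdr", "enriched"],
                )
                report.enrichment[label] = {
                    "n_terms": len(res),
                    "n_enriched": sum(r.enriched for r in res),
                }
            diff = differential_enrichment(results["wt"], results["ko"])
            report.differential_terms = [r.term_id for r in diff]
            with open(outdir / "differential_terms.json", "w") as fh:
                json.dump(
                    [dataclasses.asdict(r) for r in diff], fh, indent=1
                )

        stage_enrich()

    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
    return report
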