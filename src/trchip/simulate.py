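"""Synthetic ChIP-Seq study generator with machine-readable ground truth.

Emulates the design of a T3-induced intestinal-remodeling ChIP study:
two genotypes (wild type and TRα knockout) × two treatments (−T3 / +T3),
three technical peak-call replicates each.  True binding sites carry a
planted DR4 element; a configurable fraction falls inside gene-body-plus-
flank assignment windows (the rest intergenic, mirroring the observation
that most binding is intergenic).  Replicate peak calls add boundary
jitter, per-replicate dropouts and Poisson false peaks.  Knockout samples
retain each site with probability ``ko_retention``; T3-dependent sites are
detectable only under treatment.  A linked expression table upregulates a
configurable fraction of bound genes, attenuated in the knockout.

All randomness flows from the single config seed; a given config produces
byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .assign import assign_peaks, build_windows
from .io import (
    ExpressionRecord,
    GeneModel,
    GenomicInterval,
    Peak,
    TermAnnotation,
    write_expression_table,
    write_fasta,
    write_gff3,
    write_gmt,
    write_peaks,
)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "SAMPLES",
    "simulate",
    "simulate_terms",
    "fragments_for_sites",
    "evaluate_recovery",
]

SAMPLES = ("wt_minusT3", "wt_plusT3", "ko_minusT3", "ko_plusT3")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Generator parameters; defaults define the simulated study conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_200_000
    n_genes: int = 120
    gene_length_range: tuple = (2000, 6000)
    flank: int = 5000
    n_true_sites: int = 150
    fraction_sites_in_windows: float = 0.6
    site_width_range: tuple = (150, 400)
    jitter_sd: float = 25.0
    fp_rate: float = 0.1
    dropout_rate: float = 0.05
    n_replicates: int = 3
    ko_retention: float = 0.7
    t3_gain: float = 0.25
    p_up_given_bound: float = 0.19
    p_down_given_bound: float = 0.09
    effect_mean_log2fc: float = 1.5
    effect_sd_log2fc: float = 0.5
    ko_attenuation: float = 0.5
    min_peak_width: int = 50
    n_terms: int = 0
    term_size_range: tuple = (10, 60)

    # inter-gene spacing that keeps assignment windows of neighbours
    # disjoint, so each planted genic site maps to exactly one gene
    @property
    def min_gene_gap(self) -> int:
        return 2 * self.flank + 500

    def validate(self) -> None:
        for name in (
            "fraction_sites_in_windows",
            "fp_rate",
            "dropout_rate",
            "ko_retention",
            "t3_gain",
            "p_up_given_bound",
            "p_down_given_bound",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.p_up_given_bound + self.p_down_given_bound > 1.0:
            raise ValueError("p_up + p_down exceeds 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError(f"bad gene_length_range {self.gene_length_range}")
        wlo, whi = self.site_width_range
        if not (16 <= wlo <= whi <= lo):
            raise ValueError(
                "site widths must fit a DR4 element and the smallest gene"
            )
        n_genic = round(self.fraction_sites_in_windows * self.n_true_sites)
        if n_genic > self.n_genes:
            raise ValueError(
                f"{n_genic} genic sites exceed {self.n_genes} genes "
                "(one site per gene)"
            )
        per_chrom = -(-self.n_genes // self.n_chroms)  # ceil
        needed = per_chrom * hi + (per_chrom + 1) * self.min_gene_gap
        if needed > self.chrom_length:
            raise ValueError(
                f"genes do not fit: need ≥{needed} bases per chromosome, "
                f"have {self.chrom_length}"
            )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for key in ("gene_length_range", "site_width_range", "term_size_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("gene_length_range", "site_width_range", "term_size_range"):
            d[key] = list(d[key])
        return d


@dataclass
class TrueSite:
    chrom: str
    start: int
    end: int
    gene_id: Optional[str]  # None for intergenic sites
    t3_dependent: bool
    ko_retained: bool
    element_start: int
    element_strand: str
    base_height: float

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: dict
    genes: list
    sites: list
    peaks: dict  # sample -> {replicate_id: [Peak]}
    expression: list
    terms: list
    truth: dict
    paths: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def _random_genome(config: SimulationConfig, rng) -> dict:
    genome = {}
    for c in range(config.n_chroms):
        codes = rng.integers(0, 4, size=config.chrom_length)
        genome[f"chr{c + 1}"] = bytearray(_BASES[codes].tobytes())
    return genome


def _place_genes(config: SimulationConfig, rng) -> list:
    """Non-overlapping genes with window-disjoint spacing, round-robin."""
    per_chrom: dict = {f"chr{c + 1}": [] for c in range(config.n_chroms)}
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    for i in range(config.n_genes):
        per_chrom[f"chr{(i % config.n_chroms) + 1}"].append(int(lengths[i]))
    genes = []
    gene_index = 0
    for chrom in sorted(per_chrom):
        lens = per_chrom[chrom]
        n = len(lens)
        if n == 0:
            continue
        slack = config.chrom_length - sum(lens) - (n + 1) * config.min_gene_gap
        if slack < 0:
            raise ValueError("genes do not fit chromosome")
        extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = 0
        for j, length in enumerate(lens):
            pos += config.min_gene_gap + int(extra[j])
            gene_index += 1
            gid = f"g{gene_index:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=gid,
                    interval=GenomicInterval(chrom, pos, pos + length),
                    strand=strand,
                    name=gid.upper(),
                )
            )
            pos += length
    return genes


def _plant_sites(config: SimulationConfig, genes, genome, rng) -> list:
    n_genic = round(config.fraction_sites_in_windows * config.n_true_sites)
    n_inter = config.n_true_sites - n_genic
    wlo, whi = config.site_width_range

    chosen = rng.choice(len(genes), size=n_genic, replace=False)
    sites = []
    for gi in chosen:
        gene = genes[int(gi)]
        width = int(rng.integers(wlo, whi + 1))
        start = int(
            rng.integers(gene.interval.start, gene.interval.end - width + 1)
        )
        sites.append((gene.interval.chrom, start, start + width, gene.gene_id))

    # intergenic candidates: > flank away from every gene on its chromosome
    free: list = []
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g.interval)
    for chrom in sorted(genome):
        ivs = sorted(by_chrom.get(chrom, []), key=lambda iv: iv.start)
        cursor = 0
        for iv in ivs:
            left = iv.start - config.flank
            if left - cursor >= whi:
                free.append((chrom, cursor, left))
            cursor = iv.end + config.flank
        if config.chrom_length - cursor >= whi:
            free.append((chrom, cursor, config.chrom_length))
    if n_inter > 0 and not free:
        raise ValueError("no intergenic room for sites")
    weights = np.array([e - s - whi + 1 for _, s, e in free], dtype=float)
    weights /= weights.sum()
    for _ in range(n_inter):
        chrom, s, e = free[int(rng.choice(len(free), p=weights))]
        width = int(rng.integers(wlo, whi + 1))
        start = int(rng.integers(s, e - width + 1))
        sites.append((chrom, start, start + width, None))

    t3_dep = rng.random(config.n_true_sites) < config.t3_gain
    ko_ret = rng.random(config.n_true_sites) < config.ko_retention
    heights = rng.uniform(5.0, 50.0, size=config.n_true_sites)

    result = []
    for i, (chrom, start, end, gene_id) in enumerate(sites):
        # plant one DR4 element at the site centre
        half1 = ("A" if rng.random() < 0.5 else "G") + "GGTCA"
        half2 = ("A" if rng.random() < 0.5 else "G") + "GGTCA"
        spacer = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=4))
        element = half1 + spacer + half2
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            element = "".join(comp[b] for b in reversed(element))
        centre = (start + end) // 2
        el_start = centre - 8
        genome[chrom][el_start : el_start + 16] = element.encode()
        result.append(
            TrueSite(
                chrom=chrom,
                start=start,
                end=end,
                gene_id=gene_id,
                t3_dependent=bool(t3_dep[i]),
                ko_retained=bool(ko_ret[i]),
                element_start=el_start,
                element_strand=strand,
                base_height=float(heights[i]),
            )
        )
    result.sort(key=lambda s: (s.chrom, s.start, s.end))
    return result


def _detectable_mask(sample: str, sites) -> list:
    out = []
    for s in sites:
        if sample == "wt_minusT3":
            out.append(not s.t3_dependent)
        elif sample == "wt_plusT3":
            out.append(True)
        elif sample == "ko_minusT3":
            out.append(s.ko_retained and not s.t3_dependent)
        elif sample == "ko_plusT3":
            out.append(s.ko_retained)
        else:
            raise ValueError(f"unknown sample {sample!r}")
    return out


def _replicate_peaks(config: SimulationConfig, sites, detectable, sample, rng):
    """One noisy peak-call per replicate: jitter, dropouts, false peaks."""
    reps = {}
    det_sites = [s for s, d in zip(sites, detectable) if d]
    for r in range(1, config.n_replicates + 1):
        rep_id = f"rep{r}"
        peaks = []
        for s in det_sites:
            if rng.random() < config.dropout_rate:
                continue
            start = s.start + int(round(rng.normal(0.0, config.jitter_sd)))
            end = s.end + int(round(rng.normal(0.0, config.jitter_sd)))
            if end - start < config.min_peak_width:
                centre = (start + end) // 2
                start = centre - config.min_peak_width // 2
                end = start + config.min_peak_width
            start = max(0, start)
            end = min(config.chrom_length, end)
            if end - start < 1:
                continue
            height = s.base_height * float(np.exp(rng.normal(0.0, 0.1)))
            summit = min(max(s.element_start + 8 - start, 0), end - start - 1)
            peaks.append(
                Peak(
                    interval=GenomicInterval(s.chrom, start, end),
                    height=height,
                    summit_offset=summit,
                    sample_id=sample,
                    replicate_id=rep_id,
                )
            )
        n_fp = int(rng.poisson(config.fp_rate * max(len(det_sites), 1)))
        wlo, whi = config.site_width_range
        for _ in range(n_fp):
            chrom = f"chr{int(rng.integers(1, config.n_chroms + 1))}"
            width = int(rng.integers(wlo, whi + 1))
            start = int(rng.integers(0, config.chrom_length - width))
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, start + width),
                    height=float(rng.uniform(2.0, 10.0)),
                    sample_id=sample,
                    replicate_id=rep_id,
                )
            )
        peaks.sort(
            key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        )
        reps[rep_id] = peaks
    return reps


def _truth_bound_genes(config: SimulationConfig, genes, sites, detectable) -> list:
    windows = build_windows(genes, flank=config.flank)
    ivs = [s.interval for s, d in zip(sites, detectable) if d]
    if not ivs:
        return []
    assignments = assign_peaks(ivs, windows)
    bound: set = set()
    for a in assignments:
        bound |= a.gene_ids
    return sorted(bound)


def _draw_effect(config: SimulationConfig, rng) -> float:
    """Log2 effect size, truncated just above the 1.5-fold cutoff."""
    floor = float(np.log2(1.5)) + 0.02
    for _ in range(100):
        value = float(rng.normal(config.effect_mean_log2fc, config.effect_sd_log2fc))
        if value >= floor:
            return value
    return floor


def _expression(config: SimulationConfig, genes, wt_bound, ko_bound, rng):
    cutoff = float(np.log2(1.5))
    wt_bound = set(wt_bound)
    ko_bound = set(ko_bound)
    records = []
    truth_reg = {"wt_up": [], "wt_down": [], "ko_up": [], "ko_down": []}
    for gene in genes:
        gid = gene.gene_id
        direction = None
        if gid in wt_bound:
            u = rng.random()
            if u < config.p_up_given_bound:
                direction = "up"
            elif u < config.p_up_given_bound + config.p_down_given_bound:
                direction = "down"
        if direction is None:
            l2_wt = float(rng.normal(0.0, 0.1))
            fdr_wt = float(rng.uniform(0.0, 1.0))
            l2_ko = float(rng.normal(0.0, 0.1))
            fdr_ko = float(rng.uniform(0.0, 1.0))
        else:
            magnitude = _draw_effect(config, rng)
            sign = 1.0 if direction == "up" else -1.0
            l2_wt = sign * magnitude
            fdr_wt = float(rng.uniform(1e-8, 0.04))
            truth_reg[f"wt_{direction}"].append(gid)
            if gid in ko_bound:
                l2_ko = config.ko_attenuation * l2_wt
                fdr_ko = float(rng.uniform(1e-8, 0.04))
                if abs(l2_ko) >= cutoff and fdr_ko < 0.05:
                    truth_reg[f"ko_{direction}"].append(gid)
            else:
                l2_ko = float(rng.normal(0.0, 0.1))
                fdr_ko = float(rng.uniform(0.0, 1.0))
        records.append(
            ExpressionRecord(
                gene_id=gid,
                log2fc_wt=round(l2_wt, 6),
                fdr_wt=round(fdr_wt, 8),
                log2fc_ko=round(l2_ko, 6),
                fdr_ko=round(fdr_ko, 8),
            )
        )
    return records, truth_reg


def simulate_terms(
    gene_ids: Sequence[str],
    n_terms: int,
    size_range: tuple = (10, 60),
    rng=None,
    seed: Optional[int] = None,
) -> list:
    """Uniformly drawn gene–term annotations (a null ontology)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    gene_ids = sorted(gene_ids)
    lo, hi = size_range
    hi = min(hi, len(gene_ids))
    terms = []
    for t in range(1, n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(gene_ids), size=size, replace=False)
        terms.append(
            TermAnnotation(
                term_id=f"T{t:04d}",
                term_name=f"synthetic term {t}",
                gene_ids=frozenset(gene_ids[int(i)] for i in members),
            )
        )
    return terms


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------


def simulate(config: SimulationConfig, outdir=None) -> SimulationResult:
    """Generate the full synthetic study; optionally write the file tree.

    Outputs (when ``outdir`` is given): ``genome.fa``, ``genes.gff3``,
    ``peaks/<sample>.<rep>.narrowPeak``, ``expression.tsv``, ``truth.json``
    and, when ``n_terms > 0``, ``terms.gmt``.  Identical configs produce
    byte-identical trees.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genome_bytes = _random_genome(config, rng)
    genes = _place_genes(config, rng)
    sites = _plant_sites(config, genes, genome_bytes, rng)
    genome = {c: genome_bytes[c].decode() for c in sorted(genome_bytes)}

    peaks = {}
    detectable = {}
    for sample in SAMPLES:
        mask = _detectable_mask(sample, sites)
        detectable[sample] = mask
        peaks[sample] = _replicate_peaks(config, sites, mask, sample, rng)

    bound = {
        sample: _truth_bound_genes(config, genes, sites, detectable[sample])
        for sample in SAMPLES
    }
    wt_union = sorted(set(bound["wt_minusT3"]) | set(bound["wt_plusT3"]))
    ko_union = sorted(set(bound["ko_minusT3"]) | set(bound["ko_plusT3"]))

    expression, truth_reg = _expression(config, genes, wt_union, ko_union, rng)

    terms = (
        simulate_terms(
            [g.gene_id for g in genes],
            config.n_terms,
            config.term_size_range,
            rng=rng,
        )
        if config.n_terms > 0
        else []
    )

    truth = {
        "config": config.to_dict(),
        "samples": list(SAMPLES),
        "sites": [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "gene_id": s.gene_id,
                "t3_dependent": s.t3_dependent,
                "ko_retained": s.ko_retained,
                "element_start": s.element_start,
                "element_strand": s.element_strand,
            }
            for s in sites
        ],
        "detectable": {
            sample: [i for i, d in enumerate(detectable[sample]) if d]
            for sample in SAMPLES
        },
        "bound_genes": bound,
        "bound_genes_union": {"wt": wt_union, "ko": ko_union},
        "regulated": truth_reg,
    }

    result = SimulationResult(
        config=config,
        genome=genome,
        genes=genes,
        sites=sites,
        peaks=peaks,
        expression=expression,
        terms=terms,
        truth=truth,
    )

    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "peaks").mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "genome.fa", genome)
        write_gff3(outdir / "genes.gff3", genes)
        for sample in SAMPLES:
            for rep_id, rep_peaks in peaks[sample].items():
                write_peaks(
                    outdir / "peaks" / f"{sample}.{rep_id}.narrowPeak", rep_peaks
                )
        write_expression_table(outdir / "expression.tsv", expression)
        if terms:
            write_gmt(outdir / "terms.gmt", terms)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
        result.paths = {
            "genome": str(outdir / "genome.fa"),
            "annotation": str(outdir / "genes.gff3"),
            "peaks_dir": str(outdir / "peaks"),
            "expression": str(outdir / "expression.tsv"),
            "truth": str(outdir / "truth.json"),
        }
        if terms:
            result.paths["terms"] = str(outdir / "terms.gmt")
    return result


def fragments_for_sites(
    sites: Sequence[TrueSite],
    chrom_lengths: Mapping[str, int],
    site_depth: int = 60,
    fragment_length: int = 100,
    background_rate: float = 0.001,
    rng=None,
    seed: Optional[int] = None,
) -> list:
    """Fragment intervals for the pileup caller: site stacks + background."""
    if rng is None:
        rng = np.random.default_rng(seed)
    fragments = []
    for s in sites:
        centre = (s.start + s.end) // 2
        for _ in range(site_depth):
            mid = centre + int(rng.integers(-s.interval.width // 4,
                                            s.interval.width // 4 + 1))
            start = max(0, mid - fragment_length // 2)
            end = min(chrom_lengths[s.chrom], start + fragment_length)
            if end > start:
                fragments.append(GenomicInterval(s.chrom, start, end))
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n_bg = int(rng.poisson(background_rate * length))
        for _ in range(n_bg):
            start = int(rng.integers(0, max(length - fragment_length, 1)))
            fragments.append(
                GenomicInterval(chrom, start, min(start + fragment_length, length))
            )
    return fragments


def evaluate_recovery(
    truth: Mapping,
    consensus_by_sample: Mapping[str, Sequence],
    bound_by_sample: Optional[Mapping[str, set]] = None,
) -> dict:
    """Precision/recall of consensus calls against the planted truth.

    A consensus peak matches a true site iff they overlap by ≥ 1 base;
    site recall counts matched *detectable* sites per sample.  Gene-level
    precision/recall are added when called bound-gene sets are supplied.
    """
    sites = truth["sites"]
    report = {}
    for sample, consensus in consensus_by_sample.items():
        det_idx = truth["detectable"][sample]
        det = [
            GenomicInterval(sites[i]["chrom"], sites[i]["start"], sites[i]["end"])
            for i in det_idx
        ]
        called = [c.interval for c in consensus]
        matched_calls = sum(
            1 for c in called if any(c.overlaps(t) for t in det)
        )
        matched_sites = sum(
            1 for t in det if any(c.overlaps(t) for c in called)
        )
        entry = {
            "n_called": len(called),
            "n_detectable": len(det),
            "site_precision": matched_calls / len(called) if called else 1.0,
            "site_recall": matched_sites / len(det) if det else 1.0,
        }
        if bound_by_sample is not None and sample in bound_by_sample:
            true_bound = set(truth["bound_genes"][sample])
            called_bound = set(bound_by_sample[sample])
            tp = len(true_bound & called_bound)
            entry["gene_precision"] = (
                tp / len(called_bound) if called_bound else 1.0
            )
            entry["gene_recall"] = tp / len(true_bound) if true_bound else 1.0
        report[sample] = entry
    return report
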