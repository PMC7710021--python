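"""Consensus ChIP-seq regions across experiments and target-gene mapping.

Peaks from all experiments are pooled per chromosome and grouped by
single-linkage overlap (>= 1 shared base on 0-based half-open intervals): a
group is a connected component of the overlap graph.  A group's *support* is
the number of distinct experiments contributing a peak; groups reaching the
support threshold (default 6 of 10) become consensus regions.  Regions are
assigned to genes whose transcription start site lies within a configurable
distance of the region span (default 10 kb, inclusive; 0 when overlapping).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval, optionally tagged with its experiment."""

    chrom: str
    start: int
    end: int
    experiment_id: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class ConsensusRegion:
    """A maximal overlap group of pooled peaks with its experiment support."""

    chrom: str
    span_start: int
    span_end: int
    member_peaks: tuple[GenomicInterval, ...]
    support: int

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.span_start, self.span_end)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    body_start: int
    body_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (self.body_start <= self.tss < self.body_end):
            raise ValueError(f"gene {self.gene_id}: TSS outside gene body")


# ---------------------------------------------------------------------------
# BED / annotation I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, experiment_id: str = "") -> list[GenomicInterval]:
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{ln}: BED line needs >= 3 fields")
        name = fields[3] if len(fields) > 3 else ""
        out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), experiment_id, name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\n")


def write_consensus_bed(regions: Iterable[ConsensusRegion], path: str | Path) -> None:
    """Write consensus regions as BED with the support count in the score column."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(f"{r.chrom}\t{r.span_start}\t{r.span_end}\tconsensus_{i}\t{r.support}\n")


def read_gene_annotation(path: str | Path) -> list[GeneModel]:
    """Read a TSV with columns gene_id, chrom, strand, tss, body_start, body_end."""
    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(str(r.gene_id), str(r.chrom), str(r.strand), int(r.tss),
                  int(r.body_start), int(r.body_end))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def filter_by_length(
    peaks: Sequence[GenomicInterval], max_len: int = 3000
) -> tuple[list[GenomicInterval], int]:
    """Drop peaks longer than ``max_len`` bases (inclusive bound: 3000 stays)."""
    kept = [p for p in peaks if p.length <= max_len]
    return kept, len(peaks) - len(kept)


def _group_pooled(peaks: Sequence[GenomicInterval]) -> list[ConsensusRegion]:
    """Single-linkage overlap groups of a pooled peak list (all supports)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    regions: list[ConsensusRegion] = []
    for chrom in by_chrom:
        ivs = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end, p.experiment_id, p.name))
        group: list[GenomicInterval] = []
        group_end = -1
        for iv in ivs:
            if group and iv.start < group_end:
                group.append(iv)
                group_end = max(group_end, iv.end)
            else:
                if group:
                    regions.append(_finish_group(chrom, group))
                group = [iv]
                group_end = iv.end
        if group:
            regions.append(_finish_group(chrom, group))
    return sorted(regions, key=lambda r: (r.chrom, r.span_start, r.span_end))


def _finish_group(chrom: str, members: list[GenomicInterval]) -> ConsensusRegion:
    return ConsensusRegion(
        chrom=chrom,
        span_start=min(m.start for m in members),
        span_end=max(m.end for m in members),
        member_peaks=tuple(members),
        support=len({m.experiment_id for m in members}),
    )


def build_consensus(
    peak_sets: Mapping[str, Sequence[GenomicInterval]] | Sequence[Sequence[GenomicInterval]],
    min_support: int = 6,
) -> list[ConsensusRegion]:
    """Group overlapping peaks pooled across experiments; keep well-supported groups.

    ``peak_sets`` is one peak list per experiment (mapping id -> peaks, or a
    plain sequence, in which case experiments are numbered).  A group is kept
    iff peaks from at least ``min_support`` distinct experiments participate.
    The output is sorted by (chrom, span_start) and invariant to experiment
    order and within-file shuffling.
    """
    if isinstance(peak_sets, Mapping):
        items = list(peak_sets.items())
    else:
        items = [(f"exp{i}", ps) for i, ps in enumerate(peak_sets)]
    if len(items) < min_support:
        raise ValueError(
            f"min_support={min_support} exceeds the {len(items)} experiments supplied"
        )
    pooled = []
    for exp_id, ps in items:
        for p in ps:
            if p.experiment_id and p.experiment_id != exp_id:
                exp = p.experiment_id
            else:
                exp = exp_id
            pooled.append(GenomicInterval(p.chrom, p.start, p.end, exp, p.name))
    return [r for r in _group_pooled(pooled) if r.support >= min_support]


# ---------------------------------------------------------------------------
# Gene mapping and feedback candidates
# ---------------------------------------------------------------------------

def _tss_distance(region: ConsensusRegion, gene: GeneModel) -> int:
    """Distance from a gene's TSS to the region span; 0 when the TSS lies inside."""
    if gene.tss < region.span_start:
        return region.span_start - gene.tss
    if gene.tss >= region.span_end:
        return gene.tss - (region.span_end - 1)
    return 0


def map_regions_to_genes(
    regions: Sequence[ConsensusRegion],
    genes: Sequence[GeneModel],
    max_distance: int = 10_000,
) -> tuple[dict[str, list[int]], list[int]]:
    """Assign consensus regions to genes by TSS proximity.

    A gene is a target of a region iff its TSS lies within ``max_distance``
    bases of the region span (inclusive).  Many-to-many: a region may map to
    several genes and a gene may collect several regions.  Returns
    (gene_id -> indices of assigned regions, indices of orphan regions).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    gene_hits: dict[str, list[int]] = {}
    orphans: list[int] = []
    for ri, region in enumerate(regions):
        hit = False
        for g in by_chrom.get(region.chrom, ()):
            if _tss_distance(region, g) <= max_distance:
                gene_hits.setdefault(g.gene_id, []).append(ri)
                hit = True
        if not hit:
            orphans.append(ri)
    return gene_hits, orphans


@dataclass
class FeedbackReport:
    """Intersections naming candidate transcription-regulatory feedback loops."""

    tf_targets: list[str]
    pathway_targets: list[str]
    n_target_genes: int
    n_mealr_tfs: int
    n_pathway_components: int

    @property
    def n_tf_targets(self) -> int:
        return len(self.tf_targets)

    @property
    def n_pathway_targets(self) -> int:
        return len(self.pathway_targets)


def intersect_feedback_candidates(
    target_genes: Iterable[str],
    mealr_tf_genes: Iterable[str],
    pathway_component_genes: Iterable[str],
) -> FeedbackReport:
    """Intersect consensus target genes with enriched TFs and pathway components.

    Symbols are harmonised case-insensitively (exact match after upper-casing);
    reported membership uses the target-list spelling.
    """
    targets = {g.upper(): g for g in target_genes}
    tfs = {g.upper() for g in mealr_tf_genes}
    pathway = {g.upper() for g in pathway_component_genes}
    return FeedbackReport(
        tf_targets=sorted(targets[k] for k in targets.keys() & tfs),
        pathway_targets=sorted(targets[k] for k in targets.keys() & pathway),
        n_target_genes=len(targets),
        n_mealr_tfs=len(tfs),
        n_pathway_components=len(pathway),
    )
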