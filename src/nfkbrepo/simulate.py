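"""Seeded synthetic inputs with ground truth for every pipeline stage.

Real inputs to this pipeline — ChIP-seq peak sequences, a vertebrate PWM
library, a curated signalling network, structure–activity probability
matrices — are proprietary or large.  This module generates small seeded
stand-ins with *known planted truth*: peak sequences carrying a planted
motif, multi-experiment interval sets with a known consensus list, a random
digraph with a wired-in master regulator, and an activity matrix with known
hit drugs.  Every generator is a pure function of a :class:`FixtureSpec`;
identical spec + seed yields byte-identical outputs.

What these fixtures emulate, and what they do not, is discussed in the
package's methods note: backgrounds are i.i.d. uniform DNA, interval loci are
well separated, and networks are sparse Erdős–Rényi-like digraphs — none of
the genomic covariance structure of real data is modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .consensus import GenomicInterval
from .keynodes import AnalysisInputs, SignalingNetwork
from .motifs import BASES, LabelledSequence, PositionWeightMatrix

# stream tags keep each generator on an independent substream of the seed
_STREAM_PWM = 1
_STREAM_PEAKS = 2
_STREAM_EXPERIMENTS = 3
_STREAM_NETWORK = 4
_STREAM_DRUGS = 5


@dataclass
class FixtureSpec:
    """Sizes, rates and planted truth controlling every synthetic generator.

    Defaults mirror the study conditions the pipeline is demonstrated under:
    200 peak sequences of 200 bp with a 12-bp motif planted at rate 0.9 amid
    10 decoy motifs; ten peak experiments; a 60-node signalling network with
    12 input nodes; 200 compounds scored over 46 activities.
    """

    seed: int = 0
    # motif / peak-sequence stage
    n_positive: int = 200
    n_background_pool: int = 600
    seq_len: int = 200
    motif_length: int = 12
    concentration: float = 20.0
    planting_rate: float = 0.9
    n_decoys: int = 10
    # multi-experiment peak stage
    n_experiments: int = 10
    n_loci: int = 200
    consensus_fraction: float = 0.5
    min_support: int = 6
    oversized_loci: int = 4
    # network stage: the node universe is kept much larger than the seed
    # sets, as in curated pathway databases, so the permutation null is
    # informative and FDR-level selection is attainable
    n_nodes: int = 300
    n_input: int = 12
    n_context: int = 8
    mean_out_degree: float = 1.2
    # drug stage
    n_drugs: int = 200
    n_activities: int = 46
    n_hits: int = 3
    score_threshold: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.planting_rate <= 1.0):
            raise ValueError("planting_rate must be in [0, 1]")
        if not (0.0 <= self.consensus_fraction <= 1.0):
            raise ValueError("consensus_fraction must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# PWMs and peak sequences
# ---------------------------------------------------------------------------

def make_pwm(
    rng: np.random.Generator | int,
    length: int,
    concentration: float = 10.0,
    motif_id: str = "M_planted",
) -> PositionWeightMatrix:
    """Sample a PWM with one dominant base per position.

    Each row is Dirichlet(0.5 + concentration * e_dom) for a random dominant
    base; larger ``concentration`` gives sharper (lower-entropy) columns and
    in the limit a consensus (0/1) matrix.
    """
    if length < 4:
        raise ValueError("motif length must be >= 4")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    probs = np.empty((length, 4))
    for p in range(length):
        dom = rng.integers(4)
        alpha = np.full(4, 0.5)
        alpha[dom] += concentration
        probs[p] = rng.dirichlet(alpha)
    return PositionWeightMatrix(id=motif_id, probs=probs)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(4, size=length))


def _sample_site(rng: np.random.Generator, pwm: PositionWeightMatrix) -> str:
    return "".join(
        BASES[rng.choice(4, p=pwm.probs[p])] for p in range(pwm.length)
    )


@dataclass
class PeakDataset:
    """Synthetic peak sequences, promoter pool and planted-motif truth."""

    positives: list[LabelledSequence]
    pool: list[LabelledSequence]
    pool_intervals: list[GenomicInterval]
    peaks: list[GenomicInterval]
    planted: PositionWeightMatrix
    decoys: list[PositionWeightMatrix]
    truth: dict

    @property
    def pwms(self) -> list[PositionWeightMatrix]:
        return [self.planted] + self.decoys


def make_peak_dataset(spec: FixtureSpec) -> PeakDataset:
    """Peak sequences with planted motif occurrences plus a promoter pool.

    Each positive carries one site sampled from the planted PWM at a uniform
    random offset with probability ``planting_rate``; pool promoters are
    i.i.d. uniform DNA.  Promoters sit on a synthetic chromosome; roughly 10%
    overlap a peak interval so that background sampling has something to
    exclude.  The truth record stores planted offsets per sequence.
    """
    rng = spec.rng(_STREAM_PEAKS)
    pwm_rng = spec.rng(_STREAM_PWM)
    planted = make_pwm(pwm_rng, spec.motif_length, spec.concentration, "M_planted")
    decoys = [
        make_pwm(pwm_rng, spec.motif_length, spec.concentration, f"M_decoy{i:02d}")
        for i in range(spec.n_decoys)
    ]

    positives: list[LabelledSequence] = []
    offsets: dict[str, int | None] = {}
    for i in range(spec.n_positive):
        seq = list(_random_dna(rng, spec.seq_len))
        off: int | None = None
        if rng.random() < spec.planting_rate:
            off = int(rng.integers(spec.seq_len - planted.length + 1))
            seq[off : off + planted.length] = _sample_site(rng, planted)
        sid = f"peak_{i:04d}"
        positives.append(LabelledSequence(sid, "".join(seq), 1))
        offsets[sid] = off

    # peak intervals on a synthetic chromosome, promoters mostly elsewhere
    gap = 10 * spec.seq_len
    peaks = [
        GenomicInterval("chrS", i * gap, i * gap + spec.seq_len, "exp0", f"peak_{i:04d}")
        for i in range(spec.n_positive)
    ]
    pool: list[LabelledSequence] = []
    pool_iv: list[GenomicInterval] = []
    promoter_offset = spec.n_positive * gap  # beyond all peaks
    n_overlapping = spec.n_background_pool // 10
    for j in range(spec.n_background_pool):
        pid = f"prom_{j:04d}"
        if j < n_overlapping:
            # park on top of a peak to exercise exclusion
            k = int(rng.integers(spec.n_positive))
            start = peaks[k].start + int(rng.integers(spec.seq_len // 2))
        else:
            start = promoter_offset + j * 2 * spec.seq_len
        pool.append(LabelledSequence(pid, _random_dna(rng, spec.seq_len), 0))
        pool_iv.append(GenomicInterval("chrS", start, start + spec.seq_len, "", pid))

    truth = {
        "planted_motif": planted.id,
        "decoys": [d.id for d in decoys],
        "planting_rate": spec.planting_rate,
        "planted_offsets": offsets,
        "n_planted": sum(1 for v in offsets.values() if v is not None),
        "n_overlapping_promoters": n_overlapping,
    }
    return PeakDataset(positives, pool, pool_iv, peaks, planted, decoys, truth)


# ---------------------------------------------------------------------------
# Multi-experiment peaks
# ---------------------------------------------------------------------------

@dataclass
class MultiExperimentPeaks:
    peak_sets: dict[str, list[GenomicInterval]]
    truth: dict


def make_multi_experiment_peaks(spec: FixtureSpec) -> MultiExperimentPeaks:
    """Overlapping interval sets across experiments with a known consensus list.

    Loci are spaced far apart on one chromosome; a ``consensus_fraction`` of
    them receive mutually overlapping peaks in >= ``min_support`` experiments
    (support drawn uniformly from [min_support, n_experiments]), the rest in
    fewer.  A few extra loci carry only oversized (> 3000 bp) peaks, which
    the length filter must remove before grouping.  The truth lists the loci
    expected to survive consensus building.
    """
    rng = spec.rng(_STREAM_EXPERIMENTS)
    exp_ids = [f"exp{i}" for i in range(spec.n_experiments)]
    peak_sets: dict[str, list[GenomicInterval]] = {e: [] for e in exp_ids}
    spacing = 10_000
    expected: list[dict] = []
    n_consensus = int(round(spec.consensus_fraction * spec.n_loci))
    for li in range(spec.n_loci + spec.oversized_loci):
        center = (li + 1) * spacing
        oversized = li >= spec.n_loci
        if oversized:
            support = int(rng.integers(spec.min_support, spec.n_experiments + 1))
        elif li < n_consensus:
            support = int(rng.integers(spec.min_support, spec.n_experiments + 1))
        else:
            support = int(rng.integers(1, spec.min_support))
        chosen = rng.choice(spec.n_experiments, size=support, replace=False)
        starts, ends = [], []
        for e in chosen:
            if oversized:
                half = int(rng.integers(1750, 2200))
            else:
                half = int(rng.integers(300, 600))
            c = center + int(rng.integers(-200, 201))
            iv = GenomicInterval("chr1", c - half, c + half, exp_ids[e], f"locus_{li}")
            peak_sets[exp_ids[e]].append(iv)
            starts.append(c - half)
            ends.append(c + half)
        if not oversized and support >= spec.min_support:
            expected.append(
                {
                    "locus": li,
                    "chrom": "chr1",
                    "span_start": min(starts),
                    "span_end": max(ends),
                    "support": support,
                }
            )
    # shuffle within experiments so order carries no information
    for e in exp_ids:
        rng.shuffle(peak_sets[e])
    truth = {
        "expected_regions": expected,
        "n_expected": len(expected),
        "min_support": spec.min_support,
        "oversized_loci": spec.oversized_loci,
    }
    return MultiExperimentPeaks(peak_sets, truth)


# ---------------------------------------------------------------------------
# Signalling network
# ---------------------------------------------------------------------------

@dataclass
class NetworkFixture:
    network: SignalingNetwork
    inputs: AnalysisInputs
    regulator: str
    truth: dict


def make_network(spec: FixtureSpec) -> NetworkFixture:
    """Random digraph with a planted master regulator.

    Background nodes get Poisson-distributed out-edges to random non-input
    targets; the input nodes (standing in for NF-κB complex components) are
    sinks.  The planted regulator reaches every input node through two
    dedicated hub intermediates (depth <= 2) and nothing else directly, so
    its reachable set is dominated by the input set and its weighted-ratio
    score stands far above the permutation null.
    """
    rng = spec.rng(_STREAM_NETWORK)
    background = [f"N{i:03d}" for i in range(spec.n_nodes)]
    input_nodes = [f"NFKB_c{i:02d}" for i in range(spec.n_input)]
    context_pool = [b for b in background]
    context_nodes = list(rng.choice(context_pool, size=spec.n_context, replace=False))
    regulator, hubs = "MR_planted", ["HUB_a", "HUB_b"]

    edges: set[tuple[str, str]] = set()
    for u in background:
        k = rng.poisson(spec.mean_out_degree)
        for v in rng.choice(background, size=min(k, spec.n_nodes), replace=False):
            if v != u:
                edges.add((u, str(v)))
    # a few background nodes feed single inputs (noise, far below full
    # coverage); each feeder also hits a shared broadcast node with wide
    # fan-out, so a feeder's reach is never dominated by its one input and
    # the planted regulator keeps the top raw score
    broadcast = "BCAST"
    fanout = rng.choice(background, size=min(15, spec.n_nodes), replace=False)
    for v in fanout:
        edges.add((broadcast, str(v)))
    for u in rng.choice(background, size=max(2, spec.n_nodes // 20), replace=False):
        edges.add((str(u), str(rng.choice(input_nodes))))
        edges.add((str(u), broadcast))
    # context nodes feed the broadcast node too: whoever reaches a context
    # protein also drags in the wide fan-out, so no bystander scores above
    # the planted regulator on a one-edge fluke
    for c in context_nodes:
        edges.add((str(c), broadcast))
    # planted wiring: regulator -> hubs -> all inputs
    for h in hubs:
        edges.add((regulator, h))
    for i, inp in enumerate(input_nodes):
        edges.add((hubs[i % 2], inp))

    net = SignalingNetwork.from_edges(sorted(edges))
    inputs = AnalysisInputs(
        input_set=frozenset(input_nodes),
        context_set=frozenset(map(str, context_nodes)),
        context_weight=2.0,
        radius=10,
    )
    truth = {
        "regulator": regulator,
        "hubs": hubs,
        "input_set": sorted(input_nodes),
        "context_set": sorted(map(str, context_nodes)),
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
    }
    return NetworkFixture(net, inputs, regulator, truth)


# ---------------------------------------------------------------------------
# Drug activity matrix
# ---------------------------------------------------------------------------

@dataclass
class ActivityMatrixFixture:
    frame: "pd.DataFrame"
    activities: list[str]
    required_activity: str
    hit_drugs: list[str]
    truth: dict


def make_activity_matrix(spec: FixtureSpec) -> ActivityMatrixFixture:
    """Drug-by-activity P_a matrix with planted hit drugs.

    Non-hit compounds draw i.i.d. low probabilities (Beta(2, 48), mean 0.04)
    whose cumulative score stays below the threshold by construction (rows
    violating this are redrawn); hits draw uniform(0.08, 0.20) across the
    panel plus a strong required-activity probability, clearing the strict
    threshold.  The truth hits therefore equal exactly the set passing the
    filters.
    """
    import pandas as pd

    rng = spec.rng(_STREAM_DRUGS)
    required = "Transcription factor NF-κB inhibitor"
    activities = [required] + [f"Activity_{i:02d}" for i in range(1, spec.n_activities)]
    drug_ids = [f"drug_{i:03d}" for i in range(spec.n_drugs)]
    hit_idx = sorted(map(int, rng.choice(spec.n_drugs, size=spec.n_hits, replace=False)))
    hits = {drug_ids[i] for i in hit_idx}

    rows = np.empty((spec.n_drugs, spec.n_activities))
    for i in range(spec.n_drugs):
        if i in hit_idx:
            row = rng.uniform(0.08, 0.20, size=spec.n_activities)
            row[0] = rng.uniform(0.5, 0.95)  # required activity strongly positive
            # guarantee a clear threshold margin
            while row.sum() <= spec.score_threshold + 0.5:
                row = np.minimum(row * 1.2, 0.95)
        else:
            row = rng.beta(2, 48, size=spec.n_activities)
            while row.sum() > spec.score_threshold - 0.3:
                row = rng.beta(2, 48, size=spec.n_activities)
        rows[i] = row
    frame = pd.DataFrame(rows, index=pd.Index(drug_ids, name="drug_id"), columns=activities)
    truth = {
        "hit_drugs": sorted(hits),
        "required_activity": required,
        "threshold": spec.score_threshold,
        "n_drugs": spec.n_drugs,
        "n_activities": spec.n_activities,
    }
    return ActivityMatrixFixture(frame, activities, required, sorted(hits), truth)


# ---------------------------------------------------------------------------
# File output helpers (used by the CLI)
# ---------------------------------------------------------------------------

def write_fasta(seqs: Sequence[LabelledSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.bases}\n")


def write_peak_dataset(ds: PeakDataset, outdir: str | Path) -> None:
    from .consensus import write_bed
    from .motifs import write_transfac

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.positives, outdir / "peaks.fasta")
    write_fasta(ds.pool, outdir / "promoter_pool.fasta")
    write_bed(ds.peaks, outdir / "peaks.bed")
    write_bed(ds.pool_intervals, outdir / "promoters.bed")
    write_transfac(ds.pwms, outdir / "matrices.transfac")
    write_truth(ds.truth, outdir / "truth_peaks.json")


def write_multi_experiment_peaks(mx: MultiExperimentPeaks, outdir: str | Path) -> None:
    from .consensus import write_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for exp_id, peaks in mx.peak_sets.items():
        write_bed(peaks, outdir / f"{exp_id}.bed")
    write_truth(mx.truth, outdir / "truth_consensus.json")


def write_network_fixture(nf: NetworkFixture, outdir: str | Path) -> None:
    from .keynodes import write_network

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_network(nf.network, outdir / "network.tsv")
    Path(outdir / "inputs.txt").write_text("\n".join(sorted(nf.inputs.input_set)) + "\n")
    Path(outdir / "context.txt").write_text("\n".join(sorted(nf.inputs.context_set)) + "\n")
    write_truth(nf.truth, outdir / "truth_network.json")


def write_activity_fixture(af: ActivityMatrixFixture, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    af.frame.to_csv(outdir / "activity_matrix.tsv", sep="\t")
    Path(outdir / "activities.txt").write_text("\n".join(af.activities) + "\n")
    write_truth(af.truth, outdir / "truth_drugs.json")
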