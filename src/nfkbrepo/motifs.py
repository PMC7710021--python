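"""Position weight matrices, log-odds scanning and per-sequence motif features.

A transcription-factor binding motif is modelled as a position weight matrix
(PWM): an L x 4 column-stochastic matrix giving the probability of each base
A, C, G, T at every motif position.  Scoring against a sequence uses the
log-odds form against a background base-composition model; per-window scores
``S_w`` are aggregated into one feature ``x_i`` per (sequence, motif) pair,
yielding the design matrix for the sparse logistic-regression motif-enrichment
step (:mod:`nfkbrepo.mealr`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import logsumexp

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: complement permutation of the ACGT axis (A<->T, C<->G)
_COMPLEMENT = np.array([3, 2, 1, 0])


class TransfacParseError(ValueError):
    """Raised when a TRANSFAC matrix block cannot be parsed."""


class UnscoreableSequenceError(ValueError):
    """Raised when a sequence has no window free of ambiguous bases."""


@dataclass(frozen=True)
class BackgroundModel:
    """Base-composition background; log-odds scores are taken against it."""

    freq: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.freq) != set(BASES):
            raise ValueError(f"background must cover exactly {BASES}")
        vals = np.array([self.freq[b] for b in BASES], float)
        if np.any(vals <= 0):
            raise ValueError("all background frequencies must be positive")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls({b: 0.25 for b in BASES})

    @classmethod
    def from_sequences(cls, seqs: Iterable[str], pseudocount: float = 1.0) -> "BackgroundModel":
        counts = np.full(4, float(pseudocount))
        for s in seqs:
            su = s.upper()
            for i, b in enumerate(BASES):
                counts[i] += su.count(b)
        counts /= counts.sum()
        return cls({b: counts[i] for i, b in enumerate(BASES)})

    def as_array(self) -> np.ndarray:
        return np.array([self.freq[b] for b in BASES], float)


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Column-stochastic motif model (rows = positions, columns = A,C,G,T)."""

    id: str
    probs: np.ndarray
    tf_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError(f"PWM {self.id}: probs must be L x 4 with L >= 1")
        if np.any(probs < 0):
            raise ValueError(f"PWM {self.id}: negative probability")
        if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError(f"PWM {self.id}: rows must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            id=self.id, probs=self.probs[::-1, _COMPLEMENT], tf_names=self.tf_names
        )

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))


@dataclass(frozen=True)
class LogOddsMatrix:
    """Background-normalised scoring form of a PWM.

    Entry (p, b) is ``ln((probs[p,b] + pc * freq[b]) / ((1 + pc) * freq[b]))``
    for pseudocount ``pc > 0``; all entries are finite.
    """

    source_id: str
    scores: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, float)
        object.__setattr__(self, "scores", scores)
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if not np.all(np.isfinite(scores)):
            raise ValueError(f"log-odds matrix {self.source_id}: non-finite entry")

    def __len__(self) -> int:
        return self.scores.shape[0]

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class LabelledSequence:
    """A DNA sequence with a binary class label (1 = peak, 0 = background)."""

    id: str
    bases: str
    label: int

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError("empty sequence")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if not set(self.bases.upper()) <= set("ACGTN"):
            raise ValueError(f"sequence {self.id}: alphabet must be ACGTN")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class FeatureTable:
    """N sequences x M motifs score matrix with labels: the MEALR design matrix."""

    seq_ids: list[str]
    labels: np.ndarray
    X: np.ndarray
    matrix_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        self.X = np.asarray(self.X, float)
        n, m = self.X.shape
        if len(self.seq_ids) != n or len(self.matrix_ids) != m:
            raise ValueError("feature table dimensions inconsistent")
        if set(np.unique(self.labels)) != {0, 1}:
            raise ValueError("both classes must be present")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.matrix_ids)
        df.insert(0, "label", self.labels)
        df.insert(0, "seq_id", self.seq_ids)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            seq_ids=df["seq_id"].astype(str).tolist(),
            labels=df["label"].to_numpy(),
            X=df.drop(columns=["seq_id", "label"]).to_numpy(float),
            matrix_ids=[str(c) for c in df.columns[2:]],
        )


# ---------------------------------------------------------------------------
# TRANSFAC flat-file I/O
# ---------------------------------------------------------------------------

_ROW_RE = re.compile(r"^\d{2,}$")


def parse_transfac(path: str | Path) -> list[PositionWeightMatrix]:
    """Parse a TRANSFAC-style matrix flat file into PWMs.

    Blocks are delimited by ``//``; each needs an ``ID`` line and numbered
    count rows (``01  8 0 0 0 A``).  Count rows are normalised to
    column-stochastic probabilities.  TF names are collected from ``NA`` and
    ``BF`` lines.
    """
    text = Path(path).read_text()
    blocks = [b for b in text.split("//") if b.strip()]
    pwms: list[PositionWeightMatrix] = []
    for bi, block in enumerate(blocks):
        pwms.append(_parse_block(block, bi))
    return pwms


def _parse_block(block: str, index: int) -> PositionWeightMatrix:
    mat_id: str | None = None
    names: list[str] = []
    rows: list[np.ndarray] = []
    for line in block.splitlines():
        line = line.strip()
        if not line or line in ("XX",):
            continue
        tag, _, rest = line.partition(" ")
        rest = rest.strip()
        if tag == "ID":
            mat_id = rest or None
        elif tag in ("NA", "BF"):
            # BF lines may carry an accession before the factor name
            name = rest.split(";")[-1].strip()
            if name:
                names.append(name)
        elif _ROW_RE.match(tag):
            fields = rest.split()
            counts = []
            for f in fields[:4]:
                try:
                    counts.append(float(f))
                except ValueError:
                    break
            if len(counts) != 4:
                raise TransfacParseError(
                    f"block {index} ({mat_id or 'no ID'}): row '{line}' does not have 4 counts"
                )
            rows.append(np.array(counts))
    if mat_id is None:
        raise TransfacParseError(f"block {index}: missing ID line")
    if not rows:
        raise TransfacParseError(f"block {index} ({mat_id}): no count rows")
    counts = np.vstack(rows)
    if np.any(counts < 0):
        raise TransfacParseError(f"block {index} ({mat_id}): negative count")
    sums = counts.sum(axis=1)
    if np.any(sums <= 0):
        raise TransfacParseError(f"block {index} ({mat_id}): zero-sum count row")
    return PositionWeightMatrix(id=mat_id, probs=counts / sums[:, None], tf_names=tuple(names))


def write_transfac(pwms: Sequence[PositionWeightMatrix], path: str | Path, scale: int = 100) -> None:
    """Write PWMs as TRANSFAC matrix blocks (probabilities scaled to counts)."""
    lines: list[str] = []
    for pwm in pwms:
        lines.append(f"ID {pwm.id}")
        for name in pwm.tf_names:
            lines.append(f"NA {name}")
        lines.append("P0 A C G T")
        for p in range(pwm.length):
            counts = " ".join(f"{pwm.probs[p, b] * scale:.2f}" for b in range(4))
            lines.append(f"{p + 1:02d} {counts} {BASES[int(pwm.probs[p].argmax())]}")
        lines.append("XX")
        lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def to_log_odds(
    pwm: PositionWeightMatrix,
    bg: BackgroundModel | None = None,
    pseudocount: float = 0.01,
) -> LogOddsMatrix:
    """Convert a PWM to its log-odds scoring form (natural log).

    The pseudocount is additive and background-proportional:
    ``score(p, b) = ln((probs[p,b] + pc*freq[b]) / ((1+pc) * freq[b]))``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = bg or BackgroundModel.uniform()
    f = bg.as_array()
    scores = np.log((pwm.probs + pseudocount * f) / ((1.0 + pseudocount) * f))
    return LogOddsMatrix(source_id=pwm.id, scores=scores, pseudocount=pseudocount)


def encode_sequence(bases: str) -> np.ndarray:
    """Map a sequence to base indices; ambiguous bases (N) become -1."""
    table = np.full(128, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)].astype(np.int64)


def scan_windows(
    seq: LabelledSequence | str,
    lom: LogOddsMatrix,
    strands: str = "both",
) -> np.ndarray:
    """Score every length-L window of ``seq`` with the log-odds matrix.

    Returns W = len(seq) - L + 1 scores; with ``strands='both'`` each score is
    the maximum of the forward and reverse-complement score at that offset.
    Windows containing N score -inf.  A sequence shorter than the motif yields
    an empty array (the caller decides how to treat an unscoreable sequence).
    """
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    bases = seq.bases if isinstance(seq, LabelledSequence) else seq
    L = lom.length
    if len(bases) < L:
        return np.empty(0, float)
    idx = encode_sequence(bases)
    wins = sliding_window_view(idx, L)  # (W, L)
    valid = (wins >= 0).all(axis=1)
    safe = np.where(wins >= 0, wins, 0)
    pos = np.arange(L)
    fwd = lom.scores[pos, safe].sum(axis=1)
    if strands == "both":
        rc_scores = lom.scores[::-1, _COMPLEMENT]
        rev = rc_scores[pos, safe].sum(axis=1)
        out = np.maximum(fwd, rev)
    else:
        out = fwd
    out[~valid] = -np.inf
    return out


def aggregate_score(scores: np.ndarray, method: str = "logavgexp") -> float:
    """Collapse window scores into one per-sequence motif feature ``x``.

    ``logavgexp`` (default) is the smooth soft-maximum
    ``ln((1/W) * sum_w exp(S_w))``; ``max`` takes the best window.  Both obey
    ``max_w S_w - ln W <= x <= max_w S_w``.  Non-finite scores (windows
    overlapping N) are dropped first.
    """
    scores = np.asarray(scores, float)
    finite = scores[np.isfinite(scores)]
    if finite.size == 0:
        raise UnscoreableSequenceError("no finite window score")
    if method == "max":
        return float(finite.max())
    if method == "logavgexp":
        return float(logsumexp(finite) - np.log(finite.size))
    raise ValueError(f"unknown aggregation method: {method}")


def build_feature_matrix(
    seqs: Sequence[LabelledSequence],
    loms: Sequence[LogOddsMatrix],
    method: str = "logavgexp",
    strands: str = "both",
) -> FeatureTable:
    """Score every sequence against every motif into an N x M feature table.

    Row order follows the input sequences, column order the input matrices.
    Sequences with no valid window for some motif are imputed with the global
    minimum of that motif's finite feature values (or 0.0 if none exist), so
    the result is always finite.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    labels = np.array([s.label for s in seqs], int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("both classes (0 and 1) must be present")
    if len(loms) < 1:
        raise ValueError("need at least 1 matrix")
    X = np.full((len(seqs), len(loms)), np.nan)
    for j, lom in enumerate(loms):
        for i, s in enumerate(seqs):
            try:
                X[i, j] = aggregate_score(scan_windows(s, lom, strands=strands), method)
            except UnscoreableSequenceError:
                pass
        col = X[:, j]
        if np.isnan(col).any():
            fill = np.nanmin(col) if not np.isnan(col).all() else 0.0
            col[np.isnan(col)] = fill
    return FeatureTable(
        seq_ids=[s.id for s in seqs],
        labels=labels,
        X=X,
        matrix_ids=[lom.source_id for lom in loms],
    )
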