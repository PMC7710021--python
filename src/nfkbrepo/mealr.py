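"""Motif enrichment analysis by logistic regression (MEALR).

Discriminative motifs are found by fitting an L1-penalised (lasso) logistic
regression of peak-vs-background labels on the per-sequence motif features of
:mod:`nfkbrepo.motifs`.  The lasso drives most coefficients to exactly zero,
so the nonzero set is the selected motif combination.  Robustness comes from
two layers of replication:

* stability selection — the fit is repeated (default 5x) against freshly
  resampled background sequence sets, and only motifs selected in *every* run
  are retained;
* cross-dataset support — motifs retained in at least ``min_support`` of the
  ChIP-seq datasets (default 9 of 10) make the final list.

Because independently-named library matrices can describe near-identical
motifs, retained motifs are grouped by a PWM similarity measure (best ungapped
alignment offset over both orientations, mean column-wise Pearson correlation
rescaled to [0, 1]) and single-linkage clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .motifs import (
    FeatureTable,
    LabelledSequence,
    LogOddsMatrix,
    PositionWeightMatrix,
    build_feature_matrix,
)

logger = logging.getLogger(__name__)

#: coefficients with absolute value above this count as "in the model"
NONZERO_EPS = 1e-8

#: lambda grid used when no penalty is given (5-fold CV deviance minimiser)
DEFAULT_LAMBDA_GRID = tuple(np.geomspace(0.1, 100.0, 8))


@dataclass
class SparseLRModel:
    """Fitted L1-penalised logistic regression over motif features.

    ``coef`` is on the original feature scale; ``coef_fitted`` on the scale
    actually optimised (standardised when ``standardise=True``), which is the
    scale used for selection.
    """

    intercept: float
    coef: np.ndarray
    lam: float
    matrix_ids: list[str]
    coef_fitted: np.ndarray
    nonzero_eps: float = NONZERO_EPS

    @property
    def selected(self) -> frozenset[str]:
        mask = np.abs(self.coef_fitted) > self.nonzero_eps
        return frozenset(m for m, keep in zip(self.matrix_ids, mask) if keep)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.intercept + np.asarray(X, float) @ self.coef
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class StabilitySelection:
    """Per-run selected motif sets and their intersection."""

    per_run_selected: list[frozenset[str]]
    per_run_lambda: list[float]

    @property
    def retained(self) -> frozenset[str]:
        if not self.per_run_selected:
            return frozenset()
        out = set(self.per_run_selected[0])
        for s in self.per_run_selected[1:]:
            out &= s
        return frozenset(out)


@dataclass
class MotifCluster:
    representative: str
    members: frozenset[str]


# ---------------------------------------------------------------------------
# Background sampling
# ---------------------------------------------------------------------------

def sample_background(
    pool: Sequence,
    peaks: Iterable | None,
    n: int,
    seed: int,
    interval_of: Callable | None = None,
) -> list:
    """Draw ``n`` distinct background regions from a promoter pool.

    Pool entries overlapping any peak by >= 1 bp (half-open coordinates) are
    excluded first; ``interval_of`` maps an entry to an object with
    ``chrom``/``start``/``end`` (defaults to the entry itself when it has a
    ``chrom`` attribute, else no positional exclusion is possible).
    Reproducible for a fixed ``seed``.
    """
    if interval_of is None:
        interval_of = lambda x: x if hasattr(x, "chrom") else None
    eligible = list(pool)
    if peaks is not None:
        trees: dict[str, IntervalTree] = {}
        for p in peaks:
            trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
        kept = []
        for entry in eligible:
            iv = interval_of(entry)
            if iv is not None and iv.chrom in trees and trees[iv.chrom].overlaps(iv.start, iv.end):
                continue
            kept.append(entry)
        eligible = kept
    if len(eligible) < n:
        raise ValueError(
            f"background pool too small: need {n}, only {len(eligible)} "
            f"non-overlapping regions available (short by {n - len(eligible)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# Sparse logistic regression
# ---------------------------------------------------------------------------

def _standardise(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    constant = sd < 1e-12
    if constant.any():
        logger.warning("%d constant feature column(s); they receive beta=0", int(constant.sum()))
    sd = np.where(constant, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _polish_active_set(
    X: np.ndarray, y: np.ndarray, lam: float, beta: np.ndarray, beta0: float
) -> tuple[np.ndarray, float]:
    """Refine a lasso-LR solution on its sign pattern.

    With the active set and signs fixed, the penalised objective is smooth,
    so a quasi-Newton step with analytic gradient removes the solver's
    residual error.  Coefficients whose sign would flip are clamped to 0.
    """
    from scipy.optimize import minimize as _minimize

    active = np.abs(beta) > NONZERO_EPS
    signs = np.sign(beta[active])
    Xa = X[:, active]

    def neg_obj(params):
        b0, b = params[0], params[1:]
        z = b0 + Xa @ b
        ll = float(np.sum(y * z - np.logaddexp(0.0, z)))
        return -(ll - lam * float(signs @ b))

    def grad(params):
        b0, b = params[0], params[1:]
        p = 1.0 / (1.0 + np.exp(-(b0 + Xa @ b)))
        r = p - y
        return np.concatenate(([r.sum()], Xa.T @ r + lam * signs))

    x0 = np.concatenate(([beta0], beta[active]))
    res = _minimize(neg_obj, x0, jac=grad, method="BFGS", options={"gtol": 1e-12})
    if not res.success and neg_obj(res.x) > neg_obj(x0):
        return beta, beta0
    refined = res.x[1:]
    refined[np.sign(refined) != signs] = 0.0
    out = np.zeros_like(beta)
    out[active] = refined
    return out, float(res.x[0])


def fit_sparse_lr(
    ft: FeatureTable,
    lam: float,
    standardise: bool = True,
) -> SparseLRModel:
    """Fit the lasso logistic regression at penalty ``lam``.

    Maximises ``sum_i [y_i ln p_i + (1-y_i) ln(1-p_i)] - lam * sum_m |beta_m|``
    with an unpenalised intercept.  Features are standardised by default so
    the penalty is scale-fair; coefficients are reported on both scales.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X = ft.X
    if standardise:
        Xs, mu, sd = _standardise(X)
    else:
        Xs, mu, sd = X, np.zeros(ft.m), np.ones(ft.m)
    C = 1e12 if lam == 0 else 1.0 / lam
    # constant columns carry no signal and are kept with beta = 0 (they also
    # destabilise the saga solver, so they are excluded from the optimisation)
    varying = Xs.std(axis=0) > 1e-12
    beta_fit = np.zeros(ft.m)
    if varying.any():
        clf = LogisticRegression(
            l1_ratio=1.0, C=C, solver="saga", tol=1e-10, max_iter=200_000, random_state=0
        )
        clf.fit(Xs[:, varying], ft.labels)
        b, b0 = clf.coef_.ravel(), float(clf.intercept_[0])
        if lam > 0:  # at lam=0 separable data diverges; keep the solver's stop
            b, b0 = _polish_active_set(Xs[:, varying], ft.labels, lam, b, b0)
        beta_fit[varying] = b
        beta0_fit = b0
    else:
        p = ft.labels.mean()
        beta0_fit = float(np.log(p / (1.0 - p)))
    beta_fit[np.abs(beta_fit) <= NONZERO_EPS] = 0.0
    beta = beta_fit / sd
    beta0 = beta0_fit - float((beta_fit * mu / sd).sum())
    return SparseLRModel(
        intercept=beta0,
        coef=beta,
        lam=lam,
        matrix_ids=list(ft.matrix_ids),
        coef_fitted=beta_fit,
    )


def cv_lambda(
    ft: FeatureTable,
    lambdas: Sequence[float] = DEFAULT_LAMBDA_GRID,
    n_folds: int = 5,
    seed: int = 0,
    standardise: bool = True,
) -> float:
    """Pick the penalty minimising 5-fold cross-validated deviance."""
    X = ft.X
    if standardise:
        X, _, _ = _standardise(X)
    Cs = sorted(1.0 / np.asarray(lambdas, float))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    clf = LogisticRegressionCV(
        Cs=Cs,
        cv=cv,
        l1_ratios=(1.0,),
        solver="saga",
        scoring="neg_log_loss",
        tol=1e-4,
        max_iter=20_000,
        random_state=0,
        use_legacy_attributes=True,
    )
    clf.fit(X, ft.labels)
    return float(1.0 / clf.C_[0])


def stability_select(
    positives: Sequence[LabelledSequence],
    promoter_pool: Sequence,
    loms: Sequence[LogOddsMatrix],
    lam: float | None = None,
    runs: int = 5,
    seed: int = 0,
    peaks: Iterable | None = None,
    pool_intervals: Sequence | None = None,
    method: str = "logavgexp",
    n_background: int | None = None,
    pool_sequence_of: Callable | None = None,
) -> StabilitySelection:
    """Repeat the lasso fit against resampled backgrounds; intersect selections.

    Each run draws a fresh background sample (size = number of positives by
    default) from the promoter pool, excluding pool entries overlapping
    ``peaks``; run ``r`` uses a seed derived deterministically from
    ``(seed, r)``.  ``lam=None`` selects the penalty by cross-validation
    independently per run.  Pool entries may be :class:`LabelledSequence`
    objects or carry one via ``pool_sequence_of``; peak exclusion needs the
    pool's genomic coordinates in ``pool_intervals`` (parallel to the pool)
    or interval-bearing pool entries.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if pool_sequence_of is None:
        pool_sequence_of = lambda x: x
    n_bg = n_background if n_background is not None else len(positives)

    # Scan positives and the full pool once; runs only re-subset rows.
    pool_seqs = [pool_sequence_of(p) for p in promoter_pool]
    all_seqs = list(positives) + [
        LabelledSequence(s.id, s.bases, 0) if s.label != 0 else s for s in pool_seqs
    ]
    full = build_feature_matrix(all_seqs, loms, method=method)
    n_pos = len(positives)

    per_run: list[frozenset[str]] = []
    per_lam: list[float] = []
    for r in range(runs):
        run_seed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31))
        if peaks is None:
            interval_of: Callable = lambda i: None
        elif pool_intervals is not None:
            interval_of = lambda i: pool_intervals[i]
        else:
            interval_of = lambda i: promoter_pool[i] if hasattr(promoter_pool[i], "chrom") else None
        chosen = sample_background(
            list(range(len(promoter_pool))), peaks, n_bg, run_seed, interval_of=interval_of
        )
        rows = list(range(n_pos)) + [n_pos + i for i in chosen]
        ft = FeatureTable(
            seq_ids=[full.seq_ids[i] for i in rows],
            labels=full.labels[rows],
            X=full.X[rows],
            matrix_ids=full.matrix_ids,
        )
        run_lam = lam if lam is not None else cv_lambda(ft, seed=run_seed)
        model = fit_sparse_lr(ft, run_lam)
        per_run.append(model.selected)
        per_lam.append(run_lam)
        logger.info("run %d: lambda=%.4g selected %d motifs", r, run_lam, len(model.selected))
    return StabilitySelection(per_run_selected=per_run, per_run_lambda=per_lam)


def select_across_datasets(
    retained_sets: Sequence[Iterable[str]],
    min_support: int = 9,
) -> pd.DataFrame:
    """Keep motifs retained in at least ``min_support`` datasets.

    Returns a table (motif_id, support, included) sorted by descending
    support then motif id, covering every motif seen in any set.
    """
    if retained_sets and min_support > len(retained_sets):
        raise ValueError("min_support exceeds the number of datasets")
    support: dict[str, int] = {}
    for s in retained_sets:
        for m in set(s):
            support[m] = support.get(m, 0) + 1
    df = pd.DataFrame(
        [(m, c, c >= min_support) for m, c in support.items()],
        columns=["motif_id", "support", "included"],
    )
    return df.sort_values(["support", "motif_id"], ascending=[False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Motif similarity and clustering
# ---------------------------------------------------------------------------

def _column_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two probability columns (length-4 vectors).

    Flat columns have no direction: two flat columns correlate perfectly
    (both are uniform), a flat vs. a shaped column not at all.
    """
    sa, sb = a.std(), b.std()
    if sa < 1e-12 and sb < 1e-12:
        return 1.0
    if sa < 1e-12 or sb < 1e-12:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def motif_similarity(
    a: PositionWeightMatrix,
    b: PositionWeightMatrix,
    min_overlap: int = 4,
) -> float:
    """PWM similarity in [0, 1]: best ungapped offset over both orientations.

    At each offset the mean column-wise Pearson correlation over the
    overlapping columns (>= ``min_overlap``) is computed; the maximum over
    offsets and orientations is mapped from [-1, 1] to [0, 1].  Symmetric;
    identical matrices score 1.  If no offset reaches the minimum overlap the
    similarity is 0.
    """
    best = -np.inf
    for other in (b, b.reverse_complement()):
        pa, pb = a.probs, other.probs
        la, lb = len(pa), len(pb)
        for shift in range(-(lb - min_overlap), la - min_overlap + 1):
            lo_a, hi_a = max(0, shift), min(la, shift + lb)
            if hi_a - lo_a < min_overlap:
                continue
            cols_a = pa[lo_a:hi_a]
            cols_b = pb[lo_a - shift : hi_a - shift]
            r = np.mean([_column_pearson(ca, cb) for ca, cb in zip(cols_a, cols_b)])
            best = max(best, r)
    if not np.isfinite(best):
        return 0.0
    return float((best + 1.0) / 2.0)


def cluster_motifs(
    motifs: Sequence[PositionWeightMatrix],
    threshold: float = 0.9,
    min_overlap: int = 4,
) -> list[MotifCluster]:
    """Single-linkage clusters of the >= threshold similarity graph.

    The representative of each cluster is the member with the highest mean
    intra-cluster similarity (ties broken lexicographically by id).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    n = len(motifs)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = motif_similarity(motifs[i], motifs[j], min_overlap)
    # union-find over edges >= threshold
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if sim[i, j] >= threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for members in groups.values():
        if len(members) == 1:
            rep = members[0]
        else:
            mean_sim = {
                i: np.mean([sim[i, j] for j in members if j != i]) for i in members
            }
            rep = min(members, key=lambda i: (-mean_sim[i], motifs[i].id))
        clusters.append(
            MotifCluster(
                representative=motifs[rep].id,
                members=frozenset(motifs[i].id for i in members),
            )
        )
    return sorted(clusters, key=lambda c: c.representative)


def map_motifs_to_genes(
    motif_ids: Iterable[str],
    mapping: Mapping[str, Iterable[str]] | str | Path,
) -> tuple[dict[str, list[str]], list[str]]:
    """Map motif ids to the transcription-factor genes they model.

    ``mapping`` is either a dict ``motif_id -> gene symbols`` or a TSV path
    with columns ``matrix_id`` and ``gene`` (one pair per row).  Returns
    (gene -> sorted contributing motif ids, missing motif ids).
    """
    if not isinstance(mapping, Mapping):
        df = pd.read_csv(mapping, sep="\t")
        table: dict[str, list[str]] = {}
        for mid, gene in zip(df["matrix_id"].astype(str), df["gene"].astype(str)):
            table.setdefault(mid, []).append(gene)
        mapping = table
    genes: dict[str, set[str]] = {}
    missing: list[str] = []
    for mid in motif_ids:
        if mid not in mapping:
            missing.append(mid)
            logger.warning("motif %s has no gene mapping", mid)
            continue
        for g in mapping[mid]:
            genes.setdefault(g, set()).add(mid)
    return {g: sorted(ms) for g, ms in sorted(genes.items())}, missing
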