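"""Cumulative activity scoring and ranking of candidate repositioning drugs.

Input is a drug-by-activity probability matrix: for each compound and each
named biological activity, the probability P_a of being active (and
optionally P_i of being inactive), as produced by a structure–activity
predictor.  Given the activity list derived from the disease key nodes, each
compound receives the cumulative score

    S = sum_i P_a(i)   over the selected activities

(optionally sum_i [P_a(i) - P_i(i)]).  Compounds must exceed a score
threshold (strictly, default 3.0) and show activity for a required entry —
here the NF-κB transcription-factor inhibitor activity — to enter the final
descending-score ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

DEFAULT_REQUIRED_ACTIVITY = "Transcription factor NF-κB inhibitor"

PI_SUFFIX = ":Pi"


class ActivityMatrixError(ValueError):
    pass


@dataclass
class ActivitySpectrum:
    """Predicted activity probabilities for one compound."""

    drug_id: str
    activities: dict[str, tuple[float, float | None]]  # name -> (P_a, P_i or None)

    def __post_init__(self) -> None:
        for name, (pa, pi) in self.activities.items():
            for val, kind in ((pa, "P_a"), (pi, "P_i")):
                if val is not None and not (0.0 <= val <= 1.0):
                    raise ActivityMatrixError(
                        f"drug {self.drug_id}, activity {name!r}: {kind}={val} outside [0, 1]"
                    )

    def pa(self, activity: str) -> float | None:
        entry = self.activities.get(activity)
        return None if entry is None else entry[0]

    def pi(self, activity: str) -> float | None:
        entry = self.activities.get(activity)
        return None if entry is None else entry[1]


@dataclass
class ActivitySelection:
    """The activity panel a disease's key nodes translate into."""

    selected_activities: list[str]
    required_activity: str = DEFAULT_REQUIRED_ACTIVITY

    def __post_init__(self) -> None:
        if not self.selected_activities:
            raise ValueError("activity selection must be non-empty")
        if self.required_activity not in self.selected_activities:
            raise ValueError(
                f"required activity {self.required_activity!r} not in the selection"
            )


@dataclass
class DrugRanking:
    drug_id: str
    cumulative_score: float
    passes_threshold: bool
    passes_required: bool
    rank: int | None = None  # 1-based among passing drugs; None if filtered out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_activity_matrix(path: str | Path) -> list[ActivitySpectrum]:
    """Read a TSV of drugs x activities (first column drug id).

    A column ``<activity>:Pi`` pairs an inactivity probability with the
    P_a column ``<activity>``.  Out-of-range probabilities raise with the
    offending drug/column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    pa_cols = [c for c in df.columns if not c.endswith(PI_SUFFIX)]
    spectra = []
    for drug_id, row in df.iterrows():
        acts: dict[str, tuple[float, float | None]] = {}
        for col in pa_cols:
            pa = float(row[col])
            pi_col = col + PI_SUFFIX
            pi = float(row[pi_col]) if pi_col in df.columns else None
            for val, kind, cname in ((pa, "P_a", col), (pi, "P_i", pi_col)):
                if val is not None and not (0.0 <= val <= 1.0):
                    raise ActivityMatrixError(
                        f"{path}: drug {drug_id!r}, column {cname!r}: {kind}={val} outside [0, 1]"
                    )
            acts[col] = (pa, pi)
        spectra.append(ActivitySpectrum(str(drug_id), acts))
    return spectra


def write_ranking(rankings: Sequence[DrugRanking], path: str | Path) -> None:
    pd.DataFrame(
        {
            "drug_id": [r.drug_id for r in rankings],
            "cumulative_score": [r.cumulative_score for r in rankings],
            "passes_threshold": [r.passes_threshold for r in rankings],
            "passes_required": [r.passes_required for r in rankings],
            "rank": [r.rank for r in rankings],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Scoring, filtering, ranking
# ---------------------------------------------------------------------------

def cumulative_score(
    spec: ActivitySpectrum,
    sel: ActivitySelection,
    score_mode: str = "pa",
) -> float:
    """Sum of P_a over the selected activities (``pa_minus_pi`` subtracts P_i).

    An activity missing from a compound's spectrum contributes 0, so partial
    spectra remain usable.
    """
    total = 0.0
    for act in sel.selected_activities:
        entry = spec.activities.get(act)
        if entry is None:
            continue
        pa, pi = entry
        if score_mode == "pa":
            total += pa
        elif score_mode == "pa_minus_pi":
            total += pa - (pi or 0.0)
        else:
            raise ValueError(f"unknown score mode {score_mode!r}")
    return total


def apply_filters(
    spectra: Sequence[ActivitySpectrum],
    sel: ActivitySelection,
    threshold: float = 3.0,
    mode: str = "pa_positive",
    score_mode: str = "pa",
) -> list[DrugRanking]:
    """Evaluate both acceptance filters for every compound.

    A compound passes iff its cumulative score is *strictly* above
    ``threshold`` and the required activity is present with a positive P_a
    (``mode='pa_positive'``) or with P_a > P_i (``mode='pa_gt_pi'``).
    Returns one unranked record per input drug; :func:`rank_drugs` assigns
    ranks to the passing subset.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if mode not in ("pa_positive", "pa_gt_pi"):
        raise ValueError(f"unknown filter mode {mode!r}")
    out = []
    for spec in spectra:
        if spec.pa(sel.required_activity) is None:
            raise ActivityMatrixError(
                f"drug {spec.drug_id}: required activity "
                f"{sel.required_activity!r} absent from the spectrum"
            )
        score = cumulative_score(spec, sel, score_mode)
        pa = spec.pa(sel.required_activity)
        pi = spec.pi(sel.required_activity)
        if mode == "pa_positive":
            req_ok = pa > 0
        else:
            req_ok = pa > (pi if pi is not None else 0.0)
        out.append(
            DrugRanking(
                drug_id=spec.drug_id,
                cumulative_score=score,
                passes_threshold=score > threshold,
                passes_required=bool(req_ok),
            )
        )
    return out


def rank_drugs(records: Sequence[DrugRanking]) -> list[DrugRanking]:
    """Rank the compounds passing both filters.

    Descending cumulative score, ties broken lexicographically by drug id;
    rank 1 is the top candidate.  Non-passing records are dropped.
    """
    passing = [r for r in records if r.passes_threshold and r.passes_required]
    passing.sort(key=lambda r: (-r.cumulative_score, r.drug_id))
    return [
        DrugRanking(r.drug_id, r.cumulative_score, r.passes_threshold, r.passes_required, i + 1)
        for i, r in enumerate(passing)
    ]


def rank_activity_matrix(
    spectra: Sequence[ActivitySpectrum],
    sel: ActivitySelection,
    threshold: float = 3.0,
    mode: str = "pa_positive",
    score_mode: str = "pa",
) -> list[DrugRanking]:
    """Convenience: filters + ranking in one call."""
    return rank_drugs(apply_filters(spectra, sel, threshold, mode, score_mode))
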