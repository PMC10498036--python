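"""Dominance hierarchies from dyadic agonistic interactions: David's score.

Wins of shoving, pecking and wing-flapping contests are tallied into a
directed winner-loser matrix.  David's score summarises each individual's
success weighted by the strength of its opponents:

    w_i  = sum_j P_ij            (summed win proportions)
    w2_i = sum_j P_ij * w_j      (wins weighted by opponents' wins)
    l_i  = sum_j P_ji            (summed loss proportions)
    l2_i = sum_j P_ji * l_j      (losses weighted by opponents' losses)
    DS_i = w_i + w2_i - l_i - l2_i

where P_ij is the proportion of the i-j dyad's contests won by i.  Scores
sum to zero over the group; ranking by descending DS gives the hierarchy
(rank 1 = most dominant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InteractionMatrix",
    "DavidsScoreResult",
    "dyadic_proportions",
    "davids_score",
    "pool_trials",
    "read_interactions_csv",
]

BEHAVIOURS = ("shoving", "pecking", "wing_flapping")


class DominanceError(ValueError):
    """Invalid interaction data."""


@dataclass
class InteractionMatrix:
    """Directed win counts: ``wins[i, j]`` = contests won by *i* over *j*."""

    ids: list
    wins: np.ndarray
    behaviours: Optional[dict] = None  # per-behaviour win matrices
    feeder_time_s: Optional[np.ndarray] = None  # descriptive, not in the score
    truth: Optional[dict] = None  # generator metadata (latent abilities)

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.wins = np.asarray(self.wins)
        n = len(self.ids)
        if self.wins.shape != (n, n):
            raise DominanceError("wins matrix shape must match the id list")
        if np.any(self.wins < 0):
            raise DominanceError("win counts must be non-negative")
        if not np.issubdtype(self.wins.dtype, np.integer):
            if not np.allclose(self.wins, np.round(self.wins)):
                raise DominanceError("win counts must be integers")
            self.wins = self.wins.astype(np.int64)
        if np.any(np.diag(self.wins) != 0):
            raise DominanceError("diagonal (self-interactions) must be zero")

    @property
    def total_interactions(self) -> int:
        return int(self.wins.sum())


def dyadic_proportions(
    m: InteractionMatrix, corrected: bool = False
) -> np.ndarray:
    """Win-proportion matrix P (or the corrected dyadic index D).

    Uncorrected (default): ``P_ij = wins_ij / (wins_ij + wins_ji)``, with
    dyads that never interacted contributing 0 in both directions rather
    than being imputed at 0.5 — no information is manufactured for unseen
    pairs.  Corrected: the sample-size-adjusted dyadic index
    ``D_ij = (wins_ij + 0.5) / (n_ij + 1)``, which shrinks small-sample
    proportions toward one half (and assigns exactly 0.5 to empty dyads).
    """
    wins = m.wins.astype(float)
    n_dyad = wins + wins.T
    if corrected:
        p = (wins + 0.5) / (n_dyad + 1.0)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_dyad > 0, wins / np.where(n_dyad > 0, n_dyad, 1), 0.0)
    np.fill_diagonal(p, 0.0)
    return p


@dataclass
class DavidsScoreResult:
    """David's scores, their components and the implied rank order."""

    ids: list
    P: np.ndarray
    w: np.ndarray
    w2: np.ndarray
    l: np.ndarray
    l2: np.ndarray
    DS: np.ndarray
    rank: np.ndarray  # rank[i] = dominance rank of ids[i]; 1 = most dominant
    ties: bool = field(default=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chick_id": self.ids,
                "w": self.w,
                "w2": self.w2,
                "l": self.l,
                "l2": self.l2,
                "DS": self.DS,
                "rank": self.rank,
            }
        )


def davids_score(
    P: np.ndarray, ids: Optional[Sequence] = None
) -> DavidsScoreResult:
    """Compute David's scores and ranks from a dyadic proportion matrix.

    Ties in DS are broken by identifier order and flagged.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise DominanceError("P must be square")
    n = P.shape[0]
    if ids is None:
        ids = list(range(n))
    ids = list(ids)
    if len(ids) != n:
        raise DominanceError("id list length must match P")
    w = P.sum(axis=1)
    w2 = P @ w
    loss = P.sum(axis=0)
    l2 = P.T @ loss
    ds = w + w2 - loss - l2
    order = np.lexsort((np.arange(n), -ds))  # descending DS, ties by id order
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    ties = bool(len(np.unique(ds)) < n)
    return DavidsScoreResult(ids, P, w, w2, loss, l2, ds, rank, ties)


def score_interactions(
    m: InteractionMatrix, corrected: bool = False
) -> DavidsScoreResult:
    """Convenience: proportions then David's score on one matrix."""
    return davids_score(dyadic_proportions(m, corrected=corrected), ids=m.ids)


def pool_trials(trials: Sequence[InteractionMatrix]) -> InteractionMatrix:
    """Element-wise sum of win matrices across trials (same id sets)."""
    if not trials:
        raise DominanceError("no trials to pool")
    base = trials[0]
    wins = base.wins.copy()
    behaviours = (
        {k: v.copy() for k, v in base.behaviours.items()} if base.behaviours else None
    )
    feeder = base.feeder_time_s.copy() if base.feeder_time_s is not None else None
    for tr in trials[1:]:
        if tr.ids != base.ids:
            raise DominanceError("cannot pool trials with mismatched ids")
        wins = wins + tr.wins
        if behaviours is not None and tr.behaviours:
            for k, v in tr.behaviours.items():
                behaviours[k] = behaviours.get(k, np.zeros_like(v)) + v
        if feeder is not None and tr.feeder_time_s is not None:
            feeder = feeder + tr.feeder_time_s
    return InteractionMatrix(base.ids, wins, behaviours=behaviours, feeder_time_s=feeder)


def read_interactions_csv(path) -> list[InteractionMatrix]:
    """Load per-trial matrices from a long-format tally CSV.

    Expected columns: trial_id, winner_id, loser_id, count and optionally
    behaviour.  Ids are pooled across the whole file so every trial shares
    the same ordered id set.
    """
    frame = pd.read_csv(path)
    ids = sorted(set(frame["winner_id"].astype(str)) | set(frame["loser_id"].astype(str)))
    index = {c: i for i, c in enumerate(ids)}
    has_behaviour = "behaviour" in frame.columns
    out = []
    trial_ids = frame["trial_id"].unique() if "trial_id" in frame.columns else [0]
    for tid in sorted(trial_ids):
        part = frame if "trial_id" not in frame.columns else frame[frame["trial_id"] == tid]
        wins = np.zeros((len(ids), len(ids)), dtype=np.int64)
        behaviours: dict = {}
        for _, row in part.iterrows():
            i, j = index[str(row["winner_id"])], index[str(row["loser_id"])]
            c = int(row["count"])
            wins[i, j] += c
            if has_behaviour:
                b = str(row["behaviour"])
                behaviours.setdefault(
                    b, np.zeros((len(ids), len(ids)), dtype=np.int64)
                )[i, j] += c
        out.append(
            InteractionMatrix(ids, wins, behaviours=behaviours or None)
        )
    return out
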