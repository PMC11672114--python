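"""Multi-scorer consensus: soft-agreement reliability, majority vote with
reliability-based tie-breaking, and the PSG/in-ear intersection labels.

Soft-agreement of scorer j is the mean, over epochs, of the probabilistic
consensus of the other J-1 scorers evaluated at scorer j's own label, where
the per-epoch consensus is the stage-count vector of the other scorers
normalized by its maximum (so a stage scores 1 when it is in the others'
majority or tie set).  Epochs where any scorer assigned MOVEMENT/UNKNOWN are
removed first, keeping the stage alphabet at K = 3.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Hypnogram, ScorerPanel, STAGES3, EXCLUDED_LABELS

UNSCORED = "UNKNOWN"  # consensus placeholder on removed epochs


@dataclass
class ConsensusResult:
    labels: np.ndarray                # length T, UNSCORED on removed epochs
    soft_agreement: np.ndarray        # per scorer, in [0, 1]
    ranking: np.ndarray               # scorer indices, most reliable first
    tie_mask: np.ndarray              # epochs decided by the tie-break
    usable_mask: np.ndarray           # epochs entering the computation
    source: str = "PSG"


@dataclass
class IntersectionLabels:
    mask: np.ndarray                  # True where both consensus agree
    labels: np.ndarray                # stage per retained epoch
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())


def _stage_counts(labels: np.ndarray) -> np.ndarray:
    """(K, T) stage-count matrix of a (J, T) label matrix."""
    return np.stack([(labels == s).sum(axis=0) for s in STAGES3]).astype(float)


def soft_agreement(panel: ScorerPanel) -> np.ndarray:
    """Per-scorer soft-agreement scores in [0, 1]."""
    if panel.n_scorers < 2:
        raise ValueError("soft-agreement needs at least two scorers")
    usable = panel.usable_mask()
    if not usable.any():
        raise ValueError("no usable epochs (all contain MOVEMENT/UNKNOWN)")
    labels = panel.label_matrix()[:, usable]
    J, T = labels.shape
    scores = np.empty(J)
    for j in range(J):
        others = np.delete(labels, j, axis=0)
        counts = _stage_counts(others)          # (K, T)
        z = counts / counts.max(axis=0)         # per-epoch max normalization
        own = np.array([STAGES3.index(l) for l in labels[j]])
        scores[j] = z[own, np.arange(T)].mean()
    return scores


def rank_scorers(scores: np.ndarray) -> np.ndarray:
    """Scorer indices ordered by decreasing soft-agreement; equal scores
    break by ascending scorer index (documented determinism)."""
    return np.lexsort((np.arange(len(scores)), -scores))


def consensus_labels(panel: ScorerPanel) -> ConsensusResult:
    """Majority-vote consensus with soft-agreement tie-breaking.

    Each usable epoch gets the most voted stage; when the top vote count is
    shared, the label of the top-ranked scorer decides.  Removed epochs
    (any MOVEMENT/UNKNOWN) are marked :data:`UNSCORED`.
    """
    if panel.n_scorers < 2:
        raise ValueError("consensus needs at least two scorers")
    scores = soft_agreement(panel)
    ranking = rank_scorers(scores)
    usable = panel.usable_mask()
    labels = panel.label_matrix()
    T = panel.n_epochs

    out = np.full(T, UNSCORED, dtype=object)
    tie_mask = np.zeros(T, dtype=bool)
    counts = _stage_counts(labels[:, usable])
    top = counts.max(axis=0)
    is_tie = (counts == top).sum(axis=0) > 1
    winner = counts.argmax(axis=0)
    best = ranking[0]

    idx = np.flatnonzero(usable)
    for pos, t in enumerate(idx):
        if is_tie[pos]:
            out[t] = labels[best, t]
            tie_mask[t] = True
        else:
            out[t] = STAGES3[winner[pos]]
    return ConsensusResult(out, scores, ranking, tie_mask, usable, panel.source)


def intersection_labels(
    cons_psg: ConsensusResult | np.ndarray, cons_inear: ConsensusResult | np.ndarray
) -> IntersectionLabels:
    """Epochs where the PSG and in-ear consensus agree on a real stage."""
    a = cons_psg.labels if isinstance(cons_psg, ConsensusResult) else np.asarray(cons_psg, dtype=object)
    b = cons_inear.labels if isinstance(cons_inear, ConsensusResult) else np.asarray(cons_inear, dtype=object)
    if len(a) != len(b):
        raise ValueError(f"consensus length mismatch: {len(a)} vs {len(b)}")
    valid = ~np.isin(a.astype(str), EXCLUDED_LABELS) & ~np.isin(b.astype(str), EXCLUDED_LABELS)
    mask = valid & (a == b)
    labels = a[mask]
    counts = {s: int((labels == s).sum()) for s in STAGES3}
    return IntersectionLabels(mask, labels, counts)
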