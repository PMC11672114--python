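"""Inter- and intra-scorer agreement: Cohen's kappa, Fleiss' kappa,
Landis–Koch interpretation and per-stage precision/recall/F1 against the PSG
consensus.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support
from statsmodels.stats.inter_rater import aggregate_raters
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss

from .core import Hypnogram, ScorerPanel, STAGES3, EXCLUDED_LABELS


def _pair_usable(h1: Hypnogram, h2: Hypnogram) -> tuple[np.ndarray, np.ndarray]:
    a, b = h1.labels, h2.labels
    if len(a) != len(b):
        raise ValueError("hypnograms differ in length")
    keep = ~(
        np.isin(a.astype(str), EXCLUDED_LABELS)
        | np.isin(b.astype(str), EXCLUDED_LABELS)
    )
    if not keep.any():
        raise ValueError("no usable epochs after MOVEMENT/UNKNOWN removal")
    return a[keep], b[keep]


def cohen_kappa(h1: Hypnogram, h2: Hypnogram) -> float:
    """Chance-corrected pairwise agreement.

    kappa = (p_o - p_e) / (1 - p_e) with the expected agreement p_e from the
    product of marginals; the degenerate p_o = p_e = 1 case (both raters
    constant and identical) returns 1.
    """
    a, b = _pair_usable(h1, h2)
    cats = sorted(set(a) | set(b))
    n = len(a)
    table = np.zeros((len(cats), len(cats)))
    idx = {c: i for i, c in enumerate(cats)}
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if np.isclose(p_e, 1.0):
        return 1.0 if np.isclose(p_o, 1.0) else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def fleiss_kappa(panel: ScorerPanel) -> float:
    """Fleiss' kappa over the panel's usable epochs (fixed J per epoch).

    Returns NaN with a warning when the statistic is undefined (all raters
    using a single category on every epoch).
    """
    if panel.n_scorers < 2:
        raise ValueError("Fleiss' kappa needs at least two scorers")
    usable = panel.usable_mask()
    if not usable.any():
        raise ValueError("no usable epochs after MOVEMENT/UNKNOWN removal")
    labels = panel.label_matrix()[:, usable]
    if len(set(labels.reshape(-1))) == 1:
        warnings.warn("Fleiss' kappa undefined: single category used throughout")
        return float("nan")
    table, _ = aggregate_raters(labels.T)
    return float(_sm_fleiss(table))


#: Landis & Koch interpretation bands (upper edges, inclusive)
_LANDIS_KOCH = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
)


def interpret_kappa(kappa: float) -> str:
    """Landis–Koch qualitative band of a kappa value."""
    if kappa > 1.0 + 1e-12:
        raise ValueError("kappa cannot exceed 1")
    if kappa < 0.0:
        return "poor"
    for edge, name in _LANDIS_KOCH:
        if kappa <= edge:
            return name
    return "almost-perfect"


@dataclass
class StagePRF:
    precision: float
    recall: float
    f1: float
    undefined_precision: bool = False  # no positive predictions
    missing: bool = False              # stage absent from gold and pred


def stage_prf(gold: np.ndarray, pred: np.ndarray, stage: str) -> StagePRF:
    """One-vs-rest precision/recall/F1 for one stage, PSG consensus as gold.

    A stage never predicted yields precision 0 with an explicit flag (so
    cross-subject averaging stays defined); a stage absent from both gold
    and predictions is reported missing.
    """
    gold = np.asarray(gold, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if len(gold) != len(pred):
        raise ValueError("label sequences differ in length")
    g = gold == stage
    p = pred == stage
    if not g.any() and not p.any():
        return StagePRF(float("nan"), float("nan"), float("nan"), missing=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, _ = precision_recall_fscore_support(
            g, p, average="binary", zero_division=0
        )
    return StagePRF(float(prec), float(rec), float(f1), undefined_precision=not p.any())


def agreement_tables(
    cohen_rows: list[dict], fleiss_rows: list[dict], prf_rows: list[dict]
) -> dict[str, pd.DataFrame]:
    """Assemble tidy agreement tables with Landis–Koch bands attached."""
    cohen = pd.DataFrame(cohen_rows)
    if not cohen.empty:
        cohen["band"] = cohen["kappa"].map(interpret_kappa)
    fleiss = pd.DataFrame(fleiss_rows)
    if not fleiss.empty:
        fleiss["band"] = fleiss["kappa"].map(
            lambda k: "undefined" if np.isnan(k) else interpret_kappa(k)
        )
    return {"cohen": cohen, "fleiss": fleiss, "prf": pd.DataFrame(prf_rows)}
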