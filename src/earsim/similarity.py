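"""Jensen-Shannon divergence feature similarity: per-feature PDF estimation,
JSD in base 2 (so it lives in [0, 1]), the per-pair JSD-FSI score, and the
full in-ear + PSG-to-PSG pair sweep.

JSD-FSI of a channel pair within one sleep stage is the mean over the
selected features of (1 - JSD_n), where JSD_n compares the two channels'
distributions of feature n across that stage's epochs:

    JSD(p, q) = [KL(p || m) + KL(q || m)] / 2,   m = (p + q) / 2

1 means identical feature distributions, 0 means disjoint ones.  PDFs are
Gaussian KDEs (Scott bandwidth) evaluated on one shared 256-point grid and
renormalized to sum to 1; a histogram estimator with shared bins is
available since absolute JSD values depend on the estimator choice.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import ROLE_EOG, ROLE_INEAR, ROLE_MASTOID, ROLE_SCALP
from .features import FeatureDataset
from .selection import SelectionResult, select_for_pair

DEFAULT_GRID_SIZE = 256
DEFAULT_M_MIN = 5  # minimum usable epochs per sample


@dataclass
class PDFEstimate:
    grid: np.ndarray
    prob: np.ndarray          # sums to 1
    estimator: str
    bandwidth: float | None = None


def _point_mass(grid: np.ndarray, value: float) -> np.ndarray:
    prob = np.zeros_like(grid)
    prob[int(np.argmin(np.abs(grid - value)))] = 1.0
    return prob


def estimate_pdf(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    grid_size: int = DEFAULT_GRID_SIZE,
    m_min: int = DEFAULT_M_MIN,
    estimator: str = "kde",
) -> tuple[PDFEstimate, PDFEstimate]:
    """Discrete PDFs of two samples on one shared grid.

    The grid spans the union range padded by three bandwidths; zero-variance
    samples become a point mass on the nearest grid cell.  Samples shorter
    than ``m_min`` (after NaN removal) raise — callers skip the pair.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < m_min or len(b) < m_min:
        raise ValueError(f"sample below the minimum size {m_min}")

    def bw(x: np.ndarray) -> float:
        sd = x.std(ddof=1)
        if sd == 0:
            return 0.0
        return float(sd * len(x) ** (-1.0 / 5.0))  # Scott's rule, 1-D

    bw_a, bw_b = bw(a), bw(b)
    pad = 3.0 * max(bw_a, bw_b)
    lo = min(a.min(), b.min()) - pad
    hi = max(a.max(), b.max()) + pad
    if hi - lo <= 0:
        lo, hi = lo - 1.0, hi + 1.0
    grid = np.linspace(lo, hi, grid_size)

    def one(x: np.ndarray, x_bw: float) -> PDFEstimate:
        if x_bw == 0.0:
            return PDFEstimate(grid, _point_mass(grid, x[0]), "point-mass", None)
        if estimator == "kde":
            kde = stats.gaussian_kde(x, bw_method="scott")
            prob = kde(grid)
        elif estimator == "histogram":
            counts, edges = np.histogram(x, bins=grid_size, range=(lo, hi))
            prob = counts.astype(float)
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        total = prob.sum()
        if total <= 0:
            return PDFEstimate(grid, _point_mass(grid, float(np.median(x))), estimator, x_bw)
        return PDFEstimate(grid, prob / total, estimator, x_bw)

    return one(a, bw_a), one(b, bw_b)


def _kl(p: np.ndarray, m: np.ndarray, base: float) -> float:
    """KL(p || m); p(t)=0 terms contribute 0 (m > 0 wherever p > 0)."""
    nz = p > 0
    return float(np.sum(p[nz] * (np.log(p[nz] / m[nz]) / np.log(base))))


def jsd(p: PDFEstimate | np.ndarray, q: PDFEstimate | np.ndarray, base: float = 2.0) -> float:
    """Jensen-Shannon divergence of two discrete PDFs on a shared grid.

    With base-2 logarithms the value is 0 for identical and 1 for disjoint
    distributions.
    """
    if isinstance(p, PDFEstimate) and isinstance(q, PDFEstimate):
        if len(p.grid) != len(q.grid) or not np.allclose(p.grid, q.grid):
            raise ValueError("PDFs were estimated on different grids")
        pv, qv = p.prob, q.prob
    else:
        pv = np.asarray(p, dtype=float)
        qv = np.asarray(q, dtype=float)
        if pv.shape != qv.shape:
            raise ValueError("distributions differ in shape")
    m = (pv + qv) / 2.0
    return (_kl(pv, m, base) + _kl(qv, m, base)) / 2.0


@dataclass
class PairScore:
    score: float
    per_feature: dict[str, float]
    skipped: list[str]
    n_features: int


def jsd_fsi(
    da: FeatureDataset | pd.DataFrame,
    db: FeatureDataset | pd.DataFrame,
    selected: SelectionResult | list[str],
    m_min: int = DEFAULT_M_MIN,
    grid_size: int = DEFAULT_GRID_SIZE,
    estimator: str = "kde",
) -> PairScore:
    """Mean of (1 - JSD_n) over the selected features of one channel pair.

    Missing values are dropped per feature; features with fewer than
    ``m_min`` usable epochs on either side are skipped and excluded from N.
    """
    fa = da.data if isinstance(da, FeatureDataset) else da
    fb = db.data if isinstance(db, FeatureDataset) else db
    names = selected.selected if isinstance(selected, SelectionResult) else list(selected)
    per_feature: dict[str, float] = {}
    skipped: list[str] = []
    for name in names:
        try:
            pa, pb = estimate_pdf(
                fa[name].to_numpy(), fb[name].to_numpy(), grid_size, m_min, estimator
            )
        except ValueError:
            skipped.append(name)
            continue
        per_feature[name] = jsd(pa, pb)
    if not per_feature:
        raise ValueError("no usable features for this pair")
    score = float(np.mean([1.0 - v for v in per_feature.values()]))
    return PairScore(score, per_feature, skipped, len(per_feature))


def pair_class(role_a: str, role_b: str) -> str:
    """Label a channel pair; the mastoid-to-mastoid derivation is analysed
    among the scalp-EEG set."""
    def norm(role: str) -> str:
        return ROLE_SCALP if role == ROLE_MASTOID else role

    a, b = norm(role_a), norm(role_b)
    if ROLE_INEAR in (a, b):
        return "PSG-to-in-ear"
    kinds = {a, b}
    if kinds == {ROLE_SCALP}:
        return "scalp-to-scalp"
    if kinds == {ROLE_EOG}:
        return "EOG-to-EOG"
    return "scalp-to-EOG"


def similarity_report(
    datasets: dict[str, dict[str, FeatureDataset | None]],
    roles: dict[str, str],
    subject: str = "S01",
    inear_channel: str = "CH1",
    include_psg_pairs: bool = True,
    k_grid: list[int] | None = None,
    m_min: int = DEFAULT_M_MIN,
    estimator: str = "kde",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """JSD-FSI for every {q, CH1} pair and (optionally) every unordered PSG
    pair, per stage.

    ``datasets`` maps channel -> stage -> FeatureDataset (None marks an
    absent stage).  Feature selection runs per pair on the row-concatenated
    z-scored datasets, so both sides share one feature list.  Returns
    (scores, per-feature JSD rows) as tidy frames.
    """
    channels = list(datasets)
    psg = [c for c in channels if c != inear_channel]
    pairs: list[tuple[str, str]] = []
    if inear_channel in datasets:
        pairs.extend((q, inear_channel) for q in psg)
    if include_psg_pairs:
        pairs.extend(combinations(psg, 2))

    stages = sorted({s for per in datasets.values() for s in per})
    rows, feat_rows = [], []
    for stage in stages:
        for a, b in pairs:
            da, db = datasets[a].get(stage), datasets[b].get(stage)
            if da is None or db is None or da.n_epochs < m_min or db.n_epochs < m_min:
                continue
            sel = select_for_pair(da.data, db.data, k_grid)
            try:
                ps = jsd_fsi(da, db, sel, m_min=m_min, estimator=estimator)
            except ValueError:
                continue
            rows.append(
                {
                    "subject": subject,
                    "stage": stage,
                    "chan_a": a,
                    "chan_b": b,
                    "pair_class": pair_class(roles[a], roles[b]),
                    "score": ps.score,
                    "n_features": ps.n_features,
                    "k": sel.k,
                }
            )
            feat_rows.extend(
                {
                    "subject": subject,
                    "stage": stage,
                    "chan_a": a,
                    "chan_b": b,
                    "feature": f,
                    "jsd": v,
                }
                for f, v in ps.per_feature.items()
            )
    return pd.DataFrame(rows), pd.DataFrame(feat_rows)
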