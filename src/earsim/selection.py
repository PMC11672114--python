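"""Unsupervised redundancy removal via the maximal information compression
index (MICI) with k-NN pruning.

MICI of a feature pair is the smallest eigenvalue of its 2x2 covariance:

    lambda2 = (vx + vy - sqrt((vx + vy)^2 - 4 vx vy (1 - rho^2))) / 2

It is zero iff the pair is perfectly linearly dependent, and on z-scored
columns reduces exactly to 1 - |rho| — an identity the tests use as oracle.
Selection repeatedly keeps the feature whose k-th nearest neighbour (in MICI
dissimilarity) is closest and discards those k neighbours, shrinking k when
few features remain; the initial k is scanned and chosen by representation
entropy, ties broken toward lower redundancy rate, then smaller k.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SelectionResult:
    selected: list[str]
    k: int
    dissimilarity: pd.DataFrame       # symmetric, zero diagonal
    representation_entropy: float
    redundancy_rate: float
    discard_log: dict[str, list[str]] = field(default_factory=dict)
    constant_features: list[str] = field(default_factory=list)


def zscore_normalize(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Column-wise z-scoring (population std); constant columns become zeros
    and are returned as flagged names."""
    if len(df) < 2:
        raise ValueError("z-scoring needs at least two rows")
    mean = df.mean(axis=0)
    std = df.std(axis=0, ddof=0)
    constant = std[std == 0].index.tolist()
    std = std.replace(0.0, 1.0)
    return (df - mean) / std, constant


def mici(x: np.ndarray, y: np.ndarray) -> float:
    """Smallest covariance eigenvalue of one feature pair (lambda2 >= 0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("mici needs two equal-length columns of >= 2 values")
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return 0.0
    rho = np.corrcoef(x, y)[0, 1]
    s = vx + vy
    disc = max(s * s - 4.0 * vx * vy * (1.0 - rho * rho), 0.0)
    return float((s - np.sqrt(disc)) / 2.0)


def mici_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """All-pairs MICI dissimilarity (vectorized through the correlation
    matrix); symmetric with a zero diagonal."""
    X = df.to_numpy(dtype=float)
    v = X.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(X, rowvar=False)
    rho = np.nan_to_num(rho, nan=0.0)
    s = v[:, None] + v[None, :]
    disc = np.clip(s * s - 4.0 * np.outer(v, v) * (1.0 - rho * rho), 0.0, None)
    lam = (s - np.sqrt(disc)) / 2.0
    lam[(v == 0)[:, None] | (v == 0)[None, :]] = 0.0
    np.fill_diagonal(lam, 0.0)
    lam = np.maximum(lam, lam.T)  # enforce exact symmetry
    return pd.DataFrame(lam, index=df.columns, columns=df.columns)


def select_features(df: pd.DataFrame, k: int) -> SelectionResult:
    """Iterative k-NN pruning in MICI feature-dissimilarity space.

    ``df`` must already be z-scored; columns flagged constant should be
    dropped beforehand (see :func:`select_for_pair`).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    names = list(df.columns)
    if k >= len(names):
        raise ValueError(f"k={k} must be smaller than the feature count {len(names)}")
    dis = mici_matrix(df)
    D = dis.to_numpy()
    remaining = list(range(len(names)))
    selected: list[int] = []
    discard_log: dict[str, list[str]] = {}
    kk = k
    while remaining:
        if kk >= len(remaining):
            kk = len(remaining) - 1
        if kk == 0:
            selected.extend(remaining)
            for i in remaining:
                discard_log.setdefault(names[i], [])
            break
        sub = D[np.ix_(remaining, remaining)]
        order = np.sort(sub, axis=1)
        radii = order[:, kk]  # distance to the k-th nearest neighbour
        pick = int(np.argmin(radii))
        neigh_order = np.argsort(sub[pick], kind="stable")
        neighbours = [j for j in neigh_order if j != pick][:kk]
        keep_idx = remaining[pick]
        selected.append(keep_idx)
        discard_log[names[keep_idx]] = [names[remaining[j]] for j in neighbours]
        drop = {remaining[j] for j in neighbours} | {keep_idx}
        remaining = [i for i in remaining if i not in drop]
    sel_names = [names[i] for i in sorted(selected)]
    if len(sel_names) >= 2:
        rep_h, red = subset_quality(df, sel_names)
    else:  # a single surviving feature carries no spread to measure
        rep_h, red = 0.0, float("nan")
    return SelectionResult(sel_names, k, dis, rep_h, red, discard_log)


def subset_quality(df: pd.DataFrame, subset: list[str]) -> tuple[float, float]:
    """(representation entropy, redundancy rate) of a feature subset.

    Representation entropy is the Shannon entropy (natural log) of the
    normalized covariance eigenvalues — maximal, log d, when information is
    spread evenly; redundancy rate is the mean absolute pairwise correlation.
    """
    if len(subset) < 2:
        raise ValueError("subset quality needs at least two features")
    X = df[subset].to_numpy(dtype=float)
    cov = np.cov(X, rowvar=False)
    eig = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
    total = eig.sum()
    if total == 0:
        return 0.0, float("nan")
    p = eig / total
    p = p[p > 0]
    rep_h = float(-(p * np.log(p)).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(X, rowvar=False)
    rho = np.nan_to_num(rho, nan=1.0)
    iu = np.triu_indices(len(subset), k=1)
    red = float(np.abs(rho[iu]).mean())
    return rep_h, red


def choose_k(df: pd.DataFrame, k_grid: list[int] | None = None) -> tuple[int, SelectionResult]:
    """Scan k and keep the selection maximizing representation entropy;
    ties break toward lower redundancy rate, then smaller k."""
    n = df.shape[1]
    if k_grid is None:
        k_grid = list(range(1, max(min(10, n - 2), 1) + 1))
    if not k_grid:
        raise ValueError("empty k grid")
    best: tuple[float, float, int, SelectionResult] | None = None
    for k in sorted(k_grid):
        if k >= n:
            continue
        res = select_features(df, k)
        red = res.redundancy_rate if np.isfinite(res.redundancy_rate) else np.inf
        key = (-res.representation_entropy, red, k)
        if best is None or key < (best[0], best[1], best[2]):
            best = (key[0], key[1], key[2], res)
    if best is None:
        raise ValueError("no usable k in the grid")
    return best[2], best[3]


def select_for_pair(
    da: pd.DataFrame, db: pd.DataFrame, k_grid: list[int] | None = None
) -> SelectionResult:
    """Shared feature subset for one channel pair.

    Each dataset is z-scored separately (per channel, per stage), constant
    columns are dropped, and selection runs on the row-wise concatenation so
    both sides share one feature list.
    """
    za, ca = zscore_normalize(da)
    zb, cb = zscore_normalize(db)
    constant = sorted(set(ca) | set(cb))
    cols = [c for c in da.columns if c not in constant]
    pooled = pd.concat([za[cols], zb[cols]], axis=0, ignore_index=True)
    pooled = pooled.dropna(axis=1)  # features degenerate on any epoch subset
    _, res = choose_k(pooled, k_grid)
    res.constant_features = constant
    return res
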