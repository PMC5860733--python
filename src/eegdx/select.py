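"""Feature ranking and selection: OFR with the random-probe stopping rule.

Orthogonal forward regression greedily ranks candidate features: pick the
column with the largest squared correlation to the current (residual)
target, then Gram-Schmidt-orthogonalize the remaining columns and the
target against the pick, and repeat.  The random-probe method appends
"probe" columns — random realizations of features that are irrelevant by
construction (seeded row permutations of real columns by default) — ranks
real and probe columns jointly, and accepts a real candidate only while the
fraction of probes ranked above it stays below the user's acceptable risk.
With 100 probes and risk 0.10 this is "keep only variables that rank better
than 90% of the probes".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "build_feature_matrix",
    "fold_feature_matrices",
    "OFRRanking",
    "ofr_rank",
    "ProbeSelection",
    "probe_select",
    "decorrelate_covariate",
]

_NORM_TOL = 1e-10


def _check_primary(primary: pd.DataFrame) -> None:
    if primary.isna().any().any():
        bad = primary.isna().stack()
        subj, feat = bad[bad].index[0]
        raise ValueError(f"missing feature {feat!r} for subject {subj!r}")
    sd = primary.std(axis=0, ddof=0)
    if (sd < 1e-12).any():
        raise ValueError(f"constant feature column {sd.idxmin()!r} (zero variance)")


def build_feature_matrix(primary: pd.DataFrame) -> pd.DataFrame:
    """Standardize the primary features and append their squares.

    Input: subjects x 16 primary features.  Each primary column is scaled to
    zero mean / unit variance over subjects *before* squaring, and the
    squared columns (named ``<feature>^2``) are appended, giving the
    32-column candidate matrix.
    """
    _check_primary(primary)
    z = (primary - primary.mean(axis=0)) / primary.std(axis=0, ddof=0)
    sq = (z**2).rename(columns=lambda c: f"{c}^2")
    return pd.concat([z, sq], axis=1)


def fold_feature_matrices(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize-and-square using *training* statistics only.

    The held-out rows in ``test`` are transformed with the training fold's
    means and standard deviations, so no information leaks from them.
    """
    _check_primary(train)
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    def _tx(df: pd.DataFrame) -> pd.DataFrame:
        z = (df - mu) / sd
        return pd.concat([z, (z**2).rename(columns=lambda c: f"{c}^2")], axis=1)
    return _tx(train), _tx(test)


def _ofr_steps(X: np.ndarray, y: np.ndarray):
    """Yield (column index, squared-cosine score, cumulative explained variance).

    Operates on centered copies; remaining columns and the target are
    orthogonalized against each pick.  Stops early when every remaining
    column (or the residual target) is numerically null.
    """
    Xr = X - X.mean(axis=0)
    yr = y - y.mean()
    total = float(yr @ yr)
    if total < _NORM_TOL:
        return
    remaining = list(range(X.shape[1]))
    explained = 0.0
    while remaining:
        norms = np.array([Xr[:, j] @ Xr[:, j] for j in remaining])
        ynorm = float(yr @ yr)
        live = norms > _NORM_TOL * max(1.0, total)
        if not live.any() or ynorm < _NORM_TOL * total:
            return
        proj = np.array([Xr[:, j] @ yr for j in remaining])
        scores = np.where(live, proj**2 / np.maximum(norms * ynorm, 1e-300), -np.inf)
        k = int(np.argmax(scores))  # ties -> lowest column order
        j = remaining.pop(k)
        xj = Xr[:, j].copy()
        xj_n2 = float(xj @ xj)
        gain = (xj @ yr) ** 2 / xj_n2
        explained += gain / total
        yr = yr - (xj @ yr) / xj_n2 * xj
        for m in remaining:
            Xr[:, m] -= (xj @ Xr[:, m]) / xj_n2 * xj
        yield j, float(scores[k]), min(explained, 1.0)


@dataclass
class OFRRanking:
    order: list[int]
    scores: list[float]  # squared cosine with the residual target at selection
    cum_explained: list[float]  # non-decreasing, <= 1
    names: list[str] | None = None

    def ranked_names(self) -> list[str]:
        if self.names is None:
            return [str(j) for j in self.order]
        return [self.names[j] for j in self.order]


def ofr_rank(X: np.ndarray | pd.DataFrame, y: np.ndarray) -> OFRRanking:
    """Full OFR ranking of the columns of X against target y (e.g. +/-1 labels)."""
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    if Xa.shape[0] != ya.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    if Xa.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    order, scores, cum = [], [], []
    for j, s, ev in _ofr_steps(Xa, ya):
        order.append(j)
        scores.append(s)
        cum.append(ev)
    return OFRRanking(order=order, scores=scores, cum_explained=cum, names=names)


@dataclass
class ProbeSelection:
    accepted: list[int]  # real-column indices, in rank order
    cdf_values: list[float]  # probe-rank CDF at each real candidate considered
    candidates: list[int]  # real columns considered (accepted + the one that failed)
    risk: float
    n_probes: int
    names: list[str] | None = None

    def accepted_names(self) -> list[str]:
        if self.names is None:
            return [str(j) for j in self.accepted]
        return [self.names[j] for j in self.accepted]


def probe_select(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    n_probes: int = 100,
    risk: float = 0.10,
    seed: int = 0,
    probe_kind: str = "permute",
) -> ProbeSelection:
    """OFR ranking with random-probe stopping.

    Probes are seeded row permutations of randomly chosen real columns
    (``probe_kind="permute"``, preserving each marginal while destroying any
    association with y) or i.i.d. standard normal columns
    (``probe_kind="gauss"``).  Real and probe columns are ranked jointly; a
    real candidate is accepted while the empirical CDF of probe ranks at its
    rank (the fraction of probes ranked above it) is below ``risk``, and the
    first failure terminates the selection.
    """
    if not 0 < risk < 1:
        raise ValueError("risk must be in (0, 1)")
    if n_probes < 10:
        warnings.warn("fewer than 10 probes gives a coarse rank CDF")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    n, p = Xa.shape
    rng = np.random.default_rng(seed)
    probes = np.empty((n, n_probes))
    if probe_kind == "permute":
        for q in range(n_probes):
            probes[:, q] = Xa[rng.permutation(n), rng.integers(p)]
    elif probe_kind == "gauss":
        probes = rng.standard_normal((n, n_probes))
    else:
        raise ValueError(f"unknown probe_kind {probe_kind!r}")
    Xfull = np.concatenate([Xa, probes], axis=1)
    accepted: list[int] = []
    cdfs: list[float] = []
    candidates: list[int] = []
    probes_above = 0
    for j, _score, _ev in _ofr_steps(Xfull, ya):
        if j >= p:  # a probe took this rank
            probes_above += 1
            if (probes_above + 1) / (n_probes + 1) >= risk:
                break  # no later candidate can pass
            continue
        # permutation-style continuity correction: the candidate counts as
        # one more probe realization, so the CDF estimate is never 0 and the
        # risk -> 0 limit correctly selects nothing
        cdf = (probes_above + 1) / (n_probes + 1)
        candidates.append(j)
        cdfs.append(cdf)
        if cdf < risk:
            accepted.append(j)
        else:
            break
    return ProbeSelection(
        accepted=accepted,
        cdf_values=cdfs,
        candidates=candidates,
        risk=risk,
        n_probes=n_probes,
        names=names,
    )


def decorrelate_covariate(
    X: np.ndarray | pd.DataFrame, c: np.ndarray
) -> np.ndarray | pd.DataFrame:
    """Residualize every column of X against span{1, c} (Gram-Schmidt).

    Used to remove a covariate such as age from the features; after the
    transform every column has zero correlation with ``c``.
    """
    ca = np.asarray(c, dtype=float)
    if ca.std() < 1e-12:
        raise ValueError("covariate is constant")
    Xa = np.asarray(X, dtype=float)
    if Xa.shape[0] != ca.shape[0]:
        raise ValueError("covariate length does not match number of rows")
    cc = ca - ca.mean()
    Xc = Xa - Xa.mean(axis=0)
    out = Xc - np.outer(cc, cc @ Xc) / (cc @ cc)
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(out, index=X.index, columns=X.columns)
    return out
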