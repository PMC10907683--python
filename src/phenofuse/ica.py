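"""Temporal ICA of the daily self-report panel.

The panel of strictly positive Likert items is log-transformed and the
participants' day series are concatenated along the time axis into an
items x days matrix X. FastICA (parallel/symmetric variant, logcosh
contrast with a1 = 1) decomposes X ~= A S + eps into a time-free mixing
matrix A (item loadings) and temporally independent component time courses
S. When as many components as items are requested the residual vanishes.

Because ICA is only defined up to the order, sign, and scale of its
components, :func:`canonicalize` fixes a convention (unit-variance sources,
positive dominant loading, components ordered by explained variance) so
that decompositions can be compared across restarts; restart stability is
summarized ICASSO-style by pooling components from many seeds and
clustering them on loading similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "ConcatenatedMatrix",
    "ICADecomposition",
    "StabilityReport",
    "prepare_panel",
    "fit_ica",
    "canonicalize",
    "restart_stability",
    "center_within_participant",
    "component_offset_correlation",
    "match_components",
]

#: questionnaire families a panel item may come from
ITEM_SCALES = ("DRSP", "BAM", "BITe", "ASIQ", "PANAS", "INQ", "Misc")


@dataclass
class ConcatenatedMatrix:
    """Log-transformed panel, items x participant-days.

    ``index_map`` maps each column to its (participant_id, date) provenance,
    in participant-then-date order.
    """

    X: np.ndarray
    index_map: pd.DataFrame  # columns: participant_id, date
    items: list[str]

    @property
    def p(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]


@dataclass
class ICADecomposition:
    """X ~= A S + epsilon, with fit metadata.

    ``mean`` is the per-item mean removed before unmixing; reconstruction is
    ``A @ S + mean[:, None]`` and ``epsilon`` is the leftover (zero when
    q = p on full-rank data).
    """

    A: np.ndarray  # p x q mixing matrix (loadings)
    S: np.ndarray  # q x n source time courses
    mean: np.ndarray  # p
    epsilon: np.ndarray  # p x n
    q: int
    meta: dict = field(default_factory=dict)

    def reconstruct(self) -> np.ndarray:
        return self.A @ self.S + self.mean[:, None]


@dataclass
class StabilityReport:
    n_restarts: int
    n_converged: int
    failed_seeds: list[int]
    loadings: np.ndarray  # p x (n_ok * q) pooled canonical mixing columns
    restart_of: np.ndarray  # restart index of each pooled component
    similarity: np.ndarray  # |corr| between pooled mixing columns
    clusters: np.ndarray  # 1-based cluster label per pooled component
    cluster_tightness: dict  # cluster -> mean within-cluster similarity

    def cluster_sizes(self) -> dict:
        labels, counts = np.unique(self.clusters, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def prepare_panel(panel: pd.DataFrame, items: Optional[Sequence[str]] = None) -> ConcatenatedMatrix:
    """Log-transform the Likert panel and concatenate participants in time.

    ``panel`` has columns ``participant_id, date`` plus one strictly
    positive column per item. Days with any missing item are dropped
    (complete-row rule); a non-positive value raises with its location.
    """
    if items is None:
        items = [c for c in panel.columns if c not in ("participant_id", "date")]
    items = list(items)
    dup = panel.duplicated(subset=["participant_id", "date"])
    if dup.any():
        row = panel[dup].iloc[0]
        raise ValueError(
            f"duplicate (participant, date): ({row['participant_id']}, {row['date']})"
        )
    complete = panel.dropna(subset=items)
    for item in items:
        bad = complete[complete[item] <= 0]
        if len(bad):
            row = bad.iloc[0]
            raise ValueError(
                f"non-positive value for item {item!r} at "
                f"(participant {row['participant_id']}, date {row['date']}): {row[item]}"
            )
    complete = complete.sort_values(["participant_id", "date"], kind="stable")
    X = np.log(complete[items].to_numpy(dtype=float)).T
    index_map = complete[["participant_id", "date"]].reset_index(drop=True)
    return ConcatenatedMatrix(X=X, index_map=index_map, items=items)


def fit_ica(
    X: ConcatenatedMatrix | np.ndarray,
    q: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> ICADecomposition:
    """Symmetric (parallel) FastICA with logcosh contrast on whitened data.

    Data are PCA-whitened to ``q`` dimensions first. Non-convergence within
    ``max_iter`` iterations is reported in ``meta['converged']``, never
    hidden. Sources in the returned decomposition are canonicalized (unit
    variance, sign and order fixed).
    """
    mat = X.X if isinstance(X, ConcatenatedMatrix) else np.asarray(X, dtype=float)
    p, n = mat.shape
    if not 1 <= q <= min(p, n):
        raise ValueError(f"q={q} out of range [1, min(p={p}, n={n})]")
    if n < 3 * p:
        warnings.warn(
            f"only {n} days for {p} items; ICA estimates may be unstable",
            stacklevel=2,
        )
    centered = mat - mat.mean(axis=1, keepdims=True)
    rank = np.linalg.matrix_rank(centered)
    if rank < q:
        raise ValueError(
            f"data rank {rank} is below the requested q={q}; whitening would fail"
        )
    ica = FastICA(
        n_components=q,
        algorithm="parallel",
        fun="logcosh",
        fun_args={"alpha": 1.0},
        whiten="unit-variance",
        tol=tol,
        max_iter=max_iter,
        random_state=np.random.RandomState(seed),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        S = ica.fit_transform(mat.T).T  # q x n
    A = ica.mixing_  # p x q
    mean = ica.mean_
    converged = ica.n_iter_ < max_iter
    dec = ICADecomposition(
        A=A,
        S=S,
        mean=mean,
        epsilon=np.empty((p, 0)),
        q=q,
        meta={
            "seed": seed,
            "fun": "logcosh",
            "alpha": 1.0,
            "algorithm": "parallel",
            "tol": tol,
            "max_iter": max_iter,
            "n_iter": int(ica.n_iter_),
            "converged": bool(converged),
        },
    )
    dec = canonicalize(dec, _x=mat)
    return dec


def canonicalize(dec: ICADecomposition, _x: Optional[np.ndarray] = None) -> ICADecomposition:
    """Fix ICA's scale/sign/order indeterminacy.

    Each source row is rescaled to unit sample variance (the scale moves to
    A's column); each component's sign makes its largest-|loading| entry
    positive; components are ordered by descending contribution variance
    ||A_col||^2. The product A @ S is unchanged and the operation is
    idempotent.
    """
    A = dec.A.copy()
    S = dec.S.copy()
    sd = S.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    S /= sd[:, None]
    A *= sd[None, :]
    dominant = np.argmax(np.abs(A), axis=0)
    signs = np.sign(A[dominant, np.arange(A.shape[1])])
    signs[signs == 0] = 1.0
    A *= signs[None, :]
    S *= signs[:, None]
    order = np.argsort(-np.sum(A * A, axis=0), kind="stable")
    A = A[:, order]
    S = S[order, :]
    if _x is None:
        expected = (dec.A.shape[0], dec.S.shape[1])
        eps = dec.epsilon if dec.epsilon.shape == expected else 0.0
        _x = dec.A @ dec.S + dec.mean[:, None] + eps
    epsilon = _x - (A @ S + dec.mean[:, None])
    return ICADecomposition(
        A=A, S=S, mean=dec.mean.copy(), epsilon=epsilon, q=dec.q, meta=dict(dec.meta)
    )


def restart_stability(
    X: ConcatenatedMatrix | np.ndarray,
    q: int,
    n_restarts: int = 10,
    base_seed: int = 0,
    cut_height: float = 0.3,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> StabilityReport:
    """Assess run-to-run variability of the stochastic FastICA optimisation.

    Runs ``n_restarts`` fits with seeds ``base_seed + r``, pools all
    canonical mixing columns, and clusters them with average-linkage
    agglomerative clustering on dissimilarity 1 - |corr|, cut at
    ``cut_height``. A stable decomposition shows q tight clusters each
    containing one component from every restart. Restarts that fail to
    converge are recorded in ``failed_seeds`` and excluded from clustering.
    """
    if n_restarts < 2:
        raise ValueError("need at least 2 restarts")
    decs, restart_of, failed = [], [], []
    for r in range(n_restarts):
        d = fit_ica(X, q, seed=base_seed + r, tol=tol, max_iter=max_iter)
        if d.meta["converged"]:
            decs.append(d)
            restart_of.extend([r] * q)
        else:
            failed.append(base_seed + r)
    if not decs:
        raise RuntimeError("no restart converged; cannot assess stability")
    loadings = np.hstack([d.A for d in decs])  # p x (n_ok*q)
    corr = np.corrcoef(loadings.T)
    similarity = np.clip(np.abs(corr), 0.0, 1.0)
    dissim = 1.0 - similarity
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2
    Z = linkage(squareform(dissim, checks=False), method="average")
    clusters = fcluster(Z, t=cut_height, criterion="distance")
    tightness = {}
    for c in np.unique(clusters):
        idx = np.flatnonzero(clusters == c)
        if len(idx) == 1:
            tightness[int(c)] = 1.0
        else:
            sub = similarity[np.ix_(idx, idx)]
            tightness[int(c)] = float(
                sub[np.triu_indices_from(sub, k=1)].mean()
            )
    return StabilityReport(
        n_restarts=n_restarts,
        n_converged=len(decs),
        failed_seeds=failed,
        loadings=loadings,
        restart_of=np.array(restart_of),
        similarity=similarity,
        clusters=clusters,
        cluster_tightness=tightness,
    )


def center_within_participant(X: ConcatenatedMatrix) -> ConcatenatedMatrix:
    """Subtract each participant's per-item mean of the log panel.

    Removes stable between-participant response offsets so a refit ICA
    cannot devote a component to them; idempotent.
    """
    mat = X.X.copy()
    pids = X.index_map["participant_id"].to_numpy()
    for pid in pd.unique(pids):
        cols = np.flatnonzero(pids == pid)
        mat[:, cols] -= mat[:, cols].mean(axis=1, keepdims=True)
    return ConcatenatedMatrix(X=mat, index_map=X.index_map.copy(), items=list(X.items))


def component_offset_correlation(
    dec: ICADecomposition, X: ConcatenatedMatrix, component: int
) -> float:
    """Correlation between participants' overall response level and their
    mean score on one component.

    For each participant: mean of the log panel over items and days, and the
    mean of source row ``component`` over days. Returns the Pearson
    correlation across participants. A large magnitude indicates the
    component mostly encodes stable between-participant offsets rather than
    day-to-day dynamics.
    """
    pids = X.index_map["participant_id"].to_numpy()
    unique = pd.unique(pids)
    if len(unique) < 3:
        raise ValueError(f"need >= 3 participants, got {len(unique)}")
    mean_resp, mean_src = [], []
    for pid in unique:
        cols = np.flatnonzero(pids == pid)
        mean_resp.append(X.X[:, cols].mean())
        mean_src.append(dec.S[component, cols].mean())
    return float(np.corrcoef(mean_resp, mean_src)[0, 1])


def match_components(
    A_est: np.ndarray, A_ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve permutation/sign ambiguity between two mixing matrices.

    Finds the one-to-one assignment of estimated to reference columns that
    maximizes total |correlation| (Hungarian algorithm on 1 - |corr|).
    Returns ``(perm, signs, corrs)`` where ``A_est[:, perm[j]] * signs[j]``
    is the estimate matched to reference column ``j`` and ``corrs[j]`` its
    absolute correlation.
    """
    from scipy.optimize import linear_sum_assignment

    A_est = np.asarray(A_est, dtype=float)
    A_ref = np.asarray(A_ref, dtype=float)
    q = A_ref.shape[1]
    e = A_est - A_est.mean(axis=0)
    r = A_ref - A_ref.mean(axis=0)
    e /= np.linalg.norm(e, axis=0)
    r /= np.linalg.norm(r, axis=0)
    corr = r.T @ e  # q_ref x q_est
    _, perm = linear_sum_assignment(1.0 - np.abs(corr))
    corrs = np.abs(corr[np.arange(q), perm])
    signs = np.sign(corr[np.arange(q), perm])
    signs[signs == 0] = 1.0
    return perm, signs, corrs
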