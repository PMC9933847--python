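"""Adaptive positive-unlabeled labeling by a Markov process with restart.

Given a per-gene feature matrix and the positive (seed) set P, unlabeled
genes are assigned to one of five classes:

P (known positives) and RN (reliable negatives — the genes whose features
lie farthest from the positive-class mean) anchor a signed state vector
that sums to zero.  The state is propagated over a feature-similarity
transition matrix,

    g_r = (1 - alpha) * Wn^T g_{r-1} + alpha * g_0,

until the fixed point g_inf; ranking the remaining genes by g_inf and
cutting the ranking by quantile fractions yields LP (likely positive),
WN (weakly negative) and LN (likely negative).

The transition matrix comes from pairwise squared-Euclidean feature
distances, rescaled to similarities in [0, 1], sparsified at a quantile
threshold, and row-normalized to a stochastic matrix.  W is dense by
construction (n^2 pairwise distances), which bounds this stage to roughly
n <= 30,000 genes on ordinary memory.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix", "TransitionMatrix", "StateVector", "LabelAssignment",
    "similarity_matrix", "reduce_and_normalize", "select_reliable_negatives",
    "initial_state", "propagate", "assign_labels", "label_genes",
    "LABELS", "PropagationError",
]

LABELS = ("P", "LP", "WN", "LN", "RN")


class PropagationError(RuntimeError):
    """Raised when the restart iteration fails to converge; carries the residual."""

    def __init__(self, iterations: int, residual: float):
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"propagation did not converge in {iterations} iterations "
            f"(last residual {residual:.3e})")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric similarity in [0, 1] with unit diagonal."""

    W: np.ndarray
    order: tuple[str, ...]


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic propagation matrix after quantile sparsification."""

    Wn: sp.csr_matrix
    order: tuple[str, ...]
    q_w: float
    kept_fraction: float


@dataclass(frozen=True)
class StateVector:
    g: np.ndarray
    order: tuple[str, ...]
    iteration: int = 0
    converged: bool = False

    def as_dict(self) -> dict[str, float]:
        return {g: float(v) for g, v in zip(self.order, self.g)}


@dataclass(frozen=True)
class LabelAssignment:
    """Per-gene class in {P, LP, WN, LN, RN} plus the g_inf ranking."""

    label: Mapping[str, str]
    ranking: tuple[str, ...]  # non-P, non-RN genes by g_inf descending
    g_inf: Mapping[str, float]
    fractions: tuple[float, float, float]

    def members(self, cls: str) -> tuple[str, ...]:
        return tuple(g for g in sorted(self.label) if self.label[g] == cls)

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in LABELS}
        for c in self.label.values():
            out[c] += 1
        return out


def similarity_matrix(F: FeatureMatrix) -> SimilarityMatrix:
    """Pairwise feature similarity.

    ``e_ij`` is the squared Euclidean distance between feature rows; the
    off-diagonal similarities are ``1 - (e_ij - m)/(M - m)`` with m, M the
    attained off-diagonal min/max, and the diagonal is 1.  If every pair is
    equidistant (M = m) all off-diagonal similarities are set to 1 with a
    warning, preserving connectivity of the propagation.
    """
    X = F.X
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two genes")
    sq = (X ** 2).sum(axis=1)
    e = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(e, 0.0, out=e)  # clip FP noise
    off = ~np.eye(n, dtype=bool)
    m, M = e[off].min(), e[off].max()
    if M == m:
        warnings.warn("all pairwise feature distances are equal; "
                      "setting all similarities to 1", stacklevel=2)
        W = np.ones((n, n))
    else:
        W = 1.0 - (e - m) / (M - m)
        np.clip(W, 0.0, 1.0, out=W)
        np.fill_diagonal(W, 1.0)
    return SimilarityMatrix(W=W, order=F.order)


def reduce_and_normalize(W: SimilarityMatrix, q_w: float = 0.75) -> TransitionMatrix:
    """Sparsify at the q_w quantile of off-diagonal similarities, then row-normalize.

    The threshold is the empirical q_w-quantile of the off-diagonal entries
    (upper triangle); entries strictly below it are zeroed, entries at or
    above it are kept, and the unit diagonal is always retained, so no row
    can become all-zero.  ``Wn = D^{-1} W_r`` with D the row sums.
    """
    if not (0.0 <= q_w < 1.0):
        raise ValueError("q_w must be in [0, 1)")
    A = W.W
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    thr = float(np.quantile(A[iu], q_w))
    Wr = np.where(A >= thr, A, 0.0)
    np.fill_diagonal(Wr, 1.0)
    kept = float((A[iu] >= thr).mean())
    d = Wr.sum(axis=1)
    assert (d > 0).all()  # diagonal retained -> no zero row
    Wn = sp.csr_matrix(Wr / d[:, None])
    return TransitionMatrix(Wn=Wn, order=W.order, q_w=q_w, kept_fraction=kept)


def select_reliable_negatives(
    F: FeatureMatrix,
    positives: Sequence[str],
    n_rn: int | None = None,
) -> tuple[str, ...]:
    """The n_rn unlabeled genes farthest (Euclidean) from the positive-class mean.

    Defaults to ``n_rn = |P|`` so the signed initial state is balanced.
    Ties break by gene identifier for determinism.
    """
    pos = set(positives)
    if not pos:
        raise ValueError("positive set is empty")
    idx = {g: i for i, g in enumerate(F.order)}
    missing = pos - set(idx)
    if missing:
        raise ValueError(f"positives not in the feature matrix: {sorted(missing)[:5]}")
    if n_rn is None:
        n_rn = len(pos)
    if n_rn <= 0:
        raise ValueError("n_rn must be positive")
    unlabeled = [g for g in F.order if g not in pos]
    if n_rn > len(unlabeled):
        raise ValueError(f"n_rn={n_rn} exceeds the {len(unlabeled)} unlabeled genes")
    centroid = F.X[[idx[g] for g in pos]].mean(axis=0)
    dist = {g: float(np.linalg.norm(F.X[idx[g]] - centroid)) for g in unlabeled}
    ranked = sorted(unlabeled, key=lambda g: (-dist[g], g))
    return tuple(sorted(ranked[:n_rn]))


def initial_state(
    positives: Sequence[str],
    reliable_negatives: Sequence[str],
    order: Sequence[str],
) -> StateVector:
    """Signed, zero-sum initial state: +1 on P, -|P|/|RN| on RN, 0 elsewhere."""
    P, RN = set(positives), set(reliable_negatives)
    if not P or not RN:
        raise ValueError("P and RN must both be nonempty")
    if P & RN:
        raise ValueError("P and RN overlap")
    g0 = np.zeros(len(order))
    neg = -len(P) / len(RN)
    for i, g in enumerate(order):
        if g in P:
            g0[i] = 1.0
        elif g in RN:
            g0[i] = neg
    return StateVector(g=g0, order=tuple(order))


def propagate(
    Wn: TransitionMatrix,
    g0: StateVector,
    alpha: float = 0.8,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> StateVector:
    """Iterate ``g_r = (1 - alpha) Wn^T g_{r-1} + alpha g_0`` to its fixed point.

    Convergence is the L2 norm of successive differences dropping below
    ``tol``; because Wn is row-stochastic the iteration contracts with
    ratio at most (1 - alpha).  Non-convergence raises
    :class:`PropagationError` rather than returning silently.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    WnT = Wn.Wn.T.tocsr()
    g = g0.g.copy()
    base = alpha * g0.g
    for r in range(1, max_iter + 1):
        g_next = (1.0 - alpha) * (WnT @ g) + base
        res = float(np.linalg.norm(g_next - g))
        g = g_next
        if res < tol:
            return StateVector(g=g, order=g0.order, iteration=r, converged=True)
    raise PropagationError(max_iter, res)


def assign_labels(
    g_inf: StateVector,
    positives: Sequence[str],
    reliable_negatives: Sequence[str],
    fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> LabelAssignment:
    """Cut the g_inf ranking of unlabeled genes into LP / WN / LN.

    The u = n - |P| - |RN| remaining genes are sorted by g_inf descending
    (ties by identifier); the first ``ceil(f_LP * u)`` become LP, the next
    ``ceil(f_WN * u)`` (capped at what remains) WN, and the rest LN.
    """
    f = np.asarray(fractions, dtype=float)
    if (f <= 0).any() or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    P, RN = set(positives), set(reliable_negatives)
    vals = g_inf.as_dict()
    rest = [g for g in g_inf.order if g not in P and g not in RN]
    rest.sort(key=lambda g: (-vals[g], g))
    u = len(rest)
    n_lp = min(int(np.ceil(f[0] * u)), u)
    n_wn = min(int(np.ceil(f[1] * u)), u - n_lp)
    label: dict[str, str] = {}
    for g in g_inf.order:
        if g in P:
            label[g] = "P"
        elif g in RN:
            label[g] = "RN"
    for i, g in enumerate(rest):
        label[g] = "LP" if i < n_lp else ("WN" if i < n_lp + n_wn else "LN")
    return LabelAssignment(label=label, ranking=tuple(rest), g_inf=vals,
                           fractions=tuple(f))


def label_genes(
    F: FeatureMatrix,
    positives: Sequence[str],
    *,
    q_w: float = 0.75,
    alpha: float = 0.8,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    n_rn: int | None = None,
    fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> LabelAssignment:
    """Run the full labeling pipeline on a feature matrix.

    Convenience wrapper: similarity -> quantile reduction -> reliable
    negatives -> zero-sum initial state -> restart propagation -> quantile
    label assignment.
    """
    W = similarity_matrix(F)
    Wn = reduce_and_normalize(W, q_w)
    RN = select_reliable_negatives(F, positives, n_rn)
    g0 = initial_state(positives, RN, F.order)
    g_inf = propagate(Wn, g0, alpha=alpha, tol=tol, max_iter=max_iter)
    return assign_labels(g_inf, positives, RN, fractions)
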