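"""Simplified network component analysis (NCA) baseline.

NCA factors an expression matrix E (p genes x N samples) as E ~ A P where A
is a connectivity matrix whose zero pattern is fixed in advance and P holds
regulator (TF) activities. Unlike the sparse graphical model, the structure
is an *input*: only the nonzero values of A are learned. The decomposition is
identifiable when (1) A has full column rank, (2) removing any regulator
together with its connected genes leaves a full-column-rank connectivity
matrix — which forces at least L-1 zeros per column — and (3) P has full row
rank (requires N >= L).

The fixed-support least-squares problem is solved by alternating least
squares; column scales are normalized afterwards since E = (A c)(P / c) for
any positive c.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NCAModel",
    "NCACriteria",
    "make_random_connectivity",
    "check_nca_criteria",
    "nca_decompose",
    "prune_edges",
]


@dataclass
class NCAModel:
    A: np.ndarray  # p x L, zeros outside the mask at every iteration
    P: np.ndarray  # L x N
    mask: np.ndarray  # p x L boolean support
    reconstruction_error_trace: list[float] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.A))


@dataclass
class NCACriteria:
    full_column_rank: bool
    reduced_rank_ok: bool
    samples_ok: bool

    @property
    def all_ok(self) -> bool:
        return self.full_column_rank and self.reduced_rank_ok and self.samples_ok


def make_random_connectivity(p: int, L: int, seed: int = 0) -> np.ndarray:
    """Random support with exactly L-1 zeros per column (uniform rows).

    This is the minimal zero count needed for NCA identifiability when the
    true topology is unknown.
    """
    if L < 1:
        raise ValueError("need at least one regulator")
    if p <= L - 1:
        raise ValueError(f"need p > L-1 rows to place L-1 zeros (p={p}, L={L})")
    rng = np.random.default_rng(seed)
    mask = np.ones((p, L), dtype=bool)
    for j in range(L):
        zero_rows = rng.choice(p, size=L - 1, replace=False)
        mask[zero_rows, j] = False
    return mask


def check_nca_criteria(A_mask: np.ndarray, N: int, seed: int = 0) -> NCACriteria:
    """Diagnose the three NCA identifiability criteria on a random
    realization of the masked connectivity matrix."""
    mask = np.asarray(A_mask, dtype=bool)
    p, L = mask.shape
    rng = np.random.default_rng(seed)
    A = np.where(mask, rng.standard_normal((p, L)), 0.0)
    full_rank = np.linalg.matrix_rank(A) == L
    reduced_ok = True
    for j in range(L):
        keep_rows = ~mask[:, j]  # genes not connected to regulator j
        keep_cols = np.arange(L) != j
        sub = A[np.ix_(keep_rows, keep_cols)]
        if L > 1 and np.linalg.matrix_rank(sub) < L - 1:
            reduced_ok = False
            break
    return NCACriteria(
        full_column_rank=bool(full_rank),
        reduced_rank_ok=bool(reduced_ok),
        samples_ok=bool(N >= L),
    )


def _solve_rows(E: np.ndarray, P: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-gene least squares for A rows restricted to their support."""
    p, L = mask.shape
    A = np.zeros((p, L))
    PPt = P @ P.T
    PEt = P @ E.T  # L x p
    # Genes sharing a support pattern share the normal-equation matrix.
    patterns: dict[bytes, list[int]] = {}
    for i in range(p):
        patterns.setdefault(mask[i].tobytes(), []).append(i)
    for key, rows in patterns.items():
        s = np.frombuffer(key, dtype=bool)
        if not s.any():
            continue
        G = PPt[np.ix_(s, s)]
        rhs = PEt[np.ix_(s, rows)]
        try:
            sol = np.linalg.solve(G, rhs)
        except np.linalg.LinAlgError:
            warnings.warn("singular restricted system; adding ridge jitter", stacklevel=2)
            sol = np.linalg.solve(G + 1e-10 * np.eye(int(s.sum())), rhs)
        A[np.ix_(rows, s)] = sol.T
    return A


def _als_run(
    E: np.ndarray, mask: np.ndarray, max_iter: int, tol: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    p, L = mask.shape
    A = np.where(mask, rng.standard_normal((p, L)), 0.0)
    trace: list[float] = []
    prev_err = np.inf
    P = np.zeros((L, E.shape[1]))
    for _ in range(max_iter):
        P, *_ = np.linalg.lstsq(A, E, rcond=None)
        A = _solve_rows(E, P, mask)
        err = float(np.linalg.norm(E - A @ P) ** 2)
        trace.append(err)
        if np.isfinite(prev_err) and prev_err - err <= tol * max(prev_err, 1e-300):
            break
        prev_err = err
    return A, P, trace


def nca_decompose(
    E: np.ndarray,
    mask: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-10,
    seed: int = 0,
    n_restarts: int = 3,
) -> NCAModel:
    """Alternating least squares for E ~ A P with frozen zero pattern.

    Nonzero entries of A are initialized i.i.d. standard normal; iterations
    alternate a full least-squares solve for P with per-gene restricted
    solves for A until the relative reconstruction-error change drops below
    ``tol``. The bilinear problem is nonconvex, so ``n_restarts`` random
    initializations are run and the best final error kept. After convergence
    A's columns are scaled to unit norm with the inverse scaling applied to
    P's rows.
    """
    E = np.asarray(E, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    p, L = mask.shape
    if E.shape[0] != p:
        raise ValueError("E and mask disagree on the number of genes")
    N = E.shape[1]
    crit = check_nca_criteria(mask, N, seed=seed)
    if not crit.all_ok:
        warnings.warn(f"NCA identifiability criteria not all satisfied: {crit}", stacklevel=2)

    best: tuple[np.ndarray, np.ndarray, list[float]] | None = None
    for k in range(max(1, n_restarts)):
        A, P, trace = _als_run(E, mask, max_iter, tol, np.random.default_rng([seed, k]))
        if best is None or trace[-1] < best[2][-1]:
            best = (A, P, trace)
    A, P, trace = best

    norms = np.linalg.norm(A, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    A = A / safe
    P = P * safe[:, None]
    return NCAModel(A=A, P=P, mask=mask, reconstruction_error_trace=trace)


def prune_edges(model: NCAModel, target_edge_count: int) -> NCAModel:
    """Keep the target number of largest-|weight| entries of A, zero the rest.

    Ties are broken by (row, column) order so pruning is deterministic.
    """
    if target_edge_count < 0:
        raise ValueError("target edge count must be nonnegative")
    flat = np.abs(model.A).ravel()
    nonzero = int(np.count_nonzero(flat))
    if target_edge_count > nonzero:
        raise ValueError(
            f"target {target_edge_count} exceeds current edge count {nonzero}"
        )
    # Stable sort on (-|a|, flat index): equal magnitudes keep earliest index.
    order = np.lexsort((np.arange(flat.size), -flat))
    keep = order[:target_edge_count]
    keep = keep[flat[keep] > 0]  # never "keep" structural zeros
    A = np.zeros_like(model.A)
    A.ravel()[keep] = model.A.ravel()[keep]
    return NCAModel(
        A=A,
        P=model.P.copy(),
        mask=model.mask.copy(),
        reconstruction_error_trace=list(model.reconstruction_error_trace),
    )
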