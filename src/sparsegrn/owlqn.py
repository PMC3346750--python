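"""Orthant-wise limited-memory quasi-Newton (OWL-QN) minimizer.

Minimizes ``f(x) = loss(x) + penalty * sum_i |x_i|`` over the coordinates
flagged by a penalty mask, where ``loss`` is smooth. The L1 term is handled
through a pseudo-gradient (a particular subgradient choice that is zero
exactly when 0 is in the subdifferential) and an orthant-constrained
backtracking line search whose projection clamps sign-crossing coordinates
to exact zeros — so the sparsity pattern of the solution is literal, not a
small-float threshold.

Unpenalized coordinates (mask False, or penalty 0) reduce the algorithm to
plain L-BFGS.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["FlatProblem", "OptimResult", "pseudo_gradient", "owlqn_minimize"]

# Armijo sufficient-decrease constant and backtracking factor, per the
# published OWL-QN description.
_C1 = 1e-4
_BACKTRACK = 0.5
_MAX_LINESEARCH = 60


@dataclass
class FlatProblem:
    """A smooth loss + L1 problem over a flat parameter vector.

    ``penalty_mask`` marks which coordinates carry the L1 penalty.
    """

    dim: int
    loss_fn: Callable[[np.ndarray], float]
    grad_fn: Callable[[np.ndarray], np.ndarray]
    penalty: float = 0.0
    penalty_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("penalty must be nonnegative")
        if self.penalty_mask is None:
            self.penalty_mask = np.zeros(self.dim, dtype=bool)
        self.penalty_mask = np.asarray(self.penalty_mask, dtype=bool)
        if self.penalty_mask.shape != (self.dim,):
            raise ValueError("penalty_mask length must equal dim")

    def objective(self, x: np.ndarray) -> float:
        val = float(self.loss_fn(x))
        if self.penalty > 0:
            val += self.penalty * float(np.abs(x[self.penalty_mask]).sum())
        return val


@dataclass
class OptimResult:
    solution: np.ndarray
    objective: float
    n_iter: int
    converged: bool
    trace: list[float] = field(default_factory=list)


def pseudo_gradient(
    point: np.ndarray, grad: np.ndarray, penalty: float, mask: np.ndarray
) -> np.ndarray:
    """Subgradient choice for loss + penalty*|.| on masked coordinates.

    At nonzero coordinates it is grad + penalty*sign(x). At zeros it is the
    one-sided derivative of steepest descent if either side descends, else 0
    (the subgradient optimality condition |grad| <= penalty holds there).
    """
    pg = np.array(grad, dtype=float, copy=True)
    if penalty == 0:
        return pg
    m = np.asarray(mask, dtype=bool)
    pos = m & (point > 0)
    neg = m & (point < 0)
    pg[pos] += penalty
    pg[neg] -= penalty
    zero = m & (point == 0)
    right = grad[zero] + penalty  # derivative moving into the positive orthant
    left = grad[zero] - penalty
    val = np.zeros(right.shape)
    val[right < 0] = right[right < 0]
    val[left > 0] = left[left > 0]
    pg[zero] = val
    return pg


def _two_loop(pg: np.ndarray, s_list, y_list, rho_list) -> np.ndarray:
    """Standard L-BFGS two-loop recursion applied to the pseudo-gradient."""
    d = -pg
    if not s_list:
        return d
    alphas = []
    for s, y, rho in zip(reversed(s_list), reversed(y_list), reversed(rho_list)):
        a = rho * float(s @ d)
        alphas.append(a)
        d = d - a * y
    s, y = s_list[-1], y_list[-1]
    d = d * (float(s @ y) / float(y @ y))
    for (s, y, rho), a in zip(zip(s_list, y_list, rho_list), reversed(alphas)):
        b = rho * float(y @ d)
        d = d + (a - b) * s
    return d


def owlqn_minimize(
    problem: FlatProblem,
    x0: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-9,
    memory: int = 10,
) -> OptimResult:
    """Run OWL-QN from ``x0``; with penalty 0 this is plain L-BFGS.

    Convergence is declared when the pseudo-gradient infinity norm drops
    below ``tol`` or the relative objective decrease stays below ``tol`` for
    5 consecutive iterations. On non-finite losses the line search shrinks;
    at ``max_iter`` the best iterate is returned with converged=False.
    """
    x = np.array(x0, dtype=float).ravel()
    if x.shape[0] != problem.dim:
        raise ValueError("x0 length must equal problem.dim")
    if not np.all(np.isfinite(x)):
        raise ValueError("x0 must be finite")
    mask = problem.penalty_mask
    lam = problem.penalty

    f = problem.objective(x)
    g = np.asarray(problem.grad_fn(x), dtype=float)
    trace = [f]
    s_list: deque = deque(maxlen=memory)
    y_list: deque = deque(maxlen=memory)
    rho_list: deque = deque(maxlen=memory)

    converged = False
    n_small = 0
    it = 0
    for it in range(1, max_iter + 1):
        pg = pseudo_gradient(x, g, lam, mask)
        if float(np.max(np.abs(pg), initial=0.0)) < tol:
            converged = True
            break

        d = _two_loop(pg, s_list, y_list, rho_list)
        # Safeguard: discard direction components that disagree in sign with
        # steepest descent on the pseudo-gradient.
        d[d * (-pg) <= 0] = 0.0
        if not np.any(d):
            converged = True
            break

        # Orthant the line search is confined to.
        xi = np.sign(x)
        at_zero = x == 0
        xi[at_zero] = np.sign(-pg[at_zero])

        alpha = 1.0 if s_list else min(1.0, 1.0 / float(np.linalg.norm(d)))
        accepted = False
        x_new = x
        f_new = f
        for _ in range(_MAX_LINESEARCH):
            x_new = x + alpha * d
            crossed = mask & (x_new * xi <= 0)
            x_new[crossed] = 0.0
            f_new = problem.objective(x_new)
            if np.isfinite(f_new) and f_new <= f + _C1 * float(pg @ (x_new - x)):
                accepted = True
                break
            alpha *= _BACKTRACK
        if not accepted:
            break  # no further progress possible at machine precision

        g_new = np.asarray(problem.grad_fn(x_new), dtype=float)
        s = x_new - x
        y = g_new - g
        sy = float(s @ y)
        if sy > 1e-12 * float(np.linalg.norm(s)) * float(np.linalg.norm(y)):
            s_list.append(s)
            y_list.append(y)
            rho_list.append(1.0 / sy)

        rel_dec = (f - f_new) / max(abs(f), abs(f_new), 1.0)
        x, f, g = x_new, f_new, g_new
        trace.append(f)
        if rel_dec < tol:
            n_small += 1
            if n_small >= 5:
                converged = True
                break
        else:
            n_small = 0

    return OptimResult(
        solution=x, objective=f, n_iter=it, converged=converged, trace=trace
    )
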