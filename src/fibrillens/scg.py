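"""Scaled conjugate gradient minimisation (Moller's algorithm).

A Hessian-free conjugate-gradient method in which the curvature along the
search direction is approximated by a finite difference of gradients and
regularised by a Levenberg-Marquardt style scaling parameter ``lambda``
that is adapted from the quality of each quadratic prediction. One
:meth:`SCG.step` performs exactly one weight update ("one epoch" when the
objective is a full-batch loss).
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .errors import TrainingError

FunGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


class SCG:
    """Stateful scaled-conjugate-gradient minimiser.

    Parameters
    ----------
    fun_grad : callable returning ``(f(x), grad f(x))``
    x0 : initial point
    sigma0 : finite-difference step scale for the curvature estimate
    lambda0 : initial regularisation
    grad_tol : infinity-norm gradient threshold for :attr:`converged`
    """

    def __init__(
        self,
        fun_grad: FunGrad,
        x0: np.ndarray,
        sigma0: float = 1e-4,
        lambda0: float = 1e-6,
        grad_tol: float = 1e-8,
    ):
        self.fun_grad = fun_grad
        self.x = np.asarray(x0, dtype=float).copy()
        self.sigma0 = sigma0
        self.lam = lambda0
        self.lam_bar = 0.0
        self.grad_tol = grad_tol
        self.f, self.g = fun_grad(self.x)
        self._check(self.f, self.g)
        self.r = -self.g
        self.p = self.r.copy()
        self.success = True
        self.k = 0
        self.n = self.x.size

    @staticmethod
    def _check(f: float, g: np.ndarray) -> None:
        if not np.isfinite(f) or not np.all(np.isfinite(g)):
            raise TrainingError("non-finite objective or gradient")

    @property
    def converged(self) -> bool:
        return bool(np.max(np.abs(self.r), initial=0.0) < self.grad_tol)

    def step(self) -> float:
        """One SCG iteration; returns the objective value after the move."""
        if self.converged:
            return self.f
        p, r = self.p, self.r
        p_sq = float(p @ p)
        if p_sq == 0.0:
            return self.f

        if self.success:
            sigma = self.sigma0 / np.sqrt(p_sq)
            _, g_plus = self.fun_grad(self.x + sigma * p)
            self._s = (g_plus - self.g) / sigma
            self._delta = float(p @ self._s)

        delta = self._delta + (self.lam - self.lam_bar) * p_sq
        if delta <= 0.0:  # make the Hessian approximation positive definite
            self.lam_bar = 2.0 * (self.lam - delta / p_sq)
            delta = -delta + self.lam * p_sq
            self.lam = self.lam_bar
        mu = float(p @ r)
        alpha = mu / delta

        f_new, _ = self.fun_grad(self.x + alpha * p)
        Delta = 2.0 * delta * (self.f - f_new) / mu**2

        if Delta >= 0.0:  # successful reduction
            self.x = self.x + alpha * p
            self.f, self.g = self.fun_grad(self.x)
            self._check(self.f, self.g)
            r_new = -self.g
            self.lam_bar = 0.0
            self.success = True
            self.k += 1
            if self.k % self.n == 0:  # restart the direction periodically
                self.p = r_new.copy()
            else:
                beta = float(r_new @ r_new - r_new @ r) / mu
                self.p = r_new + beta * p
            self.r = r_new
            if Delta >= 0.75:
                self.lam = max(self.lam / 4.0, 1e-18)
        else:
            self.lam_bar = self.lam
            self.success = False

        if Delta < 0.25:
            self.lam = self.lam + delta * (1.0 - Delta) / p_sq
        self.lam = min(self.lam, 1e18)
        return self.f


def scg_minimize(
    fun_grad: FunGrad,
    x0: np.ndarray,
    max_iter: int = 500,
    grad_tol: float = 1e-10,
    **kwargs,
) -> tuple[np.ndarray, float, int]:
    """Run SCG to convergence; returns (x, f, iterations used)."""
    opt = SCG(fun_grad, x0, grad_tol=grad_tol, **kwargs)
    it = 0
    for it in range(1, max_iter + 1):
        opt.step()
        if opt.converged:
            break
    return opt.x, opt.f, it
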