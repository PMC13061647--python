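"""Rank-based CMA-ES for maximizing noisy neuronal fitness.

A from-scratch implementation of the standard (mu/mu_w, lambda) covariance
matrix adaptation evolution strategy with cumulative step-size adaptation
and rank-one plus rank-mu covariance updates, exposed through an ask/tell
interface.  Scores are *maximized* (they are firing rates); the update is
rank-based and therefore invariant to strictly increasing transformations
of the scores.

:func:`project_to_subspace` restricts the search to an orthonormal set of
axes (the Hessian-eigenbasis trick for high-dimensional latent spaces):
optimization proceeds in reduced coordinates and candidates are expanded
back to the full space before rendering.
"""

from __future__ import annotations

import copy
import logging

import numpy as np

__all__ = ["CmaEs", "SubspaceCmaEs", "cma_es_update", "project_to_subspace"]

log = logging.getLogger(__name__)


class CmaEs:
    """(mu/mu_w, lambda)-CMA-ES maximizer with default Hansen constants.

    Parameters
    ----------
    mean0:
        Initial distribution mean.
    sigma0:
        Initial global step size; the central per-latent-space calibration
        knob (texture-space default 3.0, object-space default 0.09).
    popsize:
        Offspring per generation; defaults to ``4 + floor(3 ln d)``.
    """

    def __init__(self, mean0, sigma0: float, popsize: int | None = None,
                 seed: int | None = 0):
        self.mean = np.asarray(mean0, dtype=float).copy()
        if self.mean.ndim != 1:
            raise ValueError("mean0 must be a vector")
        if sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        d = self.mean.size
        self.dim = d
        self.sigma = float(sigma0)
        self.popsize = int(popsize) if popsize else 4 + int(3 * np.log(d))
        if self.popsize < 2:
            raise ValueError("popsize must be >= 2")
        self.rng = np.random.default_rng(seed)

        # selection and recombination constants
        mu = self.popsize // 2
        w = np.log(self.popsize / 2 + 0.5) - np.log(np.arange(1, mu + 1))
        self.weights = w / w.sum()
        self.mu = mu
        self.mueff = 1.0 / np.sum(self.weights ** 2)

        # adaptation constants
        self.cc = (4 + self.mueff / d) / (d + 4 + 2 * self.mueff / d)
        self.cs = (self.mueff + 2) / (d + self.mueff + 5)
        self.c1 = 2 / ((d + 1.3) ** 2 + self.mueff)
        self.cmu = min(1 - self.c1,
                       2 * (self.mueff - 2 + 1 / self.mueff)
                       / ((d + 2) ** 2 + self.mueff))
        self.damps = (1 + 2 * max(0.0, np.sqrt((self.mueff - 1) / (d + 1)) - 1)
                      + self.cs)
        self.chiN = np.sqrt(d) * (1 - 1 / (4 * d) + 1 / (21 * d ** 2))

        # dynamic state
        self.pc = np.zeros(d)
        self.ps = np.zeros(d)
        self.C = np.eye(d)
        self.B = np.eye(d)
        self.D = np.ones(d)
        self.generation = 0
        self._pending: np.ndarray | None = None

    # -- state -------------------------------------------------------------

    @property
    def covariance(self) -> np.ndarray:
        return self.C.copy()

    def _decompose(self) -> None:
        self.C = (self.C + self.C.T) / 2.0
        eigvals, self.B = np.linalg.eigh(self.C)
        self.D = np.sqrt(np.maximum(eigvals, 1e-20))

    # -- ask / tell --------------------------------------------------------

    def ask(self) -> np.ndarray:
        """Sample the next population, shape ``(popsize, dim)``."""
        z = self.rng.standard_normal((self.popsize, self.dim))
        y = (z * self.D) @ self.B.T
        x = self.mean + self.sigma * y
        self._pending = x
        return x

    def tell(self, latents: np.ndarray, scores) -> None:
        """Rank-based update from scored candidates (maximization).

        NaN scores are excluded from recombination (logged); remaining
        weights are renormalized over the surviving parents.
        """
        x = np.asarray(latents, dtype=float)
        scores = np.asarray(scores, dtype=float)
        if x.shape != (self.popsize, self.dim):
            raise ValueError("batch shape must be (popsize, dim)")
        if scores.shape != (self.popsize,):
            raise ValueError("need one score per candidate")
        valid = ~np.isnan(scores)
        if not valid.all():
            log.warning("excluding %d NaN-scored candidates from recombination",
                        int((~valid).sum()))
        if valid.sum() < 2:
            raise ValueError("fewer than two finite scores")

        order = np.argsort(-scores[valid], kind="stable")
        xv = x[valid][order]
        mu = min(self.mu, xv.shape[0])
        w = self.weights[:mu] / self.weights[:mu].sum()

        m_old = self.mean
        y_sel = (xv[:mu] - m_old) / self.sigma
        y_w = w @ y_sel
        self.mean = m_old + self.sigma * y_w

        mueff = 1.0 / np.sum(w ** 2)
        # C^{-1/2} y_w in the eigenbasis
        c_inv_half_yw = self.B @ ((self.B.T @ y_w) / self.D)
        self.ps = ((1 - self.cs) * self.ps
                   + np.sqrt(self.cs * (2 - self.cs) * mueff) * c_inv_half_yw)
        self.generation += 1
        hs_norm = (np.linalg.norm(self.ps)
                   / np.sqrt(1 - (1 - self.cs) ** (2 * self.generation)))
        hsig = hs_norm < (1.4 + 2 / (self.dim + 1)) * self.chiN
        self.pc = ((1 - self.cc) * self.pc
                   + hsig * np.sqrt(self.cc * (2 - self.cc) * mueff) * y_w)

        rank_mu = (y_sel.T * w) @ y_sel
        delta_hs = (1 - hsig) * self.cc * (2 - self.cc)
        self.C = ((1 - self.c1 - self.cmu) * self.C
                  + self.c1 * (np.outer(self.pc, self.pc) + delta_hs * self.C)
                  + self.cmu * rank_mu)
        self.sigma *= np.exp((self.cs / self.damps)
                             * (np.linalg.norm(self.ps) / self.chiN - 1))
        self._decompose()
        self._pending = None


class SubspaceCmaEs:
    """CMA-ES restricted to an orthonormal axis set of the full space.

    Candidates are optimized in ``k`` reduced coordinates and expanded via
    the basis before rendering; the component of the initial mean orthogonal
    to the basis is held fixed.
    """

    def __init__(self, inner: CmaEs, basis: np.ndarray, offset: np.ndarray):
        self.inner = inner
        self.basis = basis          # (full_dim, k), orthonormal columns
        self.offset = offset        # fixed out-of-subspace component
        self.dim = basis.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.offset + self.basis @ self.inner.mean

    @property
    def sigma(self) -> float:
        return self.inner.sigma

    @property
    def popsize(self) -> int:
        return self.inner.popsize

    @property
    def generation(self) -> int:
        return self.inner.generation

    def ask(self) -> np.ndarray:
        y = self.inner.ask()
        return self.offset + y @ self.basis.T

    def tell(self, latents: np.ndarray, scores) -> None:
        x = np.asarray(latents, dtype=float)
        y = (x - self.offset) @ self.basis
        self.inner.tell(y, scores)


def project_to_subspace(opt: CmaEs, basis: np.ndarray) -> SubspaceCmaEs:
    """Restrict an optimizer to the span of orthonormal ``basis`` columns.

    With the identity basis this is a no-op: the reduced optimizer consumes
    its random stream exactly as the unrestricted one would, so trajectories
    coincide for a shared seed.
    """
    basis = np.asarray(basis, dtype=float)
    if basis.ndim != 2 or basis.shape[0] != opt.dim:
        raise ValueError("basis must be (latent_dim, k)")
    k = basis.shape[1]
    if k > opt.dim:
        raise ValueError("rank exceeds latent dimension")
    gram_dev = np.abs(basis.T @ basis - np.eye(k)).max()
    if gram_dev > 1e-8:
        raise ValueError(f"basis not orthonormal (Gram deviation {gram_dev:.2e})")
    inner = CmaEs(basis.T @ opt.mean, opt.sigma, popsize=opt.popsize, seed=None)
    inner.rng = copy.deepcopy(opt.rng)
    offset = opt.mean - basis @ (basis.T @ opt.mean)
    return SubspaceCmaEs(inner, basis, offset)


def cma_es_update(state: CmaEs, latents: np.ndarray, scores) -> tuple[CmaEs, np.ndarray]:
    """Functional wrapper: one rank-based update, then sample the next batch."""
    state.tell(latents, scores)
    return state, state.ask()
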