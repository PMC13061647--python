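"""Independent minimal CMA-ES used as a cross-check oracle.

A compact, self-contained transcription of the standard
(mu/mu_w, lambda)-CMA-ES update equations, written without reference to the
package implementation.  Sampling draws ``standard_normal((lam, n))`` once
per generation and maps each row through the current eigenbasis, so a shared
seed yields comparable trajectories.  Maximizes the objective.
"""

import numpy as np


class ReferenceCma:
    def __init__(self, x0, sigma, lam, seed):
        x0 = np.array(x0, dtype=float)
        n = len(x0)
        self.n = n
        self.xmean = x0
        self.sigma = float(sigma)
        self.lam = lam
        mu = lam // 2
        w = np.log(lam / 2 + 0.5) - np.log(np.arange(1, mu + 1))
        self.w = w / np.sum(w)
        self.mu = mu
        self.mueff = np.sum(self.w) ** 2 / np.sum(self.w ** 2)
        self.cc = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.cs = (self.mueff + 2) / (n + self.mueff + 5)
        self.c1 = 2 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(1 - self.c1,
                       2 * (self.mueff - 2 + 1 / self.mueff)
                       / ((n + 2) ** 2 + self.mueff))
        self.damps = (1 + 2 * max(0, np.sqrt((self.mueff - 1) / (n + 1)) - 1)
                      + self.cs)
        self.chiN = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))
        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.B = np.eye(n)
        self.D = np.ones(n)
        self.C = np.eye(n)
        self.counteval = 0
        self.rng = np.random.default_rng(seed)

    def ask(self):
        z = self.rng.standard_normal((self.lam, self.n))
        self.arx = self.xmean + self.sigma * (z * self.D) @ self.B.T
        return self.arx

    def tell(self, fitness):
        """fitness: one value per row of the last ask(); maximized."""
        idx = np.argsort(-np.asarray(fitness), kind="stable")[:self.mu]
        xsel = self.arx[idx]
        xold = self.xmean
        self.xmean = self.w @ xsel
        yw = (self.xmean - xold) / self.sigma
        cinv_yw = self.B @ ((self.B.T @ yw) / self.D)
        self.ps = ((1 - self.cs) * self.ps
                   + np.sqrt(self.cs * (2 - self.cs) * self.mueff) * cinv_yw)
        self.counteval += 1
        denom = np.sqrt(1 - (1 - self.cs) ** (2 * self.counteval))
        hsig = (np.linalg.norm(self.ps) / denom
                < (1.4 + 2 / (self.n + 1)) * self.chiN)
        self.pc = ((1 - self.cc) * self.pc
                   + hsig * np.sqrt(self.cc * (2 - self.cc) * self.mueff) * yw)
        ys = (xsel - xold) / self.sigma
        self.C = ((1 - self.c1 - self.cmu) * self.C
                  + self.c1 * (np.outer(self.pc, self.pc)
                               + (1 - hsig) * self.cc * (2 - self.cc) * self.C)
                  + self.cmu * (ys.T * self.w) @ ys)
        self.sigma *= np.exp((self.cs / self.damps)
                             * (np.linalg.norm(self.ps) / self.chiN - 1))
        self.C = np.triu(self.C) + np.triu(self.C, 1).T
        dd, self.B = np.linalg.eigh(self.C)
        self.D = np.sqrt(np.maximum(dd, 1e-20))
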