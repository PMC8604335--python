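"""Random-effects Bayesian model selection (RFX-BMS).

Treats the model identity of each subject as a draw from a multinomial with
unknown frequencies r, places a Dirichlet prior on r, and estimates the
Dirichlet posterior from the per-subject log model evidences by a
variational fixed point. From the posterior concentration alpha it derives
expected model frequencies, exceedance probabilities (EP: probability a
model is the most frequent), the Bayesian omnibus risk (BOR: posterior
probability that all frequencies are equal) and protected exceedance
probabilities PEP = EP*(1-BOR) + BOR/K.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp


class ConvergenceError(RuntimeError):
    pass


@dataclass
class BMSResult:
    labels: tuple[str, ...]
    alpha: np.ndarray
    expected_freq: np.ndarray
    ep: np.ndarray
    bor: float
    pep: np.ndarray
    n_iterations: int
    n_samples: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "alpha": list(map(float, self.alpha)),
            "expected_freq": list(map(float, self.expected_freq)),
            "ep": list(map(float, self.ep)),
            "bor": float(self.bor),
            "pep": list(map(float, self.pep)),
            "n_iterations": self.n_iterations,
            "n_samples": self.n_samples,
            "seed": self.seed,
        }


def _as_matrix(lme) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(lme, pd.DataFrame):
        return lme.to_numpy(dtype=float), tuple(map(str, lme.columns))
    arr = np.asarray(lme, dtype=float)
    return arr, tuple(f"model_{k}" for k in range(arr.shape[1]))


def rfx_bms(lme, alpha0: float | np.ndarray = 1.0,
            max_iter: int = 10_000, tol: float = 1e-6
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Variational fixed point for the Dirichlet posterior over frequencies.

    Responsibilities g_nk ~ exp(lme_nk + psi(alpha_k) - psi(sum alpha)) are
    alternated with alpha = alpha0 + sum_n g_nk until max |delta alpha| <
    ``tol``. Returns (alpha, expected_freq, responsibilities, n_iter).
    """
    L, _ = _as_matrix(lme)
    if not np.all(np.isfinite(L)):
        raise ValueError("LME matrix must be finite")
    n, K = L.shape
    a0 = np.broadcast_to(np.asarray(alpha0, dtype=float), (K,)).copy()
    if np.any(a0 <= 0):
        raise ValueError("alpha0 must be positive")
    alpha = a0.copy()
    for it in range(1, max_iter + 1):
        logu = L + digamma(alpha) - digamma(alpha.sum())
        g = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = a0 + g.sum(axis=0)
        delta = np.max(np.abs(alpha_new - alpha))
        alpha = alpha_new
        if delta < tol:
            return alpha, alpha / alpha.sum(), g, it
    raise ConvergenceError(f"RFX-BMS did not converge in {max_iter} iterations")


def exceedance_prob(alpha: np.ndarray, n_samples: int = 1_000_000,
                    seed: int = 0) -> np.ndarray:
    """Monte-Carlo exceedance probabilities from the Dirichlet posterior."""
    alpha = np.asarray(alpha, dtype=float)
    K = len(alpha)
    if K == 1:
        return np.array([1.0])
    rng = np.random.default_rng(seed)
    wins = np.zeros(K)
    chunk = 200_000
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.dirichlet(alpha, size=m)
        wins += np.bincount(np.argmax(draws, axis=1), minlength=K)
        remaining -= m
    return wins / n_samples


def _dirichlet_log_norm(alpha: np.ndarray) -> float:
    return float(gammaln(alpha).sum() - gammaln(alpha.sum()))


def free_energy_rfx(lme, alpha: np.ndarray, g: np.ndarray,
                    alpha0: float | np.ndarray = 1.0) -> float:
    """Variational free energy of the random-effects model.

    F1 = sum_nk g_nk lme_nk + sum_k (alpha0_k + sum_n g_nk - alpha_k) E[log r_k]
         + log B(alpha) - log B(alpha0) - sum_nk g_nk log g_nk
    with E[log r_k] = psi(alpha_k) - psi(sum alpha) and B the Dirichlet
    normalizer; the middle term vanishes at the converged fixed point.
    """
    L, _ = _as_matrix(lme)
    K = L.shape[1]
    a0 = np.broadcast_to(np.asarray(alpha0, dtype=float), (K,))
    elogr = digamma(alpha) - digamma(alpha.sum())
    entropy = -np.sum(g * np.log(np.maximum(g, 1e-300)))
    return float(
        np.sum(g * L)
        + np.sum((a0 + g.sum(axis=0) - alpha) * elogr)
        + _dirichlet_log_norm(alpha) - _dirichlet_log_norm(np.asarray(a0))
        + entropy)


def null_evidence(lme) -> float:
    """Log evidence of the fixed-effects null: all frequencies equal 1/K."""
    L, _ = _as_matrix(lme)
    K = L.shape[1]
    return float(np.sum(logsumexp(L, axis=1) - np.log(K)))


def bor_and_pep(lme, ep: np.ndarray, alpha: np.ndarray, g: np.ndarray,
                alpha0: float | np.ndarray = 1.0) -> tuple[float, np.ndarray]:
    """Bayesian omnibus risk and protected exceedance probabilities."""
    K = len(alpha)
    f1 = free_energy_rfx(lme, alpha, g, alpha0)
    f0 = null_evidence(lme)
    # bor = 1 / (1 + exp(F1 - F0)), computed stably
    z = f1 - f0
    bor = float(1.0 / (1.0 + np.exp(z))) if z < 700 else 0.0
    pep = ep * (1.0 - bor) + bor / K
    return bor, pep


def bms(lme, alpha0: float | np.ndarray = 1.0, n_samples: int = 1_000_000,
        seed: int = 0, labels: Optional[Sequence[str]] = None) -> BMSResult:
    """One-call RFX-BMS: Dirichlet posterior, EP, BOR and PEP."""
    L, inferred = _as_matrix(lme)
    labels = tuple(labels) if labels is not None else inferred
    alpha, freq, g, n_iter = rfx_bms(L, alpha0)
    ep = exceedance_prob(alpha, n_samples=n_samples, seed=seed)
    bor, pep = bor_and_pep(L, ep, alpha, g, alpha0)
    return BMSResult(labels=labels, alpha=alpha, expected_freq=freq, ep=ep,
                     bor=bor, pep=pep, n_iterations=n_iter,
                     n_samples=n_samples, seed=seed)
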