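"""Multivariate Bernoulli-emission hidden Markov model fit by EM.

The segmentation model: each 200-bp genomic bin is an observation
x_t ∈ {0,1}^M over M binarized chromatin tracks; the hidden state k
emits each mark m independently with probability E[k, m]. Parameters
(initial distribution π, transition matrix A, emissions E) are learned
by Baum-Welch with scaled forward-backward recursions; decoding is by
posterior-marginal argmax (Viterbi available as an option).

Fitting runs several random restarts and keeps the model with the best
final log-likelihood; given the same seed and restart count the result
is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

_EPS = 1e-12


@dataclass
class ChromStateModel:
    """Fitted HMM parameters plus optional state→family labels."""

    startprob: np.ndarray  # (K,)
    transmat: np.ndarray  # (K, K)
    emissions: np.ndarray  # (K, M) Bernoulli probability per mark
    marks: List[str]
    log_likelihood: float = np.nan
    loglik_trace: Optional[np.ndarray] = None
    labels: Optional[dict] = None  # state index -> family name

    @property
    def n_states(self) -> int:
        return self.emissions.shape[0]

    def validate(self) -> None:
        if not np.isclose(self.startprob.sum(), 1.0):
            raise ValueError("startprob must sum to 1")
        if not np.allclose(self.transmat.sum(axis=1), 1.0):
            raise ValueError("transmat rows must sum to 1")
        if ((self.emissions < 0) | (self.emissions > 1)).any():
            raise ValueError("emissions must lie in [0, 1]")


def _log_emission_matrix(x: np.ndarray, emissions: np.ndarray) -> np.ndarray:
    """(T, K) log P(x_t | state k) for binary x (T, M)."""
    e = np.clip(emissions, _EPS, 1.0 - _EPS)
    return x @ np.log(e).T + (1.0 - x) @ np.log(1.0 - e).T


def forward_backward(x: np.ndarray, model: ChromStateModel):
    """Scaled forward-backward pass.

    Returns ``(gamma, xi_sum, loglik)``: posterior state marginals
    (T, K), summed pairwise posteriors (K, K), and the data
    log-likelihood.
    """
    logb = _log_emission_matrix(x, model.emissions)
    # scale within each row to avoid underflow of exp
    b = np.exp(logb - logb.max(axis=1, keepdims=True))
    T, K = b.shape
    A = model.transmat
    alpha = np.empty((T, K))
    c = np.empty(T)  # scaling constants

    a0 = model.startprob * b[0]
    c[0] = a0.sum()
    alpha[0] = a0 / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * b[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]

    beta = np.empty((T, K))
    beta[-1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = b[t + 1] * beta[t + 1]
        beta[t] = (A @ bb) / c[t + 1]
        xi_sum += np.outer(alpha[t], bb / c[t + 1]) * A

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.log(c).sum() + logb.max(axis=1).sum())
    return gamma, xi_sum, loglik


def _em_fit(x, K, marks, rng, tol, max_iter):
    T, M = x.shape
    if K == 1:
        e = x.mean(axis=0, keepdims=True)
        model = ChromStateModel(
            startprob=np.ones(1),
            transmat=np.ones((1, 1)),
            emissions=e,
            marks=list(marks),
        )
        _, _, ll = forward_backward(x, model)
        model.log_likelihood = ll
        model.loglik_trace = np.array([ll])
        return model

    emissions = rng.uniform(0.2, 0.8, size=(K, M))
    transmat = rng.dirichlet(np.full(K, 10.0), size=K)
    startprob = rng.dirichlet(np.ones(K))
    model = ChromStateModel(startprob, transmat, emissions, list(marks))

    trace = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        gamma, xi_sum, ll = forward_backward(x, model)
        trace.append(ll)
        # M-step
        model.startprob = gamma[0] / gamma[0].sum()
        model.transmat = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True), _EPS)
        occ = gamma.sum(axis=0)
        model.emissions = (gamma.T @ x) / np.maximum(occ[:, None], _EPS)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    model.log_likelihood = trace[-1]
    model.loglik_trace = np.asarray(trace)
    return model


def learn_hmm(
    x: np.ndarray,
    n_states: int,
    marks: Optional[Sequence[str]] = None,
    seed: int = 0,
    n_restarts: int = 5,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> ChromStateModel:
    """Fit a K-state Bernoulli-emission HMM to a binary (T, M) matrix.

    EM runs until the log-likelihood change falls below ``tol`` or
    ``max_iter`` iterations; the best of ``n_restarts`` seeded random
    initializations (by final log-likelihood) is returned, its
    log-likelihood trace attached.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.size == 0:
        raise ValueError("x must be a non-empty (bins, marks) binary matrix")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("x must be binary")
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_states > x.shape[0]:
        raise ValueError(f"n_states={n_states} exceeds {x.shape[0]} bins")
    if marks is None:
        marks = [f"mark{m}" for m in range(x.shape[1])]

    streams = np.random.SeedSequence(seed).spawn(max(n_restarts, 1))
    best = None
    for ss in streams:
        model = _em_fit(x, n_states, marks, np.random.default_rng(ss), tol, max_iter)
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    best.validate()
    return best


def log_likelihood(x: np.ndarray, model: ChromStateModel) -> float:
    """Data log-likelihood under a fitted model (e.g. held-out bins)."""
    return forward_backward(np.asarray(x, dtype=float), model)[2]


def posterior_marginals(x: np.ndarray, model: ChromStateModel) -> np.ndarray:
    return forward_backward(np.asarray(x, dtype=float), model)[0]


def decode_states(model: ChromStateModel, x: np.ndarray, method: str = "posterior") -> np.ndarray:
    """Per-bin state assignment.

    ``posterior`` (default): argmax of the forward-backward posterior
    marginal, ties resolved to the lowest state index (numpy argmax).
    ``viterbi``: most probable joint path.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[1] != model.emissions.shape[1]:
        raise ValueError(
            f"x has {x.shape[1]} marks but model was trained on "
            f"{model.emissions.shape[1]}"
        )
    if method == "posterior":
        gamma = posterior_marginals(x, model)
        return gamma.argmax(axis=1)
    if method == "viterbi":
        return _viterbi(x, model)
    raise ValueError(f"unknown decode method {method!r}")


def _viterbi(x: np.ndarray, model: ChromStateModel) -> np.ndarray:
    logb = _log_emission_matrix(x, model.emissions)
    logA = np.log(np.clip(model.transmat, _EPS, None))
    T, K = logb.shape
    delta = np.log(np.clip(model.startprob, _EPS, None)) + logb[0]
    back = np.zeros((T, K), dtype=np.intp)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + logb[t]
    states = np.empty(T, dtype=np.intp)
    states[-1] = delta.argmax()
    for t in range(T - 2, -1, -1):
        states[t] = back[t + 1, states[t + 1]]
    return states


def align_states(reference_emissions: np.ndarray, model: ChromStateModel) -> np.ndarray:
    """Greedy permutation mapping model states onto reference states by
    closest emissions (L1); useful for comparing a fit to generating
    parameters up to label switching."""
    K = model.n_states
    cost = np.abs(
        reference_emissions[:, None, :] - model.emissions[None, :, :]
    ).sum(axis=2)
    perm = np.full(K, -1)
    used = set()
    for ref in np.argsort(cost.min(axis=1)):
        order = np.argsort(cost[ref])
        for j in order:
            if j not in used:
                perm[ref] = j
                used.add(j)
                break
    return perm
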