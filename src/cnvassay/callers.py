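"""Per-bin copy-number callers.

The principal caller is a first-order hidden Markov model over the copy-number
states {0..5} with negative-binomial emissions — the minimal dynamic Bayesian
network that turns independent overdispersed bin counts into holistic,
segment-aware copy-number predictions.  Two lightweight reference callers
(plain ratio rounding, and running-median smoothing before rounding) stand in
for external read-depth tools so that multi-caller consensus is exercisable
end to end.

Each chromosome is an independent chain.  Emission for state ``k`` at a bin
with normalized count ``c`` is ``NB(mean = mu * max(k, 2*eps) / 2, size = r)``
where ``eps`` is a contamination floor keeping the homozygous-deletion state
at a small positive mean.  Transitions put ``p_stay`` on the diagonal and
spread the remainder uniformly, favouring arm-scale segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import nbinom

from .genome import DEFAULT_STATES, GenomeBins
from .normalize import NormalizedBins

__all__ = [
    "HmmConfig",
    "CallerResult",
    "call_cnv_hmm",
    "call_cnv_ratio_threshold",
    "call_cnv_median_window",
    "hmm_forward_loglik",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HmmConfig:
    """Parameters of the NB-emission copy-number HMM.

    ``p_stay`` defaults to 0.98: at 500 kb bins this puts the expected
    segment length at ~25 Mb, matching arm/chromosome-scale events.
    """

    mu: float
    r: float
    p_stay: float = 0.98
    epsilon: float = 0.01
    states: tuple[int, ...] = DEFAULT_STATES
    baseline: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.p_stay < 1:
            raise ValueError("p_stay must lie strictly between 0 and 1")
        if self.mu <= 0 or self.r <= 0:
            raise ValueError("mu and r must be positive")
        if not 0 < self.epsilon < 0.5:
            raise ValueError("epsilon must lie in (0, 0.5)")

    def state_means(self) -> np.ndarray:
        k = np.asarray(self.states, dtype=float)
        return self.mu * np.maximum(k, 2.0 * self.epsilon) / 2.0


@dataclass(frozen=True)
class CallerResult:
    """One caller's per-bin state assignment with confidence."""

    caller: str
    states: np.ndarray
    confidence: np.ndarray
    genome: GenomeBins
    posterior: np.ndarray | None = field(default=None, repr=False)
    state_set: tuple[int, ...] = DEFAULT_STATES

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=int)
        conf = np.asarray(self.confidence, dtype=float)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "confidence", conf)
        if len(states) != self.genome.n_bins or len(conf) != self.genome.n_bins:
            raise ValueError("caller result length does not match the genome bin count")
        if not np.isin(states, self.state_set).all():
            raise ValueError("caller states outside the configured state set")
        if np.any((conf < 0) | (conf > 1 + 1e-12)):
            raise ValueError("confidences must lie in [0, 1]")
        if self.posterior is not None:
            rows = self.posterior.sum(axis=1)
            if np.any(np.abs(rows - 1.0) > 1e-9):
                raise ValueError("posterior rows must sum to 1")


def _prepare_counts(values: np.ndarray) -> np.ndarray:
    """Round normalized values to non-negative integers for NB evaluation."""
    values = np.asarray(values, dtype=float)
    bad = ~np.isfinite(values) | (values < 0)
    if bad.any():
        log.warning("rounding %d negative/non-finite normalized counts to 0", int(bad.sum()))
    return np.maximum(np.round(np.where(bad, 0.0, values)), 0).astype(np.int64)


def _emission_logprobs(counts: np.ndarray, cfg: HmmConfig) -> np.ndarray:
    """(n_bins, n_states) matrix of NB log-pmf values."""
    means = cfg.state_means()
    p = cfg.r / (cfg.r + means)
    return nbinom.logpmf(counts[:, None], cfg.r, p[None, :])


def _chain_slices(genome: GenomeBins):
    idx = genome.chrom_index()
    for code in np.unique(idx):
        yield np.flatnonzero(idx == code)


def _log_transition(cfg: HmmConfig) -> np.ndarray:
    S = len(cfg.states)
    trans = np.full((S, S), (1.0 - cfg.p_stay) / (S - 1))
    np.fill_diagonal(trans, cfg.p_stay)
    return np.log(trans)


def hmm_forward_loglik(values: np.ndarray, cfg: HmmConfig) -> float:
    """Log-likelihood of one chain of normalized counts under the HMM.

    Sums over all hidden state paths (forward algorithm, uniform initial
    distribution).  Exposed separately so the likelihood can be checked
    against exhaustive path enumeration on short chains.
    """
    counts = _prepare_counts(values)
    logB = _emission_logprobs(counts, cfg)
    logA = _log_transition(cfg)
    S = len(cfg.states)
    alpha = -np.log(S) + logB[0]
    for t in range(1, len(counts)):
        alpha = logsumexp(alpha[:, None] + logA, axis=0) + logB[t]
    return float(logsumexp(alpha))


def _forward_backward(logB: np.ndarray, logA: np.ndarray) -> np.ndarray:
    T, S = logB.shape
    alpha = np.empty((T, S))
    beta = np.empty((T, S))
    alpha[0] = -np.log(S) + logB[0]
    for t in range(1, T):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + logA, axis=0) + logB[t]
    beta[-1] = 0.0
    for t in range(T - 2, -1, -1):
        beta[t] = logsumexp(logA + (logB[t + 1] + beta[t + 1])[None, :], axis=1)
    post = alpha + beta
    post -= logsumexp(post, axis=1, keepdims=True)
    return np.exp(post)


def _viterbi(logB: np.ndarray, logA: np.ndarray) -> np.ndarray:
    T, S = logB.shape
    delta = -np.log(S) + logB[0]
    back = np.zeros((T, S), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + logA
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(S)] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def call_cnv_hmm(norm: NormalizedBins, cfg: HmmConfig | None = None) -> CallerResult:
    """Viterbi copy-number path with forward-backward posteriors as confidence.

    Chromosomes are decoded independently.  When ``cfg`` is omitted, the
    diploid mean comes from the normalization baseline and the NB size from
    the method-of-moments estimator.
    """
    if cfg is None:
        from .normalize import estimate_dispersion

        cfg = HmmConfig(mu=norm.diploid_mean, r=estimate_dispersion(norm))
    counts = _prepare_counts(norm.values)
    logA = _log_transition(cfg)
    states = np.empty(norm.n_bins, dtype=int)
    posterior = np.empty((norm.n_bins, len(cfg.states)))
    for chain in _chain_slices(norm.genome):
        logB = _emission_logprobs(counts[chain], cfg)
        path = _viterbi(logB, logA)
        post = _forward_backward(logB, logA)
        states[chain] = np.asarray(cfg.states)[path]
        posterior[chain] = post
    state_pos = {s: i for i, s in enumerate(cfg.states)}
    conf = posterior[np.arange(norm.n_bins), [state_pos[s] for s in states]]
    return CallerResult(
        caller="hmm", states=states, confidence=conf,
        genome=norm.genome, posterior=posterior, state_set=cfg.states,
    )


def _round_states(ratio2: np.ndarray, state_set: tuple[int, ...]):
    """Round doubled copy ratios to states, clamping to the state set.

    Confidence is the distance from the nearest rounding boundary rescaled to
    [0, 1]: a value exactly on an integer state scores 1, a value halfway
    between two states scores 0.
    """
    lo, hi = min(state_set), max(state_set)
    raw = np.round(ratio2)
    clamped = np.clip(raw, lo, hi)
    n_clamped = int(np.sum(raw != clamped))
    if n_clamped:
        log.warning("clamped %d bins implying copy number outside %s", n_clamped, list(state_set))
    frac = ratio2 - np.floor(ratio2)
    conf = 2.0 * np.abs(frac - 0.5)
    conf[raw != clamped] = 1.0  # beyond the clamp the assignment is unambiguous
    return clamped.astype(int), np.clip(conf, 0.0, 1.0)


def call_cnv_ratio_threshold(
    norm: NormalizedBins, state_set: tuple[int, ...] = DEFAULT_STATES
) -> CallerResult:
    """Stateless reference caller: ``state = round(2 * value / mu)``."""
    ratio2 = 2.0 * norm.values / norm.diploid_mean
    states, conf = _round_states(ratio2, state_set)
    return CallerResult("ratio", states, conf, norm.genome, state_set=state_set)


def call_cnv_median_window(
    norm: NormalizedBins, window: int = 5, state_set: tuple[int, ...] = DEFAULT_STATES
) -> CallerResult:
    """Running-median smoothing within chromosome, then ratio rounding.

    The window shrinks at chromosome edges; it must be odd and >= 3 so a
    single outlier bin can never carry the median.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    h = window // 2
    smoothed = np.empty(norm.n_bins)
    for chain in _chain_slices(norm.genome):
        vals = norm.values[chain]
        for j in range(len(chain)):
            lo, hi = max(0, j - h), min(len(chain), j + h + 1)
            smoothed[chain[j]] = np.median(vals[lo:hi])
    states, conf = _round_states(2.0 * smoothed / norm.diploid_mean, state_set)
    return CallerResult("medwin", states, conf, norm.genome, state_set=state_set)
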