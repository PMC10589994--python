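"""Hyper-variability statistics for cluster-formation trajectories.

Model: upon observing the n-th target of an anchor/direction, a new target
cluster is created with probability p_n (Bernoulli indicator X_n). The
number of clusters after N targets is then Poisson-Binomial,
C_N ~ PoissBin(p_1, .., p_N). Because the vast majority of anchors sit in
non-diversifying sequence, the rank-wise success probabilities can be
estimated directly from the pooled trajectories of all anchors; anchors
whose observed C_N lies far in the right tail of the fitted
Poisson-Binomial are flagged as hyper-variable.

The tail probability P[C_N >= c] is evaluated exactly through the discrete
Fourier inversion of the Poisson-Binomial characteristic function at the
(N+1)-th roots of unity; p-values are then corrected with a
memory-efficient Benjamini-Hochberg scheme that keeps only p <= 0.1 while
remembering the total number of tests m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NullModel",
    "DiversityResult",
    "TestLedger",
    "estimate_null",
    "poisson_binomial_pmf",
    "poisson_binomial_tail",
    "bh_correct",
    "effect_size",
    "P_DROP",
    "Q_CUTOFF",
]

#: p-values above this are dropped before BH ranking (but still counted in m)
P_DROP = 0.1
#: significance cutoff on the BH-adjusted q-values
Q_CUTOFF = 0.1

# products in the DFT inversion switch to complex log-space above this N
_LOGSPACE_N = 30


@dataclass(frozen=True)
class NullModel:
    """Rank-wise new-cluster probabilities estimated from pooled trajectories.

    Attributes
    ----------
    p_hat
        p_hat[n-1] estimates P[X_n = 1]; p_hat[0] is 1 by construction
        (the first target always founds a cluster).
    numer, denom
        Per-rank sums: number of trajectories with a new cluster at rank n,
        and number of trajectories that reached rank n at all.
    """

    p_hat: np.ndarray
    numer: np.ndarray
    denom: np.ndarray

    def truncated(self, N: int) -> np.ndarray:
        if N > len(self.p_hat):
            raise ValueError(f"null model only covers ranks up to {len(self.p_hat)}")
        return self.p_hat[:N]


@dataclass
class DiversityResult:
    """Outcome of one anchor x direction hyper-variability test."""

    anchor: str
    direction: str
    N: int
    C_N: int
    p_value: float
    alpha: float
    q_value: float | None = None
    max_within_read: int = 1


@dataclass
class TestLedger:
    """Bookkeeping for the memory-efficient BH correction.

    ``m`` counts every test performed; ``retained`` keeps only the tests
    with p <= P_DROP, as (test id, p-value) pairs.
    """

    m: int = 0
    retained: list[tuple[object, float]] = field(default_factory=list)

    def record(self, test_id: object, p: float, p_drop: float = P_DROP) -> None:
        self.m += 1
        if p <= p_drop:
            self.retained.append((test_id, p))


def estimate_null(trajectories: Iterable[Sequence[int]]) -> NullModel:
    """Estimate p_hat from binary new-cluster trajectories of ragged length.

    p_hat_n = (sum over trajectories of x_{m,n}) / (# trajectories with
    N_m >= n). Trajectories shorter than rank n simply do not contribute
    at that rank.
    """
    numer: np.ndarray | None = None
    denom: np.ndarray | None = None
    n_traj = 0
    for traj in trajectories:
        n_traj += 1
        arr = np.frombuffer(bytes(traj), dtype=np.uint8) if isinstance(
            traj, (bytes, bytearray)
        ) else np.asarray(traj, dtype=np.uint8)
        n = len(arr)
        if n == 0:
            continue
        if numer is None or n > len(numer):
            new_len = n if numer is None else max(n, 2 * len(numer))
            new_numer = np.zeros(new_len, dtype=np.int64)
            new_denom = np.zeros(new_len, dtype=np.int64)
            if numer is not None:
                new_numer[: len(numer)] = numer
                new_denom[: len(denom)] = denom
            numer, denom = new_numer, new_denom
        numer[:n] += arr
        denom[:n] += 1
    if n_traj == 0 or numer is None:
        raise ValueError("cannot calibrate a null model without trajectories")
    top = np.flatnonzero(denom)
    max_rank = int(top[-1]) + 1
    numer = numer[:max_rank]
    denom = denom[:max_rank]
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = np.where(denom > 0, numer / np.maximum(denom, 1), np.nan)
    return NullModel(p_hat=p_hat, numer=numer, denom=denom)


def poisson_binomial_pmf(p: Sequence[float]) -> np.ndarray:
    """Exact pmf of a Poisson-Binomial via roots-of-unity inversion.

    With R = exp(2*pi*i/(N+1)),

        P[C = k] = (1/(N+1)) * sum_l R^{-l k} * prod_n (1 + (R^l - 1) p_n)

    which is the inverse DFT of the characteristic function sampled at the
    (N+1)-th roots of unity. Each factor has modulus <= 1, but for long
    products the evaluation moves to complex log-space to avoid underflow
    collapsing intermediate terms.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    N = len(p)
    if N == 0:
        return np.ones(1)
    w = np.exp(2j * np.pi * np.arange(N + 1) / (N + 1))  # R^l, l = 0..N
    terms = 1.0 + np.outer(w - 1.0, p)  # (N+1, N)
    if N <= _LOGSPACE_N:
        f = np.prod(terms, axis=1)
    else:
        mag = np.abs(terms)
        zero_rows = np.any(mag == 0.0, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            logf = np.sum(np.log(np.where(zero_rows[:, None], 1.0, terms)), axis=1)
        f = np.where(zero_rows, 0.0, np.exp(logf))
    pmf = np.fft.fft(f).real / (N + 1)
    return np.clip(pmf, 0.0, 1.0)


def poisson_binomial_tail(c: int, N: int, p_hat: Sequence[float]) -> float:
    """P[C_N >= c] under C_N ~ PoissBin(p_hat[0..N-1]), clamped to (0, 1]."""
    if not (1 <= c <= N):
        raise ValueError("need 1 <= c <= N")
    p = np.asarray(p_hat, dtype=float)
    if len(p) < N:
        raise ValueError("p_hat shorter than N")
    pmf = poisson_binomial_pmf(p[:N])
    tail = float(pmf[c:].sum())
    return min(1.0, max(tail, 0.0))


def bh_correct(
    ledger: TestLedger, monotone: bool = True, q_cutoff: float = Q_CUTOFF
) -> dict[object, float]:
    """Memory-efficient Benjamini-Hochberg adjustment.

    The retained p-values (all <= P_DROP) are ranked ascending and adjusted
    as q(i) = p(i) * m / i with m the *total* number of tests, including
    dropped ones. With ``monotone=True`` (default) the standard step-up
    enforcement q(i) = min_{j>=i} p(j)*m/j is applied so that q is
    non-decreasing along the sorted order; with ``monotone=False`` the raw
    products are returned. Dropped tests receive no q-value. Significance
    downstream means q < ``q_cutoff``.
    """
    if not ledger.retained:
        return {}
    m = ledger.m
    if m < len(ledger.retained):
        raise ValueError("ledger.m smaller than number of retained tests")
    order = sorted(range(len(ledger.retained)), key=lambda i: ledger.retained[i][1])
    raw = np.array(
        [ledger.retained[idx][1] * m / (rank + 1) for rank, idx in enumerate(order)]
    )
    if monotone:
        q = np.minimum.accumulate(raw[::-1])[::-1]
    else:
        q = raw
    q = np.minimum(q, 1.0)
    return {ledger.retained[idx][0]: float(q[rank]) for rank, idx in enumerate(order)}


def effect_size(C_N: int, N: int, p_hat: Sequence[float]) -> float:
    """log2 fold change of observed vs expected cluster count.

    alpha = log2(C_N / E[C_N | N]) with E[C_N | N] = sum of the first N
    rank probabilities (the Poisson-Binomial mean).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    p = np.asarray(p_hat, dtype=float)
    if len(p) < N:
        raise ValueError("p_hat shorter than N")
    expected = float(p[:N].sum())
    if expected <= 0:
        raise ValueError("expected cluster count is zero")
    return float(np.log2(C_N / expected))
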