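"""K-state Gaussian-emission hidden Markov modelling of FRET trajectories.

One global model is fitted per measurement condition by Baum-Welch (EM) over
all selected traces jointly: the forward-backward pass runs per trace, the
M-step pools sufficient statistics, so every molecule shares the same state
means, emission widths and transition matrix.  Traces are then idealized to
their most probable state path with the Viterbi algorithm, which is what all
dwell-time and transition statistics are computed from.

Numerical notes: the forward-backward recursions use per-frame scaling (no
log-sum-exp needed for K <= a handful); emission s.d. is floored to avoid
variance collapse; states are always reported sorted by ascending mean so
that "state 0" is the lowest-FRET state everywhere downstream.  The inner
loops are JIT-compiled with numba.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit
from sklearn.mixture import GaussianMixture

__all__ = [
    "HmmModel",
    "IdealizedTrace",
    "FitError",
    "init_from_pooled_mixture",
    "fit_hmm",
    "viterbi_idealize",
    "select_n_states",
]

SD_FLOOR = 0.01
_SQRT2PI = math.sqrt(2.0 * math.pi)
_PDF_FLOOR = 1e-300


class FitError(RuntimeError):
    """Raised when every EM restart fails to produce a finite likelihood."""


@dataclass
class HmmModel:
    """A fitted (or initial) K-state Gaussian-emission HMM."""

    n_states: int
    means: np.ndarray
    sds: np.ndarray
    transition: np.ndarray
    initial: np.ndarray
    log_likelihood: float = np.nan
    n_iter: int = 0
    converged: bool = False
    ll_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        K = self.n_states
        if self.means.shape != (K,) or self.sds.shape != (K,):
            raise ValueError("means and sds must have n_states entries")
        if self.transition.shape != (K, K):
            raise ValueError("transition must be KxK")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")

    def sorted_by_mean(self) -> "HmmModel":
        """Canonical state order: ascending means."""
        order = np.argsort(self.means)
        return HmmModel(
            n_states=self.n_states,
            means=self.means[order],
            sds=self.sds[order],
            transition=self.transition[np.ix_(order, order)],
            initial=self.initial[order],
            log_likelihood=self.log_likelihood,
            n_iter=self.n_iter,
            converged=self.converged,
            ll_history=list(self.ll_history),
        )

    def to_json(self, path=None) -> str:
        d = {
            "n_states": self.n_states,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "transition": self.transition.tolist(),
            "initial": self.initial.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "HmmModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(**d)


@dataclass
class IdealizedTrace:
    """Viterbi state path for one trace, with run-length segments.

    ``segments`` is an ordered list of ``(state, start_frame, length)``
    partitioning the trace; frame indices refer to the trace's valid-FRET
    frame sequence.  ``idealized_fret[t]`` is the model mean of the state
    occupied at frame t.
    """

    trace_id: str
    state_path: np.ndarray
    segments: list
    idealized_fret: np.ndarray
    frame_time_s: float = 0.05


def _segments_from_path(path: np.ndarray) -> list:
    if path.size == 0:
        return []
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [path.size]))
    return [(int(path[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def init_from_pooled_mixture(fret_samples, K: int, seed=None) -> HmmModel:
    """Initial HMM from a Gaussian mixture fit to pooled frames.

    Mixture means/s.d./weights seed the emission model and initial
    distribution; the transition matrix starts sticky (0.95 on the
    diagonal).  Degenerate pooled data (zero variance) fall back to a
    single-state model.
    """
    x = np.asarray(fret_samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 50 * K:
        raise ValueError(f"need at least {50 * K} pooled samples for K={K}")
    if float(np.var(x)) < 1e-12:
        return HmmModel(
            n_states=1,
            means=np.array([float(np.mean(x))]),
            sds=np.array([SD_FLOOR]),
            transition=np.array([[1.0]]),
            initial=np.array([1.0]),
        )
    rs = np.random.RandomState(int(np.random.SeedSequence(seed).generate_state(1)[0]))
    gm = GaussianMixture(n_components=K, covariance_type="full", n_init=3, random_state=rs)
    gm.fit(x[:, None])
    means = gm.means_.ravel()
    sds = np.maximum(np.sqrt(gm.covariances_.ravel()), SD_FLOOR)
    weights = gm.weights_.ravel()
    if K == 1:
        transition = np.array([[1.0]])
    else:
        transition = np.full((K, K), 0.05 / (K - 1))
        np.fill_diagonal(transition, 0.95)
    model = HmmModel(
        n_states=K,
        means=means,
        sds=sds,
        transition=transition,
        initial=weights / weights.sum(),
    )
    return model.sorted_by_mean()


@njit(cache=True)
def _baum_welch_estep(obs, offsets, start, A, means, sds):  # pragma: no cover - numba
    K = means.size
    n_traces = offsets.size - 1
    loglik = 0.0
    g0 = np.zeros(K)
    tnum = np.zeros((K, K))
    w = np.zeros(K)
    wx = np.zeros(K)
    wx2 = np.zeros(K)
    for i in range(n_traces):
        s = offsets[i]
        e = offsets[i + 1]
        T = e - s
        if T == 0:
            continue
        B = np.empty((T, K))
        for t in range(T):
            x = obs[s + t]
            for k in range(K):
                z = (x - means[k]) / sds[k]
                p = math.exp(-0.5 * z * z) / (sds[k] * _SQRT2PI)
                B[t, k] = p if p > _PDF_FLOOR else _PDF_FLOOR
        alpha = np.empty((T, K))
        c = np.empty(T)
        tot = 0.0
        for k in range(K):
            alpha[0, k] = start[k] * B[0, k]
            tot += alpha[0, k]
        c[0] = tot
        for k in range(K):
            alpha[0, k] /= tot
        for t in range(1, T):
            tot = 0.0
            for k in range(K):
                acc = 0.0
                for j in range(K):
                    acc += alpha[t - 1, j] * A[j, k]
                v = acc * B[t, k]
                alpha[t, k] = v
                tot += v
            c[t] = tot
            for k in range(K):
                alpha[t, k] /= tot
        for t in range(T):
            loglik += math.log(c[t])
        # backward pass with on-the-fly accumulation of sufficient statistics
        beta = np.ones(K)
        xlast = obs[s + T - 1]
        for k in range(K):
            g = alpha[T - 1, k]
            w[k] += g
            wx[k] += g * xlast
            wx2[k] += g * xlast * xlast
            if T == 1:
                g0[k] += g
        for t in range(T - 2, -1, -1):
            beta_new = np.empty(K)
            for j in range(K):
                acc = 0.0
                for k in range(K):
                    acc += A[j, k] * B[t + 1, k] * beta[k]
                beta_new[j] = acc / c[t + 1]
            for j in range(K):
                ab = alpha[t, j]
                for k in range(K):
                    tnum[j, k] += ab * A[j, k] * B[t + 1, k] * beta[k] / c[t + 1]
            gsum = 0.0
            for j in range(K):
                gsum += alpha[t, j] * beta_new[j]
            x = obs[s + t]
            for j in range(K):
                g = alpha[t, j] * beta_new[j] / gsum
                w[j] += g
                wx[j] += g * x
                wx2[j] += g * x * x
                if t == 0:
                    g0[j] += g
            beta = beta_new
    return loglik, g0, tnum, w, wx, wx2


def _observations(traces) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate the finite FRET values of each trace; drop empty traces."""
    seqs = []
    for t in traces:
        v = t.values if hasattr(t, "values") else np.asarray(t, dtype=float)
        v = v[np.isfinite(v)]
        if v.size:
            seqs.append(v)
    if not seqs:
        raise ValueError("no usable FRET frames in the input traces")
    obs = np.concatenate(seqs)
    offsets = np.zeros(len(seqs) + 1, dtype=np.int64)
    np.cumsum([s.size for s in seqs], out=offsets[1:])
    return obs, offsets


def _run_em(obs, offsets, model, tol, max_iter, sd_floor):
    start = model.initial.copy()
    A = model.transition.copy()
    means = model.means.copy()
    sds = np.maximum(model.sds.copy(), sd_floor)
    history = []
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, g0, tnum, w, wx, wx2 = _baum_welch_estep(obs, offsets, start, A, means, sds)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite likelihood")
        history.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
        # M-step
        start = g0 / g0.sum()
        rows = tnum.sum(axis=1)
        for j in range(A.shape[0]):
            if rows[j] > 0:
                A[j] = tnum[j] / rows[j]
            # states never exited keep their previous row
        means = wx / w
        var = np.maximum(wx2 / w - means**2, 0.0)
        sds = np.maximum(np.sqrt(var), sd_floor)
    return HmmModel(
        n_states=model.n_states,
        means=means,
        sds=sds,
        transition=A,
        initial=start,
        log_likelihood=history[-1],
        n_iter=n_iter,
        converged=converged,
        ll_history=history,
    )


def fit_hmm(
    traces,
    K: int,
    init: HmmModel | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
    n_restarts: int = 5,
    seed=None,
    sd_floor: float = SD_FLOOR,
) -> HmmModel:
    """Fit one global K-state HMM to a collection of FRET traces.

    Baum-Welch with ``n_restarts`` EM runs: the first starts from ``init``
    (or a pooled-mixture initialisation), the rest jitter the initial means
    by +-0.05 to escape local optima.  The restart with the best final
    log-likelihood wins (ties: lowest restart index).  Output states are
    sorted by ascending mean.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    obs, offsets = _observations(traces)
    rng = np.random.default_rng(seed)
    if init is None:
        init = init_from_pooled_mixture(obs, K, seed=seed)
        if init.n_states != K:  # degenerate fallback
            K = init.n_states

    best = None
    for r in range(max(1, n_restarts)):
        model_r = init
        if r > 0:
            jitter = rng.uniform(-0.05, 0.05, size=K)
            model_r = HmmModel(
                n_states=K,
                means=np.clip(init.means + jitter, -0.2, 1.2),
                sds=init.sds.copy(),
                transition=init.transition.copy(),
                initial=init.initial.copy(),
            )
        try:
            fitted = _run_em(obs, offsets, model_r, tol, max_iter, sd_floor)
        except FloatingPointError:
            continue
        if best is None or fitted.log_likelihood > best.log_likelihood:
            best = fitted
    if best is None:
        raise FitError("all EM restarts diverged")
    return best.sorted_by_mean()


def viterbi_idealize(model: HmmModel, trace) -> IdealizedTrace:
    """Most probable state path of one trace under a fitted model.

    Operates on the trace's finite FRET values; segments are the run-length
    encoding of the path.
    """
    v = trace.values if hasattr(trace, "values") else np.asarray(trace, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("trace has no finite FRET values")
    with np.errstate(divide="ignore"):
        log_start = np.log(model.initial)
        log_A = np.log(model.transition)
    logB = (
        -0.5 * ((v[:, None] - model.means) / model.sds) ** 2
        - np.log(model.sds * _SQRT2PI)
    )
    T, K = logB.shape
    delta = log_start + logB[0]
    psi = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + log_A
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return IdealizedTrace(
        trace_id=getattr(trace, "trace_id", ""),
        state_path=path,
        segments=_segments_from_path(path),
        idealized_fret=model.means[path],
        frame_time_s=getattr(trace, "frame_time_s", 0.05),
    )


def select_n_states(traces, k_values=(1, 2, 3, 4), **fit_kwargs):
    """BIC table over candidate state counts (diagnostic only).

    Free parameters: K-1 initial, K(K-1) transition, 2K emission.
    """
    import pandas as pd

    obs, _ = _observations(traces)
    n = obs.size
    rows = []
    for K in k_values:
        model = fit_hmm(traces, K, **fit_kwargs)
        p = (K - 1) + K * (K - 1) + 2 * K
        rows.append(
            {
                "K": K,
                "log_likelihood": model.log_likelihood,
                "n_params": p,
                "bic": -2.0 * model.log_likelihood + p * np.log(n),
            }
        )
    return pd.DataFrame(rows)
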