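"""Markov-chain kinetics: implied timescales, exact MFPTs, FPT statistics.

A lag-time transition matrix T(tau) estimated from symmetrised transition
counts propagates state populations, P(t + tau) = T(tau) P(t).  Its
eigenvalues give the implied relaxation timescales

    t_i = -tau / ln |lambda_i(tau)|,   i >= 2,

whose independence of the lag is the usual Markovianity diagnostic.  Mean
first-passage times between state sets are computed exactly by graph
transformation: iterative elimination of intermediate nodes with
renormalisation of branching probabilities and waiting times, a numerically
robust alternative to solving (I - T_QQ) m = 1 directly (which serves as
the independent cross-check in the test-suite).

Empirical first-passage statistics from trajectory ensembles include the
delete-one jackknife standard error of the MFPT, a single-Gaussian fit to
the log-FPT distribution (unimodality check) and a single-exponential fit
diagnostic (Poissonian, two-state kinetics check).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import constants
from .landscape import TransitionNetwork
from .order_params import CHI_C_DEFAULT, chi_fib_frames

__all__ = [
    "TransitionMatrix",
    "FPTSample",
    "FPTStatistics",
    "transition_matrix",
    "implied_timescales",
    "mfpt_graph_transform",
    "mfpt_linear_solve",
    "fpt_statistics",
    "first_passage_from_trajectories",
]


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix at a lag time."""

    T: np.ndarray
    lag: float  # in frames or ps, caller's convention
    states: np.ndarray | None = None
    eigenvalues: np.ndarray = field(default=None)

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        rows = self.T.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-10):
            raise ValueError("rows of T must sum to 1")
        if self.states is None:
            self.states = np.arange(self.T.shape[0])
        if self.eigenvalues is None:
            self.eigenvalues = _sorted_eigenvalues(self.T)

    @property
    def stationary(self) -> np.ndarray:
        vals, vecs = np.linalg.eig(self.T.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def _sorted_eigenvalues(T: np.ndarray) -> np.ndarray:
    vals = np.linalg.eigvals(T)
    order = np.argsort(-np.abs(vals))
    vals = vals[order]
    if np.max(np.abs(vals.imag)) < 1e-10:
        vals = vals.real
    return vals


def transition_matrix(net: TransitionNetwork, lag: float | None = None
                      ) -> TransitionMatrix:
    """Row-normalise the symmetrised counts of a transition network.

    Under detailed balance (enforced by the symmetrisation) the spectrum is
    real; eigenvalues are computed on the symmetric similarity transform
    D^{1/2} T D^{-1/2} with D = diag(pi).  States with no outgoing counts
    are rejected by name.
    """
    S = net.sym_counts
    rows = S.sum(axis=1)
    dead = np.nonzero(rows == 0)[0]
    if len(dead):
        raise ValueError(
            f"state(s) {[net.states[d] for d in dead]} have no transition "
            "counts; cannot normalise")
    T = S / rows[:, None]
    # symmetric similarity transform: M_ij = S_ij / sqrt(rows_i rows_j)
    M = S / np.sqrt(np.outer(rows, rows))
    vals = np.linalg.eigvalsh(M)[::-1]
    if lag is None:
        lag = net.lag_ps if net.lag_ps is not None else float(net.lag)
    return TransitionMatrix(T=T, lag=lag, states=net.states.copy(),
                            eigenvalues=vals)


def implied_timescales(tm: TransitionMatrix | np.ndarray,
                       lag: float | None = None) -> np.ndarray:
    """Implied relaxation timescales t_i = -tau / ln |lambda_i|, i >= 2.

    Returned in the units of ``lag``, ordered with the eigenvalues
    (descending modulus).  Eigenvalues of modulus 1 beyond the first map to
    +inf (disconnected chain, flagged with a warning); zero eigenvalues map
    to 0 (instantaneous decay).
    """
    if isinstance(tm, TransitionMatrix):
        vals = tm.eigenvalues
        lag = tm.lag if lag is None else lag
    else:
        vals = _sorted_eigenvalues(np.asarray(tm, dtype=float))
        if lag is None:
            lag = 1.0
    mods = np.abs(vals[1:])
    out = np.empty(len(mods))
    for i, m in enumerate(mods):
        if m >= 1.0 - 1e-12:
            out[i] = np.inf
        elif m <= 1e-12:
            out[i] = 0.0  # numerically zero eigenvalue: instant decay
        else:
            out[i] = -lag / np.log(m)
    if np.any(np.isinf(out)):
        warnings.warn("duplicate unit eigenvalue: chain is disconnected")
    return out


# ---------------------------------------------------------------------------
# mean first-passage times
# ---------------------------------------------------------------------------

def _as_matrix(obj) -> tuple[np.ndarray, np.ndarray, float]:
    """(T, states, step_time) from a TransitionMatrix, network or array."""
    if isinstance(obj, TransitionMatrix):
        return obj.T, obj.states, float(obj.lag)
    if isinstance(obj, TransitionNetwork):
        tm = transition_matrix(obj)
        return tm.T, tm.states, float(tm.lag)
    T = np.asarray(obj, dtype=float)
    return T, np.arange(T.shape[0]), 1.0


def _gt_single_source(T: np.ndarray, source: int, targets: set,
                      tau: float) -> float:
    """MFPT from one source by graph transformation.

    Every node except the source and the targets is eliminated; branching
    probabilities and waiting times are renormalised at each elimination.
    After elimination the source only hops to itself or into the target
    set, so the MFPT is its accumulated waiting time divided by the escape
    probability.
    """
    n = T.shape[0]
    P = T.copy()
    t = np.full(n, tau)
    keep = {source} | targets
    # minimum-degree-style heuristic: eliminate low-connectivity nodes first
    order = sorted((x for x in range(n) if x not in keep),
                   key=lambda x: np.count_nonzero(P[x]) + np.count_nonzero(P[:, x]))
    for x in order:
        pxx = P[x, x]
        if pxx >= 1.0 - 1e-14:
            # absorbing intermediate: unreachable through x
            P[:, x] = 0.0
            P[x, :] = 0.0
            continue
        denom = 1.0 - pxx
        col = P[:, x].copy()
        row = P[x, :].copy()
        t = t + col * t[x] / denom
        P = P + np.outer(col, row) / denom
        P[:, x] = 0.0
        P[x, :] = 0.0
    escape = sum(P[source, b] for b in targets)
    if escape <= 1e-300:
        return float("inf")
    return t[source] / escape


def mfpt_graph_transform(obj, sources, targets,
                         weights: np.ndarray | None = None) -> float:
    """Exact MFPT from a source set to a target set by graph transformation.

    ``obj`` may be a TransitionMatrix, TransitionNetwork or a raw
    row-stochastic matrix (unit step time).  The set MFPT averages the
    per-source MFPTs weighted by the stationary distribution restricted to
    the sources (or by explicit ``weights``).  Unreachable targets give
    +inf.  The result is in the units of the matrix's lag time.
    """
    T, states, tau = _as_matrix(obj)
    index = {s.item() if hasattr(s, "item") else s: i
             for i, s in enumerate(states)}
    src = [index[s] for s in np.atleast_1d(sources)]
    tgt = {index[t] for t in np.atleast_1d(targets)}
    if not src or not tgt:
        raise ValueError("sources and targets must be non-empty")
    src = [s for s in src if s not in tgt]
    if not src:
        return 0.0  # source set inside target set

    if weights is None:
        pi = TransitionMatrix(T=T, lag=tau).stationary
        weights = pi[src]
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        weights = np.ones(len(src))
    weights = weights / weights.sum()

    values = np.array([_gt_single_source(T, s, tgt, tau) for s in src])
    return float(np.dot(weights, values))


def mfpt_linear_solve(obj, sources, targets,
                      weights: np.ndarray | None = None) -> float:
    """MFPT via the linear system (I - T_QQ) m = tau 1 over non-target states.

    Reference implementation used to cross-validate the graph
    transformation; same conventions as :func:`mfpt_graph_transform`.
    """
    T, states, tau = _as_matrix(obj)
    index = {s.item() if hasattr(s, "item") else s: i
             for i, s in enumerate(states)}
    src = [index[s] for s in np.atleast_1d(sources)]
    tgt = sorted({index[t] for t in np.atleast_1d(targets)})
    src = [s for s in src if s not in tgt]
    if not src:
        return 0.0
    q = [i for i in range(T.shape[0]) if i not in tgt]
    Tqq = T[np.ix_(q, q)]
    try:
        m = np.linalg.solve(np.eye(len(q)) - Tqq, np.full(len(q), tau))
    except np.linalg.LinAlgError:
        return float("inf")
    pos = {s: k for k, s in enumerate(q)}
    values = np.array([m[pos[s]] for s in src])
    if weights is None:
        pi = TransitionMatrix(T=T, lag=tau).stationary
        weights = pi[src]
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        weights = np.ones(len(src))
    weights = weights / weights.sum()
    return float(np.dot(weights, values))


# ---------------------------------------------------------------------------
# empirical first-passage statistics
# ---------------------------------------------------------------------------

@dataclass
class FPTSample:
    """Per-trajectory first-passage times with censoring flags.

    ``times`` are in physical units (the caller's choice); censored entries
    mark trajectories that never reached the target and are excluded from
    the mean but always reported.  ``n_excluded_start`` counts trajectories
    whose very first frame was already in the target class (tau = 0).
    """

    times: np.ndarray
    censored: np.ndarray
    unit: str = "ps"
    n_excluded_start: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.times.shape != self.censored.shape:
            raise ValueError("times and censored flags must align")
        if np.any(self.times[~self.censored] <= 0):
            raise ValueError("uncensored first-passage times must be positive")

    @property
    def uncensored(self) -> np.ndarray:
        return self.times[~self.censored]

    @property
    def censoring_fraction(self) -> float:
        return float(np.mean(self.censored)) if len(self.censored) else 0.0


@dataclass
class FPTStatistics:
    mean: float
    jackknife_se: float
    histogram: tuple  # (density, bin_edges)
    log_gaussian: dict  # mu, sigma of log10 times, KS p-value, acceptable flag
    exponential: dict  # rate, KS p-value, acceptable flag
    n: int
    censoring_fraction: float
    unit: str = "ps"


def _jackknife_se(x: np.ndarray) -> float:
    n = len(x)
    if n < 2:
        return float("nan")
    total = x.sum()
    loo = (total - x) / (n - 1)
    return float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))


def fpt_statistics(sample: FPTSample, n_bins: int = 20,
                   alpha: float = 0.01) -> FPTStatistics:
    """Summary statistics of a first-passage-time sample.

    The log-FPT Gaussian fit checks for unimodal (single-barrier) kinetics;
    the exponential fit is the Poissonian two-state diagnostic.  Both are
    scored with a Kolmogorov-Smirnov test against the fitted distribution
    and flagged unacceptable below the ``alpha`` p-value.
    """
    x = sample.uncensored
    if len(x) < 2:
        raise ValueError("need at least 2 uncensored first-passage times")
    mean = float(x.mean())
    se = _jackknife_se(x)
    hist = np.histogram(x, bins=n_bins, density=True)

    logs = np.log10(x)
    mu, sigma = float(logs.mean()), float(logs.std(ddof=1))
    if sigma > 0:
        ks_log = stats.kstest(logs, "norm", args=(mu, sigma))
        log_p = float(ks_log.pvalue)
    else:
        log_p = 1.0
    log_fit = {"mu": mu, "sigma": sigma, "ks_pvalue": log_p,
               "acceptable": log_p >= alpha}

    rate = 1.0 / mean
    ks_exp = stats.kstest(x, "expon", args=(0.0, mean))
    exp_fit = {"rate": rate, "ks_pvalue": float(ks_exp.pvalue),
               "acceptable": float(ks_exp.pvalue) >= alpha}

    return FPTStatistics(mean=mean, jackknife_se=se, histogram=hist,
                         log_gaussian=log_fit, exponential=exp_fit,
                         n=len(x), censoring_fraction=sample.censoring_fraction,
                         unit=sample.unit)


def first_passage_from_trajectories(trajs, refs, chi_c: float = CHI_C_DEFAULT,
                                    direction: str | tuple = "RC->N*",
                                    dt_frame_ps: float | None = None
                                    ) -> FPTSample:
    """First hitting times of a conformational class along trajectories.

    ``direction`` is ``"FROM->TO"`` (or a tuple), where TO is either a
    reference label, or ``"N*"`` meaning any reference with chi >= chi_c.
    Frames are classified with :func:`nstarkit.order_params.classify_nstar`
    semantics.  Trajectories whose first frame is already in the target
    class are excluded (with a warning) and counted separately; those that
    never arrive are censored at their final frame time.
    """
    if isinstance(direction, str):
        parts = direction.split("->")
        if len(parts) != 2:
            raise ValueError("direction must be 'FROM->TO'")
        target = parts[1].strip()
    else:
        target = direction[1]
    labels_of_interest = ([r.label for r in refs] if target in ("N*", "NSTAR")
                          else [target])

    times, censored = [], []
    n_excluded = 0
    for traj in trajs:
        coords = traj.coords if hasattr(traj, "coords") else np.asarray(traj)
        dt = dt_frame_ps
        if dt is None:
            dt = getattr(traj, "dt_save_ps", None)
        if dt is None:
            raise ValueError("frame spacing unknown; pass dt_frame_ps")
        if coords.shape[0] < 2:
            raise ValueError("trajectory shorter than one save stride")
        chis = np.stack([chi_fib_frames(coords, ref) for ref in refs], axis=1)
        lab = np.array([r.label for r in refs])
        in_target = np.zeros(coords.shape[0], dtype=bool)
        for j, l in enumerate(lab):
            if l in labels_of_interest:
                qualifies = chis[:, j] >= chi_c
                # target label must also be the best-matching reference
                best = np.argmax(chis, axis=1) == j
                in_target |= qualifies & (best | (target in ("N*", "NSTAR")))
        if in_target[0]:
            warnings.warn("trajectory starts inside the target class; excluded")
            n_excluded += 1
            continue
        hits = np.nonzero(in_target)[0]
        if len(hits):
            times.append(hits[0] * dt)
            censored.append(False)
        else:
            times.append((coords.shape[0] - 1) * dt)
            censored.append(True)
    return FPTSample(times=np.array(times), censored=np.array(censored),
                     unit="ps", n_excluded_start=n_excluded)
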