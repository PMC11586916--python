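"""Maximum-likelihood estimation for two-group competing-risks data.

The log-likelihood of right-censored competing-risks data for one group is

    log L(theta) = sum_i log S(T~_i)  +  sum_i sum_j 1{status_i = j} log alpha_0j(T_i)

with S the all-cause survival.  Because log S(t) = -sum_j A_j(t), the
log-likelihood is an exact SUM of per-transition terms

    l_j(theta_0j) = sum_{i: status=j} log alpha_0j(T_i) - sum_i A_0j(T~_i),

so each transition can be fitted separately.  The exponential fit is the
occurrence/exposure closed form; Gompertz and Weibull reduce to 1-D profile
likelihoods (the scale has a closed form given the shape).

Under random right-censoring the censoring distribution is treated as one
additional competing state, contributing its density for censored subjects
and its survival for the others; for exponential censoring the MLE is again
occurrence/exposure.  This censoring term is parameter-separable from theta,
so the event-intensity estimates are unchanged by it.

The constrained fit maximises log L_1(theta1) + log L_2(theta2) subject to

    max_j sup_t |alpha_0j^(1)(t) - alpha_0j^(2)(t)| = Delta.

The constraint couples the two groups only *within* a transition, so the
problem decomposes: each transition is either left at its unconstrained
optimum (if its sup-distance is below Delta) or pinned to sup-distance
exactly Delta, and at least one transition must be pinned.  Per-transition
equality subproblems are closed form for exponential pairs and solved by
SLSQP (multi-start, quadratic-penalty fallback) otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from .intensities import (
    CompetingRisksModel,
    _weibull_t_lo,
    SupDistanceResult,
    TransitionIntensity,
    default_window,
    max_pairwise_distance,
    sup_distance,
)

__all__ = [
    "CensoringModel",
    "FitResult",
    "ConstrainedFitResult",
    "log_likelihood",
    "log_likelihood_random_censoring",
    "fit_mle",
    "fit_constrained",
    "fit_constrained_single",
    "select_null_estimates",
]

CONSTRAINT_TOL = 1e-6  # max |achieved distance - Delta| on the intensity scale


# ---------------------------------------------------------------------------
# censoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CensoringModel:
    """Censoring mechanism: administrative cutoff at tau, or a parametric
    random censoring-time distribution (exponential by default).

    ``params`` follow the same conventions as the event families
    (exponential: rate; weibull: scale, shape).
    """

    kind: str  # "administrative" | "random"
    family: str = "exponential"
    params: tuple[float, ...] = ()
    tau: float = 90.0

    def __post_init__(self) -> None:
        if self.kind not in ("administrative", "random"):
            raise ValueError(f"unknown censoring kind {self.kind!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))

    @classmethod
    def administrative(cls, tau: float = 90.0) -> "CensoringModel":
        return cls(kind="administrative", tau=tau)

    @classmethod
    def exponential(cls, rate: float, tau: float = 90.0) -> "CensoringModel":
        return cls(kind="random", family="exponential", params=(rate,), tau=tau)

    @classmethod
    def parse(cls, text: str) -> "CensoringModel":
        """Parse CLI-style specs: 'administrative:90' or 'exponential:0.001'."""
        name, _, arg = text.partition(":")
        name = name.strip().lower()
        if name in ("administrative", "admin"):
            return cls.administrative(float(arg) if arg else 90.0)
        if name in ("exponential", "exp"):
            return cls.exponential(float(arg))
        raise ValueError(f"cannot parse censoring spec {text!r}")

    def _dist(self) -> TransitionIntensity:
        if self.kind != "random":
            raise ValueError("administrative censoring has no distribution")
        return TransitionIntensity(self.family, self.params)

    def log_density(self, t):
        d = self._dist()
        with np.errstate(divide="ignore"):
            return np.log(d.rate(t)) - d.cumulative(t)

    def log_survival(self, t):
        return -self._dist().cumulative(t)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n censoring times."""
        if self.kind != "random":
            raise ValueError("administrative censoring is deterministic")
        if self.family == "exponential":
            rate = self.params[0]
            if rate <= 0:
                return np.full(n, np.inf)
            return rng.exponential(1.0 / rate, size=n)
        if self.family == "weibull":
            scale, shape = self.params
            return scale * rng.weibull(shape, size=n)
        raise ValueError(f"sampling not supported for censoring family {self.family}")


# ---------------------------------------------------------------------------
# log-likelihoods
# ---------------------------------------------------------------------------


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    """Accept a GroupData-like object or a (times, status) pair."""
    if hasattr(data, "times"):
        times, status = data.times, data.status
    else:
        times, status = data
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    if times.shape != status.shape:
        raise ValueError("times and status must have equal length")
    if times.size and times.min() <= 0:
        raise ValueError("observed times must be positive")
    return times, status


def log_likelihood(m: CompetingRisksModel, data) -> float:
    """Log-likelihood under administrative censoring (survival + event terms).

    An event observed at a time where its cause intensity is zero yields
    -inf (returned, not raised).
    """
    times, status = _as_arrays(data)
    if times.size == 0:
        return 0.0
    ll = -float(np.sum(m.all_cause_cumulative(times)))
    for j, ti in enumerate(m.transitions, start=1):
        ev = times[status == j]
        if ev.size:
            with np.errstate(divide="ignore"):
                ll += float(np.sum(np.log(ti.rate(ev))))
    return ll


def log_likelihood_random_censoring(
    m: CompetingRisksModel, c: CensoringModel, data
) -> float:
    """Event-history log-likelihood plus log g(T~_i, psi) for censored rows."""
    if c.kind != "random":
        raise ValueError("censoring model must be random")
    times, status = _as_arrays(data)
    ll = log_likelihood(m, data)
    cens = times[status == 0]
    if cens.size:
        ll += float(np.sum(c.log_density(cens)))
    return ll


def censoring_log_likelihood(c: CensoringModel, data) -> float:
    """Full censoring-as-extra-state likelihood: density for censored rows,
    survival for event rows.  This is the term maximised when fitting psi."""
    times, status = _as_arrays(data)
    ll = 0.0
    cens, ev = times[status == 0], times[status > 0]
    if cens.size:
        ll += float(np.sum(c.log_density(cens)))
    if ev.size:
        ll += float(np.sum(c.log_survival(ev)))
    return ll


# ---------------------------------------------------------------------------
# per-transition fits
# ---------------------------------------------------------------------------

_ZERO_INTENSITY = TransitionIntensity("exponential", (0.0,))


@dataclass
class _TransitionFit:
    intensity: TransitionIntensity
    loglik: float  # per-transition contribution l_j
    converged: bool
    n_events: int


def _fit_exponential(times: np.ndarray, d: int, s_ev_sum: float) -> _TransitionFit:
    total = float(np.sum(times))
    if d == 0:
        return _TransitionFit(_ZERO_INTENSITY, 0.0, False, 0)
    rate = d / total
    return _TransitionFit(
        TransitionIntensity("exponential", (rate,)),
        d * np.log(rate) - d,
        True,
        d,
    )


def _fit_gompertz(times: np.ndarray, ev: np.ndarray) -> _TransitionFit:
    d = ev.size
    if d == 0:
        return _TransitionFit(_ZERO_INTENSITY, 0.0, False, 0)
    s_ev = float(np.sum(ev))
    tmax = float(np.max(times))
    bmax = min(0.5, 500.0 / tmax)

    def neg_profile(b: float) -> float:
        if b == 0.0:
            w = float(np.sum(times))
        else:
            with np.errstate(over="ignore"):
                w = float(np.sum(np.expm1(b * times))) / b
        if not np.isfinite(w) or w <= 0:
            return np.inf
        return d * np.log(w) - b * s_ev

    res = minimize_scalar(
        neg_profile, bounds=(-bmax, bmax), method="bounded", options={"xatol": 1e-8}
    )
    b = float(res.x)
    w = float(np.sum(np.expm1(b * times))) / b if b != 0.0 else float(np.sum(times))
    a = d / w
    ll = d * np.log(a) + b * s_ev - d
    at_bound = min(bmax - b, b + bmax) < 1e-6 * bmax
    return _TransitionFit(
        TransitionIntensity("gompertz", (a, b)), ll, bool(res.success) and not at_bound, d
    )


_WEIBULL_LOGK_BOUNDS = (np.log(0.05), np.log(20.0))


def _fit_weibull(times: np.ndarray, ev: np.ndarray) -> _TransitionFit:
    d = ev.size
    if d == 0:
        return _TransitionFit(_ZERO_INTENSITY, 0.0, False, 0)
    log_t = np.log(times)
    s_logev = float(np.sum(np.log(ev)))

    def neg_profile(lk: float) -> float:
        k = np.exp(lk)
        return -(d * lk - d * logsumexp(k * log_t) + (k - 1.0) * s_logev)

    res = minimize_scalar(
        neg_profile,
        bounds=_WEIBULL_LOGK_BOUNDS,
        method="bounded",
        options={"xatol": 1e-8},
    )
    lk = float(res.x)
    k = float(np.exp(lk))
    lse = float(logsumexp(k * log_t))
    scale = float(np.exp((lse - np.log(d)) / k))
    ll = d * np.log(k) - d * lse + d * np.log(d) + (k - 1.0) * s_logev - d
    at_bound = min(_WEIBULL_LOGK_BOUNDS[1] - lk, lk - _WEIBULL_LOGK_BOUNDS[0]) < 1e-8
    return _TransitionFit(
        TransitionIntensity("weibull", (scale, k)), ll, bool(res.success) and not at_bound, d
    )


def _fit_transition(family: str, times: np.ndarray, status: np.ndarray, j: int) -> _TransitionFit:
    """MLE of one cause-specific intensity from one group's data."""
    ev = times[status == j]
    if family == "exponential":
        return _fit_exponential(times, ev.size, float(np.sum(ev)))
    if family == "gompertz":
        return _fit_gompertz(times, ev)
    if family == "weibull":
        return _fit_weibull(times, ev)
    raise ValueError(f"unknown family {family!r}")


def transition_loglik(ti: TransitionIntensity, times: np.ndarray, ev: np.ndarray) -> float:
    """Per-transition log-likelihood contribution l_j(theta_0j)."""
    with np.errstate(divide="ignore"):
        ll = -float(np.sum(ti.cumulative(times)))
        if ev.size:
            ll += float(np.sum(np.log(ti.rate(ev))))
    return ll


# ---------------------------------------------------------------------------
# unconstrained MLE
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Unconstrained MLE for one group."""

    model: CompetingRisksModel
    censoring: CensoringModel | None
    loglik: float
    converged: bool
    n_events_per_state: np.ndarray
    per_transition_loglik: np.ndarray = field(default=None)  # type: ignore[assignment]


def _fit_censoring(c: CensoringModel, times: np.ndarray, status: np.ndarray) -> CensoringModel:
    """MLE psi-hat of the censoring distribution (censoring as extra state)."""
    n_cens = int(np.sum(status == 0))
    if c.family == "exponential":
        rate = n_cens / float(np.sum(times)) if times.size else 0.0
        return CensoringModel("random", "exponential", (rate,), c.tau)
    # generic: censoring is "the event", everything else is at-risk exposure
    pseudo_status = (status == 0).astype(int)
    tf = _fit_transition(c.family, times, pseudo_status, 1)
    if tf.intensity.family != c.family:  # zero censored subjects
        return CensoringModel("random", c.family, c.params, c.tau)
    return CensoringModel("random", c.family, tf.intensity.params, c.tau)


def fit_mle(
    data,
    families: list[str],
    censoring: CensoringModel | None = None,
    tau: float = 90.0,
) -> FitResult:
    """Maximum-likelihood fit of k cause-specific intensities for one group.

    ``families`` gives the parametric family per transition.  States with no
    observed events get a zero intensity and the fit is flagged
    ``converged=False``.  When ``censoring`` is a random model its parameters
    are estimated as well (occurrence/exposure for exponential censoring).
    """
    times, status = _as_arrays(data)
    k = len(families)
    if times.size and status.max() > k:
        raise ValueError(f"status {status.max()} out of range for k={k}")
    fits = [_fit_transition(f, times, status, j) for j, f in enumerate(families, 1)]
    for j, tf in enumerate(fits, 1):
        if tf.n_events == 0:
            warnings.warn(f"no events of type {j}: intensity estimated as zero", stacklevel=2)
    model = CompetingRisksModel(tuple(tf.intensity for tf in fits), tau=tau)
    loglik = float(sum(tf.loglik for tf in fits))
    cens_hat = None
    if censoring is not None and censoring.kind == "random":
        cens_hat = _fit_censoring(censoring, times, status)
        loglik += censoring_log_likelihood(cens_hat, (times, status))
    elif censoring is not None:
        cens_hat = censoring
    return FitResult(
        model=model,
        censoring=cens_hat,
        loglik=loglik,
        converged=all(tf.converged for tf in fits),
        n_events_per_state=np.array([tf.n_events for tf in fits]),
        per_transition_loglik=np.array([tf.loglik for tf in fits]),
    )


# ---------------------------------------------------------------------------
# constrained MLE
# ---------------------------------------------------------------------------


@dataclass
class _PairEquality:
    """Solution of one per-transition equality subproblem."""

    ti1: TransitionIntensity
    ti2: TransitionIntensity
    loglik: float  # l_j^(1) + l_j^(2) at the solution
    residual: float


def _exp_pair_equality(
    d1: int, r1: float, d2: int, r2: float, delta: float
) -> _PairEquality:
    """Closed-form equality-constrained fit for an exponential pair.

    Maximises d1*log(u) - r1*u + d2*log(v) - r2*v subject to |u - v| = delta.
    Writing v = u + c with c = +/-delta, the stationarity condition is the
    quadratic (r1+r2)u^2 + ((r1+r2)c - d1 - d2)u - d1*c = 0.
    """

    def pair_ll(u: float, v: float) -> float:
        ll = -r1 * u - r2 * v
        if d1 > 0:
            ll += d1 * np.log(u) if u > 0 else -np.inf
        if d2 > 0:
            ll += d2 * np.log(v) if v > 0 else -np.inf
        return ll

    r = r1 + r2
    best: tuple[float, float, float] | None = None
    for c in (delta, -delta):
        cands = [max(0.0, -c)]  # boundary
        bq = r * c - d1 - d2
        disc = bq * bq + 4.0 * r * d1 * c
        if disc >= 0:
            sq = np.sqrt(disc)
            cands += [(-bq + sq) / (2 * r), (-bq - sq) / (2 * r)]
        for u in cands:
            v = u + c
            if u < 0 or v < 0:
                continue
            ll = pair_ll(u, v)
            if np.isfinite(ll) and (best is None or ll > best[0]):
                best = (ll, u, v)
    assert best is not None
    ll, u, v = best
    return _PairEquality(
        TransitionIntensity("exponential", (u,)),
        TransitionIntensity("exponential", (v,)),
        float(ll),
        0.0,
    )


def _feasible_start(x0: np.ndarray, cons, npar: int) -> np.ndarray | None:
    """Rescale the second group's scale parameter (first transformed
    coordinate) until the pair sits on the constraint surface."""
    from scipy.optimize import brentq

    def h(c: float) -> float:
        x = x0.copy()
        x[npar] += c
        return cons(x)

    h0 = cons(x0)
    if not np.isfinite(h0):
        return None
    lo, hi = 0.0, 0.5 if h0 < 0 else -0.5
    for _ in range(12):
        if np.isfinite(h(hi)) and h(hi) * h0 < 0:
            break
        hi *= 2.0
    else:
        return None
    try:
        c = brentq(h, min(lo, hi), max(lo, hi), xtol=1e-10, maxiter=80)
    except ValueError:
        return None
    x = x0.copy()
    x[npar] += c
    return x


# --- transformed parametrisation for the general subproblem ----------------


def _to_x(ti: TransitionIntensity) -> np.ndarray:
    if ti.family == "exponential":
        return np.array([np.log(ti.params[0])])
    if ti.family == "gompertz":
        return np.array([np.log(ti.params[0]), ti.params[1]])
    return np.log(np.asarray(ti.params))  # weibull: both positive


def _from_x(family: str, x: np.ndarray) -> TransitionIntensity:
    x = np.clip(x, -700.0, 700.0)  # keep exp() finite; validation culls extremes
    if family == "exponential":
        return TransitionIntensity("exponential", (float(np.exp(x[0])),))
    if family == "gompertz":
        return TransitionIntensity("gompertz", (float(np.exp(x[0])), float(x[1])))
    return TransitionIntensity("weibull", (float(np.exp(x[0])), float(np.exp(x[1]))))


def _fallback_start(family: str, other: TransitionIntensity | None) -> TransitionIntensity:
    """Start value for a group with zero events of this type."""
    if other is not None and other.family == family:
        if family == "exponential":
            return TransitionIntensity(family, (max(other.params[0], 1e-8) * 0.5,))
        return TransitionIntensity(family, (max(other.params[0], 1e-8) * 0.5, other.params[1]))
    defaults = {"exponential": (1e-4,), "gompertz": (1e-4, 0.0), "weibull": (1e4, 1.0)}
    return TransitionIntensity(family, defaults[family])


def _general_pair_equality(
    family: str,
    times1: np.ndarray,
    ev1: np.ndarray,
    times2: np.ndarray,
    ev2: np.ndarray,
    start1: TransitionIntensity,
    start2: TransitionIntensity,
    delta: float,
    window: tuple[float, float],
    rng: np.random.Generator | None = None,
    n_jitter: int = 5,
) -> _PairEquality:
    """Equality-constrained fit of one transition pair by SLSQP.

    Started from a constraint-feasible point (the unconstrained MLEs with
    the second scale rescaled so the pair sits at distance Delta), falling
    back to the raw MLE start and jittered copies; if every SLSQP start
    fails the constraint, an exterior quadratic-penalty sequence
    (weights 1e2..1e10) is used.
    """
    npar = len(start1.params)
    lo = window[0] if family != "weibull" else max(window[0], _weibull_t_lo(window[1]))
    win = (lo, window[1])

    def unpack(x: np.ndarray) -> tuple[TransitionIntensity, TransitionIntensity]:
        return _from_x(family, x[:npar]), _from_x(family, x[npar:])

    def neg_ll(x: np.ndarray) -> float:
        try:
            t1, t2 = unpack(x)
        except (ValueError, OverflowError):
            return np.inf
        ll = transition_loglik(t1, times1, ev1) + transition_loglik(t2, times2, ev2)
        return np.inf if not np.isfinite(ll) else -ll

    def cons(x: np.ndarray, n_grid: int = 201, refine: bool = False) -> float:
        try:
            t1, t2 = unpack(x)
            return sup_distance(t1, t2, win, n_grid=n_grid, refine=refine).value - delta
        except (ValueError, OverflowError):
            return np.inf

    x0 = np.concatenate([_to_x(start1), _to_x(start2)])
    starts = [x0]
    xf = _feasible_start(x0, cons, npar)
    if xf is not None:
        starts.insert(0, xf)
    rng = rng if rng is not None else np.random.default_rng(0)

    best: tuple[float, np.ndarray] | None = None
    attempts = 0
    while best is None and attempts < 2 + n_jitter:
        if attempts < len(starts):
            s = starts[attempts]
        else:
            s = x0 + rng.normal(0.0, 0.1, size=x0.size)
        attempts += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(
                neg_ll,
                s,
                method="SLSQP",
                constraints=[{"type": "eq", "fun": cons}],
                options={"maxiter": 120, "ftol": 1e-10},
            )
        if not np.isfinite(res.fun):
            continue
        resid = abs(cons(res.x, n_grid=501, refine=True))
        if resid <= CONSTRAINT_TOL and (best is None or res.fun < best[0]):
            best = (res.fun, res.x)
    if best is None:
        # exterior quadratic-penalty fallback
        x = x0
        for w in (1e2, 1e4, 1e6, 1e8, 1e10):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = minimize(
                    lambda z: neg_ll(z) + w * cons(z) ** 2,
                    x,
                    method="Nelder-Mead",
                    options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-12},
                )
            x = res.x
        if not np.isfinite(neg_ll(x)):
            raise RuntimeError("constrained fit failed; best residual non-finite")
        best = (neg_ll(x), x)
    t1, t2 = unpack(best[1])
    return _PairEquality(t1, t2, -best[0], abs(cons(best[1], n_grid=501, refine=True)))


def _pair_equality(
    family: str,
    times1: np.ndarray,
    status1: np.ndarray,
    times2: np.ndarray,
    status2: np.ndarray,
    j: int,
    fit1: _TransitionFit,
    fit2: _TransitionFit,
    delta: float,
    window: tuple[float, float],
    rng: np.random.Generator | None = None,
) -> _PairEquality:
    ev1 = times1[status1 == j]
    ev2 = times2[status2 == j]
    if family == "exponential":
        return _exp_pair_equality(
            ev1.size, float(np.sum(times1)), ev2.size, float(np.sum(times2)), delta
        )
    s1 = fit1.intensity if fit1.intensity.family == family else _fallback_start(family, None)
    s2 = fit2.intensity if fit2.intensity.family == family else _fallback_start(family, s1)
    if fit1.intensity.family != family:
        s1 = _fallback_start(family, s2)
    return _general_pair_equality(
        family, times1, ev1, times2, ev2, s1, s2, delta, window, rng
    )


@dataclass
class ConstrainedFitResult:
    """Joint fit of both groups under max_j sup-distance = Delta."""

    model1: CompetingRisksModel
    model2: CompetingRisksModel
    joint_loglik: float
    constraint_residual: float


def fit_constrained(
    data1,
    data2,
    families: list[str],
    delta: float,
    censoring: CensoringModel | None = None,
    tau: float = 90.0,
    window: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> ConstrainedFitResult:
    """Constrained MLE: maximise log L1 + log L2 s.t. max_j sup_j = Delta.

    Censoring parameters are never part of the constraint and are therefore
    not re-estimated here.  The reported ``joint_loglik`` contains the event
    terms only (the censoring term is unaffected by the constraint).
    """
    if not delta > 0:
        raise ValueError("delta must be positive")
    times1, status1 = _as_arrays(data1)
    times2, status2 = _as_arrays(data2)
    k = len(families)
    fits1 = [_fit_transition(f, times1, status1, j) for j, f in enumerate(families, 1)]
    fits2 = [_fit_transition(f, times2, status2, j) for j, f in enumerate(families, 1)]
    if window is None:
        window = default_window(
            *(tf.intensity for tf in fits1 + fits2), tau=tau
        )
        if "weibull" in families:
            window = (max(window[0], _weibull_t_lo(tau)), window[1])

    d_j = np.array(
        [
            sup_distance(fits1[j].intensity, fits2[j].intensity, window).value
            for j in range(k)
        ]
    )
    u_ll = np.array([fits1[j].loglik + fits2[j].loglik for j in range(k)])

    eq: dict[int, _PairEquality] = {}

    def solve_eq(j: int) -> _PairEquality:
        if j not in eq:
            eq[j] = _pair_equality(
                families[j], times1, status1, times2, status2, j + 1,
                fits1[j], fits2[j], delta, window, rng,
            )
        return eq[j]

    # transitions above Delta must be pinned to the boundary
    pinned = [j for j in range(k) if d_j[j] > delta]
    for j in pinned:
        solve_eq(j)
    if not pinned and not np.any(np.isclose(d_j, delta, rtol=0, atol=CONSTRAINT_TOL)):
        # all below Delta: pin the transition with the smallest likelihood loss
        losses = [(u_ll[j] - solve_eq(j).loglik, j) for j in range(k)]
        pinned = [min(losses)[1]]

    trans1 = [tf.intensity for tf in fits1]
    trans2 = [tf.intensity for tf in fits2]
    total = 0.0
    resid = 0.0
    for j in range(k):
        if j in pinned:
            sol = eq[j]
            trans1[j], trans2[j] = sol.ti1, sol.ti2
            total += sol.loglik
            resid = max(resid, sol.residual)
        else:
            total += u_ll[j]
    m1 = CompetingRisksModel(tuple(trans1), tau=tau)
    m2 = CompetingRisksModel(tuple(trans2), tau=tau)
    achieved = max_pairwise_distance(m1, m2, window).value
    return ConstrainedFitResult(m1, m2, float(total), abs(achieved - delta))


def fit_constrained_single(
    data1,
    data2,
    families: list[str],
    j: int,
    delta_j: float,
    tau: float = 90.0,
    window: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> ConstrainedFitResult:
    """Constrained fit with the constraint on transition j only (1-based),
    sup_t |alpha_0j^(1) - alpha_0j^(2)| = Delta_j; other transitions are
    unconstrained.  Used by the per-transition (intersection-union) test."""
    times1, status1 = _as_arrays(data1)
    times2, status2 = _as_arrays(data2)
    fits1 = [_fit_transition(f, times1, status1, i) for i, f in enumerate(families, 1)]
    fits2 = [_fit_transition(f, times2, status2, i) for i, f in enumerate(families, 1)]
    if window is None:
        window = default_window(*(tf.intensity for tf in fits1 + fits2), tau=tau)
        if "weibull" in families:
            window = (max(window[0], _weibull_t_lo(tau)), window[1])
    sol = _pair_equality(
        families[j - 1], times1, status1, times2, status2, j,
        fits1[j - 1], fits2[j - 1], delta_j, window, rng,
    )
    trans1 = [tf.intensity for tf in fits1]
    trans2 = [tf.intensity for tf in fits2]
    trans1[j - 1], trans2[j - 1] = sol.ti1, sol.ti2
    total = sol.loglik + sum(
        fits1[i].loglik + fits2[i].loglik for i in range(len(families)) if i != j - 1
    )
    m1 = CompetingRisksModel(tuple(trans1), tau=tau)
    m2 = CompetingRisksModel(tuple(trans2), tau=tau)
    achieved = sup_distance(m1.transitions[j - 1], m2.transitions[j - 1], window).value
    return ConstrainedFitResult(m1, m2, float(total), abs(achieved - delta_j))


def select_null_estimates(
    unconstrained: tuple[FitResult, FitResult],
    constrained: ConstrainedFitResult,
    d_hat: float,
    delta: float,
) -> tuple[CompetingRisksModel, CompetingRisksModel]:
    """Null models used to generate bootstrap data: the unconstrained MLEs
    when d_hat >= Delta, the constrained estimates when d_hat < Delta."""
    if d_hat >= delta:
        return unconstrained[0].model, unconstrained[1].model
    return constrained.model1, constrained.model2
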