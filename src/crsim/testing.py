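"""The constrained-parametric-bootstrap similarity test.

The test certifies, at controlled Type I error, that two parametric
competing-risks models are similar: the null hypothesis is that some pair of
cause-specific intensities differs by at least Delta in sup-norm, the
alternative that all pairs differ by less than Delta.  The statistic is

    d-hat = max_j sup_t |alpha-hat_0j^(1)(t) - alpha-hat_0j^(2)(t)|

and its reference distribution is obtained by a parametric bootstrap whose
generating models are re-estimated under the boundary constraint
max_j sup_j = Delta whenever d-hat < Delta (otherwise the unconstrained fits
already lie in the null).  Small values of d-hat are evidence for
similarity: the null is rejected when the bootstrap p-value
F_B(d-hat) = mean(d* <= d-hat) falls below alpha.

Also provided: the per-transition bootstrap tests combined by the
intersection-union principle (reject only if every transition's individual
null is rejected), and the smallest rejecting threshold ("minimal Delta"),
which is well defined because rejection is monotone in Delta.

For all-exponential models with administrative or exponential censoring the
bootstrap is fully vectorised across replicates (occurrence/exposure
refits); other families use a per-replicate loop with profile-likelihood
refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .estimation import (
    CensoringModel,
    ConstrainedFitResult,
    FitResult,
    _fit_transition,
    fit_constrained,
    fit_constrained_single,
    fit_mle,
    select_null_estimates,
)
from .intensities import (
    CompetingRisksModel,
    _weibull_t_lo,
    max_pairwise_distance,
    sup_distance,
)
from .simulate import apply_censoring, latent_times_from_draws, simulate_group

__all__ = [
    "TestResult",
    "IUPResult",
    "similarity_test",
    "iup_test",
    "bootstrap_replicate",
    "minimal_delta",
]

MAX_FAILED_FRACTION = 0.05


@dataclass
class TestResult:
    """Outcome of the global similarity test."""

    d_hat: float
    delta: float
    boot_stats: np.ndarray
    q_alpha: float
    p_value: float
    reject: bool
    null_models: tuple[CompetingRisksModel, CompetingRisksModel]
    alpha: float
    B: int
    n_failed: int = 0
    d_hat_argmax: float = np.nan
    fits: tuple[FitResult, FitResult] | None = None
    constrained: ConstrainedFitResult | None = None

    def to_dict(self) -> dict:
        return {
            "d_hat": self.d_hat,
            "delta": self.delta,
            "q_alpha": self.q_alpha,
            "p_value": self.p_value,
            "reject": bool(self.reject),
            "alpha": self.alpha,
            "B": self.B,
            "n_failed": self.n_failed,
            "d_hat_argmax": self.d_hat_argmax,
        }


@dataclass
class IUPResult:
    """Per-transition tests combined by the intersection-union principle."""

    per_transition: list[TestResult]
    p_value: float
    reject: bool

    def to_dict(self) -> dict:
        return {
            "p_value": self.p_value,
            "reject": bool(self.reject),
            "per_transition": [t.to_dict() for t in self.per_transition],
        }


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _window_for(families: list[str], tau: float) -> tuple[float, float]:
    """Window used for every sup-norm in one test run.  A positive lower
    endpoint (one time unit) is used whenever Weibull transitions are
    involved, since bootstrap refits can land at shape < 1 (unbounded at
    t = 0) and sub-day evaluation points would let that boundary artefact
    dominate the statistic."""
    lo = _weibull_t_lo(tau) if "weibull" in families else 0.0
    return (lo, tau)


def _boot_censoring(
    fit: FitResult, censoring: CensoringModel | None, tau: float
) -> CensoringModel:
    if censoring is None or censoring.kind == "administrative":
        return CensoringModel.administrative(tau)
    assert fit.censoring is not None
    return fit.censoring


def _fit_theta(times, status, families, tau):
    fits = [_fit_transition(f, times, status, j) for j, f in enumerate(families, 1)]
    return CompetingRisksModel(tuple(tf.intensity for tf in fits), tau=tau)


def _quantile(d_stars: np.ndarray, alpha: float) -> float:
    """ceil(alpha*B)-th smallest bootstrap statistic."""
    b = d_stars.size
    idx = max(ceil(alpha * b), 1) - 1
    return float(np.sort(d_stars)[idx])


def _is_fast_exponential(families: list[str], *cens: CensoringModel) -> bool:
    if any(f != "exponential" for f in families):
        return False
    return all(
        c.kind == "administrative" or c.family == "exponential" for c in cens
    )


# ---------------------------------------------------------------------------
# vectorised exponential bootstrap
# ---------------------------------------------------------------------------


def _exp_group_rates(
    rates: np.ndarray,
    cens: CensoringModel,
    n: int,
    B: int,
    rng: np.random.Generator,
    draws: tuple | None = None,
) -> np.ndarray:
    """(B, k) occurrence/exposure rate estimates from B bootstrap samples of
    one all-exponential group.  ``draws`` optionally supplies pre-drawn unit
    exponentials / uniforms (event clock, cause, censoring clock) so that
    different null models can be simulated from coupled randomness."""
    k = rates.size
    lam = float(rates.sum())
    if draws is None:
        e = rng.exponential(size=(B, n))
        u = rng.random(size=(B, n))
        ec = rng.exponential(size=(B, n)) if cens.kind == "random" else None
    else:
        e, u, ec = draws
    t = e / lam if lam > 0 else np.full((B, n), np.inf)
    cp = np.cumsum(rates) / lam if lam > 0 else np.ones(k)
    cause = np.searchsorted(cp, u, side="right") + 1
    if cens.kind == "administrative":
        obs = np.minimum(t, cens.tau)
        event = t <= cens.tau
    else:
        psi = cens.params[0]
        c = ec / psi if psi > 0 else np.full((B, n), np.inf)
        obs = np.minimum(t, c)
        event = t <= c
    status = np.where(event, cause, 0)
    exposure = obs.sum(axis=1)
    est = np.empty((B, k))
    for j in range(1, k + 1):
        est[:, j - 1] = (status == j).sum(axis=1) / exposure
    return est


def _exp_bootstrap_dstars(
    null1: CompetingRisksModel,
    null2: CompetingRisksModel,
    cens1: CensoringModel,
    cens2: CensoringModel,
    n1: int,
    n2: int,
    B: int,
    rng: np.random.Generator,
    draws: tuple | None = None,
) -> np.ndarray:
    """All B bootstrap statistics (matrix of per-transition |rate diffs|
    maxima) for the all-exponential fast path."""
    r1 = np.array([ti.params[0] for ti in null1.transitions])
    r2 = np.array([ti.params[0] for ti in null2.transitions])
    est1 = _exp_group_rates(r1, cens1, n1, B, rng, None if draws is None else draws[0])
    est2 = _exp_group_rates(r2, cens2, n2, B, rng, None if draws is None else draws[1])
    return np.abs(est1 - est2)  # (B, k); caller takes max or a column


# ---------------------------------------------------------------------------
# generic bootstrap
# ---------------------------------------------------------------------------


def bootstrap_replicate(
    null_models: tuple[CompetingRisksModel, CompetingRisksModel],
    n1: int,
    n2: int,
    families: list[str],
    censoring_models: tuple[CensoringModel, CensoringModel],
    rng: np.random.Generator,
    window: tuple[float, float] | None = None,
) -> float:
    """One bootstrap replicate: simulate a two-group dataset from the null
    models, refit without constraint, return d* (max sup-distance)."""
    tau = null_models[0].tau
    if window is None:
        window = _window_for(families, tau)
    g1 = simulate_group(null_models[0], n1, censoring_models[0], rng)
    g2 = simulate_group(null_models[1], n2, censoring_models[1], rng)
    m1 = _fit_theta(g1.times, g1.status, families, tau)
    m2 = _fit_theta(g2.times, g2.status, families, tau)
    return max_pairwise_distance(m1, m2, window).value


def _generic_bootstrap_dstars(
    null1, null2, cens1, cens2, n1, n2, families, B, rng, window
) -> tuple[np.ndarray, int]:
    """(B', k) per-transition bootstrap distances via the per-replicate
    loop; replicates with non-finite statistics are dropped."""
    tau = null1.tau
    k = len(families)
    out = np.empty((B, k))
    ok = np.ones(B, dtype=bool)
    for b in range(B):
        try:
            g1 = simulate_group(null1, n1, cens1, rng)
            g2 = simulate_group(null2, n2, cens2, rng)
            m1 = _fit_theta(g1.times, g1.status, families, tau)
            m2 = _fit_theta(g2.times, g2.status, families, tau)
            for j in range(k):
                out[b, j] = sup_distance(
                    m1.transitions[j], m2.transitions[j], window
                ).value
            if not np.all(np.isfinite(out[b])):
                ok[b] = False
        except (ValueError, RuntimeError):
            ok[b] = False
    n_failed = int(B - ok.sum())
    if n_failed > MAX_FAILED_FRACTION * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap replicates failed")
    return out[ok], n_failed


def _bootstrap_dstars(
    null1, null2, cens1, cens2, n1, n2, families, B, rng, window
) -> tuple[np.ndarray, int]:
    if _is_fast_exponential(families, cens1, cens2):
        return (
            _exp_bootstrap_dstars(null1, null2, cens1, cens2, n1, n2, B, rng),
            0,
        )
    return _generic_bootstrap_dstars(
        null1, null2, cens1, cens2, n1, n2, families, B, rng, window
    )


# ---------------------------------------------------------------------------
# the tests
# ---------------------------------------------------------------------------


def similarity_test(
    data1,
    data2,
    families: list[str],
    delta: float,
    B: int = 250,
    alpha: float = 0.05,
    censoring: CensoringModel | None = None,
    rng: np.random.Generator | int | None = None,
    tau: float = 90.0,
    keep_fits: bool = False,
) -> TestResult:
    """Global similarity test for two-group competing-risks data.

    Parameters mirror the procedure: ``delta`` is the similarity threshold,
    ``B`` the number of bootstrap replicates, ``alpha`` the level,
    ``censoring`` the censoring mechanism assumed for estimation and
    bootstrap regeneration (administrative at tau when None).
    """
    if not delta > 0:
        raise ValueError("delta must be positive")
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    rng = np.random.default_rng(rng)
    window = _window_for(families, tau)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit1 = fit_mle(data1, families, censoring, tau)
        fit2 = fit_mle(data2, families, censoring, tau)
    dres = max_pairwise_distance(fit1.model, fit2.model, window)
    d_hat = dres.value

    constrained = None
    if d_hat < delta:
        constrained = fit_constrained(
            data1, data2, families, delta, censoring, tau, window, rng
        )
    null1, null2 = select_null_estimates(
        (fit1, fit2),
        constrained if constrained is not None else ConstrainedFitResult(
            fit1.model, fit2.model, np.nan, np.nan
        ),
        d_hat,
        delta,
    )
    cens1 = _boot_censoring(fit1, censoring, tau)
    cens2 = _boot_censoring(fit2, censoring, tau)
    n1, n2 = _n_of(data1), _n_of(data2)
    per, n_failed = _bootstrap_dstars(
        null1, null2, cens1, cens2, n1, n2, families, B, rng, window
    )
    d_stars = per.max(axis=1)
    p = float(np.mean(d_stars <= d_hat))
    return TestResult(
        d_hat=float(d_hat),
        delta=delta,
        boot_stats=d_stars,
        q_alpha=_quantile(d_stars, alpha),
        p_value=p,
        reject=p < alpha,
        null_models=(null1, null2),
        alpha=alpha,
        B=int(d_stars.size),
        n_failed=n_failed,
        d_hat_argmax=dres.argmax_t,
        fits=(fit1, fit2) if keep_fits else None,
        constrained=constrained,
    )


def _n_of(data) -> int:
    if hasattr(data, "times"):
        return int(np.asarray(data.times).size)
    return int(np.asarray(data[0]).size)


def iup_test(
    data1,
    data2,
    families: list[str],
    deltas,
    B: int = 250,
    alpha: float = 0.05,
    censoring: CensoringModel | None = None,
    rng: np.random.Generator | int | None = None,
    tau: float = 90.0,
) -> IUPResult:
    """Per-transition similarity tests combined by intersection-union.

    Each transition j is tested individually (statistic sup_t |difference of
    the j-th intensities|, bootstrap generated from models where only
    transition j is pinned to its threshold Delta_j); the global null is
    rejected only when every individual test rejects, and the combined
    p-value is the maximum of the individual ones.
    """
    rng = np.random.default_rng(rng)
    k = len(families)
    deltas = np.broadcast_to(np.asarray(deltas, dtype=float), (k,))
    window = _window_for(families, tau)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit1 = fit_mle(data1, families, censoring, tau)
        fit2 = fit_mle(data2, families, censoring, tau)
    cens1 = _boot_censoring(fit1, censoring, tau)
    cens2 = _boot_censoring(fit2, censoring, tau)
    n1, n2 = _n_of(data1), _n_of(data2)

    results: list[TestResult] = []
    for j in range(1, k + 1):
        dres = sup_distance(
            fit1.model.transitions[j - 1], fit2.model.transitions[j - 1], window
        )
        d_hat_j = dres.value
        if d_hat_j < deltas[j - 1]:
            con = fit_constrained_single(
                data1, data2, families, j, deltas[j - 1], tau, window, rng
            )
            null1, null2 = con.model1, con.model2
        else:
            con = None
            null1, null2 = fit1.model, fit2.model
        per, n_failed = _bootstrap_dstars(
            null1, null2, cens1, cens2, n1, n2, families, B, rng, window
        )
        d_stars_j = per[:, j - 1]
        p = float(np.mean(d_stars_j <= d_hat_j))
        results.append(
            TestResult(
                d_hat=float(d_hat_j),
                delta=float(deltas[j - 1]),
                boot_stats=d_stars_j,
                q_alpha=_quantile(d_stars_j, alpha),
                p_value=p,
                reject=p < alpha,
                null_models=(null1, null2),
                alpha=alpha,
                B=int(d_stars_j.size),
                n_failed=n_failed,
                d_hat_argmax=dres.argmax_t,
                constrained=con,
            )
        )
    p_max = max(t.p_value for t in results)
    return IUPResult(
        per_transition=results,
        p_value=p_max,
        reject=all(t.reject for t in results),
    )


# ---------------------------------------------------------------------------
# minimal Delta
# ---------------------------------------------------------------------------


def _coupled_draws(n1, n2, B, random1, random2, rng):
    """Pre-draw the bootstrap randomness (event clocks, cause uniforms,
    censoring clocks) once, to be reused for every Delta on the grid."""

    def group(n, random_cens):
        e = rng.exponential(size=(B, n))
        u = rng.random(size=(B, n))
        ec = rng.exponential(size=(B, n)) if random_cens else None
        return (e, u, ec)

    return group(n1, random1), group(n2, random2)


def minimal_delta(
    data1,
    data2,
    families: list[str],
    alpha: float = 0.05,
    B: int = 250,
    delta_grid=None,
    censoring: CensoringModel | None = None,
    rng: np.random.Generator | int | None = None,
    tau: float = 90.0,
) -> tuple[float, dict]:
    """Smallest threshold on the grid at which similarity can be claimed.

    Rejection is monotone in Delta, and the bootstrap randomness (event
    clocks, cause uniforms, censoring clocks) is drawn once and shared
    across all grid values, so the scan is coherent: once a grid point
    rejects, all larger ones do as well.  Returns (Delta-hat, details) with
    Delta-hat = +inf when no grid value rejects; details maps each examined
    Delta to its p-value.
    """
    rng = np.random.default_rng(rng)
    if delta_grid is None:
        raise ValueError("delta_grid is required")
    delta_grid = np.sort(np.asarray(delta_grid, dtype=float))
    if delta_grid.size == 0 or delta_grid[0] <= 0:
        raise ValueError("delta_grid must be positive and non-empty")
    window = _window_for(families, tau)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit1 = fit_mle(data1, families, censoring, tau)
        fit2 = fit_mle(data2, families, censoring, tau)
    d_hat = max_pairwise_distance(fit1.model, fit2.model, window).value
    cens1 = _boot_censoring(fit1, censoring, tau)
    cens2 = _boot_censoring(fit2, censoring, tau)
    n1, n2 = _n_of(data1), _n_of(data2)
    fast = _is_fast_exponential(families, cens1, cens2)
    draws = _coupled_draws(
        n1, n2, B, cens1.kind == "random", cens2.kind == "random", rng
    )

    p_by_delta: dict[float, float] = {}
    for delta in delta_grid:
        if d_hat < delta:
            con = fit_constrained(
                data1, data2, families, float(delta), censoring, tau, window, rng
            )
            null1, null2 = con.model1, con.model2
        else:
            null1, null2 = fit1.model, fit2.model
        if fast:
            per = _exp_bootstrap_dstars(
                null1, null2, cens1, cens2, n1, n2, B, rng, draws
            )
            d_stars = per.max(axis=1)
        else:
            d_stars = _coupled_generic_dstars(
                null1, null2, cens1, cens2, families, window, draws
            )
        p = float(np.mean(d_stars <= d_hat))
        p_by_delta[float(delta)] = p
        if p < alpha:
            return float(delta), {"d_hat": d_hat, "p_values": p_by_delta}
    return np.inf, {"d_hat": d_hat, "p_values": p_by_delta}


def _coupled_generic_dstars(null1, null2, cens1, cens2, families, window, draws):
    tau = null1.tau
    (e1, u1, ec1), (e2, u2, ec2) = draws
    B = e1.shape[0]
    out = np.empty(B)
    for b in range(B):
        groups = []
        for m, cens, e, u, ec in (
            (null1, cens1, e1, u1, ec1),
            (null2, cens2, e2, u2, ec2),
        ):
            t, cause = latent_times_from_draws(m, e[b], u[b])
            if cens.kind == "administrative":
                g = apply_censoring(t, cause, cens)
            else:
                psi = cens.params[0]
                c = ec[b] / psi if psi > 0 else np.full(t.shape, np.inf)
                obs = np.minimum(t, c)
                status = np.where(t <= c, cause, 0)
                from .io import GroupData

                g = GroupData(obs, status)
            groups.append(g)
        m1 = _fit_theta(groups[0].times, groups[0].status, families, tau)
        m2 = _fit_theta(groups[1].times, groups[1].status, families, tau)
        out[b] = max_pairwise_distance(m1, m2, window).value
    return out
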