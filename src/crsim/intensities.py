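"""Parametric cause-specific transition intensities and sup-norm distances.

A competing-risks model for one group is a set of k cause-specific hazards
(transition intensities) alpha_0j(t), one per target state j = 1..k, observed
over a window [0, tau].  Three parametric families are supported:

``exponential``
    constant intensity ``rate`` (one parameter).
``gompertz``
    ``scale * exp(shape * t)`` with scale > 0 and unrestricted shape; a
    negative shape gives a defective ("cure") event-time distribution with
    total cumulative hazard scale/|shape|.
``weibull``
    ``(shape/scale) * (t/scale)**(shape-1)`` with scale > 0 and shape > 0;
    for shape < 1 the intensity diverges at t = 0.

Distances between two models are measured by the sup-norm of the pairwise
intensity differences over the observation window; the test statistic of the
similarity test is the maximum of these over the k transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "FAMILIES",
    "TransitionIntensity",
    "CompetingRisksModel",
    "SupDistanceResult",
    "sup_distance",
    "max_pairwise_distance",
    "default_window",
]

#: family name -> number of parameters
FAMILIES: dict[str, int] = {"exponential": 1, "gompertz": 2, "weibull": 2}

# lower endpoint used when a Weibull shape < 1 makes the intensity
# unbounded at t = 0: one time unit (times are in days throughout), capped
# at a tenth of the window for short studies.  Sub-day evaluation points
# would let boundary artefacts of small-sample Weibull fits dominate the
# sup-norm in a region where no events are observable.
def _weibull_t_lo(tau: float) -> float:
    return min(1.0, 0.1 * tau)


class ParameterError(ValueError):
    """Raised for parameter vectors outside the family's domain."""


class UnboundedIntensityError(ValueError):
    """Raised when a sup-distance window touches a singular point (Weibull
    shape < 1 at t = 0).  Callers should move the lower endpoint above 0."""


def _validate(family: str, params: tuple[float, ...]) -> None:
    if family not in FAMILIES:
        raise ParameterError(f"unknown family {family!r}; choose from {sorted(FAMILIES)}")
    if len(params) != FAMILIES[family]:
        raise ParameterError(
            f"{family} takes {FAMILIES[family]} parameter(s), got {len(params)}"
        )
    if not all(np.isfinite(params)):
        raise ParameterError(f"non-finite parameters {params}")
    if family == "exponential":
        if params[0] < 0:
            raise ParameterError(f"exponential rate must be >= 0, got {params[0]}")
    elif family == "gompertz":
        if params[0] < 0:
            raise ParameterError(f"gompertz scale must be >= 0, got {params[0]}")
    elif family == "weibull":
        if params[0] <= 0 or params[1] <= 0:
            raise ParameterError(
                f"weibull requires scale > 0 and shape > 0, got {params}"
            )


@dataclass(frozen=True)
class TransitionIntensity:
    """One parametric cause-specific intensity alpha_0j(t, theta).

    Rate 0 (exponential) / scale 0 (gompertz) are admitted as boundary cases
    so that zero-event maximum-likelihood fits have a representation; their
    intensity is identically zero.
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        _validate(self.family, self.params)

    # -- evaluation ---------------------------------------------------------

    def rate(self, t):
        """Intensity alpha(t); vectorised over t >= 0.

        Weibull with shape < 1 returns +inf at t = 0 (flagged, not silent:
        downstream sup-norm code refuses windows containing the singularity).
        """
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("negative time")
        if self.family == "exponential":
            return np.broadcast_to(self.params[0], t.shape).copy()
        if self.family == "gompertz":
            a, b = self.params
            return a * np.exp(b * t)
        s, k = self.params
        with np.errstate(divide="ignore", over="ignore"):
            return (k / s) * (t / s) ** (k - 1.0)

    def cumulative(self, t):
        """Cumulative intensity A(t) = int_0^t alpha(u) du (closed form)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("negative time")
        if self.family == "exponential":
            return self.params[0] * t
        if self.family == "gompertz":
            a, b = self.params
            if b == 0.0:
                return a * t
            # a/b*(e^{bt}-1); expm1 keeps the b -> 0 limit accurate
            return a * np.expm1(b * t) / b
        s, k = self.params
        with np.errstate(over="ignore"):
            return (t / s) ** k

    @property
    def total_mass(self) -> float:
        """A(inf): finite only for Gompertz with negative shape (cure)."""
        if self.family == "gompertz":
            a, b = self.params
            if b < 0:
                return a / (-b)
            return np.inf if a > 0 else 0.0
        if self.family == "exponential":
            return np.inf if self.params[0] > 0 else 0.0
        return np.inf

    @property
    def unbounded_at_zero(self) -> bool:
        return self.family == "weibull" and self.params[1] < 1.0


@dataclass(frozen=True)
class CompetingRisksModel:
    """k cause-specific intensities for one group plus the window end tau."""

    transitions: tuple[TransitionIntensity, ...]
    tau: float = 90.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "transitions", tuple(self.transitions))
        if len(self.transitions) < 1:
            raise ValueError("need at least one transition")
        if not self.tau > 0:
            raise ValueError("tau must be positive")

    @property
    def k(self) -> int:
        return len(self.transitions)

    @property
    def theta(self) -> np.ndarray:
        """Concatenated parameter vector (dimension p = sum of p_j)."""
        return np.concatenate([np.asarray(ti.params) for ti in self.transitions])

    def all_cause_rate(self, t):
        return sum(ti.rate(t) for ti in self.transitions)

    def all_cause_cumulative(self, t):
        return sum(ti.cumulative(t) for ti in self.transitions)

    def survival(self, t):
        """All-cause survival S(t) = exp(-sum_j A_j(t))."""
        return np.exp(-self.all_cause_cumulative(t))


@dataclass
class SupDistanceResult:
    """Sup-norm distance; for model-level results per-transition parts too."""

    value: float
    argmax_t: float
    per_transition: list["SupDistanceResult"] = field(default_factory=list)


def default_window(
    *objs, tau: float | None = None
) -> tuple[float, float]:
    """Observation window [t_lo, t_hi] for sup-norm evaluation.

    t_hi is tau (taken from the first model if not given); t_lo is 0 unless
    some Weibull shape < 1 is present, in which case t_lo is one time unit
    (see ``_weibull_t_lo``), keeping the singular point out of the window.
    """
    intensities: list[TransitionIntensity] = []
    for o in objs:
        if isinstance(o, CompetingRisksModel):
            intensities.extend(o.transitions)
            if tau is None:
                tau = o.tau
        elif isinstance(o, TransitionIntensity):
            intensities.append(o)
    if tau is None:
        raise ValueError("tau not determinable")
    lo = 0.0
    if any(ti.unbounded_at_zero for ti in intensities):
        lo = _weibull_t_lo(float(tau))
    return (lo, float(tau))


def sup_distance(
    a: TransitionIntensity,
    b: TransitionIntensity,
    window: tuple[float, float],
    n_grid: int = 501,
    refine: bool = True,
) -> SupDistanceResult:
    """sup over the window of |a(t) - b(t)|, with the attained argmax.

    Both intensities are smooth on the window, and their difference has few
    local extrema for these families, so a moderately dense uniform grid
    followed by bounded scalar refinement around the best grid point matches
    a brute-force 1e6-point grid to ~1e-9.
    """
    lo, hi = float(window[0]), float(window[1])
    if not lo < hi:
        raise ValueError("window must satisfy t_lo < t_hi")
    if lo <= 0.0 and (a.unbounded_at_zero or b.unbounded_at_zero):
        raise UnboundedIntensityError(
            "Weibull shape < 1 is unbounded at t = 0; use a window with t_lo > 0"
        )
    # constant-vs-constant difference: exact without any grid
    if a.family == "exponential" and b.family == "exponential":
        return SupDistanceResult(abs(a.params[0] - b.params[0]), lo)

    t = np.linspace(lo, hi, n_grid)
    diff = np.abs(a.rate(t) - b.rate(t))
    i = int(np.argmax(diff))
    cands = [(diff[i], t[i])]
    if refine:
        lo_b = t[max(i - 1, 0)]
        hi_b = t[min(i + 1, n_grid - 1)]
        res = minimize_scalar(
            lambda x: -abs(float(a.rate(x) - b.rate(x))),
            bounds=(lo_b, hi_b),
            method="bounded",
            options={"xatol": 1e-9 * (hi - lo)},
        )
        if np.isfinite(res.fun):
            cands.append((-res.fun, float(res.x)))
    val, arg = max(cands, key=lambda c: c[0])
    return SupDistanceResult(float(val), float(arg))


def max_pairwise_distance(
    m1: CompetingRisksModel,
    m2: CompetingRisksModel,
    window: tuple[float, float] | None = None,
) -> SupDistanceResult:
    """max over transitions j of sup_t |alpha_0j^(1)(t) - alpha_0j^(2)(t)|.

    This is the test statistic d of the similarity test when evaluated at
    fitted models.
    """
    if m1.k != m2.k:
        raise ValueError(f"models have different numbers of states: {m1.k} != {m2.k}")
    if window is None:
        window = default_window(m1, m2)
    per = [sup_distance(a, b, window) for a, b in zip(m1.transitions, m2.transitions)]
    best = max(range(m1.k), key=lambda j: per[j].value)
    return SupDistanceResult(per[best].value, per[best].argmax_t, per)
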