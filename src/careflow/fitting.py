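"""Parametric duration models chosen by sum-of-squared-errors.

Queue and activity times are modelled by fitting a small set of
candidate families to the observed durations and keeping the family
whose density tracks the empirical histogram most closely:

    SSE(family) = sum over bins of (empirical density - fitted pdf at bin centre)^2

with equal-width, density-normalised bins spanning [min, max] of the
samples.  Parameters are estimated by maximum likelihood per family
(method-of-moments fallback where the optimiser fails).

Because gamma and Weibull both nest the exponential, on exponential
data all three MLE fits converge to the same density and their SSE
differences are pure histogram noise; a strict argmin then picks among
them by coin toss.  The SSE of a correctly specified fit fluctuates at
the multinomial noise floor of the density histogram, approximately
1/(n * w^2) for n samples and bin width w, so a family with fewer
parameters is preferred whenever its SSE is within ``parsimony_mult``
noise floors of the minimum.  Families that genuinely misfit sit many
noise floors above the minimum and are never promoted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, FitError, SamplingError

#: family name -> (parameter names, arity)
FAMILIES: dict[str, tuple[str, ...]] = {
    "exponential": ("scale",),
    "gamma": ("shape", "scale"),
    "lognormal": ("sigma", "scale"),
    "normal": ("mean", "sd"),
    "uniform": ("loc", "width"),
    "weibull": ("shape", "scale"),
}

DEFAULT_CANDIDATES = tuple(sorted(FAMILIES))

#: Noise-floor multiples within which a lower-arity family is preferred.
DEFAULT_PARSIMONY_MULT = 1.0

#: Attempts at rejecting negative draws before clamping to zero.
_MAX_REJECTS = 1000


@dataclass(frozen=True)
class FittedDistribution:
    """One fitted duration model: family name, parameter vector, fit SSE."""

    family: str
    params: tuple[float, ...]
    sse: float = 0.0
    n_samples: int = 0

    def __post_init__(self):
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))

    def validate(self) -> str | None:
        """Return a violation message, or None if the entry is usable."""
        if self.family not in FAMILIES:
            return f"unknown family {self.family!r}"
        arity = len(FAMILIES[self.family])
        if len(self.params) != arity:
            return (
                f"{self.family} expects {arity} parameters, got {len(self.params)}"
            )
        if not all(math.isfinite(p) for p in self.params):
            return f"{self.family} has non-finite parameters {self.params}"
        if self.family == "normal":
            if self.params[1] < 0:
                return f"normal sd must be >= 0, got {self.params[1]}"
        elif self.family == "uniform":
            if self.params[1] < 0:
                return f"uniform width must be >= 0, got {self.params[1]}"
        else:
            scale = self.params[-1]
            if scale < 0:
                return f"{self.family} scale must be >= 0, got {scale}"
            if self.family in ("gamma", "weibull") and self.params[0] <= 0:
                return f"{self.family} shape must be > 0, got {self.params[0]}"
            if self.family == "lognormal" and self.params[0] < 0:
                return f"lognormal sigma must be >= 0, got {self.params[0]}"
        if self.sse < 0:
            return f"sse must be >= 0, got {self.sse}"
        return None

    def mean(self) -> float:
        """Closed-form mean of the fitted family."""
        f, p = self.family, self.params
        if f == "exponential":
            return p[0]
        if f == "gamma":
            return p[0] * p[1]
        if f == "lognormal":
            return p[1] * math.exp(p[0] ** 2 / 2.0)
        if f == "normal":
            return p[0]
        if f == "uniform":
            return p[0] + p[1] / 2.0
        if f == "weibull":
            return p[1] * math.gamma(1.0 + 1.0 / p[0])
        raise SamplingError(f"unknown family {f!r}")


def _frozen(family: str, params: tuple[float, ...]):
    """scipy frozen distribution for pdf evaluation."""
    if family == "exponential":
        return stats.expon(scale=params[0])
    if family == "gamma":
        return stats.gamma(params[0], scale=params[1])
    if family == "lognormal":
        return stats.lognorm(params[0], scale=params[1])
    if family == "normal":
        return stats.norm(params[0], params[1])
    if family == "uniform":
        return stats.uniform(params[0], params[1])
    if family == "weibull":
        return stats.weibull_min(params[0], scale=params[1])
    raise SamplingError(f"unknown family {family!r}")


def _moments_params(family: str, x: np.ndarray) -> tuple[float, ...]:
    """Method-of-moments parameters, used when MLE is unavailable."""
    m = float(np.mean(x))
    v = float(np.var(x))
    if family == "exponential":
        return (m,)
    if family == "gamma":
        return (m * m / v, v / m) if v > 0 else (1.0, m)
    if family == "lognormal":
        # moments of lognormal: m = s*exp(sig^2/2), v = m^2 (exp(sig^2)-1)
        if m <= 0 or v <= 0:
            return (1.0, max(m, 1e-12))
        sig2 = math.log(1.0 + v / (m * m))
        return (math.sqrt(sig2), m * math.exp(-sig2 / 2.0))
    if family == "normal":
        return (m, math.sqrt(v))
    if family == "uniform":
        return (float(np.min(x)), float(np.ptp(x)))
    if family == "weibull":
        return (1.0, m)
    raise FitError(f"unknown family {family!r}")


def _mle_params(family: str, x: np.ndarray) -> tuple[float, ...]:
    """Maximum-likelihood parameters with location pinned at 0 for
    non-negative families; falls back to method of moments on failure."""
    try:
        if family == "exponential":
            return (float(np.mean(x)),)
        if family == "gamma":
            a, _loc, scale = stats.gamma.fit(x, floc=0)
            return (float(a), float(scale))
        if family == "lognormal":
            pos = x[x > 0]
            if pos.size < 2:
                raise ValueError("lognormal needs positive samples")
            logs = np.log(pos)
            return (max(float(np.std(logs)), 1e-12), float(np.exp(np.mean(logs))))
        if family == "normal":
            return (float(np.mean(x)), float(np.std(x)))
        if family == "uniform":
            return (float(np.min(x)), float(np.ptp(x)))
        if family == "weibull":
            c, _loc, scale = stats.weibull_min.fit(x, floc=0)
            return (float(c), float(scale))
        raise FitError(f"unknown family {family!r}")
    except FitError:
        raise
    except Exception:
        return _moments_params(family, x)


def histogram_density(
    samples: np.ndarray, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width density histogram over [min, max]; returns (density, centres)."""
    density, edges = np.histogram(samples, bins=n_bins, density=True)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return density, centres


def sse_against_histogram(
    family: str,
    params: tuple[float, ...],
    density: np.ndarray,
    centres: np.ndarray,
) -> float:
    pdf = _frozen(family, params).pdf(centres)
    pdf = np.where(np.isfinite(pdf), pdf, 0.0)
    return float(np.sum((density - pdf) ** 2))


def fit_distribution(
    samples,
    candidates=DEFAULT_CANDIDATES,
    n_bins: int = 100,
    parsimony_mult: float = DEFAULT_PARSIMONY_MULT,
) -> FittedDistribution:
    """Fit every candidate family and keep the lowest-SSE fit.

    Parameters
    ----------
    samples
        Non-negative, finite durations (minutes); at least 30 required.
    candidates
        Subset of :data:`FAMILIES` to scan.
    n_bins
        Number of equal-width histogram bins.
    parsimony_mult
        A family with fewer parameters beats one with more when its SSE
        is within ``parsimony_mult`` histogram noise floors (1/(n*w^2))
        of the minimum; 0 gives a strict argmin.  Exact ties are always
        broken by arity, then family name.

    Raises
    ------
    FitError
        Fewer than 30 samples (fall back to the empirical distribution).
    DegenerateDataError
        All samples identical (no variance to fit).
    ValueError
        Negative, non-finite samples, or an unknown candidate family.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must all be finite")
    if np.any(x < 0):
        raise ValueError("samples must all be >= 0")
    if x.size < 30:
        raise FitError(
            f"need >= 30 samples to fit a parametric family (got {x.size}); "
            "fall back to the empirical distribution"
        )
    if np.ptp(x) == 0:
        raise DegenerateDataError(
            f"all {x.size} samples equal {x[0]}; zero-variance data"
        )
    unknown = sorted(set(candidates) - set(FAMILIES))
    if unknown:
        raise ValueError(f"unknown candidate families: {unknown}")
    if not candidates:
        raise ValueError("candidate set is empty")

    density, centres = histogram_density(x, n_bins)
    fits: list[FittedDistribution] = []
    for family in sorted(set(candidates)):
        params = _mle_params(family, x)
        sse = sse_against_histogram(family, params, density, centres)
        fits.append(FittedDistribution(family, params, sse, int(x.size)))

    best_sse = min(f.sse for f in fits)
    bin_width = (float(np.max(x)) - float(np.min(x))) / n_bins
    noise_floor = 1.0 / (x.size * bin_width**2)
    # Among fits within the parsimony band: fewest parameters, then SSE,
    # then name.  With parsimony_mult=0 the band is exact ties only.
    eligible = [f for f in fits if f.sse <= best_sse + parsimony_mult * noise_floor]
    return min(eligible, key=lambda f: (len(f.params), f.sse, f.family))


def sample_duration(dist: FittedDistribution, rng: np.random.Generator) -> float:
    """One non-negative draw (minutes) from a fitted distribution.

    Negative draws (possible under the normal family) are rejected and
    redrawn up to 1000 times, then clamped to 0.
    """
    msg = dist.validate()
    if msg is not None:
        raise SamplingError(msg)
    f, p = dist.family, dist.params
    for _ in range(_MAX_REJECTS):
        if f == "exponential":
            value = rng.exponential(p[0]) if p[0] > 0 else 0.0
        elif f == "gamma":
            value = rng.standard_gamma(p[0]) * p[1]
        elif f == "lognormal":
            value = rng.lognormal(math.log(p[1]) if p[1] > 0 else -math.inf, p[0])
        elif f == "normal":
            value = rng.normal(p[0], p[1])
        elif f == "uniform":
            value = p[0] + p[1] * rng.random()
        else:  # weibull
            value = p[1] * rng.weibull(p[0])
        if value >= 0:
            return float(value)
    return 0.0
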