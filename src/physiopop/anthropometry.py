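"""Phase 1: joint simulation of age, height, body mass and cardiac output.

Heights are normal and ln body masses normal, each with a quadratic-in-age
location; the pair is drawn from a bivariate normal via the standard
marginal/conditional factorisation

    X ~ N(mu_X, sigma_X^2)
    Y | X ~ N(mu_Y + (sigma_Y/sigma_X) * rho * (X - mu_X), (1 - rho^2) * sigma_Y^2)

with each draw truncated to an interval: by default location ± 3 SD,
overridden by any user constraint.  Which variable plays the marginal role
is decided by the interval-width rule: the variable with the smaller
standardised width ``(upper - lower)/sigma`` is drawn first (height on a
tie), so the better-constrained quantity anchors the conditional.

Contextual constraints — exact values or intervals for age, height and
body mass — narrow the simulated physiology without breaking the joint
structure.  A BMI filter (default 17.5–32.5 kg·m⁻²) is applied by
rejection of (height, mass) pairs.

Truncated-normal draws use inverse-CDF sampling, consuming exactly one
uniform variate per draw in a fixed order (age, first anthropometry
variable, second variable, cardiac output), so seeded runs are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import truncnorm

from .registry import AnthropometryParams, CardiacOutputParams

__all__ = [
    "Constraint",
    "ContextualConstraints",
    "Individual",
    "ConstraintError",
    "AGE_RANGE",
    "BMI_RANGE",
    "sample_age",
    "height_location",
    "logbm_location",
    "conditioning_order",
    "sample_height_mass",
    "cardiac_output_location",
    "sample_cardiac_output",
    "sample_phase1",
]

AGE_RANGE = (16.0, 65.0)
BMI_RANGE = (17.5, 32.5)

#: default truncation half-width for unconstrained variables, in SDs
_DEFAULT_HALF_WIDTH = 3.0
#: a constraint interval entirely beyond this many SDs has no usable mass
_MAX_Z = 8.0


class ConstraintError(ValueError):
    """Contextual constraints are contradictory or carry no probability mass."""


@dataclass(frozen=True)
class Constraint:
    """Knowledge about one quantity: free, an exact value, or an interval."""

    kind: str = "free"  # "free" | "exact" | "interval"
    value: Optional[float] = None
    lo: Optional[float] = None
    hi: Optional[float] = None

    @classmethod
    def free(cls) -> "Constraint":
        return cls("free")

    @classmethod
    def exact(cls, value: float) -> "Constraint":
        return cls("exact", value=float(value))

    @classmethod
    def interval(cls, lo: float, hi: float) -> "Constraint":
        lo, hi = float(lo), float(hi)
        if not lo < hi:
            raise ConstraintError(f"interval requires lo < hi, got [{lo}, {hi}]")
        return cls("interval", lo=lo, hi=hi)

    @classmethod
    def parse(cls, spec) -> "Constraint":
        """Accept None, a number, a (lo, hi) pair, or strings '49' / '50,55' / '[50,55]'."""
        if spec is None or isinstance(spec, Constraint):
            return spec or cls.free()
        if isinstance(spec, str):
            s = spec.strip().strip("[]()")
            if "," in s:
                lo, hi = s.split(",")
                return cls.interval(float(lo), float(hi))
            return cls.exact(float(s))
        if isinstance(spec, (tuple, list)):
            return cls.interval(*spec)
        return cls.exact(spec)

    def describe(self, name: str) -> str:
        if self.kind == "exact":
            return f"{name}={self.value:g}"
        if self.kind == "interval":
            return f"{name}=[{self.lo:g}, {self.hi:g}]"
        return f"{name}=free"


@dataclass(frozen=True)
class ContextualConstraints:
    """Exact or interval knowledge about age (yr), height (cm) and body mass (kg)."""

    age: Constraint = Constraint.free()
    height: Constraint = Constraint.free()
    body_mass: Constraint = Constraint.free()

    def __post_init__(self) -> None:
        object.__setattr__(self, "age", Constraint.parse(self.age))
        object.__setattr__(self, "height", Constraint.parse(self.height))
        object.__setattr__(self, "body_mass", Constraint.parse(self.body_mass))
        a = self.age
        lo, hi = AGE_RANGE
        if a.kind == "exact" and not lo <= a.value <= hi:
            raise ConstraintError(f"age {a.value} outside the supported range [{lo}, {hi}]")
        if a.kind == "interval" and not (lo <= a.lo and a.hi <= hi):
            raise ConstraintError(
                f"age interval [{a.lo}, {a.hi}] outside the supported range [{lo}, {hi}]")

    def describe(self) -> str:
        return ", ".join([self.age.describe("age"), self.height.describe("height"),
                          self.body_mass.describe("body_mass")])


@dataclass(frozen=True)
class Individual:
    """One virtual person's phase-1 state."""

    age: float
    height: float
    body_mass: float
    cardiac_output: float

    @property
    def bmi(self) -> float:
        return self.body_mass / (self.height / 100.0) ** 2


def _truncnorm_draw(rng, loc, sigma, lower, upper):
    """Inverse-CDF truncated-normal draws; one uniform per element.

    Degenerate sigma = 0 returns the location (the sigma -> 0 limit).
    Raises if any truncation interval lies beyond ``_MAX_Z`` SDs.
    """
    loc, sigma, lower, upper = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (loc, sigma, lower, upper)))
    u = rng.random(loc.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(sigma > 0, (lower - loc) / np.where(sigma > 0, sigma, 1.0), -1.0)
        b = np.where(sigma > 0, (upper - loc) / np.where(sigma > 0, sigma, 1.0), 1.0)
    if np.any(a > _MAX_Z) or np.any(b < -_MAX_Z):
        raise ConstraintError(
            "constraint interval carries no probability mass "
            f"(beyond {_MAX_Z:g} SD of the marginal)")
    x = truncnorm.ppf(u, a, b, loc=loc, scale=np.where(sigma > 0, sigma, 1.0))
    return np.where(sigma > 0, x, np.clip(loc, lower, upper))


def sample_age(constraints: ContextualConstraints, rng: np.random.Generator,
               n: int = 1) -> np.ndarray:
    """Draw ages: uniform on [16, 65] by default, uniform on a sub-interval,
    or an exact value replicated."""
    c = constraints.age
    if c.kind == "exact":
        return np.full(n, c.value, dtype=float)
    lo, hi = (c.lo, c.hi) if c.kind == "interval" else AGE_RANGE
    return rng.uniform(lo, hi, size=n)


def height_location(age, params: AnthropometryParams):
    """Mean height (cm) at a given age: alpha + a1*A + a2*A^2."""
    age = np.asarray(age, dtype=float)
    return params.height_alpha + params.height_a1 * age + params.height_a2 * age**2


def logbm_location(age, params: AnthropometryParams):
    """Mean ln body mass (ln kg) at a given age: alpha + a1*A + a2*A^2."""
    age = np.asarray(age, dtype=float)
    return params.logbm_alpha + params.logbm_a1 * age + params.logbm_a2 * age**2


def _log_mass_constraint(c: Constraint) -> Constraint:
    """Map a natural-scale body-mass constraint onto the ln-kg scale."""
    if c.kind == "exact":
        if c.value <= 0:
            raise ConstraintError("body mass must be positive")
        return Constraint.exact(np.log(c.value))
    if c.kind == "interval":
        if c.lo <= 0:
            raise ConstraintError("body-mass interval must be positive")
        return Constraint.interval(np.log(c.lo), np.log(c.hi))
    return c


def _std_width(c: Constraint, sigma: float) -> float:
    """Standardised interval width sigma^-1 (upper - lower); defaults span ±3 SD."""
    if c.kind == "interval":
        return (c.hi - c.lo) / sigma
    return 2.0 * _DEFAULT_HALF_WIDTH


def conditioning_order(constraints: ContextualConstraints,
                       params: AnthropometryParams) -> tuple[str, str]:
    """Which of ('height', 'log_body_mass') is drawn marginally first.

    The variable with the smaller standardised constraint width is drawn
    first; height wins ties.  Exact variables need no draw and are treated
    as drawn first (they anchor the conditional).
    """
    hc = constraints.height
    mc = _log_mass_constraint(constraints.body_mass)
    if hc.kind == "exact":
        return ("height", "log_body_mass")
    if mc.kind == "exact":
        return ("log_body_mass", "height")
    w_h = _std_width(hc, params.height_sigma)
    w_m = _std_width(mc, params.logbm_sigma)
    return ("height", "log_body_mass") if w_h <= w_m else ("log_body_mass", "height")


def _bounds(c: Constraint, loc: np.ndarray, sigma: float):
    if c.kind == "interval":
        return np.full_like(loc, c.lo), np.full_like(loc, c.hi)
    half = _DEFAULT_HALF_WIDTH * sigma
    return loc - half, loc + half


def sample_height_mass(age, constraints: ContextualConstraints,
                       params: AnthropometryParams,
                       rng: np.random.Generator,
                       order: tuple[str, str] | None = None):
    """Draw (height cm, body mass kg) for each age, honouring constraints.

    Returns a pair of arrays shaped like ``age``.  Exact constraints pass
    through; otherwise the marginal/conditional truncated-normal scheme
    described in the module docstring is applied.  ``order`` overrides
    the automatic marginal-first choice (diagnostic use: the joint law is
    order-invariant).
    """
    age = np.atleast_1d(np.asarray(age, dtype=float))
    mu_h = height_location(age, params)
    mu_m = logbm_location(age, params)
    sig_h, sig_m = params.height_sigma, params.logbm_sigma
    rho = params.rho_height_logbm

    hc = constraints.height
    mc = _log_mass_constraint(constraints.body_mass)

    if hc.kind == "exact" and mc.kind == "exact":
        return (np.full_like(age, hc.value),
                np.full_like(age, constraints.body_mass.value))

    if order is None:
        order = conditioning_order(constraints, params)
    spec = {
        "height": (hc, mu_h, sig_h),
        "log_body_mass": (mc, mu_m, sig_m),
    }
    values: dict[str, np.ndarray] = {}

    first, second = order
    c1, mu1, s1 = spec[first]
    if c1.kind == "exact":
        values[first] = np.full_like(age, c1.value)
    else:
        lo, hi = _bounds(c1, mu1, s1)
        values[first] = _truncnorm_draw(rng, mu1, s1, lo, hi)

    c2, mu2, s2 = spec[second]
    if c2.kind == "exact":
        values[second] = np.full_like(age, c2.value)
    else:
        slope = (s2 / s1) * rho if s1 > 0 else 0.0
        cond_mu = mu2 + slope * (values[first] - mu1)
        cond_sigma = np.sqrt(1.0 - rho**2) * s2
        lo, hi = _bounds(c2, mu2, s2)
        values[second] = _truncnorm_draw(rng, cond_mu, cond_sigma, lo, hi)

    if constraints.body_mass.kind == "exact":
        # avoid the exp(log(x)) round-trip: exact masses pass through untouched
        mass = np.full_like(age, constraints.body_mass.value)
    else:
        mass = np.exp(values["log_body_mass"])
    return values["height"], mass


def cardiac_output_location(age, height, params: CardiacOutputParams):
    """Mean cardiac output (L·min⁻¹) given age and height."""
    age = np.asarray(age, dtype=float)
    height = np.asarray(height, dtype=float)
    base = params.alpha + params.h1 * height + params.a1 * age
    if params.form == "male_logistic":
        return base + params.a2 / (1.0 + np.exp(-params.a3 * (age - 18.0)))
    if params.form == "female_cubic":
        return base + params.a2 * age**2 + params.a3 * age**3
    raise ValueError(f"unknown cardiac-output form {params.form!r}")


def sample_cardiac_output(age, height, params: CardiacOutputParams,
                          rng: np.random.Generator):
    """Draw cardiac output ~ N(location, sigma^2), truncated below at 0."""
    loc = np.atleast_1d(cardiac_output_location(age, height, params))
    return _truncnorm_draw(rng, loc, params.sigma, 0.0, np.inf)


def sample_phase1(params, constraints: ContextualConstraints | None,
                  rng: np.random.Generator, n: int,
                  bmi_filter: bool = True,
                  bmi_range: tuple[float, float] = BMI_RANGE,
                  max_attempts: int = 10_000):
    """Vectorised phase-1 draw: (age, height, body_mass, bmi, cardiac_output).

    With the BMI filter active, (height, mass) pairs violating the BMI
    window are rejection-sampled (ages retained) up to ``max_attempts``
    rounds; persistent violation raises :class:`ConstraintError`.
    """
    constraints = constraints or ContextualConstraints()
    anthro = params.anthro
    age = sample_age(constraints, rng, n)
    height, mass = sample_height_mass(age, constraints, anthro, rng)

    if bmi_filter:
        lo, hi = bmi_range
        if constraints.height.kind == "exact" and constraints.body_mass.kind == "exact":
            bmi = mass / (height / 100.0) ** 2
            if np.any((bmi < lo) | (bmi > hi)):
                raise ConstraintError(
                    "exact height/body-mass constraints give a BMI outside "
                    f"[{lo}, {hi}]")
        else:
            bad = _bmi_violations(height, mass, lo, hi)
            attempts = 0
            while np.any(bad):
                attempts += 1
                if attempts > max_attempts:
                    raise ConstraintError(
                        f"BMI in [{lo}, {hi}] not attainable under the given "
                        f"constraints after {max_attempts} rejection rounds")
                h_new, m_new = sample_height_mass(age[bad], constraints, anthro, rng)
                height[bad], mass[bad] = h_new, m_new
                bad = _bmi_violations(height, mass, lo, hi)

    co = sample_cardiac_output(age, height, params.co, rng)
    bmi = mass / (height / 100.0) ** 2
    return age, height, mass, bmi, co


def _bmi_violations(height, mass, lo, hi):
    bmi = mass / (height / 100.0) ** 2
    return (bmi < lo) | (bmi > hi)
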