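"""Phase 2: organ/tissue masses and blood flows, with mass and flow balance.

For a phase-1 individual (age, height, body mass, BMI, cardiac output)
each of the fifteen organs gets

* a mass drawn from its normal or log-normal model (location a tabulated
  function of the covariates), truncated to the central 90% (5th–95th
  percentile) so organs are never unrealistically small or large; the
  ln-masses of adipose and skeletal muscle are drawn jointly from a
  bivariate normal with a strong negative correlation (excess body mass
  is mostly fat *or* mostly muscle, rarely both);
* a blood flow drawn as a fraction of cardiac output from a normal
  distribution truncated at ±2 SD.

Balance is then enforced: flows are rescaled by a common factor so they
sum exactly to cardiac output, and the adipose and muscle masses are
rescaled by a common factor λ so all masses sum exactly to body mass
(the thirteen other organs are kept as sampled).  Individuals whose λ
falls outside a plausibility window are rejected and resampled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .anthropometry import (
    Constraint,
    ContextualConstraints,
    Individual,
    BMI_RANGE,
    sample_phase1,
    _truncnorm_draw,
)
from .registry import (
    ORGANS,
    LOGNORMAL_ORGANS,
    OrganModel,
    PopulationKey,
    PopulationParameters,
    load_parameters,
)

__all__ = [
    "Physiology",
    "Population",
    "SimulationSettings",
    "BalanceError",
    "SimulationError",
    "Z90",
    "organ_mass_location",
    "sample_organ_masses",
    "sample_flow_fractions",
    "rebalance_flows",
    "rebalance_masses",
    "simulate_individual",
    "simulate_population",
]

#: 95th standard-normal percentile: half-width of the central-90% mass band
Z90: float = float(norm.ppf(0.95))

#: floor applied when a normal organ's 5th percentile would be non-positive
_MASS_FLOOR = 1e-4
#: floor applied when a flow fraction's -2 SD bound would be non-positive
_FRACTION_FLOOR = 1e-6

_MASS_COLS = [f"mass_{o}_kg" for o in ORGANS]
_FLOW_COLS = [f"flow_{o}_l_min" for o in ORGANS]
_PHASE1_COLS = ["age", "height_cm", "body_mass_kg", "bmi", "cardiac_output_l_min"]


class BalanceError(RuntimeError):
    """Mass balance cannot be restored for the sampled physiology."""


class SimulationError(RuntimeError):
    """The simulation failed to produce the requested population."""


@dataclass(frozen=True)
class SimulationSettings:
    """Tunable Monte-Carlo settings (defaults reproduce the reference study conditions)."""

    bmi_filter: bool = True
    bmi_range: tuple[float, float] = BMI_RANGE
    max_bmi_attempts: int = 10_000
    lambda_bounds: tuple[float, float] = (0.2, 5.0)
    max_rebalance_attempts: int = 1_000


@dataclass(frozen=True)
class Physiology:
    """One balanced virtual person: phase-1 state plus organ masses and flows."""

    individual: Individual
    masses: Mapping[str, float]
    flows: Mapping[str, float]

    def total_mass(self) -> float:
        return float(sum(self.masses.values()))

    def total_flow(self) -> float:
        return float(sum(self.flows.values()))


def organ_mass_location(model: OrganModel, gender: str, age, height,
                        body_mass, bmi):
    """Location of an organ's mass model (of ln-mass for log-normal organs).

    Evaluates the tabulated covariate form for the organ: most organs are
    linear in height; brain is linear in age; skin quadratic in body
    mass; bone uses a gender-specific form (males a logistic maturation
    term in age scaled by height, females an age quadratic plus height);
    adipose and muscle are quadratics in age plus height and BMI terms.
    """
    age = np.asarray(age, dtype=float)
    height = np.asarray(height, dtype=float)
    body_mass = np.asarray(body_mass, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    c = model.coeff
    organ = model.organ
    if organ == "brain":
        return c("alpha") + c("a1") * age
    if organ == "sexual_organs":
        return np.broadcast_to(np.float64(c("alpha")), age.shape).copy()
    if organ == "skin":
        return c("alpha") + c("m1") * body_mass + c("m2") * body_mass**2
    if organ == "bone":
        if gender == "male":
            logistic = 1.0 / (1.0 + np.exp(-c("a1") * (age - 18.0)))
            return c("alpha") + c("h1") * height + c("h2") * height * logistic
        return c("alpha") + c("a1") * age + c("a2") * age**2 + c("h1") * height
    if organ in ("adipose", "muscle"):
        return (c("alpha") + c("a1") * age + c("a2") * age**2
                + c("h1") * height + c("b1") * bmi + c("b2") * bmi**2)
    # height-linear organs: lung, heart, kidneys, liver, pancreas, spleen,
    # stomach, small/large intestine
    return c("alpha") + c("h1") * height


def _mass_band(loc, sigma, family):
    lower = loc - Z90 * sigma
    upper = loc + Z90 * sigma
    if family == "normal" and np.any(lower <= 0):
        warnings.warn(
            "5th percentile of a normal organ-mass model is non-positive; "
            f"clamping the lower truncation at {_MASS_FLOOR} kg", RuntimeWarning)
        lower = np.maximum(lower, _MASS_FLOOR)
    return lower, upper


def sample_organ_masses(params: PopulationParameters, age, height, body_mass,
                        bmi, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Raw (pre-balance) organ masses, kg, for each individual.

    Each organ is truncated to its central 90%; ln(adipose) and
    ln(muscle) are drawn jointly (adipose from its truncated marginal,
    muscle from the conditional given adipose, truncated to muscle's own
    marginal band).  Draws follow the canonical organ order.
    """
    age = np.atleast_1d(np.asarray(age, dtype=float))
    gender = params.key.gender
    rho = params.rho_adipose_muscle
    out: dict[str, np.ndarray] = {}
    adipose_state: Optional[tuple[np.ndarray, float, np.ndarray]] = None
    for organ in ORGANS:
        model = params.organs[organ]
        loc = organ_mass_location(model, gender, age, height, body_mass, bmi)
        sigma = model.sigma
        lower, upper = _mass_band(loc, sigma, model.family)
        if organ == "adipose":
            draw = _truncnorm_draw(rng, loc, sigma, lower, upper)
            adipose_state = (loc, sigma, draw)
            out[organ] = np.exp(draw)
        elif organ == "muscle":
            mu_a, sig_a, x_a = adipose_state
            slope = (sigma / sig_a) * rho if sig_a > 0 else 0.0
            cond_loc = loc + slope * (x_a - mu_a)
            cond_sigma = np.sqrt(1.0 - rho**2) * sigma
            draw = _truncnorm_draw(rng, cond_loc, cond_sigma, lower, upper)
            out[organ] = np.exp(draw)
        else:
            draw = _truncnorm_draw(rng, loc, sigma, lower, upper)
            out[organ] = np.exp(draw) if model.family == "lognormal" else draw
    return out


def sample_flow_fractions(params: PopulationParameters, n: int,
                          rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Organ blood-flow fractions of cardiac output, N(c1, sigma^2) truncated at ±2 SD."""
    out: dict[str, np.ndarray] = {}
    for organ in ORGANS:
        model = params.organs[organ]
        c1, sigma = model.flow_c1, model.flow_sigma
        lower = c1 - 2.0 * sigma
        if lower <= 0:
            lower = _FRACTION_FLOOR
        upper = c1 + 2.0 * sigma
        out[organ] = _truncnorm_draw(rng, np.full(n, c1), sigma, lower, upper)
    return out


def rebalance_flows(fractions: Mapping[str, np.ndarray], cardiac_output):
    """Rescale flow fractions so organ flows sum exactly to cardiac output."""
    co = np.asarray(cardiac_output, dtype=float)
    total = sum(np.asarray(fractions[o], dtype=float) for o in fractions)
    if np.any(total <= 0):
        raise BalanceError("flow fractions sum to zero; cannot rescale")
    return {o: co * np.asarray(fractions[o], dtype=float) / total for o in fractions}


def _mass_rescale_factor(raw: Mapping[str, np.ndarray], body_mass):
    """λ such that scaling adipose and muscle by λ restores mass balance."""
    bm = np.asarray(body_mass, dtype=float)
    others = sum(np.asarray(raw[o], dtype=float)
                 for o in raw if o not in ("adipose", "muscle"))
    soft = np.asarray(raw["adipose"], dtype=float) + np.asarray(raw["muscle"], dtype=float)
    return (bm - others) / soft


def rebalance_masses(raw_masses: Mapping[str, np.ndarray], body_mass):
    """Rescale adipose and muscle by a common factor so masses sum to body mass.

    All other organs are kept as sampled.  Raises :class:`BalanceError`
    if the other organs already exceed body mass (λ would be ≤ 0).
    """
    lam = _mass_rescale_factor(raw_masses, body_mass)
    if np.any(lam <= 0):
        raise BalanceError(
            "non-adipose/muscle organ masses meet or exceed body mass; "
            "no positive rescaling factor exists")
    out = {o: np.asarray(v, dtype=float).copy() for o, v in raw_masses.items()}
    out["adipose"] = out["adipose"] * lam
    out["muscle"] = out["muscle"] * lam
    return out


class Population:
    """A simulated population: a tidy frame plus provenance metadata.

    Columns: ``id``, the five phase-1 quantities, then ``mass_<organ>_kg``
    and ``flow_<organ>_l_min`` for the fifteen organs.
    """

    def __init__(self, frame: pd.DataFrame, key: PopulationKey,
                 constraints: ContextualConstraints,
                 settings: SimulationSettings,
                 seed=None, rejections: int = 0):
        self.frame = frame
        self.key = key
        self.constraints = constraints
        self.settings = settings
        self.seed = seed
        self.rejections = rejections

    def __len__(self) -> int:
        return len(self.frame)

    def __getitem__(self, i: int) -> Physiology:
        row = self.frame.iloc[i]
        ind = Individual(age=row["age"], height=row["height_cm"],
                         body_mass=row["body_mass_kg"],
                         cardiac_output=row["cardiac_output_l_min"])
        masses = {o: float(row[f"mass_{o}_kg"]) for o in ORGANS}
        flows = {o: float(row[f"flow_{o}_l_min"]) for o in ORGANS}
        return Physiology(individual=ind, masses=masses, flows=flows)

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    def masses(self) -> pd.DataFrame:
        return self.frame[_MASS_COLS].rename(columns=dict(zip(_MASS_COLS, ORGANS)))

    def flows(self) -> pd.DataFrame:
        return self.frame[_FLOW_COLS].rename(columns=dict(zip(_FLOW_COLS, ORGANS)))

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write the population CSV plus a JSON provenance sidecar."""
        path = Path(path)
        self.frame.to_csv(path, index=False)
        if sidecar:
            meta = {
                "country": self.key.country,
                "gender": self.key.gender,
                "ethnicity": self.key.ethnicity,
                "constraints": self.constraints.describe(),
                "settings": asdict(self.settings),
                "seed": self.seed,
                "n": len(self),
                "rejections": self.rejections,
            }
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(meta, indent=1) + "\n")

    @classmethod
    def read_csv(cls, path, key: PopulationKey | None = None) -> "Population":
        frame = pd.read_csv(path)
        return cls(frame, key=key, constraints=ContextualConstraints(),
                   settings=SimulationSettings())


def simulate_population(key, n: int,
                        constraints: ContextualConstraints | None = None,
                        settings: SimulationSettings | None = None,
                        seed=None,
                        rng: np.random.Generator | None = None) -> Population:
    """Simulate ``n`` balanced individuals from one sub-population.

    ``key`` may be a :class:`PopulationKey`, a (country, gender,
    ethnicity) tuple, or a pre-loaded :class:`PopulationParameters`.
    With a fixed ``seed`` the output is bit-reproducible.  Individuals
    whose adipose+muscle rescale factor leaves the plausibility window
    are transparently resampled; the count is reported on the returned
    :class:`Population`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(key, PopulationParameters):
        params = key
    else:
        params = load_parameters(key)
    constraints = constraints or ContextualConstraints()
    settings = settings or SimulationSettings()
    if rng is None:
        rng = np.random.default_rng(seed)

    lam_lo, lam_hi = settings.lambda_bounds
    store = {col: np.empty(n) for col in _PHASE1_COLS + _MASS_COLS + _FLOW_COLS}
    pending = np.arange(n)
    rejections = 0
    rounds = 0
    while pending.size:
        rounds += 1
        if rounds > settings.max_rebalance_attempts:
            raise SimulationError(
                "mass balance unattainable under the given constraints: "
                f"{pending.size} individuals still rejected after "
                f"{settings.max_rebalance_attempts} resampling rounds")
        m = pending.size
        age, height, mass, bmi, co = sample_phase1(
            params, constraints, rng, m,
            bmi_filter=settings.bmi_filter, bmi_range=settings.bmi_range,
            max_attempts=settings.max_bmi_attempts)
        raw = sample_organ_masses(params, age, height, mass, bmi, rng)
        fractions = sample_flow_fractions(params, m, rng)
        lam = _mass_rescale_factor(raw, mass)
        ok = (lam > lam_lo) & (lam < lam_hi)
        rejections += int(np.count_nonzero(~ok))
        idx = pending[ok]
        store["age"][idx] = age[ok]
        store["height_cm"][idx] = height[ok]
        store["body_mass_kg"][idx] = mass[ok]
        store["bmi"][idx] = bmi[ok]
        store["cardiac_output_l_min"][idx] = co[ok]
        flows = rebalance_flows({o: fractions[o][ok] for o in ORGANS}, co[ok])
        balanced = rebalance_masses({o: raw[o][ok] for o in ORGANS}, mass[ok])
        for o in ORGANS:
            store[f"mass_{o}_kg"][idx] = balanced[o]
            store[f"flow_{o}_l_min"][idx] = flows[o]
        pending = pending[~ok]

    frame = pd.DataFrame(store)
    frame.insert(0, "id", np.arange(n))
    return Population(frame, key=params.key, constraints=constraints,
                      settings=settings, seed=seed, rejections=rejections)


def simulate_individual(key, constraints: ContextualConstraints | None = None,
                        settings: SimulationSettings | None = None,
                        seed=None,
                        rng: np.random.Generator | None = None) -> Physiology:
    """Simulate a single balanced individual (``simulate_population`` with n = 1)."""
    return simulate_population(key, 1, constraints=constraints,
                               settings=settings, seed=seed, rng=rng)[0]
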