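"""Parameter registry for the twelve simulated sub-populations.

Every coefficient of the hierarchical physiology model — the age/height/
log-body-mass marginals, the cardiac-output regressions, and the fifteen
organ mass and flow models — is shipped as one JSON document per
(country, gender, ethnicity) sub-population under ``physiopop/data``.
This module loads, validates and serves those documents as typed,
immutable parameter objects.

Units: heights in cm, masses in kg (log-scale coefficients in ln kg),
cardiac output and blood flows in L·min⁻¹, ages in years.  Organ flow
models are expressed as fractions of cardiac output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

__all__ = [
    "ORGANS",
    "LOGNORMAL_ORGANS",
    "PopulationKey",
    "AnthropometryParams",
    "CardiacOutputParams",
    "OrganModel",
    "PopulationParameters",
    "ParameterError",
    "UnknownPopulationError",
    "load_parameters",
    "list_populations",
    "validate_parameters",
]

#: Canonical organ order; random draws consume the stream in this order.
ORGANS: tuple[str, ...] = (
    "lung", "brain", "heart", "kidneys", "liver", "pancreas", "spleen",
    "stomach", "small_intestine", "large_intestine", "sexual_organs",
    "skin", "bone", "adipose", "muscle",
)

#: Organs whose masses are log-normally distributed; all others are normal.
LOGNORMAL_ORGANS: frozenset[str] = frozenset({"lung", "spleen", "adipose", "muscle"})

COUNTRIES: tuple[str, ...] = ("UK", "US")
GENDERS: tuple[str, ...] = ("male", "female")
ETHNICITIES: dict[str, tuple[str, ...]] = {
    "UK": ("White", "Asian", "Black"),
    "US": ("White", "Non-Black Hispanic", "Black"),
}

# "White" and "Caucasian" are interchangeable at the interface.
_ETHNICITY_ALIASES = {
    "white": "White",
    "caucasian": "Caucasian",  # resolved to White below
    "asian": "Asian",
    "black": "Black",
    "non black hispanic": "Non-Black Hispanic",
    "nonblack hispanic": "Non-Black Hispanic",
    "hispanic": "Non-Black Hispanic",
}


class ParameterError(ValueError):
    """A shipped or user-supplied parameter set failed validation."""


class UnknownPopulationError(KeyError):
    """The (country, gender, ethnicity) triple does not name a population."""


@dataclass(frozen=True)
class PopulationKey:
    """Selects one of the twelve sub-populations (2 countries × 2 genders × 3 ethnicities)."""

    country: str
    gender: str
    ethnicity: str

    def __post_init__(self) -> None:
        country = str(self.country).upper()
        gender = str(self.gender).lower()
        eth_raw = str(self.ethnicity).strip().lower().replace("-", " ").replace("_", " ")
        eth = _ETHNICITY_ALIASES.get(eth_raw)
        if eth == "Caucasian":
            eth = "White"
        if country not in COUNTRIES:
            raise UnknownPopulationError(
                f"unknown country {self.country!r}; expected one of {COUNTRIES}")
        if gender not in GENDERS:
            raise UnknownPopulationError(
                f"unknown gender {self.gender!r}; expected one of {GENDERS}")
        if eth is None or eth not in ETHNICITIES[country]:
            raise UnknownPopulationError(
                f"unknown ethnicity {self.ethnicity!r} for {country}; "
                f"expected one of {ETHNICITIES[country]} (Caucasian == White)")
        object.__setattr__(self, "country", country)
        object.__setattr__(self, "gender", gender)
        object.__setattr__(self, "ethnicity", eth)

    @property
    def slug(self) -> str:
        eth = self.ethnicity.lower().replace("-", "_").replace(" ", "_")
        return f"{self.country.lower()}_{self.gender}_{eth}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.country} {self.gender} {self.ethnicity}"


@dataclass(frozen=True)
class AnthropometryParams:
    """Age-conditional normal marginals for height (cm) and ln body mass (ln kg).

    Both locations are quadratic in age, ``alpha + a1*A + a2*A**2``; ``rho``
    is the residual correlation between height and ln body mass used to
    couple the two marginals into a bivariate normal.
    """

    height_alpha: float
    height_a1: float
    height_a2: float
    height_sigma: float
    logbm_alpha: float
    logbm_a1: float
    logbm_a2: float
    logbm_sigma: float
    rho_height_logbm: float


@dataclass(frozen=True)
class CardiacOutputParams:
    """Cardiac output (L·min⁻¹) regression on age and height.

    Males use a logistic age term, ``alpha + h1*H + a1*A +
    a2/(1 + exp(-a3*(A - 18)))``; females a cubic polynomial,
    ``alpha + h1*H + a1*A + a2*A**2 + a3*A**3``.  Residual SD ``sigma``.
    """

    form: str  # "male_logistic" | "female_cubic"
    alpha: float
    h1: float
    a1: float
    a2: float
    a3: float
    sigma: float


#: coefficient names each organ's location form may use (missing -> 0)
_COEFF_NAMES = ("alpha", "a1", "a2", "h1", "h2", "m1", "m2", "b1", "b2")

#: required coefficients per (organ, gender); b2 for muscle is optional
_REQUIRED_COEFFS: dict[str, tuple[str, ...]] = {
    "lung": ("alpha", "h1"),
    "brain": ("alpha", "a1"),
    "heart": ("alpha", "h1"),
    "kidneys": ("alpha", "h1"),
    "liver": ("alpha", "h1"),
    "pancreas": ("alpha", "h1"),
    "spleen": ("alpha", "h1"),
    "stomach": ("alpha", "h1"),
    "small_intestine": ("alpha", "h1"),
    "large_intestine": ("alpha", "h1"),
    "sexual_organs": ("alpha",),
    "skin": ("alpha", "m1", "m2"),
    "bone": ("alpha",),  # gender-dependent, checked separately
    "adipose": ("alpha", "a1", "a2", "h1", "b1"),
    "muscle": ("alpha", "a1", "a2", "h1", "b1"),
}


@dataclass(frozen=True)
class OrganModel:
    """Mass and flow model for one organ.

    ``coeffs`` parameterise the location of the mass distribution (of
    ln-mass for log-normal organs); ``sigma`` is the corresponding SD.
    ``flow_c1``/``flow_sigma`` give the normal distribution of the organ's
    blood-flow fraction of cardiac output.
    """

    organ: str
    family: str  # "normal" | "lognormal"
    coeffs: Mapping[str, float] = field(repr=False)
    sigma: float = 0.0
    flow_c1: float = 0.0
    flow_sigma: float = 0.0

    def coeff(self, name: str) -> float:
        return float(self.coeffs.get(name, 0.0))


@dataclass(frozen=True)
class PopulationParameters:
    """The full coefficient set for one sub-population."""

    key: PopulationKey
    anthro: AnthropometryParams
    co: CardiacOutputParams
    organs: Mapping[str, OrganModel]
    rho_adipose_muscle: float


def list_populations() -> frozenset[PopulationKey]:
    """All twelve population keys shipped with the package."""
    return frozenset(
        PopulationKey(country, gender, eth)
        for country in COUNTRIES
        for gender in GENDERS
        for eth in ETHNICITIES[country]
    )


def _data_text(name: str) -> str:
    ref = resources.files("physiopop.data").joinpath(name)
    return ref.read_text(encoding="utf-8")


def load_parameters(key: PopulationKey | tuple[str, str, str]) -> PopulationParameters:
    """Load and validate the shipped parameter set for ``key``.

    Accepts a :class:`PopulationKey` or a plain ``(country, gender,
    ethnicity)`` tuple.  Raises :class:`UnknownPopulationError` for an
    illegal key and :class:`ParameterError` if the shipped data fail
    validation (which would indicate a corrupted installation).
    """
    if not isinstance(key, PopulationKey):
        key = PopulationKey(*key)
    raw = json.loads(_data_text(f"{key.slug}.json"))

    try:
        a = raw["anthropometry"]
        h, l = a["height"], a["log_body_mass"]
        anthro = AnthropometryParams(
            height_alpha=h["alpha"], height_a1=h["a1"], height_a2=h["a2"],
            height_sigma=h["sigma"],
            logbm_alpha=l["alpha"], logbm_a1=l["a1"], logbm_a2=l["a2"],
            logbm_sigma=l["sigma"],
            rho_height_logbm=a["rho"],
        )
        c = raw["cardiac_output"]
        co = CardiacOutputParams(
            form=c["form"], alpha=c["alpha"], h1=c["h1"],
            a1=c["a1"], a2=c["a2"], a3=c["a3"], sigma=c["sigma"],
        )
        organs = {}
        for organ, spec in raw["organs"].items():
            organs[organ] = OrganModel(
                organ=organ,
                family=spec["family"],
                coeffs=dict(spec["coeffs"]),
                sigma=spec["sigma"],
                flow_c1=spec["flow_c1"],
                flow_sigma=spec["flow_sigma"],
            )
        params = PopulationParameters(
            key=key, anthro=anthro, co=co, organs=organs,
            rho_adipose_muscle=raw["rho_adipose_muscle"],
        )
    except KeyError as exc:  # incomplete data file
        raise ParameterError(
            f"parameter file {key.slug}.json is missing field {exc}") from exc

    violations = validate_parameters(params)
    if violations:
        raise ParameterError(
            f"parameter file {key.slug}.json failed validation: " + "; ".join(violations))
    return params


def validate_parameters(params: PopulationParameters) -> list[str]:
    """Check all structural invariants; returns a list of violations (empty = valid)."""
    v: list[str] = []
    a = params.anthro
    if not a.height_sigma > 0:
        v.append("anthro.height_sigma: must be > 0")
    if not a.logbm_sigma > 0:
        v.append("anthro.logbm_sigma: must be > 0")
    if not abs(a.rho_height_logbm) < 1:
        v.append("anthro.rho_height_logbm: |rho| must be < 1")

    expected_form = "male_logistic" if params.key.gender == "male" else "female_cubic"
    if params.co.form != expected_form:
        v.append(f"co.form: expected {expected_form!r} for gender "
                 f"{params.key.gender!r}, got {params.co.form!r}")
    if not params.co.sigma > 0:
        v.append("co.sigma: must be > 0")

    if set(params.organs) != set(ORGANS):
        v.append(f"organs: expected {len(ORGANS)}, got {len(params.organs)}")
    if not -1 < params.rho_adipose_muscle <= 0:
        v.append("rho_adipose_muscle: must lie in (-1, 0]")

    for organ in ORGANS:
        model = params.organs.get(organ)
        if model is None:
            continue
        expected_family = "lognormal" if organ in LOGNORMAL_ORGANS else "normal"
        if model.family != expected_family:
            v.append(f"organs[{organ}].family: expected {expected_family!r}, "
                     f"got {model.family!r}")
        if not model.sigma > 0:
            v.append(f"organs[{organ}].sigma: must be > 0")
        if not model.flow_c1 > 0:
            v.append(f"organs[{organ}].flow_c1: must be > 0")
        if not model.flow_sigma > 0:
            v.append(f"organs[{organ}].flow_sigma: must be > 0")
        required = _REQUIRED_COEFFS[organ]
        if organ == "bone":
            required = (("alpha", "a1", "h1", "h2") if params.key.gender == "male"
                        else ("alpha", "a1", "a2", "h1"))
        missing = [c for c in required if c not in model.coeffs]
        if missing:
            v.append(f"organs[{organ}].coeffs: missing {missing}")
        unknown = [c for c in model.coeffs if c not in _COEFF_NAMES]
        if unknown:
            v.append(f"organs[{organ}].coeffs: unknown coefficient(s) {unknown}")
        for name, value in model.coeffs.items():
            if not math.isfinite(float(value)):
                v.append(f"organs[{organ}].coeffs[{name}]: not finite")

    total_c1 = sum(m.flow_c1 for m in params.organs.values())
    if not 0.9 < total_c1 < 1.1:
        v.append(f"organs: sum of flow_c1 = {total_c1:.4f}, expected in (0.9, 1.1)")
    return v
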