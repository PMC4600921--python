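"""Lumping organs into perfusion compartments and balance-preserving edits.

PBPK models rarely carry all fifteen tissues; organs with similar
perfusion are summed into aggregated "rapidly" and "slowly" perfused
compartments.  The default scheme lumps heart, lung, spleen, pancreas
and sexual organs (rapidly perfused) and skin plus skeletal muscle
(slowly perfused); everything else passes through unaggregated.

Two further operations support downstream use: subtracting a whole-body
blood mass from tissue masses using user-supplied per-organ blood weight
fractions (the simulated organ masses include their blood content), and
the single-component "sink" update used inside MCMC samplers for inverse
problems — after changing one organ's mass and flow, the sink tissue
(skeletal muscle by convention) absorbs the difference so mass and flow
balance are preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .organs import Physiology, Population
from .registry import ORGANS

__all__ = [
    "AggregationScheme",
    "DEFAULT_SCHEME",
    "SOHN_SCHEME",
    "aggregate",
    "aggregate_population",
    "subtract_blood",
    "sink_rebalance",
]


@dataclass(frozen=True)
class AggregationScheme:
    """Named compartments, each a disjoint set of organ names, plus a sink."""

    compartments: Mapping[str, frozenset[str]]
    sink: str = "muscle"

    def __post_init__(self) -> None:
        comps = {name: frozenset(members)
                 for name, members in self.compartments.items()}
        object.__setattr__(self, "compartments", comps)
        seen: set[str] = set()
        for name, members in comps.items():
            unknown = members - set(ORGANS)
            if unknown:
                raise ValueError(
                    f"compartment {name!r} references unknown organ(s) {sorted(unknown)}")
            overlap = members & seen
            if overlap:
                raise ValueError(
                    f"organ(s) {sorted(overlap)} assigned to more than one compartment")
            seen |= members
        if self.sink not in comps and self.sink not in ORGANS:
            raise ValueError(f"sink {self.sink!r} is neither a compartment nor an organ")

    @property
    def assigned(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.compartments.values():
            out |= members
        return frozenset(out)

    def quantities(self) -> list[str]:
        """Compartments plus pass-through organs, in canonical order."""
        names = list(self.compartments)
        names += [o for o in ORGANS if o not in self.assigned]
        return names


#: the reference scheme used for the population summary tables
DEFAULT_SCHEME = AggregationScheme(
    compartments={
        "rapidly_perfused": frozenset(
            {"heart", "lung", "spleen", "pancreas", "sexual_organs"}),
        "slowly_perfused": frozenset({"skin", "muscle"}),
    },
    sink="slowly_perfused",
)

#: four-compartment scheme matching the Sohn-style TCE model structure
SOHN_SCHEME = AggregationScheme(
    compartments={
        "fat": frozenset({"adipose"}),
        "slowly_perfused": frozenset({"skin", "muscle"}),
        "rapidly_perfused": frozenset(
            {"heart", "lung", "spleen", "pancreas", "sexual_organs"}),
        "liver": frozenset({"liver"}),
    },
    sink="slowly_perfused",
)


def _lump(values: Mapping[str, float], scheme: AggregationScheme) -> dict[str, float]:
    out = {name: float(sum(values[o] for o in members))
           for name, members in scheme.compartments.items()}
    for organ in ORGANS:
        if organ not in scheme.assigned:
            out[organ] = float(values[organ])
    return out


def aggregate(phys: Physiology, scheme: AggregationScheme = DEFAULT_SCHEME):
    """Sum organ masses and flows into the scheme's compartments.

    Unassigned organs pass through; totals are conserved exactly.
    Returns ``(masses, flows)`` dicts keyed by compartment/organ name.
    """
    return _lump(phys.masses, scheme), _lump(phys.flows, scheme)


def aggregate_population(pop: Population | pd.DataFrame,
                         scheme: AggregationScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Vectorised :func:`aggregate`: per-individual compartment columns.

    Returns a frame with the phase-1 columns plus ``mass_<name>_kg`` and
    ``flow_<name>_l_min`` for every compartment and pass-through organ.
    """
    frame = pop.frame if isinstance(pop, Population) else pop
    out = frame[[c for c in ("id", "age", "height_cm", "body_mass_kg", "bmi",
                             "cardiac_output_l_min") if c in frame.columns]].copy()
    for kind, unit in (("mass", "kg"), ("flow", "l_min")):
        for name, members in scheme.compartments.items():
            out[f"{kind}_{name}_{unit}"] = sum(
                frame[f"{kind}_{o}_{unit}"] for o in members)
        for organ in ORGANS:
            if organ not in scheme.assigned:
                out[f"{kind}_{organ}_{unit}"] = frame[f"{kind}_{organ}_{unit}"]
    return out


def subtract_blood(phys: Physiology, blood_mass: float,
                   fractions: Mapping[str, float]) -> Physiology:
    """Remove each organ's share of a whole-body blood mass.

    ``fractions[o]`` is the fraction of the blood mass resident in organ
    ``o`` (must sum to ≤ 1; organs absent from the map are untouched).
    The removed total is reported as a ``blood`` entry so overall mass is
    conserved.  There is deliberately no default fraction table: the
    reference per-organ blood content must be supplied by the caller.
    """
    if blood_mass < 0:
        raise ValueError("blood_mass must be >= 0")
    unknown = set(fractions) - set(ORGANS)
    if unknown:
        raise ValueError(f"unknown organ(s) in blood fractions: {sorted(unknown)}")
    total_fraction = float(sum(fractions.values()))
    if total_fraction > 1.0 + 1e-12:
        raise ValueError(f"blood fractions sum to {total_fraction:.4f} > 1")
    masses = dict(phys.masses)
    for organ, f in fractions.items():
        new = masses[organ] - blood_mass * f
        if new <= 0:
            raise ValueError(
                f"subtracting blood leaves organ {organ!r} with non-positive "
                f"mass ({new:.4g} kg)")
        masses[organ] = new
    masses["blood"] = blood_mass * total_fraction
    return Physiology(individual=phys.individual, masses=masses,
                      flows=dict(phys.flows))


def sink_rebalance(phys: Physiology, changed: str, new_mass: float,
                   new_flow: float, sink: str = "muscle") -> Physiology:
    """Set one organ's mass/flow and let the sink absorb the difference.

    The sink organ's mass changes by ``-(new_mass - old_mass)`` and its
    flow by ``-(new_flow - old_flow)``, so body mass and cardiac output
    totals are untouched.  Raises if the sink would go non-positive
    (signalling an invalid proposal to an MCMC caller).
    """
    if changed == sink:
        raise ValueError("changed organ and sink must differ")
    if changed not in phys.masses or sink not in phys.masses:
        raise KeyError(f"unknown organ: {changed!r} or {sink!r}")
    masses = dict(phys.masses)
    flows = dict(phys.flows)
    sink_mass = masses[sink] - (new_mass - masses[changed])
    sink_flow = flows[sink] - (new_flow - flows[changed])
    if sink_mass <= 0 or sink_flow <= 0:
        raise ValueError(
            f"sink {sink!r} cannot absorb the update "
            f"(would get mass {sink_mass:.4g} kg, flow {sink_flow:.4g} L/min)")
    masses[changed], flows[changed] = float(new_mass), float(new_flow)
    masses[sink], flows[sink] = sink_mass, sink_flow
    return Physiology(individual=phys.individual, masses=masses, flows=flows)
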