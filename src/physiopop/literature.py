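"""Literature prior samplers and the physiological-plausibility screen.

Reverse-dosimetry studies have specified human physiology with broad,
organ-by-organ priors.  Two published specifications are reproduced here
for comparison against the hierarchical simulator:

* a four-compartment adult-male specification with every mass and flow
  an independent log-normal, read as LN(geometric mean, geometric SD);
* a childbearing-age female specification with a bounded log-normal body
  weight, a bounded normal cardiac output (L/hr), and tissue mass/flow
  fractions drawn from truncated normals on published bounding intervals.

The screen classifies a sampled physiology as plausible iff every
quantity (each compartment mass and flow, plus cardiac output) lies
within the absolute min/max bounds observed in a reference population
produced by this package's own simulator.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .aggregation import AggregationScheme, SOHN_SCHEME, aggregate_population
from .anthropometry import _truncnorm_draw
from .organs import Population, simulate_population

__all__ = [
    "SOHN_PRIORS",
    "ALLEN_PRIORS",
    "sample_sohn",
    "sample_allen",
    "reference_bounds",
    "screen",
    "sohn_quantities",
]

#: LN(geometric mean, geometric SD) per compartment; volumes (L) taken as kg 1:1
SOHN_PRIORS: dict[str, dict[str, tuple[float, float]]] = {
    "mass": {
        "fat": (12.87, 2.1),
        "slowly_perfused": (42.3, 2.06),
        "rapidly_perfused": (12.94, 2.18),
        "liver": (2.18, 2.08),
    },
    "flow": {
        "fat": (0.3, 2.3),
        "slowly_perfused": (0.81, 2.22),
        "rapidly_perfused": (3.98, 2.22),
        "liver": (1.12, 2.3),
    },
}

#: body weight LN(mean-of-log, SD-of-log) with bounds; CO normal in L/hr;
#: fractions are truncated normals (mean, SD, lo, hi)
ALLEN_PRIORS = {
    "body_weight": {"log_mean": math.log(67.77), "log_sd": math.log(1.603),
                    "bounds": (30.81, 139.9)},
    "cardiac_output_l_hr": {"mean": 20.0, "sd": 10.0, "bounds": (6.8, 33.2)},
    "volume_fractions": {
        "liver": (0.026, 0.013, 0.006, 0.046),
        "kidney": (0.004, 0.002, 0.0004, 0.008),
        "brain": (0.02, 0.01, 0.002, 0.038),
        "intestine": (0.014, 0.007, 0.001, 0.027),
        "gut": (0.017, 0.0085, 0.009, 0.025),
        "richly_perfused": (0.10, 0.05, 0.01, 0.190),
        "slowly_perfused": (0.35, 0.175, 0.18, 0.52),
        "adipose": (0.273, 0.14, 0.076, 0.47),
        "remainder": (0.122, 0.061, 0.012, 0.23),
    },
    "flow_fractions": {
        "liver": (0.046, 0.023, 0.01, 0.090),
        "kidney": (0.175, 0.0875, 0.018, 0.333),
        "brain": (0.114, 0.057, 0.011, 0.217),
        "gut": (0.181, 0.0905, 0.002, 0.360),
        "richly_perfused": (0.183, 0.0915, 0.018, 0.348),
        "slowly_perfused": (0.249, 0.1245, 0.025, 0.473),
        "adipose": (0.052, 0.0256, 0.0052, 0.099),
    },
}


def sohn_quantities() -> list[str]:
    """Column names of the four-compartment comparison (plus cardiac output)."""
    cols = [f"mass_{c}_kg" for c in SOHN_PRIORS["mass"]]
    cols += [f"flow_{c}_l_min" for c in SOHN_PRIORS["flow"]]
    cols.append("cardiac_output_l_min")
    return cols


def sample_sohn(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the four-compartment log-normal physiology prior.

    Each mass and flow is an independent LN(gm, gsd) draw; cardiac
    output is the sum of the four flows.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out: dict[str, np.ndarray] = {}
    for comp, (gm, gsd) in SOHN_PRIORS["mass"].items():
        out[f"mass_{comp}_kg"] = np.exp(rng.normal(math.log(gm), math.log(gsd), n))
    flows = {}
    for comp, (gm, gsd) in SOHN_PRIORS["flow"].items():
        flows[comp] = np.exp(rng.normal(math.log(gm), math.log(gsd), n))
        out[f"flow_{comp}_l_min"] = flows[comp]
    out["cardiac_output_l_min"] = sum(flows.values())
    return pd.DataFrame(out)


def sample_allen(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the bounded childbearing-age female physiology prior.

    Body weight from the bounded log-normal; cardiac output from the
    bounded normal (converted from L/hr to L/min); each tissue mass
    (flow) is its truncated-normal fraction times body weight (cardiac
    output).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    bw_spec = ALLEN_PRIORS["body_weight"]
    lo, hi = bw_spec["bounds"]
    log_bw = _truncnorm_draw(rng, np.full(n, bw_spec["log_mean"]),
                             bw_spec["log_sd"], math.log(lo), math.log(hi))
    bw = np.exp(log_bw)
    co_spec = ALLEN_PRIORS["cardiac_output_l_hr"]
    co_l_hr = _truncnorm_draw(rng, np.full(n, co_spec["mean"]), co_spec["sd"],
                              *co_spec["bounds"])
    co = co_l_hr / 60.0
    out = {"body_weight_kg": bw, "cardiac_output_l_min": co}
    for name, (mean, sd, flo, fhi) in ALLEN_PRIORS["volume_fractions"].items():
        frac = _truncnorm_draw(rng, np.full(n, mean), sd, flo, fhi)
        out[f"mass_{name}_kg"] = frac * bw
    for name, (mean, sd, flo, fhi) in ALLEN_PRIORS["flow_fractions"].items():
        frac = _truncnorm_draw(rng, np.full(n, mean), sd, flo, fhi)
        out[f"flow_{name}_l_min"] = frac * co
    return pd.DataFrame(out)


def reference_bounds(population, scheme: AggregationScheme = SOHN_SCHEME,
                     quantities: list[str] | None = None,
                     ) -> dict[str, tuple[float, float]]:
    """Absolute [min, max] per aggregated quantity over a reference population.

    ``population`` is a :class:`Population` (or its frame).  ``quantities``
    restricts the bound set (default: every compartment/pass-through mass
    and flow column plus cardiac output).
    """
    agg = aggregate_population(population, scheme)
    if quantities is None:
        quantities = [c for c in agg.columns
                      if c.startswith(("mass_", "flow_"))] + ["cardiac_output_l_min"]
    missing = [q for q in quantities if q not in agg.columns]
    if missing:
        raise KeyError(f"quantities not present in the aggregated population: {missing}")
    return {q: (float(agg[q].min()), float(agg[q].max())) for q in quantities}


def sohn_reference_bounds(key=("US", "male", "White"), n: int = 10_000,
                          rng: np.random.Generator | None = None,
                          seed=None) -> dict[str, tuple[float, float]]:
    """Bounds for the four-compartment screen from a fresh simulated reference population."""
    pop = simulate_population(key, n, seed=seed, rng=rng)
    return reference_bounds(pop, SOHN_SCHEME, quantities=sohn_quantities())


def screen(samples: pd.DataFrame,
           bounds: Mapping[str, tuple[float, float]]) -> float:
    """Fraction of sampled physiologies with every quantity inside its bounds."""
    missing = [q for q in bounds if q not in samples.columns]
    if missing:
        raise KeyError(f"samples lack screened quantities: {missing}")
    ok = np.ones(len(samples), dtype=bool)
    for q, (lo, hi) in bounds.items():
        v = samples[q].to_numpy()
        ok &= (v >= lo) & (v <= hi)
    return float(np.mean(ok))
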