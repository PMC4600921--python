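"""Population summary tables: median and central 95% interval per quantity.

Quantiles use the linear-interpolation definition (numpy's default);
at the population sizes used here the choice of quantile method is
immaterial at reporting precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aggregation import AggregationScheme, aggregate_population
from .organs import Population

__all__ = ["summarize"]

_QUANTITY_LABELS = {
    "body_mass_kg": "Body weight (kg)",
    "cardiac_output_l_min": "Cardiac output (L/min)",
}


def summarize(population, scheme: AggregationScheme | None = None) -> pd.DataFrame:
    """Median and 2.5/97.5 percentiles for every mass, flow and phase-1 quantity.

    ``population`` is a :class:`~physiopop.organs.Population` or a
    population frame; with ``scheme`` given, organs are lumped into its
    compartments first.  Returns a frame indexed by quantity with columns
    ``median``, ``p2.5``, ``p97.5``.
    """
    frame = population.frame if isinstance(population, Population) else population
    if len(frame) == 0:
        raise ValueError("population is empty")
    if scheme is not None:
        frame = aggregate_population(frame, scheme)
    quantities = [c for c in frame.columns
                  if c not in ("id",) and pd.api.types.is_numeric_dtype(frame[c])]
    rows = []
    for q in quantities:
        v = frame[q].to_numpy(dtype=float)
        lo, med, hi = np.percentile(v, [2.5, 50.0, 97.5])
        rows.append((q, med, lo, hi))
    out = pd.DataFrame(rows, columns=["quantity", "median", "p2.5", "p97.5"])
    return out.set_index("quantity")
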