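"""Phenotype-level metrics: soluble-sugar degradation and qPCR expression.

Soluble-sugar contents are in mg per g fresh weight at 0, 8 and 72 h
postharvest.  The mapping trait is the 0->72 h reduction; a negative
reduction means the line *gained* soluble sugar during storage (observed in
some lines through starch remobilisation).  Reported metrics are rounded to
2 decimal places with round-half-even.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def sugar_reduction(c0: float, c72: float) -> float:
    """Soluble-sugar reduction over storage, c0 - c72 (mg/g; may be negative)."""
    return c0 - c72


def percent_decrease(c0: float, c72: float) -> float:
    """Percent decrease 100*(c0 - c72)/c0, 2 dp.  Requires c0 > 0."""
    if c0 <= 0:
        raise ValueError("percent decrease undefined for non-positive initial content")
    return round(100.0 * (c0 - c72) / c0, 2)


def population_summary(records: pd.DataFrame) -> dict[str, float]:
    """Population means and range of the degradation trait.

    ``records`` needs columns sugar_0h and sugar_72h (one row per line).
    Returns mean 0 h content, mean reduction, and the min/max reduction.
    """
    if len(records) == 0:
        raise ValueError("no phenotype records")
    reduction = records["sugar_0h"] - records["sugar_72h"]
    return {
        "mean_sugar_0h": round(float(records["sugar_0h"].mean()), 2),
        "mean_reduction": round(float(reduction.mean()), 2),
        "min_reduction": round(float(reduction.min()), 2),
        "max_reduction": round(float(reduction.max()), 2),
    }


def relative_expression(ct_target, ct_reference):
    """Relative qPCR expression by the 2^-dCT method against the reference
    gene; strictly decreasing in the target CT."""
    return 2.0 ** -(np.asarray(ct_target, dtype=float)
                    - np.asarray(ct_reference, dtype=float))
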