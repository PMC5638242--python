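"""Differential-expression selection and sink weighting.

Genes pass when all four filters hold: q-value below 0.05, fold change (in
whichever direction) above 1.5, at least 0.1 FPKM in one condition, and an
absolute FPKM difference of at least 1 (guarding against artificially high
fold changes at trace expression). Selected genes become flow sinks with
capacity |log2 fold change|.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .screens import InputNode

Q_MAX = 0.05
FC_MIN = 1.5
FPKM_FLOOR = 0.1
DELTA_FPKM_MIN = 1.0
MAX_CAPACITY = 10.0


def select_de_genes(
    table: pd.DataFrame,
    q_max: float = Q_MAX,
    fc_min: float = FC_MIN,
    fpkm_floor: float = FPKM_FLOOR,
    delta_fpkm_min: float = DELTA_FPKM_MIN,
    log_base: float = 2.0,
    max_capacity: float = MAX_CAPACITY,
) -> list[InputNode]:
    """Apply the four DE filters and weight genes by |log fold change|.

    Fold change is recomputed from the two FPKM columns. A zero on one side
    gives an infinite fold change that passes the FC filter via the other
    side; its capacity is capped at ``max_capacity`` to keep sink capacities
    bounded. Rows with zero FPKM in both conditions are skipped with a
    warning (fold change undefined).
    """
    nodes = []
    for _, row in table.iterrows():
        a, b, q = float(row["fpkm_a"]), float(row["fpkm_b"]), float(row["q_value"])
        if a == 0.0 and b == 0.0:
            warnings.warn(f"gene {row['gene']}: zero FPKM in both conditions; skipped")
            continue
        if q >= q_max:
            continue
        if max(a, b) < fpkm_floor:
            continue
        if abs(b - a) < delta_fpkm_min:
            continue
        fc = np.inf if (a == 0.0 or b == 0.0) else max(b / a, a / b)
        if fc <= fc_min:
            continue
        if np.isinf(fc):
            capacity = max_capacity
        else:
            capacity = min(abs(np.log(b / a) / np.log(log_base)), max_capacity)
        direction = "up" if b > a else "down"
        nodes.append(InputNode(str(row["gene"]).upper(), "expression", capacity, direction))
    return sorted(nodes, key=lambda n: n.name)
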