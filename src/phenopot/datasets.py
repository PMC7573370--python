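"""Bundled example data.

``lettuce_dynamic_traits`` returns published-style dynamic-trait summaries
for three greenhouse lettuce varieties (L1048, L454, N648): growth rates
(GR-) and accumulation rates (AC-) of the eight geometric and seven color
static traits over a 34-day vegetative window.  Useful as a compact input
for the rank statistics and as the worked example in the docs.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["lettuce_dynamic_traits"]

_VARIETIES = ["L1048", "L454", "N648"]

_GEOMETRIC = {
    "GR-PA": [22.63, 21.85, 19.26],
    "AC-PA": [310.02, 452.27, 388.88],
    "GR-PP": [2.33, 1.67, 1.93],
    "AC-PP": [88.32, 114.91, 110.60],
    "GR-CA": [22.70, 21.13, 19.94],
    "AC-CA": [356.13, 523.03, 471.48],
    "GR-CP": [2.30, 1.90, 1.81],
    "AC-CP": [62.45, 80.78, 76.82],
    "GR-PAR": [0.02, 0.02, 0.02],
    "AC-PAR": [0.62, 0.65, 0.61],
    "GR-CAR": [0.01, 0.01, 0.01],
    "AC-CAR": [0.81, 0.79, 0.77],
    "GR-AXL": [0.69, 0.57, 0.46],
    "AC-AXL": [20.29, 25.74, 23.84],
    "GR-AXS": [22.63, 21.85, 19.26],
    "AC-AXS": [310.02, 452.27, 388.88],
}

_COLOR = {
    "GR-R": [0.65, 0.33, 0.80],
    "AC-R": [81, 66, 90],
    "GR-G": [0.88, 0.57, 1.22],
    "AC-G": [84, 89, 112],
    "GR-B": [0.18, 0.12, 0.32],
    "AC-B": [51, 54, 58],
    "GR-H": [0.12, -0.03, 0.05],
    "AC-H": [32, 49, 42],
    "GR-S": [1.08, 0.81, 0.74],
    "AC-S": [100, 99, 121],
    "GR-V": [0.87, 0.56, 1.22],
    "AC-V": [85, 89, 112],
    "GR-ExG": [0.03, 0.02, 0.03],
    "AC-ExG": [0.07, 0.17, 0.56],
}


def lettuce_dynamic_traits() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(geometric, color) dynamic-trait tables, indexed by variety.

    For the variety-comparison Friedman test, blocks are the GR-/AC- trait
    columns and treatments the three varieties, i.e. pass ``df.T``.
    """
    geo = pd.DataFrame(_GEOMETRIC, index=_VARIETIES, dtype=float)
    col = pd.DataFrame(_COLOR, index=_VARIETIES, dtype=float)
    return geo, col
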