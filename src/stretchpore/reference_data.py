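"""Reference results of the atomistic unsteady-stretching study.

Condition-level summaries (replicate counts, critical-strain mean and SD,
multi-pore rate) for the pure DPPC ("pure", labels PD*) and DPPC + 40 mol%
cholesterol ("chol40", labels DC*) bilayers at seven stretching speeds, plus the quasistatic outcomes and the equilibrium bilayer areas.
These are the published inputs the statistical layer and the worked
examples operate on; they are data, not values this package computes.
"""

from __future__ import annotations

import pandas as pd

#: equilibrium bilayer areas at 323 K / 1 bar, nm^2
EQUILIBRIUM_AREA_NM2 = {"pure": 41.98, "chol40": 41.84}

#: condition-level summary of the unsteady-stretching replicates
US_SUMMARY = pd.DataFrame(
    [
        ("DC0.025", "chol40", 0.025, 3, 1.43, 0.04, 0.00),
        ("DC0.05", "chol40", 0.05, 5, 1.57, 0.12, 0.00),
        ("DC0.30", "chol40", 0.30, 6, 1.66, 0.18, 0.00),
        ("DC1.00", "chol40", 1.00, 20, 1.57, 0.18, 0.20),
        ("DC3.00", "chol40", 3.00, 20, 1.56, 0.23, 0.65),
        ("DC10.0", "chol40", 10.0, 20, 1.67, 0.22, 0.90),
        ("DC30.0", "chol40", 30.0, 20, 1.87, 0.33, 1.00),
        ("PD0.025", "pure", 0.025, 3, 0.91, 0.04, 0.00),
        ("PD0.05", "pure", 0.05, 5, 0.88, 0.08, 0.00),
        ("PD0.30", "pure", 0.30, 6, 1.05, 0.10, 0.50),
        ("PD1.00", "pure", 1.00, 20, 1.14, 0.12, 0.55),
        ("PD3.00", "pure", 3.00, 20, 1.24, 0.15, 0.85),
        ("PD10.0", "pure", 10.0, 20, 1.37, 0.15, 0.95),
        ("PD30.0", "pure", 30.0, 20, 1.48, 0.14, 1.00),
    ],
    columns=["label", "composition", "speed", "n", "mean", "sd", "multipore_rate"],
)

#: quasistatic outcomes: triplicates at discrete strains, pore formed or not
QS_OUTCOMES = {
    "chol40": [(1.20, False)] * 3 + [(1.40, True)] * 3,
    "pure": [(0.60, False)] * 3 + [(0.80, True)] * 3,
}

#: typical reference membrane areas in cell-scale experiments, um^2
EXPERIMENT_AREA_UM2 = (100.0, 1000.0)
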