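"""Shared categorical vocabularies and numeric bounds."""

from __future__ import annotations

# Falls history / within-cycle fall outcome categories. "MA" = a fall
# requiring medical attention; MA falls subdivide into hospitalised and
# non-hospitalised at event time.
FALL_CATEGORIES: tuple[str, ...] = (
    "none",
    "single_non_ma",
    "recurrent_non_ma",
    "single_ma",
    "recurrent_ma",
)

SEXES: tuple[str, str] = ("male", "female")

# Cumulative-deficit frailty severity categories, ordered.
FRAILTY_CATEGORIES: tuple[str, ...] = ("Fit", "Mild", "Moderate", "Severe")

# Category cutoffs on the 0-1 index scale (50th/85th/97th percentiles of the
# source cohort): 0-0.10 Fit, >0.10-0.23 Mild, >0.23-0.37 Moderate, >0.37 Severe.
DEFAULT_CUTOFFS: tuple[float, float, float] = (0.10, 0.23, 0.37)

# Seven contiguous age bands from 60; the last band is open-ended.
DEFAULT_AGE_BAND_EDGES: tuple[float, ...] = (60.0, 65.0, 70.0, 75.0, 80.0, 85.0, 90.0)
N_AGE_BANDS = 7

# EQ-5D-3L UK tariff bounds: worst describable state values -0.594.
EQ5D_FLOOR = -0.594
EQ5D_CEILING = 1.0

# SES quartiles: 1 most privileged ... 4 most deprived.
SES_QUARTILES: tuple[int, ...] = (1, 2, 3, 4)

N_FRAILTY_ITEMS = 52
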