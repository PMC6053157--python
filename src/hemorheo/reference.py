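"""Reference shear-thinning parameter sets for low-hematocrit human blood.

Published fitted parameters for RBC suspensions at 5, 10 and 15%
hematocrit measured in a microfluidic optical viscometer, at room
(23 °C) and body (37 °C) temperature.  Power-law entries are (K, n)
with K in cP·s^(n−1) on the apparent-viscosity scale; Carreau entries
are (μ0, μ∞, λ, n) with viscosities in cP, λ in s and the
Carreau-Yasuda shape parameter fixed at a = 2.

These rows serve as generating truths for round-trip fitting tests and
as realistic defaults for the synthetic viscosity-curve generator.
"""

from dataclasses import dataclass
from typing import Dict, Tuple

__all__ = [
    "PowerLawParams", "CarreauParams",
    "POWER_LAW_23C", "CARREAU_23C", "POWER_LAW_37C", "CARREAU_37C",
]


@dataclass(frozen=True)
class PowerLawParams:
    K: float          # consistency index, cP·s^(n-1)
    n: float          # behaviour index (dimensionless)


@dataclass(frozen=True)
class CarreauParams:
    mu_zero: float    # zero-shear viscosity, cP
    mu_inf: float     # infinite-shear viscosity, cP
    lam: float        # relaxation time, s
    n: float          # power-law index (dimensionless)
    a: float = 2.0    # Carreau-Yasuda shape parameter


# hematocrit (%) -> parameters, apparent viscosity at 23 °C
POWER_LAW_23C: Dict[int, PowerLawParams] = {
    5: PowerLawParams(9.9, 0.603),
    10: PowerLawParams(50.9, 0.156),
    15: PowerLawParams(62.2, 0.197),
}

CARREAU_23C: Dict[int, CarreauParams] = {
    5: CarreauParams(26.9, 1.6, 3.313, 0.353),
    10: CarreauParams(89.9, 1.6, 3.312, 0.369),
    15: CarreauParams(118.6, 2.3, 3.312, 0.362),
}

# hematocrit (%) -> parameters, apparent viscosity at 37 °C
POWER_LAW_37C: Dict[int, PowerLawParams] = {
    5: PowerLawParams(9.3, 0.660),
    10: PowerLawParams(10.8, 0.680),
    15: PowerLawParams(17.1, 0.568),
}

CARREAU_37C: Dict[int, CarreauParams] = {
    5: CarreauParams(23.3, 2.0, 3.313, 0.352),
    10: CarreauParams(26.4, 2.6, 3.312, 0.353),
    15: CarreauParams(139.5, 4.2, 3.314, -0.152),
}
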