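"""Growth media as exchange-reaction uptake bounds.

A medium is a mapping exchange-reaction id -> lower bound (negative flux =
uptake, so a lower bound of -1000 means effectively unlimited uptake and 0
means the compound is absent). The module also carries the M9 minimal-media
composition used throughout: trace ions opened at -1000, cob(I)alamin
capped at -0.01, glucose at -20 as default carbon source, ammonium,
phosphate and sulfate at -1000 as default N/P/S sources, and O2 at -20
(aerobic conditions).
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterator, Mapping

from .model import Model

__all__ = [
    "MediaDefinition",
    "m9_base",
    "ION_LB",
    "COBALAMIN_LB",
    "GLC_LB",
    "NH4_LB",
    "PI_LB",
    "SO4_LB",
    "O2_LB",
    "M9_ION_EXCHANGES",
    "DEFAULT_SOURCES",
    "CLASS_BOUNDS",
]

ION_LB = -1000.0
COBALAMIN_LB = -0.01
GLC_LB = -20.0
NH4_LB = -1000.0
PI_LB = -1000.0
SO4_LB = -1000.0
O2_LB = -20.0

# Trace-ion exchanges opened without limit in M9: Ca2+, Cl-, CO2, Co2+, Cu2+,
# Fe2+, Fe3+, H+, H2O, K+, Mg2+, Mn2+, molybdate, Na+, Ni2+, selenate,
# selenite, Zn2+ (BiGG identifiers).
M9_ION_EXCHANGES = (
    "EX_ca2_e",
    "EX_cl_e",
    "EX_co2_e",
    "EX_cobalt2_e",
    "EX_cu2_e",
    "EX_fe2_e",
    "EX_fe3_e",
    "EX_h_e",
    "EX_h2o_e",
    "EX_k_e",
    "EX_mg2_e",
    "EX_mn2_e",
    "EX_mobd_e",
    "EX_na1_e",
    "EX_ni2_e",
    "EX_sel_e",
    "EX_slnt_e",
    "EX_zn2_e",
)

COBALAMIN_EXCHANGE = "EX_cbl1_e"
O2_EXCHANGE = "EX_o2_e"

# default single source per element class and the uptake bound applied to a
# candidate of that class in a sole-source condition
DEFAULT_SOURCES: Dict[str, str] = {
    "carbon": "EX_glc__D_e",
    "nitrogen": "EX_nh4_e",
    "phosphorus": "EX_pi_e",
    "sulfur": "EX_so4_e",
}
CLASS_BOUNDS: Dict[str, float] = {
    "carbon": GLC_LB,
    "nitrogen": NH4_LB,
    "phosphorus": PI_LB,
    "sulfur": SO4_LB,
}


class MediaDefinition(Mapping[str, float]):
    """Immutable-ish mapping of exchange id -> uptake lower bound (<= 0)."""

    def __init__(self, bounds: Mapping[str, float], name: str = ""):
        for ex, lb in bounds.items():
            if lb > 0:
                raise ValueError(
                    f"medium {name or '<unnamed>'}: lower bound for {ex} is {lb} > 0"
                )
        self._bounds = dict(bounds)
        self.name = name

    def __getitem__(self, key: str) -> float:
        return self._bounds[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._bounds)

    def __len__(self) -> int:
        return len(self._bounds)

    def __repr__(self):  # pragma: no cover
        nz = sum(1 for v in self._bounds.values() if v != 0)
        return f"<MediaDefinition {self.name or '<unnamed>'}: {nz} open uptakes>"

    def updated(self, changes: Mapping[str, float], name: str = "") -> "MediaDefinition":
        out = dict(self._bounds)
        out.update(changes)
        return MediaDefinition(out, name or self.name)

    def nonzero(self) -> Dict[str, float]:
        return {k: v for k, v in self._bounds.items() if v != 0}


def m9_base(model: Model, glucose: bool = True, name: str = "M9") -> MediaDefinition:
    """M9 minimal medium for a model, aerobic, glucose as carbon source.

    Only exchanges the model actually declares are included; a missing ion
    exchange is warned about and skipped. All other exchanges of the model
    get a lower bound of 0 (no uptake).
    """
    wanted: Dict[str, float] = {ex: ION_LB for ex in M9_ION_EXCHANGES}
    wanted[COBALAMIN_EXCHANGE] = COBALAMIN_LB
    wanted[O2_EXCHANGE] = O2_LB
    wanted[DEFAULT_SOURCES["nitrogen"]] = NH4_LB
    wanted[DEFAULT_SOURCES["phosphorus"]] = PI_LB
    wanted[DEFAULT_SOURCES["sulfur"]] = SO4_LB
    if glucose:
        wanted[DEFAULT_SOURCES["carbon"]] = GLC_LB

    model_exchanges = {r.id for r in model.exchanges}
    bounds: Dict[str, float] = {ex: 0.0 for ex in model_exchanges}
    for ex, lb in wanted.items():
        if ex in model_exchanges:
            bounds[ex] = lb
        else:
            warnings.warn(
                f"model {model.id!r} lacks exchange {ex}; omitted from {name}",
                stacklevel=2,
            )
    return MediaDefinition(bounds, name=name)
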