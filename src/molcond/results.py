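"""Result containers shared by the full and approximate conductance paths."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import E2_OVER_H_S, S_TO_NS

#: e²/h expressed in nS, the conversion between the two reporting units.
_E2H_NS = E2_OVER_H_S * S_TO_NS


@dataclass
class ConductanceResult:
    """Linear-response conductance with optional mechanism decomposition.

    Conductances are reported both in nS and in units of e²/h.  The
    three-mechanism path additionally stores each component and its log10
    (in nS), which stays meaningful when the linear value underflows at
    cryogenic temperatures.
    """

    G_e2h: float
    method: str = "full"
    G_LB_e2h: Optional[float] = None
    G_T_e2h: Optional[float] = None
    G_M_e2h: Optional[float] = None
    T: Optional[float] = None
    T_L: Optional[float] = None
    T_R: Optional[float] = None
    Z_L: Optional[float] = None
    Z_R: Optional[float] = None
    log10_G_nS: Optional[float] = None
    log10_G_LB_nS: Optional[float] = None
    log10_G_T_nS: Optional[float] = None
    log10_G_M_nS: Optional[float] = None
    params: dict = field(default_factory=dict)

    @property
    def G_nS(self) -> float:
        return self.G_e2h * _E2H_NS

    @property
    def G_LB_nS(self) -> Optional[float]:
        return None if self.G_LB_e2h is None else self.G_LB_e2h * _E2H_NS

    @property
    def G_T_nS(self) -> Optional[float]:
        return None if self.G_T_e2h is None else self.G_T_e2h * _E2H_NS

    @property
    def G_M_nS(self) -> Optional[float]:
        return None if self.G_M_e2h is None else self.G_M_e2h * _E2H_NS

    def as_dict(self) -> dict:
        out = {"G_nS": self.G_nS, "G_e2h": self.G_e2h, "method": self.method}
        for name in ("G_LB", "G_T", "G_M"):
            v = getattr(self, f"{name}_e2h")
            if v is not None:
                out[f"{name}_nS"] = v * _E2H_NS
                out[f"{name}_e2h"] = v
        for name in ("T", "T_L", "T_R", "Z_L", "Z_R",
                     "log10_G_nS", "log10_G_LB_nS", "log10_G_T_nS", "log10_G_M_nS"):
            v = getattr(self, name)
            if v is not None:
                out[name] = float(v) if np.isfinite(v) else None
        out["parameters"] = self.params
        return out
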