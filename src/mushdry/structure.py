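"""Shrinkage and porosity evolution from the empirical gas/solid volume law.

During drying the hyphal solid shrinks ideally with water loss while the gas
fraction follows an empirical two-branch fit of the air/solid volume ratio
against moisture content (dry basis): an exponential branch below X* = 0.95
and a linear branch above it.  The printed branches do not meet at X*
(jump of about 0.19); by default they are evaluated exactly as fitted, with an
optional linear blend over [0.90, 1.00] for solver smoothness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import StructureConfig

__all__ = ["ShrinkageModel", "gas_solid_ratio", "volumes"]


@dataclass
class ShrinkageModel:
    config: StructureConfig = field(default_factory=StructureConfig)

    def gas_solid_ratio(self, x_m):
        """V_air / V_solid at moisture X_m (dry basis).

        Exponential branch a*exp(-b*X) + c below the switch, linear branch
        m*X + k above; the boundary point itself uses the linear branch.
        """
        c = self.config
        x = np.asarray(x_m, dtype=float)
        if np.any(x < 0):
            raise ValueError("moisture content must be non-negative")
        r_exp = c.exp_a * np.exp(-c.exp_b * x) + c.exp_c
        r_lin = c.lin_m * x + c.lin_k
        if c.blend:
            w = np.clip((x - c.blend_lo) / (c.blend_hi - c.blend_lo), 0.0, 1.0)
            out = (1.0 - w) * r_exp + w * r_lin
        else:
            out = np.where(x < c.x_switch, r_exp, r_lin)
        if out.ndim == 0:
            return float(out)
        return out

    def volumes(self, x_m):
        """Volume ratio and phase fractions at moisture X_m.

        Returns (V_mushroom/V_solid, phi_air, phi_w, phi_s); fractions sum to
        one exactly by construction.
        """
        c = self.config
        x = np.asarray(x_m, dtype=float)
        ratio_air = self.gas_solid_ratio(x)
        v_ratio = ratio_air + 1.0 + x * c.rho_solid / c.rho_water
        phi_s = 1.0 / v_ratio
        phi_air = ratio_air / v_ratio
        phi_w = 1.0 - phi_air - phi_s
        if np.ndim(x) == 0:
            return float(v_ratio), float(phi_air), float(phi_w), float(phi_s)
        return v_ratio, phi_air, phi_w, phi_s


def gas_solid_ratio(x_m, config: StructureConfig | None = None):
    """V_air/V_solid at moisture X_m (dry basis) with default coefficients."""
    return ShrinkageModel(config or StructureConfig()).gas_solid_ratio(x_m)


def volumes(x_m, config: StructureConfig | None = None):
    """(V_mushroom/V_solid, phi_air, phi_w, phi_s) at moisture X_m."""
    return ShrinkageModel(config or StructureConfig()).volumes(x_m)
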