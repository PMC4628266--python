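"""Effective oxygen diffusivity of parenchyma tissue.

The tissue is modelled as a harmonic (series) combination of two
pathways, weighted by the fraction w of the diffusion path that runs
through the connected pore network:

    D_eff = 1 / ( w / D_par + (1 - w) / D_ser )

* D_par = eps * D_air / tau^2 is the classical parallel porous-medium
  term: diffusion through the connected air channels, reduced by
  porosity eps and the square of the pore tortuosity tau (the measured
  void shape factor serves as a fair tortuosity estimate).
* D_ser is a Maxwell-Eucken effective diffusivity of air voids
  dispersed in a continuous matrix of cells, representing the serial
  pathway across cells between disconnected pores.  The cell phase
  diffusivity is that of water scaled by the dimensionless oxygen
  solubility R*T*H (Henry partitioning between air and cell sap).

Because the voids conduct ~10^5 times better than cells, even a few
percent of serial pathway (w slightly below 1) collapses D_eff by
orders of magnitude, which is why measured tissue diffusivities are far
below parallel-model predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "GasConstants",
    "DiffusivityResult",
    "cellular_diffusivity",
    "parallel_model",
    "maxwell_eucken_serial",
    "combined_model",
    "estimate_w",
]


@dataclass(frozen=True)
class GasConstants:
    """Physical constants of oxygen transport.

    D_air, D_water in m^2 s^-1; H in mol m^-3 kPa^-1; R in
    J mol^-1 K^-1; T in K.  Defaults are standard values near 25 C.
    """

    D_air: float = 2.15e-5
    D_water: float = 2.75e-9
    H: float = 0.0137
    R: float = 8.314
    T: float = 298.15

    def __post_init__(self) -> None:
        for name in ("D_air", "D_water", "H", "R", "T"):
            if getattr(self, name) <= 0:
                if name == "D_water" and self.D_water == 0:
                    continue  # allow the degenerate no-transport limit
                raise ValueError(f"{name} must be positive")
        if self.D_air <= self.D_water:
            raise ValueError("D_air must exceed D_water")

    @property
    def solubility(self) -> float:
        """Dimensionless air/cell-sap capacity ratio R*T*H.

        H is per kPa while R*T is in Pa m^3 mol^-1, hence the factor
        1e-3 to bring both to the same pressure unit.
        """
        return self.R * self.T * self.H * 1e-3


@dataclass
class DiffusivityResult:
    """All intermediate and final quantities of the combined model (m^2/s)."""

    D_cell: float
    D_par: float
    D_ser: float
    D_eff: float
    epsilon: float
    tau: float
    w: float


def cellular_diffusivity(c: GasConstants = GasConstants()) -> float:
    """Oxygen diffusivity of the cell phase: D_water * R * T * H.

    The water diffusivity is scaled by the dimensionless solubility so
    that fluxes are expressed per gas-phase concentration gradient;
    with default constants this is 9.3e-11 m^2/s.
    """
    return c.D_water * c.solubility


def parallel_model(epsilon: float, tau: float, c: GasConstants = GasConstants()) -> float:
    """Parallel porous-medium diffusivity eps * D_air / tau^2."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("porosity must lie in [0, 1]")
    if tau < 1.0:
        warnings.warn(f"tortuosity {tau} < 1 is unphysical")
    return epsilon * c.D_air / tau**2


def maxwell_eucken_serial(epsilon: float, c: GasConstants = GasConstants()) -> float:
    """Maxwell-Eucken diffusivity of air voids dispersed in a cell matrix.

    D_c * [2 D_c + D_a - 2 eps (D_c - D_a)] / [2 D_c + D_a + eps (D_c - D_a)]
    with D_c the cellular and D_a the air diffusivity.  Valid for
    0 <= eps < 1; at eps = 1 there is no continuous cell matrix.
    """
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("Maxwell-Eucken requires 0 <= porosity < 1")
    d_c = cellular_diffusivity(c)
    d_a = c.D_air
    return d_c * (2 * d_c + d_a - 2 * epsilon * (d_c - d_a)) / (
        2 * d_c + d_a + epsilon * (d_c - d_a)
    )


def combined_model(
    epsilon: float, tau: float, w: float, c: GasConstants = GasConstants()
) -> DiffusivityResult:
    """Weighted harmonic combination of the parallel and serial pathways.

    w = 1 recovers the parallel model, w = 0 the Maxwell-Eucken serial
    model; D_eff is continuous and monotone in w between the two.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    d_par = parallel_model(epsilon, tau, c)
    d_ser = maxwell_eucken_serial(epsilon, c)
    if w == 1.0:
        d_eff = d_par
    elif w == 0.0:
        d_eff = d_ser
    else:
        d_eff = 1.0 / (w / d_par + (1.0 - w) / d_ser)
    return DiffusivityResult(
        D_cell=cellular_diffusivity(c),
        D_par=d_par,
        D_ser=d_ser,
        D_eff=d_eff,
        epsilon=epsilon,
        tau=tau,
        w=w,
    )


def estimate_w(
    D_measured: float, epsilon: float, tau: float, c: GasConstants = GasConstants()
) -> float:
    """Invert the combined model for the weighing factor w.

    w = (1/D_ser - 1/D_measured) / (1/D_ser - 1/D_par).  A measured
    diffusivity outside the open interval (D_ser, D_par) is clipped to
    [0, 1] with a warning.
    """
    d_par = parallel_model(epsilon, tau, c)
    d_ser = maxwell_eucken_serial(epsilon, c)
    w = (1.0 / d_ser - 1.0 / D_measured) / (1.0 / d_ser - 1.0 / d_par)
    if not 0.0 <= w <= 1.0:
        warnings.warn(
            f"measured diffusivity {D_measured} outside ({d_ser:.3g}, {d_par:.3g}); clipping w"
        )
        w = min(max(w, 0.0), 1.0)
    return float(w)
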