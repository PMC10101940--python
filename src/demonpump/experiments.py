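"""Parameter sweeps mapping physiology to the model's two effective forces.

Maps nucleotide concentrations to the stream bias ``delta`` and ion
concentrations to the gradient bias ``epsilon``, then tabulates the
steady-state flux ``Phi``, the tape entropy change and the operating
regime over grids emulating the classic flux experiments on the sodium
pump: ouabain-sensitive Na efflux falls as intracellular ADP rises (at
fixed ATP) and as extracellular Na rises (at fixed ATP/ADP ratio).

All sweep output is long-format with the fixed column order
``variable, value, curve, epsilon, phi, delta_S, regime``.
"""

from __future__ import annotations

from collections.abc import Sequence

import pandas as pd

from .model_core import (
    DomainError,
    PumpParameters,
    classify_regime,
    delta_S,
    epsilon,
    phi_analytic,
)

__all__ = [
    "SWEEP_COLUMNS",
    "excess_from_concentrations",
    "sweep_adp",
    "sweep_external_na",
    "phase_diagram",
]

SWEEP_COLUMNS = ["variable", "value", "curve", "epsilon", "phi", "delta_S", "regime"]

#: Demo grid defaults: ADP 0-3000 uM at 2 mM ATP, inner/outer Na ratios 0.0-0.9.
DEFAULT_ATP_UM = 2000.0
DEFAULT_ADP_GRID_UM = tuple(float(v) for v in range(0, 3001, 250))
DEFAULT_RATIO_GRID = tuple(round(0.1 * i, 1) for i in range(10))


def excess_from_concentrations(atp_conc: float, adp_conc: float) -> float:
    """ATP excess ``delta = (ATP - ADP)/(ATP + ADP)`` from pool concentrations."""
    if atp_conc < 0 or adp_conc < 0:
        raise DomainError("concentrations must be nonnegative")
    total = atp_conc + adp_conc
    if total <= 0:
        raise DomainError("atp_conc + adp_conc must be positive")
    return (atp_conc - adp_conc) / total


def _row(variable: str, value: float, curve: str, p: PumpParameters) -> tuple:
    return (
        variable,
        value,
        curve,
        epsilon(p),
        phi_analytic(p),
        delta_S(p),
        classify_regime(p).label,
    )


def sweep_adp(
    k_h: float,
    k_l: float,
    C_h: float,
    atp_conc: float = DEFAULT_ATP_UM,
    adp_grid: Sequence[float] = DEFAULT_ADP_GRID_UM,
    ratio_grid: Sequence[float] = DEFAULT_RATIO_GRID,
) -> pd.DataFrame:
    """Flux vs. intracellular ADP at fixed ATP, one curve per C_l/C_h ratio.

    Raising ADP lowers ``delta``, so each curve is strictly decreasing; the
    ratio-0 curve (empty inner reservoir, ``epsilon = 1``) is nonpositive
    throughout.
    """
    if not len(adp_grid) or not len(ratio_grid):
        raise DomainError("adp_grid and ratio_grid must be nonempty")
    rows = []
    for ratio in ratio_grid:
        if not 0.0 <= ratio < 1.0:
            raise DomainError(f"ratio {ratio} outside [0, 1)")
        curve = f"ratio={ratio:g}"
        for adp in adp_grid:
            delta = excess_from_concentrations(atp_conc, adp)
            p = PumpParameters(delta=delta, k_h=k_h, k_l=k_l, C_h=C_h, C_l=ratio * C_h)
            rows.append(_row("adp_uM", float(adp), curve, p))
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def sweep_external_na(
    k_h: float,
    k_l: float,
    C_l: float,
    ch_grid: Sequence[float],
    delta_grid: Sequence[float],
) -> pd.DataFrame:
    """Flux vs. extracellular Na, one curve per nucleotide bias delta.

    Raising ``C_h`` raises ``epsilon``, so each curve decreases; a curve
    crosses zero where the gradient bias catches up with its delta.
    """
    if not len(ch_grid) or not len(delta_grid):
        raise DomainError("ch_grid and delta_grid must be nonempty")
    rows = []
    for delta in delta_grid:
        curve = f"delta={delta:g}"
        for ch in ch_grid:
            if ch <= C_l:
                raise DomainError(f"C_h {ch} must exceed C_l {C_l}")
            p = PumpParameters(delta=delta, k_h=k_h, k_l=k_l, C_h=ch, C_l=C_l)
            rows.append(_row("c_h", float(ch), curve, p))
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def phase_diagram(
    delta_grid: Sequence[float],
    k_h: float,
    k_l: float,
    C_h: float,
    cl_grid: Sequence[float],
) -> pd.DataFrame:
    """Regime map over the (delta, C_l) plane.

    The pump/eraser boundary is the stall curve ``delta = epsilon(C_l)``;
    each row carries the regime label plus Phi and the tape entropy change.
    """
    if not len(delta_grid) or not len(cl_grid):
        raise DomainError("delta_grid and cl_grid must be nonempty")
    rows = []
    for cl in cl_grid:
        curve = f"C_l={cl:g}"
        for delta in delta_grid:
            p = PumpParameters(delta=delta, k_h=k_h, k_l=k_l, C_h=C_h, C_l=cl)
            rows.append(_row("delta", float(delta), curve, p))
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)
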