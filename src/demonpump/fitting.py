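"""Synthetic flux experiments and kinetic parameter recovery.

Emulates the resealed-ghost flux measurements: ouabain-sensitive Na efflux
(per hour) observed along an intracellular-ADP sweep at fixed ATP and an
extracellular-Na sweep at fixed ATP/ADP ratio.  Observations follow the
model ``flux = A * Phi(k_h, k_l; design point)`` plus additive Gaussian
noise; the scale factor ``A`` (h^-1 per interaction fraction) absorbs the
unknown interaction frequency that converts the dimensionless per-interval
transfer fraction into a macroscopic rate.

Only ``(k_h, k_l, A)`` are fitted -- nucleotide levels and ion
concentrations are experimental knobs, known by design.  ``k_h`` and
``k_l`` enter the gradient bias symmetrically (through their product) but
the efficiency factor separately, so a design must combine both sweep
types to separate them; `combined_design` builds such a design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .experiments import excess_from_concentrations
from .model_core import DomainError, PumpParameters, phi_analytic

__all__ = [
    "DATASET_COLUMNS",
    "FluxDataset",
    "FitResult",
    "combined_design",
    "generate_synthetic_flux",
    "fit_flux_model",
]

DATASET_COLUMNS = ["variable", "value", "atp_uM", "adp_uM", "c_h", "c_l", "flux", "flux_sd"]


@dataclass
class FluxDataset:
    """Design matrix plus observed fluxes for one synthetic experiment.

    ``design`` holds one row per measurement with columns
    ``variable, value, atp_uM, adp_uM, c_h, c_l``; ``observed_flux`` is in
    h^-1.  ``true_params`` records the generating ``(k_h, k_l, scale)``
    when known (synthetic data only).
    """

    design: pd.DataFrame
    observed_flux: np.ndarray
    noise_sd: float
    seed: int
    true_params: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if len(self.design) < 4:
            raise DomainError("design: need at least 4 design points")
        if self.noise_sd <= 0:
            raise DomainError("noise_sd: must be positive")
        if len(self.observed_flux) != len(self.design):
            raise DomainError("observed_flux length does not match design")

    def to_frame(self) -> pd.DataFrame:
        df = self.design.copy()
        df["flux"] = self.observed_flux
        df["flux_sd"] = self.noise_sd
        return df[DATASET_COLUMNS]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, *, seed: int = 0) -> "FluxDataset":
        df = pd.read_csv(path)
        missing = set(DATASET_COLUMNS) - set(df.columns)
        if missing:
            raise DomainError(f"dataset CSV missing columns: {sorted(missing)}")
        return cls(
            design=df[DATASET_COLUMNS[:6]].copy(),
            observed_flux=df["flux"].to_numpy(dtype=float),
            noise_sd=float(df["flux_sd"].iloc[0]),
            seed=seed,
        )


@dataclass
class FitResult:
    """Recovered kinetic parameters from bounded nonlinear least squares."""

    k_h_hat: float
    k_l_hat: float
    scale_hat: float
    residual_sum_of_squares: float
    converged: bool
    bounds: tuple[float, float]
    n_starts: int
    poor_fit: bool = False
    start_costs: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "k_h_hat": self.k_h_hat,
            "k_l_hat": self.k_l_hat,
            "scale_hat": self.scale_hat,
            "residual_sum_of_squares": self.residual_sum_of_squares,
            "converged": self.converged,
            "poor_fit": self.poor_fit,
            "bounds": list(self.bounds),
            "n_starts": self.n_starts,
        }


def combined_design(
    n_adp: int = 12,
    n_na: int = 12,
    *,
    atp_uM: float = 2000.0,
    adp_max_uM: float = 3000.0,
    C_h: float = 1.3,
    C_l: float = 1.0,
    ch_min: float = 1.05,
    ch_max: float = 6.0,
    na_delta: float = 0.5,
) -> pd.DataFrame:
    """Design combining an ADP sweep and an extracellular-Na sweep.

    The ADP leg varies ``adp_uM`` from 0 to ``adp_max_uM`` at fixed ion
    concentrations; the Na leg varies ``c_h`` from just above ``C_l`` up to
    ``ch_max`` at a fixed ATP/ADP ratio (bias ``na_delta``).  Both legs are
    needed to separate ``k_h`` from ``k_l``, and the defaults keep both
    ``k*C`` products of order one and start the Na leg close to ``C_l``,
    where the efficiency factor's shape is most sensitive to ``k_h`` --
    away from that region the pair (k_h, k_l) is near-degenerate at fixed
    product and only the product is identified.
    """
    rows = []
    for adp in np.linspace(0.0, adp_max_uM, n_adp):
        rows.append(("adp_uM", float(adp), atp_uM, float(adp), C_h, C_l))
    adp_for_delta = atp_uM * (1 - na_delta) / (1 + na_delta)
    for ch in np.linspace(ch_min, ch_max, n_na):
        rows.append(("c_h", float(ch), atp_uM, adp_for_delta, float(ch), C_l))
    return pd.DataFrame(rows, columns=DATASET_COLUMNS[:6])


def _model_flux(design: pd.DataFrame, k_h: float, k_l: float, scale: float) -> np.ndarray:
    flux = np.empty(len(design))
    for i, row in enumerate(design.itertuples(index=False)):
        delta = excess_from_concentrations(row.atp_uM, row.adp_uM)
        p = PumpParameters(delta=delta, k_h=k_h, k_l=k_l, C_h=row.c_h, C_l=row.c_l)
        flux[i] = scale * phi_analytic(p)
    return flux


def generate_synthetic_flux(
    true_k_h: float,
    true_k_l: float,
    scale: float,
    design: pd.DataFrame,
    noise_sd: float,
    seed: int,
) -> FluxDataset:
    """Draw one synthetic flux dataset: ``scale * Phi`` + Gaussian noise."""
    if true_k_h <= 0 or true_k_l <= 0 or scale <= 0:
        raise DomainError("true_k_h, true_k_l and scale must be positive")
    clean = _model_flux(design, true_k_h, true_k_l, scale)
    rng = np.random.default_rng(seed)
    obs = clean + rng.normal(0.0, noise_sd, size=len(clean))
    return FluxDataset(
        design=design.reset_index(drop=True),
        observed_flux=obs,
        noise_sd=noise_sd,
        seed=seed,
        true_params={"k_h": true_k_h, "k_l": true_k_l, "scale": scale},
    )


def fit_flux_model(
    data: FluxDataset,
    init: tuple[float, float, float] = (1.0, 1.0, 1.0),
    bounds: tuple[float, float] = (1e-3, 1e3),
    *,
    n_starts: int = 5,
    start_seed: int = 12345,
    poor_fit_factor: float = 4.0,
) -> FitResult:
    """Recover ``(k_h, k_l, scale)`` by multi-start bounded least squares.

    Parameters are log-transformed for positivity; ``n_starts`` starts
    (the supplied ``init`` plus seeded log-uniform draws within
    ``bounds``) are run and the lowest-cost solution kept.  A fit whose
    residual standard deviation exceeds ``poor_fit_factor`` times the
    stated noise level is flagged ``poor_fit`` -- the negative-control
    signal for data not generated by this model family.
    """
    lo, hi = bounds
    if lo <= 0 or hi <= lo:
        raise DomainError("bounds must satisfy 0 < lo < hi")
    obs = data.observed_flux
    design = data.design

    def resid(logp: np.ndarray) -> np.ndarray:
        k_h, k_l, scale = np.exp(logp)
        return _model_flux(design, k_h, k_l, scale) - obs

    rng = np.random.default_rng(start_seed)
    starts = [np.log(np.asarray(init, dtype=float))]
    for _ in range(n_starts - 1):
        starts.append(rng.uniform(np.log(lo), np.log(hi), size=3))

    log_lo, log_hi = np.log(lo), np.log(hi)
    best = None
    costs: list[float] = []
    any_ok = False
    for x0 in starts:
        x0 = np.clip(x0, log_lo, log_hi)
        sol = least_squares(
            resid, x0, bounds=(log_lo, log_hi), xtol=1e-12, ftol=1e-12, gtol=1e-12
        )
        costs.append(float(sol.cost))
        any_ok = any_ok or sol.success
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError(
            f"all {n_starts} starts failed to converge; costs={costs}"
        )
    k_h, k_l, scale = np.exp(best.x)
    rss = float(2.0 * best.cost)
    resid_sd = np.sqrt(rss / max(len(obs) - 3, 1))
    return FitResult(
        k_h_hat=float(k_h),
        k_l_hat=float(k_l),
        scale_hat=float(scale),
        residual_sum_of_squares=rss,
        converged=any_ok,
        bounds=bounds,
        n_starts=n_starts,
        poor_fit=bool(resid_sd > poor_fit_factor * data.noise_sd),
        start_costs=costs,
    )
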