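"""Transition-state-theory rate/barrier conversions and Michaelis–Menten fits.

The Eyring relation with transmission coefficient 1,

    k = (k_B T / h) · exp(-ΔG‡ / RT),

links a first-order rate constant k (s⁻¹) at temperature T (K) to an
activation free energy ΔG‡ (kcal·mol⁻¹), and is inverted as

    ΔG‡ = R T ln(k_B T / (h k)).

Michaelis–Menten parameters (k_cat, K_M) are estimated from (substrate
concentration, rate) tables by nonlinear least squares on
v = k_cat·[E]·[S]/(K_M + [S]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import VoxsiteError

# CODATA 2018
BOLTZMANN = 1.380649e-23          # J K^-1
PLANCK = 6.62607015e-34           # J s
GAS_CONSTANT_KCAL = 1.98720425e-3  # kcal mol^-1 K^-1


@dataclass(frozen=True)
class RateConstant:
    k: float   # s^-1
    T: float   # K

    def __post_init__(self):
        if not (self.k > 0 and math.isfinite(self.k)):
            raise VoxsiteError("rate constant must be positive and finite")
        if not (self.T > 0 and math.isfinite(self.T)):
            raise VoxsiteError("temperature must be positive and finite")


@dataclass(frozen=True)
class BarrierEstimate:
    dG: float  # kcal mol^-1
    T: float   # K

    def __post_init__(self):
        if not math.isfinite(self.dG):
            raise VoxsiteError("barrier must be finite")
        if not (self.T > 0 and math.isfinite(self.T)):
            raise VoxsiteError("temperature must be positive and finite")


def barrier_from_rate(r: RateConstant) -> BarrierEstimate:
    """Activation free energy implied by a rate constant (Eyring, κ = 1)."""
    dG = GAS_CONSTANT_KCAL * r.T * math.log(BOLTZMANN * r.T / (PLANCK * r.k))
    return BarrierEstimate(dG=dG, T=r.T)


def rate_from_barrier(b: BarrierEstimate) -> RateConstant:
    """Rate constant implied by an activation free energy (Eyring, κ = 1)."""
    k = (BOLTZMANN * b.T / PLANCK) * math.exp(-b.dG / (GAS_CONSTANT_KCAL * b.T))
    return RateConstant(k=k, T=b.T)


@dataclass
class MMFit:
    """Michaelis–Menten parameters with curvature-based standard errors."""

    kcat: float            # s^-1
    KM: float              # M
    kcat_over_KM: float    # s^-1 M^-1
    se_kcat: float
    se_KM: float
    se_kcat_over_KM: float

    def __post_init__(self):
        if self.kcat <= 0 or self.KM <= 0:
            raise VoxsiteError("fitted kcat and KM must be positive")


def fit_michaelis_menten(table, enzyme_conc: float, max_iterations: int = 5000) -> MMFit:
    """Fit v = kcat·E·S/(KM + S) to (S in M, v in s⁻¹) pairs.

    Initialization: Vmax₀ = max observed rate, KM₀ = the concentration whose
    rate is nearest Vmax₀/2.  Standard errors come from the local curvature
    (covariance of the least-squares solution); the error on kcat/KM is
    propagated including the parameter covariance.
    """
    data = np.asarray(table, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise VoxsiteError("table must be (S, v) pairs")
    S, v = data[:, 0], data[:, 1]
    if enzyme_conc <= 0:
        raise VoxsiteError("enzyme concentration must be positive")
    if len(np.unique(S)) < 4:
        raise VoxsiteError("need at least 4 distinct substrate concentrations")
    if np.any(v < 0):
        raise VoxsiteError("rates must be non-negative")
    if np.all(v == 0):
        raise VoxsiteError("all rates are zero: no signal to fit")

    vmax0 = float(v.max())
    km0 = float(S[np.argmin(np.abs(v - vmax0 / 2.0))])
    km0 = max(km0, 1e-12)

    def model(s, kcat, km):
        return kcat * enzyme_conc * s / (km + s)

    try:
        popt, pcov = curve_fit(model, S, v, p0=[vmax0 / enzyme_conc, km0],
                               maxfev=max_iterations)
    except RuntimeError as exc:
        raise VoxsiteError(
            f"Michaelis–Menten fit did not converge within {max_iterations} "
            f"function evaluations: {exc}") from None
    kcat, km = float(popt[0]), float(popt[1])
    var_kcat, var_km = float(pcov[0, 0]), float(pcov[1, 1])
    cov = float(pcov[0, 1])
    ratio = kcat / km
    # first-order propagation for kcat/KM with covariance term
    var_ratio = (var_kcat / km ** 2
                 + (kcat ** 2 / km ** 4) * var_km
                 - 2.0 * (kcat / km ** 3) * cov)
    return MMFit(kcat=kcat, KM=km, kcat_over_KM=ratio,
                 se_kcat=math.sqrt(max(var_kcat, 0.0)),
                 se_KM=math.sqrt(max(var_km, 0.0)),
                 se_kcat_over_KM=math.sqrt(max(var_ratio, 0.0)))
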