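"""Linear-quadratic radiobiology for a decaying high-LET mixture.

Implements the BED formalism for a continuous, exponentially decreasing
dose rate from a mixture of radionuclides (the brachytherapy mixture rule),
extended to high-LET emitters through the maximum RBE:

* ``rbe_max`` — RBE_M = RBE_exp + (d/(α/β))·(RBE_exp² − 1)/RBE_exp, folding the
  experimental high-LET RBE into the linear term of the LQ model at the
  reference low-LET fraction dose d.
* ``bed_high`` — for initial dose rates (R₀)ₙ all decaying with the shared
  effective constant λ and repair rate μ:

      BED_H = (1/λ)·Σₙ(R₀)ₙ · { RBE_M + ΣₙΣₚ(R₀)ₙ(R₀)ₚ / [(λ+μ)(α/β)·Σₙ(R₀)ₙ] }

  Only the alpha emissions enter the dose rates (beta/gamma neglected); the
  RBE enters solely through RBE_M in the linear term.
* ``bed_low`` / ``eqd2`` — fractionated low-LET BED and the equivalent dose
  in 2-Gy fractions, for comparison with external-beam constraints.
* ``ntcp_lkb`` — Lyman–Kutcher–Burman probit: NTCP = Φ((EQD2 − TD50)/(m·TD50)).

Defaults target grade ≥2 xerostomia of the salivary glands: α/β = 3 Gy,
μ = 0.46 h⁻¹, RBE_exp = 5, d = 2 Gy, TD50 = 14 Gy_EQD2, m = 0.88.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ndtr

__all__ = [
    "RadiobiologyParams",
    "DoseRateSet",
    "rbe_max",
    "initial_dose_rates",
    "bed_high",
    "bed_low",
    "eqd2",
    "ntcp_lkb",
]


@dataclass(frozen=True)
class RadiobiologyParams:
    """LQ and LKB parameters for the xerostomia endpoint."""

    alpha_beta: float = 3.0   # Gy
    mu: float = 0.46          # h^-1 sublethal-damage repair rate
    rbe_exp: float = 5.0      # experimental high-LET RBE
    d_ref: float = 2.0        # Gy, reference low-LET fraction dose
    td50: float = 14.0        # Gy_EQD2
    m: float = 0.88           # LKB slope

    def __post_init__(self) -> None:
        for name in ("alpha_beta", "mu", "rbe_exp", "td50", "m"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if self.d_ref < 0:
            raise ValueError("d_ref must be >= 0")

    @property
    def rbe_m(self) -> float:
        return rbe_max(self.rbe_exp, self.d_ref, self.alpha_beta)


def rbe_max(rbe_exp: float, d_ref: float, alpha_beta: float) -> float:
    """Maximum RBE for the LQ linear term.

    RBE_M = RBE_exp + (d/(α/β)) · (RBE_exp² − 1)/RBE_exp.  At RBE_exp = 1 or
    d = 0 this collapses to RBE_exp.
    """
    if rbe_exp <= 0 or alpha_beta <= 0 or d_ref < 0:
        raise ValueError("rbe_exp and alpha_beta must be > 0, d_ref >= 0")
    return rbe_exp + (d_ref / alpha_beta) * (rbe_exp**2 - 1.0) / rbe_exp


@dataclass(frozen=True)
class DoseRateSet:
    """Initial dose rates of the chain members sharing one decay constant.

    ``r0`` maps nuclide → initial (t = 0) alpha dose rate in Gy/h,
    unweighted; ``lam`` is the shared effective decay constant (the slow
    washout phase of the parent); ``rbe_m`` the maximum RBE to be used in
    the linear BED term.
    """

    r0: Mapping[str, float]
    lam: float
    rbe_m: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.r0.values()):
            raise ValueError("initial dose rates must be >= 0")
        if not (self.lam > 0):
            raise ValueError("effective decay constant must be > 0")

    @property
    def total(self) -> float:
        return float(sum(self.r0.values()))


def initial_dose_rates(
    alpha_dose_per_mbq: Mapping[str, float],
    a_inj_mbq: float,
    lam: float,
    rbe_m: float,
) -> DoseRateSet:
    """(R₀)ₙ = Dₙ[Gy/MBq] · A_inj[MBq] · λ[1/h], per nuclide.

    ``alpha_dose_per_mbq`` is the non-RBE-weighted alpha-only predicted
    absorbed dose per unit injected activity (per nuclide).
    """
    if a_inj_mbq < 0:
        raise ValueError("injected activity must be >= 0")
    r0 = {name: d * a_inj_mbq * lam for name, d in alpha_dose_per_mbq.items()}
    return DoseRateSet(r0=r0, lam=lam, rbe_m=rbe_m)


def bed_high(rates: DoseRateSet, params: RadiobiologyParams) -> float:
    """Mixture BED for exponentially decaying high-LET irradiation, Gy.

    The double sum over nuclide pairs ΣₙΣₚ(R₀)ₙ(R₀)ₚ is evaluated
    explicitly; algebraically it equals (Σₙ(R₀)ₙ)², making the mixture BED
    invariant to how the total dose rate is partitioned across nuclides.
    """
    if not (rates.lam > 0):
        raise ValueError("effective decay constant must be > 0")
    r = np.asarray(list(rates.r0.values()), dtype=float)
    S = float(r.sum())
    if S == 0.0:
        return 0.0
    double_sum = float(np.sum(np.outer(r, r)))  # == S**2
    quad = double_sum / ((rates.lam + params.mu) * params.alpha_beta * S)
    return (S / rates.lam) * (rates.rbe_m + quad)


def bed_low(d_total: float, n_fractions: int, alpha_beta: float) -> float:
    """Fractionated low-LET BED: D·(1 + (D/N)/(α/β)), Gy."""
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if d_total < 0:
        raise ValueError("total dose must be >= 0")
    return d_total * (1.0 + (d_total / n_fractions) / alpha_beta)


def eqd2(bed: float | np.ndarray | Sequence[float], alpha_beta: float) -> float | np.ndarray:
    """Equivalent dose in 2-Gy fractions: BED / (1 + 2/(α/β)), Gy."""
    b = np.asarray(bed, dtype=float)
    if np.any(b < 0):
        raise ValueError("BED must be >= 0")
    out = b / (1.0 + 2.0 / alpha_beta)
    return float(out) if np.isscalar(bed) else out


def ntcp_lkb(
    eqd2_value: float | np.ndarray | Sequence[float], td50: float, m: float
) -> float | np.ndarray:
    """LKB complication probability Φ((EQD2 − TD50)/(m·TD50))."""
    if td50 <= 0 or m <= 0:
        raise ValueError("td50 and m must be > 0")
    t = (np.asarray(eqd2_value, dtype=float) - td50) / (m * td50)
    out = ndtr(t)
    return float(out) if np.isscalar(eqd2_value) else out
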