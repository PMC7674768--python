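"""Sphere-model dose coefficients for the full ²²⁵Ac chain.

Salivary glands are modelled as unit-density spheres in which alpha and beta
energy is deposited locally (absorbed fraction 1) while photons largely
escape (absorbed fraction 0 by default, overridable per organ).  Under
secular equilibrium every daughter shares the parent's residence time, so
the number of decays of nuclide *n* per MBq injected is

    N_n = τ[h] · 3600 · 10⁶ · yield_n

and the organ dose coefficient (Gy per MBq injected) is the emitted energy,
converted MeV→J, divided by the sphere mass.  The RBE-weighted coefficient
applies ``rbe_alpha`` to the alpha term only and is reported in Barendsen
units per MBq (Bd_RBE5/MBq for the default weight of 5); numerically it is
the weighted Gy-equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .chain import DecayChain

__all__ = ["MEV_TO_J", "SphereOrgan", "OrganDoseResult", "sphere_dose_coefficient", "emission_shares"]

MEV_TO_J = 1.602176634e-13
_DECAYS_PER_MBQ_H = 3600.0 * 1.0e6  # decays per (MBq·h)


@dataclass(frozen=True)
class SphereOrgan:
    """Unit-density sphere target: name, mass, photon absorbed fraction."""

    name: str
    mass_g: float
    photon_absorbed_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (self.mass_g > 0):
            raise ValueError("organ mass must be > 0 g")
        if not (0.0 <= self.photon_absorbed_fraction <= 1.0):
            raise ValueError("photon_absorbed_fraction must be in [0, 1]")


@dataclass(frozen=True)
class OrganDoseResult:
    """Per-nuclide and total dose coefficients for one organ.

    ``per_nuclide`` maps nuclide name → dict with unweighted Gy/MBq by
    radiation type (``alpha``, ``beta``, ``gamma``) and the nuclide totals
    (``total``, ``weighted``).  ``shares`` are the (α, β, γ) fractions of the
    RBE-weighted total.
    """

    organ: str
    rbe_alpha: float
    per_nuclide: Mapping[str, Mapping[str, float]]
    total_unweighted: float   # Gy/MBq injected
    total_weighted: float     # Bd_RBE{rbe}/MBq injected
    shares: tuple[float, float, float]

    @property
    def alpha_dose_per_nuclide(self) -> dict[str, float]:
        """Unweighted alpha-only dose per nuclide, Gy/MBq (input to BED)."""
        return {k: v["alpha"] for k, v in self.per_nuclide.items()}


def sphere_dose_coefficient(
    tau_h: float,
    organ: SphereOrgan,
    chain: DecayChain,
    rbe_alpha: float = 5.0,
    exclude: Iterable[str] | None = None,
) -> OrganDoseResult:
    """Predictive dose coefficient of one organ for the whole decay chain.

    Parameters
    ----------
    tau_h
        Residence time (time-integrated activity per MBq injected), hours.
    organ
        Sphere target; its mass and photon absorbed fraction.
    chain
        Decay chain with per-nuclide yields and emission energies.
    rbe_alpha
        Relative biological effectiveness applied to the alpha term of the
        weighted total (default 5).
    exclude
        Nuclide names to drop from both totals (e.g. ``["Po-213"]`` to model
        polonium diffusing away from the decay site).
    """
    if not (tau_h > 0):
        raise ValueError("residence time must be > 0 h")
    if rbe_alpha < 1.0:
        raise ValueError("rbe_alpha must be >= 1")
    excluded = set(exclude or ())
    known = set(chain.names())
    unknown = excluded - known
    if unknown:
        raise ValueError(f"unknown nuclide(s) in exclude: {sorted(unknown)}")

    mass_kg = organ.mass_g * 1e-3
    per_nuclide: dict[str, dict[str, float]] = {}
    tot_a = tot_b = tot_g = 0.0
    for node in chain.nodes:
        if node.name in excluded:
            continue
        decays = tau_h * _DECAYS_PER_MBQ_H * node.yield_per_decay
        to_gy = decays * MEV_TO_J / mass_kg
        d_a = node.emissions.e_alpha * to_gy
        d_b = node.emissions.e_beta * to_gy
        d_g = node.emissions.e_gamma * organ.photon_absorbed_fraction * to_gy
        per_nuclide[node.name] = {
            "alpha": d_a,
            "beta": d_b,
            "gamma": d_g,
            "total": d_a + d_b + d_g,
            "weighted": rbe_alpha * d_a + d_b + d_g,
        }
        tot_a += d_a
        tot_b += d_b
        tot_g += d_g

    total_unweighted = tot_a + tot_b + tot_g
    total_weighted = rbe_alpha * tot_a + tot_b + tot_g
    if total_weighted > 0:
        shares = (
            rbe_alpha * tot_a / total_weighted,
            tot_b / total_weighted,
            tot_g / total_weighted,
        )
    else:
        shares = (0.0, 0.0, 0.0)
    return OrganDoseResult(
        organ=organ.name,
        rbe_alpha=rbe_alpha,
        per_nuclide=per_nuclide,
        total_unweighted=total_unweighted,
        total_weighted=total_weighted,
        shares=shares,
    )


def emission_shares(result: OrganDoseResult) -> tuple[float, float, float]:
    """(α, β, γ) fractions of the RBE-weighted total dose; sum to 1."""
    return result.shares
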