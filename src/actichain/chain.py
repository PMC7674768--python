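"""The ²²⁵Ac decay series and its yield-weighted emission energies.

²²⁵Ac (T½ ≈ 9.9 d) heads a short cascade of alpha and beta emitters,

    ²²⁵Ac → ²²¹Fr → ²¹⁷At → ²¹³Bi → {²¹³Po (98%) | ²⁰⁹Tl (2%)} → ²⁰⁹Pb → ²⁰⁹Bi (stable)

in which every daughter is much shorter-lived than the parent.  Under the
secular-equilibrium assumption used throughout this package, each daughter
decays at the parent's effective rate and at the parent's location, so the
chain is fully described by per-nuclide *yields* (decays per ²²⁵Ac decay)
and yield-weighted emission energies per decay, by radiation type.

Energies are totals per decay (MeV/decay), not line lists: only totals enter
the unit-density sphere dose model.  The default table is packaged in
``data/nuclides_ac225.json`` and compiled from public evaluated nuclear data;
the Tl-209/Po-213 branching defaults to 2%/98%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

__all__ = [
    "EmissionSummary",
    "ChainNode",
    "DecayChain",
    "ChainValidationError",
    "build_default_chain",
    "weighted_energy_per_decay",
]

#: nuclides whose yield must be exactly 1 in a valid ²²⁵Ac chain
_UNIT_YIELD = {"Fr-221", "At-217", "Bi-213", "Pb-209"}
#: the two branches of the Bi-213 decay; their yields must sum to 1
_BRANCH = {"Po-213", "Tl-209"}


class ChainValidationError(ValueError):
    """Raised when nuclide data violate the decay-chain schema."""


@dataclass(frozen=True)
class EmissionSummary:
    """Yield-weighted emission energies per decay of one nuclide (MeV)."""

    e_alpha: float  #: total alpha energy per decay
    e_beta: float   #: mean (spectrum-averaged) beta energy per decay
    e_gamma: float  #: total photon energy per decay, incl. X-rays

    def __post_init__(self) -> None:
        for name in ("e_alpha", "e_beta", "e_gamma"):
            v = getattr(self, name)
            if not (v >= 0.0):
                raise ChainValidationError(f"{name} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class ChainNode:
    """One member of the decay series.

    ``yield_per_decay`` is the number of decays of this nuclide per decay of
    the chain parent (dimensionless, in (0, 1]).
    """

    name: str
    half_life_h: float
    yield_per_decay: float
    emissions: EmissionSummary

    def __post_init__(self) -> None:
        if not (self.half_life_h > 0.0):
            raise ChainValidationError(
                f"{self.name}: half_life_h must be > 0, got {self.half_life_h!r}"
            )
        if not (0.0 < self.yield_per_decay <= 1.0):
            raise ChainValidationError(
                f"{self.name}: yield must be in (0, 1], got {self.yield_per_decay!r}"
            )


@dataclass(frozen=True)
class DecayChain:
    """The ²²⁵Ac series: parent plus ordered daughters.

    Validation enforces the structure that justifies the equilibrium
    assumption: the parent half-life strictly exceeds every daughter's, the
    Bi-213 branches (Po-213/Tl-209) have yields summing to 1, and the
    non-branching daughters have unit yield.
    """

    parent: ChainNode
    daughters: tuple[ChainNode, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if abs(self.parent.yield_per_decay - 1.0) > 1e-12:
            raise ChainValidationError("parent yield must be 1.0")
        names = {n.name for n in self.daughters}
        branch_sum = sum(
            n.yield_per_decay for n in self.daughters if n.name in _BRANCH
        )
        if _BRANCH & names and abs(branch_sum - 1.0) > 1e-9:
            raise ChainValidationError(
                f"Po-213 and Tl-209 yields must sum to 1, got {branch_sum!r}"
            )
        for n in self.daughters:
            if n.name in _UNIT_YIELD and abs(n.yield_per_decay - 1.0) > 1e-12:
                raise ChainValidationError(f"{n.name}: yield must be 1.0")
            if n.half_life_h >= self.parent.half_life_h:
                raise ChainValidationError(
                    f"{n.name}: daughter half-life {n.half_life_h} h must be "
                    f"shorter than parent {self.parent.half_life_h} h"
                )

    @property
    def nodes(self) -> tuple[ChainNode, ...]:
        return (self.parent, *self.daughters)

    def node(self, name: str) -> ChainNode:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)


_REQUIRED_FIELDS = (
    "name",
    "half_life_h",
    "yield",
    "e_alpha_mev",
    "e_beta_mev",
    "e_gamma_mev",
)


def _node_from_record(rec: Mapping) -> ChainNode:
    for f in _REQUIRED_FIELDS:
        if f not in rec:
            raise ChainValidationError(
                f"nuclide record {rec.get('name', '<unnamed>')!r} missing field {f!r}"
            )
    return ChainNode(
        name=str(rec["name"]),
        half_life_h=float(rec["half_life_h"]),
        yield_per_decay=float(rec["yield"]),
        emissions=EmissionSummary(
            e_alpha=float(rec["e_alpha_mev"]),
            e_beta=float(rec["e_beta_mev"]),
            e_gamma=float(rec["e_gamma_mev"]),
        ),
    )


def build_default_chain(nuclide_data: str | Path | None = None) -> DecayChain:
    """Build the 7-member ²²⁵Ac chain from packaged or user-supplied data.

    Parameters
    ----------
    nuclide_data
        Optional path to a JSON file following the packaged schema
        (``{"nuclides": [{"name": ..., "half_life_h": ..., "yield": ...,
        "e_alpha_mev": ..., "e_beta_mev": ..., "e_gamma_mev": ...}, ...]}``).
        The first entry is the chain parent.  When omitted, the packaged
        ²²⁵Ac table (2%/98% Tl/Po branching) is used.
    """
    if nuclide_data is None:
        text = (
            resources.files("actichain.data")
            .joinpath("nuclides_ac225.json")
            .read_text()
        )
    else:
        text = Path(nuclide_data).read_text()
    payload = json.loads(text)
    if "nuclides" not in payload or not payload["nuclides"]:
        raise ChainValidationError("JSON must contain a non-empty 'nuclides' list")
    nodes = [_node_from_record(rec) for rec in payload["nuclides"]]
    return DecayChain(parent=nodes[0], daughters=tuple(nodes[1:]))


def weighted_energy_per_decay(
    chain: DecayChain,
    rbe_alpha: float,
    photon_absorbed_fraction: float = 0.0,
) -> dict[str, tuple[float, float]]:
    """Per-nuclide (RBE-weighted, unweighted) energy per chain decay, MeV.

    For node *n* with yield *y*:

    * unweighted = y · (e_α + e_β + e_γ·φ_γ)
    * weighted   = y · (RBE_α·e_α + e_β + e_γ·φ_γ)

    where φ_γ is the photon absorbed fraction (default 0: photons escape the
    small unit-density sphere; alpha and beta energy is deposited locally).
    """
    if rbe_alpha < 1.0:
        raise ValueError(f"rbe_alpha must be >= 1, got {rbe_alpha!r}")
    if not (0.0 <= photon_absorbed_fraction <= 1.0):
        raise ValueError("photon_absorbed_fraction must be in [0, 1]")
    out: dict[str, tuple[float, float]] = {}
    for n in chain.nodes:
        em = n.emissions
        gamma = em.e_gamma * photon_absorbed_fraction
        unweighted = n.yield_per_decay * (em.e_alpha + em.e_beta + gamma)
        weighted = n.yield_per_decay * (rbe_alpha * em.e_alpha + em.e_beta + gamma)
        out[n.name] = (weighted, unweighted)
    return out
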