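"""Excess scattering lengths and neutron match points.

In SANS the contrast of a protein component is tunable: substituting
deuterium for hydrogen in the solvent (D2O fraction ``f``) or in the
protein (deuteration fraction ``x``) shifts the scattering length
densities, so a component can be given positive, negative or zero
contrast.  At its *match point* a component is invisible.  X-rays see
only electron density, so the X-ray contrast ignores both ``f`` and ``x``.

The default constants are calibrated so that a fully hydrogenated
protein component matches out at 42% D2O and a component perdeuterated
to 69% matches pure D2O — the two standard contrast conditions used in
segmental-labelling SANS work on multi-domain proteins.  Labile-hydrogen
exchange is not modelled separately; it is folded into the effective
hydrogenated-protein density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np

if TYPE_CHECKING:
    from .topology import Topology

__all__ = [
    "SLDConstants",
    "ContrastSpec",
    "DEFAULT_SLD",
    "solvent_sld",
    "protein_sld",
    "excess_scattering_lengths",
    "match_point_solvent",
    "match_deuteration",
]


class MatchPointWarning(UserWarning):
    """A match-point solve landed outside the physically reachable range."""


@dataclass(frozen=True)
class SLDConstants:
    """Scattering length densities in Å^-2.

    ``rho_protein_h`` is the effective density of fully hydrogenated
    protein (labile-H exchange folded in); ``rho_protein_d`` of fully
    deuterated protein.  X-ray densities are electron-density based and
    independent of isotope composition.
    """

    rho_solvent_h2o: float = -0.562e-6
    rho_solvent_d2o: float = 6.404e-6
    rho_protein_h: float = 2.364e-6
    rho_protein_d: float = 8.219e-6
    rho_xray_protein: float = 12.1e-6
    rho_xray_solvent: float = 9.4e-6

    def __post_init__(self) -> None:
        if self.rho_protein_d <= self.rho_protein_h:
            raise ValueError("deuterated protein SLD must exceed hydrogenated protein SLD")
        if self.rho_solvent_d2o <= self.rho_solvent_h2o:
            raise ValueError("D2O SLD must exceed H2O SLD")


DEFAULT_SLD = SLDConstants()


def _check_fraction(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class ContrastSpec:
    """One measurement condition: probe, solvent composition, labelling.

    ``deuteration`` maps chain labels to deuteration fractions; chains
    absent from the map are hydrogenated (x = 0).
    """

    probe: str = "neutron"
    f_d2o: float = 0.0
    deuteration: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.probe not in ("xray", "neutron"):
            raise ValueError(f"probe must be 'xray' or 'neutron', got {self.probe!r}")
        _check_fraction(self.f_d2o, "f_d2o")
        for chain, x in self.deuteration.items():
            _check_fraction(x, f"deuteration[{chain!r}]")


def solvent_sld(f_d2o: float, constants: SLDConstants = DEFAULT_SLD) -> float:
    """SLD of an H2O/D2O mixture, linear in the D2O volume fraction."""
    _check_fraction(f_d2o, "f_d2o")
    return (1.0 - f_d2o) * constants.rho_solvent_h2o + f_d2o * constants.rho_solvent_d2o


def protein_sld(x, constants: SLDConstants = DEFAULT_SLD):
    """Protein SLD at deuteration fraction ``x`` (scalar or array)."""
    return constants.rho_protein_h + np.asarray(x, dtype=float) * (
        constants.rho_protein_d - constants.rho_protein_h
    )


def excess_scattering_lengths(
    topology: "Topology",
    spec: ContrastSpec,
    constants: SLDConstants = DEFAULT_SLD,
) -> np.ndarray:
    """Per-bead excess scattering length Δb_i = V_i (ρ_bead - ρ_solvent).

    For neutrons, ρ_bead interpolates linearly between the hydrogenated
    and deuterated protein densities according to the bead's chain
    deuteration fraction, and ρ_solvent according to the D2O fraction.
    For X-rays both isotope effects vanish.
    """
    if spec.probe == "xray":
        contrast = constants.rho_xray_protein - constants.rho_xray_solvent
        return topology.volumes * contrast
    x = np.array([float(spec.deuteration.get(str(c), 0.0)) for c in topology.chains])
    if np.any((x < 0) | (x > 1)):
        raise ValueError("deuteration fractions must be in [0, 1]")
    rho_bead = protein_sld(x, constants)
    return topology.volumes * (rho_bead - solvent_sld(spec.f_d2o, constants))


def match_point_solvent(
    deuteration_fraction: float, constants: SLDConstants = DEFAULT_SLD
) -> float:
    """Solvent D2O fraction at which a component of the given deuteration
    has zero contrast.  Exact linear solve; values outside [0, 1] are
    returned unclipped with a warning (not physically reachable)."""
    _check_fraction(deuteration_fraction, "deuteration_fraction")
    span = constants.rho_solvent_d2o - constants.rho_solvent_h2o
    f = (float(protein_sld(deuteration_fraction, constants)) - constants.rho_solvent_h2o) / span
    if not 0.0 <= f <= 1.0:
        warnings.warn(
            f"match point f_D2O = {f:.4f} lies outside [0, 1]; "
            "this component cannot be matched by solvent composition alone",
            MatchPointWarning,
            stacklevel=2,
        )
    return f


def match_deuteration(f_d2o: float, constants: SLDConstants = DEFAULT_SLD) -> float:
    """Deuteration fraction at which a component matches the given solvent.

    Inverse of :func:`match_point_solvent`; out-of-range solutions are
    returned unclipped with a warning."""
    _check_fraction(f_d2o, "f_d2o")
    span = constants.rho_protein_d - constants.rho_protein_h
    x = (solvent_sld(f_d2o, constants) - constants.rho_protein_h) / span
    if not 0.0 <= x <= 1.0:
        warnings.warn(
            f"required deuteration x = {x:.4f} lies outside [0, 1]; "
            "no physical labelling matches this solvent",
            MatchPointWarning,
            stacklevel=2,
        )
    return x
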