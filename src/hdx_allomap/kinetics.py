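"""Exchange kinetics at a ligand-occluded amide and experiment-design arithmetic.

At an amide shielded by a reversibly bound ligand, the observed H/D exchange
rate is set by the interplay of the complex's dissociation rate ``k_off``,
the reassociation flux ``k_on*[L]`` and the intrinsic exchange rate ``k_ex``::

    k_obs = k_off * k_ex / (k_on * [L] + k_ex)

When ligand is in vast excess (``k_on*[L] >> k_ex``) this reduces to the
affinity-limited form ``k_obs = K_D * k_ex / [L]``.  Three design regimes
follow for a saturated complex: *slow-off* (the complex never dissociates on
the exchange timescale), *intermediate* (the full expression is needed) and
*saturating* (the limiting form is valid).  The helpers here implement those
expressions plus the mixing/dilution and ligand:protein-ratio arithmetic used
to plan an exchange experiment.

Units are molar and minutes throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .units import format_ratio

__all__ = [
    "BindingKinetics",
    "ExchangeSite",
    "MixComponent",
    "MixDesign",
    "SaturationVerdict",
    "observed_exchange_rate",
    "limiting_rate",
    "fractional_occupancy",
    "mix_concentrations",
    "ligand_protein_ratio",
    "saturation_check",
]

_KD_RTOL = 1e-9


@dataclass(frozen=True)
class BindingKinetics:
    """Binding parameters of one protein-ligand pair.

    Any of ``k_on``/``k_off``/``K_D`` may be omitted; a missing member of the
    triplet is filled in from the other two, and a fully specified triplet is
    checked for consistency (``K_D == k_off / k_on``).

    Parameters
    ----------
    k_on : association rate, M^-1 min^-1
    k_off : dissociation rate, min^-1
    K_D : dissociation constant, M
    ligand_conc : total ligand concentration, M
    protein_conc : total protein concentration, M
    """

    k_on: float | None = None
    k_off: float | None = None
    K_D: float | None = None
    ligand_conc: float | None = None
    protein_conc: float | None = None

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "K_D", "ligand_conc", "protein_conc"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        for name in ("k_on", "k_off", "K_D", "protein_conc"):
            v = getattr(self, name)
            if v is not None and v == 0 and name != "k_on":
                raise ValueError(f"{name} must be strictly positive when supplied")
        if self.k_on and self.k_off and self.K_D is None:
            object.__setattr__(self, "K_D", self.k_off / self.k_on)
        elif self.k_on and self.K_D and self.k_off is None:
            object.__setattr__(self, "k_off", self.k_on * self.K_D)
        elif self.k_off and self.K_D and self.k_on is None:
            object.__setattr__(self, "k_on", self.k_off / self.K_D)
        elif self.k_on and self.k_off and self.K_D:
            if abs(self.K_D - self.k_off / self.k_on) / self.K_D >= _KD_RTOL:
                raise ValueError(
                    f"inconsistent kinetics: K_D={self.K_D} but k_off/k_on="
                    f"{self.k_off / self.k_on}"
                )


@dataclass(frozen=True)
class ExchangeSite:
    """One backbone amide with its intrinsic exchange rate.

    ``occluded`` marks a site shielded by the bound ligand (exchanging at
    k_obs in the bound state); ``allosteric_factor`` multiplies k_ex in the
    bound state for a site responding to a distal conformational change
    (1 = no effect, <1 protection, >1 deprotection). A single site cannot be
    both occluded and allosterically modulated.
    """

    residue_index: int
    k_ex: float
    occluded: bool = False
    allosteric_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.k_ex <= 0:
            raise ValueError(f"k_ex must be positive, got {self.k_ex}")
        if self.allosteric_factor <= 0:
            raise ValueError("allosteric_factor must be positive")
        if self.occluded and self.allosteric_factor != 1.0:
            raise ValueError(
                "a site cannot be both occluded and allosterically modulated"
            )


@dataclass(frozen=True)
class MixComponent:
    volume_ul: float
    conc: float = 0.0  # solute concentration, any consistent unit
    d2o_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.volume_ul < 0:
            raise ValueError("component volume must be non-negative")
        if not 0.0 <= self.d2o_fraction <= 1.0:
            raise ValueError("D2O fraction must lie in [0, 1]")


@dataclass(frozen=True)
class MixDesign:
    """A one-pot mix of components, e.g. protein stock + D2O buffer + DMSO."""

    components: Sequence[MixComponent]
    total_volume_ul: float | None = None

    def __post_init__(self) -> None:
        total = sum(c.volume_ul for c in self.components)
        if self.total_volume_ul is None:
            object.__setattr__(self, "total_volume_ul", total)
        elif abs(self.total_volume_ul - total) > 1e-9 * max(total, 1.0):
            raise ValueError(
                f"total_volume_ul={self.total_volume_ul} does not equal the "
                f"sum of component volumes ({total})"
            )


def observed_exchange_rate(kin: BindingKinetics, k_ex: float) -> float:
    """Observed exchange rate at an occluded amide in the bound state.

    ``k_obs = k_off * k_ex / (k_on * [L] + k_ex)``; bounded above by k_off
    and strictly decreasing in ligand concentration.
    """
    if kin.k_off is None or kin.k_off <= 0:
        raise ValueError(f"k_off must be positive, got {kin.k_off}")
    if k_ex <= 0:
        raise ValueError(f"k_ex must be positive, got {k_ex}")
    k_on = kin.k_on or 0.0
    lig = kin.ligand_conc or 0.0
    return kin.k_off * k_ex / (k_on * lig + k_ex)


def limiting_rate(K_D: float, k_ex: float, ligand_conc: float) -> float:
    """Saturating-excess limit ``k_obs = K_D * k_ex / [L]``.

    Valid when the reassociation flux dwarfs intrinsic exchange
    (``k_on*[L] >> k_ex``).
    """
    if ligand_conc <= 0:
        raise ValueError("ligand_conc must be positive for the limiting form")
    if k_ex <= 0:
        raise ValueError(f"k_ex must be positive, got {k_ex}")
    if K_D < 0:
        raise ValueError("K_D must be non-negative")
    return K_D * k_ex / ligand_conc


def fractional_occupancy(K_D: float, protein_conc: float, ligand_conc: float) -> float:
    """Equilibrium fraction of protein bound, with ligand depletion.

    Solves the quadratic ``x^2 - x*(P + L + K_D) + P*L = 0`` for the complex
    concentration ``x`` (total-ligand treatment, exact at any stoichiometry)
    and returns ``x / P``.
    """
    if protein_conc <= 0:
        raise ValueError("protein_conc must be positive")
    if K_D < 0 or ligand_conc < 0:
        raise ValueError("K_D and ligand_conc must be non-negative")
    if ligand_conc == 0:
        return 0.0
    b = protein_conc + ligand_conc + K_D
    disc = b * b - 4.0 * protein_conc * ligand_conc
    # smaller root via the cancellation-free form 2PL / (b + sqrt(disc))
    x = 2.0 * protein_conc * ligand_conc / (b + math.sqrt(max(disc, 0.0)))
    return min(max(x / protein_conc, 0.0), 1.0)


def mix_concentrations(design: MixDesign) -> tuple[list[float], float]:
    """Final per-component solute concentrations and D2O fraction of a mix.

    Each solute is diluted by volume: ``c_final = v_i * c_i / V_total``; the
    D2O fraction is the volume-weighted mean of the component fractions.
    """
    total = design.total_volume_ul
    if total is None or total <= 0:
        raise ValueError("total mix volume must be positive")
    concs = [c.volume_ul * c.conc / total for c in design.components]
    d2o = sum(c.volume_ul * c.d2o_fraction for c in design.components) / total
    return concs, d2o


def ligand_protein_ratio(ligand_conc: float, protein_conc: float) -> float:
    """Molar ligand:protein ratio (use :func:`units.format_ratio` to render)."""
    if protein_conc <= 0:
        raise ValueError("protein_conc must be positive")
    return ligand_conc / protein_conc


@dataclass(frozen=True)
class SaturationVerdict:
    """Design verdict for one ligand under exchange conditions."""

    occupancy: float
    kinetic_ratio: float  # k_on*[L] / k_ex
    saturating: bool
    scenario: str  # no-binding | slow-off | intermediate | saturating
    note: str = ""


def saturation_check(
    kin: BindingKinetics,
    k_ex: float,
    saturation_factor: float = 10.0,
    slow_off_threshold: float = 1e-2,
) -> SaturationVerdict:
    """Classify the exchange-design regime for one ligand.

    ``saturation_factor`` quantifies "vast excess": the limiting form is
    accepted when ``k_on*[L] >= saturation_factor * k_ex``.  A complex with
    ``k_off`` below ``slow_off_threshold`` (min^-1) would not dissociate over
    a minutes-to-hours exchange time course.
    """
    lig = kin.ligand_conc or 0.0
    if lig == 0:
        return SaturationVerdict(0.0, 0.0, False, "no-binding",
                                 "no ligand present; no binding expected")
    if kin.K_D is None or kin.protein_conc is None:
        raise ValueError("saturation_check needs K_D and protein_conc")
    occ = fractional_occupancy(kin.K_D, kin.protein_conc, lig)
    ratio = (kin.k_on or 0.0) * lig / k_ex
    saturating = ratio >= saturation_factor
    if kin.k_off is not None and kin.k_off < slow_off_threshold:
        scenario, note = "slow-off", (
            "complex would not dissociate during the exchange time course; "
            "exchange at occluded amides reports k_off"
        )
    elif saturating:
        scenario, note = "saturating", "limiting form K_D*k_ex/[L] is valid"
    else:
        scenario, note = "intermediate", (
            "full expression k_off*k_ex/(k_on[L]+k_ex) needed"
        )
    return SaturationVerdict(occ, ratio, saturating, scenario, note)


def ratio_report(ligand_conc: float, protein_conc: float) -> str:
    """Two-significant-figure rendering of the ligand:protein ratio."""
    return format_ratio(ligand_protein_ratio(ligand_conc, protein_conc))
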