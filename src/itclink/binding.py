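"""Equilibrium math for effector-modulated protein-DNA binding measured by ITC.

This module holds the pure computation layer: the 1:1 binding mass balance,
the incremental-titration (Wiseman-style) injection heat model, and the
heterotropic linkage equation that describes how the apparent protein-DNA
dissociation constant Kd_app depends on the concentration of a small-molecule
effector (2-oxoglutarate, "oxo") bound at a second site::

    Kd_app([oxo]) = Kd * (1 + [oxo]/Kd_oxo) / (1 + alpha * [oxo]/Kd_oxo)

where ``Kd`` is the intrinsic protein-DNA dissociation constant at zero
effector, ``Kd_oxo`` the protein-effector dissociation constant, and ``alpha``
the cooperativity interaction constant (alpha > 1: positive heterotropic
cooperativity; alpha < 1: negative; alpha = 1: no linkage).

Units are deliberately split and enforced rather than converted silently:
the Kd family is in uM, the Kd_oxo family and effector concentrations in mM,
volumes in uL, heats in ucal, molar enthalpies in kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TitrationProtocol",
    "Thermogram",
    "BindingParameters",
    "LinkageParameters",
    "EffectiveConstants",
    "NoCooperativityError",
    "bound_complex",
    "kdapp_linkage",
    "effective_constants",
    "half_effect_concentration",
    "classify_cooperativity",
    "injection_heat_series",
    "normalize_heats",
]

# Below this ratio of kd to the limiting concentration the quadratic root is
# numerically indistinguishable from the stoichiometric (tight-binding) limit.
TIGHT_BINDING_RATIO = 1e-6


class NoCooperativityError(ValueError):
    """Raised when a half-effect concentration is requested for alpha == 1."""


@dataclass(frozen=True)
class TitrationProtocol:
    """Instrument/run description of one incremental ITC titration.

    Parameters
    ----------
    cell_volume : float
        Active calorimeter cell volume V0, uL.
    injection_volume : float
        Volume of each titrant injection dV, uL.
    n_injections : int
        Number of programmed injections.
    cell_macromolecule_total : float
        Total macromolecule concentration initially in the cell, uM,
        interpreted according to ``cell_conc_basis``.
    syringe_titrant_total : float
        Total titrant (dsDNA) concentration in the syringe, uM.
    effector_conc : float
        Effector (2-oxoglutarate) concentration in the cell, mM.
    temperature : float
        Run temperature, degrees C.
    cell_conc_basis : str
        ``"monomer"`` or ``"site"``. The transcription factor binds DNA as a
        dimer, so a monomer-basis concentration is divided by
        ``monomer_per_site`` to obtain binding sites.
    monomer_per_site : int
        Monomers per binding site (2 for a dimeric binding unit).
    injection_interval_s : float
        Spacing between injections, s (metadata only).
    label : str
        Free-text run identity (e.g. strain + oligo id).
    """

    cell_volume: float = 200.0
    injection_volume: float = 2.0
    n_injections: int = 19
    cell_macromolecule_total: float = 10.0
    syringe_titrant_total: float = 100.0
    effector_conc: float = 0.0
    temperature: float = 25.0
    cell_conc_basis: str = "monomer"
    monomer_per_site: int = 2
    injection_interval_s: float = 150.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.cell_volume <= 0 or self.injection_volume <= 0:
            raise ValueError("volumes must be positive")
        if self.n_injections < 1:
            raise ValueError("need at least one injection")
        if self.n_injections * self.injection_volume >= self.cell_volume:
            raise ValueError(
                "total injected volume must stay below the cell volume "
                f"({self.n_injections} x {self.injection_volume} uL vs "
                f"{self.cell_volume} uL cell)"
            )
        if self.cell_macromolecule_total < 0 or self.syringe_titrant_total < 0:
            raise ValueError("concentrations must be non-negative")
        if self.effector_conc < 0:
            raise ValueError("effector concentration must be non-negative")
        if self.cell_conc_basis not in ("monomer", "site"):
            raise ValueError("cell_conc_basis must be 'monomer' or 'site'")
        if self.monomer_per_site < 1:
            raise ValueError("monomer_per_site must be >= 1")

    @property
    def cell_sites_total(self) -> float:
        """Binding-site concentration in the cell at the start of the run, uM."""
        if self.cell_conc_basis == "site":
            return self.cell_macromolecule_total
        return self.cell_macromolecule_total / self.monomer_per_site

    def with_effector(self, oxo: float) -> "TitrationProtocol":
        return replace(self, effector_conc=oxo)


@dataclass
class Thermogram:
    """Ordered per-injection heats for one titration.

    ``units`` is ``"ucal"`` for raw integrated injection heats or
    ``"kcal/mol"`` for heats normalized per mole of injectant.
    """

    heats: np.ndarray
    protocol: TitrationProtocol
    units: str = "ucal"
    first_injection_excluded: bool = False

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if self.heats.ndim != 1:
            raise ValueError("heats must be a 1-D series")
        expected = self.protocol.n_injections - int(self.first_injection_excluded)
        if self.heats.size != expected:
            raise ValueError(
                f"expected {expected} heats for {self.protocol.n_injections} "
                f"injections (first excluded: {self.first_injection_excluded}), "
                f"got {self.heats.size}"
            )
        if self.units not in ("ucal", "kcal/mol"):
            raise ValueError("units must be 'ucal' or 'kcal/mol'")

    @property
    def n_usable(self) -> int:
        return int(self.heats.size)

    def exclude_first(self) -> "Thermogram":
        """Drop the first injection (common practice for the small, unreliable
        first peak). No-op error if already excluded."""
        if self.first_injection_excluded:
            raise ValueError("first injection already excluded")
        return Thermogram(
            heats=self.heats[1:],
            protocol=self.protocol,
            units=self.units,
            first_injection_excluded=True,
        )


@dataclass(frozen=True)
class BindingParameters:
    """Single-site thermogram model parameters.

    kd : uM, on the binding-site basis (one dsDNA per protein dimer).
    delta_h : kcal/mol of complex formed.
    n_stoich : apparent stoichiometry multiplying the nominal site concentration.
    q_offset : constant per-injection background heat (heat of dilution), ucal.
    """

    kd: float
    delta_h: float
    n_stoich: float = 1.0
    q_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.n_stoich <= 0:
            raise ValueError("n_stoich must be positive")


@dataclass(frozen=True)
class LinkageParameters:
    """Ternary-linkage model parameters.

    kd_intrinsic : protein-DNA dissociation constant at zero effector, uM.
    kd_oxo : protein-effector dissociation constant in the absence of DNA, mM.
    alpha : dimensionless cooperativity interaction constant.
    """

    kd_intrinsic: float
    kd_oxo: float
    alpha: float

    def __post_init__(self) -> None:
        if self.kd_intrinsic <= 0:
            raise ValueError("kd_intrinsic must be positive")
        if self.kd_oxo <= 0:
            raise ValueError("kd_oxo must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class EffectiveConstants:
    """Derived limiting constants of the linkage model.

    kd_eff : limiting protein-DNA Kd at saturating effector, uM (= Kd/alpha).
    kd_oxo_eff : effector concentration at half-maximal change in Kd_app, mM
        (= Kd_oxo/alpha); by reciprocity also the protein-effector Kd at
        saturating DNA.
    """

    kd_eff: float
    kd_oxo_eff: float


def bound_complex(m_total: float, x_total: float, kd: float) -> float:
    """Equilibrium complex concentration for 1:1 binding, uM.

    Solves [MX]^2 - (M_t + X_t + Kd)[MX] + M_t X_t = 0 for the physical root
    using the numerically stable form 2 M_t X_t / (b + sqrt(b^2 - 4 M_t X_t)),
    which avoids cancellation for kd far below or above the concentrations.
    """
    if m_total < 0 or x_total < 0:
        raise ValueError("concentrations must be non-negative")
    if kd <= 0:
        raise ValueError("kd must be positive (tight binding: pass a small kd)")
    if m_total == 0.0 or x_total == 0.0:
        return 0.0
    lim = min(m_total, x_total)
    if kd < TIGHT_BINDING_RATIO * lim:
        return lim
    b = m_total + x_total + kd
    # cancellation-free discriminant: b^2 - 4 M X = (M - X)^2 + kd^2 + 2 kd (M + X)
    disc = (m_total - x_total) ** 2 + kd * kd + 2.0 * kd * (m_total + x_total)
    root = 2.0 * m_total * x_total / (b + math.sqrt(disc))
    return min(root, lim)


def kdapp_linkage(oxo, params: LinkageParameters):
    """Apparent protein-DNA Kd at effector concentration ``oxo`` (mM), in uM.

    Accepts a scalar or array of effector concentrations. The curve runs from
    ``kd_intrinsic`` at oxo=0 to ``kd_intrinsic/alpha`` at saturating effector,
    monotonically when alpha != 1.
    """
    oxo_arr = np.asarray(oxo, dtype=float)
    if np.any(oxo_arr < 0):
        raise ValueError("effector concentration must be non-negative")
    r = oxo_arr / params.kd_oxo
    out = params.kd_intrinsic * (1.0 + r) / (1.0 + params.alpha * r)
    return float(out) if np.isscalar(oxo) or oxo_arr.ndim == 0 else out


def effective_constants(params: LinkageParameters) -> EffectiveConstants:
    """Derived limiting constants: kd_eff = Kd/alpha, kd_oxo_eff = Kd_oxo/alpha."""
    return EffectiveConstants(
        kd_eff=params.kd_intrinsic / params.alpha,
        kd_oxo_eff=params.kd_oxo / params.alpha,
    )


def half_effect_concentration(
    params: LinkageParameters, *, tolerance: float = 1e-9
) -> float:
    """Effector concentration (mM) at half-maximal change in Kd_app.

    Equals Kd_oxo/alpha; at this concentration the linkage curve passes exactly
    through the midpoint (Kd + Kd/alpha)/2. Undefined when alpha == 1 (no
    change in Kd_app exists to halve).
    """
    if abs(params.alpha - 1.0) <= tolerance:
        raise NoCooperativityError(
            "no cooperativity (alpha = 1): half-effect concentration undefined"
        )
    return params.kd_oxo / params.alpha


def classify_cooperativity(alpha: float, tolerance: float = 0.05) -> str:
    """Classify the linkage as 'positive', 'negative' or 'none'.

    alpha > 1 + tolerance: the effector enhances DNA binding (positive
    heterotropic cooperativity); alpha < 1 - tolerance: it weakens binding.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    if alpha > 1.0 + tolerance:
        return "positive"
    if alpha < 1.0 - tolerance:
        return "negative"
    return "none"


def _cell_concentrations(protocol: TitrationProtocol, n_stoich: float):
    """Per-injection total site and titrant concentrations in the cell (uM).

    Uses the overfill/displacement convention of commercial incremental-ITC
    analysis: after injection i the species initially in the cell are diluted
    by (1 - dV/V0)**i, and the injected titrant accumulates as
    X_syr * (1 - (1 - dV/V0)**i).
    """
    i = np.arange(1, protocol.n_injections + 1)
    d = 1.0 - protocol.injection_volume / protocol.cell_volume
    dil = d**i
    sites0 = n_stoich * protocol.cell_sites_total
    m = sites0 * dil
    x = protocol.syringe_titrant_total * (1.0 - dil)
    return m, x


def injection_heat_series(
    protocol: TitrationProtocol, params: BindingParameters
) -> Thermogram:
    """Simulate the raw per-injection heat series of an incremental titration.

    For each injection the total heat content of the cell is
    Q_i = V0 * dH * [MX]_i (ucal, with V0 in uL, dH in kcal/mol, [MX] in uM);
    the measured injection heat applies the displaced-volume mean-concentration
    correction

        q_i = Q_i - Q_{i-1} + (dV/V0) * (Q_i + Q_{i-1}) / 2 + q_offset

    accounting for complex carried out of the active volume by the displaced
    liquid of each injection.
    """
    m, x = _cell_concentrations(protocol, params.n_stoich)
    mx = np.array([bound_complex(mi, xi, params.kd) for mi, xi in zip(m, x)])
    # ucal = uL * uM * kcal/mol / 1000
    q_total = protocol.cell_volume * params.delta_h * mx / 1000.0
    q_prev = np.concatenate([[0.0], q_total[:-1]])
    dv_ratio = protocol.injection_volume / protocol.cell_volume
    q = q_total - q_prev + dv_ratio * (q_total + q_prev) / 2.0 + params.q_offset
    return Thermogram(heats=q, protocol=protocol, units="ucal")


def normalize_heats(thermogram: Thermogram) -> Thermogram:
    """Convert raw heats (ucal) to kcal per mole of injectant.

    Moles injected per injection: dV (uL) * X_syr (uM) * 1e-12 mol.
    """
    if thermogram.units != "ucal":
        raise ValueError("thermogram is not in raw heat units")
    p = thermogram.protocol
    per_mol = thermogram.heats / (p.injection_volume * p.syringe_titrant_total) * 1e3
    return Thermogram(
        heats=per_mol,
        protocol=p,
        units="kcal/mol",
        first_injection_excluded=thermogram.first_injection_excluded,
    )
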