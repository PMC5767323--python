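"""Synthetic calorimetry data with the statistical structure the analysis assumes.

No public raw-data accession exists for the titrations this package analyses,
so every stage is exercised against simulated data generated here. The
generator emulates the original experimental design: Auto-iTC200-style runs at
25 degrees C, 2 uL injections every 150 s, transcription-factor monomer at
5-10 uM in the cell (dimer = one DNA binding site), double-stranded promoter
DNA at 50-100 uM in the syringe, and 2-oxoglutarate at 0, 1, 5 and 10 mM.

Ground-truth parameter sets (:func:`strain_presets`) are the fitted constants
for NtcA from the three *Prochlorococcus* strains (MIT9313, SS120, MED4)
binding their wild-type or mutated glnA promoter fragments.

Noise placement: additive Gaussian on per-injection heats (instrument-like)
and multiplicative lognormal on Kd_app points (fit-error-like). Every
stochastic output is a pure function of its inputs and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding import (
    LinkageParameters,
    Thermogram,
    TitrationProtocol,
    injection_heat_series,
    kdapp_linkage,
    BindingParameters,
)
from .fitting import LinkageDataset

__all__ = [
    "StrainPreset",
    "NoiseModel",
    "strain_presets",
    "get_preset",
    "simulate_thermogram",
    "simulate_linkage_dataset",
    "DEFAULT_OXO_LEVELS_MM",
    "DEFAULT_DELTA_H",
]

#: effector grid used in the original titration series, mM
DEFAULT_OXO_LEVELS_MM = (0.0, 1.0, 5.0, 10.0)

#: molar enthalpy assumed for simulated thermograms, kcal/mol. No enthalpies
#: are reported for these interactions; -10 kcal/mol is typical of
#: protein-DNA association and any nonzero value exercises the pipeline.
DEFAULT_DELTA_H = -10.0


@dataclass(frozen=True)
class StrainPreset:
    """Named ground-truth parameter set for one strain/promoter combination."""

    name: str
    truth: LinkageParameters
    cell_monomer_conc: float  # uM, monomer basis
    syringe_dna_conc: float  # uM
    dna_label: str  # oligo identity (wild-type or mutated promoter)
    dna_sequence: str = ""  # forward-strand 5'->3'
    wild_type: bool = True

    def protocol(self, oxo: float = 0.0, **overrides) -> TitrationProtocol:
        """Build the titration protocol this preset was measured under."""
        kwargs = dict(
            cell_macromolecule_total=self.cell_monomer_conc,
            syringe_titrant_total=self.syringe_dna_conc,
            cell_conc_basis="monomer",
            monomer_per_site=2,
            effector_conc=oxo,
            label=f"{self.name}/{self.dna_label}",
        )
        kwargs.update(overrides)
        return TitrationProtocol(**kwargs)


@dataclass(frozen=True)
class NoiseModel:
    """Noise magnitudes for the generators.

    heat_noise_sd : additive Gaussian SD per injection heat, ucal.
    kdapp_noise_cv : coefficient of variation of multiplicative lognormal
        noise on simulated Kd_app points.
    seed : mandatory for any stochastic call; identical seeds give
        bit-identical output.
    """

    heat_noise_sd: float = 0.0
    kdapp_noise_cv: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.heat_noise_sd < 0 or self.kdapp_noise_cv < 0:
            raise ValueError("noise magnitudes must be non-negative")

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError("a seed is required for stochastic simulation")
        return self.seed


# Mutated-promoter presets carry alpha = 1 (no heterotropic linkage was
# detectable) and a nominal kd_oxo; with alpha = 1 the linkage curve is
# constant, so kd_oxo is inert.
_PRESETS: dict[str, StrainPreset] = {}


def _register(preset: StrainPreset) -> None:
    _PRESETS[preset.name] = preset


_register(StrainPreset(
    name="MIT9313",
    truth=LinkageParameters(kd_intrinsic=0.97, kd_oxo=19.0, alpha=17.0),
    cell_monomer_conc=10.0,
    syringe_dna_conc=100.0,
    dna_label="DNA1",
    dna_sequence="TAGAAGGTACCTGTTGCTACAAAAAG",
))
_register(StrainPreset(
    name="MIT9313-mut",
    truth=LinkageParameters(kd_intrinsic=2.1, kd_oxo=1.0, alpha=1.0),
    cell_monomer_conc=10.0,
    syringe_dna_conc=100.0,
    dna_label="DNA2",
    dna_sequence="TAGAAGAGAAAGGATCCGCAAAAAG",
    wild_type=False,
))
_register(StrainPreset(
    name="SS120",
    truth=LinkageParameters(kd_intrinsic=6.7, kd_oxo=42.0, alpha=8.4),
    cell_monomer_conc=5.0,
    syringe_dna_conc=50.0,
    dna_label="DNA3",
    dna_sequence="CCAATAGTCACAAAAAGTACTTATTG",
))
_register(StrainPreset(
    name="SS120-mut",
    truth=LinkageParameters(kd_intrinsic=10.0, kd_oxo=1.0, alpha=1.0),
    cell_monomer_conc=5.0,
    syringe_dna_conc=50.0,
    dna_label="DNA4",
    dna_sequence="CCAATAAGCCCCACACGGCATTATTG",
    wild_type=False,
))
_register(StrainPreset(
    name="MED4",
    truth=LinkageParameters(kd_intrinsic=4.8, kd_oxo=36.0, alpha=9.3),
    cell_monomer_conc=5.0,
    syringe_dna_conc=50.0,
    dna_label="DNA5",
    dna_sequence="AAAAAGTTACCTTTGATACATAAT",
))
_register(StrainPreset(
    name="MED4-mut",
    truth=LinkageParameters(kd_intrinsic=9.5, kd_oxo=1.0, alpha=1.0),
    cell_monomer_conc=5.0,
    syringe_dna_conc=50.0,
    dna_label="DNA6",
    dna_sequence="AAAAACTAACCTTTGACTGATAAT",
    wild_type=False,
))


def strain_presets() -> dict[str, StrainPreset]:
    """All named presets (three wild-type and three mutated-promoter sets)."""
    return dict(_PRESETS)


def get_preset(name: str) -> StrainPreset:
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset '{name}'; available: {sorted(_PRESETS)}"
        ) from None


def simulate_thermogram(
    preset: StrainPreset,
    oxo: float = 0.0,
    noise: NoiseModel | None = None,
    assumed_dh: float = DEFAULT_DELTA_H,
    n_stoich: float = 1.0,
    q_offset: float = 0.0,
    **protocol_overrides,
) -> Thermogram:
    """Simulate one titration thermogram at effector concentration ``oxo`` (mM).

    The effector-conditional apparent Kd is taken from the preset's linkage
    truth, the heat series from the incremental single-site model, and
    Gaussian noise of ``noise.heat_noise_sd`` ucal is added per injection.
    """
    if oxo < 0:
        raise ValueError("effector concentration must be non-negative")
    noise = noise or NoiseModel()
    protocol = preset.protocol(oxo=oxo, **protocol_overrides)
    kdapp = kdapp_linkage(oxo, preset.truth)
    params = BindingParameters(
        kd=kdapp, delta_h=assumed_dh, n_stoich=n_stoich, q_offset=q_offset
    )
    tg = injection_heat_series(protocol, params)
    if noise.heat_noise_sd > 0:
        rng = np.random.default_rng(noise.require_seed())
        tg = Thermogram(
            heats=tg.heats + rng.normal(0.0, noise.heat_noise_sd, tg.heats.size),
            protocol=protocol,
            units="ucal",
        )
    return tg


def simulate_linkage_dataset(
    preset: StrainPreset,
    oxo_levels=DEFAULT_OXO_LEVELS_MM,
    noise: NoiseModel | None = None,
) -> LinkageDataset:
    """Simulate a (effector, Kd_app) dataset from a preset's linkage truth.

    Points are the exact linkage-curve values perturbed by multiplicative
    lognormal noise with coefficient of variation ``noise.kdapp_noise_cv``;
    each point's SE is set to cv * Kd_app. With cv = 0 the points lie exactly
    on the curve and carry no SE.
    """
    oxo_levels = np.asarray(list(oxo_levels), dtype=float)
    if oxo_levels.size == 0:
        raise ValueError("oxo_levels must be non-empty")
    if len(set(oxo_levels.tolist())) != oxo_levels.size:
        raise ValueError("oxo_levels must be distinct")
    noise = noise or NoiseModel()
    curve = kdapp_linkage(oxo_levels, preset.truth)
    cv = noise.kdapp_noise_cv
    if cv > 0:
        rng = np.random.default_rng(noise.require_seed())
        # lognormal with unit median and sd(log) = sqrt(log(1+cv^2)) so the
        # linear-scale coefficient of variation equals cv
        sigma = np.sqrt(np.log1p(cv * cv))
        kdapp = curve * np.exp(rng.normal(0.0, sigma, curve.size))
        se = cv * kdapp
    else:
        kdapp = curve
        se = None
    return LinkageDataset.from_arrays(
        oxo_levels, kdapp, se, label=f"{preset.name}/{preset.dna_label}"
    )
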