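"""End-to-end analysis: thermograms -> Kd_app series -> linkage fit -> report.

A pipeline run is described by a plain configuration mapping (usually loaded
from YAML)::

    reference: MIT9313
    seed: 1
    fit:
      exclude_first: false
    variants:
      MIT9313:
        preset: MIT9313          # simulate from a named preset, or:
        # thermograms: [a.csv, b.csv, ...]   load measured titrations
        oxo_levels: [0, 1, 5, 10]
        heat_noise_sd: 0.0

Each variant's titrations are fit individually for Kd_app, the Kd_app series
is fit with the linkage model, effective constants are derived, and all
variants are compared against the named reference. Any stage failure aborts
with the stage and variant named; partial results are never emitted silently.
Given the same configuration and seed the resulting document is
byte-identical apart from nothing (no timestamps are embedded).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .binding import Thermogram, classify_cooperativity
from .fitting import (
    LinkageDataset,
    LinkageFit,
    SingleSiteFit,
    UnderdeterminedError,
    compare_variants,
    fit_linkage,
    fit_single_site,
)
from .io import read_thermogram
from .simulate import NoiseModel, get_preset, simulate_thermogram

__all__ = ["PipelineError", "ResultsDocument", "run_pipeline", "plot_linkage"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and variant."""


@dataclass
class ResultsDocument:
    """Full record of one pipeline run: fits, comparison and provenance."""

    single_site_fits: dict[str, list[SingleSiteFit]]
    linkage_fits: dict[str, LinkageFit]
    comparison: "object"  # pandas DataFrame
    provenance: dict

    def to_dict(self) -> dict:
        def _ss(f: SingleSiteFit) -> dict:
            return {
                "oxo_mM": f.oxo, "kdapp_uM": f.kdapp, "se_kdapp_uM": f.se_kdapp,
                "delta_h_kcal_mol": f.delta_h, "n_stoich": f.n_stoich,
                "q_offset_ucal": f.q_offset, "c_value": f.c_value,
                "residual_norm": f.residual_norm, "converged": f.converged,
                "identifiable": f.identifiable, "label": f.label,
            }

        def _lf(f: LinkageFit) -> dict:
            eff = f.effective
            return {
                "kd_intrinsic_uM": f.params.kd_intrinsic,
                "kd_oxo_mM": f.params.kd_oxo,
                "alpha": f.params.alpha,
                "se_kd_intrinsic_uM": f.se_kd_intrinsic,
                "se_kd_oxo_mM": f.se_kd_oxo,
                "se_alpha": f.se_alpha,
                "kd_eff_uM": eff.kd_eff,
                "kd_oxo_eff_mM": eff.kd_oxo_eff,
                "cooperativity": classify_cooperativity(f.params.alpha)
                if not f.no_detectable_linkage else "none",
                "residual_norm": f.residual_norm,
                "converged": f.converged,
                "weighting": f.weighting_used,
                "no_detectable_linkage": f.no_detectable_linkage,
                "n_points": f.n_points,
            }

        return {
            "single_site_fits": {
                v: [_ss(f) for f in fits]
                for v, fits in self.single_site_fits.items()
            },
            "linkage_fits": {v: _lf(f) for v, f in self.linkage_fits.items()},
            "comparison": self.comparison.reset_index().to_dict(orient="records"),
            "provenance": self.provenance,
        }

    def to_json(self, path=None, *, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def render_text(self) -> str:
        """Human-readable per-variant summary and cross-variant comparison."""
        ref = self.provenance["reference"]
        lines = [
            "Effector-linkage analysis of protein-DNA binding",
            f"itclink {__version__}",
            "",
        ]
        for variant, lf in self.linkage_fits.items():
            p, eff = lf.params, lf.effective
            lines.append(f"[{variant}]")
            for ss in self.single_site_fits.get(variant, []):
                flag = "" if ss.identifiable else "  (low/high c: Kd poorly determined)"
                lines.append(
                    f"  titration oxo={ss.oxo:g} mM: Kd_app = "
                    f"{ss.kdapp:.4g} +/- {ss.se_kdapp:.2g} uM (c={ss.c_value:.2g}){flag}"
                )
            if lf.no_detectable_linkage:
                lines.append(
                    f"  linkage: no detectable effector linkage (alpha ~ 1); "
                    f"Kd = {p.kd_intrinsic:.3g} uM"
                )
            else:
                lines.append(
                    f"  linkage: Kd = {p.kd_intrinsic:.3g} +/- {lf.se_kd_intrinsic:.2g} uM, "
                    f"Kd_oxo = {p.kd_oxo:.3g} +/- {lf.se_kd_oxo:.2g} mM, "
                    f"alpha = {p.alpha:.3g} +/- {lf.se_alpha:.2g} "
                    f"({classify_cooperativity(p.alpha)} cooperativity)"
                )
                lines.append(
                    f"  derived: Kd_eff = Kd/alpha = {eff.kd_eff:.2g} uM, "
                    f"Kd_oxo_eff = Kd_oxo/alpha = {eff.kd_oxo_eff:.2g} mM"
                )
            lines.append("")
        lines.append(f"Fold differences vs reference '{ref}':")
        for variant, row in self.comparison.iterrows():
            if variant == ref:
                continue
            lines.append(
                f"  {variant}: Kd {row['kd_fold_vs_ref']:.2g}x, "
                f"Kd_oxo_eff {row['kd_oxo_eff_fold_vs_ref']:.2g}x, "
                f"alpha {row['alpha_fold_vs_ref']:.2g}x"
            )
        return "\n".join(lines) + "\n"


def _variant_seed(base_seed: int, variant_index: int, oxo_index: int) -> int:
    # deterministic per-titration stream, kept below 2**31
    return (base_seed * 1_000_003 + variant_index * 8_191 + oxo_index) % (2**31)


def _collect_thermograms(name, vcfg, base_seed, variant_index, exclude_first):
    thermos: list[Thermogram] = []
    if "thermograms" in vcfg:
        for path in vcfg["thermograms"]:
            tg = read_thermogram(path, exclude_first=exclude_first)
            thermos.append(tg)
    elif "preset" in vcfg:
        preset = get_preset(vcfg["preset"])
        oxo_levels = vcfg.get("oxo_levels", [0.0, 1.0, 5.0, 10.0])
        sd = float(vcfg.get("heat_noise_sd", 0.0))
        for j, oxo in enumerate(oxo_levels):
            noise = NoiseModel(
                heat_noise_sd=sd,
                seed=_variant_seed(base_seed, variant_index, j) if sd > 0 else None,
            )
            tg = simulate_thermogram(preset, oxo=float(oxo), noise=noise)
            if exclude_first:
                tg = tg.exclude_first()
            thermos.append(tg)
    else:
        raise PipelineError(
            f"stage=input variant={name}: need 'thermograms' or 'preset'"
        )
    return thermos


def run_pipeline(config: dict) -> ResultsDocument:
    """Run the full two-stage analysis described by ``config``.

    See the module docstring for the configuration schema. Returns a
    :class:`ResultsDocument`; raises :class:`PipelineError` naming the failed
    stage and variant on any error.
    """
    if "variants" not in config or not config["variants"]:
        raise PipelineError("stage=config: no variants defined")
    variants = config["variants"]
    reference = config.get("reference") or next(iter(variants))
    if reference not in variants:
        raise PipelineError(f"stage=config: reference '{reference}' not a variant")
    base_seed = int(config.get("seed", 0))
    fit_cfg = config.get("fit", {})
    exclude_first = bool(fit_cfg.get("exclude_first", False))
    log_scale = bool(fit_cfg.get("log_scale", True))
    weighting = fit_cfg.get("weighting", "none")

    single_site: dict[str, list[SingleSiteFit]] = {}
    linkage: dict[str, LinkageFit] = {}

    for vi, (name, vcfg) in enumerate(variants.items()):
        try:
            thermos = _collect_thermograms(
                name, vcfg, base_seed, vi, exclude_first
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage=input variant={name}: {exc}") from exc

        oxos = [t.protocol.effector_conc for t in thermos]
        if len(set(oxos)) < 3:
            raise PipelineError(
                f"stage=single_site variant={name}: underdetermined — "
                f"need >= 3 distinct effector levels, got {sorted(set(oxos))}"
            )

        fits = []
        for tg in thermos:
            try:
                ss = fit_single_site(
                    tg,
                    fix_n_stoich=fit_cfg.get("fix_n_stoich"),
                    fix_q_offset=fit_cfg.get("fix_q_offset"),
                )
            except Exception as exc:
                raise PipelineError(
                    f"stage=single_site variant={name} "
                    f"oxo={tg.protocol.effector_conc}: {exc}"
                ) from exc
            if not ss.converged:
                raise PipelineError(
                    f"stage=single_site variant={name} oxo={ss.oxo}: "
                    f"fit did not converge ({ss.message})"
                )
            logger.info(
                "variant %s oxo=%g: kdapp=%.4g uM (c=%.3g)",
                name, ss.oxo, ss.kdapp, ss.c_value,
            )
            fits.append(ss)
        single_site[name] = fits

        dataset = LinkageDataset.from_arrays(
            [f.oxo for f in fits],
            [f.kdapp for f in fits],
            [f.se_kdapp if f.se_kdapp > 0 else None for f in fits],
            label=name,
        )
        try:
            lf = fit_linkage(dataset, log_scale=log_scale, weighting=weighting)
        except UnderdeterminedError as exc:
            raise PipelineError(f"stage=linkage variant={name}: {exc}") from exc
        except Exception as exc:
            raise PipelineError(f"stage=linkage variant={name}: {exc}") from exc
        linkage[name] = lf

    try:
        comparison = compare_variants(linkage, reference)
    except Exception as exc:
        raise PipelineError(f"stage=comparison: {exc}") from exc

    provenance = {
        "software": f"itclink {__version__}",
        "seed": base_seed,
        "reference": reference,
        "config": _jsonable(config),
    }
    return ResultsDocument(
        single_site_fits=single_site,
        linkage_fits=linkage,
        comparison=comparison,
        provenance=provenance,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def plot_linkage(document: ResultsDocument, path=None, oxo_max: float = 12.0):
    """Kd_app vs effector concentration per variant, with fitted curves.

    Requires matplotlib. Returns the figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .binding import kdapp_linkage

    fig, ax = plt.subplots(figsize=(5.0, 3.6))
    grid = np.linspace(0.0, oxo_max, 200)
    for variant, lf in document.linkage_fits.items():
        fits = document.single_site_fits.get(variant, [])
        oxo = [f.oxo for f in fits]
        kd = [f.kdapp for f in fits]
        pts = ax.scatter(oxo, kd, label=variant, zorder=3)
        ax.plot(grid, kdapp_linkage(grid, lf.params),
                color=pts.get_facecolor()[0], lw=1.2)
    ax.set_xlabel("effector concentration (mM)")
    ax.set_ylabel(r"K$_{d,app}$ ($\mu$M)")
    ax.set_yscale("log")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
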