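"""Two-stage nonlinear least-squares inference for effector-linked ITC data.

Stage 1 (:func:`fit_single_site`): each titration thermogram is fit with the
single-site incremental-heat model to yield one apparent dissociation constant
Kd_app at that run's effector concentration.

Stage 2 (:func:`fit_linkage`): the (effector, Kd_app) points are fit with the
heterotropic linkage equation to estimate the intrinsic Kd, the effector
dissociation constant Kd_oxo, and the cooperativity constant alpha, from which
the effective constants Kd/alpha and Kd_oxo/alpha follow.

Positivity of Kd-family and alpha parameters is enforced by optimizing their
logarithms; linkage residuals are taken on log(Kd_app) by default so that the
order-of-magnitude span of the curve does not let the zero-effector point
dominate. Asymptotic standard errors come from the Jacobian at the optimum;
:func:`bootstrap_linkage` provides resampling intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .binding import (
    BindingParameters,
    EffectiveConstants,
    LinkageParameters,
    Thermogram,
    effective_constants,
    injection_heat_series,
    kdapp_linkage,
)

__all__ = [
    "SingleSiteFit",
    "LinkagePoint",
    "LinkageDataset",
    "LinkageFit",
    "BootstrapResult",
    "BindingSignalAbsentError",
    "UnderdeterminedError",
    "FitConvergenceError",
    "fit_single_site",
    "fit_linkage",
    "bootstrap_linkage",
    "compare_variants",
]

logger = logging.getLogger(__name__)

# c-value (site concentration / Kd) window outside which a titration cannot
# determine the affinity reliably
C_VALUE_LOW = 1.0
C_VALUE_HIGH = 1000.0


class BindingSignalAbsentError(ValueError):
    """Thermogram carries no binding signal above the noise floor."""


class UnderdeterminedError(ValueError):
    """Fewer data points than the model can be identified from."""


class FitConvergenceError(RuntimeError):
    """All restarts of a fit failed."""


@dataclass
class SingleSiteFit:
    """Result of a per-titration single-site fit."""

    kdapp: float
    delta_h: float
    n_stoich: float
    q_offset: float
    se_kdapp: float
    se_delta_h: float
    se_n_stoich: float
    se_q_offset: float
    residual_norm: float
    c_value: float
    converged: bool
    identifiable: bool
    oxo: float = 0.0
    label: str = ""
    message: str = ""

    @property
    def params(self) -> BindingParameters:
        return BindingParameters(
            kd=self.kdapp,
            delta_h=self.delta_h,
            n_stoich=self.n_stoich,
            q_offset=self.q_offset,
        )


@dataclass(frozen=True)
class LinkagePoint:
    oxo: float  # mM
    kdapp: float  # uM
    se_kdapp: float | None = None  # uM


@dataclass
class LinkageDataset:
    """(effector concentration, Kd_app) points for one promoter variant."""

    points: list[LinkagePoint]
    label: str = ""

    def __post_init__(self) -> None:
        oxos = [p.oxo for p in self.points]
        if any(o < 0 for o in oxos):
            raise ValueError("effector concentrations must be non-negative")
        if len(set(oxos)) != len(oxos):
            raise ValueError("effector concentrations must be distinct")
        if any(p.kdapp <= 0 for p in self.points):
            raise ValueError("kdapp values must be positive")
        self.points = sorted(self.points, key=lambda p: p.oxo)

    @property
    def oxo(self) -> np.ndarray:
        return np.array([p.oxo for p in self.points])

    @property
    def kdapp(self) -> np.ndarray:
        return np.array([p.kdapp for p in self.points])

    @property
    def se(self) -> np.ndarray | None:
        ses = [p.se_kdapp for p in self.points]
        if any(s is None for s in ses):
            return None
        return np.array(ses, dtype=float)

    @classmethod
    def from_arrays(cls, oxo, kdapp, se=None, label: str = "") -> "LinkageDataset":
        if se is None:
            se = [None] * len(oxo)
        pts = [LinkagePoint(float(o), float(k), None if s is None else float(s))
               for o, k, s in zip(oxo, kdapp, se)]
        return cls(points=pts, label=label)


@dataclass
class LinkageFit:
    """Fitted linkage model with uncertainties and derived constants."""

    params: LinkageParameters
    se_kd_intrinsic: float
    se_kd_oxo: float
    se_alpha: float
    residual_norm: float
    converged: bool
    weighting_used: str  # "none" | "inverse_variance"
    no_detectable_linkage: bool = False
    n_points: int = 0
    label: str = ""
    correlation: np.ndarray | None = None
    starts_tried: int = 0

    @property
    def effective(self) -> EffectiveConstants:
        # always recomputed from params, never stored separately
        return effective_constants(self.params)


@dataclass
class BootstrapResult:
    """Percentile bootstrap intervals for the linkage parameters."""

    intervals: dict[str, tuple[float, float]]
    estimates: dict[str, float]
    n_boot: int
    n_failed: int
    level: float
    method: str  # "residual" | "parametric"


# ---------------------------------------------------------------------------
# stage 1: single-site thermogram fit
# ---------------------------------------------------------------------------

def _predict_heats(protocol, kd, dh, n, offset, first_excluded: bool):
    params = BindingParameters(kd=kd, delta_h=dh, n_stoich=n, q_offset=offset)
    q = injection_heat_series(protocol, params).heats
    return q[1:] if first_excluded else q


def fit_single_site(
    thermogram: Thermogram,
    *,
    fix_n_stoich: float | None = None,
    fix_q_offset: float | None = None,
    noise_floor: float = 1e-9,
    max_nfev: int = 10_000,
) -> SingleSiteFit:
    """Fit the single-site model to one thermogram, yielding Kd_app.

    Optimizes (log kdapp, delta_h, log n_stoich, q_offset); ``fix_n_stoich``
    and/or ``fix_q_offset`` remove those parameters from the optimization.
    A small multi-start ladder over initial Kd guesses guards against the
    shallow-isotherm local optima of low-c titrations. Flags the fit as
    non-identifiable when the c-value (site concentration / Kd_app) is outside
    [1, 1000].

    Raises
    ------
    BindingSignalAbsentError
        If the heat series is flat (variance below ``noise_floor``, ucal^2).
    UnderdeterminedError
        If fewer than 5 usable injections are available.
    """
    if thermogram.units != "ucal":
        raise ValueError("fit expects raw heats in ucal")
    if thermogram.n_usable < 5:
        raise UnderdeterminedError(
            f"need >= 5 usable injections, got {thermogram.n_usable}"
        )
    heats = thermogram.heats
    if float(np.var(heats)) <= noise_floor:
        raise BindingSignalAbsentError(
            "binding signal absent: thermogram heat variance below noise floor"
        )

    protocol = thermogram.protocol
    first_excluded = thermogram.first_injection_excluded
    sites = protocol.cell_sites_total

    # crude initial guesses from the heat series itself
    total_heat = float(np.sum(heats))
    dh0 = total_heat / (protocol.cell_volume * sites / 1000.0)
    dh0 = dh0 if abs(dh0) > 1e-3 else math.copysign(1.0, total_heat or -1.0)
    offset0 = float(heats[-1]) if fix_q_offset is None else fix_q_offset
    n0 = 1.0 if fix_n_stoich is None else fix_n_stoich

    free_n = fix_n_stoich is None
    free_off = fix_q_offset is None

    def pack(kd, dh, n, off):
        theta = [math.log(kd), dh]
        if free_n:
            theta.append(math.log(n))
        if free_off:
            theta.append(off)
        return np.array(theta)

    def unpack(theta):
        kd = math.exp(theta[0])
        dh = theta[1]
        idx = 2
        n = math.exp(theta[idx]) if free_n else fix_n_stoich
        idx += free_n
        off = theta[idx] if free_off else fix_q_offset
        return kd, dh, n, off

    def residuals(theta):
        kd, dh, n, off = unpack(theta)
        return _predict_heats(protocol, kd, dh, n, off, first_excluded) - heats

    kd_starts = [sites, sites / 10.0, sites * 10.0, sites / 100.0]
    best = None
    starts_tried = 0
    for kd0 in kd_starts:
        starts_tried += 1
        try:
            sol = least_squares(
                residuals,
                pack(kd0, dh0, n0, offset0),
                method="lm",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=max_nfev,
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.debug("single-site start kd0=%g failed: %s", kd0, exc)
            continue
        if best is None or sol.cost < best.cost - 1e-15 * (1 + best.cost):
            best = sol
    logger.info(
        "single-site fit '%s': %d starts, best residual %.3g",
        protocol.label, starts_tried, float("nan") if best is None else best.cost,
    )
    if best is None or not best.success:
        return SingleSiteFit(
            kdapp=math.nan, delta_h=math.nan, n_stoich=math.nan, q_offset=math.nan,
            se_kdapp=math.nan, se_delta_h=math.nan, se_n_stoich=math.nan,
            se_q_offset=math.nan, residual_norm=math.nan, c_value=math.nan,
            converged=False, identifiable=False, oxo=protocol.effector_conc,
            label=protocol.label,
            message="no start converged" if best is None else best.message,
        )

    kd, dh, n, off = unpack(best.x)
    se_theta = _asymptotic_se(best.jac, best.fun)
    # delta method: se(exp(t)) = exp(t) * se(t)
    se = {"kd": kd * se_theta[0], "dh": se_theta[1]}
    idx = 2
    se["n"] = n * se_theta[idx] if free_n else 0.0
    idx += free_n
    se["off"] = se_theta[idx] if free_off else 0.0

    c_value = n * sites / kd
    return SingleSiteFit(
        kdapp=kd,
        delta_h=dh,
        n_stoich=n,
        q_offset=off,
        se_kdapp=se["kd"],
        se_delta_h=se["dh"],
        se_n_stoich=se["n"],
        se_q_offset=se["off"],
        residual_norm=float(np.linalg.norm(best.fun)),
        c_value=c_value,
        converged=True,
        identifiable=C_VALUE_LOW <= c_value <= C_VALUE_HIGH,
        oxo=protocol.effector_conc,
        label=protocol.label,
        message=best.message,
    )


def _asymptotic_se(jac: np.ndarray, resid: np.ndarray) -> np.ndarray:
    """Asymptotic standard errors from the Jacobian at the optimum."""
    m, p = jac.shape
    dof = max(m - p, 1)
    s2 = float(resid @ resid) / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


# ---------------------------------------------------------------------------
# stage 2: linkage fit
# ---------------------------------------------------------------------------

def _linkage_residuals_factory(dataset: LinkageDataset, log_scale: bool,
                               weights: np.ndarray | None):
    oxo = dataset.oxo
    kdapp = dataset.kdapp
    log_kdapp = np.log(kdapp)

    def residuals(theta):
        # errstate: LM may probe extreme log-parameters; non-finite residuals
        # are handled by the solver's step rejection
        with np.errstate(all="ignore"):
            kd, kdoxo, alpha = np.exp(theta)
            r = oxo / kdoxo
            pred = kd * (1.0 + r) / (1.0 + alpha * r)
            if log_scale:
                res = np.log(pred) - log_kdapp
            else:
                res = pred - kdapp
        return res if weights is None else res * weights

    return residuals


def fit_linkage(
    dataset: LinkageDataset,
    *,
    log_scale: bool = True,
    weighting: str = "none",
    fix_alpha: float | None = None,
    flat_rel_tol: float = 1e-6,
    max_nfev: int = 10_000,
) -> LinkageFit:
    """Fit Kd, Kd_oxo and alpha to a (effector, Kd_app) dataset.

    Multi-start least squares in log-parameter space. Residuals are taken on
    log(Kd_app) by default (``log_scale=False`` for linear residuals);
    ``weighting="inverse_variance"`` uses the points' standard errors. If the
    Kd_app values are flat to within ``flat_rel_tol`` relative spread, returns
    alpha = 1 with ``no_detectable_linkage`` set instead of failing.
    ``fix_alpha`` pins alpha (e.g. to 1 for a non-binding promoter variant)
    and fits the remaining parameters.

    Raises
    ------
    UnderdeterminedError
        Fewer distinct effector levels than free parameters.
    """
    n_free = 3 if fix_alpha is None else 2
    if len(dataset.points) < n_free:
        raise UnderdeterminedError(
            f"underdetermined: {len(dataset.points)} points for a "
            f"{n_free}-parameter linkage fit"
        )

    kdapp = dataset.kdapp
    oxo = dataset.oxo

    if weighting not in ("none", "inverse_variance"):
        raise ValueError("weighting must be 'none' or 'inverse_variance'")
    weights = None
    if weighting == "inverse_variance":
        se = dataset.se
        if se is None or np.any(se <= 0):
            raise ValueError("inverse-variance weighting needs positive SEs")
        weights = (kdapp / se) if log_scale else (1.0 / se)
        # log-scale: se(log k) ~ se/k, weight = 1/se(log k)

    # flat data: no detectable linkage. The threshold is the stated relative
    # tolerance, widened to the points' own relative SEs when those are known,
    # so "equal within noise" yields alpha ~ 1 with a flag rather than a
    # degenerate three-parameter fit.
    flat_thresh = flat_rel_tol
    if dataset.se is not None and np.all(dataset.se > 0):
        flat_thresh = max(flat_thresh, 2.0 * float(np.median(dataset.se / kdapp)))
    spread = (kdapp.max() - kdapp.min()) / kdapp.mean()
    if fix_alpha is None and spread < flat_thresh:
        params = LinkageParameters(
            kd_intrinsic=float(np.exp(np.mean(np.log(kdapp)))),
            kd_oxo=1.0,
            alpha=1.0,
        )
        return LinkageFit(
            params=params,
            se_kd_intrinsic=float(np.std(kdapp, ddof=1) / math.sqrt(len(kdapp)))
            if len(kdapp) > 1 else 0.0,
            se_kd_oxo=math.inf,
            se_alpha=math.inf,
            residual_norm=float(np.linalg.norm(np.log(kdapp) - np.mean(np.log(kdapp)))),
            converged=True,
            weighting_used=weighting,
            no_detectable_linkage=True,
            n_points=len(dataset.points),
            label=dataset.label,
        )

    if fix_alpha is not None:
        return _fit_linkage_fixed_alpha(
            dataset, fix_alpha, log_scale, weighting, weights, max_nfev
        )

    residuals = _linkage_residuals_factory(dataset, log_scale, weights)

    # multi-start grid
    kd0 = kdapp[np.argmin(oxo)]
    ratio = kdapp[np.argmin(oxo)] / kdapp[np.argmax(oxo)]
    alpha_starts = {max(ratio, 1e-3), 0.5, 2.0, 10.0, 30.0}
    kdoxo_starts = (1.0, 10.0, 100.0)

    best = None
    best_alpha = math.inf
    starts = 0
    for a0 in sorted(alpha_starts):
        for ko0 in kdoxo_starts:
            starts += 1
            theta0 = np.log([kd0, ko0, a0])
            try:
                sol = least_squares(
                    residuals, theta0, method="lm",
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=max_nfev,
                )
            except Exception:
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            a_here = math.exp(sol.x[2])
            better = best is None or sol.cost < best.cost * (1 - 1e-9) - 1e-30
            tie = best is not None and abs(sol.cost - best.cost) <= 1e-9 * (
                best.cost + 1e-30
            )
            if better or (tie and a_here < best_alpha):
                best = sol
                best_alpha = a_here
    logger.info(
        "linkage fit '%s': %d starts, best residual %.3g",
        dataset.label, starts, float("nan") if best is None else best.cost,
    )
    if best is None:
        raise FitConvergenceError("linkage fit: no start converged")

    kd, kdoxo, alpha = np.exp(best.x)
    se_theta = _asymptotic_se(best.jac, best.fun)
    jtj = best.jac.T @ best.jac
    corr = None
    try:
        cov = np.linalg.inv(jtj)
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
    except np.linalg.LinAlgError:
        pass

    params = LinkageParameters(kd_intrinsic=kd, kd_oxo=kdoxo, alpha=alpha)
    return LinkageFit(
        params=params,
        se_kd_intrinsic=kd * se_theta[0],
        se_kd_oxo=kdoxo * se_theta[1],
        se_alpha=alpha * se_theta[2],
        residual_norm=float(np.linalg.norm(best.fun)),
        converged=bool(best.success),
        weighting_used=weighting,
        no_detectable_linkage=False,
        n_points=len(dataset.points),
        label=dataset.label,
        correlation=corr,
        starts_tried=starts,
    )


def _fit_linkage_fixed_alpha(dataset, alpha, log_scale, weighting, weights,
                             max_nfev):
    oxo, kdapp = dataset.oxo, dataset.kdapp
    log_kdapp = np.log(kdapp)

    def residuals(theta):
        with np.errstate(all="ignore"):
            kd, kdoxo = np.exp(theta)
            r = oxo / kdoxo
            pred = kd * (1.0 + r) / (1.0 + alpha * r)
            res = (np.log(pred) - log_kdapp) if log_scale else (pred - kdapp)
        return res if weights is None else res * weights

    kd0 = kdapp[np.argmin(oxo)]
    best = None
    for ko0 in (1.0, 10.0, 100.0):
        try:
            sol = least_squares(
                residuals, np.log([kd0, ko0]), method="lm",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=max_nfev,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitConvergenceError("linkage fit (fixed alpha): no start converged")
    kd, kdoxo = np.exp(best.x)
    se_theta = _asymptotic_se(best.jac, best.fun)
    return LinkageFit(
        params=LinkageParameters(kd_intrinsic=kd, kd_oxo=kdoxo, alpha=alpha),
        se_kd_intrinsic=kd * se_theta[0],
        se_kd_oxo=kdoxo * se_theta[1],
        se_alpha=0.0,
        residual_norm=float(np.linalg.norm(best.fun)),
        converged=bool(best.success),
        weighting_used=weighting,
        no_detectable_linkage=abs(alpha - 1.0) < 1e-12,
        n_points=len(dataset.points),
        label=dataset.label,
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_linkage(
    dataset: LinkageDataset,
    n_boot: int = 500,
    seed: int | None = None,
    *,
    level: float = 0.95,
    log_scale: bool = True,
    weighting: str = "none",
    max_failure_frac: float = 0.2,
) -> BootstrapResult:
    """Percentile bootstrap intervals for (kd, kd_oxo, alpha, kd_eff, kd_oxo_eff).

    Uses parametric resampling (lognormal around the fitted curve with the
    points' SE-implied coefficients of variation) when every point carries a
    standard error, otherwise residual resampling on the log scale. Replicate
    fits warm-start from the full-data fit. Deterministic under a fixed seed.

    Raises
    ------
    FitConvergenceError
        If more than ``max_failure_frac`` of the replicates fail to fit.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if seed is None:
        raise ValueError("a seed is required for reproducible bootstrap")
    rng = np.random.default_rng(seed)

    base = fit_linkage(dataset, log_scale=log_scale, weighting=weighting)
    p = base.params
    oxo = dataset.oxo
    fitted = kdapp_linkage(oxo, p)
    log_resid = np.log(dataset.kdapp) - np.log(fitted)

    se = dataset.se
    parametric = se is not None and np.all(se > 0)
    if parametric:
        log_sd = se / dataset.kdapp  # cv on linear scale ~ sd on log scale
    theta0 = np.log([p.kd_intrinsic, p.kd_oxo, p.alpha])

    names = ("kd_intrinsic", "kd_oxo", "alpha", "kd_eff", "kd_oxo_eff")
    draws = {k: [] for k in names}
    n_failed = 0
    for _ in range(n_boot):
        if parametric:
            noise = rng.normal(0.0, log_sd)
        else:
            noise = rng.choice(log_resid, size=log_resid.size, replace=True)
        kdapp_b = fitted * np.exp(noise)
        ds_b = LinkageDataset.from_arrays(oxo, kdapp_b, label=dataset.label)
        res = _linkage_residuals_factory(ds_b, log_scale, None)
        try:
            sol = least_squares(res, theta0, method="lm",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                max_nfev=5000)
        except Exception:
            n_failed += 1
            continue
        if not (sol.success and np.all(np.isfinite(sol.x))):
            n_failed += 1
            continue
        kd, kdoxo, alpha = np.exp(sol.x)
        draws["kd_intrinsic"].append(kd)
        draws["kd_oxo"].append(kdoxo)
        draws["alpha"].append(alpha)
        draws["kd_eff"].append(kd / alpha)
        draws["kd_oxo_eff"].append(kdoxo / alpha)

    if n_failed > max_failure_frac * n_boot:
        raise FitConvergenceError(
            f"bootstrap: {n_failed}/{n_boot} replicate fits failed"
        )

    lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    eff = base.effective
    estimates = {
        "kd_intrinsic": p.kd_intrinsic, "kd_oxo": p.kd_oxo, "alpha": p.alpha,
        "kd_eff": eff.kd_eff, "kd_oxo_eff": eff.kd_oxo_eff,
    }
    intervals = {
        k: (float(np.percentile(v, lo)), float(np.percentile(v, hi)))
        for k, v in draws.items()
    }
    return BootstrapResult(
        intervals=intervals,
        estimates=estimates,
        n_boot=n_boot,
        n_failed=n_failed,
        level=level,
        method="parametric" if parametric else "residual",
    )


# ---------------------------------------------------------------------------
# cross-variant comparison
# ---------------------------------------------------------------------------

def compare_variants(fits: dict[str, LinkageFit], reference: str):
    """Fold differences of each variant's constants relative to a reference.

    Returns a pandas DataFrame with the fitted constants and the ratios
    kd / kd(ref), kd_oxo_eff / kd_oxo_eff(ref), alpha / alpha(ref). Ratios are
    reported at full precision; rounding is the report renderer's job.
    """
    import pandas as pd

    if len(fits) < 2:
        raise ValueError("need at least two variants to compare")
    if reference not in fits:
        raise KeyError(f"reference variant '{reference}' not among fits")
    ref = fits[reference]
    rows = []
    for name, fit in fits.items():
        p, eff = fit.params, fit.effective
        ref_eff = ref.effective
        rows.append({
            "variant": name,
            "kd_intrinsic_uM": p.kd_intrinsic,
            "kd_oxo_mM": p.kd_oxo,
            "alpha": p.alpha,
            "kd_eff_uM": eff.kd_eff,
            "kd_oxo_eff_mM": eff.kd_oxo_eff,
            "kd_fold_vs_ref": p.kd_intrinsic / ref.params.kd_intrinsic,
            "kd_oxo_eff_fold_vs_ref": eff.kd_oxo_eff / ref_eff.kd_oxo_eff,
            "alpha_fold_vs_ref": p.alpha / ref.params.alpha,
        })
    df = pd.DataFrame(rows).set_index("variant")
    df.attrs["reference"] = reference
    return df
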