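"""Independent brute-force oracles used to pin the equilibrium conventions.

These deliberately avoid the package's closed-form quadratic and vectorized
heat model: the complex concentration is found by scalar bisection on the
mass-balance equation, and the injection heats are rebuilt step by step.
"""

from __future__ import annotations

from decimal import Decimal, getcontext

import numpy as np

getcontext().prec = 60


def bisect_bound_complex(m_total: float, x_total: float, kd: float,
                         rel_tol: float = 1e-13, max_iter: int = 300) -> float:
    """Complex concentration by bisection on (M-mx)(X-mx) = Kd*mx.

    The mass-balance residual is evaluated in 60-digit decimal arithmetic so
    the bracketing sign is exact even in the tight-binding corner, where the
    float residual suffers catastrophic cancellation.
    """
    if m_total == 0.0 or x_total == 0.0:
        return 0.0
    m, x, k = Decimal(m_total), Decimal(x_total), Decimal(kd)

    def f(mx: Decimal) -> Decimal:
        return (m - mx) * (x - mx) - k * mx

    lo, hi = Decimal(0), min(m, x)
    tol = Decimal(rel_tol)
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= tol * hi:
            break
    return float((lo + hi) / 2)


def brute_force_heats(cell_volume: float, injection_volume: float,
                      n_injections: int, sites0: float, syringe_conc: float,
                      kd: float, delta_h: float, q_offset: float = 0.0,
                      n_stoich: float = 1.0) -> np.ndarray:
    """Re-derive the raw heat series injection by injection.

    Overfill/displacement convention: after injection i the species initially
    in the cell are diluted by (1 - dV/V0)**i and the titrant has accumulated
    to X_syr * (1 - (1 - dV/V0)**i); the displaced-volume (mean-concentration)
    correction adds (dV/V0) * (Q_i + Q_{i-1}) / 2 to each differential heat.
    """
    d = 1.0 - injection_volume / cell_volume
    q_prev = 0.0
    heats = []
    for i in range(1, n_injections + 1):
        m = n_stoich * sites0 * d**i
        x = syringe_conc * (1.0 - d**i)
        mx = bisect_bound_complex(m, x, kd)
        q_total = cell_volume * delta_h * mx / 1000.0
        dv = injection_volume / cell_volume
        heats.append(q_total - q_prev + dv * (q_total + q_prev) / 2.0 + q_offset)
        q_prev = q_total
    return np.array(heats)
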