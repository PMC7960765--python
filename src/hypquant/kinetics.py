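"""Internal-standard product quantification and Michaelis–Menten fitting.

Product concentration in each stopped reaction is recovered from LC-MS peak
areas under the shared-response-factor assumption: the internal standard
relates to the substrate exactly as it relates to the product, so the
product fraction of the total analyte signal maps directly onto the known
starting concentration. Velocities are endpoint estimates (product / time),
and (Km, vmax) come from nonlinear least squares on v = vmax·S/(Km+S),
initialized from a Hanes–Woolf linearization.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

from .synthetic_data import KineticAssay, KineticParameters

__all__ = [
    "product_concentration",
    "initial_velocity",
    "fit_michaelis_menten",
    "fit_assay",
]


def product_concentration(
    s0_um: float, area_substrate: float, area_product: float, area_is: float, is_conc: float
) -> float:
    """Product concentration (μM) of one assay row.

    Primary form: ``[P] = S0 · A_P / (A_S + A_P)``. The internal-standard
    normalized form — response factor calibrated from total analyte vs
    standard, then applied to the product area — reduces to the same value
    under the shared-response-factor assumption; both are computed and their
    agreement asserted.
    """
    if area_is <= 0:
        raise ValueError("internal standard area must be positive")
    total = area_substrate + area_product
    if total <= 0:
        raise ValueError("zero total analyte area")
    primary = s0_um * area_product / total
    # IS-normalized route: product response ratio times the calibration factor
    # (total analyte vs standard), computed as written to exercise the algebra
    cross_check = (
        is_conc * (area_product / area_is) * (s0_um * area_is / (total * is_conc))
    )
    assert abs(primary - cross_check) <= 1e-9 * max(1.0, abs(primary)), (
        "internal inconsistency in shared-response-factor algebra"
    )
    return primary


def initial_velocity(p_conc_um: float, reaction_time_min: float) -> float:
    """Endpoint velocity estimate v = [P]/t in μM/min."""
    if reaction_time_min <= 0:
        raise ValueError("reaction time must be positive")
    if p_conc_um < 0:
        raise ValueError("product concentration cannot be negative")
    return p_conc_um / reaction_time_min


def _michaelis_menten(s: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * s / (km + s)


def _hanes_woolf_init(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Initial (vmax, Km) from the S/v vs S regression; clipped to positive."""
    ok = v > 0
    if ok.sum() < 2:
        return max(float(v.max()), 1e-9), float(np.median(s))
    slope, intercept = np.polyfit(s[ok], s[ok] / v[ok], 1)
    vmax0 = 1.0 / slope if slope > 0 else float(v.max())
    km0 = intercept * vmax0 if intercept > 0 else float(np.median(s))
    return max(vmax0, 1e-9), max(km0, 1e-9)


def fit_michaelis_menten(s_um: np.ndarray, v_um_min: np.ndarray) -> KineticParameters:
    """Nonlinear least-squares fit of v = vmax·S/(Km+S).

    Velocities are weighted equally. Standard errors come from the Jacobian
    covariance. Raises on non-convergence or degenerate substrate grids.
    """
    s = np.asarray(s_um, dtype=float)
    v = np.asarray(v_um_min, dtype=float)
    if len(np.unique(s)) < 3:
        raise ValueError("need at least 3 distinct substrate concentrations")
    vmax0, km0 = _hanes_woolf_init(s, v)
    try:
        popt, pcov = curve_fit(
            _michaelis_menten,
            s,
            v,
            p0=(vmax0, km0),
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Michaelis–Menten fit did not converge: {exc}") from exc
    vmax, km = popt
    se = np.sqrt(np.diag(pcov))
    return KineticParameters(km=float(km), vmax=float(vmax), se_km=float(se[1]), se_vmax=float(se[0]))


def fit_assay(assay: KineticAssay) -> KineticParameters:
    """Full pipeline for one assay table: areas → [P] → v → (Km, vmax)."""
    rows = assay.table
    p = np.array(
        [
            product_concentration(
                row.s0_um, row.area_substrate, row.area_product, row.area_is, assay.is_conc
            )
            for row in rows.itertuples()
        ]
    )
    v = p / assay.reaction_time
    return fit_michaelis_menten(rows["s0_um"].to_numpy(), v)
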