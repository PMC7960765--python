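"""EIC extraction and relative quantification of hydroxyproline stoichiometry.

The stoichiometry of a 0..k-times oxidized peptide family is measured by
summing, per oxidation state, the integrated extracted-ion-chromatogram
areas of the first four isotopic peaks over all observed charge states.
When ammonium adducts overlap the +1 isotopic peak of the next oxidation
state, quantification falls back to monoisotopic peaks only.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .constants import C13_C12_DELTA
from .peptide_chem import (
    AMMONIUM_ADDUCT_SHIFT,
    elemental_composition,
    enumerate_oxoforms,
    isotope_distribution,
    monoisotopic_mass,
    mz,
    proline_sites,
)
from .synthetic_data import ScanSet

__all__ = [
    "EIC",
    "HypDistribution",
    "extract_eic",
    "integrate_peak",
    "quantify_stoichiometry",
    "quantify_stoichiometry_monoiso",
    "detect_adduct_overlap",
    "average_hyp",
    "percent_change",
]


@dataclass(frozen=True)
class EIC:
    """Extracted ion chromatogram: summed intensity within an m/z window."""

    target_mz: float
    tolerance_ppm: float
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.rt) <= 0):
            raise ValueError("retention times must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class HypDistribution:
    """Relative abundances of 0..k-times hydroxylated species of one peptide.

    ``fractions_percent`` are percentages summing to ~100; ``average_hyp``
    is the expected hydroxyproline count rounded to 2 decimals (half away
    from zero), matching how such tables are conventionally printed.
    """

    peptide: str
    fractions_percent: tuple[float, ...]
    average_hyp: float
    average_hyp_raw: float
    percent_change: int | None = None

    @property
    def unit_fractions(self) -> np.ndarray:
        f = np.asarray(self.fractions_percent) / 100.0
        return f / f.sum()


def extract_eic(scans: ScanSet, target_mz: float, tolerance_ppm: float = 10.0) -> EIC:
    """Per-scan sum of intensities within ±tolerance of ``target_mz``."""
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    half_window = target_mz * tolerance_ppm * 1e-6
    rts = np.array([rt for rt, _, _ in scans.scans])
    trace = np.array(
        [
            intens[np.abs(mzs - target_mz) <= half_window].sum()
            for _, mzs, intens in scans.scans
        ]
    )
    return EIC(target_mz, tolerance_ppm, rts, trace)


def integrate_peak(eic: EIC, rt_window: tuple[float, float] | None = None) -> float:
    """Trapezoidal integral of an EIC trace over an rt window (default: all)."""
    if rt_window is None:
        rt_window = (float(eic.rt[0]), float(eic.rt[-1]))
    lo, hi = rt_window
    if hi < lo:
        raise ValueError(f"inverted rt window: {rt_window}")
    mask = (eic.rt >= lo) & (eic.rt <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(eic.intensity[mask], eic.rt[mask]))


def _species_abundances(
    scans: ScanSet,
    peptide: str,
    max_ox: int,
    charges: tuple[int, ...],
    n_iso: int,
    tolerance_ppm: float,
    envelope_correction: bool,
) -> np.ndarray:
    abundances = np.zeros(max_ox + 1)
    for n_ox in range(max_ox + 1):
        pf = enumerate_oxoforms(peptide, n_ox=n_ox)[0]  # m/z independent of site
        mass = monoisotopic_mass(pf)
        for z in charges:
            mono = mz(mass, z)
            for k in range(n_iso):
                eic = extract_eic(scans, mono + k * C13_C12_DELTA / z, tolerance_ppm)
                abundances[n_ox] += integrate_peak(eic)
        if envelope_correction:
            # each oxidation state adds an oxygen, so the first n_iso peaks
            # capture a slightly different share of each species' envelope;
            # dividing by that share removes the composition-dependent bias
            env = isotope_distribution(elemental_composition(pf), n_peaks=30)
            abundances[n_ox] /= env.abundances[:n_iso].sum()
    return abundances


def quantify_stoichiometry(
    scans: ScanSet,
    peptide: str,
    max_ox: int,
    charges: tuple[int, ...] = (2, 3),
    n_iso: int = 4,
    tolerance_ppm: float = 10.0,
    control: "HypDistribution | None" = None,
    envelope_correction: bool = True,
) -> HypDistribution:
    """Relative quantification over the first ``n_iso`` isotopic peaks.

    For each oxidation state the EIC areas of the first ``n_iso`` isotopic
    peaks are summed over all charge states; fractions are normalized to
    100%. Positional isomers share m/z and are pooled by construction.
    With ``envelope_correction`` (default) each species' sum is divided by
    the theoretical envelope share of its first ``n_iso`` peaks, removing
    the small bias from oxidation-dependent isotope envelopes.
    """
    if max_ox > len(proline_sites(peptide)):
        raise ValueError("max_ox exceeds the number of prolines")
    abundances = _species_abundances(
        scans, peptide, max_ox, charges, n_iso, tolerance_ppm, envelope_correction
    )
    total = abundances.sum()
    if total <= 0:
        raise ValueError("empty quantification: no signal for any species")
    percents = tuple(100.0 * a / total for a in abundances)
    raw = _average_hyp_raw(percents)
    return HypDistribution(
        peptide=peptide,
        fractions_percent=percents,
        average_hyp=_round_half_up(raw, 2),
        average_hyp_raw=raw,
        percent_change=(
            percent_change(raw, control.average_hyp_raw) if control is not None else None
        ),
    )


def quantify_stoichiometry_monoiso(
    scans: ScanSet,
    peptide: str,
    max_ox: int,
    charges: tuple[int, ...] = (2, 3),
    tolerance_ppm: float = 10.0,
    control: "HypDistribution | None" = None,
    envelope_correction: bool = True,
) -> HypDistribution:
    """Monoisotopic-peaks-only quantification: the ammonium-adduct fallback."""
    return quantify_stoichiometry(
        scans, peptide, max_ox, charges, n_iso=1, tolerance_ppm=tolerance_ppm,
        control=control, envelope_correction=envelope_correction,
    )


def detect_adduct_overlap(
    peptide: str,
    max_ox: int,
    charges: tuple[int, ...] = (2, 3),
    tolerance_ppm: float = 10.0,
) -> list[tuple[int, int]]:
    """Flag (n_ox, charge) pairs whose +1 isotope peak can be contaminated.

    The ammonium adduct of the (n_ox−1)-oxidized species sits
    (17.026549 − 15.994915 − 1.003355)/z ≈ 0.028/z m/z away from the +1
    isotopic peak of the n_ox species; within the instrument tolerance the
    two merge and four-peak quantification overestimates the n_ox fraction.
    """
    flagged = []
    for n_ox in range(1, max_ox + 1):
        pf_prev = enumerate_oxoforms(peptide, n_ox=n_ox - 1)[0]
        pf = enumerate_oxoforms(peptide, n_ox=n_ox)[0]
        for z in sorted(charges):
            adduct_mz = mz(monoisotopic_mass(pf_prev), z, AMMONIUM_ADDUCT_SHIFT)
            plus1_mz = mz(monoisotopic_mass(pf), z) + C13_C12_DELTA / z
            if abs(adduct_mz - plus1_mz) <= plus1_mz * tolerance_ppm * 1e-6:
                flagged.append((n_ox, z))
    return flagged


def _round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero (prints 1.165 as 1.17, not 1.16)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _average_hyp_raw(fractions_percent) -> float:
    f = np.asarray(fractions_percent, dtype=float)
    if np.any(f < 0):
        raise ValueError("fractions must be non-negative")
    # percentages are used exactly as given, without renormalizing row sums
    return float(np.sum(np.arange(len(f)) * f) / 100.0)


def average_hyp(fractions_percent) -> float:
    """Expected hydroxyproline count from a percentage distribution.

    ``Σ n·f_n / 100`` reported to 2 decimals, rounding half away from zero.
    Percentages are taken as printed even when they sum to 99.9 or 100.1.
    """
    return _round_half_up(_average_hyp_raw(fractions_percent), 2)


def percent_change(av: float, av_control: float) -> int:
    """``round(100·av/av_control)`` to the nearest integer, half away from zero."""
    if av_control <= 0:
        raise ValueError("control average must be positive")
    return int(_round_half_up(100.0 * av / av_control, 0))
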