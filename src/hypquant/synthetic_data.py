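"""Ground-truthed synthetic LC-MS1 runs, MS/MS spectra and kinetics assays.

Emulates positive-mode Q-TOF measurements of peptide hydroxylation: mixtures
of 0..k-times oxidized peptidoforms appear as isotope-resolved envelopes at
2+/3+ charge states (optionally with ammonium adducts), eluting as Gaussian
chromatographic peaks; MS/MS spectra contain singly charged b/y fragments;
endpoint kinetics assays follow a Michaelis–Menten model quantified against
an internal-standard peptide. Every generator is a pure function of its
configuration and seed, and serializes its ground truth for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import C13_C12_DELTA
from .peptide_chem import (
    AMMONIUM_ADDUCT_SHIFT,
    IsotopeEnvelope,
    Peptidoform,
    elemental_composition,
    enumerate_oxoforms,
    isotope_distribution,
    monoisotopic_mass,
    mz,
    proline_sites,
)

__all__ = [
    "GroundTruth",
    "ScanSet",
    "simulate_lcms_run",
    "simulate_msms",
    "write_mgf",
    "read_mgf",
    "KineticParameters",
    "KineticAssay",
    "simulate_kinetics",
]

#: isotope peaks simulated per species (quantification uses the first four);
#: 12 peaks carry all but ~1e-6 of a 4 kDa peptide's envelope
_N_ISO_SIMULATED = 12


@dataclass(frozen=True)
class GroundTruth:
    """Configuration-plus-truth for one simulated LC-MS1 run."""

    peptide: str
    stoichiometry: tuple[float, ...]  # f_0..f_k, sums to 1
    charge_weights: dict[int, float] = field(default_factory=lambda: {2: 0.7, 3: 0.3})
    adduct_fraction: float = 0.0
    rt_centers: tuple[float, ...] | None = None  # min, one per n_ox; default grid
    rt_width: float = 0.06  # Gaussian sigma, min
    noise_cv: float = 0.0
    total_signal: float = 1e6
    mz_tolerance_ppm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.stoichiometry, dtype=float)
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("stoichiometry fractions must sum to 1")
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("stoichiometry fractions must be in [0, 1]")
        if len(f) - 1 > len(proline_sites(self.peptide)):
            raise ValueError("more oxidation states than prolines")
        if self.rt_width <= 0:
            raise ValueError("rt_width must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.rt_centers is not None and len(self.rt_centers) != len(f):
            raise ValueError("need one rt center per oxidation state")
        if not 0 <= self.adduct_fraction < 1:
            raise ValueError("adduct_fraction must be in [0, 1)")

    @property
    def max_ox(self) -> int:
        return len(self.stoichiometry) - 1

    def resolved_rt_centers(self) -> tuple[float, ...]:
        if self.rt_centers is not None:
            return self.rt_centers
        return tuple(3.0 + 0.4 * n for n in range(self.max_ox + 1))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        raw["stoichiometry"] = tuple(raw["stoichiometry"])
        if raw.get("rt_centers") is not None:
            raw["rt_centers"] = tuple(raw["rt_centers"])
        raw["charge_weights"] = {int(z): w for z, w in raw["charge_weights"].items()}
        return cls(**raw)


@dataclass(frozen=True)
class ScanSet:
    """A centroided LC-MS1 run: ordered scans of (rt, peak arrays)."""

    scans: tuple[tuple[float, np.ndarray, np.ndarray], ...]  # (rt, mz[], intensity[])
    mz_tolerance_ppm: float = 10.0

    def __post_init__(self) -> None:
        rts = [rt for rt, _, _ in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("retention times must be strictly increasing")
        for _, mzs, intens in self.scans:
            if np.any(intens < 0):
                raise ValueError("intensities must be non-negative")
            if len(mzs) != len(intens):
                raise ValueError("mz and intensity arrays must align")

    def to_csv(self, path: str | Path) -> None:
        """Write the documented ScanSet CSV dialect: rt_min, mz, intensity."""
        frames = [
            pd.DataFrame({"rt_min": rt, "mz": mzs, "intensity": intens})
            for rt, mzs, intens in self.scans
        ]
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, mz_tolerance_ppm: float = 10.0) -> "ScanSet":
        df = pd.read_csv(path)
        required = {"rt_min", "mz", "intensity"}
        if not required.issubset(df.columns):
            raise ValueError(f"ScanSet CSV must have columns {sorted(required)}")
        scans = tuple(
            (float(rt), grp["mz"].to_numpy(float), grp["intensity"].to_numpy(float))
            for rt, grp in df.groupby("rt_min", sort=True)
        )
        return cls(scans, mz_tolerance_ppm)

    def total_area(self) -> float:
        """Trapezoidal integral of the total ion current (conservation check)."""
        rts = np.array([rt for rt, _, _ in self.scans])
        tic = np.array([intens.sum() for _, _, intens in self.scans])
        return float(np.trapezoid(tic, rts))


def species_mz_table(
    peptide: str, max_ox: int, charges: tuple[int, ...], n_iso: int, adducts: bool = False
) -> pd.DataFrame:
    """Theoretical m/z values per (n_ox, charge, adduct, isotope offset).

    The m/z of an oxidation state does not depend on which proline carries
    the oxidation, so a representative (lexicographically first) peptidoform
    per n_ox suffices. Isotope peaks are spaced by the 13C-12C mass split.
    """
    rows = []
    for n_ox in range(max_ox + 1):
        pf = enumerate_oxoforms(peptide, n_ox=n_ox)[0]
        mass = monoisotopic_mass(pf)
        env = isotope_distribution(elemental_composition(pf), _N_ISO_SIMULATED)
        for z in charges:
            for adduct in ([0.0, AMMONIUM_ADDUCT_SHIFT] if adducts else [0.0]):
                for k in range(n_iso):
                    rows.append(
                        {
                            "n_ox": n_ox,
                            "charge": z,
                            "adduct": adduct > 0,
                            "iso": k,
                            "mz": mz(mass, z, adduct) + k * C13_C12_DELTA / z,
                            "envelope": env.abundances[k] if k < _N_ISO_SIMULATED else 0.0,
                        }
                    )
    return pd.DataFrame(rows)


def adduct_isotope_gap(charge: int) -> float:
    """m/z gap between the ammonium-adduct monoisotopic peak of the n-ox
    species and the +1 isotopic peak of the (n+1)-ox species, at ``charge``."""
    from .peptide_chem import OXIDATION

    return (AMMONIUM_ADDUCT_SHIFT - OXIDATION.mass_shift - C13_C12_DELTA) / charge


def simulate_lcms_run(truth: GroundTruth, scan_interval: float = 0.02) -> ScanSet:
    """Simulate a centroided MS1 run under a ground-truth configuration.

    Each species (n_ox, charge, adduct state) contributes Gaussian elution
    profiles at its first 8 isotope peak m/z values; the integrated area of
    a species is proportional to fraction × charge weight × adduct split.
    Multiplicative lognormal noise (unit mean, sigma = noise_cv) is applied
    per centroid. Fully reproducible from ``truth.seed``.
    """
    if scan_interval <= 0:
        raise ValueError("scan_interval must be positive")
    charges = tuple(sorted(truth.charge_weights))
    table = species_mz_table(
        truth.peptide, truth.max_ox, charges, _N_ISO_SIMULATED, adducts=True
    )
    centers = truth.resolved_rt_centers()
    f = np.asarray(truth.stoichiometry)

    # interference self-check: the adduct monoisotopic peak must fall inside
    # the instrument tolerance of the next species' +1 isotope peak at 2+
    if truth.adduct_fraction > 0 and 2 in charges and truth.max_ox >= 1:
        ref = table[(table.n_ox == 1) & (table.charge == 2) & ~table.adduct & (table.iso == 1)]
        gap = abs(adduct_isotope_gap(2))
        tol = float(ref.mz.iloc[0]) * truth.mz_tolerance_ppm * 1e-6
        if gap > tol:
            raise ValueError(
                f"ammonium adduct ({gap:.4f} m/z away) would not interfere with the +1 "
                f"isotope peak at the configured tolerance ({tol:.4f} m/z); "
                "widen mz_tolerance_ppm or drop the adduct"
            )

    area = np.empty(len(table))
    center = np.empty(len(table))
    for i, row in enumerate(table.itertuples()):
        split = truth.adduct_fraction if row.adduct else 1.0 - truth.adduct_fraction
        area[i] = (
            truth.total_signal
            * f[row.n_ox]
            * truth.charge_weights[row.charge]
            * split
            * row.envelope
        )
        center[i] = centers[row.n_ox]

    lo = min(centers) - 5 * truth.rt_width
    hi = max(centers) + 5 * truth.rt_width
    rts = np.arange(lo, hi + scan_interval / 2, scan_interval)
    # intensity[scan, peak] = area * N(rt; center, sigma)
    gauss = np.exp(-0.5 * ((rts[:, None] - center[None, :]) / truth.rt_width) ** 2)
    gauss /= truth.rt_width * np.sqrt(2 * np.pi)
    intensity = area[None, :] * gauss

    rng = np.random.default_rng(truth.seed)
    if truth.noise_cv > 0:
        cv = truth.noise_cv
        noise = rng.lognormal(mean=-0.5 * cv**2, sigma=cv, size=intensity.shape)
        intensity = intensity * noise

    mzs = table.mz.to_numpy()
    order = np.argsort(mzs)
    mzs = mzs[order]
    intensity = intensity[:, order]
    keep = intensity > truth.total_signal * 1e-12  # drop numerically silent centroids
    scans = tuple(
        (float(rt), mzs[keep[i]], intensity[i][keep[i]])
        for i, rt in enumerate(rts)
        if keep[i].any()
    )
    return ScanSet(scans, truth.mz_tolerance_ppm)


# ---------------------------------------------------------------------------
# MS/MS


def simulate_msms(
    pf: Peptidoform, charge: int = 2, noise_cv: float = 0.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Singly charged b/y fragment spectrum of a peptidoform.

    All 2(L-1) fragments appear with equal base intensity modulated by
    multiplicative lognormal noise; oxidation mass is carried by every
    fragment covering the modified position.
    """
    from .site_localization import theoretical_fragments

    frags = theoretical_fragments(pf)
    mzs = np.array([f.mz for f in frags])
    rng = np.random.default_rng(seed)
    base = np.full(len(mzs), 1000.0)
    if noise_cv > 0:
        base = base * rng.lognormal(mean=-0.5 * noise_cv**2, sigma=noise_cv, size=len(mzs))
    order = np.argsort(mzs)
    return mzs[order], base[order]


def write_mgf(
    path: str | Path,
    spectra: list[tuple[Peptidoform, int, np.ndarray, np.ndarray]],
) -> None:
    """Write MS/MS spectra as MGF; TITLE carries the ground-truth peptidoform."""
    from pyteomics import mgf as _mgf

    entries = []
    for pf, charge, mzs, intensities in spectra:
        precursor = mz(monoisotopic_mass(pf), charge)
        entries.append(
            {
                "m/z array": mzs,
                "intensity array": intensities,
                "params": {
                    "title": pf.to_string(),
                    "pepmass": precursor,
                    "charge": charge,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_mgf(path: str | Path) -> list[dict]:
    """Read an MGF peak list (thin wrapper over pyteomics)."""
    from pyteomics import mgf as _mgf

    with _mgf.read(str(path)) as reader:
        return list(reader)


# ---------------------------------------------------------------------------
# Kinetics


@dataclass(frozen=True)
class KineticParameters:
    """Michaelis–Menten parameters (Km in μM, vmax in μM/min)."""

    km: float
    vmax: float
    se_km: float | None = None
    se_vmax: float | None = None

    def __post_init__(self) -> None:
        if self.km <= 0 or self.vmax <= 0:
            raise ValueError("Km and vmax must be positive")

    def velocity(self, s: np.ndarray | float) -> np.ndarray | float:
        return self.vmax * np.asarray(s) / (self.km + np.asarray(s))


@dataclass(frozen=True)
class KineticAssay:
    """Endpoint assay table: one stopped reaction per substrate concentration."""

    table: pd.DataFrame  # columns: s0_um, area_substrate, area_product, area_is
    reaction_time: float  # min
    is_conc: float  # μM

    def __post_init__(self) -> None:
        required = {"s0_um", "area_substrate", "area_product", "area_is"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"assay table must have columns {sorted(required)}")
        if (self.table["s0_um"] <= 0).any():
            raise ValueError("substrate concentrations must be positive")
        if self.reaction_time <= 0:
            raise ValueError("reaction_time must be positive")

    def to_csv(self, path: str | Path) -> None:
        df = self.table.copy()
        df["reaction_time_min"] = self.reaction_time
        df["is_conc_um"] = self.is_conc
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "KineticAssay":
        df = pd.read_csv(path)
        return cls(
            df[["s0_um", "area_substrate", "area_product", "area_is"]],
            reaction_time=float(df["reaction_time_min"].iloc[0]),
            is_conc=float(df["is_conc_um"].iloc[0]),
        )


def default_substrate_grid(n: int = 8, lo: float = 22.0, hi: float = 5610.0) -> np.ndarray:
    """Log-spaced substrate concentrations (μM) over the assayed range."""
    return np.geomspace(lo, hi, n)


def simulate_kinetics(
    params: KineticParameters,
    substrate_concs: np.ndarray | list[float] | None = None,
    reaction_time: float = 30.0,
    is_conc: float = 100.0,
    response_factor_analyte: float = 1.0,
    response_factor_is: float = 0.8,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> KineticAssay:
    """Simulate an endpoint internal-standard assay from a Michaelis–Menten model.

    Product per reaction is ``vmax·S/(Km+S) × t`` (initial-rate regime, capped
    at S). Substrate and product share one LC-MS response factor — the stated
    assumption of the quantification scheme — while the internal standard has
    its own; all areas carry multiplicative lognormal noise.
    """
    if substrate_concs is None:
        substrate_concs = default_substrate_grid()
    s0 = np.asarray(substrate_concs, dtype=float)
    if np.any(s0 <= 0) or is_conc <= 0:
        raise ValueError("all concentrations must be positive")
    if reaction_time <= 0:
        raise ValueError("reaction_time must be positive")
    product = np.minimum(params.velocity(s0) * reaction_time, s0)
    rng = np.random.default_rng(seed)

    def noisy(x: np.ndarray) -> np.ndarray:
        if noise_cv == 0:
            return x
        return x * rng.lognormal(mean=-0.5 * noise_cv**2, sigma=noise_cv, size=x.shape)

    table = pd.DataFrame(
        {
            "s0_um": s0,
            "area_substrate": noisy(response_factor_analyte * (s0 - product)),
            "area_product": noisy(response_factor_analyte * product),
            "area_is": noisy(response_factor_is * np.full_like(s0, is_conc)),
            "true_product_um": product,
        }
    )
    return KineticAssay(table, reaction_time=reaction_time, is_conc=is_conc)
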