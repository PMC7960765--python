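"""Peptide mass arithmetic, isotope envelopes, digestion and oxoform enumeration.

The unit of computation is the :class:`Peptidoform`: a peptide sequence plus
positioned modifications (1-based residue coordinates, matching the residue
numbering used for proline sites such as P4/P6/P22 of the IgA1 hinge peptide).
Two built-in modifications cover the chemistry of the workflow: proline
oxidation to 4-hydroxyproline (+15.994915 Da) and cysteine
carbamidomethylation (+57.021464 Da, iodoacetamide alkylation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    AMMONIA_MASS as AMMONIUM_ADDUCT_SHIFT,
    ATOMIC_MASS,
    ISOTOPES,
    PROTON_MASS,
    RESIDUE_COMPOSITIONS,
)

__all__ = [
    "ElementalComposition",
    "Modification",
    "OXIDATION",
    "CARBAMIDOMETHYL",
    "Peptidoform",
    "IsotopeEnvelope",
    "elemental_composition",
    "monoisotopic_mass",
    "mz",
    "AMMONIUM_ADDUCT_SHIFT",
    "isotope_distribution",
    "tryptic_digest",
    "DigestFragment",
    "enumerate_oxoforms",
    "proline_sites",
]


@dataclass(frozen=True)
class ElementalComposition:
    """Element → count map; counts are non-negative for concrete molecules.

    Signed deltas (used by modifications) are represented with plain dicts;
    subtraction that would drive a count negative raises.
    """

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {el: int(n) for el, n in self.counts.items() if n != 0}
        for el, n in cleaned.items():
            if n < 0:
                raise ValueError(f"negative count for element {el}: {n}")
        object.__setattr__(self, "counts", cleaned)

    def __add__(self, other: "ElementalComposition | dict[str, int]") -> "ElementalComposition":
        other_counts = other.counts if isinstance(other, ElementalComposition) else other
        merged = dict(self.counts)
        for el, n in other_counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition | dict[str, int]") -> "ElementalComposition":
        other_counts = other.counts if isinstance(other, ElementalComposition) else other
        return self + {el: -n for el, n in other_counts.items()}

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def total_atoms(self) -> int:
        return sum(self.counts.values())

    def monoisotopic_mass(self) -> float:
        try:
            return sum(ATOMIC_MASS[el] * n for el, n in self.counts.items())
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValueError(f"element with no mass table: {exc.args[0]}") from None


@dataclass(frozen=True)
class Modification:
    """A covalent modification: mass shift plus elemental delta.

    ``composition_delta`` is a signed element→count dict; its monoisotopic
    mass must agree with ``mass_shift`` to 1e-6 Da.
    """

    name: str
    mass_shift: float
    composition_delta: dict[str, int]
    allowed_residues: frozenset[str]

    def __post_init__(self) -> None:
        delta_mass = sum(ATOMIC_MASS[el] * n for el, n in self.composition_delta.items())
        if abs(delta_mass - self.mass_shift) > 1e-6:
            raise ValueError(
                f"modification {self.name}: mass_shift {self.mass_shift} differs from "
                f"composition mass {delta_mass:.7f} by more than 1e-6 Da"
            )


OXIDATION = Modification(
    name="ox", mass_shift=15.994915, composition_delta={"O": 1}, allowed_residues=frozenset("P")
)
CARBAMIDOMETHYL = Modification(
    name="cam",
    mass_shift=57.021464,
    composition_delta={"C": 2, "H": 3, "N": 1, "O": 1},
    allowed_residues=frozenset("C"),
)

_MODS_BY_NAME = {"ox": OXIDATION, "cam": CARBAMIDOMETHYL}


@dataclass(frozen=True)
class Peptidoform:
    """A peptide sequence with positioned modifications (1-based positions)."""

    sequence: str
    mods: tuple[tuple[int, Modification], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in RESIDUE_COMPOSITIONS:
                raise ValueError(f"unknown residue letter {aa!r} at position {i}")
        mods = tuple(sorted(self.mods, key=lambda pm: pm[0]))
        seen: set[int] = set()
        for pos, mod in mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"mod position {pos} outside [1, {len(self.sequence)}]")
            residue = self.sequence[pos - 1]
            if residue not in mod.allowed_residues:
                raise ValueError(
                    f"modification {mod.name} not allowed on residue {residue} at position {pos}"
                )
            if pos in seen:
                raise ValueError(f"more than one modification at position {pos}")
            seen.add(pos)
        object.__setattr__(self, "mods", mods)

    def __len__(self) -> int:
        return len(self.sequence)

    def mod_positions(self, name: str | None = None) -> tuple[int, ...]:
        return tuple(pos for pos, mod in self.mods if name is None or mod.name == name)

    def to_string(self) -> str:
        """Compact text form, e.g. ``VTVP...|ox:18;cam:13`` (round-trips)."""
        if not self.mods:
            return self.sequence
        tags = ";".join(f"{mod.name}:{pos}" for pos, mod in self.mods)
        return f"{self.sequence}|{tags}"

    @classmethod
    def from_string(cls, text: str) -> "Peptidoform":
        if "|" not in text:
            return cls(text)
        sequence, tags = text.split("|", 1)
        mods = []
        for tag in tags.split(";"):
            if not tag:
                continue
            name, pos = tag.split(":")
            mods.append((int(pos), _MODS_BY_NAME[name]))
        return cls(sequence, tuple(mods))

    @classmethod
    def with_fixed_cam(
        cls, sequence: str, ox_sites: tuple[int, ...] | list[int] = ()
    ) -> "Peptidoform":
        """Build a peptidoform with carbamidomethyl on every Cys plus optional
        oxidations — the fixed/variable modification scheme of the workflow."""
        mods = [(i, CARBAMIDOMETHYL) for i, aa in enumerate(sequence, start=1) if aa == "C"]
        mods.extend((pos, OXIDATION) for pos in ox_sites)
        return cls(sequence, tuple(mods))


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Aggregated isotope pattern: (nominal offset, relative abundance) pairs.

    Offsets start at 0 for the monoisotopic peak; abundances sum to 1.
    """

    peaks: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        offsets = [o for o, _ in self.peaks]
        abundances = [a for _, a in self.peaks]
        if offsets != sorted(set(offsets)) or (offsets and offsets[0] != 0):
            raise ValueError("offsets must be strictly increasing from 0")
        if any(a < 0 for a in abundances):
            raise ValueError("abundances must be non-negative")
        if abs(sum(abundances) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")

    @property
    def abundances(self) -> np.ndarray:
        return np.array([a for _, a in self.peaks])


def elemental_composition(pf: Peptidoform) -> ElementalComposition:
    """Sum of residue compositions + one water + all modification deltas."""
    comp = ElementalComposition({"H": 2, "O": 1})
    for aa in pf.sequence:
        comp = comp + RESIDUE_COMPOSITIONS[aa]
    for _, mod in pf.mods:
        comp = comp + mod.composition_delta
    return comp


def monoisotopic_mass(pf: Peptidoform | str) -> float:
    """Neutral monoisotopic mass of a peptidoform in Da."""
    if isinstance(pf, str):
        pf = Peptidoform(pf)
    return elemental_composition(pf).monoisotopic_mass()


def mz(neutral_mass: float, charge: int, adduct_shift: float = 0.0) -> float:
    """m/z of ``[M + charge·H + adduct]^charge+``.

    ``adduct_shift`` is the neutral mass added on top of protonation; the
    ammonium adduct uses :data:`AMMONIUM_ADDUCT_SHIFT` (+17.026549 Da, i.e.
    NH3 on top of the extra proton).
    """
    if charge <= 0:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return (neutral_mass + charge * PROTON_MASS + adduct_shift) / charge


def isotope_distribution(
    comp: ElementalComposition, n_peaks: int = 4
) -> IsotopeEnvelope:
    """Aggregated isotope envelope by iterative convolution of element patterns.

    Per-element single-atom patterns (nominal offsets vs abundance) are raised
    to the atom count by binary-exponentiation convolution and multiplied
    together, then truncated to ``n_peaks`` offsets and renormalized.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if comp.total_atoms() == 0:
        raise ValueError("empty composition")
    # work on a generous internal width so truncation happens only at the end
    width = n_peaks + 8
    result = np.zeros(width)
    result[0] = 1.0
    for element, count in comp.counts.items():
        if element not in ISOTOPES:
            raise ValueError(f"element with no isotope table: {element}")
        single = np.zeros(width)
        for offset, _mass, abundance in ISOTOPES[element]:
            if offset < width:
                single[offset] = abundance
        result = np.convolve(result, _power_pattern(single, count, width))[:width]
    truncated = result[:n_peaks]
    total = truncated.sum()
    if total <= 0:  # pragma: no cover - unreachable for real compositions
        raise ValueError("degenerate envelope")
    truncated = truncated / total
    return IsotopeEnvelope(tuple((i, float(a)) for i, a in enumerate(truncated)))


def _power_pattern(single: np.ndarray, count: int, width: int) -> np.ndarray:
    """``single`` convolved with itself ``count`` times (binary exponentiation)."""
    result = np.zeros(width)
    result[0] = 1.0
    base = single.copy()
    n = count
    while n > 0:
        if n & 1:
            result = np.convolve(result, base)[:width]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:width]
    return result


@dataclass(frozen=True)
class DigestFragment:
    """A tryptic peptide with 1-based inclusive coordinates in the parent."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int


def tryptic_digest(sequence: str, missed_cleavages: int = 0) -> list[DigestFragment]:
    """In-silico tryptic digestion: cleave after K/R unless followed by P.

    With ``missed_cleavages = m`` every union of up to ``m + 1`` adjacent
    fully-cleaved fragments is emitted, ordered by start position then length.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    cut_after = [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    boundaries = [0] + [i + 1 for i in cut_after] + [len(sequence)]
    fragments = []
    n = len(boundaries) - 1
    for i in range(n):
        for j in range(i, min(i + missed_cleavages + 1, n)):
            start, end = boundaries[i], boundaries[j + 1]
            fragments.append(
                DigestFragment(sequence[start:end], start + 1, end, missed_cleavages=j - i)
            )
    fragments.sort(key=lambda f: (f.start, f.end))
    return fragments


def proline_sites(sequence: str) -> tuple[int, ...]:
    """1-based positions of every proline in ``sequence``."""
    return tuple(i for i, aa in enumerate(sequence, start=1) if aa == "P")


def enumerate_oxoforms(
    sequence: str,
    candidate_sites: tuple[int, ...] | list[int] | None = None,
    n_ox: int = 0,
    fixed_cam: bool = True,
) -> list[Peptidoform]:
    """All placements of ``n_ox`` oxidations over ``candidate_sites``.

    Sites default to every proline. Returns the C(|sites|, n_ox) peptidoforms
    in deterministic lexicographic order of site tuples. Carbamidomethyl is
    applied to every Cys by default (fixed modification).
    """
    if candidate_sites is None:
        candidate_sites = proline_sites(sequence)
    sites = tuple(sorted(candidate_sites))
    for pos in sites:
        if not 1 <= pos <= len(sequence) or sequence[pos - 1] != "P":
            raise ValueError(f"candidate site {pos} is not a proline residue")
    if not 0 <= n_ox <= len(sites):
        raise ValueError(f"n_ox={n_ox} outside [0, {len(sites)}]")
    builder = Peptidoform.with_fixed_cam if fixed_cam else (
        lambda seq, ox: Peptidoform(seq, tuple((p, OXIDATION) for p in ox))
    )
    return [builder(sequence, combo) for combo in itertools.combinations(sites, n_ox)]
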