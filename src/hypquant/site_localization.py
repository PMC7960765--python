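"""Hydroxylation-site assignment from MS/MS b/y fragment spectra.

Positional isomers of an n-times oxidized peptide differ in which b/y
fragments carry the +15.9949 Da shift; the assigner enumerates every
possible site placement, counts matched fragments against the observed
spectrum, and returns the best-scoring placement — surfacing ties instead
of breaking them, since a spectrum that lacks the discriminating fragments
genuinely cannot localize the site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import PROTON_MASS, WATER_MASS, RESIDUE_COMPOSITIONS, ATOMIC_MASS
from .peptide_chem import Peptidoform, enumerate_oxoforms, proline_sites

__all__ = [
    "FragmentIon",
    "SiteAssignment",
    "theoretical_fragments",
    "match_spectrum",
    "localize",
]


@dataclass(frozen=True)
class FragmentIon:
    """A singly charged b- or y-ion; ``covers`` is the residue span it carries."""

    series: str  # 'b' or 'y'
    index: int  # 1..L-1
    mz: float
    covers: frozenset[int]


@dataclass(frozen=True)
class SiteAssignment:
    peptide: str
    n_ox: int
    sites: frozenset[int]
    score: int
    ambiguous_with: tuple[frozenset[int], ...] = field(default_factory=tuple)

    @property
    def is_ambiguous(self) -> bool:
        return len(self.ambiguous_with) > 0


def _residue_mass(aa: str) -> float:
    return sum(ATOMIC_MASS[el] * n for el, n in RESIDUE_COMPOSITIONS[aa].items())


def theoretical_fragments(pf: Peptidoform) -> list[FragmentIon]:
    """All singly charged b1..b(L-1) and y1..y(L-1) ions of a peptidoform."""
    length = len(pf)
    if length < 2:
        raise ValueError("peptide must have at least 2 residues to fragment")
    mod_mass = dict.fromkeys(range(1, length + 1), 0.0)
    for pos, mod in pf.mods:
        # composition-derived shift, exactly consistent with intact masses
        mod_mass[pos] = sum(
            ATOMIC_MASS[el] * n for el, n in mod.composition_delta.items()
        )
    residue = [
        _residue_mass(aa) + mod_mass[i] for i, aa in enumerate(pf.sequence, start=1)
    ]
    fragments = []
    prefix = 0.0
    for i in range(1, length):
        prefix += residue[i - 1]
        fragments.append(
            FragmentIon("b", i, prefix + PROTON_MASS, frozenset(range(1, i + 1)))
        )
    suffix = 0.0
    for j in range(1, length):
        suffix += residue[length - j]
        fragments.append(
            FragmentIon(
                "y", j, suffix + WATER_MASS + PROTON_MASS,
                frozenset(range(length - j + 1, length + 1)),
            )
        )
    return fragments


def match_spectrum(
    observed_mz: np.ndarray,
    theoretical: list[FragmentIon],
    tolerance_ppm: float = 10.0,
) -> list[tuple[FragmentIon, float]]:
    """Greedy nearest one-to-one matching of observed peaks to fragment ions."""
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    observed = np.asarray(observed_mz, dtype=float)
    if observed.size == 0:
        return []
    # candidate pairs within tolerance, closest-first
    pairs = []
    for frag in theoretical:
        delta = np.abs(observed - frag.mz)
        tol = frag.mz * tolerance_ppm * 1e-6
        for idx in np.flatnonzero(delta <= tol):
            pairs.append((float(delta[idx]), int(idx), frag))
    pairs.sort(key=lambda t: (t[0], t[1], t[2].series, t[2].index))
    used_obs: set[int] = set()
    used_frag: set[tuple[str, int]] = set()
    matches = []
    for _, idx, frag in pairs:
        key = (frag.series, frag.index)
        if idx in used_obs or key in used_frag:
            continue
        used_obs.add(idx)
        used_frag.add(key)
        matches.append((frag, float(observed[idx])))
    return matches


def localize(
    observed_mz: np.ndarray,
    peptide: str,
    n_ox: int,
    tolerance_ppm: float = 10.0,
) -> SiteAssignment:
    """Best-scoring placement of ``n_ox`` oxidations over the prolines.

    Scores every C(#Pro, n_ox) positional isomer by matched-fragment count.
    Equal-best placements are all reported in ``ambiguous_with``.
    """
    sites = proline_sites(peptide)
    if n_ox > len(sites):
        raise ValueError(f"n_ox={n_ox} exceeds the {len(sites)} prolines in {peptide}")
    scored: list[tuple[int, frozenset[int]]] = []
    for pf in enumerate_oxoforms(peptide, n_ox=n_ox):
        placement = frozenset(pf.mod_positions("ox"))
        score = len(match_spectrum(observed_mz, theoretical_fragments(pf), tolerance_ppm))
        scored.append((score, placement))
    best_score = max(score for score, _ in scored)
    winners = sorted(
        (placement for score, placement in scored if score == best_score),
        key=sorted,
    )
    return SiteAssignment(
        peptide=peptide,
        n_ox=n_ox,
        sites=winners[0],
        score=best_score,
        ambiguous_with=tuple(winners[1:]),
    )
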