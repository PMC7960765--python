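"""Position-specific consensus motifs around hydroxylated prolines.

A motif is an ordered list of allowed-residue sets over a window anchored on
the modified proline (default −1..+3, the five-residue context plant prolyl
4-hydroxylases are known to read). Motifs are derived as the per-offset
union of residues observed around confirmed sites, serialized in bracket
notation (e.g. ``[STP]-P-[STP]-[TP]-[SP]``), and matched strictly: windows
running past a terminus never match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "PositionalMotif",
    "extract_windows",
    "consensus_motif",
    "match_motif",
]

DEFAULT_WINDOW = (-1, 3)


@dataclass(frozen=True)
class PositionalMotif:
    """Allowed-residue sets per offset; the anchor offset 0 is fixed to {P}."""

    window: tuple[int, int]
    allowed: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        start, end = self.window
        if not start <= 0 <= end:
            raise ValueError("window must cover the anchor offset 0")
        if len(self.allowed) != end - start + 1:
            raise ValueError("one residue set needed per window offset")
        if any(not s for s in self.allowed):
            raise ValueError("every allowed set must be non-empty")
        if self.allowed[-start] != frozenset("P"):
            raise ValueError("anchor set must be exactly {P}")

    def to_text(self) -> str:
        """Bracket notation with the anchor printed bare: ``[STP]-P-[STP]-...``."""
        parts = []
        start = self.window[0]
        for offset, residues in zip(range(start, self.window[1] + 1), self.allowed):
            if offset == 0:
                parts.append("P")
            elif len(residues) == 1:
                parts.append(next(iter(residues)))
            else:
                parts.append("[" + "".join(sorted(residues)) + "]")
        return "-".join(parts)

    @classmethod
    def from_text(cls, text: str, anchor_offset: int | None = None) -> "PositionalMotif":
        """Parse bracket notation; ``P`` or ``Pro`` marks the anchor.

        If several positions are bare ``P``, ``anchor_offset`` (0-based index
        into the dash-separated fields) disambiguates; otherwise the first
        bare ``P`` is the anchor.
        """
        fields = text.strip().split("-")
        sets: list[frozenset[str]] = []
        bare_p: list[int] = []
        for i, fieldtext in enumerate(fields):
            fieldtext = fieldtext.strip()
            if fieldtext in ("P", "Pro"):
                sets.append(frozenset("P"))
                bare_p.append(i)
            else:
                m = re.fullmatch(r"\[([A-Z]+)\]|([A-Z])", fieldtext)
                if not m:
                    raise ValueError(f"cannot parse motif field {fieldtext!r}")
                sets.append(frozenset(m.group(1) or m.group(2)))
        if anchor_offset is None:
            if not bare_p:
                raise ValueError("no anchor position (bare P/Pro) in motif")
            anchor_offset = bare_p[0]
        window = (-anchor_offset, len(fields) - 1 - anchor_offset)
        return cls(window, tuple(sets))


def extract_windows(
    sequence: str,
    sites: tuple[int, ...] | list[int],
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> tuple[list[str], list[int]]:
    """Residue windows around each site (1-based positions).

    Returns ``(windows, skipped_sites)``: sites whose window would run past a
    terminus are skipped and reported rather than padded.
    """
    start, end = window
    windows = []
    skipped = []
    for site in sorted(sites):
        if not 1 <= site <= len(sequence) or sequence[site - 1] != "P":
            raise ValueError(f"site {site} is not a proline in the sequence")
        lo, hi = site + start, site + end
        if lo < 1 or hi > len(sequence):
            skipped.append(site)
            continue
        windows.append(sequence[lo - 1 : hi])
    return windows, skipped


def consensus_motif(
    windows: list[str], window: tuple[int, int] = DEFAULT_WINDOW
) -> PositionalMotif:
    """Per-offset union of observed residues, with the anchor forced to {P}."""
    if not windows:
        raise ValueError("need at least one window to build a consensus")
    width = window[1] - window[0] + 1
    if any(len(w) != width for w in windows):
        raise ValueError(f"every window must have length {width}")
    sets = [frozenset(w[i] for w in windows) for i in range(width)]
    sets[-window[0]] = frozenset("P")
    return PositionalMotif(window, tuple(sets))


def match_motif(motif: PositionalMotif, sequence: str) -> list[int]:
    """1-based anchor positions where the motif matches (strict boundaries)."""
    start, end = motif.window
    anchors = []
    for pos in range(1, len(sequence) + 1):
        lo, hi = pos + start, pos + end
        if lo < 1 or hi > len(sequence):
            continue
        segment = sequence[lo - 1 : hi]
        if all(aa in allowed for aa, allowed in zip(segment, motif.allowed)):
            anchors.append(pos)
    return anchors
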