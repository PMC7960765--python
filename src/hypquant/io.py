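"""Sequence file I/O (thin wrappers over pyteomics FASTA)."""

from __future__ import annotations

from pathlib import Path

from pyteomics import fasta as _fasta

__all__ = ["read_fasta", "write_fasta"]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (description, sequence) pairs from a FASTA file."""
    with _fasta.read(str(path)) as reader:
        return [(entry.description, entry.sequence) for entry in reader]


def write_fasta(path: str | Path, entries: list[tuple[str, str]]) -> None:
    """Write (description, sequence) pairs as FASTA, descriptions preserved."""
    _fasta.write(entries, str(path), file_mode="w")
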