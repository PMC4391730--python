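"""Minimal FASTA helpers (dict-of-strings genome model)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from pyfaidx import Fasta


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into {name: sequence}."""
    with Fasta(str(path), as_raw=True, rebuild=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path: str | Path, *, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
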