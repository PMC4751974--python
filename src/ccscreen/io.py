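"""File formats: register-annotated FASTA and melt-curve CSV."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .heptad import RegisteredPeptide
from .meltfit import MeltCurve

__all__ = [
    "read_fasta_with_register",
    "write_fasta_with_register",
    "read_melt_curve",
    "write_melt_curve",
]


def _parse_sidecar(path: str | Path) -> dict[str, str]:
    registers: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pid, reg = line.split(None, 1)
        registers[pid] = reg.strip()
    return registers


def read_fasta_with_register(
    path: str | Path, sidecar: str | Path | None = None
) -> list[RegisteredPeptide]:
    """Read peptides from FASTA with heptad registers.

    The register comes from a ``register=...`` key in the header description
    or, failing that, from a plain-text sidecar file of ``id register``
    lines.  Registers are validated on construction (length mismatch, bad
    letters and broken heptad order all raise).
    """
    side = _parse_sidecar(sidecar) if sidecar is not None else {}
    peptides: list[RegisteredPeptide] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        register = None
        for token in rec.description.split():
            if token.startswith("register="):
                register = token.removeprefix("register=")
        if register is None:
            register = side.get(rec.id)
        if register is None:
            raise ValueError(f"{path}: no register for peptide {rec.id!r} "
                             "(header tag or sidecar required)")
        peptides.append(
            RegisteredPeptide(id=rec.id, sequence=str(rec.seq).upper(), register=register)
        )
    return peptides


def write_fasta_with_register(
    peptides: Iterable[RegisteredPeptide], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for p in peptides:
            fh.write(f">{p.id} register={p.register}\n{p.sequence}\n")


def read_melt_curve(path: str | Path, pt: float) -> MeltCurve:
    """CSV with ``temperature`` and ``signal`` columns; Pt in mol/L."""
    df = pd.read_csv(path)
    missing = {"temperature", "signal"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: melt-curve CSV lacks column(s) {sorted(missing)}")
    return MeltCurve(
        temperature=df["temperature"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        pt=pt,
    )


def write_melt_curve(curve: MeltCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"temperature": curve.temperature, "signal": curve.signal}
    ).to_csv(path, index=False)
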