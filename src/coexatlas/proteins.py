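"""Protein physiochemical properties: molecular weight, isoelectric point,
instability index, and residue composition.

Conventions follow the Expasy ProtParam tool: average residue masses plus
one water for the molecular weight; Bjellqvist pKa values with
residue-specific termini and charge-balance bisection for the isoelectric
point; the Guruprasad dipeptide weight sum scaled by 10/L for the
instability index (values above 40 conventionally flag an unstable
protein).  Ambiguity codes (B, Z, X, ...) are rejected, not approximated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._protdata import (
    AMINO_ACID_AVG_MASS,
    DIWV,
    NEGATIVE_PKS,
    PK_CTERMINAL,
    PK_NTERMINAL,
    POSITIVE_PKS,
    STANDARD_AA,
    WATER_AVG,
)

_STANDARD = set(STANDARD_AA)


def _validate(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError("empty protein sequence")
    for pos, aa in enumerate(seq, start=1):
        if aa not in _STANDARD:
            raise ValueError(f"non-standard residue {aa!r} at position {pos}")
    return seq


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Da: residue masses plus one water."""
    seq = _validate(seq)
    return sum(AMINO_ACID_AVG_MASS[aa] - WATER_AVG for aa in seq) + WATER_AVG


def charge_at_pH(seq: str, pH: float) -> float:
    """Net charge from Henderson–Hasselbalch over side chains and termini."""
    seq = _validate(seq)
    counts = {aa: seq.count(aa) for aa in "KRHDECY"}
    pos_pks = dict(POSITIVE_PKS)
    neg_pks = dict(NEGATIVE_PKS)
    pos_pks["Nterm"] = PK_NTERMINAL.get(seq[0], pos_pks["Nterm"])
    neg_pks["Cterm"] = PK_CTERMINAL.get(seq[-1], neg_pks["Cterm"])
    counts["Nterm"] = counts["Cterm"] = 1
    positive = sum(
        counts[g] / (10.0 ** (pH - pk) + 1.0) for g, pk in pos_pks.items()
    )
    negative = sum(
        counts[g] / (10.0 ** (pk - pH) + 1.0) for g, pk in neg_pks.items()
    )
    return positive - negative


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH of zero net charge, located by bisection on [0, 14].

    The charge is strictly decreasing in pH, so bisection converges; the
    search stops when |charge| < ``tol`` or the bracket collapses.
    """
    seq = _validate(seq)
    lo, hi = 0.0, 14.0
    pH = 7.0
    for _ in range(200):
        charge = charge_at_pH(seq, pH)
        if abs(charge) < tol or hi - lo < 1e-9:
            break
        if charge > 0:
            lo = pH
        else:
            hi = pH
        pH = (lo + hi) / 2.0
    return pH


def instability_index(seq: str) -> float:
    """(10 / L) × sum of dipeptide instability weights over the sequence."""
    seq = _validate(seq)
    if len(seq) < 2:
        raise ValueError("instability index requires at least 2 residues")
    total = sum(DIWV[a][b] for a, b in zip(seq[:-1], seq[1:]))
    return 10.0 / len(seq) * total


def composition_percent(seq: str, residues: Sequence[str] | None = None) -> dict[str, float]:
    """Percentage of each requested residue (all 20 by default)."""
    seq = _validate(seq)
    residues = list(residues) if residues is not None else list(STANDARD_AA)
    return {r: 100.0 * seq.count(r) / len(seq) for r in residues}


@dataclass
class ProteinRecord:
    """A protein sequence with its derived physiochemical properties."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = _validate(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def molecular_weight(self) -> float:
        return molecular_weight(self.sequence)

    @property
    def isoelectric_point(self) -> float:
        return isoelectric_point(self.sequence)

    @property
    def instability_index(self) -> float:
        return instability_index(self.sequence)

    def composition(self, residues: Sequence[str] | None = None) -> dict[str, float]:
        return composition_percent(self.sequence, residues)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file."""
    from Bio import SeqIO

    return [ProteinRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def characterize(
    records: Iterable[ProteinRecord],
    residues: Sequence[str] = ("Q", "S", "G"),
) -> pd.DataFrame:
    """Tabulate length, MW, pI, instability and residue percentages."""
    rows = []
    for rec in records:
        row = {
            "id": rec.id,
            "length": rec.length,
            "molecular_weight": rec.molecular_weight,
            "isoelectric_point": rec.isoelectric_point,
            "instability_index": rec.instability_index,
        }
        for r, pct in rec.composition(residues).items():
            row[f"pct_{r}"] = pct
        rows.append(row)
    return pd.DataFrame(rows)
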