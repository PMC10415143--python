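"""Sequence-derived construct bookkeeping: theoretical masses and oligomeric state.

Theoretical molecular weights use average (isotope-abundance-weighted)
residue masses, the quantity SEC-MALS molar masses are compared against —
the sum of average residue masses over the construct's range plus one water
mass for the termini. Oligomeric state is called by rounding the ratio of
measured to theoretical mass and accepting the call when the measured mass
lies within a fractional tolerance of the implied n-mer mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .lfq_io import write_table

__all__ = [
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "ConstructSpec",
    "theoretical_mw",
    "oligomer_state",
    "read_fasta",
    "read_construct_table",
    "construct_report",
]

#: average residue masses in Da (amino acid minus water), standard 20 residues
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01528  # Da

OLIGOMER_LABELS = {1: "monomer", 2: "dimer", 3: "trimer", 4: "tetramer",
                   5: "pentamer", 6: "hexamer"}


@dataclass
class ConstructSpec:
    """A protein construct: a residue range of a parent sequence.

    ``start``/``end`` are 1-based and inclusive at both ends, the convention
    used for construct naming (e.g. a catalytic core spanning amino acids
    222-552).
    """

    name: str
    sequence: str
    start: int
    end: int
    measured_kda: float | None = None
    measured_sd_kda: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end <= len(self.sequence):
            raise ValueError(
                f"range {self.start}-{self.end} outside sequence of "
                f"length {len(self.sequence)}"
            )

    @property
    def subsequence(self) -> str:
        return self.sequence[self.start - 1 : self.end]

    @property
    def theoretical_kda(self) -> float:
        return theoretical_mw(self.sequence, (self.start, self.end))


def theoretical_mw(sequence: str, residue_range: tuple[int, int] | None = None) -> float:
    """Theoretical average molecular weight of a (sub)sequence in kDa.

    ``residue_range`` is 1-based inclusive; omitted means the whole
    sequence. Unknown residue letters raise an error naming the position.
    """
    sequence = sequence.strip().upper()
    if residue_range is not None:
        start, end = residue_range
        if not 1 <= start <= end <= len(sequence):
            raise ValueError(
                f"range {start}-{end} outside sequence of length {len(sequence)}"
            )
        sequence = sequence[start - 1 : end]
    if not sequence:
        raise ValueError("empty sequence")
    offset = residue_range[0] if residue_range else 1
    total = 0.0
    for i, residue in enumerate(sequence):
        try:
            total += AVERAGE_RESIDUE_MASS[residue]
        except KeyError:
            raise ValueError(
                f"unknown residue {residue!r} at position {offset + i}"
            ) from None
    return (total + WATER_MASS) / 1000.0


def oligomer_state(
    measured_kda: float,
    theoretical_kda: float,
    tolerance_frac: float = 0.15,
) -> tuple[int, str]:
    """Infer stoichiometry from a measured vs theoretical (monomer) mass.

    ``n = round(measured/theoretical)``; the call is accepted when the
    measured mass is within ``tolerance_frac`` (fraction of the n-mer mass)
    of ``n * theoretical``, otherwise the label is ``"ambiguous"``. A
    measured mass of 166.7 kDa against a 79.3 kDa monomer is a dimer; 36.8
    against 36.7 is a monomer.
    """
    if measured_kda <= 0 or theoretical_kda <= 0:
        raise ValueError("masses must be positive")
    if not 0 < tolerance_frac < 0.5:
        raise ValueError("tolerance_frac must be in (0, 0.5)")
    n = round(measured_kda / theoretical_kda)
    if n == 0:
        raise ValueError(
            f"measured mass {measured_kda} kDa is below half the theoretical "
            f"monomer mass {theoretical_kda} kDa"
        )
    if abs(measured_kda - n * theoretical_kda) <= tolerance_frac * n * theoretical_kda:
        label = OLIGOMER_LABELS.get(n, f"{n}-mer")
    else:
        label = "ambiguous"
    return n, label


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{record id: sequence}``."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_construct_table(path: str | Path, sequences: dict[str, str]) -> list[ConstructSpec]:
    """Read a construct table (TSV: name, parent, start, end[, measured_kda, measured_sd_kda])."""
    df = pd.read_csv(path, sep="\t", comment="#")
    constructs = []
    for _, row in df.iterrows():
        parent = str(row["parent"])
        if parent not in sequences:
            raise ValueError(f"parent sequence {parent!r} not in FASTA input")
        constructs.append(
            ConstructSpec(
                name=str(row["name"]),
                sequence=sequences[parent],
                start=int(row["start"]),
                end=int(row["end"]),
                measured_kda=float(row["measured_kda"])
                if "measured_kda" in df.columns and pd.notna(row.get("measured_kda"))
                else None,
                measured_sd_kda=float(row["measured_sd_kda"])
                if "measured_sd_kda" in df.columns and pd.notna(row.get("measured_sd_kda"))
                else None,
            )
        )
    return constructs


def construct_report(
    constructs: list[ConstructSpec],
    path: str | Path | None = None,
    tolerance_frac: float = 0.15,
) -> pd.DataFrame:
    """Tabulate theoretical masses and (where measured) oligomer calls."""
    rows = []
    for spec in constructs:
        row: dict[str, object] = {
            "name": spec.name,
            "range": f"{spec.start}-{spec.end}",
            "theoretical_kda": round(spec.theoretical_kda, 1),
        }
        if spec.measured_kda is not None:
            n, label = oligomer_state(spec.measured_kda, spec.theoretical_kda,
                                      tolerance_frac)
            row.update(measured_kda=spec.measured_kda, stoichiometry=n, state=label)
        rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        write_table(df, path, params={"tolerance_frac": tolerance_frac}, index=False)
    return df
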