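"""Peptide-level constants: exchangeable-hydrogen counts and natural
monoisotopic abundance.

The number of exchangeable hydrogens (N_EH) of a peptide is the sum of the
per-residue exchange counts; the per-residue values are empirical constants
supplied as a small two-column table.  A literature default ships with the
package (``data/residue_neh.tsv``) and any table of the same shape may be
substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

log = logging.getLogger(__name__)

#: Natural abundance of deuterium among hydrogen atoms.
DEFAULT_P_H = 0.000115

_STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: Most-abundant (lightest) isotope fraction per element, used for the
#: theoretical natural monoisotopic relative abundance of a composition.
MOST_ABUNDANT_ISOTOPE_FRACTION: dict[str, float] = {
    "H": 1.0 - DEFAULT_P_H,
    "C": 0.9893,
    "N": 0.99636,
    "O": 0.99757,
    "S": 0.9499,
}


class UnknownResidueError(ValueError):
    """A sequence contains a residue absent from the exchange table."""


@dataclass(frozen=True)
class ResidueExchangeTable:
    """Mapping of one-letter residue codes to exchangeable-hydrogen counts."""

    contributions: Mapping[str, float]
    allow_nonstandard: bool = False

    def __post_init__(self) -> None:
        missing = _STANDARD_RESIDUES - set(self.contributions)
        if missing:
            raise ValueError(
                "residue exchange table is missing standard residues: "
                + ", ".join(sorted(missing))
            )
        bad = {r: v for r, v in self.contributions.items() if v < 0}
        if bad:
            raise ValueError(f"negative exchangeable-hydrogen counts: {bad}")

    def __getitem__(self, residue: str) -> float:
        return self.contributions[residue]

    def __contains__(self, residue: str) -> bool:
        return residue in self.contributions

    @classmethod
    def from_file(cls, path: str | Path, allow_nonstandard: bool = False) -> "ResidueExchangeTable":
        """Read a two-column (residue, n_eh) whitespace/tab table.

        Lines starting with ``#`` are comments.
        """
        contributions: dict[str, float] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'residue n_eh', got {raw!r}")
            residue, value = parts
            contributions[residue] = float(value)
        return cls(contributions, allow_nonstandard=allow_nonstandard)

    @classmethod
    def default(cls, allow_nonstandard: bool = False) -> "ResidueExchangeTable":
        """The packaged literature default table."""
        ref = resources.files("turnoverkit").joinpath("data/residue_neh.tsv")
        with resources.as_file(ref) as path:
            return cls.from_file(path, allow_nonstandard=allow_nonstandard)


def compute_neh(sequence: str, table: ResidueExchangeTable) -> float:
    """Sum the per-residue exchangeable-hydrogen contributions of ``sequence``.

    Raises :class:`UnknownResidueError` naming the residue and its 1-based
    position unless the table was built with ``allow_nonstandard=True``, in
    which case unknown residues contribute zero (with a logged warning).
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    total = 0.0
    for pos, residue in enumerate(sequence, start=1):
        if residue in table:
            total += table[residue]
        elif table.allow_nonstandard:
            log.warning(
                "residue %r at position %d not in exchange table; counted as 0",
                residue, pos,
            )
        else:
            raise UnknownResidueError(
                f"unknown residue {residue!r} at position {pos} of {sequence!r}"
            )
    return total


def natural_monoisotopic_abundance(
    composition: Mapping[str, float],
    isotope_fractions: Mapping[str, float] | None = None,
) -> float:
    """Probability that every atom of ``composition`` is its lightest isotope.

    The product over elements of (most-abundant-isotope fraction)**count;
    an empty composition gives 1.0.
    """
    fractions = MOST_ABUNDANT_ISOTOPE_FRACTION if isotope_fractions is None else isotope_fractions
    result = 1.0
    for element, count in composition.items():
        if count < 0:
            raise ValueError(f"negative count for element {element!r}")
        if element not in fractions:
            raise ValueError(f"no most-abundant-isotope fraction configured for {element!r}")
        result *= fractions[element] ** count
    return result


@dataclass
class PeptideRecord:
    """A peptide with its parent protein, N_EH count, and natural monoisotopic RA."""

    sequence: str
    protein_id: str
    n_eh: float
    i0_natural: float
    composition: Mapping[str, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.n_eh <= 0:
            raise ValueError(f"n_eh must be positive, got {self.n_eh}")
        if not (0.0 < self.i0_natural <= 1.0):
            raise ValueError(f"i0_natural must be in (0, 1], got {self.i0_natural}")

    @classmethod
    def from_sequence(
        cls,
        sequence: str,
        protein_id: str,
        i0_natural: float,
        table: ResidueExchangeTable | None = None,
    ) -> "PeptideRecord":
        table = table if table is not None else ResidueExchangeTable.default()
        return cls(
            sequence=sequence,
            protein_id=protein_id,
            n_eh=compute_neh(sequence, table),
            i0_natural=i0_natural,
        )


def load_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an id -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
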