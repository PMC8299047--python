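"""Peptide-to-protein roll-up: TOP3 label-free areas and TMT reporter sums.

TOP3 reports a protein's abundance as the mean of its three most intense
peptide areas, counting both unique and razor peptides; TMT roll-up sums
reporter-ion intensities per channel over unique peptides only.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PeptideQuantRecord:
    """One quantified peptide: label-free area and/or TMT reporter channel
    intensities, with the unique/razor assignment of its protein mapping."""

    peptide_sequence: str
    protein_id: str
    is_unique: bool = True
    is_razor: bool = False
    area: float | None = None
    reporter_intensities: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.peptide_sequence:
            raise ValueError("empty peptide sequence")
        bad = set(self.peptide_sequence) - STANDARD_AA
        if bad:
            raise ValueError(f"{self.peptide_sequence!r}: non-standard "
                             f"residues {sorted(bad)}")
        if self.area is not None and self.area < 0:
            raise ValueError("negative peptide area")
        if self.reporter_intensities is not None:
            if any(x < 0 for x in self.reporter_intensities):
                raise ValueError("negative reporter intensity")


@dataclass(frozen=True)
class ProteinQuant:
    protein_id: str
    abundance: tuple[float, ...]  # one value (label-free) or one per channel
    n_peptides_used: int


def top3_rollup(records: Iterable[PeptideQuantRecord],
                protein_id: str) -> ProteinQuant | None:
    """Mean of the three largest unique-or-razor peptide areas.

    With fewer than three eligible peptides the mean of the available areas
    is used; with none, the protein is omitted (None, not an exception).
    """
    areas = sorted((r.area for r in records
                    if r.protein_id == protein_id
                    and (r.is_unique or r.is_razor)
                    and r.area is not None),
                   reverse=True)
    if not areas:
        return None
    top = areas[:3]
    return ProteinQuant(protein_id, (float(np.mean(top)),), len(top))


def tmt_rollup(records: Iterable[PeptideQuantRecord],
               protein_id: str) -> ProteinQuant | None:
    """Per-channel sum of reporter intensities over unique peptides only.

    Razor peptides are excluded; zero-intensity channels contribute zero.
    """
    rows = [r.reporter_intensities for r in records
            if r.protein_id == protein_id and r.is_unique and not r.is_razor
            and r.reporter_intensities is not None]
    if not rows:
        return None
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{protein_id}: inconsistent channel counts {widths}")
    total = tuple(float(x) for x in np.sum(rows, axis=0))
    return ProteinQuant(protein_id, total, len(rows))


def top3_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Assemble a protein x sample abundance matrix by TOP3 from a long table.

    ``table`` needs columns protein_id, sample_id, area and boolean
    is_unique / is_razor columns (missing flag columns default to unique).
    """
    df = table.copy()
    if "is_unique" not in df:
        df["is_unique"] = True
    if "is_razor" not in df:
        df["is_razor"] = False
    df = df[(df["is_unique"] | df["is_razor"]) & df["area"].notna()]

    def _top3(s: pd.Series) -> float:
        return float(s.nlargest(3).mean())

    wide = (df.groupby(["protein_id", "sample_id"])["area"]
              .apply(_top3).unstack("sample_id"))
    return wide
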