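"""Plasma proteome profiling by NSAF and blood-origin bookkeeping.

NSAF (normalized spectral abundance factor) turns spectral counts into
length-normalized relative abundances that sum to one.  Blood-origin
classification marks plasma proteins that lack transcript evidence in tumor
tissue; per-sample blood fractions quantify how much of a tissue proteome is
attributable to plasma carry-over.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: gene-symbol prefixes flagged as immunoglobulins (documented heuristic)
IMMUNOGLOBULIN_PREFIXES = ("IGH", "IGK", "IGL")


@dataclass(frozen=True)
class SpectralCountRecord:
    protein_id: str
    spectral_count: int
    length: int

    def __post_init__(self) -> None:
        if self.spectral_count < 0:
            raise ValueError("spectral count must be >= 0")
        if self.length < 1:
            raise ValueError("protein length must be >= 1")


def nsaf(records: Iterable[SpectralCountRecord]) -> pd.Series:
    """NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j); sums to 1."""
    recs = list(records)
    if not recs:
        raise ValueError("no records")
    saf = np.array([r.spectral_count / r.length for r in recs], dtype=float)
    total = saf.sum()
    if total == 0:
        raise ValueError("all spectral counts are zero")
    return pd.Series(saf / total, index=[r.protein_id for r in recs],
                     name="nsaf")


def nsaf_from_frame(counts: pd.DataFrame,
                    lengths: Mapping[str, int] | None = None) -> pd.Series:
    """NSAF from a table with protein_id, spectral_count and length columns.

    When ``lengths`` (e.g. from the FASTA) is given it takes precedence over
    the table's length column; disagreements are reported.
    """
    df = counts.set_index("protein_id") if "protein_id" in counts else counts
    length = df["length"].astype(int)
    if lengths is not None:
        fasta_len = pd.Series(lengths)
        common = length.index.intersection(fasta_len.index)
        mismatch = common[length.loc[common] != fasta_len.loc[common]]
        if len(mismatch):
            import warnings
            warnings.warn(f"{len(mismatch)} proteins have table lengths "
                          "disagreeing with the FASTA; FASTA lengths used",
                          stacklevel=2)
        length = length.copy()
        length.loc[common] = fasta_len.loc[common]
    return nsaf(SpectralCountRecord(pid, int(c), int(l))
                for pid, c, l in zip(df.index, df["spectral_count"], length))


def classify_origin(plasma_proteins: Mapping[str, str] | set,
                    tissue_protein_genes: set,
                    tissue_transcript_genes: set) -> pd.DataFrame:
    """Blood-origin call per plasma protein.

    ``plasma_proteins`` maps protein id -> gene symbol (a bare set of genes
    is accepted and used as both).  A protein is blood-origin iff its gene
    has no tissue transcript evidence; otherwise it is tissue-expressed.
    """
    if isinstance(plasma_proteins, Mapping):
        items = list(plasma_proteins.items())
    else:
        items = [(g, g) for g in plasma_proteins]
    rows = []
    for pid, gene in items:
        in_tissue_prot = gene in tissue_protein_genes
        in_tissue_rna = gene in tissue_transcript_genes
        origin = "tissue-expressed" if in_tissue_rna else "blood"
        rows.append((pid, gene, origin, True, in_tissue_prot, in_tissue_rna,
                     gene.startswith(IMMUNOGLOBULIN_PREFIXES)))
    return pd.DataFrame(rows, columns=[
        "protein_id", "gene", "origin", "in_plasma", "in_tissue_proteome",
        "in_tissue_transcriptome", "is_immunoglobulin"]).set_index("protein_id")


def tissue_blood_fraction(per_sample_identifications: Mapping[str, set],
                          blood_set: set) -> pd.Series:
    """Per-sample percent of identified proteins that are blood-origin.

    100 * |sample ∩ blood| / |sample|; empty samples yield NaN (flagged).
    """
    out = {}
    for sample, prots in per_sample_identifications.items():
        if not prots:
            out[sample] = float("nan")
        else:
            out[sample] = 100.0 * len(set(prots) & blood_set) / len(prots)
    return pd.Series(out, name="blood_fraction_pct")


def panel_overlap(identified: set, panel: Iterable[str]
                  ) -> tuple[float, list[str]]:
    """Percent of a marker panel recovered in the identified set."""
    panel_set = set(panel)
    if not panel_set:
        raise ValueError("empty panel")
    members = sorted(set(identified) & panel_set)
    return 100.0 * len(members) / len(panel_set), members
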