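"""Readers and writers for the plain-text formats the pipeline exchanges.

Abundance matrices travel as TSV (rows = proteins/sites, columns = samples)
with a two-column batch sidecar; proteomes as FASTA; annotation sets as GMT;
ground truth and configs as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .normalize import AbundanceMatrix
from .proteogenomics import MutationSpec, ProteinSequence


def read_abundance_tsv(matrix_path, batches_path, scale: str = "linear"
                       ) -> AbundanceMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    batches = pd.read_csv(batches_path, sep="\t", index_col=0).iloc[:, 0]
    return AbundanceMatrix(values, batches, scale)


def write_abundance_tsv(matrix: AbundanceMatrix, matrix_path,
                        batches_path=None) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="protein_id")
    if batches_path is not None:
        matrix.batches.rename("batch").to_csv(batches_path, sep="\t",
                                              index_label="sample_id")


def read_fasta(path) -> list[ProteinSequence]:
    """FASTA -> proteins; gene and PE level parsed from ``GN=``/``PE=`` tags
    when present (UniProt-style headers), else gene = record id."""
    proteins = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, pe = rec.id, None
        for tok in rec.description.split():
            if tok.startswith("GN="):
                gene = tok[3:]
            elif tok.startswith("PE="):
                try:
                    pe = int(tok[3:])
                except ValueError:
                    pass
        proteins.append(ProteinSequence(rec.id, gene, str(rec.seq).upper(), pe))
    return proteins


def write_fasta(proteins: Iterable[ProteinSequence], path) -> None:
    records = []
    for p in proteins:
        desc = f"GN={p.gene}" + (f" PE={p.pe_level}" if p.pe_level else "")
        records.append(SeqRecord(Seq(p.residues), id=p.id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_gmt(path) -> dict[str, set]:
    """GMT: one set per line, tab-separated: name, description, members..."""
    sets: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path,
              description: str = "na") -> None:
    lines = ["\t".join([name, description, *sorted(set(members))])
             for name, members in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_mutation_panel(path) -> list[MutationSpec]:
    """TSV with columns gene, position, wt_residue, mut_residue[, label]."""
    df = pd.read_csv(path, sep="\t")
    return [MutationSpec(r.gene, int(r.position), r.wt_residue, r.mut_residue,
                         getattr(r, "label", "") or "")
            for r in df.itertuples()]


def write_mutation_panel(panel: Iterable[MutationSpec], path) -> None:
    pd.DataFrame([{"gene": m.gene, "position": m.position,
                   "wt_residue": m.wt_residue, "mut_residue": m.mut_residue,
                   "label": m.label} for m in panel]
                 ).to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
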