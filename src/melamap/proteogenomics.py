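"""Mutation-aware proteogenomics: in-silico digestion and variant peptide calls.

Derives the tryptic (or Arg-C-like) peptides that distinguish a mutated
proteoform from its wild-type counterpart, checks peptide uniqueness against a
proteome with the I/L-equivalence convention, and provides the bookkeeping used
for "missing protein" claims (protein-existence tiers, two-peptide rule).

Coordinates are 1-based inclusive throughout, matching mutation nomenclature
such as NRAS Q61K.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: tolerated but flagged: selenocysteine and unknown residue
EXTENDED_AA = STANDARD_AA | {"U", "X"}

#: residues after which each enzyme cleaves (cleavage is suppressed before P)
_ENZYME_SITES = {"trypsin": "KR", "argc": "R"}


@dataclass(frozen=True)
class ProteinSequence:
    """A protein entry: accession, gene symbol, residues, PE evidence tier."""

    id: str
    gene: str
    residues: str
    pe_level: int | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - EXTENDED_AA
        if bad:
            raise ValueError(f"{self.id}: non-amino-acid characters {sorted(bad)}")

    @property
    def nonstandard_residues(self) -> set[str]:
        return set(self.residues) - STANDARD_AA

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MutationSpec:
    """Single amino-acid substitution defining a mutated proteoform."""

    gene: str
    position: int  # 1-based
    wt_residue: str
    mut_residue: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.wt_residue == self.mut_residue:
            raise ValueError(f"{self.gene}: WT and mutant residue are both "
                             f"{self.wt_residue!r}")
        if self.position < 1:
            raise ValueError(f"{self.gene}: position must be >= 1")
        if not self.label:
            object.__setattr__(
                self, "label",
                f"{self.wt_residue}{self.position}{self.mut_residue}")

    def reversed(self) -> "MutationSpec":
        return MutationSpec(self.gene, self.position, self.mut_residue,
                            self.wt_residue,
                            f"{self.mut_residue}{self.position}{self.wt_residue}")


@dataclass(frozen=True)
class Peptide:
    """A digest product with 1-based inclusive coordinates."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int


@dataclass
class DigestResult:
    peptides: list[Peptide]

    def sequences(self) -> set[str]:
        return {p.sequence for p in self.peptides}


@dataclass(frozen=True)
class MutantPeptideCall:
    mutation: MutationSpec
    peptide: str
    start: int
    end: int
    missed_cleavages: int
    distinguishable: bool
    cleavage_change: str  # "none" | "gained" | "lost"
    evidence: str = "direct"


def cleavage_sites(residues: str, enzyme: str = "trypsin") -> list[int]:
    """1-based positions P such that the enzyme cleaves between P and P+1.

    Trypsin cleaves after K/R, Arg-C-like digestion after R only; in both
    cases cleavage is suppressed when the next residue is proline.  The
    C-terminal residue is not a site (there is nothing to cleave off).
    """
    try:
        after = _ENZYME_SITES[enzyme]
    except KeyError:
        raise ValueError(f"unknown enzyme {enzyme!r}; "
                         f"expected one of {sorted(_ENZYME_SITES)}") from None
    return [i + 1 for i in range(len(residues) - 1)
            if residues[i] in after and residues[i + 1] != "P"]


def digest(seq: ProteinSequence | str, enzyme: str = "trypsin",
           max_missed: int = 0) -> DigestResult:
    """Enumerate all peptides with 0..max_missed missed cleavages.

    At 0 missed cleavages the peptides tile the protein; a peptide with k
    missed cleavages is the concatenation of k+1 adjacent fully-cleaved
    segments.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    if not residues:
        raise ValueError("empty sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    sites = cleavage_sites(residues, enzyme)
    bounds = [0] + sites + [len(residues)]  # segment k spans bounds[k]..bounds[k+1]
    nseg = len(bounds) - 1
    peptides = []
    for i in range(nseg):
        for k in range(max_missed + 1):
            j = i + k + 1
            if j > nseg:
                break
            lo, hi = bounds[i], bounds[j]
            peptides.append(Peptide(residues[lo:hi], lo + 1, hi, k))
    return DigestResult(peptides)


def apply_mutation(seq: ProteinSequence, m: MutationSpec) -> ProteinSequence:
    """Substitute one residue; errors if the stated WT residue does not match."""
    if not 1 <= m.position <= len(seq):
        raise ValueError(f"{m.label}: position {m.position} outside "
                         f"{seq.id} (length {len(seq)})")
    found = seq.residues[m.position - 1]
    if found != m.wt_residue:
        raise ValueError(f"{seq.id} {m.label}: expected {m.wt_residue!r} at "
                         f"position {m.position}, found {found!r}")
    mutated = (seq.residues[:m.position - 1] + m.mut_residue
               + seq.residues[m.position:])
    return replace(seq, id=f"{seq.id}:{m.label}", residues=mutated)


def mutant_specific_peptides(seq: ProteinSequence, m: MutationSpec,
                             max_missed: int = 2,
                             enzyme: str = "trypsin") -> list[MutantPeptideCall]:
    """Digest the mutated proteoform and flag the peptides that betray it.

    Returns the mutant digest peptides overlapping the mutated position; when
    the substitution itself creates a new cleavage site (e.g. Q61K), the
    peptide starting immediately after that new site is included too, since
    its N-terminal boundary only exists in the mutant (this is how the short
    Q61K/R peptides lacking the WT "-EEYSAMR" tail arise).  A peptide is
    ``distinguishable`` iff its sequence is absent from the WT digest at the
    same missed-cleavage limit.
    """
    mut_seq = apply_mutation(seq, m)
    wt_digest = digest(seq, enzyme, max_missed)
    mut_digest = digest(mut_seq, enzyme, max_missed)
    wt_seqs = wt_digest.sequences()

    wt_sites = set(cleavage_sites(seq.residues, enzyme))
    mut_sites = set(cleavage_sites(mut_seq.residues, enzyme))
    gained = mut_sites - wt_sites
    lost = wt_sites - mut_sites
    if gained:
        change = "gained"
    elif lost:
        change = "lost"
    else:
        change = "none"

    calls = []
    for pep in mut_digest.peptides:
        covers = pep.start <= m.position <= pep.end
        starts_after_new_site = pep.start - 1 in gained
        if covers or starts_after_new_site:
            calls.append(MutantPeptideCall(
                mutation=m, peptide=pep.sequence, start=pep.start, end=pep.end,
                missed_cleavages=pep.missed_cleavages,
                distinguishable=pep.sequence not in wt_seqs,
                cleavage_change=change))
    return calls


def infer_indirect_cleavage_evidence(observed_peptide: str,
                                     seq: ProteinSequence,
                                     enzyme: str = "trypsin"
                                     ) -> list[MutationSpec]:
    """Mutation candidates explaining an unexpected peptide N-terminus.

    If an observed peptide maps into a protein at a position whose preceding
    residue is not a canonical cleavage residue, the cleavage that produced
    its N-terminus is unexplained; a substitution of that preceding residue
    to K or R (Arg only for Arg-C-like digestion) would create the site.
    Candidates are evidence, never confirmed calls.
    """
    if not observed_peptide:
        raise ValueError("empty peptide")
    residues = seq.residues
    after = _ENZYME_SITES["trypsin" if enzyme == "trypsin" else "argc"]
    candidates: list[MutationSpec] = []
    start = residues.find(observed_peptide)
    if start == -1:
        raise ValueError(f"peptide {observed_peptide!r} not found in {seq.id}")
    while start != -1:
        if start > 0:  # N-terminal match needs no cleavage
            prev = residues[start - 1]
            if prev not in after:
                for target in after:
                    if target != prev:
                        candidates.append(MutationSpec(
                            seq.gene, start, prev, target))
        start = residues.find(observed_peptide, start + 1)
    return candidates


def _il_collapse(s: str) -> str:
    return s.replace("L", "I")


def peptide_uniqueness(peptide: str, proteome: Sequence[ProteinSequence],
                       il_equivalent: bool = True) -> set[str]:
    """Protein ids containing the peptide as an exact substring.

    I and L are indistinguishable by mass, so they are treated as equal by
    default (the convention of peptide-uniqueness checkers).  A peptide is
    considered unique when the genes of the mapped proteins form a single
    symbol (see :func:`is_unique_peptide`).
    """
    if not peptide:
        raise ValueError("empty peptide")
    if not proteome:
        raise ValueError("empty proteome")
    query = _il_collapse(peptide) if il_equivalent else peptide
    hits = set()
    for prot in proteome:
        subject = _il_collapse(prot.residues) if il_equivalent else prot.residues
        if query in subject:
            hits.add(prot.id)
    return hits


def is_unique_peptide(peptide: str, proteome: Sequence[ProteinSequence],
                      il_equivalent: bool = True) -> bool:
    hits = peptide_uniqueness(peptide, proteome, il_equivalent)
    genes = {p.gene for p in proteome if p.id in hits}
    return len(genes) == 1


def hpp_missing_protein_check(protein_id: str,
                              unique_peptides: Iterable[str],
                              min_length: int = 9,
                              min_peptides: int = 2) -> tuple[bool, int]:
    """Two-peptide rule for protein-level evidence claims.

    A missing-protein identification is accepted when at least two uniquely
    mapping peptides of length >= 9 residues support it.  Returns
    (pass, number of qualifying peptides).
    """
    qualifying = sum(1 for p in set(unique_peptides) if len(p) >= min_length)
    return qualifying >= min_peptides, qualifying


def pe_category_tally(proteins: Iterable[ProteinSequence]
                      ) -> dict[str, int]:
    """Count proteins per protein-existence tier (PE1..PE5 + unknown)."""
    counts = Counter()
    total = 0
    for p in proteins:
        total += 1
        if p.pe_level in (1, 2, 3, 4, 5):
            counts[f"PE{p.pe_level}"] += 1
        else:
            counts["unknown"] += 1
    tally = {f"PE{i}": counts.get(f"PE{i}", 0) for i in range(1, 6)}
    tally["unknown"] = counts.get("unknown", 0)
    tally["total"] = total
    return tally


def transcript_evidence_pct(n_with_transcript: int, n_total: int) -> float:
    """Percentage of a protein set that also has transcript-level evidence."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_with_transcript <= n_total:
        raise ValueError("n_with_transcript outside [0, n_total]")
    return 100.0 * n_with_transcript / n_total


#: Recurrent melanoma driver substitutions detectable at the peptide level.
MELANOMA_DRIVER_PANEL: tuple[MutationSpec, ...] = (
    MutationSpec("BRAF", 600, "V", "E", "V600E"),
    MutationSpec("NRAS", 61, "Q", "K", "Q61K"),
    MutationSpec("NRAS", 61, "Q", "R", "Q61R"),
    MutationSpec("NRAS", 12, "G", "A", "G12A"),
    MutationSpec("KRAS", 13, "G", "D", "G13D"),
    MutationSpec("KIT", 566, "N", "D", "N566D"),
    MutationSpec("CDKN2A", 114, "P", "L", "P114L"),
    MutationSpec("GNA11", 266, "N", "K", "N266K"),
)
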