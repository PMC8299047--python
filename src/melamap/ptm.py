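"""Phosphoproteome and acetylome analysis.

Phospho side: Class I site filtering by localization probability, peptide
multiplicity histograms, centered 15-residue sequence windows, iterative
motif-x-style binomial motif enrichment, kinase prediction from enriched
motifs, and kinome coverage accounting (directly identified kinases united
with motif-predicted ones).

Acetyl side: site occupancy (stoichiometry) from endogenous "light" acetyl
signal vs heavy-isotope chemically acetylated signal, per-sample occupancy
distributions, and hypergeometric pathway over-representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "_"


# ---------------------------------------------------------------------------
# phosphosites


@dataclass(frozen=True)
class PhosphoPeptide:
    """A phosphopeptide with its site assignments on the protein."""

    sequence: str
    protein_id: str
    site_positions: tuple[int, ...]       # 1-based protein coordinates
    site_residues: tuple[str, ...]        # S/T/Y per site
    localization_probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.site_positions) == len(self.localization_probs)
                == len(self.site_residues)):
            raise ValueError("site fields must have equal lengths")
        if any(not 0 <= p <= 1 for p in self.localization_probs):
            raise ValueError("localization probabilities must lie in [0, 1]")
        bad = set(self.site_residues) - {"S", "T", "Y"}
        if bad:
            raise ValueError(f"phosphosites must be S/T/Y, got {sorted(bad)}")

    @property
    def multiplicity(self) -> int:
        return len(self.site_positions)


def classify_sites(peptides: Iterable[PhosphoPeptide],
                   threshold: float = 0.75) -> list[tuple[str, int, str, float]]:
    """Class I sites: localization probability >= threshold (inclusive).

    Returns (protein_id, position, residue, probability) tuples.
    """
    out = []
    for pep in peptides:
        for pos, res, prob in zip(pep.site_positions, pep.site_residues,
                                  pep.localization_probs):
            if prob >= threshold:
                out.append((pep.protein_id, pos, res, prob))
    return out


def multiplicity_histogram(peptides: Iterable[PhosphoPeptide]
                           ) -> tuple[int, int, int]:
    """Counts of mono-, di-, and multi- (>=3) phosphorylated peptides."""
    mono = di = multi = 0
    for pep in peptides:
        m = pep.multiplicity
        if m == 1:
            mono += 1
        elif m == 2:
            di += 1
        elif m >= 3:
            multi += 1
    return mono, di, multi


@dataclass(frozen=True)
class SiteWindow:
    """Site-centered sequence window of fixed odd width (default 15)."""

    window: str
    center_residue: str
    protein_id: str = ""
    position: int = 0

    def __post_init__(self) -> None:
        if len(self.window) % 2 != 1:
            raise ValueError("window width must be odd")
        center = self.window[len(self.window) // 2]
        if center != self.center_residue:
            raise ValueError(f"window center {center!r} != declared "
                             f"{self.center_residue!r}")


def extract_window(residues: str, position: int, width: int = 15,
                   pad: str = PAD, protein_id: str = "",
                   require_sty: bool = True) -> SiteWindow:
    """Window of ``width`` residues centered on a 1-based site position.

    Positions beyond the protein termini are filled with the pad character,
    so every window has uniform length and the site sits exactly in the
    middle (index 8, 1-based).
    """
    if width % 2 != 1:
        raise ValueError("width must be odd")
    if not 1 <= position <= len(residues):
        raise ValueError(f"position {position} outside sequence "
                         f"(length {len(residues)})")
    center = residues[position - 1]
    if require_sty and center not in "STY":
        raise ValueError(f"residue at position {position} is {center!r}, "
                         "not a phospho-acceptor (S/T/Y)")
    flank = width // 2
    lo = position - 1 - flank
    hi = position + flank
    left = pad * max(0, -lo) + residues[max(0, lo):position - 1]
    right = residues[position:hi] + pad * max(0, hi - len(residues))
    return SiteWindow(left + center + right, center, protein_id, position)


# ---------------------------------------------------------------------------
# motif enrichment (motif-x style iterative binomial search)


@dataclass(frozen=True)
class Motif:
    """A phosphorylation motif: center residue plus fixed flank residues.

    ``fixed`` holds (offset, residue) pairs with offsets relative to the
    phospho-acceptor (negative = N-terminal side).
    """

    center: str
    fixed: tuple[tuple[int, str], ...]

    @property
    def pattern(self) -> str:
        """Compact dash notation, e.g. ``R-x-x-S#`` or ``S#-P``."""
        offsets = [o for o, _ in self.fixed]
        lo = min([0] + offsets)
        hi = max([0] + offsets)
        lookup = dict(self.fixed)
        parts = []
        for off in range(lo, hi + 1):
            if off == 0:
                parts.append(self.center + "#")
            elif off in lookup:
                parts.append(lookup[off])
            else:
                parts.append("x")
        return "-".join(parts)


def parse_motif(pattern: str) -> Motif:
    """Parse dash notation back into a :class:`Motif`."""
    parts = pattern.split("-")
    center_idx = [i for i, p in enumerate(parts) if p.endswith("#")]
    if len(center_idx) != 1:
        raise ValueError(f"motif {pattern!r} must mark exactly one center "
                         "with '#'")
    c = center_idx[0]
    center = parts[c][:-1]
    if center not in "STY":
        raise ValueError(f"motif {pattern!r}: center must be S/T/Y")
    fixed = []
    for i, tok in enumerate(parts):
        if i == c or tok == "x":
            continue
        if len(tok) != 1 or tok not in AMINO_ACIDS:
            raise ValueError(f"motif {pattern!r}: bad token {tok!r}")
        fixed.append((i - c, tok))
    return Motif(center, tuple(sorted(fixed)))


@dataclass(frozen=True)
class MotifHit:
    motif: Motif
    p_cumulative: float
    n_foreground: int
    fold_enrichment: float


def _to_char_matrix(windows: Sequence[str], width: int) -> np.ndarray:
    arr = np.frombuffer("".join(windows).encode("ascii"), dtype="S1")
    return arr.reshape(len(windows), width)


def enrich_motifs(foreground: Sequence[str], background: Sequence[str],
                  p_cutoff: float = 1e-6, min_occurrences: int = 20,
                  max_motifs: int = 50) -> list[MotifHit]:
    """Iterative binomial motif search on fixed-width site windows.

    At each step the (position, residue) pair minimizing the binomial tail
    probability of its foreground count given the background frequency is
    fixed, both sets are filtered to windows carrying it, and the search
    recurses until no pair reaches ``p_cutoff`` with at least
    ``min_occurrences`` foreground occurrences.  The finished motif's
    instances are removed from both sets and the search restarts, so
    successive motifs partition the foreground.  Ties are broken by position
    index, then residue, making the search fully deterministic.
    """
    if not foreground:
        raise ValueError("empty foreground")
    if len(background) < len(foreground):
        raise ValueError("background must be at least as large as foreground")
    widths = {len(w) for w in list(foreground) + list(background)}
    if len(widths) != 1:
        raise ValueError(f"windows have inconsistent widths {widths}")
    width = widths.pop()
    if width % 2 != 1:
        raise ValueError("window width must be odd")
    center = width // 2

    fg_all = _to_char_matrix(foreground, width)
    bg_all = _to_char_matrix(background, width)
    residues = np.array([aa.encode() for aa in AMINO_ACIDS], dtype="S1")

    hits: list[MotifHit] = []
    for center_res in "STY":  # each acceptor residue searched separately
        c = center_res.encode()
        fg = fg_all[fg_all[:, center] == c]
        bg = bg_all[bg_all[:, center] == c]
        hits.extend(_search_center(fg, bg, center_res, center, width,
                                   residues, p_cutoff, min_occurrences,
                                   max_motifs - len(hits)))
    return hits


def _search_center(fg: np.ndarray, bg: np.ndarray, center_res: str,
                   center: int, width: int, residues: np.ndarray,
                   p_cutoff: float, min_occurrences: int,
                   max_motifs: int) -> list[MotifHit]:
    hits: list[MotifHit] = []
    while len(fg) and len(bg) and len(hits) < max_motifs:
        cur_fg, cur_bg = fg, bg
        fixed: list[tuple[int, str]] = []
        p_cum = 1.0
        while True:
            # count each residue at each non-center, not-yet-fixed position
            fg_counts = np.stack([(cur_fg == r).sum(axis=0) for r in residues])
            bg_counts = np.stack([(cur_bg == r).sum(axis=0) for r in residues])
            n_fg, n_bg = len(cur_fg), len(cur_bg)
            freq = bg_counts / max(n_bg, 1)
            pvals = stats.binom.sf(fg_counts - 1, n_fg, np.clip(freq, 1e-12, 1))
            taken = {center} | {o + center for o, _ in fixed}
            best = None
            for pos in range(width):  # position-major order fixes ties
                if pos in taken:
                    continue
                for ri in range(len(residues)):
                    k = int(fg_counts[ri, pos])
                    if k < min_occurrences:
                        continue
                    p = float(pvals[ri, pos])
                    if p > p_cutoff:
                        continue
                    if best is None or p < best[0]:
                        best = (p, pos, ri)
            if best is None:
                break
            p, pos, ri = best
            aa = AMINO_ACIDS[ri]
            fixed.append((pos - center, aa))
            p_cum *= p
            keep_fg = cur_fg[:, pos] == residues[ri]
            keep_bg = cur_bg[:, pos] == residues[ri]
            cur_fg, cur_bg = cur_fg[keep_fg], cur_bg[keep_bg]
        if not fixed:
            break
        motif = Motif(center_res, tuple(sorted(fixed)))
        n_match = len(cur_fg)
        fg_frac = n_match / len(fg)
        bg_frac = max(len(cur_bg), 1) / max(len(bg), 1)
        hits.append(MotifHit(motif, p_cum, n_match, fg_frac / bg_frac))
        # remove matched instances and restart
        fg = fg[~_matches(fg, motif, center, residues)]
        bg = bg[~_matches(bg, motif, center, residues)]
        if len(bg) < max(len(fg), 1):
            break
    return hits


def _matches(mat: np.ndarray, motif: Motif, center: int,
             residues: np.ndarray) -> np.ndarray:
    mask = np.ones(len(mat), dtype=bool)
    for off, aa in motif.fixed:
        mask &= mat[:, center + off] == aa.encode()
    return mask


# ---------------------------------------------------------------------------
# kinase prediction and kinome coverage

#: Small curated kinase -> substrate-motif table (a synthetic stand-in
#: fixture covering well-known consensus motifs; editable/replaceable).
DEFAULT_KINASE_MOTIFS: dict[str, tuple[str, ...]] = {
    "R-x-x-S#": ("PRKACA", "CAMK2A", "RPS6KA1"),
    "R-x-R-x-x-S#": ("AKT1", "SGK1"),
    "S#-P": ("CDK1", "CDK2", "MAPK1", "MAPK3", "GSK3B"),
    "T#-P": ("CDK1", "MAPK1", "MAPK3"),
    "S#-x-x-E": ("CSNK2A1",),
    "S#-x-x-D": ("CSNK2A1",),
    "L-x-R-x-x-S#": ("CHEK1", "CHEK2"),
    "R-R-x-S#": ("PRKACA", "PRKCA"),
}


def predict_kinases(motif_hits: Iterable[MotifHit],
                    kinase_motif_table: Mapping[str, Iterable[str]] | None = None
                    ) -> dict[str, int]:
    """Kinases whose substrate motif matches an enriched motif.

    A table motif matches an enriched motif when it has the same central
    acceptor residue and its fixed flank constraints are a subset of the
    enriched motif's.  Returns kinase -> number of supporting foreground
    windows (summed over matching motifs).
    """
    table = (DEFAULT_KINASE_MOTIFS if kinase_motif_table is None
             else kinase_motif_table)
    parsed = {parse_motif(p): tuple(k) for p, k in table.items()}
    support: dict[str, int] = {}
    for hit in motif_hits:
        enriched = set(hit.motif.fixed)
        for table_motif, kinases in parsed.items():
            if (table_motif.center == hit.motif.center
                    and set(table_motif.fixed) <= enriched):
                for kin in kinases:
                    support[kin] = support.get(kin, 0) + hit.n_foreground
    return support


@dataclass(frozen=True)
class KinomeCoverage:
    identified: frozenset
    predicted: frozenset
    union_count: int
    coverage_fraction: float  # percent of the kinome


def kinome_union(identified: set, predicted: set, kinome: set
                 ) -> KinomeCoverage:
    """Union of directly identified and motif-predicted kinases vs the kinome."""
    if not kinome:
        raise ValueError("empty kinome")
    ident, pred, kin = set(identified), set(predicted), set(kinome)
    stray = (ident | pred) - kin
    if stray:
        logger.warning("%d kinases outside the supplied kinome: %s",
                       len(stray), sorted(stray)[:5])
    union = ident | pred
    return KinomeCoverage(frozenset(ident), frozenset(pred), len(union),
                          100.0 * len(union & kin) / len(kin))


# ---------------------------------------------------------------------------
# acetylome occupancy


def acetyl_occupancy(light: float, heavy: float) -> float:
    """Site occupancy in percent: 100 * light / (light + heavy).

    Light is the endogenous acetyl signal, heavy the chemically acetylated
    (heavy-isotope) signal from the previously unmodified fraction.  Returns
    NaN (undefined) when both channels are zero.
    """
    if light < 0 or heavy < 0:
        raise ValueError("intensities must be non-negative")
    total = light + heavy
    if total == 0:
        return float("nan")
    return 100.0 * light / total


def occupancy_table(sites: pd.DataFrame) -> pd.DataFrame:
    """Add an ``occupancy`` (%) column from light/heavy intensity columns."""
    if ((sites["light_intensity"] < 0) | (sites["heavy_intensity"] < 0)).any():
        raise ValueError("intensities must be non-negative")
    out = sites.copy()
    total = out["light_intensity"] + out["heavy_intensity"]
    with np.errstate(invalid="ignore", divide="ignore"):
        occ = 100.0 * out["light_intensity"] / total
    occ[total == 0] = np.nan
    out["occupancy"] = occ
    return out


def occupancy_distribution(sites: pd.DataFrame,
                           sample_col: str = "sample_id",
                           group_col: str = "group"
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample and per-group occupancy summaries.

    Expects an ``occupancy`` column (see :func:`occupancy_table`); undefined
    (NaN) occupancies are excluded from the statistics and counted in
    ``n_undefined``.  Returns (per_sample, per_group) frames with median and
    quartiles.
    """
    df = sites
    if "occupancy" not in df.columns:
        df = occupancy_table(df)
    rows = []
    for (sample, group), sub in df.groupby([sample_col, group_col],
                                           sort=True):
        occ = sub["occupancy"].dropna()
        if occ.empty:
            rows.append((sample, group, 0, len(sub), np.nan, np.nan, np.nan))
            continue
        rows.append((sample, group, len(occ), len(sub) - len(occ),
                     float(occ.median()), float(occ.quantile(0.25)),
                     float(occ.quantile(0.75))))
    per_sample = pd.DataFrame(
        rows, columns=[sample_col, group_col, "n", "n_undefined",
                       "median", "q1", "q3"]).set_index(sample_col)
    grp_rows = []
    for group, sub in df.groupby(group_col, sort=True):
        occ = sub["occupancy"].dropna()
        grp_rows.append((group, len(occ), float(occ.median()),
                         float(occ.quantile(0.25)), float(occ.quantile(0.75))))
    per_group = pd.DataFrame(
        grp_rows, columns=[group_col, "n", "median", "q1", "q3"]
    ).set_index(group_col)
    return per_sample, per_group


def set_enrichment(target: set, annotations: Mapping[str, set],
                   background: set) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a target set.

    ``target`` must be a subset of ``background``.  Per term, the upper
    hypergeometric tail P(X >= k) with k = |term ∩ target| drawn from
    K = |term ∩ background| successes in a draw of |target| from
    |background|; BH adjustment across terms.
    """
    target, background = set(target), set(background)
    if not target <= background:
        raise ValueError("target must be a subset of the background")
    M, N = len(background), len(target)
    rows = []
    for term, members in annotations.items():
        K = len(set(members) & background)
        if K == 0:
            continue
        k = len(set(members) & target)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        rows.append((term, k, K, p))
    out = pd.DataFrame(rows, columns=["term", "n_target", "n_background",
                                      "p_raw"]).set_index("term")
    if len(out):
        out["p_adjusted"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    else:
        out["p_adjusted"] = pd.Series(dtype=float)
    return out
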