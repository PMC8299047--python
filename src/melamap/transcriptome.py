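"""Proteome-transcriptome integration.

Overlaps the protein-coding genes identified by proteomics with a transcript
table and the annotated human gene complement, correlates gene-level protein
and transcript abundances, and runs 1D annotation enrichment on the
protein-minus-transcript differences: a rank-based test asking whether the
genes of an annotation term shift systematically within one ranked score list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapSummary:
    n_protein_only: int
    n_transcript_only: int
    n_both: int
    n_neither_of_human: int
    coverage_predicted_pct: float
    coverage_identified_pct: float | None = None


def filter_transcripts(table: pd.DataFrame, min_reads: int = 10,
                       gene_col: str = "gene") -> pd.DataFrame:
    """Keep transcripts with max read count >= min_reads; collapse to genes.

    The detection criterion is the maximum over samples (a transcript seen
    with >= min_reads anywhere counts as detected); transcripts of one gene
    are collapsed by the per-sample maximum.
    """
    sample_cols = [c for c in table.columns if c != gene_col]
    kept = table[table[sample_cols].max(axis=1) >= min_reads]
    return kept.groupby(gene_col)[sample_cols].max()


def transcript_medians(gene_table: pd.DataFrame, log2: bool = True) -> pd.Series:
    """Per-gene median abundance over samples with nonzero counts.

    Counts are log2-transformed (zeros excluded) before taking the median, so
    the value is comparable to log2 protein relative abundances.
    """
    vals = gene_table.where(gene_table > 0)
    if log2:
        vals = np.log2(vals)
    return vals.median(axis=1, skipna=True).dropna()


def transcript_detection_fraction(gene_table: pd.DataFrame) -> pd.Series:
    """Fraction of samples in which each gene has a nonzero count."""
    return (gene_table > 0).mean(axis=1)


def overlap_sets(protein_genes: set, transcript_genes: set, human_genes: set,
                 human_identified_genes: set | None = None) -> OverlapSummary:
    """Three-way gene overlap and human-proteome coverage percentages.

    ``coverage_predicted_pct`` is the share of the annotated human gene
    complement identified at the protein level; ``coverage_identified_pct``
    uses the experimentally observed (PE1) subset when provided.
    """
    if not human_genes:
        raise ValueError("empty human gene set")
    p, t, h = set(protein_genes), set(transcript_genes), set(human_genes)
    cov_pred = 100.0 * len(p & h) / len(h)
    cov_ident = None
    if human_identified_genes is not None:
        hi = set(human_identified_genes)
        if not hi:
            raise ValueError("empty identified human gene set")
        cov_ident = 100.0 * len(p & hi) / len(hi)
    return OverlapSummary(
        n_protein_only=len(p - t),
        n_transcript_only=len(t - p),
        n_both=len(p & t),
        n_neither_of_human=len(h - p - t),
        coverage_predicted_pct=cov_pred,
        coverage_identified_pct=cov_ident)


def minmax_scale(values, lo: float = 10.0, hi: float = 35.0) -> np.ndarray:
    """Affine map of the values onto [lo, hi] (min -> lo, max -> hi)."""
    arr = np.asarray(values, dtype=float)
    vmin, vmax = np.nanmin(arr), np.nanmax(arr)
    if vmax == vmin:
        raise ValueError("cannot min-max scale a constant vector")
    return lo + (arr - vmin) * (hi - lo) / (vmax - vmin)


def correlate(protein_medians: pd.Series, transcript_medians: pd.Series,
              detected_fraction: pd.Series | None = None,
              min_detected_fraction: float | None = None
              ) -> tuple[float, int]:
    """Pearson correlation of gene-matched protein and transcript medians.

    Optionally restricted to transcripts detected in at least
    ``min_detected_fraction`` of the transcriptome samples.  Returns (r, n).
    """
    genes = protein_medians.index.intersection(transcript_medians.index)
    if min_detected_fraction is not None:
        if detected_fraction is None:
            raise ValueError("detection filter requested without per-gene "
                             "detected_fraction")
        keep = detected_fraction[detected_fraction >= min_detected_fraction].index
        genes = genes.intersection(keep)
    x = protein_medians.loc[genes].astype(float)
    y = transcript_medians.loc[genes].astype(float)
    ok = x.notna() & y.notna()
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need >= 3 gene pairs, have {len(x)}")
    r, _ = stats.pearsonr(x, y)
    return float(r), int(len(x))


def enrichment_score_1d(ranks_members: np.ndarray, n: int, n_in: int) -> float:
    """Rank-shift score in [-1, 1]: +1 when members hold the top ranks.

    With genes ranked ascending (rank n = largest score), the score is
    s = 2 * (mean member rank - (n+1)/2) / (n - n_in); it is 0 in expectation
    under exchangeability and hits +/-1 exactly at the extremes.
    """
    return float(2.0 * (ranks_members.mean() - (n + 1) / 2.0) / (n - n_in))


def enrichment_1d(scores: pd.Series, annotations: Mapping[str, set],
                  min_members: int = 5) -> pd.DataFrame:
    """1D annotation enrichment over one ranked score list.

    Per term: the rank-shift score above plus a two-sided Mann-Whitney U test
    of member vs non-member scores; Benjamini-Hochberg adjustment across the
    tested terms.  Tied scores receive mid-ranks.  Terms with fewer than
    ``min_members`` members present, or covering all genes, are skipped.
    """
    scores = scores.dropna()
    n = len(scores)
    ranks = scores.rank(method="average")
    rows = []
    for term, members in annotations.items():
        in_mask = scores.index.isin(members)
        n_in = int(in_mask.sum())
        if n_in < min_members or n_in == n:
            logger.info("term %r skipped (%d members in scores)", term, n_in)
            continue
        s = enrichment_score_1d(ranks.to_numpy()[in_mask], n, n_in)
        _, p = stats.mannwhitneyu(scores[in_mask], scores[~in_mask],
                                  alternative="two-sided")
        rows.append((term, s, float(p), n_in))
    if not rows:
        return pd.DataFrame(columns=["term", "score", "p_raw", "p_adjusted",
                                     "n_members"]).set_index("term")
    out = pd.DataFrame(rows, columns=["term", "score", "p_raw", "n_members"]
                       ).set_index("term")
    out["p_adjusted"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    return out[["score", "p_raw", "p_adjusted", "n_members"]]
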