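"""Synthetic data with the statistical structure the melanoma pipeline assumes.

Every generator is seeded and reproducible (one master seed; each generator
draws from its own deterministically derived child stream) and returns the
ground truth needed to verify downstream recovery: the planted reference
proteins, batch offsets, acetylation occupancies, motifs and blood-origin
labels.

The abundance model is log-normal in log2 space with a uniform spread tuned
to the configured dynamic range (default six orders of magnitude), additive
per-batch offsets plus per-sample shifts in log2 space, and a logistic
detection curve in log-abundance, so detection probability rises
monotonically with true abundance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .normalize import AbundanceMatrix
from .proteogenomics import MutationSpec, ProteinSequence
from .quantify import PeptideQuantRecord

_STREAM = {"abundance": 0, "transcriptome": 1, "acetylome": 2, "phospho": 3,
           "peptides": 4, "plasma": 5, "proteome": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Child generator for a named sub-stream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAM[stream],)))


@dataclass
class SimConfig:
    """Study-scale simulation parameters.

    Defaults mirror the study conditions: 2000 proteins across 5 batches of
    20 samples with 45 planted reference proteins, abundances spanning six
    orders of magnitude, and low acetylation occupancy (Beta(1, 9), mean 10%).
    """

    n_proteins: int = 2000
    n_batches: int = 5
    samples_per_batch: int = 20
    n_reference: int = 45
    dynamic_range_log10: float = 6.0
    base_log2_abundance: float = 10.0
    batch_shift_sd: float = 1.0          # log2 units
    sample_shift_sd: float = 0.3         # log2 units
    noise_sd_reference: float = 0.2      # log2 units
    noise_sd_range: tuple[float, float] = (0.3, 1.2)
    detection_midpoint: float = 13.0     # log2 abundance at 50% detection
    detection_slope: float = 1.5
    reference_cv_pct: float = 60.0
    enforce_reference_exclusivity: bool = True
    rho_transcript: float = 0.44
    occupancy_alpha: float = 1.0
    occupancy_beta: float = 9.0
    occupancy_noise_sd: float = 0.15     # ln-scale multiplicative noise
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_batches", "samples_per_batch"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.n_reference <= self.n_proteins:
            raise ValueError("need 0 <= n_reference <= n_proteins")
        if self.dynamic_range_log10 <= 0:
            raise ValueError("dynamic_range_log10 must be positive")
        if not -1 <= self.rho_transcript <= 1:
            raise ValueError("rho_transcript must lie in [-1, 1]")
        if self.occupancy_alpha <= 0 or self.occupancy_beta <= 0:
            raise ValueError("Beta occupancy parameters must be positive")

    @property
    def n_samples(self) -> int:
        return self.n_batches * self.samples_per_batch


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    reference_ids: set = field(default_factory=set)
    batch_offsets: pd.Series | None = None
    sample_shifts: pd.Series | None = None
    true_abundances: pd.Series | None = None   # log2 scale
    true_occupancies: pd.Series | None = None  # fractions in [0, 1]
    planted_motifs: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)


def detection_probability(true_log2: np.ndarray, config: SimConfig
                          ) -> np.ndarray:
    """Logistic detection curve: monotone non-decreasing in true abundance."""
    z = (np.asarray(true_log2, dtype=float)
         - config.detection_midpoint) / config.detection_slope
    return 1.0 / (1.0 + np.exp(-z))


def gen_abundance_matrix(config: SimConfig
                         ) -> tuple[AbundanceMatrix, GroundTruth]:
    """Multi-batch linear-scale abundance matrix with planted references.

    Reference proteins are detected in every sample and kept below the
    per-batch CV criterion; every non-reference protein is guaranteed to
    violate at least one criterion (a qualifying non-reference protein gets
    one value knocked out), so the reference filter recovers exactly the
    planted set.  Set ``enforce_reference_exclusivity=False`` for degenerate
    noise-free scenarios where all proteins may legitimately qualify.
    """
    rng = _rng(config.seed, "abundance")
    n, ns = config.n_proteins, config.n_samples
    protein_ids = [f"P{i:05d}" for i in range(n)]
    batch_labels = [f"B{b + 1}" for b in range(config.n_batches)]
    sample_ids, batch_of = [], {}
    for b, batch in enumerate(batch_labels):
        for s in range(config.samples_per_batch):
            sid = f"{batch}S{s + 1:02d}"
            sample_ids.append(sid)
            batch_of[sid] = batch
    batches = pd.Series(batch_of)

    span = config.dynamic_range_log10 * math.log2(10)
    true_log2 = rng.uniform(config.base_log2_abundance,
                            config.base_log2_abundance + span, n)
    ref_idx = rng.choice(n, size=config.n_reference, replace=False)
    is_ref = np.zeros(n, dtype=bool)
    is_ref[ref_idx] = True
    # reference proteins live in the well-detected regime
    true_log2[is_ref] = rng.uniform(
        config.base_log2_abundance + 0.5 * span,
        config.base_log2_abundance + span, config.n_reference)

    batch_off = rng.normal(0.0, config.batch_shift_sd, config.n_batches)
    sample_shift = rng.normal(0.0, config.sample_shift_sd, ns)
    noise_sd = rng.uniform(*config.noise_sd_range, n)
    noise_sd[is_ref] = config.noise_sd_reference

    per_sample_off = np.array(
        [batch_off[batch_labels.index(batches[s])] for s in sample_ids])
    log2_vals = (true_log2[:, None] + per_sample_off[None, :]
                 + sample_shift[None, :]
                 + rng.normal(0.0, 1.0, (n, ns)) * noise_sd[:, None])

    detect_p = detection_probability(true_log2, config)
    detected = rng.random((n, ns)) < detect_p[:, None]
    detected[is_ref] = True

    sample_to_col = {s: j for j, s in enumerate(sample_ids)}
    batch_cols = {b: [sample_to_col[s] for s in sample_ids if batch_of[s] == b]
                  for b in batch_labels}

    linear = np.exp2(log2_vals)
    cv_limit = config.reference_cv_pct

    def _batch_cv(row: np.ndarray, cols: list[int]) -> float:
        v = row[cols]
        m = v.mean()
        return 100.0 * v.std(ddof=1) / m if m > 0 else np.inf

    # keep planted references safely under the CV criterion in every batch
    for i in np.flatnonzero(is_ref):
        for b in batch_labels:
            cols = batch_cols[b]
            while _batch_cv(linear[i], cols) >= 0.9 * cv_limit:
                v = linear[i, cols]
                linear[i, cols] = v.mean() + 0.5 * (v - v.mean())

    if config.enforce_reference_exclusivity:
        # any fully-detected, low-CV non-reference protein loses one value
        for i in np.flatnonzero(~is_ref):
            if not detected[i].all():
                continue
            if all(_batch_cv(linear[i], batch_cols[b]) < cv_limit
                   for b in batch_labels):
                detected[i, rng.integers(ns)] = False

    values = pd.DataFrame(np.where(detected, linear, np.nan),
                          index=protein_ids, columns=sample_ids)
    truth = GroundTruth(
        reference_ids={protein_ids[i] for i in ref_idx},
        batch_offsets=pd.Series(batch_off, index=batch_labels),
        sample_shifts=pd.Series(sample_shift, index=sample_ids),
        true_abundances=pd.Series(true_log2, index=protein_ids))
    return AbundanceMatrix(values, batches, "linear"), truth


def gen_paired_transcriptome(matrix: AbundanceMatrix, rho: float, seed: int,
                             n_samples: int = 100,
                             frac_transcript_only: float = 0.10,
                             frac_protein_only: float = 0.03,
                             count_noise_sd: float = 0.05,
                             quantize: bool = True
                             ) -> tuple[pd.DataFrame, GroundTruth]:
    """Transcript count table whose gene medians correlate with the proteome.

    Gene-level log2 transcript abundance is built by the bivariate-normal
    construction t = rho * z + sqrt(1 - rho^2) * e around the standardized
    protein medians, so the Pearson correlation between transcript and
    protein medians converges to ``rho``.  A configurable fraction of genes
    is transcript-only (no protein) or protein-only (dropped from the table).
    Returns a transcript-level table (index transcript id, ``gene`` column,
    one count column per sample).
    """
    if not -1 <= rho <= 1:
        raise ValueError("rho must lie in [-1, 1]")
    rng = _rng(seed, "transcriptome")
    with np.errstate(invalid="ignore"):
        p_med = np.log2(matrix.values).median(axis=1, skipna=True).dropna()
    genes = np.array(p_med.index)
    n_drop = int(round(frac_protein_only * len(genes)))
    if n_drop:
        dropped = rng.choice(len(genes), n_drop, replace=False)
        keep = np.ones(len(genes), dtype=bool)
        keep[dropped] = False
        genes = genes[keep]
    z = (p_med[genes] - p_med[genes].mean()) / p_med[genes].std(ddof=0)
    e = rng.standard_normal(len(genes))
    t_z = rho * z.to_numpy() + math.sqrt(max(0.0, 1 - rho * rho)) * e
    t_log2 = 12.0 + 2.5 * t_z

    extra = int(round(frac_transcript_only * len(genes)))
    extra_genes = [f"TX{i:05d}" for i in range(extra)]
    t_log2 = np.concatenate([t_log2, rng.uniform(6, 18, extra)])
    all_genes = list(genes) + extra_genes

    noise = (rng.normal(0.0, count_noise_sd, (len(all_genes), n_samples))
             if count_noise_sd > 0 else np.zeros((len(all_genes), n_samples)))
    counts = np.exp2(t_log2[:, None] + noise)
    if quantize:
        counts = np.rint(counts)
    table = pd.DataFrame(counts,
                         index=[f"{g}.1" for g in all_genes],
                         columns=[f"T{j + 1:03d}" for j in range(n_samples)])
    table.insert(0, "gene", all_genes)
    truth = GroundTruth(extras={
        "rho": rho,
        "shared_genes": list(genes),
        "transcript_only_genes": extra_genes,
        "true_transcript_log2": pd.Series(t_log2, index=all_genes)})
    return table, truth


_ACETYL_GROUPS = (("primary", 16), ("lymph_node", 23), ("other_metastasis", 21))


def gen_acetylome(config: SimConfig, n_samples: int = 60,
                  sites_per_sample: tuple[int, int] = (200, 2000),
                  n_site_pool: int = 3000,
                  intensity_log2_mean: float = 20.0,
                  intensity_log2_sd: float = 2.0
                  ) -> tuple[pd.DataFrame, GroundTruth]:
    """Acetyl-site light/heavy intensity pairs with Beta-distributed occupancy.

    Each site in the pool carries a true occupancy theta ~ Beta(alpha, beta);
    in every sample where the site is observed, light = theta * I * eps and
    heavy = (1 - theta) * I * eps' with site intensity I log-normal and
    independent multiplicative noise eps (ln-sd ``occupancy_noise_sd``).  The
    sample grouping follows the cohort: 16 primary, 23 lymph-node and 21
    other-metastasis samples (rescaled for other n_samples).
    """
    rng = _rng(config.seed, "acetylome")
    lo, hi = sites_per_sample
    if not 1 <= lo <= hi:
        raise ValueError("invalid sites_per_sample range")
    theta = rng.beta(config.occupancy_alpha, config.occupancy_beta, n_site_pool)
    site_protein = [f"ACP{i // 4:04d}" for i in range(n_site_pool)]
    site_pos = rng.integers(5, 800, n_site_pool)
    # pool index keeps keys unique even if a (protein, position) pair repeats
    site_key = [f"{i:05d}:{p}:K{pos}"
                for i, (p, pos) in enumerate(zip(site_protein, site_pos))]

    groups: list[str] = []
    total_w = sum(w for _, w in _ACETYL_GROUPS)
    for name, w in _ACETYL_GROUPS:
        groups += [name] * round(n_samples * w / total_w)
    groups = (groups + [_ACETYL_GROUPS[-1][0]] * n_samples)[:n_samples]

    rows = []
    for j in range(n_samples):
        sid = f"A{j + 1:02d}"
        n_sites = int(rng.integers(lo, hi + 1))
        n_sites = min(n_sites, n_site_pool)
        chosen = rng.choice(n_site_pool, n_sites, replace=False)
        inten = np.exp2(rng.normal(intensity_log2_mean, intensity_log2_sd,
                                   n_sites))
        if config.occupancy_noise_sd > 0:
            eps_l = np.exp(rng.normal(0, config.occupancy_noise_sd, n_sites))
            eps_h = np.exp(rng.normal(0, config.occupancy_noise_sd, n_sites))
        else:
            eps_l = eps_h = np.ones(n_sites)
        th = theta[chosen]
        rows.append(pd.DataFrame({
            "sample_id": sid, "group": groups[j],
            "protein_id": np.array(site_protein)[chosen],
            "lysine_position": site_pos[chosen],
            "site_key": np.array(site_key)[chosen],
            "light_intensity": th * inten * eps_l,
            "heavy_intensity": (1 - th) * inten * eps_h}))
    table = pd.concat(rows, ignore_index=True)
    truth = GroundTruth(true_occupancies=pd.Series(theta, index=site_key))
    return table, truth


@dataclass
class PhosphoSim:
    peptides: list
    foreground_windows: list[str]
    background_windows: list[str]
    ground_truth: GroundTruth


def gen_phospho_table(seed: int = 0, n_foreground: int = 2000,
                      n_background: int = 20000, width: int = 15,
                      planted_motif: str = "R-x-x-S#",
                      planted_fraction: float = 0.30) -> PhosphoSim:
    """Phosphopeptides plus site windows with one planted motif.

    Background windows have uniform flank composition (each residue at 5%);
    a ``planted_fraction`` of the foreground carries the planted motif's
    fixed residues, so the motif search should recover it as the top hit.
    """
    from .ptm import AMINO_ACIDS, PhosphoPeptide, parse_motif
    if not 0 <= planted_fraction <= 1:
        raise ValueError("planted_fraction must lie in [0, 1]")
    rng = _rng(seed, "phospho")
    motif = parse_motif(planted_motif)
    center = width // 2
    aa = np.array(list(AMINO_ACIDS))
    sty = np.array(list("STY"))

    def _windows(count: int) -> np.ndarray:
        w = aa[rng.integers(0, len(aa), (count, width))]
        w[:, center] = sty[rng.choice(3, count, p=[0.65, 0.25, 0.10])]
        return w

    bg = _windows(n_background)
    fg = _windows(n_foreground)
    n_plant = int(round(planted_fraction * n_foreground))
    fg[:n_plant, center] = motif.center
    for off, res in motif.fixed:
        fg[:n_plant, center + off] = res
    perm = rng.permutation(n_foreground)
    fg = fg[perm]

    fg_windows = ["".join(row) for row in fg]
    bg_windows = ["".join(row) for row in bg]

    mult = rng.choice([1, 2, 3, 4], n_foreground, p=[0.62, 0.26, 0.08, 0.04])
    high = rng.random(n_foreground) < 0.85
    probs = np.where(high, rng.beta(12, 1, n_foreground),
                     rng.beta(2, 3, n_foreground))
    peptides = []
    for i, win in enumerate(fg_windows):
        m = int(mult[i])
        positions = tuple(8 + 3 * k for k in range(m))
        residues = (win[center],) + tuple(
            sty[rng.integers(0, 3)] for _ in range(m - 1))
        p_extra = tuple(float(rng.beta(5, 2)) for _ in range(m - 1))
        peptides.append(PhosphoPeptide(
            sequence=win.replace("_", ""), protein_id=f"PHP{i:05d}",
            site_positions=positions, site_residues=residues,
            localization_probs=(float(probs[i]),) + p_extra))
    truth = GroundTruth(planted_motifs=[motif.pattern],
                        extras={"planted_fraction": planted_fraction,
                                "n_planted": n_plant})
    return PhosphoSim(peptides, fg_windows, bg_windows, truth)


def gen_peptide_table(seed: int = 0, n_proteins: int = 40,
                      peptides_range: tuple[int, int] = (1, 12),
                      n_channels: int = 0
                      ) -> tuple[list[PeptideQuantRecord], GroundTruth]:
    """Peptide quantification records with known per-protein true abundance."""
    rng = _rng(seed, "peptides")
    aa = np.array(list("ACDEFGHILMNQSTVWY"))
    records: list[PeptideQuantRecord] = []
    true_ab = {}
    for i in range(n_proteins):
        pid = f"QP{i:04d}"
        true = float(np.exp2(rng.uniform(10, 25)))
        true_ab[pid] = true
        n_pep = int(rng.integers(peptides_range[0], peptides_range[1] + 1))
        for j in range(n_pep):
            seq = "".join(aa[rng.integers(0, len(aa), rng.integers(7, 25))]) + "K"
            unique = bool(rng.random() < 0.85)
            area = true * float(rng.lognormal(0, 0.5))
            reporters = None
            if n_channels:
                reporters = tuple(float(true * rng.lognormal(0, 0.3))
                                  for _ in range(n_channels))
            records.append(PeptideQuantRecord(
                peptide_sequence=seq, protein_id=pid, is_unique=unique,
                is_razor=not unique, area=area,
                reporter_intensities=reporters))
    truth = GroundTruth(true_abundances=pd.Series(true_ab))
    return records, truth


@dataclass
class PlasmaSim:
    counts: pd.DataFrame            # protein_id, gene, spectral_count, length
    plasma_genes: set
    blood_genes: set                # ground truth blood-origin genes
    tissue_protein_genes: set
    tissue_transcript_genes: set
    per_sample_genes: dict[str, set]
    ground_truth: GroundTruth


def gen_plasma_counts(seed: int = 0, n_plasma: int = 1000,
                      n_blood: int = 112, ig_fraction: float = 0.84,
                      n_tissue_genes: int = 12000,
                      n_tissue_samples: int = 50,
                      blood_detect_prob: float = 0.45) -> PlasmaSim:
    """Plasma spectral counts with planted blood-origin proteins.

    ``n_blood`` plasma genes are withheld from the tissue transcriptome (the
    blood-origin ground truth); a configurable share of them get
    immunoglobulin-style gene symbols.  Per-sample tissue identification sets
    include each blood gene with probability ``blood_detect_prob``, keeping
    the per-sample blood fraction small.
    """
    if n_blood > n_plasma:
        raise ValueError("n_blood cannot exceed n_plasma")
    rng = _rng(seed, "plasma")
    genes = [f"GEN{i:05d}" for i in range(n_plasma)]
    blood_idx = sorted(rng.choice(n_plasma, n_blood, replace=False))
    n_ig = int(round(ig_fraction * n_blood))
    ig_prefixes = ("IGHV", "IGKV", "IGLV")
    for k, idx in enumerate(blood_idx[:n_ig]):
        genes[idx] = f"{ig_prefixes[k % 3]}{k + 1}-{k % 7 + 1}"
    blood_genes = {genes[i] for i in blood_idx}
    plasma_genes = set(genes)

    lengths = rng.integers(100, 3001, n_plasma)
    lam = np.exp(rng.normal(2.0, 1.0, n_plasma))
    counts = 1 + rng.poisson(lam)
    table = pd.DataFrame({"protein_id": [f"PL{i:04d}" for i in range(n_plasma)],
                          "gene": genes,
                          "spectral_count": counts,
                          "length": lengths})

    tissue_only = [f"TGEN{i:05d}" for i in range(n_tissue_genes)]
    tissue_transcript_genes = (plasma_genes - blood_genes) | set(tissue_only)
    tissue_protein_genes = set(
        rng.choice(sorted(tissue_transcript_genes),
                   int(0.8 * len(tissue_transcript_genes)), replace=False))

    per_sample: dict[str, set] = {}
    tissue_pool = np.array(sorted(tissue_protein_genes))
    blood_pool = np.array(sorted(blood_genes))
    for j in range(n_tissue_samples):
        base = set(rng.choice(tissue_pool, min(8000, len(tissue_pool)),
                              replace=False))
        hit = blood_pool[rng.random(len(blood_pool)) < blood_detect_prob]
        per_sample[f"MM{j + 1:03d}"] = base | set(hit)
    truth = GroundTruth(extras={"blood_genes": blood_genes,
                                "ig_fraction": ig_fraction})
    return PlasmaSim(table, plasma_genes, blood_genes, tissue_protein_genes,
                     tissue_transcript_genes, per_sample, truth)


# ---------------------------------------------------------------------------
# toy proteome embedding the driver-mutation contexts

#: authentic local sequence contexts (1-based start, context, protein length)
_TOY_CONTEXTS: dict[str, tuple[int, str, int]] = {
    "BRAF": (585, "HEDLTVKIGDFGLATVKSRWSGSHQFEQLSGSILWMAPEVIR", 766),
    "NRAS": (1, "MTEYKLVVVGAGGVGKSALTIQLIQNHFVDEYDPTIEDSYRK"
                "QVVIDGETCLLDILDTAGQEEYSAMRDQYMR", 189),
    "KRAS": (1, "MTEYKLVVVGAGGVGKSALTIQLIQNHFVDEYDPTIEDSYRK", 188),
    "KIT": (558, "KVVEEINGNNYVYIDPTQLPYDHKWEFPR", 976),
    "CDKN2A": (108, "DAWGRLPVDLAEELGHRDVAR", 156),
    "GNA11": (260, "RVLTSGNSSVILFLNKKDLL", 359),
}

_FILLER_ALPHABET = np.array(list("ACDEFGHILMNQSTVWY"))  # no K/R/P


def gen_toy_proteome(seed: int = 0
                     ) -> tuple[list[ProteinSequence], list[MutationSpec]]:
    """Six synthetic proteins embedding the driver-mutation panel contexts.

    Each protein carries the authentic wild-type sequence around its panel
    mutation site, placed at the true residue coordinates; the remainder is
    random filler free of K, R and P so it cannot interfere with tryptic
    cleavage around the contexts.  Returns (proteome, mutation panel).
    """
    from .proteogenomics import MELANOMA_DRIVER_PANEL
    rng = _rng(seed, "proteome")
    proteins = []
    for gene, (start, context, length) in _TOY_CONTEXTS.items():
        residues = _FILLER_ALPHABET[rng.integers(0, len(_FILLER_ALPHABET),
                                                 length)]
        residues = "".join(residues)
        end = start - 1 + len(context)
        if end > length:
            raise AssertionError(f"{gene}: context exceeds protein length")
        residues = residues[:start - 1] + context + residues[end:]
        proteins.append(ProteinSequence(f"TOY_{gene}", gene, residues,
                                        pe_level=1))
    return proteins, list(MELANOMA_DRIVER_PANEL)
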