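"""Synthetic expression atlases with planted, recoverable structure.

The generator emulates the statistical features of a normalized microarray
compendium that the downstream pipeline exercises: groups of co-expressed
genes (planted modules) whose log-scale profiles are noisy linear
transforms of a shared latent profile, a background of independently
varying genes, a block of near-constant "flat" genes that the variance
filters must remove, and blocks of near-duplicate samples that the
redundancy weighting must down-weight.  Term annotations enriched inside
the planted modules and random protein sequences round out the inputs so
every pipeline stage is testable without external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import RAW, ExpressionAtlas
from .proteins import STANDARD_AA, ProteinRecord

# per-gene baseline offsets (log10) so sample columns are not collinear
_BASELINE_SPREAD = 0.5
# flat genes: raw-scale additive noise, clipped so range stays below 16
_FLAT_CV = 0.02
_FLAT_CLIP = 7.0
# log10-sd of gene expression variation around its baseline
_MODULE_AMPLITUDE = 0.4
# background genes correlate pairwise at this level: strong enough to enter
# the network well below the module correlations, weak enough to sit far
# from them (see generate_atlas)
_BACKGROUND_PAIR_CORR = 0.55


@dataclass
class AtlasSpec:
    """Ground-truth parameters of a synthetic atlas.

    ``within_module_corr`` is the family-mean within-module Pearson
    correlation on the log scale; individual modules are staggered around
    it by ``corr_stagger`` (see :func:`module_corr_targets`), emulating the
    mix of tight and loose modules real compendia contain.  ``noise_sd`` is
    the log-scale sd of the per-gene noise a typical (family-mean
    tightness) gene carries; ``redundancy_groups`` lists (group size,
    log-scale perturbation sd) blocks of near-duplicate samples;
    ``expression_scale`` sets the base raw magnitude.
    """

    n_genes: int = 200
    n_samples: int = 100
    module_sizes: tuple = (30, 30, 30, 30)
    within_module_corr: float = 0.95
    noise_sd: float = 0.1
    n_flat_genes: int = 40
    redundancy_groups: tuple = ((8, 0.05), (8, 0.05), (8, 0.05))
    expression_scale: float = 1000.0
    corr_stagger: float = 0.9
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_samples <= 0:
            raise ValueError("n_genes and n_samples must be positive")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if not (0.0 <= self.within_module_corr <= 1.0):
            raise ValueError("within_module_corr must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_flat_genes < 0:
            raise ValueError("n_flat_genes must be non-negative")
        if sum(self.module_sizes) + self.n_flat_genes > self.n_genes:
            raise ValueError("module and flat gene counts exceed n_genes")
        n_redundant = sum(size for size, _ in self.redundancy_groups)
        if n_redundant > self.n_samples:
            raise ValueError("redundancy groups exceed n_samples")
        if any(size < 2 or sd < 0 for size, sd in self.redundancy_groups):
            raise ValueError("redundancy groups need size >= 2 and sd >= 0")
        if self.expression_scale <= 1:
            raise ValueError("expression_scale must exceed 1")


@dataclass
class GroundTruth:
    """Planted structure of a generated atlas.

    ``module_labels`` maps every gene to its module (0 = background,
    including flat genes); ``flat_genes`` marks the genes the variance
    filters should remove; ``sample_groups`` maps every sample to its
    redundancy group (0 = singleton).  ``planted_terms`` is filled by
    :func:`generate_annotation`.
    """

    module_labels: dict[str, int]
    sample_groups: dict[str, int]
    flat_genes: set = field(default_factory=set)
    latents: dict[int, np.ndarray] = field(default_factory=dict)
    planted_terms: dict[str, set] = field(default_factory=dict)

    def module_genes(self, module: int) -> set:
        return {g for g, m in self.module_labels.items() if m == module}


def module_corr_targets(rho: float, n_modules: int, stagger: float) -> np.ndarray:
    """Per-module correlation targets staggered around a family mean.

    Real compendia contain modules of very different tightness; staggering
    keeps their threshold transitions apart, which is what gives the
    network-density curve its characteristic interior minimum.  Module m
    gets 1 − (1 − rho)·g_m with multipliers g spread over
    [1 − stagger, 1 + stagger] and normalized to mean 1, so the family mean
    stays at ``rho``.  ``stagger=0`` makes every module equally tight.
    """
    if n_modules == 1 or stagger == 0:
        return np.clip(np.full(n_modules, rho), 0.0, 0.999)
    mult = np.linspace(1.0 + stagger, 1.0 - stagger, n_modules)
    mult /= mult.mean()
    return np.clip(1.0 - (1.0 - rho) * mult, 0.0, 0.999)


def generate_atlas(spec: AtlasSpec) -> tuple[ExpressionAtlas, GroundTruth]:
    """Generate a raw-scale atlas with planted modules and redundant samples.

    On the log scale a module gene is ``baseline + loading × (a·latent +
    ε)`` with loadings uniform in [0.5, 1.5] and the latent weight ``a``
    chosen so every within-module gene pair attains the module's target
    correlation; module targets are staggered around ``within_module_corr``
    (see :func:`module_corr_targets`).  Values are then exponentiated to
    the raw scale.  Background genes form weakly correlated pairs;  flat
    genes are built directly on the raw scale with clipped additive noise
    so that both variance filters reject them.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_mod = sum(spec.module_sizes)
    n_bg = spec.n_genes - n_mod - spec.n_flat_genes
    n_var = n_mod + n_bg
    mu = np.log10(spec.expression_scale)

    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    sample_ids = [f"S{j:03d}" for j in range(spec.n_samples)]

    rho_targets = module_corr_targets(
        spec.within_module_corr, spec.n_modules, spec.corr_stagger
    )
    if spec.noise_sd == 0:
        rho_targets = np.ones_like(rho_targets)

    log_matrix = np.zeros((n_var, spec.n_samples))
    module_labels: dict[str, int] = {}
    latents: dict[int, np.ndarray] = {}
    row = 0
    for m, (size, rho_m) in enumerate(zip(spec.module_sizes, rho_targets), start=1):
        latent = rng.standard_normal(spec.n_samples)
        latents[m] = latent
        # gene = loading × (signal·latent + noise·ε): the signal/noise split
        # realizes the module's target correlation, while the total log-sd
        # is the same for every module — noise_sd sets the noise level a
        # typical (family-mean tightness) gene carries
        if rho_m >= 1.0 or spec.noise_sd == 0:
            signal, noise_amp = _MODULE_AMPLITUDE, 0.0
        else:
            total = spec.noise_sd / np.sqrt(1.0 - spec.within_module_corr)
            signal = total * np.sqrt(rho_m)
            noise_amp = total * np.sqrt(1.0 - rho_m)
        loadings = rng.uniform(0.7, 1.5, size=size)
        for loading in loadings:
            eps = rng.standard_normal(spec.n_samples)
            log_matrix[row] = loading * (signal * latent + noise_amp * eps)
            module_labels[gene_ids[row]] = m
            row += 1
    # background genes: weakly correlated pairs (plus a lone independent
    # gene when the count is odd), variable enough to pass the filters
    rho_bg = _BACKGROUND_PAIR_CORR
    if spec.noise_sd == 0:
        total_bg = _MODULE_AMPLITUDE
    else:
        total_bg = spec.noise_sd / np.sqrt(1.0 - spec.within_module_corr)
    bg_left = n_bg
    while bg_left > 0:
        loadings = rng.uniform(0.7, 1.5, size=2)
        if bg_left >= 2:
            pair_latent = rng.standard_normal(spec.n_samples)
            for loading in loadings:
                eps = rng.standard_normal(spec.n_samples)
                log_matrix[row] = loading * total_bg * (
                    np.sqrt(rho_bg) * pair_latent + np.sqrt(1.0 - rho_bg) * eps
                )
                module_labels[gene_ids[row]] = 0
                row += 1
            bg_left -= 2
        else:
            log_matrix[row] = loadings[0] * total_bg * rng.standard_normal(spec.n_samples)
            module_labels[gene_ids[row]] = 0
            row += 1
            bg_left -= 1
    baselines = mu + rng.uniform(-_BASELINE_SPREAD, _BASELINE_SPREAD, size=n_var)
    log_matrix += baselines[:, None]

    # near-duplicate sample blocks: trailing columns, each group a copy of
    # its first column plus log-scale perturbation
    sample_groups = {s: 0 for s in sample_ids}
    col = spec.n_samples
    for gi, (size, perturb_sd) in enumerate(spec.redundancy_groups, start=1):
        block = range(col - size, col)
        seed_col = log_matrix[:, block[0]].copy()
        for j in block:
            sample_groups[sample_ids[j]] = gi
            if j != block[0]:
                log_matrix[:, j] = seed_col + rng.standard_normal(n_var) * perturb_sd
                for m in latents:  # keep the recorded latent state consistent
                    latents[m][j] = latents[m][block[0]]
        col -= size

    raw = 10.0 ** log_matrix

    flat_rows = []
    flat_genes = set()
    baseline = spec.expression_scale * 0.1
    for i in range(spec.n_flat_genes):
        noise = rng.standard_normal(spec.n_samples) * baseline * _FLAT_CV
        np.clip(noise, -_FLAT_CLIP, _FLAT_CLIP, out=noise)
        flat_rows.append(baseline + noise)
        gid = gene_ids[n_var + i]
        flat_genes.add(gid)
        module_labels[gid] = 0
    values = np.vstack([raw] + ([np.vstack(flat_rows)] if flat_rows else []))

    data = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    atlas = ExpressionAtlas(data=data, scale_state=RAW)
    truth = GroundTruth(
        module_labels=module_labels,
        sample_groups=sample_groups,
        flat_genes=flat_genes,
        latents=latents,
    )
    return atlas, truth


def generate_annotation(
    truth: GroundTruth,
    n_terms: int,
    enrichment_frac: float = 0.9,
    seed: int = 0,
    background_scatter: float = 0.0,
) -> dict[str, set]:
    """Plant one enriched term per module plus random filler terms.

    Term ``T001``..``T00M`` covers ``enrichment_frac`` of module 1..M's
    genes plus, with probability ``background_scatter``, each non-module
    gene.  The remaining ``n_terms - M`` terms are assigned random gene
    subsets.  Returns (and records on the truth object) a term → genes map.
    """
    modules = sorted({m for m in truth.module_labels.values() if m > 0})
    if n_terms < len(modules):
        raise ValueError("n_terms must be at least the number of planted modules")
    if not (0.0 < enrichment_frac <= 1.0):
        raise ValueError("enrichment_frac must lie in (0, 1]")
    if not (0.0 <= background_scatter < 1.0):
        raise ValueError("background_scatter must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = sorted(truth.module_labels)
    annotation: dict[str, set] = {}
    for m in modules:
        term = f"T{m:03d}"
        members = sorted(truth.module_genes(m))
        n_pick = max(1, int(round(enrichment_frac * len(members))))
        picked = set(rng.choice(members, size=n_pick, replace=False))
        if background_scatter:
            others = [g for g in genes if truth.module_labels[g] != m]
            scatter = rng.random(len(others)) < background_scatter
            picked |= {g for g, s in zip(others, scatter) if s}
        annotation[term] = picked
    n_filler = n_terms - len(modules)
    filler_size = max(3, int(round(0.05 * len(genes))))
    for i in range(n_filler):
        term = f"T{len(modules) + i + 1:03d}"
        annotation[term] = set(rng.choice(genes, size=min(filler_size, len(genes)), replace=False))
    truth.planted_terms = {f"T{m:03d}": annotation[f"T{m:03d}"] for m in modules}
    return annotation


def generate_proteins(
    n: int, length_range: tuple[int, int] = (50, 300), seed: int = 0
) -> list[ProteinRecord]:
    """Random sequences over the 20 standard amino acids."""
    lo, hi = length_range
    if lo < 2 or hi < lo:
        raise ValueError("length_range must satisfy 2 <= min <= max")
    rng = np.random.default_rng(seed)
    alphabet = list(STANDARD_AA)
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=length))
        records.append(ProteinRecord(f"P{i:04d}", seq))
    return records


def write_ground_truth(truth: GroundTruth, prefix) -> None:
    """Write gene→module and sample→group maps as two-column TSVs."""
    pd.DataFrame(
        sorted(truth.module_labels.items()), columns=["gene", "module"]
    ).to_csv(f"{prefix}_modules.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.sample_groups.items()), columns=["sample", "group"]
    ).to_csv(f"{prefix}_sample_groups.tsv", sep="\t", index=False)
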