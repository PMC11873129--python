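"""Synthetic study generator with planted ground truth.

Emulates the three data layers the pipeline consumes, at desk scale:

* a multi-region post-mortem DNA-methylation cohort (beta matrices in (0,1)
  with planted correlated probe modules, one of which tracks a binary
  neuropsychiatric trait, plus age/sex/batch/cell-proportion/PMI covariate
  effects);
* a single-nucleus expression reference with cell-type marker structure,
  where the markers of one designated subtype overlap the trait module's
  annotated genes;
* a genotyped longitudinal cohort (LD-blocked dosages, GWAS summary
  statistics for a depression-like trait, and Geriatric Depression Scale
  trajectories) whose polygenic liability is partially localised to the
  genomic windows around the trait module's CpG sites.

Every generator is a pure function of :class:`SimConfig`; the master seed is
split into fixed sub-streams so the three layers can be generated
independently yet reproducibly. The returned :class:`PlantedTruth` records
what was planted and is the reference for recovery tests.

Beta values are produced by a logistic squash of a Gaussian factor model:
this keeps the (0,1) support of methylation fractions while making the
module structure linear on the logit scale. Realistic bimodality of real
450K arrays is deliberately not modelled.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "MethylationStudy",
    "CellReference",
    "GeneticCohort",
    "ConfigError",
    "simulate_methylation_study",
    "simulate_cell_reference",
    "simulate_genetic_cohort",
    "simulate_survival_cohort",
    "write_fixture_bundle",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_covariate_effects() -> dict[str, float]:
    return {"age": 0.10, "sex": 0.20, "batch": 0.30, "neun_prop": 0.30, "pmi": 0.05}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with the default study conditions.

    Methylation defaults emulate the substantia-nigra arm of a ~90-donor
    Parkinson's brain-bank cohort; genetics defaults emulate a de-novo PD
    cohort followed annually for eight years with a large external
    depression GWAS as the discovery set.
    """

    # methylation cohort
    n_samples: int = 88
    n_probes: int = 2000
    n_modules: int = 3
    module_sizes: tuple[int, ...] = (200, 200, 200)
    loading_sd: float = 1.0
    noise_sd: float = 0.5
    trait_module_r: float = 0.5
    trait_prevalence: float = 0.40
    covariate_effects: Mapping[str, float] = field(
        default_factory=_default_covariate_effects
    )
    regions: tuple[str, ...] = ("SN", "CN", "FC")
    trait_region: str = "SN"
    # cell reference
    n_genes: int = 1200
    n_celltypes: int = 6
    n_markers_per_type: int = 80
    n_overlap_markers: int = 40
    cells_per_type: int = 150
    marker_fold: float = 5.0
    marker_fold_sd: float = 0.5
    celltype_mod_sd: float = 0.25
    module_gene_pool_size: int = 200
    # genetics (desk-scale panel: discovery n keeps per-variant power of a
    # large GWAS roughly proportionate to the reduced variant count)
    n_variants: int = 2000
    ld_block_len: int = 20
    ld_rho: float = 0.8
    variant_spacing: int = 50_000
    n_causal: int = 30
    causal_in_window_frac: float = 0.5
    h2_liability: float = 0.3
    n_discovery: int = 20_000
    n_target: int = 500
    # longitudinal phenotype
    n_visits: int = 9
    visit_interval_months: int = 12
    seed: int = 0

    #: genomic centres (chr1) of the trait module's CpG clusters
    CPG_CLUSTER_CENTERS: tuple[int, ...] = (8_000_000, 25_000_000, 40_000_000)
    CPG_CLUSTER_HALFWIDTH: int = 100_000
    WINDOW_FLANK: int = 1_000_000

    def validate(self) -> None:
        if len(self.module_sizes) != self.n_modules:
            raise ConfigError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_probes:
            raise ConfigError("sum(module_sizes) exceeds n_probes")
        if not -1 < self.trait_module_r < 1:
            raise ConfigError("trait_module_r must be in (-1, 1)")
        if not 0 < self.trait_prevalence < 1:
            raise ConfigError("trait_prevalence must be in (0, 1)")
        if self.loading_sd < 0 or self.noise_sd < 0:
            raise ConfigError("loading_sd and noise_sd must be non-negative")
        if self.marker_fold < 1:
            raise ConfigError("marker_fold must be >= 1")
        if self.n_celltypes < 2:
            raise ConfigError("n_celltypes must be >= 2")
        if self.n_celltypes * self.n_markers_per_type > self.n_genes:
            raise ConfigError("marker sets exceed n_genes")
        if self.n_overlap_markers > self.n_markers_per_type:
            raise ConfigError("n_overlap_markers exceeds n_markers_per_type")
        if self.n_variants < self.ld_block_len:
            raise ConfigError("n_variants must be >= ld_block_len")
        if not 0 <= self.causal_in_window_frac <= 1:
            raise ConfigError("causal_in_window_frac must be in [0, 1]")
        if not 0 <= self.h2_liability <= 1:
            raise ConfigError("h2_liability must be in [0, 1]")
        if self.trait_region not in self.regions:
            raise ConfigError("trait_region must be one of regions")

    def rng(self, stream: int) -> np.random.Generator:
        """Sub-stream generator: one master seed, fixed offsets per layer."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class PlantedTruth:
    """Ground truth of the planted structure (the recovery-test surface)."""

    probe_module_truth: dict[str, str] = field(default_factory=dict)
    trait_module_id: str = ""
    trait_region: str = ""
    module_gene_pool: list[str] = field(default_factory=list)
    enriched_celltype: str = ""
    celltype_markers: dict[str, list[str]] = field(default_factory=dict)
    causal_variants: list[str] = field(default_factory=list)
    causal_in_window: dict[str, bool] = field(default_factory=dict)
    windows: list[tuple[str, int, int]] = field(default_factory=list)
    methylation_liability: dict[str, float] = field(default_factory=dict)
    genetic_liability: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        d["windows"] = [tuple(w) for w in d.get("windows", [])]
        return cls(**d)


@dataclass
class MethylationStudy:
    betas: dict[str, pd.DataFrame]  # region -> probes x samples
    meta: pd.DataFrame  # one row per (sample, region)
    traits: pd.DataFrame  # one row per sample
    annotation: pd.DataFrame  # probe, chr, pos, genes
    truth: PlantedTruth


@dataclass
class CellReference:
    counts: pd.DataFrame  # genes x cells, integer counts
    cells: pd.DataFrame  # cell, cell_class, subtype
    truth: PlantedTruth


@dataclass
class GeneticCohort:
    sumstats: pd.DataFrame  # SNP CHR BP A1 A2 BETA SE P INFO
    dosages: pd.DataFrame  # samples x variants
    pheno: pd.DataFrame  # sample, visit_month, GDS, UPDRS3, age, sex
    truth: PlantedTruth


# ---------------------------------------------------------------------------
# methylation cohort
# ---------------------------------------------------------------------------

def _biserial_adjusted_r(r: float, prevalence: float) -> float:
    """Latent correlation needed so the binary-trait Spearman targets ``r``.

    Dichotomising a liability at threshold c attenuates a latent correlation
    by phi(c)/sqrt(p(1-p)); divide it out so the observable correlation with
    the binary trait converges to the requested value.
    """
    c = norm.ppf(1 - prevalence)
    k = norm.pdf(c) / np.sqrt(prevalence * (1 - prevalence))
    return float(np.clip(r / k, -0.999, 0.999))


def _sample_metadata(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_samples
    samples = [f"S{i + 1:03d}" for i in range(n)]
    age = rng.normal(78.25, 6.17, n).round(1)
    sex = rng.choice(["F", "M"], n)
    years = np.clip(rng.normal(12.63, 8.28, n), 1.0, None).round(1)
    braak_lb = np.clip(np.round(rng.normal(5.54, 0.81, n)), 0, 6).astype(int)
    braak_nft = np.clip(np.round(rng.normal(1.91, 0.72, n)), 0, 6).astype(int)
    rows = []
    for region in config.regions:
        batch = rng.choice(["B1", "B2"], n)
        neun = np.clip(rng.beta(10, 15, n), 0.01, 0.99)
        pmi = np.clip(rng.normal(48, 12, n), 4, None).round(1)
        rows.append(
            pd.DataFrame(
                {
                    "sample": samples,
                    "region": region,
                    "age": age,
                    "sex": sex,
                    "batch": batch,
                    "neun_prop": neun.round(4),
                    "pmi": pmi,
                    "braak_lb": braak_lb,
                    "braak_nft": braak_nft,
                    "years_disease": years,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _gene_names(config: SimConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(config.n_genes)]


def _module_gene_pool(config: SimConfig) -> list[str]:
    """Gene pool of the trait module: a subset of the designated subtype's
    markers plus non-marker filler genes. Markers of other subtypes (and
    the designated subtype's remaining markers) stay out of the pool, so
    exactly one cell type is planted as enriched while its specificity tail
    also contains non-target genes."""
    genes = _gene_names(config)
    n_over = config.n_overlap_markers
    non_marker_start = config.n_celltypes * config.n_markers_per_type
    filler = genes[
        non_marker_start : non_marker_start + config.module_gene_pool_size - n_over
    ]
    return genes[:n_over] + filler


def _probe_annotation(
    config: SimConfig,
    probes: list[str],
    module_of: dict[str, str],
    trait_module: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    genes = _gene_names(config)
    pool = _module_gene_pool(config)
    other = [g for g in genes if g not in set(pool)]
    centers = config.CPG_CLUSTER_CENTERS
    half = config.CPG_CLUSTER_HALFWIDTH
    chrs, poss, gene_col = [], [], []
    for p in probes:
        if module_of[p] == trait_module:
            c = centers[rng.integers(len(centers))]
            chrs.append("chr1")
            poss.append(int(c + rng.integers(-half, half + 1)))
            source = pool if rng.random() < 0.85 else other
        else:
            chrs.append(f"chr{rng.integers(2, 23)}")
            poss.append(int(rng.integers(1_000_000, 130_000_000)))
            source = other
        k = 1 + (rng.random() < 0.3) + (rng.random() < 0.1)
        gene_col.append(";".join(rng.choice(source, size=k, replace=False)))
    return pd.DataFrame({"probe": probes, "chr": chrs, "pos": poss, "genes": gene_col})


def simulate_methylation_study(config: SimConfig) -> MethylationStudy:
    """Generate the multi-region methylation cohort with planted modules.

    Per module a standard-normal latent factor is drawn over samples in each
    region; member probes are a logistic squash of intercept + loading *
    latent + covariate terms + Gaussian noise. Exactly one module's latent
    (in ``trait_region``) is correlated with the binary trait's liability so
    that the observable eigengene-trait Spearman correlation targets
    ``trait_module_r``. Noise probes carry covariate and noise terms only.
    """
    config.validate()
    rng = config.rng(1)
    n = config.n_samples

    meta = _sample_metadata(config, rng)
    samples = meta.loc[meta["region"] == config.regions[0], "sample"].tolist()

    probes = [f"cg{i:06d}" for i in range(config.n_probes)]
    order = rng.permutation(config.n_probes)
    module_labels = [f"M{m + 1}" for m in range(config.n_modules)]
    module_of = {p: "noise" for p in probes}
    start = 0
    for label, size in zip(module_labels, config.module_sizes):
        for idx in order[start : start + size]:
            module_of[probes[idx]] = label
        start += size
    trait_module = module_labels[0] if module_labels else ""

    # per-probe parameters, shared across regions
    intercept = rng.normal(0.0, 1.25, config.n_probes)
    # mostly-positive loadings keep the sign-oriented eigengene aligned with
    # the latent factor; the minority of negative loadings is what makes the
    # unsigned network choice matter
    loading = config.loading_sd * rng.choice(
        [-1.0, 1.0], config.n_probes, p=[0.3, 0.7]
    )
    cov_names = list(config.covariate_effects)
    cov_coef = {
        c: config.covariate_effects[c] * rng.normal(size=config.n_probes)
        for c in cov_names
    }

    # trait liability tied to the trait module's latent in the trait region
    latents = {
        r: rng.normal(size=(config.n_modules, n)) for r in config.regions
    }
    a = _biserial_adjusted_r(config.trait_module_r, config.trait_prevalence)
    l_trait = latents[config.trait_region][0] if config.n_modules else np.zeros(n)
    liability = a * l_trait + np.sqrt(1 - a**2) * rng.normal(size=n)
    cut = norm.ppf(1 - config.trait_prevalence)
    depression = (liability > cut).astype(int)

    module_index = np.array(
        [module_labels.index(module_of[p]) if module_of[p] != "noise" else -1 for p in probes]
    )

    betas: dict[str, pd.DataFrame] = {}
    for region in config.regions:
        sub = meta[meta["region"] == region]
        cov_std = {
            "age": _standardize(sub["age"].to_numpy(float)),
            "sex": (sub["sex"].to_numpy() == "M").astype(float),
            "batch": (sub["batch"].to_numpy() == "B2").astype(float),
            "neun_prop": _standardize(sub["neun_prop"].to_numpy(float)),
            "pmi": _standardize(sub["pmi"].to_numpy(float)),
        }
        x = intercept[:, None] + config.noise_sd * rng.normal(
            size=(config.n_probes, n)
        )
        in_module = module_index >= 0
        x[in_module] += (
            loading[in_module, None]
            * latents[region][module_index[in_module], :]
        )
        for c in cov_names:
            if c in cov_std:
                x += cov_coef[c][:, None] * cov_std[c][None, :]
        betas[region] = pd.DataFrame(
            expit(x), index=probes, columns=samples
        )

    rng_tr = config.rng(11)
    traits = pd.DataFrame({"sample": samples})
    traits["depression"] = depression
    for name, prev in [
        ("dementia", 0.50),
        ("hallucinations", 0.40),
        ("anxiety", 0.35),
        ("aggression", 0.25),
        ("sleep_disorder", 0.45),
    ]:
        traits[name] = (rng_tr.random(n) < prev).astype(int)
    premorbid = np.zeros(n, int)
    dep_idx = np.flatnonzero(depression == 1)
    premorbid[dep_idx] = (rng_tr.random(dep_idx.size) < 0.3).astype(int)
    traits["premorbid_depression"] = premorbid
    traits["years_disease"] = meta.loc[
        meta["region"] == config.regions[0], "years_disease"
    ].to_numpy()

    annotation = _probe_annotation(config, probes, module_of, trait_module, rng)

    truth = PlantedTruth(
        probe_module_truth=module_of,
        trait_module_id=trait_module,
        trait_region=config.trait_region,
        module_gene_pool=_module_gene_pool(config),
        methylation_liability=dict(zip(samples, np.round(liability, 6))),
    )
    return MethylationStudy(betas, meta, traits, annotation, truth)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


# ---------------------------------------------------------------------------
# single-nucleus expression reference
# ---------------------------------------------------------------------------

_BROAD_CLASSES = ("Excitatory", "Inhibitory", "Dopaminergic")


def simulate_cell_reference(config: SimConfig) -> CellReference:
    """Negative-binomial single-nucleus counts with disjoint marker sets.

    Each subtype's markers have mean expression multiplied by
    ``marker_fold`` in that subtype. Subtype 0 (an excitatory population)
    is the planted enriched type: its markers sit inside the trait module's
    gene pool. Two annotation granularities (broad class, subtype) are
    emitted.
    """
    config.validate()
    rng = config.rng(2)
    genes = _gene_names(config)
    n_mark = config.n_markers_per_type

    subtypes = []
    for i in range(config.n_celltypes):
        cls = _BROAD_CLASSES[i % len(_BROAD_CLASSES)]
        subtypes.append((f"{cls[:2]}_T{i}", cls))

    base_mean = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    # mild type-specific modulation of every gene (real nuclei show weak DE
    # almost everywhere); markers get a heterogeneous marker_fold on top
    type_mod = rng.lognormal(
        mean=0.0, sigma=config.celltype_mod_sd, size=(config.n_celltypes, config.n_genes)
    )
    marker_folds = rng.lognormal(
        mean=np.log(config.marker_fold),
        sigma=config.marker_fold_sd,
        size=(config.n_celltypes, n_mark),
    )
    cells, classes, subs = [], [], []
    blocks = []
    for i, (sub, cls) in enumerate(subtypes):
        mu = base_mean * type_mod[i]
        mu[i * n_mark : (i + 1) * n_mark] *= marker_folds[i]
        theta = 2.0
        p = theta / (theta + mu)
        counts = rng.negative_binomial(
            theta, p[:, None], size=(config.n_genes, config.cells_per_type)
        )
        blocks.append(counts)
        for j in range(config.cells_per_type):
            cells.append(f"{sub}_c{j:03d}")
            classes.append(cls)
            subs.append(sub)

    counts = pd.DataFrame(np.hstack(blocks), index=genes, columns=cells)
    ann = pd.DataFrame({"cell": cells, "cell_class": classes, "subtype": subs})
    truth = PlantedTruth(
        enriched_celltype=subtypes[0][0],
        celltype_markers={
            sub: genes[i * n_mark : (i + 1) * n_mark]
            for i, (sub, _) in enumerate(subtypes)
        },
        module_gene_pool=_module_gene_pool(config),
    )
    return CellReference(counts, ann, truth)


# ---------------------------------------------------------------------------
# genetic cohort
# ---------------------------------------------------------------------------

_UNAMBIGUOUS_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                      ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def _canonical_windows(config: SimConfig) -> list[tuple[str, int, int]]:
    """±1 Mb windows around the trait module's CpG clusters (merged)."""
    flank = config.WINDOW_FLANK + config.CPG_CLUSTER_HALFWIDTH
    wins = sorted(
        (max(0, c - flank), c + flank) for c in config.CPG_CLUSTER_CENTERS
    )
    merged: list[list[int]] = []
    for s, e in wins:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [("chr1", s, e) for s, e in merged]


def simulate_genetic_cohort(config: SimConfig) -> GeneticCohort:
    """LD-blocked genotypes, GWAS summary statistics and GDS trajectories.

    Haplotypes are thresholded Gaussian AR(1) processes within fixed-length
    blocks (independent across blocks), so adjacent-variant correlation
    decays geometrically. A fraction ``causal_in_window_frac`` of causal
    variants lies within ±1 Mb of the trait module's CpG clusters.
    Summary statistics are direct + LD-tagged effects plus sampling noise at
    the discovery sample size. The target cohort's liability is the
    standardised genetic score scaled to ``h2_liability`` plus environment;
    GDS-like scores (integers 0-15) are a monotone binning of a latent
    AR(1) trajectory rising with liability and time.
    """
    config.validate()
    rng = config.rng(3)
    V, n = config.n_variants, config.n_target
    bp = (np.arange(V) + 1) * config.variant_spacing
    variants = [f"rs{i + 1:06d}" for i in range(V)]
    freq = rng.uniform(0.1, 0.5, V)

    # haplotypes: latent Gaussian AR(1) per block, thresholded at the
    # allele-frequency quantile
    L = config.ld_block_len
    rho = config.ld_rho if L > 1 else 0.0
    z = np.empty((2 * n, V))
    for start in range(0, V, L):
        end = min(start + L, V)
        blk = np.empty((2 * n, end - start))
        blk[:, 0] = rng.normal(size=2 * n)
        for j in range(1, end - start):
            blk[:, j] = rho * blk[:, j - 1] + np.sqrt(1 - rho**2) * rng.normal(
                size=2 * n
            )
        z[:, start:end] = blk
    hap = (z < norm.ppf(freq)[None, :]).astype(np.int8)
    dos = (hap[0::2] + hap[1::2]).astype(float)  # n x V in {0,1,2}

    # causal architecture split inside/outside the module windows
    windows = _canonical_windows(config)
    centers = np.array(config.CPG_CLUSTER_CENTERS)
    dist = np.min(np.abs(bp[:, None] - centers[None, :]), axis=1)
    in_win_strict = dist <= 0.9 * config.WINDOW_FLANK  # safely inside
    out_strict = dist > 1.2 * config.WINDOW_FLANK  # safely outside
    n_in = int(round(config.causal_in_window_frac * config.n_causal))
    n_out = config.n_causal - n_in
    in_candidates = np.flatnonzero(in_win_strict)
    out_candidates = np.flatnonzero(out_strict)
    if n_in > in_candidates.size:
        raise ConfigError(
            f"{n_in} in-window causal variants requested but only "
            f"{in_candidates.size} variants fall inside the module windows "
            "(panel too small for causal_in_window_frac)"
        )
    if n_out > out_candidates.size:
        raise ConfigError("not enough variants outside the module windows")
    cin = rng.choice(in_candidates, n_in, replace=False)
    cout = rng.choice(out_candidates, n_out, replace=False)
    causal = np.sort(np.concatenate([cin, cout]))

    sd_v = dos.std(axis=0)
    sd_v[sd_v == 0] = 1.0
    zs = (dos - dos.mean(axis=0)) / sd_v
    u = np.zeros(V)
    u[causal] = rng.normal(size=causal.size)
    g_raw = zs @ u
    sd_g = g_raw.std() if g_raw.std() > 0 else 1.0
    g = g_raw / sd_g
    h2 = config.h2_liability
    liability = np.sqrt(h2) * g + np.sqrt(1 - h2) * rng.normal(size=n)

    # summary stats: marginal standardized effects = blockwise LD * direct
    b_std = np.sqrt(h2) * u / sd_g
    marg = np.zeros(V)
    for start in range(0, V, L):
        end = min(start + L, V)
        zb = zs[:, start:end]
        R = np.corrcoef(zb, rowvar=False)
        R = np.atleast_2d(R)
        marg[start:end] = R @ b_std[start:end]
    se_std = 1.0 / np.sqrt(config.n_discovery)
    bhat_std = marg + rng.normal(0, se_std, V)
    zstat = bhat_std / se_std
    pvals = np.clip(2 * norm.sf(np.abs(zstat)), 1e-300, 1.0)
    info = rng.uniform(0.85, 1.0, V)
    info[causal] = np.maximum(info[causal], 0.95)

    pair_idx = rng.integers(0, len(_UNAMBIGUOUS_PAIRS), V)
    a1 = np.array([_UNAMBIGUOUS_PAIRS[i][0] for i in pair_idx], dtype=object)
    a2 = np.array([_UNAMBIGUOUS_PAIRS[i][1] for i in pair_idx], dtype=object)
    ambiguous = (rng.random(V) < 0.08) & ~np.isin(np.arange(V), causal)
    amb_idx = rng.integers(0, len(_AMBIGUOUS_PAIRS), V)
    a1[ambiguous] = [_AMBIGUOUS_PAIRS[i][0] for i in amb_idx[ambiguous]]
    a2[ambiguous] = [_AMBIGUOUS_PAIRS[i][1] for i in amb_idx[ambiguous]]

    sumstats = pd.DataFrame(
        {
            "SNP": variants,
            "CHR": 1,
            "BP": bp,
            "A1": a1,
            "A2": a2,
            "BETA": bhat_std / sd_v,
            "SE": se_std / sd_v,
            "P": pvals,
            "INFO": info.round(4),
        }
    )

    target_samples = [f"T{i + 1:04d}" for i in range(n)]
    dosages = pd.DataFrame(dos, index=target_samples, columns=variants)

    # longitudinal GDS: latent AR(1) trajectory rising with liability & time
    months = np.arange(config.n_visits) * config.visit_interval_months
    t_years = months / 12.0
    phi, innov_sd = 0.6, 0.8 * np.sqrt(1 - 0.6**2)
    base = 0.8 * liability
    eps = np.empty((n, config.n_visits))
    eps[:, 0] = rng.normal(0, 0.8, n)
    for j in range(1, config.n_visits):
        eps[:, j] = phi * eps[:, j - 1] + rng.normal(0, innov_sd, n)
    y = base[:, None] + 0.12 * t_years[None, :] + eps
    gds = np.clip(np.round(1.5 + 1.8 * y), 0, 15).astype(int)

    age0 = rng.normal(61.0, 9.7, n).round(1)
    sex = rng.choice(["F", "M"], n)
    updrs = np.clip(
        20 + 1.5 * t_years[None, :] + 0.5 * liability[:, None]
        + rng.normal(0, 5, (n, config.n_visits)),
        0,
        80,
    ).round(1)
    rows = []
    for i, s in enumerate(target_samples):
        for j, m in enumerate(months):
            rows.append(
                (s, int(m), int(gds[i, j]), float(updrs[i, j]),
                 float(age0[i] + m / 12.0), sex[i])
            )
    pheno = pd.DataFrame(
        rows, columns=["sample", "visit_month", "GDS", "UPDRS3", "age", "sex"]
    )

    truth = PlantedTruth(
        causal_variants=[variants[i] for i in causal],
        causal_in_window={variants[i]: bool(in_win_strict[i]) for i in causal},
        windows=windows,
        genetic_liability=dict(zip(target_samples, np.round(liability, 6))),
    )
    return GeneticCohort(sumstats, dosages, pheno, truth)


def simulate_survival_cohort(
    n: int,
    log_hr: float,
    baseline_rate: float = 0.0055,
    censor_time: float = 96.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival data with a known log hazard ratio per SD.

    Returns counting-process rows (sample, start, stop, event, z) for
    calibration checks of the Cox fitter; ``z`` is a standard-normal
    covariate with true coefficient ``log_hr``.
    """
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    z = (z - z.mean()) / z.std()
    rate = baseline_rate * np.exp(log_hr * z)
    t = rng.exponential(1.0 / rate)
    event = t <= censor_time
    stop = np.minimum(t, censor_time)
    return pd.DataFrame(
        {
            "sample": [f"X{i:04d}" for i in range(n)],
            "start": 0.0,
            "stop": stop,
            "event": event.astype(int),
            "z": z,
        }
    )


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def write_fixture_bundle(config: SimConfig, outdir: str | Path) -> dict:
    """Write the full synthetic study to ``outdir`` in interchange formats.

    Returns a manifest (also written as ``manifest.json``) listing every
    file with its SHA-256 checksum, the seed, and the truth file. The same
    config reproduces byte-identical files.
    """
    from scipy.io import mmwrite

    outdir = Path(outdir)
    if not outdir.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {outdir}")
    config.validate()

    meth = simulate_methylation_study(config)
    cells = simulate_cell_reference(config)
    gen = simulate_genetic_cohort(config)

    files: dict[str, Path] = {}

    def _tsv(name: str, df: pd.DataFrame, **kw) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", float_format="%.6g", **kw)
        files[name] = path

    for region, beta in meth.betas.items():
        _tsv(f"beta_{region}.tsv", beta, index_label="probe")
    _tsv("sample_meta.tsv", meth.meta, index=False)
    _tsv("traits.tsv", meth.traits, index=False)
    _tsv("probe_annotation.tsv", meth.annotation, index=False)

    from scipy import sparse

    mtx_path = outdir / "expression.mtx"
    mmwrite(mtx_path, sparse.csr_matrix(cells.counts.to_numpy()))
    files["expression.mtx"] = mtx_path
    _tsv("expression_genes.tsv", pd.DataFrame({"gene": cells.counts.index}), index=False)
    _tsv("cell_annotation.tsv", cells.cells, index=False)

    ss_path = outdir / "sumstats.txt"
    gen.sumstats.to_csv(ss_path, sep=" ", index=False, float_format="%.6g")
    files["sumstats.txt"] = ss_path
    _tsv("dosages.tsv", gen.dosages, index_label="sample")
    _tsv("longitudinal_pheno.tsv", gen.pheno, index=False)

    truth = PlantedTruth(
        probe_module_truth=meth.truth.probe_module_truth,
        trait_module_id=meth.truth.trait_module_id,
        trait_region=meth.truth.trait_region,
        module_gene_pool=meth.truth.module_gene_pool,
        enriched_celltype=cells.truth.enriched_celltype,
        celltype_markers=cells.truth.celltype_markers,
        causal_variants=gen.truth.causal_variants,
        causal_in_window=gen.truth.causal_in_window,
        windows=gen.truth.windows,
        methylation_liability=meth.truth.methylation_liability,
        genetic_liability=gen.truth.genetic_liability,
    )
    truth_path = outdir / "truth.json"
    truth_path.write_text(truth.to_json())
    files["truth.json"] = truth_path

    manifest = {
        "seed": config.seed,
        "truth_file": "truth.json",
        "files": {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in sorted(files.items())
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
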