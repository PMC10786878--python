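"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is deterministic given its config seed; per-component
substreams are derived from a single top-level seed with
:func:`derive_seeds`, so partial reruns reproduce exactly.

The IP-MS generator emulates label-based quantification at MS1 scale:
log2 intensities are Normal(base_g, noise_sd/sqrt(2)) around protein
baselines base_g ~ Normal(25, 2), so one replicate's bait-minus-control
log2FC has SD ``noise_sd``; true interactors and the bait gain
``effect_size`` log2 units in bait samples; missingness is intensity-dependent (logistic in
the underlying log2 intensity, i.e. missing-not-at-random left censoring)
calibrated by bisection to hit the requested overall rate. The genotype
generator builds haplotypes from latent AR(1) Gaussians thresholded at the
allele-frequency quantile — cheap, controllable LD, not a coalescent model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    GeneAnnotation,
    GwasSummary,
    QuantTable,
    ReferencePanel,
    ValidationError,
    canonical_edge,
)
from .network import PPINetwork

logger = logging.getLogger(__name__)

BASELINE_MEAN = 25.0  # typical MS1 log2 intensity
BASELINE_SD = 2.0


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation configurations."""


def derive_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent substream seeds (< 2^31) from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# IP-MS quantification tables
# ---------------------------------------------------------------------------

@dataclass
class IpmsSimConfig:
    """Study conditions for one simulated IP-MS experiment."""

    n_proteins: int = 5000
    n_true_interactors: int = 50
    n_bait_reps: int = 2
    n_ctrl_reps: int = 2
    effect_size: float = 2.0      # mean log2 enrichment of true interactors
    noise_sd: float = 0.5         # SD of a replicate's log2FC measurement (log2 units)
    missing_rate: float = 0.1     # target overall missing fraction
    mnar_steepness: float = 3.0   # logistic slope per log2 unit (sharp left censoring)
    background_sd: float = 0.0    # SD of per-protein bait-vs-control background shifts
    n_contaminants: int = 10
    n_low_peptide: int = 10
    seed: int = 0
    bait: str = "BAIT1"
    dataset: str = "sim1"
    cell_type: str = "EC"
    ip_method: str = "endogenous"
    facility: str = "sim"

    def __post_init__(self) -> None:
        counts = (self.n_proteins, self.n_true_interactors, self.n_bait_reps,
                  self.n_ctrl_reps, self.n_contaminants, self.n_low_peptide)
        if any(c < 0 for c in counts):
            raise ConfigurationError("counts must be non-negative")
        if self.n_true_interactors + self.n_contaminants + self.n_low_peptide > self.n_proteins:
            raise ConfigurationError(
                "n_true_interactors + n_contaminants + n_low_peptide exceeds n_proteins")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if self.n_bait_reps < 1 or self.n_ctrl_reps < 1:
            raise ConfigurationError("need at least one bait and one control replicate")


def _calibrate_missing_threshold(v: np.ndarray, steepness: float,
                                 rate: float) -> float:
    """Bisection for the logistic midpoint v0 such that the mean missingness
    probability over all cells equals ``rate``."""
    def mean_rate(v0: float) -> float:
        return float(np.mean(stats.logistic.cdf(-steepness * (v - v0))))

    lo, hi = v.min() - 60.0, v.max() + 60.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_rate(mid) < rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_ipms_dataset(
    config: IpmsSimConfig,
    gene_symbols: Sequence[str] | None = None,
    spiked_genes: Sequence[str] | None = None,
) -> tuple[QuantTable, pd.DataFrame]:
    """Simulate one bait-vs-control IP-MS quantification table.

    Returns the raw-scale (unlogged) table with missing entries plus a truth
    table marking each row's role (bait / interactor / contaminant /
    low_peptide / background). True interactors and the bait have expected
    log2(bait/control) equal to ``effect_size``; everything else 0.

    ``gene_symbols`` optionally supplies the background gene namespace
    (e.g. from a simulated gene annotation); defaults to GENE00001-style
    symbols. ``spiked_genes`` optionally pins the identity of the true
    interactors (they must be clean background rows); by default they are
    drawn at random. The bait row is appended beyond ``n_proteins``.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_struct, rng_noise, rng_miss = (np.random.default_rng(s) for s in ss.spawn(3))

    n = cfg.n_proteins
    if gene_symbols is None:
        symbols = [f"GENE{i + 1:05d}" for i in range(n)]
    else:
        if len(gene_symbols) < n:
            raise ConfigurationError("gene_symbols shorter than n_proteins")
        symbols = list(gene_symbols[:n])
    symbols = np.array(symbols, dtype=object)

    # roles: contaminants and low-peptide rows occupy the tail indices so the
    # spiked interactors are drawn from clean background rows
    idx = np.arange(n)
    cont_idx = idx[n - cfg.n_contaminants:] if cfg.n_contaminants else idx[:0]
    low_idx = idx[n - cfg.n_contaminants - cfg.n_low_peptide: n - cfg.n_contaminants]
    clean = idx[: n - cfg.n_contaminants - cfg.n_low_peptide]
    if spiked_genes is None:
        spiked = np.sort(rng_struct.choice(clean, size=cfg.n_true_interactors, replace=False))
    else:
        if len(spiked_genes) != cfg.n_true_interactors:
            raise ConfigurationError("spiked_genes length must equal n_true_interactors")
        pos = {s: i for i, s in enumerate(symbols)}
        try:
            spiked = np.sort([pos[g] for g in spiked_genes])
        except KeyError as exc:
            raise ConfigurationError(f"spiked gene {exc.args[0]!r} not in namespace") from None
        if np.any(spiked >= len(clean)):
            raise ConfigurationError("spiked genes must map to clean background rows")
        rng_struct.choice(clean, size=cfg.n_true_interactors, replace=False)  # keep stream aligned

    symbols[cont_idx] = [f"KRT{i + 1}" for i in range(len(cont_idx))]
    protein_ids = np.array([f"P{i + 1:06d}" for i in range(n)], dtype=object)
    peptides = np.full(n, 0, dtype=int)
    peptides[:] = rng_struct.integers(2, 30, size=n)
    peptides[low_idx] = 1

    # append the bait row
    protein_ids = np.append(protein_ids, "PBAIT00")
    symbols = np.append(symbols, cfg.bait)
    peptides = np.append(peptides, int(rng_struct.integers(5, 30)))
    n_rows = n + 1
    bait_row = n
    enriched = np.zeros(n_rows, dtype=bool)
    enriched[spiked] = True
    enriched[bait_row] = True

    Rb, Rc = cfg.n_bait_reps, cfg.n_ctrl_reps
    sample_names = ([f"bait_rep{r + 1}" for r in range(Rb)]
                    + [f"ctrl_rep{r + 1}" for r in range(Rc)])
    is_bait_col = np.array([True] * Rb + [False] * Rc)

    base = rng_struct.normal(BASELINE_MEAN, BASELINE_SD, size=n_rows)
    # optional zero-mean per-protein background binding shift: emulates the
    # heterogeneous non-specific binding of real bait-vs-control IPs, which
    # is what drives replicate log2FC correlation in real data
    bg = (rng_struct.normal(0.0, cfg.background_sd, size=n_rows)
          if cfg.background_sd > 0 else np.zeros(n_rows))
    # noise_sd is the SD of one replicate's log2FC (bait minus control), so
    # each intensity cell carries noise_sd/sqrt(2)
    cell_sd = cfg.noise_sd / math.sqrt(2.0)
    v = (base[:, None]
         + (cfg.effect_size * enriched + bg)[:, None] * is_bait_col[None, :]
         + rng_noise.normal(0.0, cell_sd, size=(n_rows, Rb + Rc)))

    raw = np.exp2(v)
    if cfg.missing_rate > 0:
        v0 = _calibrate_missing_threshold(v, cfg.mnar_steepness, cfg.missing_rate)
        pmiss = stats.logistic.cdf(-cfg.mnar_steepness * (v - v0))
        miss = rng_miss.random(v.shape) < pmiss
        raw[miss] = np.nan
        realized = miss.mean()
        if abs(realized - cfg.missing_rate) > 0.05:
            logger.warning("realized missing rate %.3f far from target %.3f",
                           realized, cfg.missing_rate)

    intensities = pd.DataFrame(raw, index=pd.Index(protein_ids, name="protein_id"),
                               columns=sample_names)
    proteins = pd.DataFrame({
        "gene_symbol": symbols,
        "unique_peptides": peptides,
        "species_flag": "human",
    }, index=intensities.index)
    samples = pd.DataFrame({
        "role": ["bait"] * Rb + ["control"] * Rc,
        "replicate": list(range(1, Rb + 1)) + list(range(1, Rc + 1)),
        "dataset": cfg.dataset,
        "cell_type": cfg.cell_type,
        "ip_method": cfg.ip_method,
        "facility": cfg.facility,
    }, index=pd.Index(sample_names, name="sample"))
    table = QuantTable(intensities, proteins, samples)

    role = np.full(n_rows, "background", dtype=object)
    role[spiked] = "interactor"
    role[cont_idx] = "contaminant"
    role[low_idx] = "low_peptide"
    role[bait_row] = "bait"
    truth = pd.DataFrame({
        "protein_id": protein_ids,
        "gene_symbol": symbols,
        "role": role,
        "is_true_interactor": role == "interactor",
    })
    return table, truth


# ---------------------------------------------------------------------------
# Reference genotype panels
# ---------------------------------------------------------------------------

@dataclass
class PanelSimConfig:
    """Conditions for the latent-AR(1) genotype panel."""

    n_samples: int = 500
    n_snps: int = 1000
    rho: float = 0.8              # adjacent-SNP latent correlation
    maf_range: tuple[float, float] = (0.05, 0.5)
    chrom: str = "1"
    bp_spacing: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rho < 1):
            raise ConfigurationError("rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf bounds must be ordered and within (0, 0.5]")
        if self.n_samples < 2:
            raise ConfigurationError("need at least 2 samples")
        if self.n_snps < 1:
            raise ConfigurationError("need at least 1 SNP")


def simulate_reference_panel(config: PanelSimConfig) -> ReferencePanel:
    """Diploid dosage panel from two independent latent-AR(1) haplotypes.

    Latent haplotype Gaussians satisfy corr(x_i, x_j) = rho^|i-j|; the
    allele at SNP j is carried when the latent value falls below the
    Phi^-1(maf_j) threshold, so the allele frequency equals maf_j.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_maf, rng_lat = (np.random.default_rng(s) for s in ss.spawn(2))
    m = cfg.n_snps
    maf = rng_maf.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    thresh = stats.norm.ppf(maf)

    n_hap = 2 * cfg.n_samples
    eps = rng_lat.standard_normal((n_hap, m))
    x = np.empty_like(eps)
    x[:, 0] = eps[:, 0]
    c = math.sqrt(1.0 - cfg.rho**2)
    for j in range(1, m):
        x[:, j] = cfg.rho * x[:, j - 1] + c * eps[:, j]
    alleles = (x < thresh).astype(np.int8)
    dosage = alleles[: cfg.n_samples] + alleles[cfg.n_samples:]

    snp_ids = [f"rs{cfg.chrom}_{j + 1}" for j in range(m)]
    positions = [(j + 1) * cfg.bp_spacing for j in range(m)]
    dosages = pd.DataFrame(dosage.astype(float), columns=snp_ids,
                           index=pd.Index([f"S{i + 1:04d}" for i in range(cfg.n_samples)],
                                          name="sample"))
    variants = pd.DataFrame({"snp": snp_ids, "chrom": cfg.chrom, "pos": positions})
    return ReferencePanel(dosages, variants)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_gwas_summary(
    panel: ReferencePanel,
    causal_gene_ids: Iterable[str],
    gene_annotation: GeneAnnotation,
    effect_size: float,
    seed: int = 0,
) -> GwasSummary:
    """Per-SNP z-scores ~ MVN(mean, R) with R the panel SNP correlation.

    The mean is 0 (null) except for SNPs inside causal gene bodies, which
    are lifted by ``effect_size``. Near-singular R is stabilized by flooring
    its eigenvalues at 1e-8 before sampling. Two-sided p-values attached.
    """
    causal = set(causal_gene_ids)
    ann = gene_annotation.table
    missing = causal - set(ann["gene"])
    if missing:
        raise ValidationError(f"causal genes absent from annotation: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    variants = panel.variants
    z = np.empty(len(variants))
    mean = np.zeros(len(variants))
    if causal and effect_size:
        sub = ann[ann["gene"].isin(causal)]
        for row in sub.itertuples(index=False):
            inside = ((variants["chrom"].astype(str) == str(row.chrom))
                      & (variants["pos"] >= row.start) & (variants["pos"] <= row.end))
            mean[inside.to_numpy()] = effect_size
    for chrom, grp in variants.groupby("chrom", sort=False):
        cols = list(grp["snp"])
        ii = grp.index.to_numpy()
        X = panel.dosages[cols].to_numpy(dtype=float)
        if len(cols) == 1:
            z[ii] = mean[ii] + rng.standard_normal(1)
            continue
        with np.errstate(invalid="ignore"):
            R = np.corrcoef(X, rowvar=False)
        R = np.atleast_2d(np.nan_to_num(R, nan=0.0))
        np.fill_diagonal(R, 1.0)
        w, V = np.linalg.eigh((R + R.T) / 2.0)
        w = np.maximum(w, 1e-8)
        A = V * np.sqrt(w)
        z[ii] = mean[ii] + A @ rng.standard_normal(len(cols))
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    table = variants.assign(p=p, z=z)
    return GwasSummary(table)


# ---------------------------------------------------------------------------
# Gene annotation and gene-set collections
# ---------------------------------------------------------------------------

def simulate_gene_annotation_and_sets(
    n_genes: int,
    n_sets: int,
    set_size_range: tuple[int, int] = (20, 50),
    enrichment_spec: Mapping[str, tuple[Sequence[str], int]] | None = None,
    seed: int = 0,
    n_chromosomes: int = 2,
) -> tuple[GeneAnnotation, dict[str, set[str]]]:
    """Non-overlapping gene intervals on synthetic chromosomes plus a
    GMT-style collection.

    Gene sets are uniform random samples except the sets named in
    ``enrichment_spec``: for set name S mapped to ``(designated_genes, x0)``,
    exactly ``x0`` members come from the designated list (e.g. a spiked
    interactor list) and the rest from outside it, so the generated overlap
    is x0 by construction.
    """
    lo, hi = set_size_range
    if hi > n_genes:
        raise ConfigurationError("set sizes must not exceed n_genes")
    ss = np.random.SeedSequence(seed)
    rng_ann, rng_sets = (np.random.default_rng(s) for s in ss.spawn(2))

    genes = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    per_chrom = math.ceil(n_genes / n_chromosomes)
    rows = []
    g = 0
    for c in range(1, n_chromosomes + 1):
        pos = 1
        for _ in range(per_chrom):
            if g >= n_genes:
                break
            length = int(rng_ann.integers(5_000, 50_000))
            gap = int(rng_ann.integers(10_000, 100_000))
            start = pos + gap
            rows.append({"gene": genes[g], "chrom": str(c), "start": start,
                         "end": start + length - 1,
                         "strand": "+" if rng_ann.random() < 0.5 else "-",
                         "biotype": "protein_coding"})
            pos = start + length
            g += 1
    annotation = GeneAnnotation(pd.DataFrame(rows))

    spec = dict(enrichment_spec or {})
    gene_arr = np.array(genes, dtype=object)
    sets: dict[str, set[str]] = {}
    for s in range(n_sets):
        name = f"SET{s + 1:03d}"
        size = int(rng_sets.integers(lo, hi + 1))
        if name in spec:
            designated, x0 = spec[name]
            designated = list(dict.fromkeys(designated))
            if x0 > size or x0 > len(designated):
                raise ConfigurationError(
                    f"set {name}: requested overlap {x0} exceeds set size or designated list")
            outside = [g for g in genes if g not in set(designated)]
            if size - x0 > len(outside):
                raise ConfigurationError(f"set {name}: not enough genes outside the list")
            members = (list(rng_sets.choice(np.array(designated, dtype=object),
                                            size=x0, replace=False))
                       + list(rng_sets.choice(np.array(outside, dtype=object),
                                              size=size - x0, replace=False)))
        else:
            members = list(rng_sets.choice(gene_arr, size=size, replace=False))
        sets[name] = set(members)
    unknown = set(spec) - set(sets)
    if unknown:
        raise ConfigurationError(f"enrichment_spec names unknown sets: {sorted(unknown)}")
    return annotation, sets


# ---------------------------------------------------------------------------
# Reference interaction edge lists
# ---------------------------------------------------------------------------

def simulate_reference_interactions(
    gene_ids: Sequence[str],
    n_edges: int,
    overlap_with_network: int = 0,
    seed: int = 0,
    network: PPINetwork | None = None,
) -> set[tuple[str, str]]:
    """Random undirected unique edges over ``gene_ids`` with exactly
    ``overlap_with_network`` edges shared with ``network``."""
    genes = list(dict.fromkeys(gene_ids))
    n_possible = len(genes) * (len(genes) - 1) // 2
    if n_edges > n_possible:
        raise ConfigurationError("n_edges exceeds the number of possible pairs")
    rng = np.random.default_rng(seed)
    edges: set[tuple[str, str]] = set()
    net_edges: set[tuple[str, str]] = set()
    if overlap_with_network:
        if network is None:
            raise ConfigurationError("overlap requested but no network supplied")
        net_edges = network.edge_pairs
        if overlap_with_network > len(net_edges):
            raise ConfigurationError("requested overlap exceeds network edge count")
        chosen = rng.choice(len(net_edges), size=overlap_with_network, replace=False)
        ordered = sorted(net_edges)
        edges |= {ordered[i] for i in chosen}
    elif network is not None:
        net_edges = network.edge_pairs
    guard = 0
    while len(edges) < n_edges:
        a, b = rng.choice(len(genes), size=2, replace=False)
        e = canonical_edge(genes[a], genes[b])
        if e in net_edges:
            continue  # keep the network overlap exactly as requested
        edges.add(e)
        guard += 1
        if guard > 100 * n_edges + 1000:
            raise ConfigurationError("could not place the requested number of edges")
    return edges
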