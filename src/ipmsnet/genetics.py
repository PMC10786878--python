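"""Genetic-risk enrichment and locus-gene prioritization.

Gene-based association uses the SNP-wise mean model: for a gene with m
assigned SNPs, the statistic is the mean of the SNP chi-square values,

    T = (1/m) * sum_j z_j^2,      z_j^2 = upper-tail chi2(1) quantile of p_j.

Under the null (z ~ MVN(0, R), R the SNP correlation matrix in a reference
panel), m*T is distributed as sum_i lambda_i * chi2_1 with lambda the
eigenvalues of R. The tail probability is computed by numerical inversion
of the characteristic function (Imhof's method), falling back to a
Satterthwaite scaled-chi-square approximation when integration does not
converge.

The competitive gene-set test regresses gene Z-scores (probit of 1 - p) on
set membership plus gene-length and SNP-count covariates over a chosen
background (rest of the genome for global tests, non-interactor genes for
conditional tests), reporting a one-tailed p for positive enrichment.
Analytically the test ignores gene-gene correlation of Z-scores; a
permutation mode re-draws membership labels within the background to form
an empirical null for the membership coefficient.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneAnnotation, GwasSummary, ReferencePanel, ValidationError
from .network import PPINetwork

logger = logging.getLogger(__name__)

#: MHC region excluded from gene-based analysis (closed interval, GRCh37).
MHC_REGION = ("6", 28_500_000, 33_400_000)

#: Smallest eigenvalue retained in SNP correlation matrices.
EIGEN_FLOOR = 1e-8

P_CLAMP_LO = 1e-300
P_CLAMP_HI = 1.0 - 1e-16


def _norm_chrom(c: str) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


# ---------------------------------------------------------------------------
# SNP-to-gene annotation
# ---------------------------------------------------------------------------

def annotate_genes_to_snps(
    annotation: GeneAnnotation,
    gwas: GwasSummary,
    window: int = 50_000,
    mhc: tuple[str, int, int] | None = MHC_REGION,
) -> dict[str, list[str]]:
    """Assign each SNP to every gene whose +/- ``window`` flank contains it.

    SNPs inside the MHC interval (closed, both endpoints included) are
    excluded globally before assignment. A SNP may belong to several genes.
    """
    snps = gwas.table.copy()
    snps["chrom"] = snps["chrom"].map(_norm_chrom)
    if mhc is not None:
        mchrom, mstart, mend = _norm_chrom(mhc[0]), mhc[1], mhc[2]
        in_mhc = ((snps["chrom"] == mchrom)
                  & (snps["pos"] >= mstart) & (snps["pos"] <= mend))
        if in_mhc.any():
            logger.info("excluding %d SNPs in the MHC region", int(in_mhc.sum()))
        snps = snps[~in_mhc]
    out: dict[str, list[str]] = {}
    by_chrom = {c: g.sort_values("pos") for c, g in snps.groupby("chrom")}
    for row in annotation.table.itertuples(index=False):
        chrom = _norm_chrom(row.chrom)
        if chrom not in by_chrom:
            continue
        g = by_chrom[chrom]
        lo, hi = row.start - window, row.end + window
        sel = g[(g["pos"] >= lo) & (g["pos"] <= hi)]
        if len(sel):
            out[row.gene] = list(sel["snp"])
    if not out:
        raise ValidationError("no SNPs annotated to any gene")
    return out


# ---------------------------------------------------------------------------
# LD arithmetic
# ---------------------------------------------------------------------------

def compute_r2(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete
    over missing entries."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("dosage vectors differ in length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValidationError("need >=2 paired samples")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValidationError("constant dosage vector; r2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class Locus:
    """An LD-defined genomic interval around a GWAS index variant."""

    index_snp: str
    chrom: str
    start: int
    end: int
    index_pos: int
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError("locus start > end")
        if not (self.start <= self.index_pos <= self.end):
            raise ValidationError("index variant outside its locus")


def ld_clump_locus(index_variant: str, panel: ReferencePanel,
                   r2_min: float = 0.6, pad: int = 50_000) -> Locus:
    """LD locus of an index variant: all same-chromosome panel SNPs with
    r^2 > ``r2_min`` to it, padded by ``pad`` bp on either end (floored at
    1). The index variant is always a member."""
    var = panel.variants.set_index("snp")
    if index_variant not in var.index:
        raise ValidationError(f"index variant {index_variant!r} not in panel")
    idx_dose = panel.dosage(index_variant)
    if np.nanstd(idx_dose) == 0:
        raise ValidationError(f"index variant {index_variant!r} is monomorphic")
    chrom = var.loc[index_variant, "chrom"]
    same = var[var["chrom"] == chrom]
    members = [index_variant]
    for snp in same.index:
        if snp == index_variant:
            continue
        other = panel.dosage(snp)
        try:
            if compute_r2(idx_dose, other) > r2_min:
                members.append(snp)
        except ValidationError:
            continue  # monomorphic partner carries no LD information
    positions = var.loc[members, "pos"].astype(int)
    return Locus(
        index_snp=index_variant,
        chrom=str(chrom),
        start=max(1, int(positions.min()) - pad),
        end=int(positions.max()) + pad,
        index_pos=int(var.loc[index_variant, "pos"]),
        members=sorted(members, key=lambda s: int(var.loc[s, "pos"])),
    )


# ---------------------------------------------------------------------------
# Gene-based association (SNP-wise mean model)
# ---------------------------------------------------------------------------

def _imhof_integrand(u: np.ndarray, q: float, lam: np.ndarray) -> np.ndarray:
    lu = lam[:, None] * u
    theta = 0.5 * np.sum(np.arctan(lu), axis=0) - 0.5 * q * u
    log_rho = 0.25 * np.sum(np.log1p(lu * lu), axis=0)
    return np.sin(theta) / (u * np.exp(log_rho))


def _imhof_tail(q: float, lam: np.ndarray) -> float | None:
    """P(sum_i lam_i * chi2_1 > q) by Imhof's characteristic-function
    inversion, integrated with composite Simpson on an adaptive cutoff.

    The integrand envelope decays like u^-(m/2 + 1), so the cutoff U is
    grown until the crude tail bound E(U) * U is negligible; the step is
    tied to the oscillation period 4*pi/q. Returns None when no acceptable
    cutoff/step is found (caller falls back to Satterthwaite).
    """
    m = lam.size
    half_q = max(q, 1e-3) / 2.0

    def envelope(u: float) -> float:
        return float(np.exp(-(np.log(u) + 0.25 * np.sum(np.log1p((lam * u) ** 2)))))

    # truncation point: after adding the first-order oscillatory tail term,
    # the residual is O(envelope * (1 + m/2) / (U * half_q^2))
    U = 1.0 / max(lam.min(), 1e-6)
    for _ in range(80):
        if envelope(U) * (1.0 + m / 2.0) / (U * half_q**2) < 1e-11:
            break
        U *= 1.5
    else:
        return None
    period = 2.0 * np.pi / half_q
    n = int(min(500_000, max(20_000, 24 * U / period)))
    n += n % 2  # Simpson needs an even interval count
    h = U / n
    u = np.linspace(h, U, n)
    f = _imhof_integrand(u, q, lam)
    w = np.ones(n)
    w[0:-1:2] = 4.0  # nodes h, 3h, ... (odd Simpson positions after the origin)
    w[1:-1:2] = 2.0
    w[-1] = 1.0
    # integrand -> (sum lam - q)/2 as u -> 0: finite limit at the origin
    f0 = 0.5 * (lam.sum() - q)
    val = (h / 3.0) * (f0 + np.dot(w, f))
    # first-order tail of the truncated oscillatory integral (by parts,
    # using theta'(u) ~ -q/2 for large u)
    theta_U = 0.5 * np.sum(np.arctan(lam * U)) - half_q * U
    val -= envelope(U) * np.cos(theta_U) / half_q
    if not np.isfinite(val):
        return None
    p = 0.5 + val / np.pi
    if p < -1e-6 or p > 1 + 1e-6:
        return None
    return float(min(max(p, 0.0), 1.0))


def _satterthwaite_tail(q: float, lam: np.ndarray) -> float:
    """Scaled chi-square moment match: scale = sum(l^2)/sum(l),
    df = (sum l)^2 / sum(l^2)."""
    s1, s2 = lam.sum(), np.square(lam).sum()
    scale = s2 / s1
    df = s1 * s1 / s2
    return float(stats.chi2.sf(q / scale, df))


def quadform_tail(q: float, eigenvalues: np.ndarray) -> float:
    """Upper-tail probability of a weighted sum of chi2_1 variables."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < 0):
        warnings.warn("negative eigenvalues floored at 0")
        lam = np.maximum(lam, 0.0)
    lam = lam[lam > EIGEN_FLOOR]
    if lam.size == 0:
        raise ValidationError("all eigenvalues zero; degenerate null")
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], 1))
    p = _imhof_tail(q, lam)
    if p is None or p <= 0.0:
        p = _satterthwaite_tail(q, lam)
    return p


def gene_based_test(snp_pvalues, R: np.ndarray | None = None) -> float:
    """Gene p-value under the SNP-wise mean model.

    ``snp_pvalues`` are the per-SNP two-sided GWAS p-values for the m SNPs
    assigned to the gene; ``R`` is the m x m dosage correlation matrix from
    the reference panel (identity when omitted). With m = 1 the gene p
    equals the SNP p exactly.
    """
    p = np.asarray(snp_pvalues, dtype=float)
    m = p.size
    if m == 0:
        raise ValidationError("gene has no SNPs")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("SNP p-values must lie in (0, 1]")
    if m == 1:
        return float(p[0])
    z2 = stats.chi2.isf(p, df=1)
    q = float(z2.sum())  # = m * T
    if R is None:
        lam = np.ones(m)
    else:
        R = np.asarray(R, dtype=float)
        if R.shape != (m, m):
            raise ValidationError("R shape does not match the SNP count")
        lam = np.linalg.eigvalsh((R + R.T) / 2.0)
    return quadform_tail(q, lam)


def panel_correlation(panel: ReferencePanel, snps: list[str]) -> np.ndarray:
    """Dosage correlation matrix for ``snps``; monomorphic variants get zero
    correlation to everything (unit diagonal kept)."""
    X = panel.dosages[snps].to_numpy(dtype=float)
    sd = np.nanstd(X, axis=0)
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    R[np.isnan(R)] = 0.0
    np.fill_diagonal(R, 1.0)
    if np.any(sd == 0):
        logger.debug("monomorphic SNPs in correlation block: %d", int((sd == 0).sum()))
    return R


def gene_analysis(
    gwas: GwasSummary,
    panel: ReferencePanel,
    annotation: GeneAnnotation,
    window: int = 50_000,
    mhc: tuple[str, int, int] | None = MHC_REGION,
) -> pd.DataFrame:
    """Gene-based p-values and covariates for every annotated gene.

    Returns a DataFrame indexed by gene with columns ``chrom``, ``start``,
    ``end``, ``n_snps``, ``p``, ``z`` (probit of 1 - p, clamped to stay
    finite), ``length``, ``log_length``, ``log_n_snps``.
    """
    coding = annotation.protein_coding()
    gene_snps = annotate_genes_to_snps(coding, gwas, window=window, mhc=mhc)
    plook = gwas.table.set_index("snp")["p"]
    panel_snps = set(panel.variants["snp"])
    rows = []
    for row in coding.table.itertuples(index=False):
        snps = gene_snps.get(row.gene)
        if not snps:
            continue
        usable = [s for s in snps if s in panel_snps]
        if not usable:
            continue
        pvals = plook.loc[usable].to_numpy(dtype=float)
        R = panel_correlation(panel, usable) if len(usable) > 1 else None
        gp = gene_based_test(pvals, R)
        gp_cl = min(max(gp, P_CLAMP_LO), P_CLAMP_HI)
        length = row.end - row.start + 1
        rows.append({
            "gene": row.gene, "chrom": _norm_chrom(row.chrom),
            "start": row.start, "end": row.end,
            "n_snps": len(usable), "p": gp,
            "z": float(stats.norm.isf(gp_cl)),
            "length": length,
            "log_length": math.log(length),
            "log_n_snps": math.log(len(usable)),
        })
    if not rows:
        raise ValidationError("no genes could be tested")
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# Competitive gene-set test
# ---------------------------------------------------------------------------

def competitive_geneset_test(
    gene_results: pd.DataFrame,
    member_genes,
    background=None,
    covariates: tuple[str, ...] = ("log_length", "log_n_snps"),
    permutations: int = 0,
    seed: int | None = None,
) -> dict:
    """One-tailed competitive test for positive enrichment of association.

    Regresses gene Z on a membership indicator plus covariates over the
    background genes (the whole ``gene_results`` table when ``background``
    is None, i.e. "rest of the genome"; pass interactors | non-interactors
    for the conditional test). ``permutations > 0`` adds an empirical
    one-tailed p from re-drawn membership labels within the background.
    """
    members = set(member_genes)
    if background is None:
        frame = gene_results
    else:
        bg = set(background) | members
        frame = gene_results.loc[gene_results.index.intersection(bg)]
    member_mask = frame.index.isin(members)
    n_mem = int(member_mask.sum())
    n_non = int(len(frame) - n_mem)
    if n_mem < 2 or n_non < 2:
        raise ValidationError(
            f"need >=2 member and >=2 non-member genes in background "
            f"(got {n_mem} and {n_non})")

    y = frame["z"].to_numpy(dtype=float)
    cols = [member_mask.astype(float)]
    names = ["membership"]
    for cov in covariates:
        v = frame[cov].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            warnings.warn(f"covariate {cov!r} constant over background; dropped")
            continue
        cols.append(v)
        names.append(cov)
    X = np.column_stack([np.ones(len(frame)), *cols])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(frame) - X.shape[1]
    if dof <= 0:
        raise ValidationError("not enough genes for the covariate model")
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = math.sqrt(sigma2 * XtX_inv[1, 1])
    b = float(beta[1])
    # degenerate fit (e.g. constant response): no evidence either way
    scale = max(1.0, float(np.abs(y).max()) ** 2)
    if se <= 1e-12 * scale and abs(b) <= 1e-8 * scale:
        b, tstat = 0.0, 0.0
    else:
        tstat = b / se if se > 0 else math.copysign(math.inf, b)
    p_one = float(stats.t.sf(tstat, dof))
    out = {
        "beta": b, "se": se, "t": tstat, "p": p_one,
        "n_members": n_mem, "n_background": int(len(frame)),
        "df": dof, "covariates": names[1:],
        "notes": "analytic one-tailed p; gene-gene Z correlation ignored",
    }
    if permutations:
        rng = np.random.default_rng(seed)
        null_beta = np.empty(permutations)
        base_cols = X[:, 2:]  # intercept handled separately
        for i in range(permutations):
            perm = rng.permutation(member_mask).astype(float)
            Xp = np.column_stack([np.ones(len(frame)), perm, base_cols])
            bp, *_ = np.linalg.lstsq(Xp, y, rcond=None)
            null_beta[i] = bp[1]
        out["p_permutation"] = float((1 + np.sum(null_beta >= b)) / (1 + permutations))
    return out


# ---------------------------------------------------------------------------
# Locus-gene prioritization
# ---------------------------------------------------------------------------

def genes_in_locus(locus: Locus, annotation: GeneAnnotation) -> list[str]:
    """Protein-coding genes whose interval overlaps the locus (1-based
    inclusive on both sides)."""
    t = annotation.protein_coding().table
    chrom = t["chrom"].map(_norm_chrom)
    sel = t[(chrom == _norm_chrom(locus.chrom))
            & (t["start"] <= locus.end) & (t["end"] >= locus.start)]
    return sorted(sel["gene"])


def prioritize_locus_genes(
    loci: list[Locus],
    annotation: GeneAnnotation,
    networks: dict[str, PPINetwork],
) -> tuple[pd.DataFrame, dict]:
    """Intersect locus genes with index genes and interactors.

    Per locus and gene: flags ``is_index`` and ``is_interactor``, with the
    linking baits and the network (cell-type) labels. Overlapping loci are
    kept separate (one row per locus-gene pair); the summary deduplicates to
    unique prioritized genes overall and per network.
    """
    rows = []
    for locus in loci:
        genes = genes_in_locus(locus, annotation)
        for gene in genes:
            nets, baits = [], set()
            is_index = False
            for name, net in networks.items():
                if gene in net.index_proteins:
                    is_index = True
                    nets.append(name)
                if gene in net.interactors:
                    nets.append(name)
                    link = net.edges.loc[net.edges["prey"] == gene, "bait"]
                    baits |= set(link)
            rows.append({
                "locus": locus.index_snp, "chrom": locus.chrom,
                "locus_start": locus.start, "locus_end": locus.end,
                "gene": gene,
                "is_index": is_index,
                "is_interactor": bool(baits),
                "linking_baits": ",".join(sorted(baits)),
                "networks": ",".join(sorted(set(nets))),
            })
    table = pd.DataFrame(rows, columns=[
        "locus", "chrom", "locus_start", "locus_end", "gene",
        "is_index", "is_interactor", "linking_baits", "networks"])
    if len(table):
        prioritized = table[table["is_index"] | table["is_interactor"]]
        uniq = set(prioritized["gene"])
    else:
        uniq = set()
    per_network: dict[str, int] = {}
    for name, net in networks.items():
        per_network[name] = len({g for g in uniq
                                 if g in net.interactors or g in net.index_proteins})
    summary = {"n_unique_prioritized": len(uniq),
               "prioritized_genes": sorted(uniq),
               "per_network": per_network}
    return table, summary


def social_manhattan_table(
    prioritized: pd.DataFrame,
    gwas: GwasSummary,
    networks: dict[str, PPINetwork],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for a social Manhattan plot.

    Nodes: one row per prioritized gene with its chromosomal position, the
    -log10 GWAS p of its tagging index SNP, and its role. Genes whose
    tagging SNP has no GWAS record are excluded with a warning. Edges:
    index-interactor links among plotted genes, a subset of the network
    edge set.
    """
    plook = gwas.table.set_index("snp")["p"]
    sel = prioritized[prioritized["is_index"] | prioritized["is_interactor"]]
    nodes = []
    seen = set()
    for row in sel.itertuples(index=False):
        if row.gene in seen:
            continue
        if row.locus not in plook.index:
            warnings.warn(f"gene {row.gene}: tagging SNP {row.locus} absent from GWAS; excluded")
            continue
        seen.add(row.gene)
        nodes.append({
            "gene": row.gene, "chrom": row.chrom,
            "pos": (row.locus_start + row.locus_end) // 2,
            "tag_snp": row.locus,
            "minus_log10_p": float(-np.log10(plook.loc[row.locus])),
            "role": "index" if row.is_index else "interactor",
        })
    node_df = pd.DataFrame(nodes, columns=["gene", "chrom", "pos", "tag_snp",
                                           "minus_log10_p", "role"])
    plotted = set(node_df["gene"]) if len(node_df) else set()
    edge_rows = []
    seen_edges = set()
    for name, net in networks.items():
        for e in net.edges.itertuples(index=False):
            if e.bait in plotted and e.prey in plotted:
                key = tuple(sorted((e.bait, e.prey)))
                if key in seen_edges:
                    continue
                seen_edges.add(key)
                known = getattr(e, "known", pd.NA)
                edge_rows.append({"gene_a": key[0], "gene_b": key[1],
                                  "network": name,
                                  "known": known})
    edge_df = pd.DataFrame(edge_rows, columns=["gene_a", "gene_b", "network", "known"])
    return node_df, edge_df


def plot_social_manhattan(nodes: pd.DataFrame, edges: pd.DataFrame, path=None):
    """Render the social Manhattan plot (genomic position vs. -log10 p with
    PPI edges drawn between points)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted(nodes["chrom"].unique(), key=str)
    offsets = {}
    acc = 0
    for c in chroms:
        offsets[c] = acc
        acc += nodes.loc[nodes["chrom"] == c, "pos"].max() + 1_000_000
    x = nodes["chrom"].map(offsets) + nodes["pos"]
    fig, ax = plt.subplots(figsize=(9, 4))
    colors = nodes["role"].map({"index": "#c0392b", "interactor": "#2c3e50"})
    coords = dict(zip(nodes["gene"], zip(x, nodes["minus_log10_p"])))
    for e in edges.itertuples(index=False):
        xa, ya = coords[e.gene_a]
        xb, yb = coords[e.gene_b]
        ax.plot([xa, xb], [ya, yb], color="0.7", lw=0.8, zorder=1)
    ax.scatter(x, nodes["minus_log10_p"], c=colors, s=25, zorder=2)
    for g, (xi, yi) in coords.items():
        ax.annotate(g, (xi, yi), fontsize=6, xytext=(2, 2),
                    textcoords="offset points")
    ax.set_xlabel("genomic position")
    ax.set_ylabel("-log10 GWAS p of tagging SNP")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
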