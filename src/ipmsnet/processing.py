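"""Raw quantification table -> per-replicate log2 fold changes.

The five processing steps, in order: (1) log2 transform and median
normalization per sample; (2) removal of non-human/uncharacterized proteins,
contaminants, unresolved isoforms and low-peptide-evidence proteins;
(3) gene-symbol mapping (see :func:`ipmsnet.io.apply_symbol_mapping`);
(4) missing-value imputation from a width-0.3, downshift-1.8 normal relative
to each sample's observed distribution; (5) paired bait-minus-control log2
fold changes per replicate.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import QuantTable, ValidationError

logger = logging.getLogger(__name__)

#: Default contaminant patterns matched (case-insensitively, full symbol)
#: against gene symbols and accessions: keratins, keratin-associated
#: proteins, trypsins.
DEFAULT_CONTAMINANT_PATTERNS = (r"KRT\d.*", r"KRTAP.*", r"TRY(P|PSIN).*", r"PRSS[12]")


@dataclass
class LogFcMatrix:
    """Per-protein log2 fold change per paired bait/control replicate.

    ``logfc`` is indexed by gene symbol (post-mapping) with one column per
    replicate index. ``provenance`` records the dataset id, normalization
    constants, imputation seed and filter attrition counts.
    """

    logfc: pd.DataFrame
    dataset: str = "dataset"
    bait: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.logfc.isna().any().any():
            raise ValidationError("log2FC matrix contains missing entries")

    @property
    def n_replicates(self) -> int:
        return self.logfc.shape[1]


def normalize_log2_median(table: QuantTable) -> QuantTable:
    """Log2-transform each sample and shift it so the observed median is 0.

    Missing cells stay missing. Centering at 0 (rather than any global
    constant) makes downstream log2FC values invariant to the target choice.
    """
    if table.log_scale:
        raise ValidationError("table is already on log2 scale")
    new = table.copy()
    vals = new.intensities.to_numpy(dtype=float, copy=True)
    vals[vals == 0] = np.nan  # zero means non-detection in MS reports
    if np.nanmin(vals, initial=np.inf) < 0:
        raise ValidationError("negative intensity present")
    logv = np.log2(vals)
    medians = np.nanmedian(logv, axis=0)
    n_obs = np.sum(~np.isnan(logv), axis=0)
    if np.any(n_obs < 2):
        bad = [s for s, n in zip(new.intensities.columns, n_obs) if n < 2]
        raise ValidationError(f"samples with <2 observed values: {bad}")
    centered = logv - medians
    new.intensities = pd.DataFrame(centered, index=new.intensities.index,
                                   columns=new.intensities.columns)
    new.log_scale = True
    new.validate()
    norm_constants = dict(zip(new.intensities.columns, medians))
    new.__dict__["normalization_constants"] = norm_constants
    return new


def _contaminant_regex(patterns) -> re.Pattern:
    return re.compile("|".join(f"(?:{p})" for p in patterns), re.IGNORECASE)


def filter_proteins(
    table: QuantTable,
    contaminant_patterns=DEFAULT_CONTAMINANT_PATTERNS,
) -> tuple[QuantTable, dict[str, list[str]]]:
    """Remove low-evidence rows; return the filtered table and a removal report.

    Rules (a row failing any rule is removed; the report lists each rule's
    hits separately, so the surviving set is order-independent):

    - ``non_human``: ``species_flag`` != "human"
    - ``uncharacterized``: ``species_flag`` == "uncharacterized" or blank symbol
    - ``contaminant``: gene symbol or accession matches a contaminant pattern
    - ``unresolved_isoform``: >=2 accessions mapped to the same gene whose
      intensity vectors are identical across all samples (all removed)
    - ``low_peptide``: supported by <2 unique peptides
    """
    prot = table.proteins
    rx = _contaminant_regex(contaminant_patterns)

    report: dict[str, list[str]] = {}
    species = prot["species_flag"].astype(str)
    report["non_human"] = list(prot.index[~species.isin(["human", "uncharacterized"])])
    report["uncharacterized"] = list(prot.index[
        (species == "uncharacterized") | (prot["gene_symbol"].astype(str) == "")
    ])
    hit = [bool(rx.fullmatch(str(sym)) or rx.fullmatch(str(acc)))
           for acc, sym in zip(prot.index, prot["gene_symbol"])]
    report["contaminant"] = list(prot.index[hit])
    report["low_peptide"] = list(prot.index[prot["unique_peptides"] < 2])

    iso: list[str] = []
    vals = table.intensities
    for _gene, grp in prot.groupby("gene_symbol"):
        if len(grp) < 2:
            continue
        rows = vals.loc[grp.index]
        arr = rows.to_numpy(dtype=float)
        # identical including the missingness pattern
        same = np.zeros(len(grp), dtype=bool)
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                a, b = arr[i], arr[j]
                eq = (a == b) | (np.isnan(a) & np.isnan(b))
                if eq.all():
                    same[i] = same[j] = True
        iso.extend(grp.index[same])
    report["unresolved_isoform"] = iso

    removed = set().union(*report.values())
    keep = [p for p in prot.index if p not in removed]
    if not keep:
        logger.warning("filter_proteins: no proteins survive filtering")
    out = QuantTable(table.intensities.loc[keep], prot.loc[keep].copy(),
                     table.samples.copy(), log_scale=table.log_scale)
    return out, report


def impute_missing(table: QuantTable, width: float = 0.3, shift: float = 1.8,
                   seed: int | None = None) -> QuantTable:
    """Impute missing cells from a downshifted normal, per sample.

    For each sample with observed mean mu and SD sigma, missing cells are
    drawn from Normal(mu - shift*sigma, (width*sigma)^2) — the standard
    left-censoring model for intensities missing because they fall below the
    detection limit. Observed values are untouched; deterministic given seed.
    """
    if not table.log_scale:
        raise ValidationError("impute_missing expects a normalized log2 table")
    rng = np.random.default_rng(seed)
    new = table.copy()
    vals = new.intensities.to_numpy(dtype=float, copy=True)
    for j, sample in enumerate(new.intensities.columns):
        col = vals[:, j]
        miss = np.isnan(col)
        if miss.all():
            raise ValidationError(f"sample {sample!r} has no observed values")
        if not miss.any():
            continue
        mu = col[~miss].mean()
        sigma = col[~miss].std(ddof=1)
        col[miss] = rng.normal(mu - shift * sigma, width * sigma, size=miss.sum())
    new.intensities = pd.DataFrame(vals, index=new.intensities.index,
                                   columns=new.intensities.columns)
    return new


def compute_replicate_logfc(table: QuantTable, dataset: str | None = None,
                            bait: str | None = None) -> LogFcMatrix:
    """Paired log2FC: bait log2 intensity minus control log2 intensity,
    matched by replicate index.

    Requires a fully imputed log2 table with equal bait and control replicate
    counts. Rows are re-indexed by gene symbol (duplicate symbols keep the
    accession suffix to stay unique).
    """
    if not table.log_scale:
        raise ValidationError("compute_replicate_logfc expects a log2 table")
    if table.intensities.isna().any().any():
        raise ValidationError("table contains missing values; impute first")
    bait_meta = table.samples[table.samples["role"] == "bait"]
    ctrl_meta = table.samples[table.samples["role"] == "control"]
    reps = sorted(bait_meta["replicate"])
    if reps != sorted(ctrl_meta["replicate"]):
        raise ValidationError("bait and control replicate indices do not pair")
    cols = {}
    for r in reps:
        b = bait_meta.index[bait_meta["replicate"] == r]
        c = ctrl_meta.index[ctrl_meta["replicate"] == r]
        if len(b) != 1 or len(c) != 1:
            raise ValidationError(f"replicate {r}: pairing is not one-to-one")
        cols[r] = (table.intensities[b[0]] - table.intensities[c[0]])
    logfc = pd.DataFrame(cols)
    # index by gene symbol, disambiguating duplicates with the accession
    syms = table.proteins["gene_symbol"].astype(str)
    counts = syms.value_counts()
    labels = [s if counts[s] == 1 else f"{s}|{acc}"
              for acc, s in zip(syms.index, syms)]
    logfc.index = pd.Index(labels, name="gene")
    if dataset is None:
        ds_vals = table.samples["dataset"].unique()
        dataset = str(ds_vals[0]) if len(ds_vals) == 1 else "combined"
    prov = {"dataset": dataset,
            "n_proteins": int(logfc.shape[0]),
            "n_replicates": int(logfc.shape[1])}
    return LogFcMatrix(logfc, dataset=dataset, bait=bait, provenance=prov)
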