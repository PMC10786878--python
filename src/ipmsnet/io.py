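"""Readers, writers and validated in-memory containers for every external format.

All tabular formats are plain delimited text (TSV unless noted). Genomic
coordinates are 1-based inclusive internally; BED-style 0-based half-open
input is converted at the boundary. Gene identity is the HGNC-style symbol
throughout; an optional accession-to-symbol mapping can be applied at load
time.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tokens treated as a missing intensity on input. MS quantification reports
#: conventionally use 0 for non-detection, so 0 also maps to missing.
MISSING_TOKENS = ("", "NA", "NaN", "nan", "N/A", "null")

VALID_ROLES = ("bait", "control")

PROTEIN_COLUMNS = ["protein_id", "gene_symbol", "unique_peptides", "species_flag"]
SAMPLE_COLUMNS = ["role", "replicate", "dataset", "cell_type", "ip_method", "facility"]


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates its contract."""


# ---------------------------------------------------------------------------
# Quantification tables
# ---------------------------------------------------------------------------

@dataclass
class QuantTable:
    """Protein x sample intensity matrix with protein evidence and sample roles.

    Parameters
    ----------
    intensities
        DataFrame indexed by ``protein_id`` with one column per sample.
        Values are non-negative intensities (raw or log2 scale, see
        ``log_scale``); missing measurements are NaN.
    proteins
        Per-protein metadata indexed by ``protein_id`` with columns
        ``gene_symbol``, ``unique_peptides``, ``species_flag``.
    samples
        Per-sample metadata indexed by sample name with columns ``role``
        (bait|control), ``replicate`` (1..R), ``dataset``, ``cell_type``,
        ``ip_method``, ``facility``.
    log_scale
        True once intensities have been log2 transformed.
    """

    intensities: pd.DataFrame
    proteins: pd.DataFrame
    samples: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.intensities.index.equals(self.proteins.index):
            raise ValidationError("intensity rows and protein metadata rows differ")
        if list(self.intensities.columns) != list(self.samples.index):
            raise ValidationError("intensity columns and sample metadata rows differ")
        if self.intensities.index.duplicated().any():
            dups = self.intensities.index[self.intensities.index.duplicated()].unique()
            raise ValidationError(f"duplicate protein ids: {', '.join(map(str, dups))}")
        bad_roles = set(self.samples["role"]) - set(VALID_ROLES)
        if bad_roles:
            raise ValidationError(f"unknown sample roles: {sorted(bad_roles)}")
        bait = self.samples[self.samples["role"] == "bait"]
        ctrl = self.samples[self.samples["role"] == "control"]
        for ds in self.samples["dataset"].unique():
            b = set(bait.loc[bait["dataset"] == ds, "replicate"])
            c = set(ctrl.loc[ctrl["dataset"] == ds, "replicate"])
            if b != c:
                raise ValidationError(
                    f"dataset {ds}: bait replicate indices {sorted(b)} do not match "
                    f"control replicate indices {sorted(c)}"
                )
        if not self.log_scale:
            vals = self.intensities.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValidationError("negative intensities on raw scale")

    # convenience views -----------------------------------------------------
    @property
    def bait_samples(self) -> list[str]:
        return list(self.samples.index[self.samples["role"] == "bait"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.samples.index[self.samples["role"] == "control"])

    @property
    def gene_symbols(self) -> pd.Series:
        return self.proteins["gene_symbol"]

    def copy(self) -> "QuantTable":
        return QuantTable(
            self.intensities.copy(), self.proteins.copy(), self.samples.copy(),
            log_scale=self.log_scale,
        )


def _coerce_missing(series: pd.Series) -> pd.Series:
    """Map blank/NA/NaN/0 to NaN and parse the rest as float."""
    s = series.replace(list(MISSING_TOKENS), np.nan)
    s = pd.to_numeric(s, errors="raise")
    return s.mask(s == 0)


def read_quant_table(
    path: str | Path,
    metadata_spec: str | Path | Mapping[str, Mapping[str, object]],
) -> QuantTable:
    """Read a protein quantification report.

    The report is a TSV with columns ``protein_id``, ``gene_symbol``,
    ``unique_peptides``, ``species_flag`` followed by one column per sample.
    ``metadata_spec`` maps each sample column to its role metadata, either as
    a nested mapping ``{sample: {role, replicate, ...}}`` or as the path of a
    TSV with a ``sample`` column plus the metadata columns.

    Blank, NA/NaN and zero intensity cells are recorded as missing.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "gene_symbol": str},
                     keep_default_na=False)
    for col in PROTEIN_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if df["protein_id"].duplicated().any():
        dups = sorted(df.loc[df["protein_id"].duplicated(), "protein_id"].unique())
        raise ValidationError(f"{path}: duplicate protein ids: {', '.join(dups)}")

    if isinstance(metadata_spec, (str, Path)):
        meta = pd.read_csv(metadata_spec, sep="\t").set_index("sample")
    else:
        meta = pd.DataFrame.from_dict(dict(metadata_spec), orient="index")
        meta.index.name = "sample"
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValidationError(f"sample metadata lacks columns: {missing_cols}")
    meta = meta[SAMPLE_COLUMNS].copy()
    meta["replicate"] = meta["replicate"].astype(int)

    sample_cols = [c for c in df.columns if c not in PROTEIN_COLUMNS]
    absent = [s for s in meta.index if s not in sample_cols]
    if absent:
        raise ValidationError(f"{path}: metadata refers to absent sample columns {absent}")
    intensities = pd.DataFrame(
        {s: _coerce_missing(df[s]) for s in meta.index}
    ).set_index(df["protein_id"].rename("protein_id"))
    proteins = df[PROTEIN_COLUMNS].set_index("protein_id")
    proteins["unique_peptides"] = proteins["unique_peptides"].astype(int)
    return QuantTable(intensities, proteins, meta)


def write_quant_table(table: QuantTable, path: str | Path,
                      samples_path: str | Path | None = None) -> None:
    """Write a quantification report plus its sample-metadata sidecar.

    The sidecar defaults to ``<path>.samples.tsv``. Missing intensities are
    written as empty cells, so write -> read is a lossless round trip.
    """
    path = Path(path)
    out = table.proteins.reset_index()
    data = table.intensities.reset_index(drop=True)
    out = pd.concat([out, data.set_index(out.index)], axis=1)
    out = out.sort_values("protein_id")
    out.to_csv(path, sep="\t", index=False, na_rep="")
    sp = Path(samples_path) if samples_path else Path(str(path) + ".samples.tsv")
    table.samples.rename_axis("sample").reset_index().to_csv(sp, sep="\t", index=False)


def apply_symbol_mapping(table: QuantTable, mapping: Mapping[str, str]) -> QuantTable:
    """Map accessions to gene symbols via ``mapping`` (accession -> symbol)."""
    new = table.copy()
    new.proteins["gene_symbol"] = [
        mapping.get(acc, sym)
        for acc, sym in zip(new.proteins.index, new.proteins["gene_symbol"])
    ]
    return new


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Gene intervals: ``gene``, ``chrom``, ``start``, ``end`` (1-based
    inclusive), ``strand``, ``biotype``. Strand is carried but ignored by all
    locus arithmetic (windows are symmetric)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        req = ["gene", "chrom", "start", "end"]
        for col in req:
            if col not in t.columns:
                raise ValidationError(f"gene annotation lacks column {col!r}")
        if "strand" not in t.columns:
            t = t.assign(strand=".")
        if "biotype" not in t.columns:
            t = t.assign(biotype="protein_coding")
        if t["gene"].duplicated().any():
            raise ValidationError("duplicate gene ids in annotation")
        if (t["start"] > t["end"]).any():
            bad = t.loc[t["start"] > t["end"], "gene"].tolist()
            raise ValidationError(f"start > end for genes: {bad}")
        self.table = t.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def protein_coding(self) -> "GeneAnnotation":
        return GeneAnnotation(self.table[self.table["biotype"] == "protein_coding"]
                              .reset_index(drop=True))


def read_gene_annotation(path: str | Path, dialect: str = "tsv") -> GeneAnnotation:
    """Read gene intervals. ``dialect='tsv'`` expects 1-based inclusive
    ``gene/chrom/start/end[/strand/biotype]`` columns; ``dialect='bed'``
    expects 0-based half-open BED columns and converts to 1-based inclusive.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    elif dialect == "bed":
        df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
        cols = ["chrom", "start", "end", "gene", "score", "strand"][: df.shape[1]]
        df.columns = cols
        df["start"] = df["start"].astype(int) + 1  # 0-based half-open -> 1-based inclusive
        df = df.drop(columns=[c for c in ("score",) if c in df.columns])
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return GeneAnnotation(df)


def write_gene_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    cols = ["gene", "chrom", "start", "end", "strand", "biotype"]
    annotation.table[cols].sort_values(["chrom", "start", "gene"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

@dataclass
class GwasSummary:
    """Per-SNP association results: ``snp``, ``chrom``, ``pos``, ``p`` in
    (0, 1], optional ``z`` and ``n``. Positions are sorted within chromosome
    after load."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("snp", "chrom", "pos", "p"):
            if col not in t.columns:
                raise ValidationError(f"GWAS summary lacks column {col!r}")
        if t["snp"].duplicated().any():
            raise ValidationError("duplicate SNP ids in GWAS summary")
        p = t["p"].to_numpy(dtype=float)
        if np.any(p <= 0) or np.any(p > 1):
            bad = t.loc[(t["p"] <= 0) | (t["p"] > 1), "snp"].tolist()[:5]
            raise ValidationError(f"p-values outside (0, 1] for SNPs {bad}")
        self.table = (t.sort_values(["chrom", "pos"], kind="mergesort")
                      .reset_index(drop=True))

    def pvalues(self, snps: Iterable[str]) -> np.ndarray:
        lookup = self.table.set_index("snp")["p"]
        return lookup.loc[list(snps)].to_numpy(dtype=float)


def read_gwas_summary(path: str | Path) -> GwasSummary:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df.columns = [c.lower() for c in df.columns]
    rename = {"chr": "chrom", "bp": "pos"}
    df = df.rename(columns=rename)
    return GwasSummary(df)


def write_gwas_summary(gwas: GwasSummary, path: str | Path) -> None:
    gwas.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reference genotype panels
# ---------------------------------------------------------------------------

@dataclass
class ReferencePanel:
    """Dosage matrix (samples x variants, entries in {0,1,2} or NaN) with a
    variant map (``snp``, ``chrom``, ``pos``)."""

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.variants["snp"]):
            raise ValidationError("dosage columns and variant map disagree")
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValidationError("dosages must be 0, 1, 2 or missing")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    def dosage(self, snp: str) -> np.ndarray:
        if snp not in self.dosages.columns:
            raise KeyError(f"variant {snp!r} not in panel")
        return self.dosages[snp].to_numpy(dtype=float)


def read_panel(path: str | Path, variants_path: str | Path) -> ReferencePanel:
    """Read a dosage TSV (first column sample id, one column per variant)
    plus a variant map TSV (``snp``, ``chrom``, ``pos``)."""
    dos = pd.read_csv(path, sep="\t", index_col=0)
    var = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str})
    return ReferencePanel(dos, var)


def write_panel(panel: ReferencePanel, path: str | Path,
                variants_path: str | Path) -> None:
    panel.dosages.rename_axis("sample").to_csv(path, sep="\t", na_rep="NA")
    panel.variants.to_csv(variants_path, sep="\t", index=False)


def read_panel_vcf(path: str | Path) -> ReferencePanel:
    """Read a VCF into a dosage panel; biallelic SNPs only, GT -> dosage.

    Non-biallelic records are skipped and the skip count logged.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    rows = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        gts = np.asarray(rec.genotypes, dtype=object)
        dose = np.array([
            np.nan if g[0] < 0 or g[1] < 0 else float(g[0] + g[1]) for g in gts
        ])
        snp = rec.ID or f"{rec.CHROM}:{rec.POS}"
        cols[snp] = dose
        rows.append((snp, str(rec.CHROM), int(rec.POS)))
    if skipped:
        logger.info("read_panel_vcf: skipped %d non-biallelic records", skipped)
    dos = pd.DataFrame(cols, index=pd.Index(samples, name="sample"))
    var = pd.DataFrame(rows, columns=["snp", "chrom", "pos"])
    return ReferencePanel(dos, var)


# ---------------------------------------------------------------------------
# Gene sets (GMT) and edge lists
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: ``name TAB description TAB member...`` per line.

    Duplicate members within a set are deduplicated with a warning; empty
    sets and malformed lines raise with the offending line number.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{i}: malformed GMT line (needs name, "
                                      f"description and >=1 member)")
            name, _desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ValidationError(f"{path}:{i}: empty gene set {name!r}")
            if len(members) != len(set(members)):
                warnings.warn(f"{path}:{i}: duplicate members in set {name!r}; deduplicated")
            if name in sets:
                raise ValidationError(f"{path}:{i}: duplicate set name {name!r}")
            sets[name] = set(members)
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            desc = (descriptions or {}).get(name, "na")
            members = sorted(set(sets[name]))
            fh.write("\t".join([name, desc, *members]) + "\n")


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Unordered gene pair as a sorted tuple; used as edge identity."""
    return (a, b) if a <= b else (b, a)


def read_edge_list(path: str | Path) -> set[tuple[str, str]]:
    """Read a two-column delimited edge list into canonical undirected edges.

    "A B" and "B A" collapse to one edge; self-loops are dropped.
    """
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[\t ]+", line)
            if len(parts) < 2:
                raise ValidationError(f"{path}:{i}: expected two columns")
            a, b = parts[0], parts[1]
            if a == b:
                continue
            edges.add(canonical_edge(a, b))
    return edges


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    canon = sorted(canonical_edge(a, b) for a, b in edges)
    with open(path, "w") as fh:
        for a, b in canon:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def write_results(tables: Mapping[str, pd.DataFrame], directory: str | Path) -> None:
    """Write named result tables as TSVs with deterministic order.

    Columns keep their declared order; rows are sorted by all columns so a
    write -> read -> write cycle is byte-stable.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        out = df.sort_values(list(df.columns), kind="mergesort").reset_index(drop=True)
        out.to_csv(directory / f"{name}.tsv", sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
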