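"""Pipeline configuration: one structured text file with full defaulting.

Every fixed analysis constant lives here — significance thresholds
(log2FC > 0, FDR <= 0.1), the replicate-correlation QC gate (> 0.6), the
imputation parameters (width 0.3 SD, downshift 1.8 SD), the LD clumping
rule (r^2 > 0.6, +/- 50 kb), the SNP-to-gene window (+/- 50 kb) and the
MHC exclusion interval (chr6:28.5-33.4 Mb) — so no stage carries hidden
constants.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised for invalid pipeline configurations, with field context."""


@dataclass
class Thresholds:
    lfc_min: float = 0.0      # strict lower bound on average log2FC
    fdr_max: float = 0.1      # inclusive BH FDR cutoff
    corr_min: float = 0.6     # strict replicate-correlation QC gate
    r2_min: float = 0.6       # strict LD r^2 bound for clumping
    window: int = 50_000      # SNP-to-gene flank, bp

    def validate(self) -> None:
        if not (0 <= self.fdr_max <= 1):
            raise ConfigError("thresholds.fdr_max must lie in [0, 1]")
        if not (-1 <= self.corr_min <= 1):
            raise ConfigError("thresholds.corr_min must lie in [-1, 1]")
        if not (0 <= self.r2_min <= 1):
            raise ConfigError("thresholds.r2_min must lie in [0, 1]")
        if self.window < 0:
            raise ConfigError("thresholds.window must be non-negative")


@dataclass
class Imputation:
    width: float = 0.3   # SD of the imputation normal, in units of sample SD
    shift: float = 1.8   # downshift of its mean, in units of sample SD

    def validate(self) -> None:
        if self.width <= 0:
            raise ConfigError("imputation.width must be positive")
        if self.shift < 0:
            raise ConfigError("imputation.shift must be non-negative")


@dataclass
class SimulationConfig:
    """Scale of the end-to-end synthetic study driven by the CLI."""

    n_genes: int = 400
    n_sets: int = 10
    set_size_range: tuple[int, int] = (20, 50)
    n_chromosomes: int = 2
    n_baits: int = 3
    cell_types: tuple[str, str] = ("EC", "SMC")
    n_designated: int = 40       # shared pool of true-interactor genes
    n_spiked: int = 30           # spiked per dataset (cell types offset within the pool)
    forced_overlap: int = 18     # designated genes forced into the boosted set
    n_proteins: int = 300
    effect_size: float = 2.0
    noise_sd: float = 0.5
    missing_rate: float = 0.1
    mnar_steepness: float = 3.0
    background_sd: float = 0.7   # heterogeneous background binding (realistic IPs)
    n_contaminants: int = 10
    n_low_peptide: int = 10
    n_replicates: int = 2
    panel_samples: int = 400
    panel_snps_per_chrom: int = 800
    panel_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    gwas_effect: float = 2.0     # mean z lift for SNPs in causal gene bodies
    n_reference_edges: int = 60

    def validate(self) -> None:
        if self.n_baits < 1 or self.n_genes <= self.n_baits:
            raise ConfigError("simulation.n_genes must exceed simulation.n_baits")
        if self.n_proteins > self.n_genes - self.n_baits:
            raise ConfigError("simulation.n_proteins exceeds the non-bait gene namespace")
        if self.n_spiked > self.n_designated:
            raise ConfigError("simulation.n_spiked exceeds n_designated")
        if self.n_designated > self.n_proteins - self.n_contaminants - self.n_low_peptide:
            raise ConfigError("designated pool does not fit the clean protein rows")


@dataclass
class PipelineConfig:
    out_dir: str = "results"
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    imputation: Imputation = field(default_factory=Imputation)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    mhc_chrom: str = "6"
    mhc_start: int = 28_500_000
    mhc_end: int = 33_400_000
    permutations: int = 0        # B for the permutation-mode competitive test
    n_index_loci: int = 10
    index_p_max: float = 1e-3    # index-variant significance at synthetic scale
    conditional: bool = True     # run conditional tests alongside global ones

    def validate(self) -> None:
        self.thresholds.validate()
        self.imputation.validate()
        self.simulation.validate()
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")
        if not (0 < self.index_p_max <= 1):
            raise ConfigError("index_p_max must lie in (0, 1]")

    @property
    def mhc(self) -> tuple[str, int, int]:
        return (self.mhc_chrom, self.mhc_start, self.mhc_end)

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return plain(asdict(self))

    def sha256(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})

        def build(dc, payload):
            if payload is None:
                return dc()
            known = {f.name for f in fields(dc)}
            bad = set(payload) - known
            if bad:
                raise ConfigError(f"{dc.__name__}: unknown fields {sorted(bad)}")
            kwargs = {}
            for f in fields(dc):
                if f.name in payload:
                    v = payload[f.name]
                    kwargs[f.name] = tuple(v) if isinstance(v, list) else v
            return dc(**kwargs)

        cfg = cls(
            **{k: v for k, v in data.items()
               if k not in ("thresholds", "imputation", "simulation")
               and k in {f.name for f in fields(cls)}},
            thresholds=build(Thresholds, data.get("thresholds")),
            imputation=build(Imputation, data.get("imputation")),
            simulation=build(SimulationConfig, data.get("simulation")),
        )
        unknown = set(data) - {f.name for f in fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
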