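"""Per-dataset interactor statistics: moderated one-sample test, FDR,
significance calls, and dataset-level quality control.

The test is a one-sample empirical-Bayes moderated t-test: each protein's
replicate log2FC variance s_g^2 is shrunk toward a prior variance s0^2 with
prior degrees of freedom d0, both estimated across all proteins by moment
matching on the log sample variances. With R replicates and residual df
d = R - 1:

    s_tilde_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)
    t_g = mean_g / (s_tilde_g / sqrt(R))      ~  t(d0 + d)

and the reference becomes standard normal when d0 is infinite (all proteins
share one variance). A protein is called an interactor when its average
log2FC exceeds 0 strictly and its Benjamini-Hochberg FDR is at most 0.1.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io import ValidationError
from .processing import LogFcMatrix

logger = logging.getLogger(__name__)

RIBOSOMAL_PREFIXES = ("RPL", "RPS")


@dataclass
class InteractorStats:
    """Moderated-test results for one IP-MS dataset.

    ``table`` is indexed by gene with columns ``logfc`` (average over
    replicates), ``s2``, ``t``, ``pvalue``, ``fdr``, ``significant``.
    """

    table: pd.DataFrame
    d0: float
    s0_2: float
    df_resid: int
    n_replicates: int
    dataset: str = "dataset"
    bait: str | None = None
    replicate_correlation: float | None = None
    qc_pass: bool | None = None

    @property
    def detected(self) -> set[str]:
        return set(self.table.index)

    @property
    def significant(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


def estimate_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Moment-matching estimate of the prior df d0 and prior variance s0^2.

    Works on e_g = ln(s_g^2) - digamma(d/2) + ln(d/2) over rows with
    positive sample variance: solves trigamma(d0/2) = max(var(e) -
    trigamma(d/2), 0) for d0 (infinite when the max is 0), then
    s0^2 = exp(mean(e) + digamma(d0/2) - ln(d0/2)).
    """
    pos = s2[s2 > 0]
    if pos.size < 2:
        raise ValidationError("too few positive-variance rows to estimate the variance prior")
    e = np.log(pos) - special.digamma(d / 2.0) + np.log(d / 2.0)
    target = np.var(e, ddof=1) - special.polygamma(1, d / 2.0)
    if target <= 0:
        return math.inf, float(np.exp(np.mean(e)))
    # trigamma is decreasing: bracket d0/2 then solve
    f = lambda x: special.polygamma(1, x) - target
    lo, hi = 1e-8, 1e8
    half_d0 = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
    d0 = 2.0 * half_d0
    s0_2 = float(np.exp(np.mean(e) + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_2


def moderated_one_sample_test(
    logfc: LogFcMatrix,
    d0_override: float | None = None,
    sided: str = "two-sided",
    lfc_min: float = 0.0,
    fdr_max: float = 0.1,
) -> InteractorStats:
    """Moderated one-sample test of mean log2FC = 0 for every protein.

    ``d0_override=0`` reproduces the classical one-sample t-test;
    ``d0_override=math.inf`` forces the common-variance z branch. P-values
    are two-sided by default; the directional log2FC > 0 gate is applied
    separately by :func:`call_interactors`.
    """
    X = logfc.logfc.to_numpy(dtype=float)
    n_prot, R = X.shape
    if R < 2:
        raise ValidationError("need >=2 replicate log2FC columns")
    if n_prot < 10:
        raise ValidationError("need >=10 proteins to estimate the variance prior")
    d = R - 1
    mean = X.mean(axis=1)
    s2 = X.var(axis=1, ddof=1)

    if d0_override is None:
        d0, s0_2 = estimate_prior(s2, d)
    elif d0_override == 0:
        d0, s0_2 = 0.0, float("nan")
    else:
        d0 = float(d0_override)
        _, s0_2 = estimate_prior(s2, d)

    if d0 == 0:
        s_tilde2 = s2.copy()
    elif math.isinf(d0):
        s_tilde2 = np.full(n_prot, s0_2)
    else:
        s_tilde2 = (d0 * s0_2 + d * s2) / (d0 + d)
    if np.any(s_tilde2 <= 0):
        raise ValidationError("zero posterior variance; cannot form the statistic")

    t = mean / np.sqrt(s_tilde2 / R)
    if math.isinf(d0):
        sf = stats.norm.sf(np.abs(t))
    else:
        sf = stats.t.sf(np.abs(t), df=d0 + d)
    if sided == "two-sided":
        p = 2.0 * sf
    elif sided == "greater":
        p = np.where(t > 0, sf, 1.0 - sf)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    p = np.clip(p, 0.0, 1.0)

    table = pd.DataFrame(
        {"logfc": mean, "s2": s2, "t": t, "pvalue": p},
        index=logfc.logfc.index,
    )
    table["fdr"] = benjamini_hochberg(table["pvalue"].to_numpy())
    table["significant"] = (table["logfc"] > lfc_min) & (table["fdr"] <= fdr_max)
    corr = replicate_correlation(logfc)
    return InteractorStats(
        table, d0=d0, s0_2=s0_2, df_resid=d, n_replicates=R,
        dataset=logfc.dataset, bait=logfc.bait, replicate_correlation=corr,
    )


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1; stable under ties
    and invariant to input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvalues must be one-dimensional")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_interactors(stats_obj: InteractorStats, lfc_min: float = 0.0,
                     fdr_max: float = 0.1) -> set[str]:
    """Significant interactors: log2FC strictly above ``lfc_min`` and FDR at
    most ``fdr_max``. The bait itself is flagged via QC, never returned as
    its own interactor."""
    t = stats_obj.table
    called = set(t.index[(t["logfc"] > lfc_min) & (t["fdr"] <= fdr_max)])
    called.discard(stats_obj.bait)
    return called


def replicate_correlation(logfc: LogFcMatrix) -> float:
    """Pearson correlation of log2FC between replicates (mean of pairwise
    correlations when there are more than two)."""
    X = logfc.logfc.to_numpy(dtype=float)
    R = X.shape[1]
    if R < 2:
        raise ValidationError("need >=2 replicates for a correlation")
    pairs = [stats.pearsonr(X[:, i], X[:, j]).statistic
             for i, j in itertools.combinations(range(R), 2)]
    return float(np.mean(pairs))


@dataclass
class QCResult:
    passed: bool
    reason: str
    correlation: float | None
    metrics: dict = field(default_factory=dict)


def qc_dataset(
    stats_obj: InteractorStats,
    corr_min: float = 0.6,
    known_interactors: set[str] | None = None,
) -> QCResult:
    """Dataset-level QC: pass iff the replicate log2FC correlation exceeds
    ``corr_min`` and the bait itself is called significant.

    Also reports QC metrics: detected/significant counts, ribosomal
    (RPL-/RPS- prefix) detected/significant counts, and — when a set of
    known bait interactors is supplied — the overlap between significant
    proteins and known interactors with a one-tailed hypergeometric p
    against the detected background.
    """
    from .enrichment import hypergeometric_test

    t = stats_obj.table
    corr = stats_obj.replicate_correlation
    bait = stats_obj.bait
    metrics: dict[str, float] = {
        "replicate_correlation": corr,
        "n_detected": int(len(t)),
        "n_significant": int(t["significant"].sum()),
    }
    upper = pd.Index(t.index.astype(str)).str.upper()
    ribo = upper.str.startswith(RIBOSOMAL_PREFIXES)
    metrics["n_ribosomal_detected"] = int(ribo.sum())
    metrics["n_ribosomal_significant"] = int((ribo & t["significant"].to_numpy()).sum())

    if known_interactors is not None:
        detected = set(t.index)
        sig = set(t.index[t["significant"]])
        known_det = known_interactors & detected
        overlap = sig & known_det
        metrics["n_known_detected"] = len(known_det)
        metrics["n_known_significant"] = len(overlap)
        if known_det and sig:
            metrics["known_overlap_p"] = hypergeometric_test(
                len(detected), len(sig), len(known_det), len(overlap))
        else:
            metrics["known_overlap_p"] = 1.0

    if bait is None or bait not in t.index:
        return QCResult(False, "bait_not_detected", corr, metrics)
    bait_sig = bool(t.loc[bait, "significant"])
    metrics["bait_logfc"] = float(t.loc[bait, "logfc"])
    metrics["bait_fdr"] = float(t.loc[bait, "fdr"])
    if corr is None or corr <= corr_min:
        return QCResult(False, "low_replicate_correlation", corr, metrics)
    if not bait_sig:
        return QCResult(False, "bait_not_significant", corr, metrics)
    return QCResult(True, "pass", corr, metrics)


def compare_datasets_overlap(stats_a: InteractorStats,
                             stats_b: InteractorStats) -> dict:
    """Interactor overlap between two IPs with a one-tailed hypergeometric p.

    The population N is all genes detected in both IPs; k and n are the
    significant interactors of each IP within N; x is their overlap.
    """
    from .enrichment import hypergeometric_test

    detected = stats_a.detected & stats_b.detected
    if not detected:
        raise ValidationError("no genes detected in both datasets")
    k_set = stats_a.significant & detected
    n_set = stats_b.significant & detected
    x_set = k_set & n_set
    N, k, n, x = len(detected), len(k_set), len(n_set), len(x_set)
    p = hypergeometric_test(N, k, n, x)
    return {
        "N": N, "k": k, "n": n, "x": x, "p": p,
        "only_a": len(k_set - n_set), "only_b": len(n_set - k_set),
        "shared": x,
    }


def compare_qc_across_conditions(metrics: pd.DataFrame,
                                 condition: str) -> pd.DataFrame:
    """Two-tailed Wilcoxon rank-sum test per QC metric between the two
    groups defined by the ``condition`` column of ``metrics``."""
    from .enrichment import wilcoxon_rank_sum

    groups = metrics[condition].unique()
    if len(groups) != 2:
        raise ValidationError(f"condition {condition!r} must define exactly 2 groups")
    g1 = metrics[metrics[condition] == groups[0]]
    g2 = metrics[metrics[condition] == groups[1]]
    rows = []
    for col in metrics.columns:
        if col == condition or not pd.api.types.is_numeric_dtype(metrics[col]):
            continue
        a = g1[col].dropna().to_numpy(dtype=float)
        b = g2[col].dropna().to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValidationError(f"metric {col!r}: empty group")
        rows.append({"metric": col, "group_a": groups[0], "group_b": groups[1],
                     "n_a": a.size, "n_b": b.size,
                     "p": wilcoxon_rank_sum(a, b)})
    return pd.DataFrame(rows)
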