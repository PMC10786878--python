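"""Overlap statistics: one-tailed hypergeometric tests with global and
conditional population constructions, Bonferroni handling, and Wilcoxon
rank-sum comparisons.

Population conventions for gene-set enrichment follow the network analyses:
in global mode the population N is every gene annotated in at least one set
of the collection; in conditional mode N is further restricted to the genes
encoded by interactors or non-interactors of the network, so that the
background reflects what the assay can detect in that cell type.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .io import ValidationError

logger = logging.getLogger(__name__)


def hypergeometric_test(N: int, k: int, n: int, x: int) -> float:
    """Upper-tail hypergeometric p: P(X >= x) with X ~ Hypergeom(N, k, n).

    p = sum_{i=x}^{min(k, n)} C(k, i) C(N-k, n-i) / C(N, n), accumulated in
    log space. The observed overlap x is included in the tail, the standard
    one-tailed enrichment convention.
    """
    for name, v in (("N", N), ("k", k), ("n", n), ("x", x)):
        if int(v) != v or v < 0:
            raise ValidationError(f"{name} must be a non-negative integer, got {v}")
    N, k, n, x = int(N), int(k), int(n), int(x)
    if k > N or n > N:
        raise ValidationError(f"k={k} and n={n} must not exceed N={N}")
    if x > min(k, n) or x < max(0, k + n - N):
        raise ValidationError(f"x={x} impossible for N={N}, k={k}, n={n}")
    if x == 0:
        return 1.0
    i = np.arange(x, min(k, n) + 1)
    log_terms = (
        gammaln(k + 1) - gammaln(i + 1) - gammaln(k - i + 1)
        + gammaln(N - k + 1) - gammaln(n - i + 1) - gammaln(N - k - n + i + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


@dataclass
class EnrichmentResult:
    set_name: str
    N: int
    k: int
    n: int
    x: int
    p: float
    p_bonferroni: float
    mode: str
    tier: str  # none | nominal | bonferroni

    def __post_init__(self) -> None:
        if self.x > min(self.k, self.n) or self.N < max(self.k, self.n):
            raise ValidationError("inconsistent enrichment counts")


def _tier(p: float, p_bonf: float, alpha: float = 0.05) -> str:
    if p_bonf < alpha:
        return "bonferroni"
    if p < alpha:
        return "nominal"
    return "none"


def geneset_enrichment(
    gene_list: Iterable[str],
    collection: Mapping[str, set[str]],
    mode: str = "global",
    universe: Iterable[str] | None = None,
    non_interactors: Iterable[str] | None = None,
) -> pd.DataFrame:
    """One-tailed hypergeometric enrichment of ``gene_list`` in each set.

    Parameters
    ----------
    gene_list
        The query genes (typically network interactors; a companion run may
        pass the non-interactors in global mode).
    collection
        Named gene sets (e.g. read from GMT).
    mode
        ``"global"``: population N = genes annotated in >=1 set of the
        collection (intersected with ``universe`` when given).
        ``"conditional"``: N further restricted to
        ``gene_list | non_interactors`` (the assay-detected background).
    universe
        Optional explicit universe to intersect with the annotated genes.
    non_interactors
        Required in conditional mode.

    The Bonferroni denominator is the number of sets actually tested.
    """
    if not collection:
        raise ValidationError("empty gene-set collection")
    query = set(gene_list)
    annotated: set[str] = set().union(*collection.values())
    population = annotated if universe is None else annotated & set(universe)
    if mode == "conditional":
        if non_interactors is None:
            raise ValidationError("conditional mode requires the non-interactor background")
        population = population & (query | set(non_interactors))
    elif mode != "global":
        raise ValueError(f"unknown mode {mode!r}")

    m = len(collection)
    rows = []
    for name in sorted(collection):
        members = collection[name]
        N_set = population
        if not N_set:
            logger.warning("set %s: empty population after restriction", name)
            continue
        k_set = query & N_set
        n_set = members & N_set
        x_set = k_set & n_set
        N, k, n, x = len(N_set), len(k_set), len(n_set), len(x_set)
        p = hypergeometric_test(N, k, n, x)
        pb = min(1.0, p * m)
        rows.append(EnrichmentResult(name, N, k, n, x, p, pb, mode, _tier(p, pb)))
    return pd.DataFrame([r.__dict__ for r in rows])


def wilcoxon_rank_sum(sample_a, sample_b, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when min(n_a, n_b) <= 8 and there are no ties;
    normal approximation with tie and continuity correction otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        warnings.warn("all values identical across both samples; p = 1")
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.pvalue)
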