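"""Target-anticorrelation statistic and triple-test enrichment consensus.

Anticorrelation procedure
-------------------------
For a miRNA with predicted target set T, compute the Pearson correlation of
each target gene with the miRNA across samples (r_t), build an empirical
null by repeatedly drawing |T| non-target genes and pooling their
correlations (r_0), and compare the two distributions with a two-sample
Kolmogorov-Smirnov test. A left shift of r_t relative to r_0 is the
signature of genuine miRNA-mediated repression.

Because the pooled null re-uses a finite pool of non-target genes across
bootstrap draws, its values are not independent draws; the KS p-value is
therefore computed with an *effective* null sample size equal to the
number of distinct non-target genes, via the classical asymptotic
two-sample formula. Using the raw pooled length would overstate the
evidence.

Enrichment consensus
--------------------
Overrepresentation of each miRNA's target set in a gene cluster is tested
three ways (binomial, one-sided Fisher, hypergeometric); each family of
p-values is Hochberg-adjusted across miRNAs, and a miRNA is called only
when all three adjusted p-values fall below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InputError, UndefinedCorrelationError
from .simulate import ExpressionMatrix


@dataclass
class AnticorrConfig:
    B: int = 1000
    rng_seed: int = 0
    sample_layout: str = "per-sample"  # or "per-age-mean"
    ks_alternative: str = "two-sided"  # or "targets-less"

    def __post_init__(self) -> None:
        if self.B < 1:
            raise InputError("B must be >= 1")
        if self.sample_layout not in ("per-sample", "per-age-mean"):
            raise InputError(f"unknown sample_layout {self.sample_layout!r}")
        if self.ks_alternative not in ("two-sided", "targets-less"):
            raise InputError(f"unknown ks_alternative {self.ks_alternative!r}")


@dataclass
class AnticorrResult:
    target_r: pd.Series
    null_r: np.ndarray
    D: float
    p: float
    n_null_effective: int


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on zero variance or length < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise InputError("pearson requires two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    return float(sps.pearsonr(x, y).statistic)


def _layout(
    expr: ExpressionMatrix, mirna: pd.Series, cfg: AnticorrConfig
) -> tuple[pd.DataFrame, np.ndarray]:
    """Return (gene x point matrix, miRNA vector) in the configured layout."""
    values = expr.values
    m = mirna.reindex(values.columns)
    if m.isna().any():
        raise InputError("miRNA vector does not cover all expression samples")
    if cfg.sample_layout == "per-age-mean":
        groups = expr.samples["age_weeks"]
        values = values.T.groupby(groups).mean().T
        m = m.groupby(groups).mean().reindex(values.columns)
    if values.shape[1] < 3:
        raise InputError("need at least 3 points to correlate")
    return values, m.to_numpy(dtype=float)


def _row_correlations(matrix: np.ndarray, vector: np.ndarray) -> np.ndarray:
    """Pearson r of every matrix row against ``vector`` (vectorised)."""
    x = matrix - matrix.mean(axis=1, keepdims=True)
    y = vector - vector.mean()
    denom = np.sqrt((x ** 2).sum(axis=1) * (y ** 2).sum())
    if (denom == 0).any() or (y ** 2).sum() == 0:
        raise UndefinedCorrelationError(
            "zero variance in a gene or the miRNA vector: correlation undefined"
        )
    return (x @ y) / denom


def target_correlations(
    expr: ExpressionMatrix,
    mirna: pd.Series,
    targets: Iterable[str],
    cfg: AnticorrConfig | None = None,
) -> pd.Series:
    """Pearson r of each target gene with the miRNA, indexed by sorted gene id."""
    cfg = cfg or AnticorrConfig()
    targets = sorted(set(targets))
    missing = [t for t in targets if t not in expr.values.index]
    if missing:
        raise InputError(f"targets absent from the expression matrix: {missing[:5]}")
    values, m = _layout(expr, mirna, cfg)
    if not targets:
        return pd.Series(dtype=float, name="r")
    r = _row_correlations(values.loc[targets].to_numpy(dtype=float), m)
    return pd.Series(r, index=pd.Index(targets, name="gene_id"), name="r")


def bootstrap_null(
    expr: ExpressionMatrix,
    mirna: pd.Series,
    targets: Iterable[str],
    cfg: AnticorrConfig | None = None,
) -> np.ndarray:
    """Pooled null correlations from B size-matched non-target gene draws.

    Each draw samples |targets| genes without replacement from the
    non-target pool (draws are independent, so genes recur across draws);
    the correlations of all drawn genes are pooled into one vector of
    length ``B * |targets|``. Seeded by ``cfg.rng_seed``.
    """
    cfg = cfg or AnticorrConfig()
    target_set = set(targets)
    pool = [g for g in expr.values.index if g not in target_set]
    n_draw = len(target_set)
    if len(pool) < n_draw:
        raise InputError(
            f"non-target pool ({len(pool)}) smaller than the target set ({n_draw})"
        )
    values, m = _layout(expr, mirna, cfg)
    pool_r = _row_correlations(values.loc[pool].to_numpy(dtype=float), m)
    rng = np.random.default_rng(cfg.rng_seed)
    keys = rng.random((cfg.B, len(pool)))
    idx = np.argpartition(keys, n_draw - 1, axis=1)[:, :n_draw]
    return pool_r[idx].ravel()


def _ks_statistic(a: np.ndarray, b: np.ndarray, alternative: str) -> float:
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / len(a)
    cdf_b = np.searchsorted(b, grid, side="right") / len(b)
    diff = cdf_a - cdf_b
    if alternative == "targets-less":
        # targets shifted left => their ECDF runs above the null's
        return float(diff.max())
    return float(np.abs(diff).max())


def ks_compare(
    r_t: Sequence[float],
    r_0: Sequence[float],
    cfg: AnticorrConfig | None = None,
    n_null_effective: int | None = None,
) -> tuple[float, float]:
    """Two-sample KS comparison of target and null correlation distributions.

    D is the sup of the ECDF difference over the pooled values (absolute
    for two-sided; signed, target-above-null, for ``targets-less``). The
    p-value uses the asymptotic two-sample formula with effective sizes
    ``(len(r_t), n_null_effective or len(r_0))`` — callers whose null is a
    pooled bootstrap should pass the distinct-gene count (see module notes).
    """
    cfg = cfg or AnticorrConfig()
    r_t = np.asarray(r_t, dtype=float)
    r_0 = np.asarray(r_0, dtype=float)
    if len(r_t) == 0 or len(r_0) == 0:
        raise InputError("both correlation vectors must be non-empty")
    d = _ks_statistic(r_t, r_0, cfg.ks_alternative)
    n = len(r_t)
    m = n_null_effective if n_null_effective is not None else len(r_0)
    ne = n * m / (n + m)
    if cfg.ks_alternative == "targets-less":
        p = float(np.exp(-2.0 * ne * d * d))
    else:
        p = float(sps.kstwobign.sf(np.sqrt(ne) * d))
    return d, min(1.0, p)


def anticorrelation_test(
    expr: ExpressionMatrix,
    mirna: pd.Series,
    targets: Iterable[str],
    cfg: AnticorrConfig | None = None,
) -> AnticorrResult:
    """Full procedure: target correlations, bootstrap null, KS comparison."""
    cfg = cfg or AnticorrConfig()
    r_t = target_correlations(expr, mirna, targets, cfg)
    r_0 = bootstrap_null(expr, mirna, targets, cfg)
    n_pool = len(expr.values.index) - len(set(targets))
    d, p = ks_compare(r_t.to_numpy(), r_0, cfg, n_null_effective=n_pool)
    return AnticorrResult(r_t, r_0, d, p, n_pool)


# ---------------------------------------------------------------------------
# target-set overrepresentation
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentRecord:
    mirna_id: str
    cluster_id: str
    k: int  # targets in the cluster
    n: int  # cluster size
    K: int  # target-set size
    N: int  # universe size
    p_binomial: float
    p_fisher: float
    p_hypergeometric: float
    adj_binomial: float = float("nan")
    adj_fisher: float = float("nan")
    adj_hypergeometric: float = float("nan")
    consensus: bool = False


def enrichment_tests(
    cluster: Iterable[str], targets: Iterable[str], universe: Iterable[str]
) -> tuple[float, float, float, tuple[int, int, int, int]]:
    """One-sided overrepresentation p-values for the 2x2 cluster x target table.

    Returns ``(p_binomial, p_fisher, p_hypergeometric, (k, n, K, N))``.
    The binomial test models k target hits among n cluster draws with
    success probability K/N; Fisher and hypergeometric act on the exact
    2x2 table and agree to numerical precision (one-sided Fisher *is* the
    hypergeometric upper tail).
    """
    universe = set(universe)
    if not universe:
        raise InputError("empty universe")
    cluster = set(cluster)
    targets = set(targets)
    if not cluster <= universe or not targets <= universe:
        raise InputError("cluster and target set must be subsets of the universe")
    N, n, K = len(universe), len(cluster), len(targets)
    k = len(cluster & targets)
    p_binom = float(sps.binom.sf(k - 1, n, K / N)) if n else 1.0
    p_hyper = float(sps.hypergeom.sf(k - 1, N, K, n))
    table = [[k, K - k], [n - k, N - K - (n - k)]]
    p_fisher = float(sps.fisher_exact(table, alternative="greater")[1])
    return p_binom, p_fisher, p_hyper, (k, n, K, N)


def hochberg(p: Sequence[float]) -> np.ndarray:
    """Hochberg step-up adjusted p-values (FWER control)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="simes-hochberg")[1]


def consensus_enrichment(
    records: Sequence[EnrichmentRecord], alpha: float = 0.05
) -> list[EnrichmentRecord]:
    """Hochberg-adjust each test's p-values across miRNAs; flag consensus.

    A miRNA's targets are called overrepresented only when the adjusted
    p-value is below ``alpha`` in *all three* tests.
    """
    if not records:
        return []
    clusters = {r.cluster_id for r in records}
    if len(clusters) > 1:
        raise InputError("all records must refer to the same cluster")
    adj_b = hochberg([r.p_binomial for r in records])
    adj_f = hochberg([r.p_fisher for r in records])
    adj_h = hochberg([r.p_hypergeometric for r in records])
    out = []
    for r, ab, af, ah in zip(records, adj_b, adj_f, adj_h):
        out.append(
            EnrichmentRecord(
                r.mirna_id, r.cluster_id, r.k, r.n, r.K, r.N,
                r.p_binomial, r.p_fisher, r.p_hypergeometric,
                adj_binomial=float(ab), adj_fisher=float(af),
                adj_hypergeometric=float(ah),
                consensus=bool(ab < alpha and af < alpha and ah < alpha),
            )
        )
    return out


def enrich_mirnas(
    target_sets: dict[str, set[str]],
    cluster: Iterable[str],
    universe: Iterable[str],
    cluster_id: str = "cluster",
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Convenience driver: test every miRNA's target set and apply consensus."""
    records = []
    for mirna_id, tset in target_sets.items():
        pb, pf, ph, (k, n, K, N) = enrichment_tests(cluster, tset, universe)
        records.append(
            EnrichmentRecord(mirna_id, cluster_id, k, n, K, N, pb, pf, ph)
        )
    return consensus_enrichment(records, alpha=alpha)
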