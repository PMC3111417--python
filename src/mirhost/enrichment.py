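"""Permutation null and Wilcoxon-Mann-Whitney enrichment.

For every (target, dataset) the design is fitted twice: once with the true
host profiles and once after permuting the assignment of host labels to host
expression profiles.  All rescaled coefficients from the permuted fits,
pooled over pairs and datasets, form the empirical null.  Each
(host, target) pair is then scored with a two-sided WMW rank-sum P-value of
its cross-dataset real weight sample against the pool (``p_real``) and, as a
matched negative control, of its permuted weight sample against the pool
(``p_perm``).  A pair whose mean real weight exceeds the null mean is a
predicted *repressive* ("negative") interaction.

All randomness flows through one seeded :class:`numpy.random.Generator`, so
every P/Q value is reproducible bit-for-bit given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.stats

from .annotation import TargetDesign
from .errors import EmptyDatasetError, PermutationError
from .expression import ExpressionDataset, normalize_host_profile
from .regression import WeightVector, fit as fit_method

logger = logging.getLogger(__name__)

#: smallest reportable p-value; keeps p in (0, 1] and -log10(p) finite
_P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# host-label permutation
# ---------------------------------------------------------------------------

def draw_host_permutation(
    host_ids: Sequence[str], rng: np.random.Generator
) -> dict[str, str]:
    """Uniform non-identity permutation of host labels over profiles.

    Returns a mapping ``host -> host whose profile it receives``.  The
    identity assignment is excluded whenever an alternative exists; a
    single-host universe cannot be permuted.
    """
    hosts = list(host_ids)
    if len(hosts) < 2:
        raise PermutationError(
            f"cannot permute a host universe of size {len(hosts)}"
        )
    n = len(hosts)
    while True:
        perm = rng.permutation(n)
        if not np.array_equal(perm, np.arange(n)):
            break
    return {hosts[i]: hosts[perm[i]] for i in range(n)}


def permute_hosts(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Columns of ``X`` rearranged by a uniform non-identity permutation.

    The multiset of host profiles is preserved; with two columns the only
    admissible draw is the swap.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D, got shape {X.shape}")
    labels = [str(i) for i in range(X.shape[1])]
    mapping = draw_host_permutation(labels, rng)
    order = [int(mapping[lab]) for lab in labels]
    return X[:, order]


# ---------------------------------------------------------------------------
# two-sided WMW rank-sum p-value
# ---------------------------------------------------------------------------

def wmw_two_sided(sample: np.ndarray, pool: np.ndarray) -> float:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum P-value of sample vs pool.

    Exact enumeration of the U distribution when ``min(n, m) <= 8`` and the
    combined data are tie-free; otherwise the normal approximation with
    midranks and the variance tie correction (no continuity correction, so
    identical distributions give p = 1 exactly).
    """
    x = np.asarray(sample, dtype=float).ravel()
    y = np.asarray(pool, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("wmw_two_sided: empty sample or pool")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < n + m
    if min(n, m) <= 8 and not has_ties:
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(max(res.pvalue, _P_FLOOR))
    ranks = scipy.stats.rankdata(combined)
    r1 = float(ranks[:n].sum())
    u1 = r1 - n * (n + 1) / 2.0
    mu = n * m / 2.0
    big_n = n + m
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float((counts.astype(float) ** 3 - counts).sum())
    sigma2 = n * m / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    if sigma2 <= 0.0:  # all values identical
        return 1.0
    z = (u1 - mu) / np.sqrt(sigma2)
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return float(min(1.0, max(p, _P_FLOOR)))


# ---------------------------------------------------------------------------
# fitting engine: real and permuted weights for a compendium
# ---------------------------------------------------------------------------

@dataclass
class PairWeights:
    """Cross-dataset rescaled weight samples for one (host, target) pair."""

    real: list[float] = field(default_factory=list)
    perm: list[float] = field(default_factory=list)
    datasets: list[str] = field(default_factory=list)


@dataclass
class FitResult:
    """All real and permuted fits for one method over a compendium."""

    method: str
    real_vectors: list[WeightVector]
    perm_vectors: list[WeightVector]
    pairs: dict[tuple[str, str], PairWeights]


def _dataset_host_profiles(
    ds: ExpressionDataset, hosts: Iterable[str]
) -> dict[str, np.ndarray]:
    """Unit-norm profiles for the design hosts present in this dataset."""
    profiles: dict[str, np.ndarray] = {}
    for host in hosts:
        if host not in ds:
            logger.info("%s: host %s absent, column dropped", ds.dataset_id, host)
            continue
        try:
            profiles[host] = normalize_host_profile(ds, host).x
        except Exception as exc:  # degenerate zero-norm profile
            logger.warning("%s: host %s dropped (%s)", ds.dataset_id, host, exc)
    return profiles


def fit_compendium(
    datasets: Sequence[ExpressionDataset],
    designs: Sequence[TargetDesign],
    methods: Sequence[str],
    rng: np.random.Generator,
    n_perms: int = 1,
    permute_scope: str = "universe",
) -> dict[str, FitResult]:
    """Fit every (target, dataset) with real and permuted host assignments.

    ``permute_scope`` is ``"universe"`` (host labels permuted over all design
    hosts present in the dataset; the default) or ``"design"`` (labels
    permuted within each design's own columns).  The same permutation draw is
    shared by all methods so method comparisons are paired.

    Datasets are assumed preprocessed (see :func:`mirhost.expression.filter_genes`).
    """
    if permute_scope not in ("universe", "design"):
        raise ValueError(f"unknown permute_scope {permute_scope!r}")
    all_hosts = sorted({h for dg in designs for h in dg.host_gene_ids})
    results = {
        m: FitResult(method=m, real_vectors=[], perm_vectors=[], pairs={})
        for m in methods
    }

    for ds in datasets:
        profiles = _dataset_host_profiles(ds, all_hosts)
        if not profiles:
            logger.warning("%s: no design host present, dataset skipped", ds.dataset_id)
            continue
        column_means = ds.values.mean(axis=0)
        universe = sorted(profiles)
        # one permutation per replicate, shared across designs and methods
        perm_maps: list[dict[str, str] | None] = []
        for _ in range(n_perms):
            if permute_scope == "universe":
                if len(universe) >= 2:
                    perm_maps.append(draw_host_permutation(universe, rng))
                else:
                    logger.warning(
                        "%s: single-host universe, permutation skipped",
                        ds.dataset_id,
                    )
                    perm_maps.append(None)
            else:
                perm_maps.append(None)  # drawn per design below

        for design in designs:
            present = [h for h in design.host_gene_ids if h in profiles]
            if not present:
                logger.info(
                    "%s: all hosts of target %s absent, design skipped",
                    ds.dataset_id,
                    design.target_gene_id,
                )
                continue
            if design.target_gene_id not in ds:
                logger.info(
                    "%s: target %s absent, design skipped",
                    ds.dataset_id,
                    design.target_gene_id,
                )
                continue
            X = np.column_stack([profiles[h] for h in present])
            d = column_means - ds.row(design.target_gene_id)

            perm_columns: list[np.ndarray | None] = []
            for pmap in perm_maps:
                if permute_scope == "design":
                    if len(present) >= 2:
                        pmap = draw_host_permutation(present, rng)
                    else:
                        pmap = None
                if pmap is None:
                    perm_columns.append(None)
                else:
                    perm_columns.append(
                        np.column_stack([profiles[pmap[h]] for h in present])
                    )

            for method in methods:
                vec = fit_method(
                    method,
                    X,
                    d,
                    host_gene_ids=present,
                    target_gene_id=design.target_gene_id,
                    dataset_id=ds.dataset_id,
                )
                res = results[method]
                res.real_vectors.append(vec)
                if not vec.degenerate:
                    for host, w in zip(present, vec.rescaled):
                        pair = res.pairs.setdefault(
                            (host, design.target_gene_id), PairWeights()
                        )
                        pair.real.append(float(w))
                        pair.datasets.append(ds.dataset_id)
                for Xp in perm_columns:
                    if Xp is None:
                        continue
                    pvec = fit_method(
                        method,
                        Xp,
                        d,
                        host_gene_ids=present,
                        target_gene_id=design.target_gene_id,
                        dataset_id=ds.dataset_id,
                    )
                    res.perm_vectors.append(pvec)
                    if not pvec.degenerate:
                        for host, w in zip(present, pvec.rescaled):
                            pair = res.pairs.setdefault(
                                (host, design.target_gene_id), PairWeights()
                            )
                            pair.perm.append(float(w))
    return results


# ---------------------------------------------------------------------------
# null pool and pair scores
# ---------------------------------------------------------------------------

@dataclass
class NullPool:
    """Pooled rescaled weights from all permuted fits for one method."""

    method: str
    weights: np.ndarray
    rng_seed: int | None = None
    pair_perm: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size == 0:
            raise EmptyDatasetError(f"{self.method}: empty permutation null pool")

    @property
    def mean(self) -> float:
        return float(self.weights.mean())


def build_null_pool(
    designs: Sequence[TargetDesign],
    datasets: Sequence[ExpressionDataset],
    method: str,
    n_perms: int = 1,
    rng_seed: int | np.random.Generator = 0,
    permute_scope: str = "universe",
) -> NullPool:
    """Fit permuted designs across the compendium and pool the weights.

    Convenience wrapper over :func:`fit_compendium` for a single method; the
    pipeline reuses the fit results directly instead.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    fits = fit_compendium(
        datasets, designs, [method], rng, n_perms=n_perms, permute_scope=permute_scope
    )
    return null_pool_from_fits(
        fits[method], rng_seed if isinstance(rng_seed, int) else None
    )


def null_pool_from_fits(fit_result: FitResult, rng_seed: int | None = None) -> NullPool:
    """Pool all non-degenerate permuted coefficients of a :class:`FitResult`."""
    weights = np.concatenate(
        [v.rescaled for v in fit_result.perm_vectors if not v.degenerate]
        or [np.empty(0)]
    )
    pair_perm = {
        key: np.asarray(pw.perm, dtype=float)
        for key, pw in fit_result.pairs.items()
        if pw.perm
    }
    return NullPool(
        method=fit_result.method,
        weights=weights,
        rng_seed=rng_seed,
        pair_perm=pair_perm,
    )


@dataclass
class InteractionScore:
    """Enrichment score for one (host, target) pair.

    ``sign`` is ``"negative"`` (predicted repression) when the mean real
    weight exceeds the null-pool mean, else ``"non-negative"``.  ``p_perm``
    is the matched permuted control (NaN when no permuted sample exists).
    ``significant`` is filled by the calibration step.
    """

    host_gene_id: str
    target_gene_id: str
    method: str
    n_datasets: int
    p_real: float
    p_perm: float
    mean_weight: float
    null_mean: float
    sign: str
    significant: bool = False


def score_pair(
    host_gene_id: str,
    target_gene_id: str,
    weights_real: np.ndarray,
    weights_perm: np.ndarray,
    pool: NullPool,
) -> InteractionScore:
    """WMW enrichment of one pair's real and permuted weights vs the pool."""
    weights_real = np.asarray(weights_real, dtype=float)
    if weights_real.size == 0:
        raise ValueError(
            f"pair ({host_gene_id}, {target_gene_id}): no real weights"
        )
    weights_perm = np.asarray(weights_perm, dtype=float)
    p_real = wmw_two_sided(weights_real, pool.weights)
    p_perm = (
        wmw_two_sided(weights_perm, pool.weights) if weights_perm.size else float("nan")
    )
    mean_weight = float(weights_real.mean())
    return InteractionScore(
        host_gene_id=host_gene_id,
        target_gene_id=target_gene_id,
        method=pool.method,
        n_datasets=int(weights_real.size),
        p_real=p_real,
        p_perm=p_perm,
        mean_weight=mean_weight,
        null_mean=pool.mean,
        sign="negative" if mean_weight > pool.mean else "non-negative",
    )


def score_all_pairs(fit_result: FitResult, pool: NullPool) -> list[InteractionScore]:
    """Scores for every pair with at least one real weight, in sorted order."""
    scores = []
    for (host, target) in sorted(fit_result.pairs):
        pw = fit_result.pairs[(host, target)]
        if not pw.real:
            logger.info("pair (%s, %s): no real weights, skipped", host, target)
            continue
        scores.append(
            score_pair(
                host,
                target,
                np.asarray(pw.real),
                np.asarray(pw.perm),
                pool,
            )
        )
    return scores
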