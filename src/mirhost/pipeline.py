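"""End-to-end orchestration: load/simulate -> fit -> score -> classify -> export.

The stages run in a fixed order: per-target designs are built from the
annotation maps; every (target, dataset) is fitted with real and permuted
host assignments; the pooled permuted weights form the null against which
each pair's P (real) and Q (permuted control) values are computed; a cutoff
(fixed 0.01 by default, or ROC-chosen) flags significant interactions; hosts
are classified as good/bad surrogates; and the scores, network edge list,
surrogacy report and a JSON run summary are written.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .annotation import (
    HostMap,
    TargetDesign,
    TargetMap,
    build_all_designs,
    load_host_map,
    load_target_map,
)
from .calibration import (
    DEFAULT_CUTOFF,
    RocCurve,
    SurrogacyReport,
    build_roc,
    choose_cutoff,
    classify_all_hosts,
    classify_interactions,
    export_network,
    export_scores,
    export_surrogacy,
)
from .enrichment import (
    FitResult,
    InteractionScore,
    NullPool,
    fit_compendium,
    null_pool_from_fits,
    score_all_pairs,
)
from .errors import ConfigError, DataError
from .expression import ExpressionDataset, filter_genes, read_expression_tsv
from .regression import METHODS, WeightTable
from .simulate import SimulationConfig, simulate_compendium

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source must be given: either the three file inputs
    (``expression_dir``, ``host_map_path``, ``target_map_path``) or a
    ``sim_config``.
    """

    expression_dir: str | Path | None = None
    host_map_path: str | Path | None = None
    target_map_path: str | Path | None = None
    sim_config: SimulationConfig | None = None
    methods: tuple[str, ...] = ("ULM",)
    cutoff_mode: str = "fixed"  # fixed | roc
    fixed_cutoff: float = DEFAULT_CUTOFF
    target_specificity: float = 1.0
    n_perms: int = 1
    rng_seed: int = 0
    filter_percentile: float = 0.10
    permute_scope: str = "universe"
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        file_input = self.expression_dir is not None
        if file_input and self.sim_config is not None:
            raise ConfigError("give either file inputs or sim_config, not both")
        if not file_input and self.sim_config is None:
            raise ConfigError("no input source: set expression_dir or sim_config")
        if file_input:
            for name in ("expression_dir", "host_map_path", "target_map_path"):
                if getattr(self, name) is None:
                    raise ConfigError(f"missing required input path: {name}")
        if self.cutoff_mode not in ("fixed", "roc"):
            raise ConfigError(f"unknown cutoff_mode {self.cutoff_mode!r}")
        if self.cutoff_mode == "fixed" and not 0.0 < self.fixed_cutoff <= 1.0:
            raise ConfigError(f"fixed cutoff must be in (0, 1], got {self.fixed_cutoff}")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ConfigError(f"unknown method(s): {sorted(unknown)}")
        if not self.methods:
            raise ConfigError("at least one method required")
        if self.n_perms < 1:
            raise ConfigError("n_perms must be >= 1")


@dataclass
class MethodResult:
    """Everything computed for one method in a run."""

    method: str
    scores: list[InteractionScore]
    cutoff: float
    roc: RocCurve | None
    reports: list[SurrogacyReport]
    pool: NullPool
    fits: FitResult


@dataclass
class AnalysisResult:
    designs: list[TargetDesign]
    per_method: dict[str, MethodResult]
    summary: dict = field(default_factory=dict)


def load_expression_dir(expression_dir: str | Path) -> list[ExpressionDataset]:
    """Read every ``*.tsv`` in a directory as one dataset (id = file stem)."""
    paths = sorted(Path(expression_dir).glob("*.tsv"))
    if not paths:
        raise DataError(f"{expression_dir}: no .tsv expression files found")
    return [read_expression_tsv(p, p.stem) for p in paths]


def run_analysis(
    datasets: Sequence[ExpressionDataset],
    host_map: HostMap,
    target_map: TargetMap,
    methods: Sequence[str] = ("ULM",),
    cutoff_mode: str = "fixed",
    fixed_cutoff: float = DEFAULT_CUTOFF,
    target_specificity: float = 1.0,
    n_perms: int = 1,
    rng_seed: int = 0,
    filter_percentile: float = 0.10,
    permute_scope: str = "universe",
    prefiltered: bool = False,
) -> AnalysisResult:
    """Run fit -> pool -> score -> classify on in-memory inputs."""
    datasets = sorted(datasets, key=lambda ds: ds.dataset_id)
    if not prefiltered:
        datasets = [filter_genes(ds, filter_percentile) for ds in datasets]
    designs = build_all_designs(host_map, target_map)
    if not designs:
        raise DataError("no target has a putative regulator with a known host")
    rng = np.random.default_rng(rng_seed)
    fits = fit_compendium(
        datasets,
        designs,
        list(methods),
        rng,
        n_perms=n_perms,
        permute_scope=permute_scope,
    )
    per_method: dict[str, MethodResult] = {}
    for method in methods:
        fit_result = fits[method]
        pool = null_pool_from_fits(fit_result, rng_seed)
        scores = score_all_pairs(fit_result, pool)
        roc = None
        if cutoff_mode == "roc":
            p_perm = [s.p_perm for s in scores if np.isfinite(s.p_perm)]
            roc = build_roc([s.p_real for s in scores], p_perm, method=method)
            cutoff = choose_cutoff(roc, target_specificity)
        else:
            cutoff = fixed_cutoff
        scores = classify_interactions(scores, cutoff)
        reports = classify_all_hosts(scores, cutoff)
        per_method[method] = MethodResult(
            method=method,
            scores=scores,
            cutoff=cutoff,
            roc=roc,
            reports=reports,
            pool=pool,
            fits=fit_result,
        )
    summary = {
        "version": __version__,
        "rng_seed": rng_seed,
        "n_datasets": len(datasets),
        "n_designs": len(designs),
        "methods": list(methods),
        "cutoff_mode": cutoff_mode,
        "n_perms": n_perms,
        "permute_scope": permute_scope,
        "per_method": {
            m: {
                "cutoff": res.cutoff,
                "pool_size": int(res.pool.weights.size),
                "n_pairs_scored": len(res.scores),
                "n_significant": sum(s.significant for s in res.scores),
                "n_significant_negative": sum(
                    s.significant and s.sign == "negative" for s in res.scores
                ),
                "n_good_surrogates": sum(
                    r.call == "good_surrogate" for r in res.reports
                ),
                "roc_auc": res.roc.auc if res.roc is not None else None,
            }
            for m, res in per_method.items()
        },
    }
    return AnalysisResult(designs=designs, per_method=per_method, summary=summary)


def write_outputs(result: AnalysisResult, out_dir: str | Path) -> list[Path]:
    """Write scores/network/surrogacy TSVs per method plus summary.json.

    On failure every file created by this call is removed, so a run never
    leaves partial outputs behind.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    designs = {d.target_gene_id: d for d in result.designs}
    try:
        for method, res in result.per_method.items():
            tag = method.lower()
            path = out / f"scores_{tag}.tsv"
            export_scores(res.scores, path)
            written.append(path)
            path = out / f"network_{tag}.tsv"
            export_network(res.scores, designs, path)
            written.append(path)
            path = out / f"surrogacy_{tag}.tsv"
            export_surrogacy(res.reports, path)
            written.append(path)
        path = out / "summary.json"
        path.write_text(
            json.dumps(result.summary, indent=1, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        written.append(path)
    except BaseException:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return written


def run_pipeline(cfg: RunConfig) -> AnalysisResult:
    """Execute a full run from a :class:`RunConfig`; writes outputs if asked."""
    if cfg.sim_config is not None:
        comp = simulate_compendium(cfg.sim_config)
        datasets, host_map, target_map = comp.datasets, comp.host_map, comp.target_map
    else:
        datasets = load_expression_dir(cfg.expression_dir)
        host_map = load_host_map(cfg.host_map_path)
        target_map = load_target_map(cfg.target_map_path, host_map)
    result = run_analysis(
        datasets,
        host_map,
        target_map,
        methods=cfg.methods,
        cutoff_mode=cfg.cutoff_mode,
        fixed_cutoff=cfg.fixed_cutoff,
        target_specificity=cfg.target_specificity,
        n_perms=cfg.n_perms,
        rng_seed=cfg.rng_seed,
        filter_percentile=cfg.filter_percentile,
        permute_scope=cfg.permute_scope,
    )
    if cfg.out_dir is not None:
        write_outputs(result, cfg.out_dir)
    return result


def weight_table_from_fits(result: AnalysisResult) -> WeightTable:
    """Real-fit weight vectors of every method as one :class:`WeightTable`."""
    table = WeightTable()
    for res in result.per_method.values():
        for vec in res.fits.real_vectors:
            table.add(vec)
    return table


def run_config_to_json(cfg: RunConfig, path: str | Path) -> None:
    blob = dataclasses.asdict(cfg)
    for key in ("expression_dir", "host_map_path", "target_map_path", "out_dir"):
        if blob[key] is not None:
            blob[key] = str(blob[key])
    Path(path).write_text(json.dumps(blob, indent=1) + "\n", encoding="utf-8")
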