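"""Synthetic multi-dataset expression compendia with known ground truth.

The generator plants host -> target repressive interactions inside a
compendium of independently drawn datasets, emulating the study setting the
method is built for: many small expression studies, host genes acting as
surrogates for their intronic miRNAs, targets down-regulated additively on
the linear scale.

Three host scenarios control how well a host's mRNA tracks its intronic
miRNA's activity:

``coupled``
    host and miRNA share a promoter and no differential post-transcriptional
    regulation: the miRNA activity *is* the host profile (good surrogate).
``independent_promoter``
    the miRNA is transcribed from its own promoter: activity is a latent
    profile independent of the host's (host uninformative).
``mirna_targeted_host``
    host and miRNA share a promoter but the host mRNA is degraded by another,
    co-expressed miRNA: the emitted host profile becomes anti-correlated with
    the miRNA activity, so real interactions surface with *negative* fitted
    weights (bad surrogate).

Host profiles are drawn i.i.d. Gaussian per dataset around zero and carry a
shared per-dataset factor (co-expression between hosts); targets and
background genes sit on a positive linear-scale baseline.  All randomness
comes from one seeded generator, so a config is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation import HostMap, TargetMap
from .calibration import SurrogacyReport
from .enrichment import InteractionScore
from .errors import ConfigError
from .expression import ExpressionDataset

logger = logging.getLogger(__name__)

SCENARIOS = ("coupled", "independent_promoter", "mirna_targeted_host")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated compendium.

    Defaults describe a mid-sized compendium: 50 datasets of 30 samples,
    12 host genes with one intronic miRNA each, 20 targets each repressed by
    3 co-regulating hosts (plus 3 decoy hosts in the design), planted weights
    drawn from [0.5, 2], per-sample Gaussian noise sd 0.5, and host profiles
    sharing a per-dataset co-expression factor (pairwise correlation 0.5,
    reflecting the co-expressed, often paralogous host families whose miRNAs
    co-target one mRNA).
    """

    rng_seed: int = 0
    n_datasets: int = 50
    n_samples: int = 30
    n_hosts: int = 12
    n_targets: int = 20
    n_background: int = 500
    regulators_per_target: int = 3
    n_decoys: int = 3
    planted_edges: list[tuple[str, str, float]] | None = None
    w_range: tuple[float, float] = (0.5, 2.0)
    noise_sd: float = 0.5
    host_correlation: float = 0.5
    host_amplitude: float = 8.0
    baseline_mean: float = 10.0
    baseline_sd: float = 0.2
    mirnas_per_host: int = 1
    host_scenarios: list[str] | None = None
    degradation_strength: float = 2.0
    comirna_noise_sd: float = 0.5
    regulator_assignment: str = "round_robin"

    def __post_init__(self) -> None:
        positive = {
            "n_datasets": self.n_datasets,
            "n_samples": self.n_samples,
            "n_hosts": self.n_hosts,
            "n_targets": self.n_targets,
            "mirnas_per_host": self.mirnas_per_host,
        }
        for name, value in positive.items():
            if int(value) < 1:
                raise ConfigError(f"{name} must be positive, got {value}")
        if self.n_background < 0 or self.regulators_per_target < 0 or self.n_decoys < 0:
            raise ConfigError("counts must be non-negative")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 <= self.host_correlation < 1.0:
            raise ConfigError("host_correlation must be in [0, 1)")
        if self.regulators_per_target + self.n_decoys > self.n_hosts:
            raise ConfigError(
                f"regulators_per_target + n_decoys = "
                f"{self.regulators_per_target + self.n_decoys} exceeds "
                f"n_hosts = {self.n_hosts}"
            )
        if self.w_range[0] > self.w_range[1] or self.w_range[0] <= 0:
            raise ConfigError(f"invalid w_range {self.w_range}")
        if self.regulator_assignment not in ("round_robin", "random"):
            raise ConfigError(
                f"unknown regulator_assignment {self.regulator_assignment!r}"
            )
        if self.host_scenarios is not None:
            if len(self.host_scenarios) != self.n_hosts:
                raise ConfigError("host_scenarios length must equal n_hosts")
            unknown = set(self.host_scenarios) - set(SCENARIOS)
            if unknown:
                raise ConfigError(f"unknown scenario(s): {sorted(unknown)}")
        if self.planted_edges is not None:
            hosts = set(_host_ids(self.n_hosts))
            targets = set(_target_ids(self.n_targets))
            for host, target, w in self.planted_edges:
                if host not in hosts or target not in targets:
                    raise ConfigError(f"planted edge ({host}, {target}) has unknown id")
                if w <= 0:
                    raise ConfigError(f"planted weight must be > 0, got {w}")

    def to_json(self, path: str | Path) -> None:
        blob = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(blob, indent=1) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        blob = json.loads(Path(path).read_text(encoding="utf-8"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(blob) - known
        if unknown:
            raise ConfigError(f"unknown simulation config key(s): {sorted(unknown)}")
        if "planted_edges" in blob and blob["planted_edges"] is not None:
            blob["planted_edges"] = [tuple(e) for e in blob["planted_edges"]]
        if "w_range" in blob:
            blob["w_range"] = tuple(blob["w_range"])
        return cls(**blob)


@dataclass
class GroundTruth:
    """Planted edges and per-host scenario labels of a simulated compendium."""

    edges: list[tuple[str, str, float]]
    host_scenario: dict[str, str]

    @property
    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(h, t) for h, t, _ in self.edges}


@dataclass
class SimulatedCompendium:
    datasets: list[ExpressionDataset]
    host_map: HostMap
    target_map: TargetMap
    truth: GroundTruth
    config: SimulationConfig
    designs_hosts: dict[str, list[str]] = field(default_factory=dict)


def _host_ids(n: int) -> list[str]:
    return [f"HOST{i + 1:02d}" for i in range(n)]


def _target_ids(n: int) -> list[str]:
    return [f"TGT{i + 1:03d}" for i in range(n)]


def _mirna_ids(host_index: int, per_host: int) -> list[str]:
    base = f"mir-{host_index + 1:03d}"
    if per_host == 1:
        return [base]
    return [f"{base}{chr(ord('a') + j)}" for j in range(per_host)]


def simulate_compendium(cfg: SimulationConfig) -> SimulatedCompendium:
    """Generate datasets, annotation maps and ground truth from a config."""
    rng = np.random.default_rng(cfg.rng_seed)
    hosts = _host_ids(cfg.n_hosts)
    targets = _target_ids(cfg.n_targets)
    scenarios = dict(
        zip(hosts, cfg.host_scenarios or ["coupled"] * cfg.n_hosts)
    )

    host_map_records = []
    mirnas_of: dict[str, list[str]] = {}
    for i, host in enumerate(hosts):
        mirnas_of[host] = _mirna_ids(i, cfg.mirnas_per_host)
        for mirna in mirnas_of[host]:
            host_map_records.append((mirna, host))

    # planted edges and per-target design hosts (regulators + decoys)
    edges: list[tuple[str, str, float]] = []
    regulators: dict[str, list[str]] = {t: [] for t in targets}
    if cfg.planted_edges is not None:
        for host, target, w in cfg.planted_edges:
            edges.append((host, target, float(w)))
            regulators[target].append(host)
    else:
        for j, target in enumerate(targets):
            if cfg.regulators_per_target == 0:
                continue
            if cfg.regulator_assignment == "round_robin":
                start = (j * cfg.regulators_per_target) % cfg.n_hosts
                chosen = [
                    hosts[(start + k) % cfg.n_hosts]
                    for k in range(cfg.regulators_per_target)
                ]
            else:
                chosen = list(
                    rng.choice(hosts, size=cfg.regulators_per_target, replace=False)
                )
            for host in chosen:
                w = (
                    cfg.w_range[0]
                    if cfg.w_range[0] == cfg.w_range[1]
                    else float(rng.uniform(*cfg.w_range))
                )
                edges.append((host, target, w))
            regulators[target] = chosen

    design_hosts: dict[str, list[str]] = {}
    for target in targets:
        regs = list(dict.fromkeys(regulators[target]))
        others = [h for h in hosts if h not in regs]
        n_extra = min(cfg.n_decoys, len(others))
        decoys = list(rng.choice(others, size=n_extra, replace=False)) if n_extra else []
        design_hosts[target] = sorted(regs + decoys)

    target_map_records = []
    for target in targets:
        for host in design_hosts[target]:
            for mirna in mirnas_of[host]:
                target_map_records.append((mirna, target))

    edge_weights: dict[str, dict[str, float]] = {t: {} for t in targets}
    for host, target, w in edges:
        edge_weights[target][host] = edge_weights[target].get(host, 0.0) + w

    gamma = cfg.degradation_strength
    c = cfg.comirna_noise_sd
    # analytic sd of the degraded host profile a - gamma*(a + c*delta)/sqrt(1+c^2)
    q_corr = 1.0 / np.sqrt(1.0 + c * c)
    degraded_sd = float(np.sqrt(max(1.0 + gamma * gamma - 2.0 * gamma * q_corr, 1e-12)))

    datasets: list[ExpressionDataset] = []
    sample_ids = [f"S{j + 1:02d}" for j in range(cfg.n_samples)]
    background_ids = [f"BG{i + 1:04d}" for i in range(cfg.n_background)]
    rho = cfg.host_correlation
    for k in range(cfg.n_datasets):
        S = cfg.n_samples
        shared = rng.standard_normal(S)
        emitted_host = np.empty((cfg.n_hosts, S))
        activity_unit: dict[str, np.ndarray] = {}
        for i, host in enumerate(hosts):
            g = rng.standard_normal(S)
            a = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * g
            scenario = scenarios[host]
            if scenario == "coupled":
                emitted = a
                activity = a
            elif scenario == "independent_promoter":
                emitted = a
                activity = rng.standard_normal(S)
            else:  # mirna_targeted_host
                delta = rng.standard_normal(S)
                q = (a + c * delta) * q_corr
                emitted = (a - gamma * q) / degraded_sd
                activity = a
            emitted_host[i] = cfg.host_amplitude * emitted
            activity_unit[host] = activity / np.linalg.norm(activity)

        target_rows = np.empty((cfg.n_targets, S))
        for j, target in enumerate(targets):
            base = rng.normal(cfg.baseline_mean, cfg.baseline_sd)
            noise = (
                rng.normal(0.0, cfg.noise_sd, S) if cfg.noise_sd > 0 else np.zeros(S)
            )
            signal = np.zeros(S)
            for host, w in edge_weights[target].items():
                signal += w * activity_unit[host]
            target_rows[j] = base - signal + noise

        if cfg.n_background:
            bases = rng.normal(
                cfg.baseline_mean, cfg.baseline_sd, size=(cfg.n_background, 1)
            )
            bg_noise = (
                rng.normal(0.0, cfg.noise_sd, size=(cfg.n_background, S))
                if cfg.noise_sd > 0
                else np.zeros((cfg.n_background, S))
            )
            background_rows = bases + bg_noise
            values = np.vstack([emitted_host, target_rows, background_rows])
            gene_ids = hosts + targets + background_ids
        else:
            values = np.vstack([emitted_host, target_rows])
            gene_ids = hosts + targets

        datasets.append(
            ExpressionDataset(
                dataset_id=f"SIM{k + 1:03d}",
                gene_ids=list(gene_ids),
                sample_ids=list(sample_ids),
                values=values,
            )
        )

    return SimulatedCompendium(
        datasets=datasets,
        host_map=HostMap(records=tuple(host_map_records)),
        target_map=TargetMap(records=tuple(target_map_records)),
        truth=GroundTruth(edges=edges, host_scenario=scenarios),
        config=cfg,
        designs_hosts=design_hosts,
    )


def write_compendium(comp: SimulatedCompendium, out_dir: str | Path) -> None:
    """Emit the compendium in the exact TSV formats the readers consume."""
    out = Path(out_dir)
    (out / "expression").mkdir(parents=True, exist_ok=True)
    for ds in comp.datasets:
        ds.to_frame().rename_axis("gene_id").to_csv(
            out / "expression" / f"{ds.dataset_id}.tsv", sep="\t", float_format="%.8g"
        )
    with open(out / "host_map.tsv", "w", encoding="utf-8") as fh:
        for mirna, host in comp.host_map.records:
            fh.write(f"{mirna}\t{host}\n")
    with open(out / "target_map.tsv", "w", encoding="utf-8") as fh:
        for mirna, target in comp.target_map.records:
            fh.write(f"{mirna}\t{target}\n")
    truth = {
        "edges": [[h, t, w] for h, t, w in comp.truth.edges],
        "host_scenario": comp.truth.host_scenario,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------

@dataclass
class RecoveryMetrics:
    """Planted-edge recovery of a scored, classified run."""

    sensitivity: float
    specificity: float
    precision: float
    n_planted: int
    n_scored_pairs: int
    n_predicted: int


def evaluate_recovery(
    scores: Sequence[InteractionScore], truth: GroundTruth
) -> RecoveryMetrics:
    """Sensitivity/specificity/precision of significant-negative calls
    against the planted edges, over all scored (host, target) pairs."""
    universe = {(s.host_gene_id, s.target_gene_id) for s in scores}
    for host, target in universe:
        if host not in truth.host_scenario:
            raise ConfigError(f"scored host {host!r} not in ground truth")
    predicted = {
        (s.host_gene_id, s.target_gene_id)
        for s in scores
        if s.significant and s.sign == "negative"
    }
    planted = truth.edge_pairs
    tp = len(predicted & planted)
    fp = len(predicted - planted)
    negatives = universe - planted
    sensitivity = tp / len(planted) if planted else float("nan")
    specificity = 1.0 - fp / len(negatives) if negatives else float("nan")
    precision = tp / len(predicted) if predicted else float("nan")
    return RecoveryMetrics(
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        n_planted=len(planted),
        n_scored_pairs=len(universe),
        n_predicted=len(predicted),
    )


def evaluate_surrogacy(
    reports: Sequence[SurrogacyReport], truth: GroundTruth
) -> tuple[float, dict[str, float]]:
    """Fraction of hosts whose surrogacy call matches their scenario.

    A ``coupled`` host should be called ``good_surrogate``; hosts decoupled
    from their miRNA activity (``independent_promoter``,
    ``mirna_targeted_host``) should be ``bad_surrogate`` or ``uninformative``.
    Returns overall accuracy and per-scenario accuracy.
    """
    per_scenario_hits: dict[str, list[bool]] = {}
    for rep in reports:
        scenario = truth.host_scenario.get(rep.host_gene_id)
        if scenario is None:
            raise ConfigError(f"report host {rep.host_gene_id!r} not in ground truth")
        if scenario == "coupled":
            correct = rep.call == "good_surrogate"
        else:
            correct = rep.call in ("bad_surrogate", "uninformative")
        per_scenario_hits.setdefault(scenario, []).append(correct)
    all_hits = [h for hits in per_scenario_hits.values() for h in hits]
    accuracy = float(np.mean(all_hits)) if all_hits else float("nan")
    return accuracy, {
        sc: float(np.mean(hits)) for sc, hits in per_scenario_hits.items()
    }
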