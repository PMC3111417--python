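"""miRNA-host and miRNA-target annotation and the host-target design.

A target's candidate regulators arrive as (miRNA, target) predictions; each
miRNA sits in the intron of one or more host genes.  Because host expression
is the observable surrogate, regression weights are assigned to *hosts*: a
miRNA duplicated in two hosts contributes two design columns, while several
miRNAs sharing one host collapse to a single column whose score is later
fanned back out to each miRNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping

from .errors import AnnotationParseError, NoRegulatorError

logger = logging.getLogger(__name__)


def _read_two_column_tsv(path: str | Path, what: str) -> list[tuple[str, str]]:
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise AnnotationParseError(
                    f"{path}:{lineno}: malformed {what} row {line!r} "
                    "(need mirna_id<TAB>gene_symbol)"
                )
            pair = (fields[0], fields[1])
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    if not pairs:
        raise AnnotationParseError(f"{path}: empty {what} table")
    return pairs


@dataclass(frozen=True)
class HostMap:
    """Deduplicated (mirna_id, host_gene_id) association records."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for mirna, host in self.records:
            if not mirna or not host:
                raise AnnotationParseError("empty id in host map record")

    def hosts_of(self, mirna_id: str) -> list[str]:
        return [h for m, h in self.records if m == mirna_id]

    def mirnas_of(self, host_gene_id: str) -> list[str]:
        return [m for m, h in self.records if h == host_gene_id]

    @property
    def mirna_ids(self) -> list[str]:
        return sorted({m for m, _ in self.records})

    @property
    def host_gene_ids(self) -> list[str]:
        return sorted({h for _, h in self.records})


@dataclass(frozen=True)
class TargetMap:
    """Deduplicated putative (mirna_id, target_gene_id) prediction records."""

    records: tuple[tuple[str, str], ...]

    def mirnas_targeting(self, target_gene_id: str) -> list[str]:
        return [m for m, t in self.records if t == target_gene_id]

    @property
    def target_gene_ids(self) -> list[str]:
        return sorted({t for _, t in self.records})


@dataclass
class TargetDesign:
    """Per-target regression design: one column per distinct host gene.

    ``mirna_edges`` records, for every host column, which of its intronic
    miRNAs put it in the design (used by :func:`fanout_to_mirnas`).
    """

    target_gene_id: str
    host_gene_ids: list[str]
    mirna_edges: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        assert len(set(self.host_gene_ids)) == len(self.host_gene_ids)
        assert all(self.mirna_edges.get(h) for h in self.host_gene_ids)


def load_host_map(path: str | Path) -> HostMap:
    """Load a mirna_id<TAB>host_gene_symbol TSV (deduplicated)."""
    return HostMap(records=tuple(_read_two_column_tsv(path, "host map")))


def load_target_map(path: str | Path, host_map: HostMap | None = None) -> TargetMap:
    """Load a mirna_id<TAB>target_gene_symbol TSV (deduplicated).

    With ``host_map`` given, predictions whose miRNA has no known host are
    logged and dropped: they cannot enter any design.
    """
    pairs = _read_two_column_tsv(path, "target map")
    if host_map is not None:
        known = {m for m, _ in host_map.records}
        unresolved = sorted({m for m, _ in pairs if m not in known})
        if unresolved:
            logger.warning(
                "target map: dropped %d prediction(s) for miRNA(s) with no host: %s",
                sum(1 for m, _ in pairs if m not in known),
                unresolved[:10],
            )
            pairs = [(m, t) for m, t in pairs if m in known]
        if not pairs:
            raise AnnotationParseError("target map: no prediction with a known host")
    return TargetMap(records=tuple(pairs))


def build_design(
    target_gene_id: str, host_map: HostMap, target_map: TargetMap
) -> TargetDesign:
    """Collapse a target's putative miRNA regulators into host columns.

    Hosts are ordered lexicographically so that weight vectors align across
    datasets.  Raises :class:`NoRegulatorError` when no putative miRNA of the
    target resolves to a host.
    """
    mirnas = target_map.mirnas_targeting(target_gene_id)
    edges: dict[str, list[str]] = {}
    for mirna in mirnas:
        for host in host_map.hosts_of(mirna):
            edges.setdefault(host, [])
            if mirna not in edges[host]:
                edges[host].append(mirna)
    if not edges:
        raise NoRegulatorError(
            f"target {target_gene_id!r}: no putative regulator with a known host"
        )
    hosts = sorted(edges)
    return TargetDesign(
        target_gene_id=target_gene_id,
        host_gene_ids=hosts,
        mirna_edges={h: tuple(edges[h]) for h in hosts},
    )


def build_all_designs(
    host_map: HostMap,
    target_map: TargetMap,
    targets: Iterable[str] | None = None,
) -> list[TargetDesign]:
    """Designs for every target in the map (targets with no host are skipped)."""
    designs = []
    for target in targets if targets is not None else target_map.target_gene_ids:
        try:
            designs.append(build_design(target, host_map, target_map))
        except NoRegulatorError as exc:
            logger.info("skipping target: %s", exc)
    return designs


def fanout_to_mirnas(
    design: TargetDesign, host_results: Mapping[str, Any]
) -> list[tuple[str, str, str, Any]]:
    """Copy each host-level result to every (miRNA, host) edge of the design.

    Returns rows ``(mirna_id, target_gene_id, host_gene_id, result)``, one per
    miRNA driving the host's inclusion; hosts absent from ``host_results``
    contribute nothing.
    """
    rows: list[tuple[str, str, str, Any]] = []
    for host in design.host_gene_ids:
        if host not in host_results:
            continue
        for mirna in design.mirna_edges[host]:
            rows.append((mirna, design.target_gene_id, host, host_results[host]))
    return rows
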