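"""Cutoff selection, interaction classification and surrogacy calls.

The significance cutoff on the enrichment P-value is either the fixed 0.01
default or chosen by ROC analysis in which the real pairs' ``-log10 p_real``
values are the positive scores and the permuted controls' ``-log10 p_perm``
the negative scores: the cutoff is the least stringent threshold whose false
positive rate on the permuted controls still meets the requested specificity.

A host gene is called a *good surrogate* for its intronic miRNAs when a
strict majority of its significant target interactions are negative
(repressive); hosts with significant but predominantly non-negative
interactions are *bad surrogates*, and hosts with no significant interaction
are *uninformative*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import sklearn.metrics

from .annotation import TargetDesign, fanout_to_mirnas
from .enrichment import InteractionScore

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.01


@dataclass
class RocCurve:
    """ROC of real vs permuted-control enrichment scores.

    ``thresholds`` are on the ``-log10 P`` scale, descending (most stringent
    first), aligned with ``fpr``/``tpr``; predicted-positive at threshold
    ``t`` means ``-log10 P >= t``.
    """

    method: str
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    @property
    def auc(self) -> float:
        return float(sklearn.metrics.auc(self.fpr, self.tpr))


def _neglog10(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return -np.log10(np.clip(p, 1e-300, 1.0))


def build_roc(
    p_real: Sequence[float], p_perm: Sequence[float], method: str = ""
) -> RocCurve:
    """ROC over thresholds on -log10 P; positives real, negatives permuted."""
    pos = _neglog10(np.asarray(p_real, dtype=float))
    neg = _neglog10(np.asarray(p_perm, dtype=float))
    pos = pos[np.isfinite(pos)]
    neg = neg[np.isfinite(neg)]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("build_roc: empty positive or negative score set")
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    scores = np.concatenate([pos, neg])
    fpr, tpr, thresholds = sklearn.metrics.roc_curve(labels, scores)
    return RocCurve(method=method, fpr=fpr, tpr=tpr, thresholds=thresholds)


def choose_cutoff(roc: RocCurve, target_specificity: float = 1.0) -> float:
    """P-value cutoff whose FPR on permuted controls meets the specificity.

    Scans the curve for the smallest ``-log10 P`` threshold with
    ``FPR <= 1 - target_specificity`` (i.e. the least stringent admissible
    cutoff, maximizing sensitivity) and returns it as a P-value.  When no
    finite threshold qualifies, the most stringent finite threshold is
    returned with a warning.
    """
    if not 0.0 <= target_specificity <= 1.0:
        raise ValueError("target_specificity must be in [0, 1]")
    allowed_fpr = 1.0 - target_specificity
    finite = np.isfinite(roc.thresholds)
    ok = (roc.fpr <= allowed_fpr + 1e-12) & finite
    if ok.any():
        # thresholds descend; the last admissible index is the smallest one
        threshold = float(roc.thresholds[np.nonzero(ok)[0][-1]])
    else:
        threshold = float(roc.thresholds[finite][0]) if finite.any() else np.inf
        logger.warning(
            "choose_cutoff: specificity %.3f unachievable, returning most "
            "stringent threshold %.3g",
            target_specificity,
            threshold,
        )
    return float(10.0 ** (-threshold))


def classify_interactions(
    scores: Sequence[InteractionScore], cutoff: float = DEFAULT_CUTOFF
) -> list[InteractionScore]:
    """Annotate scores with the significance flag ``p_real <= cutoff``."""
    return [replace(s, significant=bool(s.p_real <= cutoff)) for s in scores]


@dataclass
class SurrogacyReport:
    """Per-host summary of significant interactions and the surrogacy call.

    ``pct_negative`` and ``mean_neglog_p`` are the host's coordinates in the
    negative-share vs mean-enrichment plane used to separate good from bad
    surrogates (NaN when the host has no significant interaction).
    """

    host_gene_id: str
    n_putative: int
    n_significant: int
    n_negative: int
    mean_neglog_p: float
    pct_negative: float
    call: str  # good_surrogate | bad_surrogate | uninformative

    def __post_init__(self) -> None:
        assert 0 <= self.n_negative <= self.n_significant <= self.n_putative


def classify_host(
    host_gene_id: str,
    scores: Sequence[InteractionScore],
    cutoff: float = DEFAULT_CUTOFF,
) -> SurrogacyReport:
    """Surrogacy call for one host from its (already scored) target pairs.

    Good surrogate: strict majority of significant interactions negative.
    Ties go to ``bad_surrogate`` (conservative: a good-surrogate call licenses
    downstream target claims); no significant interaction is ``uninformative``.
    """
    mine = [s for s in scores if s.host_gene_id == host_gene_id]
    sig = [s for s in mine if s.p_real <= cutoff]
    neg = [s for s in sig if s.sign == "negative"]
    n_sig, n_neg = len(sig), len(neg)
    if n_sig == 0:
        call = "uninformative"
    elif n_neg > n_sig - n_neg:
        call = "good_surrogate"
    else:
        call = "bad_surrogate"
    return SurrogacyReport(
        host_gene_id=host_gene_id,
        n_putative=len(mine),
        n_significant=n_sig,
        n_negative=n_neg,
        mean_neglog_p=(
            float(np.mean(_neglog10([s.p_real for s in sig]))) if sig else float("nan")
        ),
        pct_negative=100.0 * n_neg / n_sig if n_sig else float("nan"),
        call=call,
    )


def classify_all_hosts(
    scores: Sequence[InteractionScore], cutoff: float = DEFAULT_CUTOFF
) -> list[SurrogacyReport]:
    hosts = sorted({s.host_gene_id for s in scores})
    return [classify_host(h, scores, cutoff) for h in hosts]


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

SCORES_COLUMNS = [
    "method",
    "host",
    "target",
    "n_datasets",
    "p_real",
    "p_perm",
    "mean_weight",
    "null_mean",
    "sign",
    "significant",
]


def scores_to_frame(scores: Sequence[InteractionScore]) -> pd.DataFrame:
    rows = [
        (
            s.method,
            s.host_gene_id,
            s.target_gene_id,
            s.n_datasets,
            s.p_real,
            s.p_perm,
            s.mean_weight,
            s.null_mean,
            s.sign,
            s.significant,
        )
        for s in scores
    ]
    frame = pd.DataFrame(rows, columns=SCORES_COLUMNS)
    return frame.sort_values(["method", "host", "target"], kind="stable").reset_index(
        drop=True
    )


def export_scores(scores: Sequence[InteractionScore], path: str | Path) -> None:
    scores_to_frame(scores).to_csv(path, sep="\t", index=False, float_format="%.6g")


def export_network(
    scores: Sequence[InteractionScore],
    designs: Mapping[str, TargetDesign] | Sequence[TargetDesign],
    path: str | Path,
) -> pd.DataFrame:
    """Significant *negative* edges as a host-miRNA-target TSV edge list.

    Each host-target edge is fanned out to one row per intronic miRNA that
    put the host in the target's design; rows are sorted for deterministic
    output.  Returns the exported frame.
    """
    if not isinstance(designs, Mapping):
        designs = {d.target_gene_id: d for d in designs}
    rows = []
    for s in scores:
        if not (s.significant and s.sign == "negative"):
            continue
        design = designs.get(s.target_gene_id)
        if design is None:
            logger.warning("no design for scored target %s", s.target_gene_id)
            continue
        for mirna, target, host, p in fanout_to_mirnas(
            design, {s.host_gene_id: s.p_real}
        ):
            rows.append((host, mirna, target, p, s.sign))
    frame = pd.DataFrame(rows, columns=["host", "mirna", "target", "score", "sign"])
    frame = frame.sort_values(["host", "mirna", "target"], kind="stable").reset_index(
        drop=True
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return frame


def export_surrogacy(reports: Sequence[SurrogacyReport], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            (
                r.host_gene_id,
                r.n_putative,
                r.n_significant,
                r.n_negative,
                r.mean_neglog_p,
                r.pct_negative,
                r.call,
            )
            for r in sorted(reports, key=lambda r: r.host_gene_id)
        ],
        columns=[
            "host",
            "n_putative",
            "n_significant",
            "n_negative",
            "mean_neglog_p",
            "pct_negative",
            "call",
        ],
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
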