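"""Per-dataset weight fitting: ULM (OLS), CLM (NNLS) and the CORR baseline.

The model for one target gene in one dataset is ``d = X w + eps`` with ``d``
the down-regulation vector over S samples, ``X`` the S x M matrix of unit-norm
host profiles and spherical Gaussian noise, so the OLS solution is the maximum
likelihood estimate of ``w``.  No intercept is fitted: ``d`` is already
referenced to the dataset-wide per-sample mean by construction.  A positive
weight means the host's intronic miRNA is predicted to *repress* the target.

Weights are compared across datasets only after rescaling to unit L1 norm
(each coefficient divided by the sum of absolute coefficients), which removes
per-dataset scale so the cross-dataset samples are commensurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

logger = logging.getLogger(__name__)

METHODS = ("ULM", "CLM", "CORR")

#: relative reciprocal-condition threshold below which X'X is treated singular
_RCOND = 1e-10


@dataclass
class WeightVector:
    """Fitted coefficients for one (target, dataset, method).

    ``rescaled`` is ``raw / sum(|raw|)`` or ``None`` when ``raw`` is all-zero
    (the ``degenerate`` flag); degenerate fits are excluded from pooling so
    they do not spike the permutation null at zero.
    """

    target_gene_id: str
    dataset_id: str
    method: str
    host_gene_ids: list[str]
    raw: np.ndarray
    rescaled: np.ndarray | None
    degenerate: bool = False
    flags: tuple[str, ...] = ()

    def residual(self, X: np.ndarray, d: np.ndarray) -> np.ndarray:
        """Model residual d - X @ raw (the implicit noise term)."""
        return np.asarray(d, float) - np.asarray(X, float) @ self.raw


def _check_shapes(X: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    d = np.asarray(d, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D, got shape {X.shape}")
    if d.ndim != 1 or d.shape[0] != X.shape[0]:
        raise ValueError(f"shape mismatch: X is {X.shape}, d has length {d.shape}")
    if X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError(f"need at least one sample and one host, got {X.shape}")
    return X, d


def rescale_l1(raw: np.ndarray) -> tuple[np.ndarray | None, bool]:
    """L1-rescale a weight vector; returns ``(rescaled, degenerate)``.

    All-zero input is degenerate: there is no direction information to keep,
    so no rescaled vector is produced.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.isfinite(raw).all():
        raise ValueError("raw weights must be finite")
    total = float(np.abs(raw).sum())
    if total == 0.0:
        return None, True
    return raw / total, False


def _make_vector(
    raw: np.ndarray,
    method: str,
    host_gene_ids: Sequence[str] | None,
    target_gene_id: str,
    dataset_id: str,
    flags: tuple[str, ...] = (),
) -> WeightVector:
    hosts = (
        list(host_gene_ids)
        if host_gene_ids is not None
        else [f"h{i}" for i in range(raw.shape[0])]
    )
    if len(hosts) != raw.shape[0]:
        raise ValueError("host_gene_ids length does not match coefficient count")
    rescaled, degenerate = rescale_l1(raw)
    return WeightVector(
        target_gene_id=target_gene_id,
        dataset_id=dataset_id,
        method=method,
        host_gene_ids=hosts,
        raw=raw,
        rescaled=rescaled,
        degenerate=degenerate,
        flags=flags,
    )


def fit_ulm(
    X: np.ndarray,
    d: np.ndarray,
    host_gene_ids: Sequence[str] | None = None,
    target_gene_id: str = "",
    dataset_id: str = "",
) -> WeightVector:
    """Ordinary least squares fit of ``d = X w`` (the unconstrained model).

    Solved through the normal equations; when ``X'X`` is singular (fewer
    samples than hosts, collinear hosts) the minimum-norm pseudo-inverse
    solution is used and a warning logged.
    """
    X, d = _check_shapes(X, d)
    xtx = X.T @ X
    xtd = X.T @ d
    flags: tuple[str, ...] = ()
    # 1/cond via SVD: cheap at these sizes and robust to exact singularity
    svals = np.linalg.svd(xtx, compute_uv=False)
    if svals[-1] <= _RCOND * svals[0] or svals[0] == 0.0:
        raw = np.linalg.pinv(X) @ d
        flags = ("singular_minimum_norm",)
        logger.warning(
            "ULM %s/%s: singular X'X, using minimum-norm solution",
            dataset_id,
            target_gene_id,
        )
    else:
        raw = np.linalg.solve(xtx, xtd)
    return _make_vector(raw, "ULM", host_gene_ids, target_gene_id, dataset_id, flags)


def fit_clm(
    X: np.ndarray,
    d: np.ndarray,
    host_gene_ids: Sequence[str] | None = None,
    target_gene_id: str = "",
    dataset_id: str = "",
) -> WeightVector:
    """Non-negative least squares fit (weights constrained to repression)."""
    X, d = _check_shapes(X, d)
    raw, _ = scipy.optimize.nnls(X, d)
    return _make_vector(raw, "CLM", host_gene_ids, target_gene_id, dataset_id)


def fit_corr(
    X: np.ndarray,
    d: np.ndarray,
    host_gene_ids: Sequence[str] | None = None,
    target_gene_id: str = "",
    dataset_id: str = "",
) -> WeightVector:
    """Pearson correlation of each host profile with ``d`` (HOCTAR-like).

    Correlating with the *down-regulation* vector (not raw target expression)
    keeps the sign convention of the linear models: positive means repression.
    Constant columns or a constant ``d`` yield a zero coefficient and a flag.
    """
    X, d = _check_shapes(X, d)
    dc = d - d.mean()
    d_ss = float(dc @ dc)
    raw = np.zeros(X.shape[1])
    flagged = False
    if d_ss > 0.0:
        xc = X - X.mean(axis=0, keepdims=True)
        x_ss = (xc * xc).sum(axis=0)
        ok = x_ss > 0.0
        raw[ok] = (xc[:, ok].T @ dc) / np.sqrt(x_ss[ok] * d_ss)
        flagged = not ok.all()
    else:
        flagged = True
    flags = ("constant_input",) if flagged else ()
    return _make_vector(raw, "CORR", host_gene_ids, target_gene_id, dataset_id, flags)


_FITTERS = {"ULM": fit_ulm, "CLM": fit_clm, "CORR": fit_corr}


def fit(method: str, X: np.ndarray, d: np.ndarray, **kw) -> WeightVector:
    """Dispatch to :func:`fit_ulm` / :func:`fit_clm` / :func:`fit_corr`."""
    try:
        fitter = _FITTERS[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return fitter(X, d, **kw)


class WeightTable:
    """All fitted weight vectors, indexable by (target, host, method).

    Stores one row per coefficient; at most one :class:`WeightVector` may be
    added per (target, dataset, method).
    """

    _COLUMNS = ["method", "dataset", "target", "host", "raw", "rescaled", "degenerate"]

    def __init__(self, vectors: Iterable[WeightVector] = ()) -> None:
        self._rows: list[tuple] = []
        self._keys: set[tuple[str, str, str]] = set()
        for vec in vectors:
            self.add(vec)

    def add(self, vec: WeightVector) -> None:
        key = (vec.target_gene_id, vec.dataset_id, vec.method)
        if key in self._keys:
            raise ValueError(f"duplicate weight vector for {key}")
        self._keys.add(key)
        for i, host in enumerate(vec.host_gene_ids):
            self._rows.append(
                (
                    vec.method,
                    vec.dataset_id,
                    vec.target_gene_id,
                    host,
                    float(vec.raw[i]),
                    float(vec.rescaled[i]) if vec.rescaled is not None else np.nan,
                    vec.degenerate,
                )
            )

    def __len__(self) -> int:
        return len(self._rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=self._COLUMNS)

    def weights_for(
        self, target_gene_id: str, host_gene_id: str, method: str
    ) -> np.ndarray:
        """Cross-dataset rescaled weight sample for one pair (non-degenerate)."""
        out = [
            rescaled
            for (m, _ds, tgt, host, _raw, rescaled, degenerate) in self._rows
            if m == method
            and tgt == target_gene_id
            and host == host_gene_id
            and not degenerate
        ]
        return np.asarray(out, dtype=float)

    def pooled_rescaled(self, method: str) -> np.ndarray:
        """Every non-degenerate rescaled coefficient for one method."""
        return np.asarray(
            [row[5] for row in self._rows if row[0] == method and not row[6]],
            dtype=float,
        )

    def to_tsv(self, path) -> None:
        frame = self.to_frame().drop(columns="degenerate")
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "WeightTable":
        table = cls()
        group_cols = ["target", "dataset", "method"]
        for (target, dataset, method), grp in frame.groupby(group_cols, sort=True):
            raw = grp["raw"].to_numpy(dtype=float)
            table.add(
                _make_vector(raw, method, list(grp["host"]), target, dataset)
            )
        return table
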