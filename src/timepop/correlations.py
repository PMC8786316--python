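"""Pearson-correlation battery on time-normalized, z-scored SDF tensors.

Five modes cover the single-cell and population comparisons used to relate
activity within and across task phases and stimuli:

* ``pairwise_cells`` — correlations between all unit pairs over their
  concatenated stimulus traces (symmetric matrix, diagonal excluded).
* ``population_vector_bins`` — for each stimulus and normalized time bin,
  the across-unit correlation between the measurement population vector and
  the corresponding reproduction population vector.
* ``cell_cross_phase`` — per unit, the correlation of its concatenated
  measurement traces with its concatenated reproduction traces.
* ``population_stimulus_pairs`` — for every stimulus pair, the correlation
  of the full (units x bins) population activity between the two stimuli.
* ``cell_stimulus_pairs`` — the same stimulus-pair correlations computed per
  unit (one entry per unit and pair; the per-unit mean is also reported).

Significance per entry is the standard t-distribution test for a Pearson
correlation, two-sided, with no multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .sdf import SDFTensor

__all__ = ["CorrelationReport", "correlate", "significant_fraction"]

MODES = (
    "pairwise_cells",
    "population_vector_bins",
    "cell_cross_phase",
    "population_stimulus_pairs",
    "cell_stimulus_pairs",
)


@dataclass
class CorrelationReport:
    """Correlations plus per-entry two-sided p-values for one mode.

    ``r`` and ``p`` share a shape; undefined entries (zero variance, or the
    excluded diagonal of ``pairwise_cells``) are NaN and do not enter
    :func:`significant_fraction`.
    """

    mode: str
    r: np.ndarray
    p: np.ndarray
    labels: dict = field(default_factory=dict)

    def significant_fraction(self, alpha: float = 0.05) -> float:
        return significant_fraction(self, alpha)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    n = len(x)
    if n < 3 or x.std() < 1e-12 or y.std() < 1e-12:
        return np.nan, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def _pairwise_cells(a: SDFTensor) -> CorrelationReport:
    X = a.values.reshape(a.n_units, -1)
    n_units, n = X.shape
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    r = np.clip(r, -1.0, 1.0)
    r[sd < 1e-12, :] = np.nan
    r[:, sd < 1e-12] = np.nan
    np.fill_diagonal(r, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.isnan(r)] = np.nan
    return CorrelationReport("pairwise_cells", r, p)


def _population_vector_bins(a: SDFTensor, b: SDFTensor) -> CorrelationReport:
    va, vb = a.values, b.values
    if va.shape != vb.shape:
        raise ValueError("tensors must share shape for population_vector_bins")
    n_s, n_b = va.shape[1], va.shape[2]
    r = np.full((n_s, n_b), np.nan)
    p = np.full((n_s, n_b), np.nan)
    for j in range(n_s):
        for i in range(n_b):
            r[j, i], p[j, i] = _pearson(va[:, j, i], vb[:, j, i])
    return CorrelationReport("population_vector_bins", r, p)


def _cell_cross_phase(a: SDFTensor, b: SDFTensor) -> CorrelationReport:
    va = a.values.reshape(a.n_units, -1)
    vb = b.values.reshape(b.n_units, -1)
    if va.shape != vb.shape:
        raise ValueError("tensors must share shape for cell_cross_phase")
    r = np.full(va.shape[0], np.nan)
    p = np.full(va.shape[0], np.nan)
    for u in range(va.shape[0]):
        r[u], p[u] = _pearson(va[u], vb[u])
    return CorrelationReport("cell_cross_phase", r, p)


def _population_stimulus_pairs(a: SDFTensor) -> CorrelationReport:
    v = a.values
    pairs = list(combinations(range(v.shape[1]), 2))
    r = np.full(len(pairs), np.nan)
    p = np.full(len(pairs), np.nan)
    for k, (j1, j2) in enumerate(pairs):
        r[k], p[k] = _pearson(v[:, j1, :], v[:, j2, :])
    return CorrelationReport("population_stimulus_pairs", r, p, labels={"pairs": pairs})


def _cell_stimulus_pairs(a: SDFTensor) -> CorrelationReport:
    v = a.values
    pairs = list(combinations(range(v.shape[1]), 2))
    r = np.full((v.shape[0], len(pairs)), np.nan)
    p = np.full((v.shape[0], len(pairs)), np.nan)
    for u in range(v.shape[0]):
        for k, (j1, j2) in enumerate(pairs):
            r[u, k], p[u, k] = _pearson(v[u, j1], v[u, j2])
    with np.errstate(invalid="ignore"):
        mean_r = np.nanmean(r, axis=1)
    return CorrelationReport(
        "cell_stimulus_pairs", r, p, labels={"pairs": pairs, "mean_r": mean_r}
    )


def correlate(a: SDFTensor, b: SDFTensor | None = None, mode: str = "pairwise_cells") -> CorrelationReport:
    """Compute one correlation mode on time-normalized SDF tensors."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
    if mode in ("population_vector_bins", "cell_cross_phase"):
        if b is None:
            raise ValueError(f"mode {mode!r} requires two tensors")
        return _population_vector_bins(a, b) if mode == "population_vector_bins" else _cell_cross_phase(a, b)
    if mode == "pairwise_cells":
        return _pairwise_cells(a)
    if mode == "population_stimulus_pairs":
        return _population_stimulus_pairs(a)
    return _cell_stimulus_pairs(a)


def significant_fraction(report: CorrelationReport, alpha: float = 0.05) -> float:
    """Share of defined entries with p < alpha.

    For the symmetric ``pairwise_cells`` matrix each unordered pair counts
    once (upper triangle).
    """
    p = report.p
    if report.mode == "pairwise_cells":
        p = p[np.triu_indices(p.shape[0], k=1)]
    defined = ~np.isnan(p)
    if not defined.any():
        return float("nan")
    return float(np.mean(p[defined] < alpha))
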