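"""Repertoire diversity and between-repertoire similarity.

Diversity is summarized by clonality (one minus Pielou's evenness, the
ratio of observed to maximum Shannon entropy) and by R20, the fraction of
clonotypes — ordered by decreasing frequency — needed to accumulate 20% of
the repertoire mass.  Similarity between repertoires uses the
Jensen–Shannon divergence (base 2, reported as the divergence itself, not
its square root) on clone-frequency or V/J gene-usage distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ContractError, NormalizationError, UndefinedMetricError
from .model import Repertoire

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class DiversityResult:
    """Entropy-family diversity summary of one repertoire."""

    shannon_entropy: float  # base 2 (bits); pielou/clonality are base-invariant
    pielou_index: float
    clonality: float
    n_clonotypes: int


def shannon_entropy(frequencies: np.ndarray, base: float = 2.0) -> float:
    f = np.asarray(frequencies, dtype=np.float64)
    f = f[f > 0]
    return float(-(f * np.log(f)).sum() / math.log(base))


def clonality(repertoire: Repertoire) -> float:
    """1 − Pielou's evenness; 0 for a perfectly even repertoire, 1 for a
    monoclonal one (the S = 1 limit is defined as 1)."""
    return clonality_result(repertoire).clonality


def clonality_result(repertoire: Repertoire) -> DiversityResult:
    s = repertoire.n_clonotypes
    if s == 0:
        raise UndefinedMetricError("clonality of an empty repertoire")
    h = shannon_entropy(repertoire.frequencies)
    if s == 1:
        # 0/0 limit: a monoclonal repertoire is maximally clonal
        return DiversityResult(shannon_entropy=0.0, pielou_index=0.0,
                               clonality=1.0, n_clonotypes=1)
    h_max = math.log2(s)
    pielou = h / h_max
    return DiversityResult(shannon_entropy=h, pielou_index=pielou,
                           clonality=1.0 - pielou, n_clonotypes=s)


def r20(repertoire: Repertoire, mass: float = 0.2) -> float:
    """Fraction of clonotypes (descending frequency) whose cumulative
    frequency first reaches ``mass``.  No fractional interpolation: the
    count k is the smallest integer with cumsum >= mass and k/S is
    returned."""
    if not 0 < mass < 1:
        raise ConfigError("mass must lie in (0, 1)")
    s = repertoire.n_clonotypes
    if s == 0:
        raise UndefinedMetricError("r20 of an empty repertoire")
    freqs = np.sort(repertoire.frequencies)[::-1]
    cum = np.cumsum(freqs)
    # guard against float undershoot at the final element
    cum[-1] = max(cum[-1], 1.0)
    k = int(np.searchsorted(cum, mass - 1e-12)) + 1
    return k / s


def richness(repertoire: Repertoire) -> float:
    """Number of unique clonotypes (useful through downsampled_metric)."""
    return float(repertoire.n_clonotypes)


# ----------------------------------------------------------------------
# Jensen–Shannon divergence
# ----------------------------------------------------------------------


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen–Shannon divergence, base 2, on a shared zero-filled support.

    ``JSD = ½ KL(p‖m) + ½ KL(q‖m)`` with ``m = (p+q)/2`` and ``0·log 0 = 0``.
    Bounded in [0, 1]; 0 iff p = q, 1 for disjoint supports.  Inputs must
    each sum to 1 (callers renormalize explicitly).
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ContractError("p and q must share a common support")
    for name, vec in (("p", p), ("q", q)):
        if (vec < 0).any():
            raise NormalizationError(f"{name} has negative mass")
        if abs(vec.sum() - 1.0) > _NORM_TOL:
            raise NormalizationError(f"{name} sums to {vec.sum()!r}, not 1")
    m = 0.5 * (p + q)
    div = 0.0
    for vec in (p, q):
        pos = vec > 0
        div += 0.5 * float((vec[pos] * np.log2(vec[pos] / m[pos])).sum())
    # clip float jitter at the boundaries
    return min(max(div, 0.0), 1.0)


def _freq_series(repertoire: Repertoire, top_k: int | None) -> pd.Series:
    s = repertoire.df["frequency"]
    if top_k is not None and len(s) > top_k:
        s = s.nlargest(top_k)
    return s


def clone_turnover(baseline: Repertoire, later: Repertoire, top_k: int = 1000) -> float:
    """JSD between the clone-frequency distributions of two repertoires,
    restricted to the union of each repertoire's ``top_k`` most frequent
    clonotypes (absent clones zero-filled, each vector renormalized over
    the union)."""
    if not baseline.same_sample_axis(later):
        raise ContractError("clone_turnover requires the same patient and phenotype")
    support = _freq_series(baseline, top_k).index.union(
        _freq_series(later, top_k).index)
    # full frequencies on the union support; clones absent from a repertoire
    # contribute zero
    pv = baseline.df["frequency"].reindex(support, fill_value=0.0).to_numpy()
    qv = later.df["frequency"].reindex(support, fill_value=0.0).to_numpy()
    return jsd(pv / pv.sum(), qv / qv.sum())


# ----------------------------------------------------------------------
# gene usage
# ----------------------------------------------------------------------

USAGE_AXES = ("V", "J", "VJ")


@dataclass(frozen=True)
class UsageDistribution:
    """Normalized gene (or gene-pair) usage weights for one repertoire."""

    axis: str
    weights: pd.Series  # index: gene or (v, j) pair; values sum to 1


def usage_distribution(
    repertoire: Repertoire,
    axis: str = "VJ",
    weighting: str = "frequency",
) -> UsageDistribution:
    """Aggregate clone mass (default) or clonotype counts per gene/pair."""
    if axis not in USAGE_AXES:
        raise ConfigError(f"axis must be one of {USAGE_AXES}")
    if weighting not in ("frequency", "clonotype"):
        raise ConfigError("weighting must be 'frequency' or 'clonotype'")
    if repertoire.n_clonotypes == 0:
        raise UndefinedMetricError("usage of an empty repertoire")
    df = repertoire.df.reset_index()
    df["_w"] = df["frequency"] if weighting == "frequency" else 1.0
    cols = {"V": ["v_gene"], "J": ["j_gene"], "VJ": ["v_gene", "j_gene"]}[axis]
    weights = df.groupby(cols)["_w"].sum().sort_index()
    if axis != "VJ":
        weights.index = weights.index.get_level_values(0) if isinstance(
            weights.index, pd.MultiIndex) else weights.index
    weights = weights / weights.sum()
    weights.name = None
    return UsageDistribution(axis=axis, weights=weights)


def usage_turnover(baseline: Repertoire, later: Repertoire, axis: str = "VJ",
                   weighting: str = "frequency") -> float:
    """JSD between gene-usage distributions on the unioned support."""
    p = usage_distribution(baseline, axis, weighting).weights
    q = usage_distribution(later, axis, weighting).weights
    support = p.index.union(q.index)
    pv = p.reindex(support, fill_value=0.0).to_numpy()
    qv = q.reindex(support, fill_value=0.0).to_numpy()
    return jsd(pv, qv)


def vj_matrix(repertoire: Repertoire) -> pd.DataFrame:
    """V × J frequency-weighted usage matrix (circos-plot input).

    Row sums equal the V usage distribution and column sums the J usage
    distribution; all entries sum to 1.
    """
    usage = usage_distribution(repertoire, axis="VJ", weighting="frequency").weights
    matrix = usage.unstack(fill_value=0.0)
    matrix.index.name = "v_gene"
    matrix.columns.name = "j_gene"
    return matrix
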