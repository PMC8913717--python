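"""Phenotype ambiguity correction and depth normalization by repeated
downsampling.

Ambiguity correction resolves clonotypes shared between the CD4 and CD8
fractions of the same sample: the clonotype is assigned to the fraction
holding at least twice the other's reads (the boundary counts as assignable)
and removed from both otherwise, after which frequencies are recomputed over
the remaining reads.

Depth normalization subsamples reads uniformly without replacement
(multivariate hypergeometric) to a common target depth; scalar metrics are
reported as the mean over many independent downsampling replicates
(default 1000).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .exceptions import ConfigError, ContractError, DepthError
from .model import Repertoire


@dataclass(frozen=True)
class AmbiguityReport:
    """Outcome counts of one CD4/CD8 ambiguity correction."""

    n_shared: int
    n_assigned_cd4: int
    n_assigned_cd8: int
    n_removed: int
    removed_read_fraction_cd4: float
    removed_read_fraction_cd8: float


def correct_ambiguity(
    cd4: Repertoire,
    cd8: Repertoire,
    *,
    ratio: float = 2.0,
) -> tuple[Repertoire, Repertoire, AmbiguityReport]:
    """Resolve clonotypes present in both phenotype fractions.

    For each shared key: if one fraction has ``>= ratio`` times the other's
    reads it keeps the clonotype (reads unchanged) and the other loses it;
    when neither dominates, the clonotype is removed from both.  Frequencies
    are recomputed over the surviving reads.  Read counts of retained
    clonotypes are never altered.
    """
    if cd4.patient_id != cd8.patient_id or cd4.timepoint != cd8.timepoint \
            or cd4.condition != cd8.condition:
        raise ContractError(
            "ambiguity correction requires matched patient/timepoint/condition: "
            f"{cd4.sample_id} vs {cd8.sample_id}"
        )
    if {cd4.phenotype, cd8.phenotype} != {"CD4", "CD8"}:
        raise ContractError("expected one CD4 and one CD8 repertoire")
    if ratio <= 1:
        raise ConfigError("ambiguity ratio must exceed 1")

    shared = cd4.df.index.intersection(cd8.df.index)
    if len(shared) == 0:
        report = AmbiguityReport(0, 0, 0, 0, 0.0, 0.0)
        return cd4, cd8, report

    r4 = cd4.df.loc[shared, "reads"].to_numpy(dtype=np.float64)
    r8 = cd8.df.loc[shared, "reads"].to_numpy(dtype=np.float64)
    to_cd4 = r4 >= ratio * r8
    to_cd8 = r8 >= ratio * r4
    removed = ~(to_cd4 | to_cd8)

    drop_from_cd4 = shared[to_cd8 | removed]
    drop_from_cd8 = shared[to_cd4 | removed]

    new_cd4 = cd4.drop_keys(drop_from_cd4) if len(drop_from_cd4) else cd4
    new_cd8 = cd8.drop_keys(drop_from_cd8) if len(drop_from_cd8) else cd8

    report = AmbiguityReport(
        n_shared=int(len(shared)),
        n_assigned_cd4=int(to_cd4.sum()),
        n_assigned_cd8=int(to_cd8.sum()),
        n_removed=int(removed.sum()),
        removed_read_fraction_cd4=float(r4[to_cd8 | removed].sum() / cd4.total_reads),
        removed_read_fraction_cd8=float(r8[to_cd4 | removed].sum() / cd8.total_reads),
    )
    return new_cd4, new_cd8, report


# ----------------------------------------------------------------------
# downsampling
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class DownsampleConfig:
    """Replicated-downsampling settings.

    ``target_depth`` may be a positive integer or ``"auto"`` (the minimum
    total read count within the relevant phenotype group, resolved by the
    caller via :func:`group_depth`).
    """

    n_replicates: int = 1000
    target_depth: int | str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if isinstance(self.target_depth, int) and self.target_depth < 1:
            raise ConfigError("target_depth must be positive")


def group_depth(repertoires: Iterable[Repertoire]) -> int:
    """Depth policy: the lowest total read count within the group."""
    depths = [r.total_reads for r in repertoires]
    if not depths:
        raise ConfigError("empty depth group")
    return min(depths)


def _substream(seed: int, sample_id: str, replicate: int) -> np.random.Generator:
    """Deterministic per-(sample, replicate) RNG substream.

    The stream depends only on the master seed, a stable hash of the sample
    identity and the replicate number, so adding samples to a run never
    perturbs existing replicates.
    """
    digest = hashlib.sha256(sample_id.encode("utf-8")).digest()
    sample_hash = int.from_bytes(digest[:8], "big")
    return np.random.Generator(
        np.random.Philox(key=np.uint64(sample_hash ^ (seed & 0xFFFFFFFFFFFFFFFF)),
                         counter=[0, 0, 0, replicate])
    )


def downsample(
    repertoire: Repertoire,
    depth: int,
    rng: np.random.Generator,
) -> Repertoire:
    """Draw ``depth`` reads uniformly without replacement.

    The per-clonotype sampled counts follow the multivariate hypergeometric
    distribution over the original read multiset; clonotypes drawn zero
    times are dropped and frequencies are recomputed over ``depth``.
    """
    total = repertoire.total_reads
    if depth > total:
        raise DepthError(f"depth {depth} exceeds total reads {total}")
    if depth == total:
        return repertoire.with_reads(repertoire.reads)
    counts = rng.multivariate_hypergeometric(repertoire.reads, depth)
    return repertoire.with_reads(counts)


def downsample_replicates(
    repertoire: Repertoire,
    config: DownsampleConfig,
    depth: int | None = None,
) -> Iterable[Repertoire]:
    """Yield ``config.n_replicates`` independent downsampled repertoires."""
    if depth is None:
        if not isinstance(config.target_depth, int):
            raise ConfigError("auto target depth requires an explicit group depth")
        depth = config.target_depth
    for replicate in range(config.n_replicates):
        rng = _substream(config.seed, repertoire.sample_id, replicate)
        yield downsample(repertoire, depth, rng)


def downsampled_metric(
    repertoire: Repertoire,
    metric: Callable[[Repertoire], float],
    config: DownsampleConfig,
    depth: int | None = None,
) -> tuple[float, float]:
    """Mean and SD of ``metric`` across independent downsampling replicates.

    Deterministic (bit-reproducible) for a fixed seed, sample identity and
    replicate count.
    """
    values = np.array(
        [metric(rep) for rep in downsample_replicates(repertoire, config, depth)],
        dtype=np.float64,
    )
    return float(values.mean()), float(values.std(ddof=0))


def downsampled_metrics(
    repertoire: Repertoire,
    metrics: dict[str, Callable[[Repertoire], float]],
    config: DownsampleConfig,
    depth: int | None = None,
) -> dict[str, tuple[float, float]]:
    """Evaluate several metrics on the *same* replicate stream (one pass)."""
    acc: dict[str, list[float]] = {name: [] for name in metrics}
    for rep in downsample_replicates(repertoire, config, depth):
        for name, fn in metrics.items():
            acc[name].append(fn(rep))
    out: dict[str, tuple[float, float]] = {}
    for name, values in acc.items():
        arr = np.asarray(values, dtype=np.float64)
        out[name] = (float(arr.mean()), float(arr.std(ddof=0)))
    return out
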