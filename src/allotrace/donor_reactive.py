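"""Donor-reactive clonotype calling from the pre-transplant MLR pair and
longitudinal tracking through bulk repertoires.

A clonotype is called donor-reactive when its read count in the
MLR-stimulated pre-transplant sample is at least ``threshold`` (default 5)
times its read count in the unstimulated pre-transplant sample.  By default
the fold is computed on depth-normalized reads — both members of the pair
scaled to a common depth, i.e. the replicate-mean of downsampling — so that
library depth does not confound the fold; raw-read folds are available via
``mode="raw"``.  Clonotypes absent from the unstimulated sample (infinite
fold) are included when their normalized stimulated reads reach a
configurable floor (default 2), or excluded outright.

The set is defined once pre-transplant and frozen; tracking reports, per
bulk repertoire, the percentage of clonotypes that are donor-reactive and
their cumulative frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ContractError
from .model import ClonotypeKey, Repertoire, timepoint_rank


@dataclass
class DonorReactiveSet:
    """Frozen per-patient/phenotype set of donor-reactive clonotype keys."""

    patient_id: str
    phenotype: str
    keys: pd.MultiIndex
    fold_threshold: float = 5.0

    @property
    def n_keys(self) -> int:
        return len(self.keys)

    def key_set(self) -> set[ClonotypeKey]:
        return {ClonotypeKey(*k) for k in self.keys}


def call_donor_reactive(
    unstim: Repertoire,
    stim: Repertoire,
    threshold: float = 5.0,
    *,
    mode: str = "normalized",
    absent_rule: str = "include",
    min_stim_reads: float = 2.0,
) -> DonorReactiveSet:
    """Call the donor-reactive set from the pre-transplant bulk/MLR pair.

    Parameters
    ----------
    unstim, stim
        preTx bulk and preTx MLR-stimulated repertoires of the same
        patient and phenotype.
    threshold
        Fold-change cut, applied at equality (``fold >= threshold``).
    mode
        ``"normalized"`` (default) scales both read vectors to the common
        depth ``min(total_unstim, total_stim)`` before computing folds —
        the exact mean over infinitely many without-replacement
        downsampling replicates; ``"raw"`` uses reads as-is.
    absent_rule
        ``"include"`` admits clonotypes absent from the unstimulated sample
        when their (normalized) stimulated reads are >= ``min_stim_reads``;
        ``"exclude"`` drops all such clonotypes.
    """
    if unstim.patient_id != stim.patient_id or unstim.phenotype != stim.phenotype:
        raise ContractError("MLR pair must share patient and phenotype")
    if unstim.timepoint != "preTx" or stim.timepoint != "preTx":
        raise ContractError("donor-reactive calling requires preTx repertoires")
    if unstim.condition != "bulk" or stim.condition != "stimulated":
        raise ContractError("expected (bulk, stimulated) pair in that order")
    if threshold <= 1:
        raise ConfigError("fold threshold must exceed 1")
    if mode not in ("normalized", "raw"):
        raise ConfigError("mode must be 'normalized' or 'raw'")
    if absent_rule not in ("include", "exclude"):
        raise ConfigError("absent_rule must be 'include' or 'exclude'")

    if mode == "normalized":
        depth = float(min(unstim.total_reads, stim.total_reads))
        scale_u = depth / unstim.total_reads
        scale_s = depth / stim.total_reads
    else:
        scale_u = scale_s = 1.0

    stim_reads = stim.df["reads"] * scale_s
    unstim_reads = unstim.df["reads"] * scale_u

    shared = stim.df.index.intersection(unstim.df.index)
    folds = stim_reads.loc[shared] / unstim_reads.loc[shared]
    called = shared[folds.to_numpy() >= threshold]

    if absent_rule == "include":
        absent = stim.df.index.difference(unstim.df.index)
        passing = absent[stim_reads.loc[absent].to_numpy() >= min_stim_reads]
        called = called.append(passing)

    called = called.sort_values()
    return DonorReactiveSet(
        patient_id=unstim.patient_id,
        phenotype=unstim.phenotype,
        keys=called,
        fold_threshold=threshold,
    )


@dataclass(frozen=True)
class TrackingRecord:
    """Donor-reactive share of one bulk repertoire."""

    patient_id: str
    phenotype: str
    timepoint: str
    pct_clonotypes_donor_reactive: float
    cum_freq_donor_reactive: float


def track_donor_reactive(reactive: DonorReactiveSet, bulk: Repertoire) -> TrackingRecord:
    """Percentage of bulk clonotypes that are donor-reactive and their
    cumulative frequency (both on the 0–100 scale)."""
    if bulk.patient_id != reactive.patient_id or bulk.phenotype != reactive.phenotype:
        raise ContractError("tracking requires the same patient and phenotype")
    hit = bulk.df.index.intersection(reactive.keys)
    pct = 100.0 * len(hit) / bulk.n_clonotypes
    cum = 100.0 * float(bulk.df.loc[hit, "frequency"].sum()) if len(hit) else 0.0
    return TrackingRecord(
        patient_id=bulk.patient_id,
        phenotype=bulk.phenotype,
        timepoint=bulk.timepoint,
        pct_clonotypes_donor_reactive=pct,
        cum_freq_donor_reactive=cum,
    )


def tracking_fraction(reactive: DonorReactiveSet, bulk: Repertoire) -> float:
    """Scalar metric adapter: pct of clonotypes donor-reactive (for
    downsampled_metric)."""
    return track_donor_reactive(reactive, bulk).pct_clonotypes_donor_reactive


def tracking_mass(reactive: DonorReactiveSet, bulk: Repertoire) -> float:
    """Scalar metric adapter: cumulative donor-reactive frequency (%)"""
    return track_donor_reactive(reactive, bulk).cum_freq_donor_reactive


def delta_table(
    records: pd.DataFrame,
    *,
    value: str,
    post_policy: str = "first_post",
) -> pd.DataFrame:
    """Per-patient pre-to-post change of a tracking metric.

    ``records`` is a long table with columns ``patient_id, group,
    phenotype, timepoint`` and the metric column ``value``.  The post value
    is the first post-transplant timepoint (M1; ``post_policy="first_post"``)
    or the mean over all post timepoints (``"mean_post"``).  Patients with
    no preTx row are excluded.  Returns one row per patient/phenotype with
    pre, post and delta plus group labels.
    """
    if post_policy not in ("first_post", "mean_post"):
        raise ConfigError("post_policy must be 'first_post' or 'mean_post'")
    rows = []
    for (patient, phenotype), sub in records.groupby(["patient_id", "phenotype"]):
        pre = sub[sub["timepoint"] == "preTx"]
        post = sub[sub["timepoint"] != "preTx"]
        if len(pre) == 0 or len(post) == 0:
            continue
        pre_value = float(pre[value].iloc[0])
        if post_policy == "first_post":
            post = post.iloc[np.argsort([timepoint_rank(t) for t in post["timepoint"]])]
            post_value = float(post[value].iloc[0])
        else:
            post_value = float(post[value].mean())
        rows.append(
            {
                "patient_id": patient,
                "group": sub["group"].iloc[0] if "group" in sub else "",
                "phenotype": phenotype,
                "pre": pre_value,
                "post": post_value,
                "delta": post_value - pre_value,
            }
        )
    return pd.DataFrame(rows)


def delta_summary(deltas: pd.DataFrame) -> pd.DataFrame:
    """Group-level mean ± SD of pre, post and delta per phenotype."""
    out = (
        deltas.groupby(["group", "phenotype"])[["pre", "post", "delta"]]
        .agg(["mean", "std"])
    )
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()
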