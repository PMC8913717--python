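"""End-to-end orchestration: ingest -> ambiguity-correct -> call
donor-reactive -> downsample-and-measure -> annotate -> test.

One :class:`RunConfig` drives the whole run; every source of randomness
flows from its single seed, so identical config + seed yields byte-identical
output tables.  Outputs are long-format TSV, one metric family per file,
ready to be plotted without recomputation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from functools import partial
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .diversity import clonality, clone_turnover, r20, richness, usage_turnover, vj_matrix
from .donor_reactive import (
    DonorReactiveSet,
    call_donor_reactive,
    delta_table,
    tracking_fraction,
    tracking_mass,
)
from .exceptions import ConfigError
from .io import CohortManifest, read_manifest, read_specificity_table
from .model import PHENOTYPES, Repertoire, timepoint_rank
from .preprocessing import (
    DownsampleConfig,
    correct_ambiguity,
    downsample_replicates,
    downsampled_metrics,
    group_depth,
)
from .specificity import annotate, key_mass, matched_keys, specific_mass
from .stats import headline_contrasts, t_test

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from YAML."""

    manifest: str
    out_dir: str
    specificity: str | None = None
    n_replicates: int = 1000
    seed: int = 0
    fold_threshold: float = 5.0
    fold_mode: str = "normalized"
    absent_rule: str = "include"
    min_stim_reads: float = 2.0
    ambiguity_ratio: float = 2.0
    top_k: int = 1000
    post_policy: str = "first_post"
    correction: str = "auto"
    depth_policy: str = "pooled"  # "pooled" | "per_patient"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # hash identifies the analysis, not its location
        blob = yaml.safe_dump(payload, sort_keys=True).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        if self.fold_threshold <= 1:
            raise ConfigError("fold_threshold must exceed 1")
        if self.depth_policy not in ("pooled", "per_patient"):
            raise ConfigError("depth_policy must be 'pooled' or 'per_patient'")
        if not Path(self.manifest).exists():
            raise ConfigError(f"manifest not found: {self.manifest}")
        if self.specificity is not None and not Path(self.specificity).exists():
            raise ConfigError(f"specificity table not found: {self.specificity}")


@dataclass
class RunProvenance:
    config_hash: str
    seed: int
    version: str
    n_samples: int
    per_stage_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


@dataclass
class PipelineResult:
    """In-memory view of the output bundle."""

    metrics: pd.DataFrame          # long: metric, patient, group, phen, tp, mean, sd
    tracking: pd.DataFrame         # donor-reactive tracking (Fig 6 data)
    turnover: pd.DataFrame         # JSD vs baseline (Fig 4 data)
    specificity: pd.DataFrame      # per-species virus mass
    deltas: pd.DataFrame
    reactive_sets: dict[tuple[str, str], DonorReactiveSet]
    reports: list
    provenance: RunProvenance


def _load_cohort(manifest: CohortManifest,
                 repertoires: dict | None = None) -> dict[tuple, Repertoire]:
    """Load every manifest row (or adopt pre-loaded repertoires)."""
    if repertoires is not None:
        return dict(repertoires)
    loaded: dict[tuple, Repertoire] = {}
    for row in manifest.rows().itertuples(index=False):
        key = (row.patient_id, row.timepoint, row.phenotype, row.condition)
        loaded[key] = manifest.load(*key)
    return loaded


def run_pipeline(
    config: RunConfig,
    *,
    repertoires: dict[tuple, Repertoire] | None = None,
    write: bool = True,
) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    ``repertoires`` may inject pre-loaded samples (keyed by
    ``(patient, timepoint, phenotype, condition)``) to skip file ingestion;
    the manifest still provides the cohort structure.
    """
    config.validate()
    manifest = read_manifest(config.manifest)
    warnings: list[str] = []
    samples = _load_cohort(manifest, repertoires)

    # ------------------------------------------------------------------
    # stage: ambiguity correction (full-depth, before any downsampling)
    # ------------------------------------------------------------------
    n_in = sum(rep.n_clonotypes for rep in samples.values())
    axes = {(p, t, c) for (p, t, _ph, c) in samples}
    n_removed_pairs = 0
    for patient, timepoint, condition in sorted(axes):
        k4 = (patient, timepoint, "CD4", condition)
        k8 = (patient, timepoint, "CD8", condition)
        if k4 in samples and k8 in samples:
            cd4, cd8, report = correct_ambiguity(
                samples[k4], samples[k8], ratio=config.ambiguity_ratio)
            samples[k4], samples[k8] = cd4, cd8
            n_removed_pairs += report.n_removed
    n_out = sum(rep.n_clonotypes for rep in samples.values())
    assert n_out <= n_in, "ambiguity correction must never add clonotypes"

    # ------------------------------------------------------------------
    # stage: depth groups
    # ------------------------------------------------------------------
    def depth_for(key: tuple) -> int:
        patient, _tp, phenotype, condition = key
        members = [
            rep for k, rep in samples.items()
            if k[2] == phenotype and k[3] == condition
            and (config.depth_policy == "pooled" or k[0] == patient)
        ]
        return group_depth(members)

    ds_config = DownsampleConfig(n_replicates=config.n_replicates, seed=config.seed)

    # ------------------------------------------------------------------
    # stage: donor-reactive calling (frozen from the preTx pair)
    # ------------------------------------------------------------------
    reactive_sets: dict[tuple[str, str], DonorReactiveSet] = {}
    for patient in manifest.patients:
        for phenotype in PHENOTYPES:
            ku = (patient, "preTx", phenotype, "bulk")
            ks = (patient, "preTx", phenotype, "stimulated")
            if ku not in samples or ks not in samples:
                continue
            reactive_sets[(patient, phenotype)] = call_donor_reactive(
                samples[ku], samples[ks], config.fold_threshold,
                mode=config.fold_mode, absent_rule=config.absent_rule,
                min_stim_reads=config.min_stim_reads)

    # ------------------------------------------------------------------
    # stage: specificity database
    # ------------------------------------------------------------------
    db = read_specificity_table(config.specificity) if config.specificity else None
    species = sorted({r.antigen_species for r in db}) if db else []
    if db is None:
        warnings.append("specificity stage skipped: no table supplied")

    # ------------------------------------------------------------------
    # stage: downsampled per-sample metrics
    # ------------------------------------------------------------------
    metric_rows: list[dict] = []
    tracking_rows: list[dict] = []
    spec_rows: list[dict] = []
    bulk_keys = sorted(
        (k for k in samples if k[3] == "bulk"),
        key=lambda k: (k[0], timepoint_rank(k[1]), k[2]),
    )
    for key in bulk_keys:
        patient, timepoint, phenotype, _ = key
        rep = samples[key]
        depth = depth_for(key)
        group = manifest.group_of(patient)
        metrics = {"clonality": clonality, "r20": r20, "clonotype_count": richness}
        reactive = reactive_sets.get((patient, phenotype))
        if reactive is not None:
            metrics["pct_clonotypes"] = partial(tracking_fraction, reactive)
            metrics["cum_freq"] = partial(tracking_mass, reactive)
        for sp in species:
            # keys are invariant under subsampling: match once at full depth
            metrics[f"{sp}_mass"] = partial(key_mass, matched_keys(rep, db, sp))
        values = downsampled_metrics(rep, metrics, ds_config, depth)
        base = {"patient_id": patient, "group": group, "phenotype": phenotype,
                "timepoint": timepoint}
        for name in ("clonality", "r20", "clonotype_count"):
            mean, sd = values[name]
            metric_rows.append({**base, "metric": name, "mean": mean, "sd": sd})
        if reactive is not None:
            tracking_rows.append({
                **base,
                "pct_clonotypes": values["pct_clonotypes"][0],
                "pct_clonotypes_sd": values["pct_clonotypes"][1],
                "cum_freq": values["cum_freq"][0],
                "cum_freq_sd": values["cum_freq"][1],
            })
        labels = annotate(rep, db) if db else None
        for sp in species:
            n_matched = sum(sp in s for s in labels)
            spec_rows.append({
                **base, "antigen_species": sp,
                "n_clonotypes": int(n_matched),
                "cum_freq": values[f"{sp}_mass"][0],
                "cum_freq_sd": values[f"{sp}_mass"][1],
            })

    metric_table = pd.DataFrame(metric_rows)
    tracking = pd.DataFrame(tracking_rows)
    spec_table = pd.DataFrame(spec_rows)

    # ------------------------------------------------------------------
    # stage: turnover vs baseline (paired downsampling replicate streams)
    # ------------------------------------------------------------------
    turnover_rows: list[dict] = []
    for patient in manifest.patients:
        for phenotype in PHENOTYPES:
            kb = (patient, "preTx", phenotype, "bulk")
            if kb not in samples:
                continue
            baseline = samples[kb]
            for timepoint in ("M1", "M3", "M12"):
                kt = (patient, timepoint, phenotype, "bulk")
                if kt not in samples:
                    continue
                later = samples[kt]
                depth = min(depth_for(kb), depth_for(kt))
                clone_vals, vj_vals = [], []
                for b_rep, l_rep in zip(
                        downsample_replicates(baseline, ds_config, depth),
                        downsample_replicates(later, ds_config, depth)):
                    clone_vals.append(clone_turnover(b_rep, l_rep, config.top_k))
                    vj_vals.append(usage_turnover(b_rep, l_rep, axis="VJ"))
                turnover_rows.append({
                    "patient_id": patient,
                    "group": manifest.group_of(patient),
                    "phenotype": phenotype,
                    "timepoint": timepoint,
                    "jsd_top_clones": float(np.mean(clone_vals)),
                    "jsd_top_clones_sd": float(np.std(clone_vals)),
                    "jsd_vj_usage": float(np.mean(vj_vals)),
                    "jsd_vj_usage_sd": float(np.std(vj_vals)),
                })
    turnover = pd.DataFrame(turnover_rows)

    # ------------------------------------------------------------------
    # stage: statistics battery
    # ------------------------------------------------------------------
    metric_tables = {
        name: metric_table[metric_table["metric"] == name]
        for name in ("clonality", "r20")
    }
    if len(turnover):
        jsd_tab = turnover.rename(columns={"jsd_top_clones": "mean"})
        metric_tables["jsd_vs_baseline"] = jsd_tab
    reports = []
    deltas = pd.DataFrame()
    if len(tracking):
        reports = headline_contrasts(
            tracking, metric_tables,
            spec_table if len(spec_table) else None,
            post_policy=config.post_policy, correction=config.correction)
        deltas = pd.concat(
            [
                delta_table(tracking[tracking["phenotype"] == ph],
                            value=value, post_policy=config.post_policy)
                .assign(phenotype=ph, value=value)
                for ph in sorted(tracking["phenotype"].unique())
                for value in ("pct_clonotypes", "cum_freq")
            ],
            ignore_index=True,
        )
        if db is not None:
            reports.extend(_enrichment_contrasts(samples, reactive_sets, db, manifest))

    provenance = RunProvenance(
        config_hash=config.config_hash(),
        seed=config.seed,
        version=__version__,
        n_samples=len(samples),
        per_stage_counts={
            "clonotypes_ingested": n_in,
            "clonotypes_after_ambiguity": n_out,
            "ambiguous_removed": n_removed_pairs,
            "reactive_sets": len(reactive_sets),
            "bulk_samples": len(bulk_keys),
        },
        warnings=warnings,
    )

    result = PipelineResult(
        metrics=metric_table, tracking=tracking, turnover=turnover,
        specificity=spec_table, deltas=deltas, reactive_sets=reactive_sets,
        reports=reports, provenance=provenance)
    if write:
        _write_bundle(result, samples, Path(config.out_dir))
    return result


def _enrichment_contrasts(samples, reactive_sets, db, manifest):
    """Paired t of per-antigen mass: donor-reactive repertoire vs preTx bulk."""
    from .stats import ContrastReport

    reports = []
    for phenotype in PHENOTYPES:
        for sp in sorted({r.antigen_species for r in db}):
            bulk_vals, reactive_vals = [], []
            for patient in manifest.patients:
                key = (patient, phenotype)
                ks = (patient, "preTx", phenotype, "stimulated")
                kb = (patient, "preTx", phenotype, "bulk")
                if key not in reactive_sets or ks not in samples or kb not in samples:
                    continue
                reactive = reactive_sets[key]
                if reactive.n_keys == 0:
                    continue
                try:
                    dr_rep = samples[ks].subset(reactive.keys)
                except Exception:
                    continue
                reactive_vals.append(specific_mass(dr_rep, db, sp))
                bulk_vals.append(specific_mass(samples[kb], db, sp))
            if len(bulk_vals) >= 2:
                res = t_test(bulk_vals, reactive_vals, paired=True)
                reports.append(ContrastReport(
                    name=f"{phenotype} {sp} mass: bulk vs donor-reactive (paired)",
                    kind="paired_t", result=res))
    return reports


def _write_bundle(result: PipelineResult, samples, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)

    def dump(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out_dir / name, sep="\t", index=False, float_format=_FLOAT_FMT)

    metrics = result.metrics
    dump(metrics[metrics["metric"] == "clonotype_count"], "clonotype_counts.tsv")
    dump(metrics[metrics["metric"] == "clonality"], "clonality.tsv")
    dump(metrics[metrics["metric"] == "r20"], "r20.tsv")
    dump(result.turnover, "jsd_turnover.tsv")
    dump(result.tracking, "donor_reactive_tracking.tsv")
    if len(result.specificity):
        dump(result.specificity, "specificity_summary.tsv")
    if len(result.deltas):
        dump(result.deltas, "donor_reactive_deltas.tsv")

    vj_dir = out_dir / "vj_matrices"
    vj_dir.mkdir(exist_ok=True)
    for key in sorted(k for k in samples if k[3] == "bulk"):
        rep = samples[key]
        matrix = vj_matrix(rep)
        matrix.to_csv(vj_dir / (rep.sample_id.replace("|", "_") + ".tsv"),
                      sep="\t", float_format=_FLOAT_FMT)

    keys_dir = out_dir / "reactive_keys"
    keys_dir.mkdir(exist_ok=True)
    for (patient, phenotype), reactive in sorted(result.reactive_sets.items()):
        pd.DataFrame(list(reactive.keys), columns=["cdr3_nt", "v_gene", "j_gene"]) \
            .to_csv(keys_dir / f"{patient}_{phenotype}.tsv", sep="\t", index=False)

    with open(out_dir / "stats_report.txt", "w", encoding="utf-8") as fh:
        for report in result.reports:
            fh.write(report.format() + "\n")

    with open(out_dir / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(result.provenance), fh, indent=2, sort_keys=True)
        fh.write("\n")
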