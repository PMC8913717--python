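"""Synthetic cohort generator with programmed ground truth.

Emits a complete cohort — manifest plus one clonotype table per
patient × timepoint × phenotype × condition — whose every planted effect
(donor-reactive set and its post-transplant expansion, virus-specific
clonotype mass, persistence/turnover, group-specific lymphodepletion,
CD4/CD8 cross-contamination) is recorded in a :class:`GroundTruth` object
so the analysis pipeline can be validated against known truth.

Latent clone frequencies follow a heavy-tailed law (Zipf by default); reads
are drawn multinomially at a per-sample depth, with every latent clone
floored at one read so the emitted unique-clonotype count is controlled
exactly (the configured count ranges default to a 1:10 scale-down of
realistic CD4/CD8 repertoire sizes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError
from .genes import (
    CODON_TABLE,
    SENSE_CODONS,
    TRBD_GENES,
    TRBJ_GENES,
    TRBV_GENES,
    reverse_translate,
)
from .io import (
    CohortManifest,
    SpecificityRecord,
    write_clonotype_table,
    write_manifest,
    write_specificity_table,
)
from .model import Repertoire

POST_TIMEPOINTS = ("M1", "M3", "M12")

# ----------------------------------------------------------------------
# toy specificity database (deterministic, ships with the package)
# ----------------------------------------------------------------------

_CMV_CDR3 = (
    "CASSLAPGATNEKLFF", "CASSPQRNTEAFF", "CASSLEGYTEAFF", "CASSIRSSYEQYF",
    "CASSPDRVGQETQYF", "CASSLVGDGYTF", "CASSYQGGNYGYTF", "CASSLTGGRNQPQHF",
    "CASRDWDYTDTQYF", "CASSPGQEAKNIQYF", "CASSFHGFNQPQHF", "CASSLGQAYEQYF",
)
_EBV_CDR3 = (
    "CASSQSPGGTQYF", "CASSLGHRDSSYEQYF", "CSARDGTGNGYTF", "CASSPGDEQFF",
    "CASSSRSSYNEQFF", "CASSLLGWTEAFF", "CASSDSGYNEQFF", "CASSYSTGDEQYF",
    "CASSARSGELFF", "CASSPTGGELFF", "CASSQEGPYNSPLHF", "CASSLNRGQETQYF",
)
_OTHER_CDR3 = (
    "CASSDTSGSTDTQYF", "CASSEARTRAFF", "CASSPLSGSYNEQFF",
    "CASSYGGEGYTF", "CASRGDSSYEQYF", "CASSLRDRVNTEAFF",
)


def toy_specificity_records() -> list[SpecificityRecord]:
    """30-record deterministic VDJdb-style toy table (CMV/EBV/InfluenzaA)."""
    records = [SpecificityRecord(c, "CMV") for c in _CMV_CDR3]
    records += [SpecificityRecord(c, "EBV") for c in _EBV_CDR3]
    records += [SpecificityRecord(c, "InfluenzaA") for c in _OTHER_CDR3]
    return records


# ----------------------------------------------------------------------
# cohort specification
# ----------------------------------------------------------------------


def _default_count_range() -> dict[str, tuple[int, int]]:
    # 1:10 scale-down of realistic CD4/CD8 unique clonotype count ranges
    return {"CD4": (2633, 10773), "CD8": (719, 8753)}


def _default_multipliers() -> dict[str, dict[str, float]]:
    mult = {"M1": 2.0, "M3": 1.8, "M12": 1.6}
    return {"ATLG": dict(mult), "basiliximab": dict(mult)}


def _default_virus_fraction() -> dict[str, float]:
    return {"CMV": 0.002, "EBV": 0.002}


@dataclass
class CohortSpec:
    """Knobs of the synthetic cohort generator."""

    n_patients_per_group: int = 5
    timepoints: tuple[str, ...] = ("preTx",) + POST_TIMEPOINTS
    clonotype_count_range: dict[str, tuple[int, int]] = field(
        default_factory=_default_count_range)
    clone_size_law: tuple = ("zipf", 1.2)  # or ("lognormal", mu, sigma)
    donor_reactive_fraction: float = 0.01
    reactive_fold_log_mean: float = math.log(15.0)
    reactive_fold_log_sd: float = 0.3
    reactive_fold_floor: float = 10.0
    bystander_fold_log_sd: float = 0.25
    post_tx_reactive_multiplier: dict[str, dict[str, float]] = field(
        default_factory=_default_multipliers)
    persistence_prob: float = 0.85
    drift_log_sd: float = 0.3
    depletion_depth_factor: float = 0.25  # ATLG M1 sequencing-depth multiplier
    ambiguity_contamination_rate: float = 0.005
    virus_specific_fraction: dict[str, float] = field(
        default_factory=_default_virus_fraction)
    reads_per_clonotype: int = 15
    dominant_clone: bool = False  # plant a persistent >10% clone per patient
    seed: int = 0

    def validate(self) -> None:
        for phenotype, (lo, hi) in self.clonotype_count_range.items():
            if lo < 1 or hi < lo:
                raise ConfigError(f"bad clonotype range for {phenotype}")
            if self.donor_reactive_fraction * lo < 1:
                raise ConfigError(
                    "infeasible spec: donor_reactive_fraction x count < 1")
        if not 0 <= self.persistence_prob <= 1:
            raise ConfigError("persistence_prob must be in [0,1]")
        if not 0 <= self.ambiguity_contamination_rate <= 1:
            raise ConfigError("contamination rate must be in [0,1]")
        if self.reactive_fold_floor <= 1:
            raise ConfigError("reactive folds must exceed 1")

    @property
    def patients(self) -> list[tuple[str, str]]:
        atlg = [(f"P{i + 1:02d}", "ATLG") for i in range(self.n_patients_per_group)]
        basi = [(f"P{i + 1 + self.n_patients_per_group:02d}", "basiliximab")
                for i in range(self.n_patients_per_group)]
        return atlg + basi


@dataclass
class GroundTruth:
    """Planted truth for every quantity the pipeline estimates."""

    reactive_keys: dict[tuple[str, str], pd.MultiIndex]
    virus_keys: dict[tuple[str, str, str], pd.MultiIndex]
    sample_truth: pd.DataFrame  # one row per bulk sample: realized planted masses
    spec: CohortSpec

    def true_delta(self, phenotype: str, value: str = "reactive_mass",
                   post: str = "M1") -> float:
        """Cohort-mean latent pre-to-post change of a truth column."""
        df = self.sample_truth
        df = df[df["phenotype"] == phenotype]
        pre = df[df["timepoint"] == "preTx"].set_index("patient_id")[value]
        later = df[df["timepoint"] == post].set_index("patient_id")[value]
        return float((later - pre.loc[later.index]).mean())


# ----------------------------------------------------------------------
# low-level draws
# ----------------------------------------------------------------------


def _draw_cdr3s(rng: np.random.Generator, n: int) -> tuple[list[str], list[str]]:
    """n random in-frame CDR3s, 30–54 nt in codon steps, plus translations."""
    codons = np.asarray(SENSE_CODONS)
    aa_of = np.asarray([CODON_TABLE[c] for c in SENSE_CODONS])
    lengths = rng.integers(10, 19, size=n)  # codons
    idx = rng.integers(0, len(codons), size=int(lengths.sum()))
    bounds = np.cumsum(lengths)[:-1]
    nt = ["".join(part) for part in np.split(codons[idx], bounds)]
    aa = ["".join(part) for part in np.split(aa_of[idx], bounds)]
    return nt, aa


def _clone_weights(rng: np.random.Generator, law: tuple, s: int) -> np.ndarray:
    if law[0] == "zipf":
        w = np.arange(1, s + 1, dtype=np.float64) ** (-float(law[1]))
    elif law[0] == "lognormal":
        w = rng.lognormal(float(law[1]), float(law[2]), size=s)
    else:
        raise ConfigError(f"unknown clone size law {law[0]!r}")
    rng.shuffle(w)
    return w / w.sum()


def _sample_reads(rng: np.random.Generator, freqs: np.ndarray, depth: int) -> np.ndarray:
    """Multinomial read draw with a one-read floor so every latent clone is
    observed (pins the emitted unique-clonotype count)."""
    counts = rng.multinomial(depth, freqs / freqs.sum())
    return counts + (counts == 0)


# ----------------------------------------------------------------------
# generator
# ----------------------------------------------------------------------


@dataclass
class _Latent:
    """Latent clone pool of one patient/phenotype."""

    frame: pd.DataFrame  # cdr3_nt, cdr3_aa, v_gene, d_gene, j_gene
    base_weight: np.ndarray
    reactive: np.ndarray  # boolean mask
    virus: dict[str, np.ndarray]  # species -> boolean mask


def _build_latent(rng: np.random.Generator, spec: CohortSpec,
                  phenotype: str) -> _Latent:
    lo, hi = spec.clonotype_count_range[phenotype]
    margin = int(math.ceil(spec.ambiguity_contamination_rate * hi)) + 1
    s = int(rng.integers(lo, max(lo + 1, hi - margin)))
    nt, aa = _draw_cdr3s(rng, s)
    v_usage = rng.dirichlet(np.ones(len(TRBV_GENES)))
    j_usage = rng.dirichlet(np.ones(len(TRBJ_GENES)))
    frame = pd.DataFrame(
        {
            "cdr3_nt": nt,
            "cdr3_aa": aa,
            "v_gene": rng.choice(TRBV_GENES, size=s, p=v_usage),
            "d_gene": rng.choice(TRBD_GENES, size=s),
            "j_gene": rng.choice(TRBJ_GENES, size=s, p=j_usage),
        }
    )
    weights = _clone_weights(rng, spec.clone_size_law, s)
    if spec.dominant_clone:
        top = int(rng.integers(0, s))
        weights = weights * (1 - 0.12) / weights.sum()
        weights[top] += 0.12
    weights = weights / weights.sum()

    # planted reactive clones must be robustly detectable: expected unstim
    # reads >= 20 (Poisson noise cannot push the measured fold below the
    # threshold) but frequency-capped to bound per-patient mass variance
    depth = spec.reads_per_clonotype * s
    eligible = (weights >= 20.0 / depth) & (weights <= 0.01)
    n_reactive = max(1, round(spec.donor_reactive_fraction * s))
    pool = np.flatnonzero(eligible)
    if len(pool) < n_reactive:
        pool = np.argsort(weights)[::-1][: max(n_reactive * 2, 10)]
    reactive = np.zeros(s, dtype=bool)
    reactive[rng.choice(pool, size=n_reactive, replace=False)] = True

    virus: dict[str, np.ndarray] = {}
    db = {"CMV": list(_CMV_CDR3), "EBV": list(_EBV_CDR3)}
    taken = reactive.copy()
    for species, fraction in spec.virus_specific_fraction.items():
        seqs = db.get(species, [])
        n_vs = min(len(seqs), max(1, round(fraction * s)))
        candidates = np.flatnonzero(~taken & (weights >= 1.0 / depth))
        chosen = rng.choice(candidates, size=n_vs, replace=False)
        mask = np.zeros(s, dtype=bool)
        mask[chosen] = True
        for rank, clone in enumerate(chosen):
            frame.loc[clone, "cdr3_aa"] = seqs[rank]
            frame.loc[clone, "cdr3_nt"] = reverse_translate(seqs[rank])
        taken |= mask
        virus[species] = mask
    return _Latent(frame=frame, base_weight=weights, reactive=reactive, virus=virus)


def _key_index(frame: pd.DataFrame, mask: np.ndarray) -> pd.MultiIndex:
    sub = frame.loc[np.flatnonzero(mask), ["cdr3_nt", "v_gene", "j_gene"]]
    return pd.MultiIndex.from_frame(sub)


class _PatientSimulator:
    """Draws every sample of one patient from its latent clone pools."""

    def __init__(self, rng: np.random.Generator, spec: CohortSpec,
                 patient_id: str, group: str):
        self.rng = rng
        self.spec = spec
        self.patient_id = patient_id
        self.group = group
        self.latent = {p: _build_latent(rng, spec, p) for p in ("CD4", "CD8")}

    # -- frequency vectors -------------------------------------------------
    def _bulk_weights(self, phenotype: str, timepoint: str) -> tuple[pd.DataFrame, np.ndarray]:
        lat = self.latent[phenotype]
        s = len(lat.frame)
        if timepoint == "preTx":
            return lat.frame, lat.base_weight.copy()
        rng = self.rng
        spec = self.spec
        drift = rng.lognormal(0.0, spec.drift_log_sd, size=s)
        weights = lat.base_weight * drift
        mult = spec.post_tx_reactive_multiplier[self.group].get(timepoint, 1.0)
        weights[lat.reactive] *= mult
        survive = lat.reactive | (rng.random(s) < spec.persistence_prob)
        lost = int((~survive).sum())
        weights[~survive] = 0.0
        frame = lat.frame
        if lost:
            # repertoire turnover: lost clones replaced by novel low-frequency ones
            nt, aa = _draw_cdr3s(rng, lost)
            novel = pd.DataFrame(
                {
                    "cdr3_nt": nt,
                    "cdr3_aa": aa,
                    "v_gene": rng.choice(TRBV_GENES, size=lost),
                    "d_gene": rng.choice(TRBD_GENES, size=lost),
                    "j_gene": rng.choice(TRBJ_GENES, size=lost),
                }
            )
            tail = np.sort(lat.base_weight)[: max(1, s // 2)]
            novel_w = rng.choice(tail, size=lost, replace=True)
            frame = pd.concat([lat.frame, novel], ignore_index=True)
            weights = np.concatenate([weights, novel_w])
        keep = weights > 0
        return frame.loc[keep].reset_index(drop=True), weights[keep]

    def _stim_weights(self, phenotype: str) -> tuple[pd.DataFrame, np.ndarray]:
        lat = self.latent[phenotype]
        s = len(lat.frame)
        rng = self.rng
        spec = self.spec
        folds = rng.lognormal(0.0, spec.bystander_fold_log_sd, size=s)
        reactive_folds = np.maximum(
            rng.lognormal(spec.reactive_fold_log_mean, spec.reactive_fold_log_sd,
                          size=int(lat.reactive.sum())),
            spec.reactive_fold_floor,
        )
        folds[lat.reactive] = reactive_folds
        weights = lat.base_weight * folds
        weights = weights / weights.sum()
        depth = spec.reads_per_clonotype * s
        keep = lat.reactive | (weights >= 0.5 / depth)
        return lat.frame.loc[keep].reset_index(drop=True), weights[keep]

    # -- assembled samples -------------------------------------------------
    def sample(self, phenotype: str, timepoint: str, condition: str,
               pool: tuple[pd.DataFrame, np.ndarray] | None = None,
               contamination: tuple[pd.DataFrame, np.ndarray] | None = None,
               ) -> tuple[Repertoire, dict[str, float]]:
        spec = self.spec
        if pool is not None:
            frame, weights = pool
            frame, weights = frame.copy(), weights.copy()
        elif condition == "stimulated":
            frame, weights = self._stim_weights(phenotype)
        else:
            frame, weights = self._bulk_weights(phenotype, timepoint)
        if contamination is not None and condition == "bulk":
            other_frame, other_weights = contamination
            m = max(1, round(spec.ambiguity_contamination_rate * len(frame)))
            order = np.argsort(other_weights)[::-1][:m]
            inject = other_frame.loc[order].reset_index(drop=True)
            inject_w = np.full(m, spec.ambiguity_contamination_rate / m * weights.sum())
            frame = pd.concat([frame, inject], ignore_index=True)
            weights = np.concatenate([weights, inject_w])
        freqs = weights / weights.sum()
        depth = spec.reads_per_clonotype * len(self.latent[phenotype].frame)
        if condition == "bulk" and timepoint == "M1" and self.group == "ATLG":
            depth = max(len(frame), int(depth * spec.depletion_depth_factor))
        reads = _sample_reads(self.rng, freqs, depth)
        frame = frame.assign(reads=reads)
        repertoire = Repertoire.from_frame(
            frame,
            patient_id=self.patient_id,
            timepoint=timepoint,
            phenotype=phenotype,
            condition=condition,
        )
        truth = self._sample_truth(phenotype, repertoire)
        return repertoire, truth

    def _sample_truth(self, phenotype: str,
                      repertoire: Repertoire) -> dict[str, float]:
        """Realized planted-subset composition of the emitted sample."""
        lat = self.latent[phenotype]
        keys = repertoire.df.index
        freq = repertoire.df["frequency"]
        reactive_idx = _key_index(lat.frame, lat.reactive)
        hit = keys.intersection(reactive_idx)
        truth = {
            "reactive_mass": 100.0 * float(freq.loc[hit].sum()) if len(hit) else 0.0,
            "reactive_pct": 100.0 * len(hit) / len(keys),
        }
        for species, mask in lat.virus.items():
            vidx = keys.intersection(_key_index(lat.frame, mask))
            truth[f"{species}_mass"] = (
                100.0 * float(freq.loc[vidx].sum()) if len(vidx) else 0.0)
        return truth


@dataclass
class SyntheticCohort:
    """In-memory result of :func:`generate_cohort`."""

    manifest: CohortManifest
    repertoires: dict[tuple[str, str, str, str], Repertoire]
    truth: GroundTruth

    def iter_samples(self) -> Iterator[Repertoire]:
        return iter(self.repertoires.values())


def generate_cohort(spec: CohortSpec, out_dir: str | Path | None = None,
                    ) -> SyntheticCohort:
    """Generate a full synthetic cohort; optionally write it to ``out_dir``.

    Deterministic for a fixed ``spec.seed``: the same seed yields a
    byte-identical cohort on disk.
    """
    spec.validate()
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(spec.seed)))

    repertoires: dict[tuple[str, str, str, str], Repertoire] = {}
    manifest_rows: list[dict[str, str]] = []
    truth_rows: list[dict[str, object]] = []
    reactive_keys: dict[tuple[str, str], pd.MultiIndex] = {}
    virus_keys: dict[tuple[str, str, str], pd.MultiIndex] = {}

    for patient_id, group in spec.patients:
        sim = _PatientSimulator(rng, spec, patient_id, group)
        for phenotype in ("CD4", "CD8"):
            lat = sim.latent[phenotype]
            reactive_keys[(patient_id, phenotype)] = _key_index(lat.frame, lat.reactive)
            for species, mask in lat.virus.items():
                virus_keys[(patient_id, phenotype, species)] = _key_index(lat.frame, mask)

        for timepoint in spec.timepoints:
            # build both phenotypes' weight vectors first so contamination
            # can cross between them
            pools = {p: sim._bulk_weights(p, timepoint) for p in ("CD4", "CD8")}
            for phenotype, other in (("CD4", "CD8"), ("CD8", "CD4")):
                rep, truth = sim.sample(phenotype, timepoint, "bulk",
                                        pool=pools[phenotype],
                                        contamination=pools[other])
                key = (patient_id, timepoint, phenotype, "bulk")
                repertoires[key] = rep
                manifest_rows.append(_manifest_row(patient_id, group, timepoint,
                                                   phenotype, "bulk"))
                truth_rows.append({"patient_id": patient_id, "group": group,
                                   "phenotype": phenotype, "timepoint": timepoint,
                                   **truth})
        for phenotype in ("CD4", "CD8"):
            rep, _ = sim.sample(phenotype, "preTx", "stimulated")
            key = (patient_id, "preTx", phenotype, "stimulated")
            repertoires[key] = rep
            manifest_rows.append(_manifest_row(patient_id, group, "preTx",
                                               phenotype, "stimulated"))

    manifest_df = pd.DataFrame(manifest_rows)
    truth = GroundTruth(
        reactive_keys=reactive_keys,
        virus_keys=virus_keys,
        sample_truth=pd.DataFrame(truth_rows),
        spec=spec,
    )
    manifest = CohortManifest(df=manifest_df, root=Path(out_dir or "."))
    cohort = SyntheticCohort(manifest=manifest, repertoires=repertoires, truth=truth)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _manifest_row(patient_id: str, group: str, timepoint: str, phenotype: str,
                  condition: str) -> dict[str, str]:
    return {
        "patient_id": patient_id,
        "group": group,
        "timepoint": timepoint,
        "phenotype": phenotype,
        "condition": condition,
        "path": f"{patient_id}_{timepoint}_{phenotype}_{condition}.tsv",
    }


def _write_cohort(cohort: SyntheticCohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for (patient, timepoint, phenotype, condition), rep in cohort.repertoires.items():
        write_clonotype_table(
            rep, out_dir / f"{patient}_{timepoint}_{phenotype}_{condition}.tsv")
    write_manifest(cohort.manifest, out_dir / "manifest.tsv")
    write_specificity_table(toy_specificity_records(), out_dir / "specificity.tsv")
    cohort.truth.sample_truth.to_csv(out_dir / "ground_truth.tsv", sep="\t",
                                     index=False, float_format="%.10g")
    reactive_dump = {
        f"{patient}|{phenotype}": ["|".join(k) for k in keys]
        for (patient, phenotype), keys in cohort.truth.reactive_keys.items()
    }
    with open(out_dir / "ground_truth_keys.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(reactive_dump, fh, sort_keys=True)


# ----------------------------------------------------------------------
# hand-checkable fixtures
# ----------------------------------------------------------------------


def write_fixture_suite(out_dir: str | Path) -> None:
    """Emit small deterministic fixtures with adjacent expected-value files:
    the 10/4, 6/4 and 8/4 ambiguity boundary cases, fold-change boundary
    cases around 5, and the closed-form JSD worked example."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def tsv(name: str, rows: list[tuple[str, str, str, str, str, int]]) -> None:
        df = pd.DataFrame(rows, columns=["cdr3_nt", "cdr3_aa", "v_gene",
                                         "d_gene", "j_gene", "reads"])
        df["frequency"] = df["reads"] / df["reads"].sum()
        df.to_csv(out / name, sep="\t", index=False)

    shared = [("TGTGCCAGCAGC", "CASS", "TRBV5-1", "", "TRBJ2-7"),
              ("TGTGCCAGCAGT", "CASS", "TRBV6-1", "", "TRBJ2-1"),
              ("TGTGCCAGCAGA", "CASR", "TRBV9", "", "TRBJ1-1")]
    cd4_reads, cd8_reads = [10, 6, 8], [4, 4, 4]
    tsv("ambiguity_boundary_cd4.tsv",
        [(*s, r) for s, r in zip(shared, cd4_reads)]
        + [("TGTGCCTTTTTT", "CAFF", "TRBV2", "", "TRBJ1-2", 5)])
    tsv("ambiguity_boundary_cd8.tsv",
        [(*s, r) for s, r in zip(shared, cd8_reads)]
        + [("TGTGCCGGGGGG", "CAGG", "TRBV2", "", "TRBJ1-2", 5)])
    (out / "ambiguity_boundary_expected.txt").write_text(
        "10/4 -> CD4; 6/4 -> removed from both; 8/4 -> CD4 (>= boundary)\n")

    unstim = [(nt, "CAS", "TRBV2", "", "TRBJ1-1")
              for nt in ("TGTGCCAAA", "TGTGCCCCC", "TGTGCCGGG",
                         "TGTGCCTTT", "TGTGCCACG")]
    unstim_reads = [100, 100, 100, 100, 100]
    stim_reads = [100, 490, 500, 510, 5000]
    tsv("fold_boundary_unstim.tsv", [(*s, r) for s, r in zip(unstim, unstim_reads)])
    tsv("fold_boundary_stim.tsv", [(*s, r) for s, r in zip(unstim, stim_reads)])
    (out / "fold_boundary_expected.txt").write_text(
        "equal depths; folds 1, 4.9, 5.0, 5.1, 50 -> called: the last three\n")

    (out / "jsd_closed_form.tsv").write_text(
        "p\tq\n0.5\t0\n0.5\t0.5\n0\t0.5\n")
    (out / "jsd_closed_form_expected.txt").write_text("JSD(p, q) = 0.5 (base 2)\n")
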