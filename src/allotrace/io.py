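"""Readers and writers for clonotype tables, cohort manifests and
specificity tables.

Clonotype tables are TSV with a configurable column map.  The default
dialect matches MiXCR export headers (``cloneCount``, ``nSeqCDR3``,
``aaSeqCDR3``, ``allVHitsWithScore`` ...); the writer always emits the fixed
canonical header ``cdr3_nt  cdr3_aa  v_gene  d_gene  j_gene  reads
frequency``.  Gzip-compressed inputs are accepted by ``.gz`` extension and
all text is UTF-8.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import pandas as pd

from .exceptions import EmptyRepertoireError, FormatError, ManifestError
from .model import KEY_FIELDS, PHENOTYPES, TIMEPOINTS, Repertoire

_ALLELE_RE = re.compile(r"[*(].*$")


def clean_gene(raw: object) -> str:
    """Normalize a gene call: first hit only, allele/score suffix stripped.

    ``"TRBV5-1*01(123.4), TRBV5-2*00(50)" -> "TRBV5-1"``.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return ""
    text = str(raw).strip()
    if not text or text.lower() == "nan":
        return ""
    first = text.split(",")[0].strip()
    return _ALLELE_RE.sub("", first).strip()


@dataclass(frozen=True)
class TableDialect:
    """Column mapping for a clonotype TSV dialect."""

    count: str
    cdr3_nt: str
    cdr3_aa: str
    v: str
    d: str
    j: str
    sep: str = "\t"

    @property
    def required(self) -> tuple[str, ...]:
        # the D column is optional in practice but listed for diagnostics
        return (self.count, self.cdr3_nt, self.cdr3_aa, self.v, self.j)


MIXCR_DIALECT = TableDialect(
    count="cloneCount",
    cdr3_nt="nSeqCDR3",
    cdr3_aa="aaSeqCDR3",
    v="allVHitsWithScore",
    d="allDHitsWithScore",
    j="allJHitsWithScore",
)

CANONICAL_DIALECT = TableDialect(
    count="reads",
    cdr3_nt="cdr3_nt",
    cdr3_aa="cdr3_aa",
    v="v_gene",
    d="d_gene",
    j="j_gene",
)

#: dialects tried, in order, when none is given explicitly
KNOWN_DIALECTS = (CANONICAL_DIALECT, MIXCR_DIALECT)


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _sniff_dialect(columns: list[str]) -> TableDialect:
    for dialect in KNOWN_DIALECTS:
        if set(dialect.required).issubset(columns):
            return dialect
    raise FormatError(
        f"could not match header {columns!r} to a known clonotype dialect"
    )


def read_clonotype_table(
    path: str | Path,
    dialect: TableDialect | None = None,
    *,
    patient_id: str = "",
    timepoint: str = "preTx",
    phenotype: str = "CD4",
    condition: str = "bulk",
) -> Repertoire:
    """Read one clonotype TSV into a :class:`Repertoire`.

    Duplicate identity keys are collapsed by summing reads and frequencies
    are recomputed from reads; any frequency column in the file is ignored.
    """
    with _open_text(path) as handle:
        table = pd.read_csv(handle, sep=dialect.sep if dialect else "\t", dtype=str)
    if dialect is None:
        dialect = _sniff_dialect(list(table.columns))
    missing = [c for c in dialect.required if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing mapped column(s) {missing}")
    frame = pd.DataFrame(
        {
            "cdr3_nt": table[dialect.cdr3_nt].astype(str).str.upper(),
            "cdr3_aa": table[dialect.cdr3_aa].astype(str),
            "v_gene": table[dialect.v].map(clean_gene),
            "d_gene": table[dialect.d].map(clean_gene)
            if dialect.d in table.columns
            else "",
            "j_gene": table[dialect.j].map(clean_gene),
            "reads": pd.to_numeric(table[dialect.count], errors="coerce"),
        }
    )
    frame = frame.dropna(subset=["reads"])
    frame = frame[frame["reads"] >= 1]
    if len(frame) == 0:
        raise EmptyRepertoireError(f"{path}: zero usable clonotype rows")
    frame["reads"] = frame["reads"].round().astype("int64")
    return Repertoire.from_frame(
        frame,
        patient_id=patient_id,
        timepoint=timepoint,
        phenotype=phenotype,
        condition=condition,
    )


def write_clonotype_table(repertoire: Repertoire, path: str | Path) -> None:
    """Write a repertoire with the fixed canonical header.

    Frequencies are serialized to 12 significant digits so a read/write
    round trip preserves them at that precision; integer fields round-trip
    bit-exactly.
    """
    df = repertoire.df.reset_index()
    df = df[["cdr3_nt", "cdr3_aa", "v_gene", "d_gene", "j_gene", "reads", "frequency"]]
    df["frequency"] = df["frequency"].map(lambda x: f"{x:.12g}")
    df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# cohort manifest
# ----------------------------------------------------------------------

MANIFEST_COLUMNS = ("patient_id", "group", "timepoint", "phenotype", "condition", "path")
TREATMENT_GROUPS = ("ATLG", "basiliximab")


@dataclass
class CohortManifest:
    """Validated table of one clonotype file per sample axis."""

    df: pd.DataFrame
    root: Path = field(default_factory=Path)

    @property
    def patients(self) -> list[str]:
        return sorted(self.df["patient_id"].unique())

    def group_of(self, patient_id: str) -> str:
        return str(self.df.loc[self.df["patient_id"] == patient_id, "group"].iloc[0])

    def rows(self) -> pd.DataFrame:
        return self.df

    def lookup(self, patient_id: str, timepoint: str, phenotype: str, condition: str) -> Path:
        mask = (
            (self.df["patient_id"] == patient_id)
            & (self.df["timepoint"] == timepoint)
            & (self.df["phenotype"] == phenotype)
            & (self.df["condition"] == condition)
        )
        sub = self.df[mask]
        if len(sub) == 0:
            raise ManifestError(
                f"no manifest row for {patient_id}/{timepoint}/{phenotype}/{condition}"
            )
        return self.root / str(sub["path"].iloc[0])

    def load(self, patient_id: str, timepoint: str, phenotype: str, condition: str,
             dialect: TableDialect | None = None) -> Repertoire:
        return read_clonotype_table(
            self.lookup(patient_id, timepoint, phenotype, condition),
            dialect,
            patient_id=patient_id,
            timepoint=timepoint,
            phenotype=phenotype,
            condition=condition,
        )


def read_manifest(path: str | Path) -> CohortManifest:
    """Read and validate a cohort manifest (TSV or CSV by extension).

    Validation enforces: required columns present, no duplicate sample axis,
    known timepoint/phenotype/condition/group labels, and — because
    donor-reactive calling is impossible without it — a preTx bulk and a
    preTx stimulated sample for every patient/phenotype.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing column(s) {missing}")
    df = df[list(MANIFEST_COLUMNS)].copy()

    bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ManifestError(f"unknown timepoint label(s) {sorted(bad_tp)}")
    bad_ph = set(df["phenotype"]) - set(PHENOTYPES)
    if bad_ph:
        raise ManifestError(f"unknown phenotype label(s) {sorted(bad_ph)}")
    bad_cond = set(df["condition"]) - {"bulk", "stimulated"}
    if bad_cond:
        raise ManifestError(f"unknown condition label(s) {sorted(bad_cond)}")
    bad_grp = set(df["group"]) - set(TREATMENT_GROUPS)
    if bad_grp:
        raise ManifestError(f"unknown treatment group(s) {sorted(bad_grp)}")

    axis = ["patient_id", "timepoint", "phenotype", "condition"]
    dupes = df[df.duplicated(axis, keep=False)]
    if len(dupes):
        first = dupes.iloc[0]
        raise ManifestError(
            "duplicate manifest entry for "
            f"{first['patient_id']}/{first['timepoint']}/"
            f"{first['phenotype']}/{first['condition']}"
        )

    groups = df.groupby("patient_id")["group"].nunique()
    if (groups > 1).any():
        raise ManifestError("a patient is assigned to more than one treatment group")

    for patient in df["patient_id"].unique():
        for phenotype in PHENOTYPES:
            sub = df[(df["patient_id"] == patient) & (df["phenotype"] == phenotype)]
            if len(sub) == 0:
                continue
            for condition in ("bulk", "stimulated"):
                hit = sub[(sub["timepoint"] == "preTx") & (sub["condition"] == condition)]
                if len(hit) == 0:
                    raise ManifestError(
                        f"patient {patient} phenotype {phenotype} lacks a "
                        f"preTx {condition} sample"
                    )

    df["timepoint"] = pd.Categorical(df["timepoint"], categories=TIMEPOINTS, ordered=True)
    df = df.sort_values(axis, kind="stable").reset_index(drop=True)
    df["timepoint"] = df["timepoint"].astype(str)
    return CohortManifest(df=df, root=path.parent)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    manifest.df.to_csv(path, sep=sep, index=False)


# ----------------------------------------------------------------------
# specificity table (VDJdb TSV dialect)
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class SpecificityRecord:
    """One CDR3-to-antigen association (TRB / HomoSapiens only)."""

    cdr3_aa: str
    antigen_species: str


def read_specificity_table(path: str | Path) -> list[SpecificityRecord]:
    """Read a VDJdb-style TSV (columns ``cdr3, gene, species,
    antigen.species``), keep TRB/HomoSapiens rows and deduplicate on
    (cdr3_aa, antigen_species)."""
    with _open_text(path) as handle:
        df = pd.read_csv(handle, sep="\t", dtype=str)
    required = ["cdr3", "gene", "species", "antigen.species"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: specificity table missing column(s) {missing}")
    df = df[(df["gene"] == "TRB") & (df["species"] == "HomoSapiens")]
    df = df.dropna(subset=["cdr3", "antigen.species"])
    seen: set[tuple[str, str]] = set()
    records: list[SpecificityRecord] = []
    for cdr3, antigen in zip(df["cdr3"], df["antigen.species"]):
        pair = (str(cdr3).upper(), str(antigen))
        if pair in seen or not pair[0] or not pair[1]:
            continue
        seen.add(pair)
        records.append(SpecificityRecord(cdr3_aa=pair[0], antigen_species=pair[1]))
    return records


def write_specificity_table(records: list[SpecificityRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "cdr3": [r.cdr3_aa for r in records],
            "gene": "TRB",
            "species": "HomoSapiens",
            "antigen.species": [r.antigen_species for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
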