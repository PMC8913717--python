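"""Antigen-specificity annotation by CDR3 amino-acid matching.

Clonotypes are labeled with an antigen species (e.g. CMV, EBV) when their
CDR3 amino-acid sequence exactly matches a record of a VDJdb-style table.
The default match scope is the CDR3 aa sequence alone (case-insensitive);
an optional stricter scope has no effect here because specificity records
carry no V/J in the supported dialect subset, but fuzzy matching within
Hamming distance 1 is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exceptions import ConfigError
from .io import SpecificityRecord
from .model import Repertoire


@dataclass(frozen=True)
class SpecificitySummary:
    """Virus-specific share of one repertoire for one antigen species."""

    patient_id: str
    phenotype: str
    timepoint: str
    antigen_species: str
    n_matched_clonotypes: int
    cum_freq: float  # percentage


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    return sum(x != y for x, y in zip(a, b)) <= 1


def annotate(
    repertoire: Repertoire,
    db: list[SpecificityRecord],
    *,
    fuzzy: bool = False,
) -> pd.Series:
    """Label clonotypes with matching antigen species.

    Returns a Series aligned to the repertoire index whose values are
    frozensets of antigen-species labels (possibly empty; a clonotype may
    carry several labels).  Matching is exact, case-insensitive CDR3 aa
    equality; with ``fuzzy=True`` a single amino-acid mismatch is allowed.
    """
    by_cdr3: dict[str, set[str]] = {}
    for record in db:
        by_cdr3.setdefault(record.cdr3_aa.upper(), set()).add(record.antigen_species)

    def match(aa: str) -> frozenset[str]:
        aa = aa.upper()
        labels = set(by_cdr3.get(aa, ()))
        if fuzzy:
            for ref, species in by_cdr3.items():
                if _hamming1(aa, ref):
                    labels |= species
        return frozenset(labels)

    return repertoire.df["cdr3_aa"].map(match)


def summarize_specificity(
    repertoire: Repertoire,
    labels: pd.Series,
    species: list[str] | None = None,
) -> list[SpecificitySummary]:
    """Count labeled clonotypes and sum their frequencies per species.

    ``labels`` must come from :func:`annotate` on the same repertoire.  A
    clonotype matching several species is counted once per species.  When
    ``species`` is given, a summary row (possibly all-zero) is emitted for
    each requested species; otherwise only observed species appear.
    """
    if not labels.index.equals(repertoire.df.index):
        raise ConfigError("labels are not aligned to the repertoire")
    observed: dict[str, tuple[int, float]] = {}
    freqs = repertoire.df["frequency"]
    for key, labelset in labels.items():
        for sp in labelset:
            n, f = observed.get(sp, (0, 0.0))
            observed[sp] = (n + 1, f + float(freqs.loc[key]))
    wanted = species if species is not None else sorted(observed)
    return [
        SpecificitySummary(
            patient_id=repertoire.patient_id,
            phenotype=repertoire.phenotype,
            timepoint=repertoire.timepoint,
            antigen_species=sp,
            n_matched_clonotypes=observed.get(sp, (0, 0.0))[0],
            cum_freq=100.0 * observed.get(sp, (0, 0.0))[1],
        )
        for sp in wanted
    ]


def specific_mass(repertoire: Repertoire, db: list[SpecificityRecord],
                  antigen_species: str) -> float:
    """Scalar metric adapter: cumulative frequency (%) of clonotypes
    matching one antigen species (for downsampled_metric)."""
    labels = annotate(repertoire, db)
    summaries = summarize_specificity(repertoire, labels, species=[antigen_species])
    return summaries[0].cum_freq


def matched_keys(repertoire: Repertoire, db: list[SpecificityRecord],
                 antigen_species: str) -> pd.MultiIndex:
    """Identity keys of clonotypes matching one antigen species.

    Matching is on the *amino-acid* sequence, so this is a convenience for
    metric adapters that track the matched key set through downsampling of
    the same repertoire (keys never change under subsampling).
    """
    wanted = {r.cdr3_aa.upper() for r in db if r.antigen_species == antigen_species}
    hit = repertoire.df["cdr3_aa"].str.upper().isin(wanted)
    return repertoire.df.index[hit]


def key_mass(keys: pd.MultiIndex, repertoire: Repertoire) -> float:
    """Cumulative frequency (%) of the given identity keys in a repertoire."""
    hit = repertoire.df.index.intersection(keys)
    return 100.0 * float(repertoire.df.loc[hit, "frequency"].sum()) if len(hit) else 0.0
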