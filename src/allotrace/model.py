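"""Canonical in-memory data model shared by every pipeline stage.

A :class:`Repertoire` wraps a :class:`pandas.DataFrame` indexed by the
clonotype identity key ``(cdr3_nt, v_gene, j_gene)``.  Nucleotide-level
identity with V/J genes is the strictest key supported by the exported
columns and the standard convention for tracking clones within a patient;
the D gene is excluded because it is frequently unassigned.  Gene names are
stored allele-stripped (``TRBV5-1*01 -> TRBV5-1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .exceptions import ContractError, EmptyRepertoireError

#: index level names forming the clonotype identity key
KEY_FIELDS = ("cdr3_nt", "v_gene", "j_gene")

#: non-key per-clonotype columns
VALUE_FIELDS = ("cdr3_aa", "d_gene", "reads", "frequency")

#: ordered bulk sampling timepoints
TIMEPOINTS = ("preTx", "M1", "M3", "M12")

PHENOTYPES = ("CD4", "CD8")
CONDITIONS = ("bulk", "stimulated")

FREQ_TOL = 1e-9


class ClonotypeKey(NamedTuple):
    """Identity of a clonotype within one patient: CDR3 nt + V + J."""

    cdr3_nt: str
    v_gene: str
    j_gene: str


@dataclass(frozen=True)
class Clonotype:
    """One TCR-beta clonotype record."""

    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    d_gene: str
    j_gene: str
    reads: int
    frequency: float

    @property
    def key(self) -> ClonotypeKey:
        return ClonotypeKey(self.cdr3_nt, self.v_gene, self.j_gene)


def timepoint_rank(label: str) -> int:
    """Ordinal position of a timepoint label (preTx < M1 < M3 < M12)."""
    return TIMEPOINTS.index(label)


@dataclass
class Repertoire:
    """The clonotype multiset of one sorted sample.

    Parameters
    ----------
    patient_id, timepoint, phenotype, condition
        Sample metadata; ``timepoint`` is one of ``preTx, M1, M3, M12`` and
        ``condition`` is ``bulk`` or ``stimulated`` (the MLR product).
    df
        Frame indexed by the ``(cdr3_nt, v_gene, j_gene)`` key with columns
        ``cdr3_aa, d_gene, reads, frequency``.  Use :meth:`from_frame` to
        build one from raw rows; it collapses duplicate keys, sorts the
        index canonically and recomputes frequencies.
    """

    patient_id: str
    timepoint: str
    phenotype: str
    condition: str
    df: pd.DataFrame = field(repr=False)

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        *,
        patient_id: str = "",
        timepoint: str = "preTx",
        phenotype: str = "CD4",
        condition: str = "bulk",
    ) -> "Repertoire":
        """Build a repertoire from a flat frame of clonotype rows.

        ``frame`` must contain the columns ``cdr3_nt, cdr3_aa, v_gene,
        d_gene, j_gene, reads``.  Rows sharing an identity key are collapsed
        by summing reads (keeping the first row's annotation columns); any
        input frequency column is ignored and recomputed from reads so the
        normalization invariant holds by construction.  The result is
        independent of the input row order.
        """
        if len(frame) == 0:
            raise EmptyRepertoireError("clonotype table has zero usable rows")
        frame = frame.copy()
        frame["reads"] = frame["reads"].astype(np.int64)
        if (frame["reads"] < 1).any():
            frame = frame[frame["reads"] >= 1]
            if len(frame) == 0:
                raise EmptyRepertoireError("all rows had zero reads")
        grouped = (
            frame.groupby(list(KEY_FIELDS), sort=True)
            .agg(cdr3_aa=("cdr3_aa", "first"), d_gene=("d_gene", "first"), reads=("reads", "sum"))
        )
        grouped["frequency"] = grouped["reads"] / grouped["reads"].sum()
        return cls(
            patient_id=patient_id,
            timepoint=timepoint,
            phenotype=phenotype,
            condition=condition,
            df=grouped[list(VALUE_FIELDS)],
        )

    @classmethod
    def from_clonotypes(cls, clonotypes: Iterable[Clonotype], **meta: str) -> "Repertoire":
        rows = pd.DataFrame(
            [
                {
                    "cdr3_nt": c.cdr3_nt,
                    "cdr3_aa": c.cdr3_aa,
                    "v_gene": c.v_gene,
                    "d_gene": c.d_gene,
                    "j_gene": c.j_gene,
                    "reads": c.reads,
                }
                for c in clonotypes
            ]
        )
        return cls.from_frame(rows, **meta)

    # ------------------------------------------------------------------
    # basic accessors
    # ------------------------------------------------------------------
    @property
    def n_clonotypes(self) -> int:
        return len(self.df)

    @property
    def total_reads(self) -> int:
        return int(self.df["reads"].sum())

    @property
    def reads(self) -> np.ndarray:
        return self.df["reads"].to_numpy(dtype=np.int64)

    @property
    def frequencies(self) -> np.ndarray:
        return self.df["frequency"].to_numpy(dtype=np.float64)

    @property
    def keys(self) -> pd.MultiIndex:
        return self.df.index

    def key_set(self) -> set[ClonotypeKey]:
        return {ClonotypeKey(*k) for k in self.df.index}

    def clonotypes(self) -> list[Clonotype]:
        return [
            Clonotype(
                cdr3_nt=key[0],
                cdr3_aa=row.cdr3_aa,
                v_gene=key[1],
                d_gene=row.d_gene,
                j_gene=key[2],
                reads=int(row.reads),
                frequency=float(row.frequency),
            )
            for key, row in self.df.iterrows()
        ]

    # ------------------------------------------------------------------
    # derived repertoires
    # ------------------------------------------------------------------
    def with_reads(self, new_reads: np.ndarray, *, drop_zero: bool = True) -> "Repertoire":
        """Return a copy with ``new_reads`` (aligned to ``self.df``) and
        recomputed frequencies; rows drawn zero times are dropped."""
        df = self.df.copy()
        df["reads"] = np.asarray(new_reads, dtype=np.int64)
        if drop_zero:
            df = df[df["reads"] > 0]
        if len(df) == 0:
            raise EmptyRepertoireError("no clonotypes left after resampling")
        df["frequency"] = df["reads"] / df["reads"].sum()
        return replace(self, df=df)

    def subset(self, keys) -> "Repertoire":
        """Restrict to the given identity keys (intersection), renormalized."""
        idx = self.df.index.intersection(keys)
        if len(idx) == 0:
            raise EmptyRepertoireError("key subset is empty")
        df = self.df.loc[idx].copy()
        df["frequency"] = df["reads"] / df["reads"].sum()
        return replace(self, df=df)

    def drop_keys(self, keys) -> "Repertoire":
        idx = self.df.index.difference(keys)
        if len(idx) == 0:
            raise EmptyRepertoireError("all clonotypes removed")
        df = self.df.loc[idx].copy()
        df["frequency"] = df["reads"] / df["reads"].sum()
        return replace(self, df=df)

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Assert the structural invariants; raise ContractError on failure."""
        if self.df.index.has_duplicates:
            raise ContractError("duplicate clonotype keys")
        if (self.df["reads"] < 1).any():
            raise ContractError("reads must be >= 1")
        total = self.df["frequency"].sum()
        if abs(total - 1.0) > FREQ_TOL:
            raise ContractError(f"frequencies sum to {total!r}, not 1")

    def same_sample_axis(self, other: "Repertoire") -> bool:
        return self.patient_id == other.patient_id and self.phenotype == other.phenotype

    @property
    def sample_id(self) -> str:
        return f"{self.patient_id}|{self.timepoint}|{self.phenotype}|{self.condition}"
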