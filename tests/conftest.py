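"""Shared fixtures and builders for the test suite.

All fixtures are generated programmatically — no binary artifacts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from allotrace.model import Repertoire


def build_repertoire(
    reads,
    *,
    v_genes=None,
    j_genes=None,
    cdr3_aa=None,
    patient_id: str = "P01",
    timepoint: str = "preTx",
    phenotype: str = "CD4",
    condition: str = "bulk",
) -> Repertoire:
    """Construct a repertoire from a read vector with auto-generated keys.

    ``reads`` may be a list of ints or a dict {cdr3_nt: reads}.
    """
    if isinstance(reads, dict):
        nts = list(reads)
        counts = [reads[k] for k in nts]
    else:
        counts = list(reads)
        nts = [f"TGT{_encode(i)}TTT" for i in range(len(counts))]
    n = len(counts)
    frame = pd.DataFrame(
        {
            "cdr3_nt": nts,
            "cdr3_aa": cdr3_aa if cdr3_aa is not None else ["CASSF"] * n,
            "v_gene": v_genes if v_genes is not None else ["TRBV5-1"] * n,
            "d_gene": "",
            "j_gene": j_genes if j_genes is not None else ["TRBJ2-7"] * n,
            "reads": counts,
        }
    )
    return Repertoire.from_frame(
        frame,
        patient_id=patient_id,
        timepoint=timepoint,
        phenotype=phenotype,
        condition=condition,
    )


def _encode(i: int) -> str:
    """Deterministic distinct in-frame nucleotide triplet block for index i."""
    alphabet = "ACGT"
    s = ""
    for _ in range(6):
        s += alphabet[i % 4]
        i //= 4
    return s


def uniform_repertoire(s: int, reads_each: int = 10, **meta) -> Repertoire:
    return build_repertoire([reads_each] * s, **meta)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_pair() -> tuple[Repertoire, Repertoire]:
    """Matched CD4/CD8 repertoires sharing three keys with reads
    (10 vs 4), (6 vs 4) and (8 vs 4), plus private clones."""
    shared = {"TGTGCCAAAAAATTT": 10, "TGTGCCCCCCCCTTT": 6, "TGTGCCGGGGGGTTT": 8}
    cd4 = build_repertoire({**shared, "TGTAAACCCGGGTTT": 5}, phenotype="CD4")
    cd8 = build_repertoire(
        {"TGTGCCAAAAAATTT": 4, "TGTGCCCCCCCCTTT": 4, "TGTGCCGGGGGGTTT": 4,
         "TGTTTTGGGCCCAAA": 7},
        phenotype="CD8",
    )
    return cd4, cd8


@pytest.fixture(scope="session")
def small_cohort():
    """A small written synthetic cohort shared across tests (session scope)."""
    import tempfile
    from pathlib import Path

    from allotrace.synthetic import CohortSpec, generate_cohort

    tmp = tempfile.mkdtemp(prefix="allotrace_cohort_")
    spec = CohortSpec(seed=7)
    spec.clonotype_count_range = {"CD4": (800, 1200), "CD8": (720, 1000)}
    cohort = generate_cohort(spec, tmp)
    return Path(tmp), cohort
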