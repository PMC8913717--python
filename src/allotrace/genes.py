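"""Bundled human TRB gene-name lists and codon tables for the synthetic
cohort generator."""

from __future__ import annotations

TRBV_GENES: tuple[str, ...] = (
    "TRBV2", "TRBV3-1", "TRBV4-1", "TRBV4-2", "TRBV4-3",
    "TRBV5-1", "TRBV5-4", "TRBV5-5", "TRBV5-6", "TRBV5-8",
    "TRBV6-1", "TRBV6-2", "TRBV6-3", "TRBV6-4", "TRBV6-5",
    "TRBV6-6", "TRBV6-8", "TRBV6-9", "TRBV7-2", "TRBV7-3",
    "TRBV7-4", "TRBV7-6", "TRBV7-7", "TRBV7-8", "TRBV7-9",
    "TRBV9", "TRBV10-1", "TRBV10-2", "TRBV10-3", "TRBV11-1",
    "TRBV11-2", "TRBV11-3", "TRBV12-3", "TRBV12-4", "TRBV12-5",
    "TRBV13", "TRBV14", "TRBV15", "TRBV16", "TRBV18",
    "TRBV19", "TRBV20-1", "TRBV24-1", "TRBV25-1", "TRBV27",
    "TRBV28", "TRBV29-1", "TRBV30",
)

TRBJ_GENES: tuple[str, ...] = (
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-6",
    "TRBJ2-7",
)

TRBD_GENES: tuple[str, ...] = ("TRBD1", "TRBD2", "")

_BASES = "TCAG"
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

#: codon -> amino acid, standard genetic code
CODON_TABLE: dict[str, str] = {
    b1 + b2 + b3: _AA_ORDER[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}

#: sense (non-stop) codons only — synthetic CDR3s stay in frame
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
)

#: one deterministic codon per amino acid (reverse translation)
AA_TO_CODON: dict[str, str] = {}
for _codon in SENSE_CODONS:
    AA_TO_CODON.setdefault(CODON_TABLE[_codon], _codon)


def reverse_translate(aa_seq: str) -> str:
    """Deterministic nucleotide sequence encoding ``aa_seq``."""
    return "".join(AA_TO_CODON[aa] for aa in aa_seq.upper())
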