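"""Thin genetic-code helpers (default: mold mitochondrial code, table 4).

Fungal mitochondria read TGA as tryptophan, so the only stop codons under the
default table are TAA and TAG.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

MOLD_MITO_TABLE = 4


@lru_cache(maxsize=None)
def _table(transl_table: int):
    return CodonTable.unambiguous_dna_by_id[transl_table]


@lru_cache(maxsize=None)
def stop_codons(transl_table: int = MOLD_MITO_TABLE) -> frozenset[str]:
    return frozenset(_table(transl_table).stop_codons)


def translate_codon(codon: str, transl_table: int = MOLD_MITO_TABLE) -> str:
    """One-letter amino acid, ``*`` for a stop, ``X`` for ambiguity."""
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - set("ACGT"):
        return "X"
    tab = _table(transl_table)
    if codon in tab.stop_codons:
        return "*"
    return tab.forward_table[codon]


def translate(seq: str, transl_table: int = MOLD_MITO_TABLE) -> str:
    return "".join(
        translate_codon(seq[i : i + 3], transl_table) for i in range(0, len(seq) - 2, 3)
    )


def is_synonymous(ref_codon: str, alt_codon: str,
                  transl_table: int = MOLD_MITO_TABLE) -> bool:
    return translate_codon(ref_codon, transl_table) == translate_codon(
        alt_codon, transl_table
    )
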