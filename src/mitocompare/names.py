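"""Gene-name normalization.

Public fungal mitogenome records use heterogeneous symbols for the same genes
(ND4L/nad4L, CYTB/cob, COX1/cox1, LSU/rnl, tRNA-Met/trnM ...).  All analysis
modules work on the canonical lowercase symbols; normalization is table-driven
and user-extensible.
"""

from __future__ import annotations

import re

from .model import CORE_GENES

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

_BUILTIN: dict[str, str] = {
    # NADH dehydrogenase subunits
    **{f"nd{i}": f"nad{i}" for i in range(1, 7)},
    **{f"nadh{i}": f"nad{i}" for i in range(1, 7)},
    "nd4l": "nad4L", "nad4l": "nad4L", "nadh4l": "nad4L",
    # cytochrome b
    "cytb": "cob", "cob": "cob", "cb": "cob", "mt-cyb": "cob",
    # cytochrome c oxidase
    "co1": "cox1", "coi": "cox1", "coxi": "cox1",
    "co2": "cox2", "coii": "cox2", "coxii": "cox2",
    "co3": "cox3", "coiii": "cox3", "coxiii": "cox3",
    # ATP synthase
    "atpase6": "atp6", "atpase8": "atp8", "atpase9": "atp9",
    "atp 6": "atp6", "atp 8": "atp8", "atp 9": "atp9", "olil": "atp9",
    # rRNAs
    "lsu": "rnl", "rrnl": "rnl", "l-rrna": "rnl", "16s": "rnl",
    "large subunit ribosomal rna": "rnl", "lsu rrna": "rnl",
    "ssu": "rns", "rrns": "rns", "s-rrna": "rns", "12s": "rns",
    "small subunit ribosomal rna": "rns", "ssu rrna": "rns",
    # ribosomal protein S3
    "var1": "rps3", "rps-3": "rps3",
}
_BUILTIN.update({g.lower(): g for g in CORE_GENES})
_BUILTIN["rps3"] = "rps3"

_TRNA_RE = re.compile(r"^trn([a-z]{1,3})[-_]?(?:\(([a-z]{3,4})\))?", re.IGNORECASE)
_TRNA_PRODUCT_RE = re.compile(r"^trna[-_ ]([a-z]{3})", re.IGNORECASE)


class GeneNameMap:
    """Synonym -> canonical symbol table, total over the 16 core genes.

    Unknown names pass through unchanged but are reported as nonstandard by
    :meth:`normalize`.
    """

    def __init__(self, extra: dict[str, str] | None = None):
        self.table = dict(_BUILTIN)
        if extra:
            self.table.update({k.lower(): v for k, v in extra.items()})

    @classmethod
    def from_config(cls, path: str) -> "GeneNameMap":
        """Load extra synonyms from a two-column TSV (synonym, canonical)."""
        extra: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                syn, canon = line.split("\t")[:2]
                extra[syn] = canon
        return cls(extra)

    def normalize(self, raw: str, product: str | None = None) -> tuple[str, bool]:
        """Return ``(canonical_name, is_standard)``.

        tRNAs normalize to ``trn<one-letter amino acid>``; duplicate
        disambiguation (``trnM_1`` ...) is the caller's job because it needs
        genome order.
        """
        name = raw.strip()
        key = name.lower().replace(" ", "")
        if key in self.table:
            return self.table[key], True
        m = _TRNA_RE.match(name)
        if m:
            aa = m.group(1)
            if len(aa) == 1:
                return "trn" + aa.upper(), True
            one = AA3_TO_1.get(aa.capitalize())
            if one:
                return "trn" + one, True
        if product:
            pm = _TRNA_PRODUCT_RE.match(product.strip())
            if pm:
                one = AA3_TO_1.get(pm.group(1).capitalize())
                if one:
                    return "trn" + one, True
            pl = product.lower()
            if "ribosomal protein s3" in pl:
                return "rps3", True
        if re.fullmatch(r"orf\d+", key):
            return key, True
        return name, False


def disambiguate(names: list[str]) -> list[str]:
    """Suffix duplicated names with _1, _2 ... in input (genome) order."""
    counts: dict[str, int] = {}
    for n in names:
        counts[n] = counts.get(n, 0) + 1
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if counts[n] > 1:
            seen[n] = seen.get(n, 0) + 1
            out.append(f"{n}_{seen[n]}")
        else:
            out.append(n)
    return out
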