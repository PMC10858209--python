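"""Gene-name normalization.

Mitogenome annotations spell the same gene many ways (ND5 / NAD5 / NADH-5,
COI / COX1, D-loop / control region ...).  This module maps every spelling to
one canonical token plus a feature class; unknown names pass through flagged
``unmapped:<raw>`` rather than raising.
"""

from __future__ import annotations

import re

__all__ = [
    "CANONICAL_TOKENS",
    "CANONICAL_ORDER",
    "normalize_gene_name",
    "ftype_of",
]

# Canonical tokens and their feature class.
_PCGS = ("ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
         "COI", "COII", "COIII", "ATP6", "ATP8", "CYTB")
_TRNAS = tuple("trn" + aa for aa in (
    "F", "V", "L1", "L2", "I", "Q", "M", "W", "A", "N", "C", "Y",
    "S1", "S2", "D", "K", "G", "R", "H", "E", "T", "P"))
_RRNAS = ("rrnS", "rrnL")

CANONICAL_TOKENS: dict[str, str] = {}
CANONICAL_TOKENS.update({g: "PCG" for g in _PCGS})
CANONICAL_TOKENS.update({t: "tRNA" for t in _TRNAS})
CANONICAL_TOKENS.update({r: "rRNA" for r in _RRNAS})
CANONICAL_TOKENS["CR"] = "control"
CANONICAL_TOKENS["OL"] = "origin"
CANONICAL_TOKENS["OH"] = "origin"

#: Canonical vertebrate mitogenome feature order (heavy-strand linearization
#: anchored at trnF), including the replication origins and control region.
CANONICAL_ORDER = (
    "trnF", "rrnS", "trnV", "rrnL", "trnL2", "ND1", "trnI", "trnQ", "trnM",
    "ND2", "trnW", "trnA", "trnN", "OL", "trnC", "trnY", "COI", "trnS2",
    "trnD", "COII", "trnK", "ATP8", "ATP6", "COIII", "trnG", "ND3", "trnR",
    "ND4L", "ND4", "trnH", "trnS1", "trnL1", "ND5", "ND6", "trnE", "CYTB",
    "trnT", "trnP", "OH", "CR",
)

_AA3_TO_1 = {
    "PHE": "F", "VAL": "V", "LEU": "L", "ILE": "I", "GLN": "Q", "MET": "M",
    "TRP": "W", "ALA": "A", "ASN": "N", "CYS": "C", "TYR": "Y", "SER": "S",
    "ASP": "D", "LYS": "K", "GLY": "G", "ARG": "R", "HIS": "H", "GLU": "E",
    "THR": "T", "PRO": "P",
}

_PCG_ALIASES = {
    "NAD1": "ND1", "NAD2": "ND2", "NAD3": "ND3", "NAD4": "ND4",
    "NAD4L": "ND4L", "NAD5": "ND5", "NAD6": "ND6",
    "NADH1": "ND1", "NADH2": "ND2", "NADH3": "ND3", "NADH4": "ND4",
    "NADH4L": "ND4L", "NADH5": "ND5", "NADH6": "ND6",
    "ND1": "ND1", "ND2": "ND2", "ND3": "ND3", "ND4": "ND4", "ND4L": "ND4L",
    "ND5": "ND5", "ND6": "ND6",
    "COX1": "COI", "COXI": "COI", "CO1": "COI", "COI": "COI",
    "COX2": "COII", "COXII": "COII", "CO2": "COII", "COII": "COII",
    "COX3": "COIII", "COXIII": "COIII", "CO3": "COIII", "COIII": "COIII",
    "ATP6": "ATP6", "ATPASE6": "ATP6", "ATP8": "ATP8", "ATPASE8": "ATP8",
    "CYTB": "CYTB", "CYB": "CYTB", "COB": "CYTB", "CYTOCHROMEB": "CYTB",
}

_OTHER_ALIASES = {
    "12S": "rrnS", "12SRRNA": "rrnS", "RRNS": "rrnS", "SRRNA": "rrnS",
    "12SRIBOSOMALRNA": "rrnS", "SSU": "rrnS",
    "16S": "rrnL", "16SRRNA": "rrnL", "RRNL": "rrnL", "LRRNA": "rrnL",
    "16SRIBOSOMALRNA": "rrnL", "LSU": "rrnL",
    "DLOOP": "CR", "CR": "CR", "CONTROLREGION": "CR", "DLOOPREGION": "CR",
    "OL": "OL", "ORIL": "OL", "OLR": "OL", "LSTRANDORIGIN": "OL",
    "ORIGINOFLSTRANDREPLICATION": "OL",
    "OH": "OH", "ORIH": "OH", "HSTRANDORIGIN": "OH",
    "ORIGINOFHSTRANDREPLICATION": "OH",
}

# trailing duplicate markers: "_0", "-1", " a", " b" (never a bare gene digit)
_COPY_SUFFIX = re.compile(r"(?:[_-]\d+|\s+[ab])$", re.IGNORECASE)
_ANTICODON = re.compile(r"\(([a-z]{3})\)", re.IGNORECASE)


def _strip_copy_suffix(name: str) -> str:
    # Protect gene numerals (ND5, ATP6 ...) -- only strip when what is left
    # still looks like a name, e.g. "NADH5_1" -> "NADH5", "ATP6 b" -> "ATP6".
    m = _COPY_SUFFIX.search(name)
    if m and m.start() > 0:
        head = name[:m.start()]
        if re.search(r"[A-Za-z]", head):
            return head
    return name


def _trna_token(body: str) -> str | None:
    """Map a tRNA spelling body ('PHE', 'SER2', 'S1', 'L') to a trn token."""
    body = body.strip().replace(" ", "")
    m = re.fullmatch(r"([A-Z]{3})(\d?)", body)
    if m and m.group(1) in _AA3_TO_1:
        aa = _AA3_TO_1[m.group(1)]
        num = m.group(2)
    else:
        m = re.fullmatch(r"([A-Z])(\d?)", body)
        if not m:
            return None
        aa, num = m.group(1), m.group(2)
    if aa in ("L", "S"):
        num = num or "1"  # unnumbered Leu/Ser: default to family 1
        token = f"trn{aa}{num}"
    else:
        token = f"trn{aa}"
    return token if token in CANONICAL_TOKENS else None


def normalize_gene_name(raw: str) -> tuple[str, str]:
    """Return ``(canonical_token, ftype)`` for an annotation spelling.

    Deterministic and case-insensitive.  Unknown spellings return
    ``("unmapped:<raw>", "unknown")``.

    >>> normalize_gene_name("NAD4L")
    ('ND4L', 'PCG')
    >>> normalize_gene_name("tRNA-Ser 1(gct)")
    ('trnS1', 'tRNA')
    """
    raw = raw.strip()
    work = _ANTICODON.sub("", raw).strip()

    # Try the spelling as-is first so gene numerals survive ("NADH-5");
    # only then retry with a duplicate marker stripped ("NADH5_1", "ATP6 b").
    for candidate in (work, _strip_copy_suffix(work)):
        resolved = _resolve(candidate.upper())
        if resolved is not None:
            return resolved
    return f"unmapped:{raw}", "unknown"


def _resolve(up: str) -> tuple[str, str] | None:
    trna_m = re.match(r"^T(?:RNA|RN)[\s_-]*(.+)$", up)
    if trna_m:
        token = _trna_token(trna_m.group(1))
        if token:
            return token, "tRNA"
    if up.startswith("TRN") and len(up) <= 6:
        token = _trna_token(up[3:])
        if token:
            return token, "tRNA"

    squeezed = re.sub(r"[\s_\-./]", "", up)
    if squeezed in _PCG_ALIASES:
        return _PCG_ALIASES[squeezed], "PCG"
    if squeezed in _OTHER_ALIASES:
        tok = _OTHER_ALIASES[squeezed]
        return tok, CANONICAL_TOKENS[tok]
    if squeezed in CANONICAL_TOKENS:
        return squeezed, CANONICAL_TOKENS[squeezed]
    return None


def ftype_of(canonical: str) -> str:
    return CANONICAL_TOKENS.get(canonical, "unknown")
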