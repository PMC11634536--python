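"""Alteration-type classification from REF/ALT allele strings.

Handles both encoding conventions found in the wild: VCF-anchored indels
(shared leading base, e.g. REF=A, ALT=AT) and MAF-style "-" placeholders
(REF=-, ALT=T).  Classification compares raw lengths and never trims a
shared prefix — trimming would rewrite the alleles, and classification
must not rewrite data.
"""

from __future__ import annotations

__all__ = ["classify_alteration", "ALTERATION_TYPES"]

ALTERATION_TYPES = ("SNV", "MNV", "INS", "DEL", "UNKNOWN")

_ALLELE_CHARS = frozenset("ACGTN")


def _is_empty(allele: str) -> bool:
    """The MAF empty marker '-' or a genuinely empty string."""
    return allele in ("", "-")


def classify_alteration(ref: str, alt: str) -> str:
    """Classify a (ref, alt) allele pair as SNV, MNV, INS, DEL or UNKNOWN.

    Rules, in order:

    1. non-allelic characters on either side (anything outside A/C/G/T/N,
       case-insensitive; "-" is only valid standing alone) -> UNKNOWN
    2. both sides empty/"-" -> UNKNOWN (degenerate, carries no event)
    3. ref empty/"-" -> INS; alt empty/"-" -> DEL
    4. equal length 1, ref != alt -> SNV
    5. equal length > 1, ref != alt -> MNV
    6. len(ref) < len(alt) -> INS; len(ref) > len(alt) -> DEL
    7. ref == alt -> UNKNOWN

    Total and deterministic; swapping ref and alt maps INS<->DEL and fixes
    SNV/MNV/UNKNOWN.
    """
    r = (ref or "").strip().upper()
    a = (alt or "").strip().upper()
    for allele in (r, a):
        if not _is_empty(allele) and not set(allele) <= _ALLELE_CHARS:
            return "UNKNOWN"
    if _is_empty(r) and _is_empty(a):
        return "UNKNOWN"
    if _is_empty(r):
        return "INS"
    if _is_empty(a):
        return "DEL"
    if len(r) == len(a):
        if r == a:
            return "UNKNOWN"
        return "SNV" if len(r) == 1 else "MNV"
    return "INS" if len(r) < len(a) else "DEL"
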