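"""Low-level DNA sequence helpers shared by all modules.

Canonical motif orientation rule (used everywhere a hexamer is named):

1. palindromes are their own canonical form;
2. if exactly one orientation starts with the half-site prefix ``CA``, it wins;
3. otherwise an alias table of conventional printed forms is consulted
   (covers e.g. ``CATGTG`` over ``CACATG`` and ``CGCGTT`` over ``AACGCG``);
4. otherwise the lexicographically smaller orientation wins.
"""

from __future__ import annotations

from itertools import product

from .errors import InvalidArgumentError

DNA_ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Conventional printed orientations for motifs where neither rule 1 nor 2
# settles the choice.  Both orientations of each entry map to the entry.
_ALIAS_FORMS = (
    "CATGTG",
    "CGCGTT",
    "AGGGGG",
    "AGCGGG",
    "AGGGGC",
    "CGGGGG",
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_motif(motif: str, k: int | None = 6) -> str:
    m = motif.upper()
    if k is not None and len(m) != k:
        raise InvalidArgumentError(f"expected a {k}-mer, got {motif!r}")
    if any(b not in DNA_ALPHABET for b in m):
        raise InvalidArgumentError(f"motif {motif!r} contains non-ACGT characters")
    return m


_ALIASES: dict[str, str] = {}
for _form in _ALIAS_FORMS:
    _ALIASES[_form] = _form
    _ALIASES[revcomp(_form)] = _form


def canonical(motif: str) -> str:
    """Return the canonical orientation of a motif (see module docstring)."""
    m = _validate_motif(motif, k=None)
    rc = revcomp(m)
    if m == rc:
        return m
    fwd_ca, rev_ca = m.startswith("CA"), rc.startswith("CA")
    if fwd_ca != rev_ca:
        return m if fwd_ca else rc
    alias = _ALIASES.get(m)
    if alias is not None:
        return alias
    return min(m, rc)


def is_palindrome(motif: str) -> bool:
    m = _validate_motif(motif, k=None)
    return m == revcomp(m)


def is_ebox(hexamer: str) -> bool:
    """True if the hexamer matches CANNTG in either orientation."""
    m = _validate_motif(hexamer)
    rc = revcomp(m)
    pat = lambda s: s.startswith("CA") and s.endswith("TG")  # noqa: E731
    return pat(m) or pat(rc)


def _has_half_site(hexamer: str) -> bool:
    for s in (hexamer, revcomp(hexamer)):
        if s[:3] in ("CAC", "CAT") or s[3:] in ("GTG", "ATG"):
            return True
    return False


def is_gc_rich(hexamer: str) -> bool:
    """Low-complexity G/C-rich class: at most one A/T base and no half-site."""
    m = _validate_motif(hexamer)
    at = sum(b in "AT" for b in m)
    return at <= 1 and not _has_half_site(m)


def classify_hexamer(hexamer: str) -> str:
    """Class label: 'E-box', 'GC-rich' or 'variant/non-E-box'."""
    if is_ebox(hexamer):
        return "E-box"
    if is_gc_rich(hexamer):
        return "GC-rich"
    return "variant/non-E-box"


def all_kmers(k: int):
    """Yield all 4**k DNA k-mers in lexicographic order."""
    for tup in product(DNA_ALPHABET, repeat=k):
        yield "".join(tup)
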