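"""PROSITE-syntax pattern parsing and matching.

Implements the subset of PROSITE pattern syntax needed for active-site
screening: ``x`` (any residue), ``[..]`` (alternatives), ``{..}``
(exclusions), ``(n)`` / ``(n,m)`` repetition, ``<`` / ``>`` anchors and
the optional trailing period.  Patterns are compiled to Python regular
expressions; matching returns all leftmost non-overlapping occurrences
as 1-based inclusive spans.

The two aldehyde-dehydrogenase active-site motifs used for candidate
screening are bundled as module constants (motif definitions transcribed
for convenience; consult the PROSITE database for authoritative entries).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import PatternError

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PrositePattern:
    """A named PROSITE-syntax pattern (e.g. an active-site signature)."""

    pattern_id: str
    pattern: str


# ALDH glutamic-acid active site signature.
PS00687 = PrositePattern("PS00687", "[LIVMFGA]-E-[LIMSTAC]-[GS]-G-[KNLM]-[SADN]-[TAPFV]")
# ALDH cysteine active site signature.
PS00070 = PrositePattern("PS00070", "[FYLVA]-[ELMSTAC]-[GS]-G-x-[DNEKRQS]-x(2)-[LIVMFA]-[LIVMFYWA]-[LIVMFYWGS]-[QEDNKHRSTA]-C-[LIVMFS]-x(4)")


def compile_pattern(pattern: str) -> re.Pattern[str]:
    """Compile a PROSITE pattern string to a Python regex.

    Raises :class:`PatternError` with the failing 0-based position on
    malformed input.
    """
    src = pattern.strip()
    if src.endswith("."):
        src = src[:-1]
    if not src:
        raise PatternError("empty pattern", 0)
    out: list[str] = []
    i = 0
    n = len(src)
    anchored_start = False
    anchored_end = False
    if src.startswith("<"):
        anchored_start = True
        i = 1
    first_element = True
    while i < n:
        if not first_element:
            if src[i] != "-":
                raise PatternError(f"expected '-' between elements at position {i}", i)
            i += 1
            if i >= n:
                raise PatternError("pattern ends with dangling '-'", i)
        first_element = False
        ch = src[i]
        if ch == "x":
            atom = "."
            i += 1
        elif ch == "[":
            j = src.find("]", i)
            if j < 0:
                raise PatternError(f"unclosed '[' at position {i}", i)
            body = src[i + 1 : j]
            if not body or any(c not in _AA + "<>" for c in body):
                raise PatternError(f"bad alternative set {body!r} at position {i}", i)
            atom = "[" + body.replace("<", "").replace(">", "") + "]"
            i = j + 1
        elif ch == "{":
            j = src.find("}", i)
            if j < 0:
                raise PatternError(f"unclosed '{{' at position {i}", i)
            body = src[i + 1 : j]
            if not body or any(c not in _AA for c in body):
                raise PatternError(f"bad exclusion set {body!r} at position {i}", i)
            atom = "[^" + body + "]"
            i = j + 1
        elif ch in _AA:
            atom = ch
            i += 1
        else:
            raise PatternError(f"unexpected character {ch!r} at position {i}", i)
        # optional repetition qualifier
        if i < n and src[i] == "(":
            j = src.find(")", i)
            if j < 0:
                raise PatternError(f"unclosed '(' at position {i}", i)
            body = src[i + 1 : j]
            m = re.fullmatch(r"(\d+)(?:,(\d+))?", body)
            if not m:
                raise PatternError(f"bad repetition {body!r} at position {i}", i)
            lo = int(m.group(1))
            hi = m.group(2)
            atom += f"{{{lo}}}" if hi is None else f"{{{lo},{hi}}}"
            i = j + 1
        # the C-terminal anchor attaches directly to the last element
        if i < n and src[i] == ">":
            if i != n - 1:
                raise PatternError(f"'>' anchor not at pattern end (position {i})", i)
            anchored_end = True
            i += 1
        out.append(atom)
    regex = "".join(out)
    if anchored_start:
        regex = "^" + regex
    if anchored_end:
        regex = regex + "$"
    return re.compile(regex)


def match_prosite_pattern(seq: str, pat: PrositePattern | str) -> list[tuple[int, int]]:
    """All leftmost non-overlapping matches of *pat* in *seq*.

    Returns 1-based inclusive (start, end) spans, in sequence order.
    """
    pattern = pat.pattern if isinstance(pat, PrositePattern) else pat
    rx = compile_pattern(pattern)
    return [(m.start() + 1, m.end()) for m in rx.finditer(seq.upper()) if m.end() > m.start()]
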