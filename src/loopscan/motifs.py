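"""The carrier-family motif grammar: compile residue-class patterns and
scan protein sequences for them.

Pattern strings use four token kinds: a literal residue letter, the
wildcard ``x``, a bracketed class ``[YF]``, and ``π`` for "any small
residue" (set configurable, default G/A/S/C/T).  Scanning reports every
(possibly overlapping) match; anchor-proximity disambiguation is the job
of :func:`annotate_mcf`, so the scanner stays a pure primitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import MotifScanError, MotifSyntaxError
from .templates import STANDARD_AA

#: default membership of the small-residue class π
DEFAULT_SMALL_RESIDUES = "GASCT"

#: the conserved matrix-side motifs of the carrier family, plus the
#: cytoplasmic-side signatures, named as the field names them
MCF_MOTIFS: dict[str, str] = {
    "Px[DE]xx[KR]xRxQxQ": "Px[DE]xx[KR]xRxQxQ",
    "[DE]G": "[DE]G",
    "[YF]xG": "[YF]xG",
    "DCxx[RK]": "DCxx[RK]",
    "[YWF][KR]G": "[YWF][KR]G",
    "[YF][DE]xx[RK]": "[YF][DE]xx[RK]",
    "GxxxG": "GxxxG",
    "πxxxπ": "πxxxπ",
}

#: relaxed P-kink/capping-arginine prefix used to validate the loop N-end
#: region in sequences whose full Px[DE]xx[KR]xRxQxQ copy carries indels
CAPPING_PREFIX = "Px[DE]xx[KR]"

#: expected anchor triplet of each motif in the carrier numbering
#: (domain-1 residue number of the first motif residue)
DEFAULT_ANCHOR_TRIPLETS: dict[str, int] = {
    "Px[DE]xx[KR]xRxQxQ": 27,
    "[YF]xG": 50,
    "DCxx[RK]": 55,
    "[DE]G": 64,
    "[YWF][KR]G": 70,
}


@dataclass(frozen=True)
class MotifToken:
    text: str  # source text, preserved for round-tripping
    residues: frozenset[str]


@dataclass(frozen=True)
class MotifPattern:
    name: str
    tokens: tuple[MotifToken, ...]

    def __len__(self) -> int:
        return len(self.tokens)

    def detokenize(self) -> str:
        return "".join(t.text for t in self.tokens)


@dataclass(frozen=True)
class MotifHit:
    pattern_name: str
    start: int  # 1-based residue number of the first matched residue
    match: str
    domain: int | None = None

    @property
    def end(self) -> int:
        return self.start + len(self.match) - 1


def compile_pattern(
    spec: str,
    name: str | None = None,
    small_residues: str = DEFAULT_SMALL_RESIDUES,
) -> MotifPattern:
    """Compile a pattern string into an ordered token list.

    Raises :class:`MotifSyntaxError` on unbalanced brackets, empty or
    invalid classes, or letters outside the 20 standard residues.
    """
    tokens: list[MotifToken] = []
    i = 0
    while i < len(spec):
        ch = spec[i]
        if ch == "[":
            close = spec.find("]", i)
            if close < 0:
                raise MotifSyntaxError(f"unbalanced '[' at position {i} in {spec!r}")
            members = spec[i + 1 : close]
            if not members:
                raise MotifSyntaxError(f"empty class at position {i} in {spec!r}")
            bad = [m for m in members if m not in STANDARD_AA]
            if bad:
                raise MotifSyntaxError(f"invalid class members {bad} in {spec!r}")
            tokens.append(MotifToken(text=spec[i : close + 1], residues=frozenset(members)))
            i = close + 1
        elif ch == "]":
            raise MotifSyntaxError(f"unbalanced ']' at position {i} in {spec!r}")
        elif ch == "x":
            tokens.append(MotifToken(text="x", residues=frozenset(STANDARD_AA)))
            i += 1
        elif ch == "π":
            if not small_residues:
                raise MotifSyntaxError("small-residue set for π is empty")
            tokens.append(MotifToken(text="π", residues=frozenset(small_residues)))
            i += 1
        elif ch in STANDARD_AA:
            tokens.append(MotifToken(text=ch, residues=frozenset(ch)))
            i += 1
        else:
            raise MotifSyntaxError(f"unexpected character {ch!r} at position {i} in {spec!r}")
    if not tokens:
        raise MotifSyntaxError("pattern has no tokens")
    return MotifPattern(name=name if name is not None else spec, tokens=tuple(tokens))


_AA_CODES = np.frombuffer(STANDARD_AA.encode(), dtype=np.uint8)


def scan(
    seq: str,
    pattern: MotifPattern | str,
    window: tuple[int, int] | None = None,
) -> list[MotifHit]:
    """Find all (overlapping) matches of a pattern in a protein sequence.

    ``window`` is an inclusive 1-based residue interval restricting where
    matches may *start and end*; positions are residue numbers on the full
    sequence.  Hits come back in ascending start order, equivalent to
    exhaustive position-by-position matching.
    """
    if isinstance(pattern, str):
        pattern = compile_pattern(pattern)
    n = len(seq)
    if window is None:
        lo, hi = 1, n
    else:
        lo, hi = window
        if lo < 1 or hi > n or lo > hi:
            raise MotifScanError(f"window {window} outside sequence of length {n}")
    region = seq[lo - 1 : hi].upper()
    bad = [lo + i for i, ch in enumerate(region) if ch not in STANDARD_AA]
    if bad:
        raise MotifScanError(f"non-standard letters at positions {bad}")

    m = len(pattern)
    if m > len(region):
        return []
    codes = np.frombuffer(region.encode(), dtype=np.uint8)
    n_starts = len(region) - m + 1
    valid = np.ones(n_starts, dtype=bool)
    for offset, token in enumerate(pattern.tokens):
        token_codes = np.frombuffer("".join(sorted(token.residues)).encode(), dtype=np.uint8)
        mask = np.isin(codes[offset : offset + n_starts], token_codes)
        valid &= mask
    return [
        MotifHit(
            pattern_name=pattern.name,
            start=lo + int(i),
            match=region[i : i + m],
        )
        for i in np.nonzero(valid)[0]
    ]


def annotate_mcf(
    seq: str,
    triplet_map,
    patterns: Mapping[str, str] | None = None,
    anchor_triplets: Mapping[str, int] | None = None,
    small_residues: str = DEFAULT_SMALL_RESIDUES,
) -> list[MotifHit]:
    """Annotate one instance of each matrix-side motif per domain.

    For each domain the candidate hit whose start is nearest the motif's
    expected anchor (the residue of the anchor triplet in that domain) is
    chosen.  Zero candidates or distance ties produce ``UserWarning``s
    rather than silent resolution; annotation is never fatal.
    """
    if patterns is None:
        patterns = {
            name: MCF_MOTIFS[name]
            for name in ("Px[DE]xx[KR]xRxQxQ", "[YF]xG", "DCxx[RK]", "[DE]G", "[YWF][KR]G")
        }
    if anchor_triplets is None:
        anchor_triplets = DEFAULT_ANCHOR_TRIPLETS

    covered = triplet_map.covered_residues()
    annotated: list[MotifHit] = []
    for name, spec in patterns.items():
        pattern = compile_pattern(spec, name=name, small_residues=small_residues)
        anchor_t = anchor_triplets.get(name)
        if anchor_t is None:
            continue
        hits = scan(seq, pattern)
        for d in (1, 2, 3):
            expected = _expected_residue(triplet_map, d, anchor_t)
            if expected is None:
                warnings.warn(
                    f"{name}: no anchor residue derivable for domain {d}", stacklevel=2
                )
                continue
            span = triplet_map.domain_span(d)
            # admit hits starting within the domain span, padded by the
            # pattern length so anchors at span edges are not lost
            pad = len(pattern) + 8
            candidates = [
                h for h in hits if span[0] - pad <= h.start <= span[1] + pad
            ]
            if not candidates:
                warnings.warn(f"{name}: no candidate hit in domain {d}", stacklevel=2)
                continue
            dists = [abs(h.start - expected) for h in candidates]
            best = min(dists)
            nearest = [h for h, dist in zip(candidates, dists) if dist == best]
            if len(nearest) > 1:
                warnings.warn(
                    f"{name}: ambiguous placement in domain {d} "
                    f"(starts {[h.start for h in nearest]})",
                    stacklevel=2,
                )
            chosen = nearest[0]
            annotated.append(
                MotifHit(
                    pattern_name=name,
                    start=chosen.start,
                    match=chosen.match,
                    domain=d,
                )
            )
    annotated.sort(key=lambda h: (h.domain or 0, h.start))
    return annotated


def _expected_residue(tmap, domain: int, triplet: int) -> int | None:
    """Residue of ``triplet`` in ``domain``, extrapolating past the span."""
    try:
        partner = tmap.triplet_partners(triplet)[domain - 1]
        if partner is not None:
            return partner
    except Exception:
        pass
    # extrapolate from the nearest covered triplet with a member in domain
    best = None
    for t in tmap.triplets:
        partner = tmap.triplet_partners(t)[domain - 1]
        if partner is None:
            continue
        if best is None or abs(t - triplet) < abs(best[0] - triplet):
            best = (t, partner)
    if best is None:
        return None
    return best[1] + (triplet - best[0])


def hits_to_table(hits: Iterable[MotifHit]) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.DataFrame.from_records(
        [
            {
                "pattern": h.pattern_name,
                "domain": h.domain,
                "start": h.start,
                "match": h.match,
            }
            for h in hits
        ]
    )
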