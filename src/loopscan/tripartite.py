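"""Triplet mapping across the three homologous domains of the carrier fold.

The carrier fold is a tandem triplication of a ~100-residue domain.  A
"triplet" is the group of up to three residues occupying one column of a
three-row alignment of the domains, indexed by the residue number of the
domain-1 member.  Columns where domain 1 is gapped receive fractional
triplet labels ("between t and t+1") and are excluded from asymmetry
summaries, which index triplets strictly by domain-1 numbering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence  # noqa: F401

from Bio import AlignIO

from .errors import AlignmentError, DerivationError, TripletLookupError

#: triplet → (domain-1, domain-2, domain-3 residue number) anchor table for
#: the bovine carrier numbering; used to validate user-supplied alignments.
DEFAULT_TRIPLET_ANCHORS: dict[int, tuple[int, int, int]] = {
    27: (27, 132, 229),
    30: (30, 139, 236),
    37: (37, 142, 239),
    38: (38, 143, 240),
    50: (50, 153, 250),
    65: (65, 168, 265),
}

_GAP_CHARS = "-."
_HEADER_RANGE = re.compile(r"/(\d+)-(\d+)$")


@dataclass(frozen=True)
class TripletColumn:
    """One alignment column: triplet label plus per-domain residues."""

    triplet: float  # integer for real triplets, fractional when domain 1 gapped
    residues: tuple[int | None, int | None, int | None]

    @property
    def gapped(self) -> bool:
        return self.triplet != int(self.triplet)


class TripletMap:
    """Bidirectional residue-number ↔ (domain, triplet) mapping."""

    def __init__(self, columns: Sequence[TripletColumn], rows: Sequence[str]):
        self.columns = tuple(columns)
        self.rows = tuple(rows)  # aligned sequences with gap characters
        self._by_residue: dict[int, tuple[int, float]] = {}
        self._by_triplet: dict[int, tuple[int | None, int | None, int | None]] = {}
        for col in self.columns:
            for d, res in enumerate(col.residues, start=1):
                if res is None:
                    continue
                if res in self._by_residue:
                    raise AlignmentError(f"residue {res} appears in two columns")
                label = int(col.triplet) if not col.gapped else col.triplet
                self._by_residue[res] = (d, label)
            if not col.gapped:
                self._by_triplet[int(col.triplet)] = col.residues

    # -- queries -------------------------------------------------------
    def map_residue(self, residue_number: int) -> tuple[int, float]:
        """Return ``(domain index 1-3, triplet number)`` for a residue.

        The triplet number is an integer for ordinary columns and a
        fraction between t and t+1 for columns where domain 1 is gapped.
        """
        try:
            return self._by_residue[residue_number]
        except KeyError:
            raise TripletLookupError(
                f"residue {residue_number} is outside the aligned span"
            ) from None

    def triplet_partners(self, triplet: int) -> tuple[int | None, int | None, int | None]:
        """Residue numbers of the (up to 3) members of a triplet column."""
        try:
            return self._by_triplet[triplet]
        except KeyError:
            raise TripletLookupError(f"unknown triplet {triplet}") from None

    @property
    def triplets(self) -> list[int]:
        return sorted(self._by_triplet)

    def domain_span(self, domain: int) -> tuple[int, int]:
        """Inclusive (min, max) residue number covered for a domain."""
        residues = [r for r, (d, _) in self._by_residue.items() if d == domain]
        if not residues:
            raise TripletLookupError(f"domain {domain} has no aligned residues")
        return (min(residues), max(residues))

    def covered_residues(self) -> list[int]:
        return sorted(self._by_residue)

    # -- export --------------------------------------------------------
    def to_table(self) -> "pandas.DataFrame":  # noqa: F821 - lazy import
        import pandas as pd

        records = [
            {
                "triplet": col.triplet,
                "res_d1": col.residues[0],
                "res_d2": col.residues[1],
                "res_d3": col.residues[2],
            }
            for col in self.columns
        ]
        return pd.DataFrame.from_records(records)


def _load_rows(alignment) -> tuple[list[str], list[str]]:
    """Accept a path, a Biopython alignment, or (id, seq) pairs."""
    if isinstance(alignment, (str, Path)):
        aln = AlignIO.read(str(alignment), "fasta")
        return [rec.id for rec in aln], [str(rec.seq).upper() for rec in aln]
    if hasattr(alignment, "__iter__") and not hasattr(alignment, "get_alignment_length"):
        pairs = list(alignment)
        if pairs and isinstance(pairs[0], (tuple, list)):
            return [p[0] for p in pairs], [str(p[1]).upper() for p in pairs]
        return [f"row{i + 1}" for i in range(len(pairs))], [str(s).upper() for s in pairs]
    return [rec.id for rec in alignment], [str(rec.seq).upper() for rec in alignment]


def build_triplet_map(
    alignment,
    domain_starts: tuple[int, int, int] | None = None,
) -> TripletMap:
    """Build a :class:`TripletMap` from a three-row domain alignment.

    ``alignment`` may be an aligned-FASTA path, a Biopython alignment, or
    an iterable of sequences / ``(id, sequence)`` pairs.  ``domain_starts``
    gives the first residue number of each domain; when omitted it is
    parsed from ``>id/start-end`` FASTA headers.
    """
    ids, rows = _load_rows(alignment)
    if len(rows) != 3:
        raise AlignmentError(f"expected exactly 3 aligned rows, got {len(rows)}")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise AlignmentError("aligned rows have unequal lengths")
    if domain_starts is None:
        starts = []
        for rec_id in ids:
            m = _HEADER_RANGE.search(rec_id)
            if not m:
                raise AlignmentError(
                    "domain_starts not given and header "
                    f"{rec_id!r} has no '/start-end' suffix"
                )
            starts.append(int(m.group(1)))
        domain_starts = tuple(starts)  # type: ignore[assignment]

    counters = list(domain_starts)
    raw_columns: list[list[int | None]] = []
    for c in range(length):
        residues: list[int | None] = []
        for d in range(3):
            ch = rows[d][c]
            if ch in _GAP_CHARS:
                residues.append(None)
            else:
                residues.append(counters[d])
                counters[d] += 1
        raw_columns.append(residues)

    # triplet labels: domain-1 residue number, interpolated across d1 gaps
    columns: list[TripletColumn] = []
    d1_numbers = [col[0] for col in raw_columns]
    for c, residues in enumerate(raw_columns):
        if residues[0] is not None:
            label = float(residues[0])
        else:
            prev_vals = [v for v in d1_numbers[:c] if v is not None]
            next_vals = [v for v in d1_numbers[c + 1 :] if v is not None]
            if prev_vals:
                lo = prev_vals[-1]
            elif next_vals:
                lo = next_vals[0] - 1
            else:
                raise AlignmentError("domain 1 row is entirely gaps")
            # position of this gap within its run of consecutive d1 gaps
            run_start = c
            while run_start > 0 and d1_numbers[run_start - 1] is None:
                run_start -= 1
            run_end = c
            while run_end + 1 < length and d1_numbers[run_end + 1] is None:
                run_end += 1
            k = c - run_start + 1
            n = run_end - run_start + 1
            label = lo + k / (n + 1)
        columns.append(TripletColumn(triplet=label, residues=tuple(residues)))

    # triplet numbers must strictly increase along domain-1 positions
    labels = [col.triplet for col in columns]
    if any(b <= a for a, b in zip(labels, labels[1:])):
        raise AlignmentError("triplet labels are not strictly increasing")
    return TripletMap(columns=columns, rows=rows)


def validate_anchors(
    tmap: TripletMap,
    anchors: Mapping[int, tuple[int, int, int]] = DEFAULT_TRIPLET_ANCHORS,
) -> None:
    """Check a map against known triplet anchors; raise on any violation."""
    problems = []
    for triplet, expected in anchors.items():
        try:
            got = tmap.triplet_partners(triplet)
        except TripletLookupError:
            problems.append(f"triplet {triplet} missing")
            continue
        if tuple(got) != tuple(expected):
            problems.append(f"triplet {triplet}: expected {expected}, got {got}")
    if problems:
        raise AlignmentError("anchor validation failed: " + "; ".join(problems))


# ---------------------------------------------------------------------------
# Structural elements

@dataclass(frozen=True)
class ElementMap:
    """Named residue-number ranges (inclusive) per domain.

    ``elements[domain][name] = (start, end)``.  The ranges of interest are
    ``matrix_loop`` (between the odd-numbered helix C-end and the matrix
    helix) and ``matrix_helix`` (the short amphipathic helix ending at the
    G of the [DE]G motif); ``domain_span`` is the full aligned extent.
    """

    elements: Mapping[int, Mapping[str, tuple[int, int]]]

    def __post_init__(self):
        for d, named in self.elements.items():
            loop = named.get("matrix_loop")
            helix = named.get("matrix_helix")
            if loop and helix and not loop[1] < helix[0]:
                raise DerivationError(
                    f"domain {d}: matrix loop {loop} does not precede matrix helix {helix}"
                )

    def range(self, domain: int, name: str) -> tuple[int, int]:
        return self.elements[domain][name]

    def element_of(self, residue_number: int) -> tuple[int, str] | None:
        """Return ``(domain, element_name)`` for a residue, or None.

        The most specific (narrowest) containing range wins.
        """
        best: tuple[int, str] | None = None
        best_width = None
        for d, named in self.elements.items():
            for name, (start, end) in named.items():
                if start <= residue_number <= end:
                    width = end - start
                    if best_width is None or width < best_width:
                        best = (d, name)
                        best_width = width
        return best

    def domain_of(self, residue_number: int) -> int | None:
        hit = self.element_of(residue_number)
        return hit[0] if hit else None

    def residues_in(self, domain: int, name: str) -> list[int]:
        start, end = self.range(domain, name)
        return list(range(start, end + 1))


def derive_elements(
    tmap: TripletMap,
    motif_hits: Iterable,
    plug_triplet: int = 37,
) -> ElementMap:
    """Derive matrix-loop and matrix-helix ranges from motif anchors.

    Per domain the matrix loop runs from the residue after the
    hydrophobic-plug triplet (``plug_triplet``, 37 in the carrier
    convention) to the residue before the [YF]xG aromatic, and the matrix
    helix from that aromatic to the G of the [DE]G motif.

    ``motif_hits`` must contain, per domain, a ``"[YF]xG"`` hit and a
    ``"[DE]G"`` hit (as produced by :func:`loopscan.motifs.annotate_mcf`);
    missing anchors raise :class:`DerivationError` listing them.
    """
    hits_by = {}
    for hit in motif_hits:
        if hit.domain is None:
            continue
        hits_by[(hit.pattern_name, hit.domain)] = hit
    try:
        plug = tmap.triplet_partners(plug_triplet)
    except TripletLookupError as exc:
        raise DerivationError(str(exc)) from None

    missing = []
    elements: dict[int, dict[str, tuple[int, int]]] = {}
    for d in (1, 2, 3):
        yxg = hits_by.get(("[YF]xG", d))
        deg = hits_by.get(("[DE]G", d))
        if yxg is None:
            missing.append(f"[YF]xG in domain {d}")
        if deg is None:
            missing.append(f"[DE]G in domain {d}")
        if yxg is None or deg is None:
            continue
        if plug[d - 1] is None:
            missing.append(f"plug triplet {plug_triplet} member in domain {d}")
            continue
        loop_start = plug[d - 1] + 1
        loop_end = yxg.start - 1
        helix_start = yxg.start
        helix_end = deg.start + 1  # the G
        span = tmap.domain_span(d)
        elements[d] = {
            "matrix_loop": (loop_start, loop_end),
            "matrix_helix": (helix_start, helix_end),
            "domain_span": span,
        }
    if missing:
        raise DerivationError("missing anchors: " + ", ".join(missing))
    return ElementMap(elements=elements)
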