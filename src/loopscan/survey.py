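"""Family-wide [DE]G-motif survey and position-frequency (logo) matrices.

Each carrier of the SLC25 family carries a [DE]G motif at the C-end of
the short matrix helix in each of its three domains.  The survey locates
that motif per domain, records whether its first residue is D, E or
something else, removes the members the analysis excludes (carriers
outside the inner mitochondrial membrane, and carriers with a charged
residue in the motif's second position), and reports per-domain E
frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.stats import entropy

from .errors import AlignmentError, MotifScanError
from .motifs import scan
from .templates import STANDARD_AA

#: carriers reported to localise outside the inner mitochondrial membrane
OUTSIDE_IMM = ("MTCH1", "MTCH2", "SLC25A46", "PM34")
#: carriers with an unexpected charged residue in the second motif position
CHARGED_SECOND_POSITION = ("SLC25A47", "SLC25A51", "SLC25A52")

_CHARGED = set("DEKRH")


@dataclass(frozen=True)
class CarrierEntry:
    """One family member with its per-domain first-residue calls."""

    identifier: str
    sequence: str
    calls: tuple[str, str, str] | None = None  # each in {"D", "E", "other"}
    exclusion: str | None = None  # None | "outside-IMM" | "charged-second-position"
    flags: tuple[str, ...] = ()


def read_family_fasta(path: str | Path) -> list[CarrierEntry]:
    return [
        CarrierEntry(identifier=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def locate_deg(
    sequence: str,
    windows: Sequence[tuple[int, int]],
) -> tuple[str, str, str]:
    """Call the [DE]G first residue in each of three domain windows.

    Within each window the candidate nearest the window's C-end (the
    matrix-helix C-end anchor) wins.  If no D/E-preceded G exists but a G
    preceded by some other residue does, the call is ``"other"`` and a
    warning flags the unusual first position; with no G-anchored
    candidate at all the call is also ``"other"``.
    """
    if len(windows) != 3:
        raise ValueError("exactly three domain windows are required")
    calls = []
    for d, window in enumerate(windows, start=1):
        try:
            deg_hits = scan(sequence, "[DE]G", window=window)
        except MotifScanError:
            deg_hits = []
        if deg_hits:
            best = max(deg_hits, key=lambda h: h.start)  # nearest the C-end
            calls.append(best.match[0])
            continue
        try:
            xg_hits = scan(sequence, "xG", window=window)
        except MotifScanError:
            xg_hits = []
        if xg_hits:
            first = max(xg_hits, key=lambda h: h.start).match[0]
            warnings.warn(
                f"domain {d}: G anchored by {first!r} instead of D/E", stacklevel=2
            )
        else:
            warnings.warn(f"domain {d}: no G-anchored candidate in window", stacklevel=2)
        calls.append("other")
    return tuple(calls)  # type: ignore[return-value]


def call_entries(
    entries: Iterable[CarrierEntry],
    windows: Mapping[str, Sequence[tuple[int, int]]] | Sequence[tuple[int, int]],
) -> list[CarrierEntry]:
    """Attach per-domain [DE]G calls to every entry.

    ``windows`` is either one set of three windows shared by all members
    (a generator-made family with a fixed layout) or a mapping
    identifier → three windows.
    """
    out = []
    for e in entries:
        w = windows[e.identifier] if isinstance(windows, Mapping) else windows
        out.append(replace(e, calls=locate_deg(e.sequence, w)))
    return out


def apply_exclusions(
    entries: Iterable[CarrierEntry],
    outside_imm: Sequence[str] = OUTSIDE_IMM,
    charged_second: Sequence[str] = CHARGED_SECOND_POSITION,
) -> tuple[list[CarrierEntry], list[CarrierEntry]]:
    """Split entries into (retained, excluded).

    An entry named on both lists is excluded once with both flags
    recorded.  Listed names absent from the input only warn.
    """
    entries = list(entries)
    names = {e.identifier for e in entries}
    for listed in list(outside_imm) + list(charged_second):
        if listed not in names:
            warnings.warn(f"exclusion-listed carrier {listed!r} not in input", stacklevel=2)
    retained, excluded = [], []
    for e in entries:
        flags = []
        if e.identifier in outside_imm:
            flags.append("outside-IMM")
        if e.identifier in charged_second:
            flags.append("charged-second-position")
        if flags:
            excluded.append(replace(e, exclusion=flags[0], flags=tuple(flags)))
        else:
            retained.append(e)
    return retained, excluded


def e_frequency(
    entries: Iterable[CarrierEntry],
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-domain fraction of E calls among entries, optionally stratified
    by user-supplied group labels (identifier → group)."""
    rows = []
    entries = list(entries)
    for e in entries:
        if e.calls is None:
            raise ValueError(f"entry {e.identifier} has no domain calls")
    def _freqs(members: list[CarrierEntry]) -> dict:
        n = len(members)
        out = {"n": n}
        for d in range(3):
            count = sum(1 for m in members if m.calls[d] == "E")
            out[f"domain{d + 1}_E_freq"] = count / n if n else float("nan")
        return out

    if groups is None:
        rows.append({"group": "all", **_freqs(entries)})
    else:
        for group in sorted(set(groups.values())):
            members = [e for e in entries if groups.get(e.identifier) == group]
            rows.append({"group": group, **_freqs(members)})
    return pd.DataFrame(rows)


def survey_table(retained: Iterable[CarrierEntry], excluded: Iterable[CarrierEntry]) -> pd.DataFrame:
    rows = []
    for e in list(retained) + list(excluded):
        calls = e.calls or ("", "", "")
        rows.append(
            {
                "carrier": e.identifier,
                "d1_call": calls[0],
                "d2_call": calls[1],
                "d3_call": calls[2],
                "exclusion": ",".join(e.flags) if e.flags else "none",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Position frequency matrices (sequence logos)

@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-column residue counts of an alignment plus information content.

    Information content of a column is ``log2(20) - H`` where ``H`` is the
    Shannon entropy (bits) of the column's residue frequencies; gaps are
    excluded from the frequency normalisation and counted separately.
    """

    counts: pd.DataFrame  # index: residues + "-", columns: 1-based positions
    information: np.ndarray  # bits per column

    @property
    def n_columns(self) -> int:
        return self.counts.shape[1]

    def to_tsv(self, path) -> None:
        table = self.counts.copy()
        table.loc["information_bits"] = np.round(self.information, 6)
        table.to_csv(path, sep="\t")


def build_pfm(
    sequences: Iterable[str],
    small_sample_correction: bool = False,
) -> PositionFrequencyMatrix:
    """Build a position frequency matrix from equal-length aligned rows.

    ``small_sample_correction`` subtracts the standard e(n) = (s-1)/(2·ln2·n)
    correction from each column's information content (off by default).
    """
    seqs = [s.upper() for s in sequences]
    if not seqs:
        raise AlignmentError("no sequences given")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise AlignmentError("ragged alignment: sequences differ in length")

    alphabet = list(STANDARD_AA) + ["-"]
    counts = np.zeros((len(alphabet), length), dtype=int)
    index = {ch: i for i, ch in enumerate(alphabet)}
    for s in seqs:
        for pos, ch in enumerate(s):
            if ch in (".", "-"):
                ch = "-"
            elif ch not in index:
                raise AlignmentError(f"non-standard letter {ch!r} at column {pos + 1}")
            counts[index[ch], pos] += 1

    max_bits = np.log2(20.0)
    info = np.zeros(length)
    residue_counts = counts[:-1]
    for pos in range(length):
        col = residue_counts[:, pos]
        total = col.sum()
        if total == 0:
            info[pos] = 0.0
            continue
        h = entropy(col / total, base=2)
        ic = max_bits - h
        if small_sample_correction:
            ic -= 19.0 / (2.0 * np.log(2) * total)
        info[pos] = max(ic, 0.0) if small_sample_correction else ic
    frame = pd.DataFrame(counts, index=alphabet, columns=range(1, length + 1))
    return PositionFrequencyMatrix(counts=frame, information=info)
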