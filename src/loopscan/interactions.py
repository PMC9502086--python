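"""Polar contact enumeration, windowed occupancy, threshold filtering and
the loop-interaction taxonomy.

Occupancy of a residue-pair contact is the percentage of analysed frames
in which the minimum distance between the two atom sets is within the
cutoff (0.33 nm by default, inclusive).  Analysis defaults to the
trailing portion of each trajectory (the equilibrated part); retained
interactions are those whose occupancy averaged over parallel
trajectories is strictly above 25%.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import templates
from .core_io import (
    BACKBONE_NH_CTX,
    BACKBONE_O_CTX,
    SIDECHAIN_CTX,
    Trajectory,
    format_interaction_label,
)
from .errors import LoopscanError
from .tripartite import ElementMap

DEFAULT_CUTOFF_NM = 0.33
DEFAULT_THRESHOLD_PCT = 25.0
DEFAULT_WINDOW_PS = 2_000_000.0  # trailing 2 us
DEFAULT_WINDOW_FRACTION = 2.0 / 3.0  # fallback for short fixtures


# ---------------------------------------------------------------------------
# Analysis window

@dataclass(frozen=True)
class Window:
    """The trailing part of a trajectory to analyse.

    ``kind`` is ``"all"``, ``"last_ps"`` (trailing span in ps) or
    ``"last_fraction"`` (trailing fraction of frames).
    """

    kind: str = "all"
    value: float = 0.0

    @classmethod
    def all(cls) -> "Window":
        return cls("all", 0.0)

    @classmethod
    def last_ps(cls, span_ps: float) -> "Window":
        return cls("last_ps", float(span_ps))

    @classmethod
    def last_fraction(cls, fraction: float) -> "Window":
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        return cls("last_fraction", float(fraction))

    def frame_slice(self, times: np.ndarray) -> slice:
        n = len(times)
        if n == 0:
            raise LoopscanError("empty trajectory")
        if self.kind == "all":
            return slice(0, n)
        if self.kind == "last_ps":
            start_time = times[-1] - self.value
            first = int(np.searchsorted(times, start_time, side="right"))
            if first >= n:
                raise LoopscanError(
                    f"window of {self.value} ps trailing excludes every frame"
                )
            return slice(first, n)
        if self.kind == "last_fraction":
            count = max(1, int(np.ceil(self.value * n)))
            return slice(n - count, n)
        raise ValueError(f"unknown window kind {self.kind!r}")

    def describe(self) -> str:
        if self.kind == "all":
            return "all frames"
        if self.kind == "last_ps":
            return f"trailing {self.value:g} ps"
        return f"trailing {self.value:.3f} fraction of frames"


def default_window(traj: Trajectory) -> Window:
    """Trailing 2 us, degrading to the trailing 2/3 of short trajectories."""
    span = float(traj.times[-1] - traj.times[0])
    if span > DEFAULT_WINDOW_PS:
        return Window.last_ps(DEFAULT_WINDOW_PS)
    return Window.last_fraction(DEFAULT_WINDOW_FRACTION)


# ---------------------------------------------------------------------------
# Pair specifications

@dataclass(frozen=True)
class ContactPairSpec:
    """A candidate polar contact between two residue atom groups."""

    residue_a: int
    resname_a: str
    atoms_a: tuple[str, ...]
    context_a: str  # "", "(O)" or "(NH)"
    residue_b: int
    resname_b: str
    atoms_b: tuple[str, ...]
    context_b: str
    kind: str = "H-bond"  # or "salt-bridge"

    def __post_init__(self):
        if not self.atoms_a or not self.atoms_b:
            raise ValueError("atom sets must be non-empty")
        if self.kind not in ("H-bond", "salt-bridge"):
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if self.kind == "salt-bridge":
            basic = set(templates.BASIC_SIDECHAIN.get(self.resname_a.upper(), ()))
            acidic = set(templates.ACIDIC_SIDECHAIN.get(self.resname_b.upper(), ()))
            fwd = set(self.atoms_a) <= basic and set(self.atoms_b) <= acidic
            basic_b = set(templates.BASIC_SIDECHAIN.get(self.resname_b.upper(), ()))
            acidic_a = set(templates.ACIDIC_SIDECHAIN.get(self.resname_a.upper(), ()))
            rev = set(self.atoms_b) <= basic_b and set(self.atoms_a) <= acidic_a
            if not (fwd or rev):
                raise ValueError(
                    "salt-bridge atom sets must pair basic side-chain N atoms "
                    "with acidic carboxylate O atoms"
                )

    @property
    def label(self) -> str:
        return format_interaction_label(
            (self.resname_a, self.residue_a),
            self.context_a,
            (self.resname_b, self.residue_b),
            self.context_b,
        )


@dataclass(frozen=True)
class InteractionRecord:
    """A pair spec with per-trajectory occupancies and its taxonomy slot."""

    spec: ContactPairSpec
    occupancies: tuple[float, ...]
    window: str = "all frames"
    category: str | None = None

    @property
    def average(self) -> float:
        return float(np.mean(self.occupancies))

    def rounded(self) -> tuple[list[int], int]:
        """Occupancies as integers via round-half-up, as tables print them."""
        per = [int(Decimal(o).quantize(0, rounding=ROUND_HALF_UP)) for o in self.occupancies]
        avg = int(Decimal(self.average).quantize(0, rounding=ROUND_HALF_UP))
        return per, avg


# ---------------------------------------------------------------------------
# Distances

def min_distance(frame_coords: np.ndarray, idx_a: Sequence[int], idx_b: Sequence[int]) -> float:
    """Minimum Euclidean distance (nm) over the Cartesian product of two
    atom index sets, within one frame's ``(n_atoms, 3)`` coordinates."""
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise LoopscanError("min_distance called with an empty atom set")
    a = frame_coords[np.asarray(idx_a, dtype=int)]
    b = frame_coords[np.asarray(idx_b, dtype=int)]
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=-1)).min())


def min_distance_series(
    traj: Trajectory, idx_a: Sequence[int], idx_b: Sequence[int]
) -> np.ndarray:
    """Per-frame minimum distance (nm) between two atom index sets."""
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise LoopscanError("min_distance_series called with an empty atom set")
    a = traj.coordinates[:, np.asarray(idx_a, dtype=int)]
    b = traj.coordinates[:, np.asarray(idx_b, dtype=int)]
    diff = a[:, :, None, :] - b[:, None, :, :]
    return np.sqrt((diff**2).sum(axis=-1)).min(axis=(1, 2))


def _spec_indices(traj: Trajectory, spec: ContactPairSpec) -> tuple[list[int], list[int]]:
    idx_a = [traj.atom_index(spec.residue_a, name) for name in spec.atoms_a]
    idx_b = [traj.atom_index(spec.residue_b, name) for name in spec.atoms_b]
    return idx_a, idx_b


def occupancy(
    traj: Trajectory,
    spec: ContactPairSpec,
    cutoff: float = DEFAULT_CUTOFF_NM,
    window: Window | None = None,
) -> float:
    """Contact occupancy (%) of a pair over the analysis window.

    A frame counts as in contact when the minimum distance between the
    two atom sets is ≤ cutoff (inclusive at the boundary).
    """
    if window is None:
        window = Window.all()
    sl = window.frame_slice(traj.times)
    idx_a, idx_b = _spec_indices(traj, spec)
    series = min_distance_series(traj, idx_a, idx_b)[sl]
    if series.size == 0:
        raise LoopscanError("analysis window contains no frames")
    return 100.0 * float(np.count_nonzero(series <= cutoff)) / series.size


def compute_records(
    trajectories: Sequence[Trajectory],
    specs: Iterable[ContactPairSpec],
    cutoff: float = DEFAULT_CUTOFF_NM,
    window: Window | None = None,
) -> list[InteractionRecord]:
    """Occupancy of every spec in every (parallel) trajectory."""
    records = []
    for spec in specs:
        occs = tuple(occupancy(t, spec, cutoff=cutoff, window=window) for t in trajectories)
        desc = (window or Window.all()).describe()
        records.append(InteractionRecord(spec=spec, occupancies=occs, window=desc))
    return records


# ---------------------------------------------------------------------------
# Pair enumeration

def _polar_groups(resname: str, resnum: int) -> list[dict]:
    """Backbone and side-chain polar atom groups of one residue."""
    rn = resname.upper()
    groups = [
        {
            "ctx": BACKBONE_O_CTX,
            "atoms": (templates.BACKBONE_ACCEPTOR,),
            "donor": False,
            "acceptor": True,
            "charge": None,
        }
    ]
    if rn != "PRO":
        groups.append(
            {
                "ctx": BACKBONE_NH_CTX,
                "atoms": (templates.BACKBONE_DONOR,),
                "donor": True,
                "acceptor": False,
                "charge": None,
            }
        )
    polar = templates.SIDECHAIN_POLAR.get(rn)
    if polar:
        atoms = tuple(polar)
        charge = None
        if rn in templates.BASIC_SIDECHAIN:
            charge = "basic"
            atoms = templates.BASIC_SIDECHAIN[rn]
        elif rn in templates.ACIDIC_SIDECHAIN:
            charge = "acidic"
            atoms = templates.ACIDIC_SIDECHAIN[rn]
        groups.append(
            {
                "ctx": SIDECHAIN_CTX,
                "atoms": atoms,
                "donor": bool(templates.sidechain_donor_atoms(rn)),
                "acceptor": bool(templates.sidechain_acceptor_atoms(rn)),
                "charge": charge,
            }
        )
    return groups


def _in_screened_region(res_a: int, res_b: int, element_map: ElementMap | None) -> bool:
    """The screening taxonomy: intra-loop pairs, loop vs same-domain matrix
    helix, and inter-domain pairs.  Without an element map, screen all."""
    if element_map is None:
        return True
    ea = element_map.element_of(res_a)
    eb = element_map.element_of(res_b)
    if ea is None or eb is None:
        return False
    (da, na), (db, nb) = ea, eb
    if da != db:
        return True  # domain-domain interface
    if na == "matrix_loop" and nb == "matrix_loop":
        return True
    if {na, nb} == {"matrix_loop", "matrix_helix"}:
        return True
    return False


def enumerate_pairs(
    traj: Trajectory,
    element_map: ElementMap | None = None,
    max_residue_distance: float = 0.6,
) -> list[ContactPairSpec]:
    """Enumerate candidate donor/acceptor pair specs for a trajectory.

    Residue pairs are restricted to the screening taxonomy regions (see
    :func:`_in_screened_region`), pre-filtered by requiring the minimum
    heavy-atom distance to come within ``max_residue_distance`` nm in at
    least one frame.  Self-pairs and backbone–backbone contacts between
    sequence neighbours (i, i+1) are excluded.
    """
    residues = traj.residue_numbers()
    heavy_idx = {
        r: [
            i
            for i, a in enumerate(traj.atoms)
            if a.residue_number == r and not a.name.startswith("H") and a.element != "H"
        ]
        for r in residues
    }
    specs: list[ContactPairSpec] = []
    for res_a, res_b in itertools.combinations(residues, 2):
        if not _in_screened_region(res_a, res_b, element_map):
            continue
        dmin = min_distance_series(traj, heavy_idx[res_a], heavy_idx[res_b]).min()
        if dmin > max_residue_distance:
            continue
        name_a = traj.residue_name(res_a)
        name_b = traj.residue_name(res_b)
        adjacent = abs(res_a - res_b) == 1
        for ga in _polar_groups(name_a, res_a):
            for gb in _polar_groups(name_b, res_b):
                if adjacent and ga["ctx"] != SIDECHAIN_CTX and gb["ctx"] != SIDECHAIN_CTX:
                    continue  # i,i+1 backbone pairs are trivial neighbours
                donor_ok = (ga["donor"] and gb["acceptor"]) or (ga["acceptor"] and gb["donor"])
                if not donor_ok:
                    continue
                salt = {ga["charge"], gb["charge"]} == {"basic", "acidic"}
                atoms_a = [a for a in ga["atoms"] if _atom_exists(traj, res_a, a)]
                atoms_b = [b for b in gb["atoms"] if _atom_exists(traj, res_b, b)]
                if not atoms_a or not atoms_b:
                    continue
                specs.append(
                    ContactPairSpec(
                        residue_a=res_a,
                        resname_a=name_a,
                        atoms_a=tuple(atoms_a),
                        context_a=ga["ctx"],
                        residue_b=res_b,
                        resname_b=name_b,
                        atoms_b=tuple(atoms_b),
                        context_b=gb["ctx"],
                        kind="salt-bridge" if salt else "H-bond",
                    )
                )
    return specs


def _atom_exists(traj: Trajectory, resnum: int, name: str) -> bool:
    return any(a.residue_number == resnum and a.name == name for a in traj.atoms)


# ---------------------------------------------------------------------------
# Filtering and taxonomy

def classify(spec: ContactPairSpec, element_map: ElementMap | None) -> str:
    """Assign one taxonomy category to a pair: ``intra-loop``,
    ``loop-matrix-helix``, ``inter-domain(i-j)`` or ``other``."""
    if element_map is None:
        return "other"
    ea = element_map.element_of(spec.residue_a)
    eb = element_map.element_of(spec.residue_b)
    if ea is None or eb is None:
        warnings.warn(
            f"{spec.label}: residue not covered by the element map; "
            "classified as 'other'",
            stacklevel=2,
        )
        return "other"
    (da, na), (db, nb) = ea, eb
    if da != db:
        lo, hi = sorted((da, db))
        interface = "3-1" if (lo, hi) == (1, 3) else f"{lo}-{hi}"
        return f"inter-domain({interface})"
    if na == "matrix_loop" and nb == "matrix_loop":
        return "intra-loop"
    if {na, nb} == {"matrix_loop", "matrix_helix"}:
        return "loop-matrix-helix"
    return "other"


def filter_and_classify(
    records: Iterable[InteractionRecord],
    threshold: float = DEFAULT_THRESHOLD_PCT,
    element_map: ElementMap | None = None,
) -> list[InteractionRecord]:
    """Retain records with average occupancy strictly above the threshold
    and assign each retained record exactly one taxonomy category."""
    retained = []
    for rec in records:
        if rec.average > threshold:
            retained.append(replace(rec, category=classify(rec.spec, element_map)))
    return retained


def interface_strength(
    records: Iterable[InteractionRecord],
    element_map: ElementMap | None = None,
) -> pd.DataFrame:
    """Occupancy totals and counts per taxonomy cell.

    Cells are (intra-loop × domain), (loop-matrix-helix × domain) and the
    three domain-domain interfaces, in a fixed deterministic order; cells
    with no records report zero.  ``element_map`` supplies the domain of
    intra-domain records; without it they fall into ``other``.
    """
    cells = [
        ("intra-loop", "1"),
        ("intra-loop", "2"),
        ("intra-loop", "3"),
        ("loop-matrix-helix", "1"),
        ("loop-matrix-helix", "2"),
        ("loop-matrix-helix", "3"),
        ("inter-domain", "1-2"),
        ("inter-domain", "2-3"),
        ("inter-domain", "3-1"),
        ("other", "-"),
    ]
    totals = {cell: 0.0 for cell in cells}
    counts = {cell: 0 for cell in cells}
    for rec in records:
        cat = rec.category or "other"
        if cat.startswith("inter-domain("):
            cell = ("inter-domain", cat[len("inter-domain(") : -1])
        elif cat in ("intra-loop", "loop-matrix-helix"):
            domain = element_map.domain_of(rec.spec.residue_a) if element_map else None
            cell = (cat, str(domain)) if domain else ("other", "-")
        else:
            cell = ("other", "-")
        if cell not in totals:
            cell = ("other", "-")
        totals[cell] += rec.average
        counts[cell] += 1
    return pd.DataFrame(
        {
            "category": [c for c, _ in cells],
            "slot": [w for _, w in cells],
            "total_occupancy": [totals[cell] for cell in cells],
            "count": [counts[cell] for cell in cells],
        }
    )


def records_to_table(records: Iterable[InteractionRecord]) -> pd.DataFrame:
    """Export records as a table mirroring the occupancy-table convention:
    label, per-trajectory occupancies (round-half-up integers), average,
    kind and category."""
    rows = []
    for rec in records:
        per, avg = rec.rounded()
        row = {"label": rec.spec.label}
        for i, o in enumerate(per, start=1):
            row[f"traj_{i}"] = o
        row["average"] = avg
        row["kind"] = rec.spec.kind
        row["category"] = rec.category or ""
        row["window"] = rec.window
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["label", "average", "kind", "category", "window"])
    return pd.DataFrame(rows)
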