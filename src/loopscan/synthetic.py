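"""Synthetic inputs with known ground truth.

Two families of generators:

* contact trajectories — residue pairs whose bound/unbound state follows
  a two-state Markov (telegraph) process with prescribed stationary
  occupancy p and lag-1 autocorrelation φ, rendered as atom coordinates
  (standard residue templates) with Gaussian positional noise;
* tripartite sequences and carrier families — three homologous domains
  with the matrix-side motifs planted at recorded positions and
  controlled D/E choices in the [DE]G position.

Everything is reproducible from an explicit integer seed (NumPy PCG64;
no environment-dependent parallelism).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import templates
from .core_io import Atom, Trajectory
from .errors import ScenarioError
from .interactions import ContactPairSpec
from .tripartite import TripletMap, build_triplet_map

# ---------------------------------------------------------------------------
# Contact trajectories

#: template atom sitting at the origin (the designated contact atom)
CONTACT_ATOM = {
    "ARG": "NH1",
    "LYS": "NZ",
    "GLU": "OE1",
    "ASP": "OD1",
    "SER": "OG",
    "GLN": "OE1",
    "GLY": "O",
    "ALA": "CB",
}


@dataclass(frozen=True)
class ContactPairScenario:
    """One synthetic residue pair with prescribed contact statistics."""

    p: float  # target stationary occupancy, in (0, 1]
    phi: float = 0.0  # lag-1 autocorrelation of the telegraph process
    bound_nm: float = 0.25
    unbound_nm: float = 0.45
    sigma_nm: float = 0.02
    residue_a: str = "ARG"
    residue_b: str = "GLU"
    resid_a: int | None = None
    resid_b: int | None = None

    def validate(self, cutoff_nm: float) -> None:
        if not 0 < self.p <= 1:
            raise ScenarioError(f"target occupancy p={self.p} outside (0, 1]")
        if not 0 <= self.phi < 1:
            raise ScenarioError(f"autocorrelation phi={self.phi} outside [0, 1)")
        if not self.bound_nm + 3 * self.sigma_nm < cutoff_nm:
            raise ScenarioError(
                f"separability violated: bound {self.bound_nm} + 3σ "
                f"not below cutoff {cutoff_nm}"
            )
        if not cutoff_nm < self.unbound_nm - 3 * self.sigma_nm:
            raise ScenarioError(
                f"separability violated: cutoff {cutoff_nm} not below "
                f"unbound {self.unbound_nm} - 3σ"
            )


@dataclass(frozen=True)
class ContactScenario:
    """A full synthetic-trajectory recipe; ``seed`` is mandatory."""

    pairs: tuple[ContactPairScenario, ...]
    n_frames: int
    seed: int
    frame_spacing_ps: float = 10.0
    cutoff_nm: float = 0.33
    pair_offset_nm: float = 10.0  # spatial separation between pairs

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ScenarioError("n_frames must be >= 1")
        resids: set[int] = set()
        for pair in self.pairs:
            pair.validate(self.cutoff_nm)
            for r in (pair.resid_a, pair.resid_b):
                if r is not None:
                    if r in resids:
                        raise ScenarioError(f"residue number {r} used twice")
                    resids.add(r)


@dataclass
class ContactTruth:
    """Ground truth emitted alongside a synthetic contact trajectory."""

    specs: list[ContactPairSpec]
    states: np.ndarray  # (n_pairs, n_frames) boolean bound/unbound
    scenario: ContactScenario

    def realized_occupancy(self, pair_index: int, frame_slice: slice | None = None) -> float:
        s = self.states[pair_index]
        if frame_slice is not None:
            s = s[frame_slice]
        return 100.0 * float(np.count_nonzero(s)) / s.size

    def to_table(self) -> pd.DataFrame:
        rows = []
        for i, spec in enumerate(self.specs):
            sc = self.scenario.pairs[i]
            rows.append(
                {
                    "label": spec.label,
                    "target_occupancy_pct": 100.0 * sc.p,
                    "phi": sc.phi,
                    "realized_occupancy_pct": self.realized_occupancy(i),
                }
            )
        return pd.DataFrame(rows)


def simulate_telegraph(
    p: float, phi: float, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """A stationary two-state Markov chain with P(bound) = p and lag-1
    autocorrelation φ.  φ = 0 recovers i.i.d. Bernoulli frames."""
    stay_bound = phi + (1 - phi) * p
    gain = (1 - phi) * p
    u = rng.random(n_frames)
    states = np.empty(n_frames, dtype=bool)
    states[0] = u[0] < p
    for t in range(1, n_frames):
        threshold = stay_bound if states[t - 1] else gain
        states[t] = u[t] < threshold
    return states


def effective_sample_size(n: int, phi: float) -> float:
    """Effective number of independent frames under lag-1 autocorrelation φ."""
    return n * (1 - phi) / (1 + phi)


def _pair_spec(sc: ContactPairScenario, resid_a: int, resid_b: int) -> ContactPairSpec:
    rn_a, rn_b = sc.residue_a.upper(), sc.residue_b.upper()

    def sidechain_set(rn: str) -> tuple[str, ...]:
        if rn in templates.BASIC_SIDECHAIN:
            return templates.BASIC_SIDECHAIN[rn]
        if rn in templates.ACIDIC_SIDECHAIN:
            return templates.ACIDIC_SIDECHAIN[rn]
        polar = templates.SIDECHAIN_POLAR.get(rn)
        if polar:
            return tuple(polar)
        return (CONTACT_ATOM[rn],)

    basic_acidic = (rn_a in templates.BASIC_SIDECHAIN and rn_b in templates.ACIDIC_SIDECHAIN) or (
        rn_b in templates.BASIC_SIDECHAIN and rn_a in templates.ACIDIC_SIDECHAIN
    )
    return ContactPairSpec(
        residue_a=resid_a,
        resname_a=rn_a,
        atoms_a=sidechain_set(rn_a),
        context_a="",
        residue_b=resid_b,
        resname_b=rn_b,
        atoms_b=sidechain_set(rn_b),
        context_b="",
        kind="salt-bridge" if basic_acidic else "H-bond",
    )


def gen_contact_trajectory(scenario: ContactScenario) -> tuple[Trajectory, ContactTruth]:
    """Render a contact scenario as a coordinate trajectory plus truth.

    Residue A of each pair is anchored; residue B is rigidly offset along
    z to the bound/unbound tip distance of the current telegraph state,
    then displaced by one isotropic Gaussian (σ per axis) per frame.
    Pairs are spatially separated so they cannot cross-contact.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    n_frames = scenario.n_frames

    atoms: list[Atom] = []
    specs: list[ContactPairSpec] = []
    states = np.empty((len(scenario.pairs), n_frames), dtype=bool)
    static_coords: list[np.ndarray] = []  # per atom, the noise-free position
    mobile_atom_idx: list[list[int]] = []  # atoms of residue B, per pair
    tip_z: list[np.ndarray] = []

    serial = 1
    next_resid = 1
    for k, sc in enumerate(scenario.pairs):
        resid_a = sc.resid_a if sc.resid_a is not None else next_resid
        next_resid = max(next_resid, resid_a + 1)
        resid_b = sc.resid_b if sc.resid_b is not None else next_resid
        next_resid = max(next_resid, resid_b + 1)
        base_x = k * scenario.pair_offset_nm
        rn_a, rn_b = sc.residue_a.upper(), sc.residue_b.upper()
        for rn, resid in ((rn_a, resid_a), (rn_b, resid_b)):
            if rn not in templates.RESIDUE_TEMPLATES:
                raise ScenarioError(f"no coordinate template for residue {rn}")
        for name, (x, y, z) in templates.RESIDUE_TEMPLATES[rn_a].items():
            atoms.append(Atom(serial, name, rn_a, resid_a, "A", name[:1]))
            static_coords.append(np.array([base_x + x, y, z]))
            serial += 1
        b_idx = []
        for name, (x, y, z) in templates.RESIDUE_TEMPLATES[rn_b].items():
            atoms.append(Atom(serial, name, rn_b, resid_b, "A", name[:1]))
            # mirror through the contact plane: tip stays at z offset 0
            static_coords.append(np.array([base_x + x, y, -z]))
            b_idx.append(len(static_coords) - 1)
            serial += 1
        mobile_atom_idx.append(b_idx)
        states[k] = simulate_telegraph(sc.p, sc.phi, n_frames, rng)
        tip_z.append(np.where(states[k], sc.bound_nm, sc.unbound_nm))
        specs.append(_pair_spec(sc, resid_a, resid_b))

    base = np.asarray(static_coords)  # (n_atoms, 3)
    coords = np.broadcast_to(base, (n_frames,) + base.shape).copy()
    for k, sc in enumerate(scenario.pairs):
        displacement = np.zeros((n_frames, 3))
        displacement[:, 2] = tip_z[k]
        if sc.sigma_nm > 0:
            displacement += rng.normal(0.0, sc.sigma_nm, size=(n_frames, 3))
        idx = np.asarray(mobile_atom_idx[k], dtype=int)
        coords[:, idx, :] += displacement[:, None, :]

    traj = Trajectory(
        atoms=atoms,
        coordinates=coords,
        frame_spacing=scenario.frame_spacing_ps,
    )
    return traj, ContactTruth(specs=specs, states=states, scenario=scenario)


# ---------------------------------------------------------------------------
# Tripartite sequences

#: 0-based offsets of the planted motifs within each domain
MOTIF_OFFSETS = {
    "Px[DE]xx[KR]xRxQxQ": 0,
    "[YF]xG": 23,
    "DCxx[RK]": 28,
    "[DE]G": 37,
    "[YWF][KR]G": 43,
}
MIN_DOMAIN_LENGTH = 50

#: filler alphabet: residues that cannot complete any planted motif
FILLER_ALPHABET = "AILVMNHST"


@dataclass(frozen=True)
class SequenceScenario:
    """Recipe for tripartite sequences / families with planted motifs."""

    seed: int
    domain_length: int = 60
    deg_letters: tuple[str, str, str] = ("E", "D", "E")
    family_size: int = 1
    e_probs: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def validate(self) -> None:
        if self.domain_length < MIN_DOMAIN_LENGTH:
            raise ScenarioError(
                f"domain_length must be >= {MIN_DOMAIN_LENGTH} so planted "
                "motifs do not collide"
            )
        for letter in self.deg_letters:
            if letter not in ("D", "E"):
                raise ScenarioError(f"[DE]G first residue must be D or E, got {letter!r}")
        if self.family_size < 1:
            raise ScenarioError("family_size must be >= 1")
        for p in self.e_probs:
            if not 0 <= p <= 1:
                raise ScenarioError(f"E probability {p} outside [0, 1]")


@dataclass
class TripartiteTruth:
    """Everything the generator planted, for oracle-style assertions."""

    sequence: str
    domain_starts: tuple[int, int, int]
    alignment_rows: list[tuple[str, str]]  # (id, aligned sequence)
    motif_starts: dict[tuple[str, int], int]  # (motif, domain) -> residue number
    deg_letters: tuple[str, str, str]
    elements: dict[int, dict[str, tuple[int, int]]]
    anchor_triplets: dict[str, int]
    plug_triplet: int
    deg_windows: tuple[tuple[int, int], ...]  # matrix-helix range per domain

    def triplet_map(self) -> TripletMap:
        return build_triplet_map(self.alignment_rows, self.domain_starts)


def _domain_sequence(
    length: int, deg_letter: str, rng: np.random.Generator
) -> tuple[str, dict[str, int]]:
    """One domain with the canonical matrix-side motif layout planted."""
    filler = rng.choice(list(FILLER_ALPHABET), size=length)
    seq = list(filler)

    def plant(offset: int, letters: str):
        for i, ch in enumerate(letters):
            seq[offset + i] = ch

    f = lambda: str(rng.choice(list(FILLER_ALPHABET)))  # noqa: E731
    px = MOTIF_OFFSETS["Px[DE]xx[KR]xRxQxQ"]
    plant(px, "P" + f() + "E" + f() + f() + "K" + f() + "R" + f() + "Q" + f() + "Q")
    yxg = MOTIF_OFFSETS["[YF]xG"]
    plant(yxg, "Y" + f() + "G")
    dc = MOTIF_OFFSETS["DCxx[RK]"]
    plant(dc, "DC" + f() + f() + "R")
    deg = MOTIF_OFFSETS["[DE]G"]
    plant(deg, deg_letter + "G")
    ywf = MOTIF_OFFSETS["[YWF][KR]G"]
    plant(ywf, "Y" + "R" + "G")
    return "".join(seq), dict(MOTIF_OFFSETS)


def gen_tripartite_sequence(scenario: SequenceScenario) -> TripartiteTruth:
    """Generate one tripartite sequence, its truth annotation and the
    gap-free three-row domain alignment."""
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    L = scenario.domain_length
    domains = []
    for d in range(3):
        seq_d, _ = _domain_sequence(L, scenario.deg_letters[d], rng)
        domains.append(seq_d)
    sequence = "".join(domains)
    starts = (1, L + 1, 2 * L + 1)

    motif_starts: dict[tuple[str, int], int] = {}
    elements: dict[int, dict[str, tuple[int, int]]] = {}
    windows = []
    for d in range(1, 4):
        s = starts[d - 1]
        for motif, offset in MOTIF_OFFSETS.items():
            motif_starts[(motif, d)] = s + offset
        # the final Q of the matrix-gate motif (one past the hydrophobic
        # plug position) is the loop N-end
        loop = (s + MOTIF_OFFSETS["Px[DE]xx[KR]xRxQxQ"] + 11, s + MOTIF_OFFSETS["[YF]xG"] - 1)
        helix = (s + MOTIF_OFFSETS["[YF]xG"], s + MOTIF_OFFSETS["[DE]G"] + 1)
        elements[d] = {
            "matrix_loop": loop,
            "matrix_helix": helix,
            "domain_span": (s, s + L - 1),
        }
        windows.append(helix)

    anchor_triplets = {motif: 1 + offset for motif, offset in MOTIF_OFFSETS.items()}
    return TripartiteTruth(
        sequence=sequence,
        domain_starts=starts,
        alignment_rows=[
            (f"domain{d}/{starts[d - 1]}-{starts[d - 1] + L - 1}", domains[d - 1])
            for d in (1, 2, 3)
        ],
        motif_starts=motif_starts,
        deg_letters=scenario.deg_letters,
        elements=elements,
        anchor_triplets=anchor_triplets,
        plug_triplet=1 + MOTIF_OFFSETS["Px[DE]xx[KR]xRxQxQ"] + 10,
        deg_windows=tuple(windows),
    )


# ---------------------------------------------------------------------------
# Carrier families

@dataclass
class FamilyTruth:
    entries: list[tuple[str, str]]  # (identifier, sequence)
    table: pd.DataFrame  # identifier, d1/d2/d3 planted letters
    deg_windows: tuple[tuple[int, int], ...]


def gen_family(
    scenario: SequenceScenario,
    names: Sequence[str] | None = None,
) -> FamilyTruth:
    """Generate a family of tripartite carriers.

    Per member and domain, the [DE]G first residue is E with probability
    ``e_probs[d]`` (else D).  ``names`` overrides the default identifiers
    (e.g. to plant names appearing on the exclusion lists).
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    n = scenario.family_size
    if names is not None and len(names) != n:
        raise ScenarioError(f"{len(names)} names given for family of {n}")
    entries = []
    rows = []
    windows = None
    for i in range(n):
        letters = tuple(
            "E" if rng.random() < scenario.e_probs[d] else "D" for d in range(3)
        )
        member_seed = int(rng.integers(0, 2**31 - 1))
        truth = gen_tripartite_sequence(
            SequenceScenario(
                seed=member_seed,
                domain_length=scenario.domain_length,
                deg_letters=letters,  # type: ignore[arg-type]
            )
        )
        windows = truth.deg_windows
        ident = names[i] if names is not None else f"MC{i + 1:03d}"
        entries.append((ident, truth.sequence))
        rows.append(
            {"identifier": ident, "d1": letters[0], "d2": letters[1], "d3": letters[2]}
        )
    return FamilyTruth(
        entries=entries, table=pd.DataFrame(rows), deg_windows=windows
    )


def write_family_fasta(truth: FamilyTruth, path) -> None:
    with open(path, "w") as handle:
        for ident, seq in truth.entries:
            handle.write(f">{ident}\n")
            for i in range(0, len(seq), 60):
                handle.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Carrier-like fixture
#
# A synthetic stand-in for the bovine carrier: filler residues are
# arbitrary, but every residue identity and alignment relationship the
# analysis relies on (triplet anchors, motif placements, the RRRMMM run,
# D167/G168 and E264/G265, T232, capping arginines, ...) is honoured.

_AAC_RESIDUES = {
    # domain 1 (27-65)
    27: "P", 29: "E", 30: "R", 31: "V", 32: "K", 36: "Q", 37: "V", 38: "Q",
    39: "H", 40: "A", 41: "S", 50: "Y", 52: "G", 55: "D", 56: "C", 59: "R",
    64: "E", 65: "G",
    # inter-domain turn with the stacking arginine
    70: "Y", 71: "R", 72: "G",
    # domain 2 (132-168)
    132: "P", 134: "E", 137: "K", 139: "R", 141: "A", 142: "A", 143: "D",
    144: "N", 145: "G", 151: "R", 152: "E", 153: "F", 155: "G", 158: "D",
    159: "C", 162: "K", 166: "S", 167: "D", 168: "G",
    # domain 3 (229-265)
    229: "P", 231: "D", 232: "T", 234: "R", 235: "R", 236: "R", 237: "M",
    238: "M", 239: "M", 240: "Q", 241: "S", 242: "G", 243: "R", 244: "K",
    247: "D", 250: "Y", 252: "G", 255: "D", 256: "C", 259: "K", 264: "E",
    265: "G",
}

AAC_DOMAIN_STARTS = (27, 132, 229)
AAC_SEQUENCE_LENGTH = 270


@dataclass
class CarrierFixture:
    """Synthetic carrier-like sequence + gapped three-domain alignment."""

    sequence: str
    alignment_rows: list[tuple[str, str]]
    domain_starts: tuple[int, int, int]
    elements: dict[int, dict[str, tuple[int, int]]]

    def triplet_map(self) -> TripletMap:
        return build_triplet_map(self.alignment_rows, self.domain_starts)

    def write_alignment_fasta(self, path) -> None:
        with open(path, "w") as handle:
            for ident, row in self.alignment_rows:
                handle.write(f">{ident}\n{row}\n")


def _res(seq: str, number: int) -> str:
    return seq[number - 1]


def _slice(seq: str, start: int, end: int) -> str:
    return seq[start - 1 : end]


def aac_like(seed: int = 20220917) -> CarrierFixture:
    """Build the synthetic carrier-like fixture.

    The alignment reproduces the indel structure the triplet anchors
    imply: domains 2/3 carry a four-residue insertion between the kink
    proline and the capping arginine (so triplets 27→(27,132,229) and
    30→(30,139,236) coexist), domain 1 is four longer between the capping
    arginine and the hydrophobic plug, and two residues longer inside the
    matrix loop.
    """
    rng = np.random.default_rng(seed)
    seq = [str(rng.choice(list(FILLER_ALPHABET))) for _ in range(AAC_SEQUENCE_LENGTH)]
    for pos, letter in _AAC_RESIDUES.items():
        seq[pos - 1] = letter
    sequence = "".join(seq)

    gap = "-"
    d1 = _slice(sequence, 27, 29) + gap * 4 + _slice(sequence, 30, 65)
    d2 = (
        _slice(sequence, 132, 141)
        + gap * 4
        + _slice(sequence, 142, 152)
        + gap * 2
        + _slice(sequence, 153, 168)
    )
    d3 = (
        _slice(sequence, 229, 238)
        + gap * 4
        + _slice(sequence, 239, 249)
        + gap * 2
        + _slice(sequence, 250, 265)
    )
    rows = [
        ("domain1/27-65", d1),
        ("domain2/132-168", d2),
        ("domain3/229-265", d3),
    ]
    elements = {
        1: {"matrix_loop": (38, 49), "matrix_helix": (50, 65), "domain_span": (27, 65)},
        2: {"matrix_loop": (143, 152), "matrix_helix": (153, 168), "domain_span": (132, 168)},
        3: {"matrix_loop": (240, 249), "matrix_helix": (250, 265), "domain_span": (229, 265)},
    }
    return CarrierFixture(
        sequence=sequence,
        alignment_rows=rows,
        domain_starts=AAC_DOMAIN_STARTS,
        elements=elements,
    )
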