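"""Per-residue RMSF, the side-chain orientation angle θ, and
minimum-distance time series.

θ is the angle at a vertex atom between rays to two reference atoms; the
default spec reproduces the capping-arginine orientation metric
(Cζ of R236 — Cα of R236 — Cα of T232).  RMSF is computed after
least-squares (Kabsch) superposition of every frame onto a reference
structure over Cα atoms, so rigid-body motion does not contribute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core_io import Selection, Trajectory, select
from .errors import LoopscanError, SelectionError
from .interactions import min_distance_series

#: (residue_number, atom_name) references: rays vertex->a and vertex->c
AtomRef = tuple[int, str]


@dataclass(frozen=True)
class AngleSpec:
    """Three atom references A, B, C with the vertex at B."""

    a: AtomRef = (236, "CZ")
    b: AtomRef = (236, "CA")
    c: AtomRef = (232, "CA")

    def __post_init__(self):
        if len({self.a, self.b, self.c}) != 3:
            raise ValueError("angle spec needs three distinct atoms")


THETA_SPEC = AngleSpec()  # the capping-arginine orientation angle


@dataclass(frozen=True)
class SeriesResult:
    """A named per-frame scalar series (angle in degrees or distance in nm)."""

    times: np.ndarray  # ps
    values: np.ndarray
    metric: str

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise ValueError("times and values must have equal length")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, self.metric: self.values})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def _ref_index(traj: Trajectory, ref: AtomRef) -> int:
    try:
        return traj.atom_index(ref[0], ref[1])
    except SelectionError:
        raise SelectionError(f"angle atom {ref[1]} of residue {ref[0]} not found") from None


def angle_series(traj: Trajectory, spec: AngleSpec = THETA_SPEC) -> SeriesResult:
    """Per-frame angle (degrees, in [0, 180]) at the vertex of an AngleSpec."""
    ia, ib, ic = (_ref_index(traj, r) for r in (spec.a, spec.b, spec.c))
    va = traj.coordinates[:, ia] - traj.coordinates[:, ib]
    vc = traj.coordinates[:, ic] - traj.coordinates[:, ib]
    na = np.linalg.norm(va, axis=1)
    nc = np.linalg.norm(vc, axis=1)
    if np.any(na == 0) or np.any(nc == 0):
        raise LoopscanError("degenerate angle: coincident atoms in some frame")
    cosang = np.clip((va * vc).sum(axis=1) / (na * nc), -1.0, 1.0)
    return SeriesResult(
        times=traj.times, values=np.degrees(np.arccos(cosang)), metric="theta_deg"
    )


# ---------------------------------------------------------------------------
# RMSF

def _kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation/translation of ``mobile`` onto ``target``.

    Returns (rotation matrix, translation) applied as ``x @ R.T + t``.
    """
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - mu_t, mobile - mu_m)
    R = rot.as_matrix()
    t = mu_t - mu_m @ R.T
    return R, t


def rmsf(
    traj: Trajectory,
    selection: Selection | str | None = None,
    reference: str = "first",
    fit_selection: Selection | str | None = None,
) -> pd.DataFrame:
    """Per-residue Cα root-mean-square fluctuation (nm).

    Every frame is least-squares superposed onto the reference structure
    over the fit atoms (all Cα by default), then
    ``RMSF_i = sqrt(mean_t ||x_i(t) - x̄_i||^2)`` for each selected
    residue's Cα.  ``reference`` is ``"first"`` (default) or ``"mean"``
    (two-pass: fit to the first frame, then refit to the time average).
    """
    if traj.n_frames < 2:
        raise LoopscanError("RMSF needs at least 2 frames")
    if fit_selection is None:
        fit_selection = "name CA"
    if isinstance(fit_selection, str):
        fit_selection = select(traj, fit_selection)
    if selection is None:
        selection = fit_selection
    elif isinstance(selection, str):
        selection = select(traj, selection)

    fit_idx = np.asarray(fit_selection.resolved_atoms, dtype=int)
    sel_idx = np.asarray(selection.resolved_atoms, dtype=int)
    if reference not in ("first", "mean"):
        raise ValueError("reference must be 'first' or 'mean'")

    def superpose_all(target_fit: np.ndarray) -> np.ndarray:
        out = np.empty((traj.n_frames, len(sel_idx), 3))
        for f in range(traj.n_frames):
            R, t = _kabsch_superpose(traj.coordinates[f, fit_idx], target_fit)
            out[f] = traj.coordinates[f, sel_idx] @ R.T + t
        return out

    target = traj.coordinates[0, fit_idx]
    aligned = superpose_all(target)
    if reference == "mean":
        # refit everything onto the time-average of the first pass
        mean_fit = np.empty((len(fit_idx), 3))
        first_pass = np.empty((traj.n_frames, len(fit_idx), 3))
        for f in range(traj.n_frames):
            R, t = _kabsch_superpose(traj.coordinates[f, fit_idx], target)
            first_pass[f] = traj.coordinates[f, fit_idx] @ R.T + t
        mean_fit = first_pass.mean(axis=0)
        aligned = superpose_all(mean_fit)

    mean_pos = aligned.mean(axis=0)
    fluct = np.sqrt(((aligned - mean_pos) ** 2).sum(axis=2).mean(axis=0))
    residues = [traj.atoms[i].residue_number for i in sel_idx]
    return pd.DataFrame({"residue": residues, "rmsf_nm": fluct})


# ---------------------------------------------------------------------------
# Minimum-distance series

def distance_series(
    traj: Trajectory,
    res_a: int | Sequence[int],
    res_b: int | Sequence[int],
    scope: str = "heavy",
) -> SeriesResult:
    """Per-frame minimum distance (nm) between two residues (or residue
    groups).  ``scope`` is ``"heavy"`` (all non-hydrogen atoms) or
    ``"sidechain"`` (heavy atoms beyond Cα)."""
    if scope not in ("heavy", "sidechain"):
        raise ValueError("scope must be 'heavy' or 'sidechain'")
    backbone = {"N", "CA", "C", "O", "OXT"}

    def indices(res) -> list[int]:
        res_set = {res} if isinstance(res, int) else set(res)
        idx = [
            i
            for i, a in enumerate(traj.atoms)
            if a.residue_number in res_set
            and a.element != "H"
            and not a.name.startswith("H")
            and (scope == "heavy" or a.name not in backbone)
        ]
        if not idx:
            raise SelectionError(f"no {scope} atoms for residue(s) {res}")
        return idx

    values = min_distance_series(traj, indices(res_a), indices(res_b))
    return SeriesResult(times=traj.times, values=values, metric="min_distance_nm")
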