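"""End-to-end orchestration from a single JSON config.

The pipeline chains: motif annotation → triplet map → element derivation
→ pair enumeration → occupancy → filter/classify → interface strength →
geometry metrics → family survey, writing a table bundle plus a JSON
manifest that embeds the full parameterisation and a checksum of every
output, so reruns with an identical config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core_io import read_multimodel_pdb
from .errors import PipelineError
from .geometry import AngleSpec, angle_series, distance_series, rmsf
from .interactions import (
    DEFAULT_CUTOFF_NM,
    DEFAULT_THRESHOLD_PCT,
    DEFAULT_WINDOW_FRACTION,
    DEFAULT_WINDOW_PS,
    Window,
    compute_records,
    enumerate_pairs,
    filter_and_classify,
    interface_strength,
    records_to_table,
)
from .motifs import annotate_mcf
from .survey import (
    CHARGED_SECOND_POSITION,
    OUTSIDE_IMM,
    apply_exclusions,
    call_entries,
    e_frequency,
    read_family_fasta,
    survey_table,
)
from .tripartite import ElementMap, build_triplet_map, derive_elements

logger = logging.getLogger("loopscan")


@dataclass
class RunConfig:
    """Run parameterisation; defaults match the reference analysis
    (0.33 nm cutoff, trailing 2 us window, strict 25% threshold)."""

    output_dir: str
    trajectories: list[str] = field(default_factory=list)
    alignment: str | None = None
    domain_starts: list[int] | None = None
    sequence: str | None = None  # protein sequence for motif annotation
    elements: dict | None = None  # explicit element ranges, overrides derivation
    family_fasta: str | None = None
    deg_windows: list[list[int]] | None = None
    groups: dict | None = None
    cutoff_nm: float = DEFAULT_CUTOFF_NM
    threshold_pct: float = DEFAULT_THRESHOLD_PCT
    window_ps: float = DEFAULT_WINDOW_PS
    window_fraction_fallback: float = DEFAULT_WINDOW_FRACTION
    max_residue_distance_nm: float = 0.6
    plug_triplet: int = 37
    theta_atoms: list[list] | None = None  # [[resid, name] x 3]
    rmsf_enabled: bool = False
    mindist_pairs: list[list[int]] = field(default_factory=list)
    outside_imm: list[str] = field(default_factory=lambda: list(OUTSIDE_IMM))
    charged_second: list[str] = field(default_factory=lambda: list(CHARGED_SECOND_POSITION))
    frame_spacing_ps: float = 10.0
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = json.load(handle)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest (also written to disk).

    Any stage failure aborts with :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    manifest: dict = {"version": __version__, "parameters": config.to_dict(), "stages": []}

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    # --- triplet map & elements ---------------------------------------
    tmap = None
    element_map = None
    try:
        if config.alignment:
            stage("triplet_map")
            starts = tuple(config.domain_starts) if config.domain_starts else None
            tmap = build_triplet_map(config.alignment, starts)
            _write_tsv(tmap.to_table(), outdir / "triplet_map.tsv")
            outputs.append(outdir / "triplet_map.tsv")
    except Exception as exc:
        raise PipelineError("triplet_map", exc) from exc

    try:
        if config.elements is not None:
            stage("elements(explicit)")
            element_map = ElementMap(
                elements={
                    int(d): {name: tuple(rng) for name, rng in named.items()}
                    for d, named in config.elements.items()
                }
            )
        elif tmap is not None and config.sequence:
            stage("motif_annotation")
            hits = annotate_mcf(config.sequence, tmap)
            stage("element_derivation")
            element_map = derive_elements(tmap, hits, plug_triplet=config.plug_triplet)
    except Exception as exc:
        raise PipelineError("element_derivation", exc) from exc

    # --- trajectories & interactions ----------------------------------
    trajs = []
    try:
        if config.trajectories:
            stage("read_trajectories")
            trajs = [
                read_multimodel_pdb(p, frame_spacing=config.frame_spacing_ps)
                for p in config.trajectories
            ]
    except Exception as exc:
        raise PipelineError("read_trajectories", exc) from exc

    records = []
    if trajs:
        try:
            stage("pair_enumeration")
            specs = enumerate_pairs(
                trajs[0], element_map, max_residue_distance=config.max_residue_distance_nm
            )
            stage("occupancy")
            span = float(trajs[0].times[-1] - trajs[0].times[0])
            if span > config.window_ps:
                window = Window.last_ps(config.window_ps)
            else:
                window = Window.last_fraction(config.window_fraction_fallback)
                logger.info(
                    "trajectory span %.0f ps shorter than the %.0f ps window; "
                    "using trailing fraction %.3f",
                    span,
                    config.window_ps,
                    config.window_fraction_fallback,
                )
            all_records = compute_records(trajs, specs, cutoff=config.cutoff_nm, window=window)
            stage("filter_classify")
            records = filter_and_classify(
                all_records, threshold=config.threshold_pct, element_map=element_map
            )
            _write_tsv(records_to_table(records), outdir / "interactions.tsv")
            outputs.append(outdir / "interactions.tsv")
            stage("interface_strength")
            _write_tsv(
                interface_strength(records, element_map), outdir / "interface_summary.tsv"
            )
            outputs.append(outdir / "interface_summary.tsv")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("interactions", exc) from exc

        # --- geometry -------------------------------------------------
        try:
            if config.theta_atoms:
                stage("theta")
                (ra, na), (rb, nb), (rc, nc) = config.theta_atoms
                spec = AngleSpec(a=(int(ra), na), b=(int(rb), nb), c=(int(rc), nc))
                for i, traj in enumerate(trajs, start=1):
                    series = angle_series(traj, spec)
                    series.to_tsv(outdir / f"theta_traj{i}.tsv")
                    outputs.append(outdir / f"theta_traj{i}.tsv")
            if config.rmsf_enabled:
                stage("rmsf")
                for i, traj in enumerate(trajs, start=1):
                    _write_tsv(rmsf(traj), outdir / f"rmsf_traj{i}.tsv")
                    outputs.append(outdir / f"rmsf_traj{i}.tsv")
            for res_a, res_b in config.mindist_pairs:
                stage(f"mindist({res_a},{res_b})")
                for i, traj in enumerate(trajs, start=1):
                    series = distance_series(traj, int(res_a), int(res_b))
                    series.to_tsv(outdir / f"mindist_{res_a}_{res_b}_traj{i}.tsv")
                    outputs.append(outdir / f"mindist_{res_a}_{res_b}_traj{i}.tsv")
        except Exception as exc:
            raise PipelineError("geometry", exc) from exc

    # --- family survey -------------------------------------------------
    if config.family_fasta:
        try:
            stage("family_survey")
            entries = read_family_fasta(config.family_fasta)
            if not config.deg_windows:
                raise ValueError("deg_windows are required for the family survey")
            windows = [tuple(w) for w in config.deg_windows]
            called = call_entries(entries, windows)
            retained, excluded = apply_exclusions(
                called, config.outside_imm, config.charged_second
            )
            _write_tsv(survey_table(retained, excluded), outdir / "survey.tsv")
            outputs.append(outdir / "survey.tsv")
            _write_tsv(e_frequency(retained, config.groups), outdir / "e_frequency.tsv")
            outputs.append(outdir / "e_frequency.tsv")
        except Exception as exc:
            raise PipelineError("family_survey", exc) from exc

    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(outputs)}
    manifest["n_retained_interactions"] = len(records)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
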