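"""End-to-end pipeline: ingest -> fits -> matrix -> embeddings -> ranges -> tree.

Driven by a :class:`PipelineConfig` (loadable from YAML); writes a
deterministic report bundle (CSV/JSON tables, PNG figures, run manifest)
into an output directory.  Every table carries the config hash that
produced it, so bundles are reproducible and self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import yaml

from . import age_range as ar
from . import embedding as emb
from . import io as ndio
from . import multistep as ms
from . import simulate as sim
from . import trajectories as traj
from . import tree as ndtree

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fit", "matrix", "embed", "ranges", "tree", "all")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name (and stratum if known)."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclasses.dataclass
class PipelineConfig:
    """Everything needed to run the pipeline reproducibly.

    ``input_csv`` switches from the synthetic panel to user data; all
    thresholds and parameters below mirror the module defaults.
    """

    input_csv: str | None = None
    seed: int = 0
    noise_sigma: float = 0.1
    n_studies: int = 3
    bin_jitter: float = 2.0
    age_grid_min: int = 30
    age_grid_max: int = 79
    truncation: bool = True
    gate_r2: float = ms.DEFAULT_GATE_R2
    apply_registry_filter: bool = True
    umap_neighbors: int = emb.DEFAULT_UMAP_NEIGHBORS
    umap_min_dist: float = emb.DEFAULT_UMAP_MIN_DIST
    shared_bin_width: float = 2.0
    sex_mode: str = "pooled"
    run_umap: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.gate_r2:
            raise ValueError("gate_r2 must be >= 0")
        if self.age_grid_min >= self.age_grid_max:
            raise ValueError("age_grid_min must be < age_grid_max")
        if self.shared_bin_width <= 0:
            raise ValueError("shared_bin_width must be positive")
        if self.sex_mode not in ("pooled", "split"):
            raise ValueError("sex_mode must be 'pooled' or 'split'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @property
    def age_grid(self) -> list[float]:
        return [float(a) for a in range(self.age_grid_min, self.age_grid_max + 1)]


def _load_panel(config: PipelineConfig) -> list[ndio.IncidenceDataset]:
    if config.input_csv:
        panel = ndio.read_incidence_table(config.input_csv)
    else:
        panel = sim.default_panel(
            seed=config.seed,
            noise_sigma=config.noise_sigma,
            n_studies=config.n_studies,
        )
    if config.apply_registry_filter:
        panel = ndio.filter_registry(panel)
    return panel


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, stage: str = "all"
) -> dict:
    """Run the pipeline up to ``stage`` and write the report bundle.

    Returns a report dict with the in-memory results and the artifact
    paths.  Idempotent: a rerun with the same config writes byte-identical
    CSV/JSON artifacts.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"config={config.config_hash()} seed={config.seed}"
    artifacts: dict[str, str] = {}
    report: dict = {"config_hash": config.config_hash(), "artifacts": artifacts}
    notes: list[str] = []

    def want(s: str) -> bool:
        return stage == "all" or STAGES.index(stage) >= STAGES.index(s)

    # ---- simulate / ingest ------------------------------------------------
    try:
        panel = _load_panel(config)
    except Exception as exc:
        raise PipelineStageError("simulate", str(exc)) from exc
    report["panel"] = panel
    panel_csv = outdir / "panel.csv"
    ndio.write_incidence_table(panel, panel_csv, header_comment=tag)
    artifacts["panel"] = panel_csv.name
    if not config.input_csv:
        sim.write_manifest(
            sim.default_specs(
                noise_sigma=config.noise_sigma, n_studies=config.n_studies
            ),
            config.seed,
            outdir / "panel_manifest.json",
        )
        artifacts["panel_manifest"] = "panel_manifest.json"
    if not want("fit"):
        _write_manifest(config, outdir, artifacts, notes)
        return report

    # ---- multistep fits ---------------------------------------------------
    grouped = ndio.group_by_stratum(panel)
    fits: dict[str, ms.MultistepFit] = {}
    for label, dsets in grouped.items():
        try:
            fits[label] = ms.MultistepModel.from_datasets(
                dsets, gate_r2=config.gate_r2, truncation=config.truncation
            ).fit()
        except Exception as exc:
            raise PipelineStageError("fit", f"stratum {label}: {exc}") from exc
    report["fits"] = fits
    fits_frame = ar.fits_to_frame(fits)
    _write_csv(fits_frame, outdir / "fits.csv", tag)
    artifacts["fits"] = "fits.csv"
    if not want("matrix"):
        _write_manifest(config, outdir, artifacts, notes)
        return report

    # ---- harmonized incidence matrix -------------------------------------
    try:
        matrix = traj.build_incidence_matrix(panel, config.age_grid)
    except Exception as exc:
        raise PipelineStageError("matrix", str(exc)) from exc
    report["matrix"] = matrix
    matrix.to_csv(outdir / "incidence_matrix.csv", header_comment=tag)
    matrix.coverage_to_json(outdir / "incidence_matrix_coverage.json")
    artifacts["incidence_matrix"] = "incidence_matrix.csv"
    artifacts["incidence_matrix_coverage"] = "incidence_matrix_coverage.json"
    if not want("embed"):
        _write_manifest(config, outdir, artifacts, notes)
        return report

    # ---- embeddings -------------------------------------------------------
    try:
        profiles = traj.dataset_profile_table(panel, config.age_grid)
        pca = emb.pca_embed(profiles)
        report["pca"] = pca
        _write_csv(
            pca.coordinates.rename_axis("profile").reset_index(),
            outdir / "pca.csv",
            tag
            + " explained_pct="
            + ",".join(f"{v:.3f}" for v in pca.explained_variance_pct),
        )
        emb.plot_embedding(pca, outdir / "pca.png")
        artifacts["pca"] = "pca.csv"
        if config.run_umap:
            um = emb.umap_embed(
                profiles,
                n_neighbors=config.umap_neighbors,
                min_dist=config.umap_min_dist,
                seed=config.seed,
            )
            report["umap"] = um
            _write_csv(
                um.coordinates.rename_axis("profile").reset_index(),
                outdir / "umap.csv",
                tag,
            )
            emb.plot_embedding(um, outdir / "umap.png")
            artifacts["umap"] = "umap.csv"
    except Exception as exc:
        raise PipelineStageError("embed", str(exc)) from exc
    if not want("ranges"):
        _write_manifest(config, outdir, artifacts, notes)
        return report

    # ---- age ranges, years/step, shared bins ------------------------------
    try:
        summaries = [
            ar.summarize_stratum(
                label, dsets, fits.get(label), truncation=config.truncation
            )
            for label, dsets in grouped.items()
        ]
        report["summaries"] = summaries
        _write_csv(ar.summaries_to_frame(summaries), outdir / "age_ranges.csv", tag)
        artifacts["age_ranges"] = "age_ranges.csv"
        shared = ar.shared_age_bins(summaries, config.shared_bin_width)
        _write_csv(shared, outdir / "shared_age_bins.csv", tag)
        artifacts["shared_age_bins"] = "shared_age_bins.csv"
        report["shared_bins"] = shared
        n_gated = sum(1 for s in summaries if s.passes_linearity)
        if n_gated >= 3:
            report["steps_vs_range"] = ar.fit_steps_vs_range(summaries)
        else:
            report["steps_vs_range"] = None
            notes.append(
                f"steps-vs-range regression skipped: only {n_gated} strata "
                "pass the linearity gate (need >= 3)"
            )
    except Exception as exc:
        raise PipelineStageError("ranges", str(exc)) from exc
    if not want("tree"):
        _write_manifest(config, outdir, artifacts, notes)
        return report

    # ---- genealogy tree ---------------------------------------------------
    try:
        allocatable = [
            (s.label, s.n_steps)
            for s in summaries
            if s.passes_linearity and s.n_steps is not None
        ]
        if len(allocatable) < 2:
            notes.append("tree: no allocatable diseases (linearity gate)")
            allocation = ndtree.allocate_steps(
                ndtree.build_sharing_matrix(allocatable)
            )
        else:
            allocation = ndtree.allocate_steps(
                ndtree.build_sharing_matrix(allocatable)
            )
        report["allocation"] = allocation
        tree = ndtree.build_tree(allocation, summaries, sex_mode=config.sex_mode)
        report["tree"] = tree
        tree.to_json(
            outdir / "tree.json", config_hash=config.config_hash(), seed=config.seed
        )
        artifacts["tree"] = "tree.json"
        if allocation.allocations:
            _write_csv(
                ndtree.allocations_to_frame(allocation),
                outdir / "allocations.csv",
                tag,
            )
            artifacts["allocations"] = "allocations.csv"
        ndtree.plot_tree(tree, outdir / "tree.png")
    except Exception as exc:
        raise PipelineStageError("tree", str(exc)) from exc

    _write_manifest(config, outdir, artifacts, notes)
    report["notes"] = notes
    return report


def _write_csv(frame, path: Path, tag: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {tag}\n")
        frame.to_csv(fh, index=False)


def _write_manifest(
    config: PipelineConfig, outdir: Path, artifacts: dict, notes: Sequence[str]
) -> None:
    from . import __version__

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "artifacts": dict(sorted(artifacts.items())),
        "notes": list(notes),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    artifacts["manifest"] = "manifest.json"
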