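"""End-to-end runs: encode → correct → align → select hits, with provenance.

A run consumes either an image tree or a precomputed feature table, writes
every intermediate as CSV into a run directory, and records configuration,
seed, versions, timings and stage diagnostics in ``report.json``.  Re-running
with the same config and inputs reproduces intermediates byte-identically;
existing upstream intermediates are reused, so deleting a downstream file and
re-running regenerates it from the retained upstream state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .encoding import DEFAULT_FILENAME_REGEX, encode_screen, get_encoder
from .hit_selection import run_negative_mode, run_positive_mode
from .normalization import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    MAD_FLOOR,
    pca_plate_diagnostic,
    robust_z_align,
    spatial_correct,
)
from .plate_model import ControlRole, FeatureTable, read_platemap

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Everything a run needs; fully serialized into the run report."""

    platemap: str
    out_dir: str
    images: str | None = None
    features: str | None = None
    filename_regex: str = DEFAULT_FILENAME_REGEX
    encoder: str = "default"
    batch_size: int = 16
    pad_to_tile: bool = False
    fields_per_well: int = 4
    channels: int = 2
    polish_tol: float = DEFAULT_TOL
    polish_max_iter: int = DEFAULT_MAX_ITER
    mad_floor: float = MAD_FLOOR
    mode: str = "negative"  # positive | negative
    hit_fraction: float = 0.01
    k_clusters: int = 6
    per_channel: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_or(path: Path, compute, reader=FeatureTable.read_csv):
    """Reuse an existing intermediate (resumable runs) or compute and persist."""
    if path.exists():
        logger.info("reusing existing %s", path.name)
        return reader(path)
    obj = compute()
    obj.to_csv(path)
    return obj


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Stages: (optional) encoding of the image tree, per-plate spatial
    correction, negative-control alignment, then hit selection in the
    configured mode.  Any stage failure aborts with the stage named; partial
    outputs are retained in the run directory.
    """
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.digest(),
        "stages": {},
    }
    layouts = read_platemap(cfg.platemap, cfg.fields_per_well, cfg.channels)
    if cfg.mode == "positive" and not any(
        lay.wells_with_role(ControlRole.positive) for lay in layouts
    ):
        raise PipelineError("mode=positive but the plate map has no positive-control wells")
    if cfg.mode not in ("positive", "negative"):
        raise PipelineError(f"mode must be positive|negative, got {cfg.mode!r}")

    def _stage(name, fn):
        t = time.time()
        try:
            result = fn()
        except Exception as err:
            report["stages"][name] = {"status": "failed", "error": str(err)}
            (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
            raise PipelineError(f"stage {name!r} failed: {err}") from err
        report["stages"][name] = {"status": "ok", "seconds": round(time.time() - t, 3)}
        return result

    # -- encode --------------------------------------------------------------
    def _encode():
        if cfg.features:
            return FeatureTable.read_csv(cfg.features)
        if not cfg.images:
            raise PipelineError("config needs either 'features' or 'images'")
        return encode_screen(
            Path(cfg.images),
            layouts,
            get_encoder(cfg.encoder),
            batch_size=cfg.batch_size,
            filename_regex=cfg.filename_regex,
            pad_to_tile=cfg.pad_to_tile,
        )

    raw = _stage("encode", lambda: _load_or(out / "features_raw.csv", _encode))

    # -- normalize -----------------------------------------------------------
    try:
        diag_before = pca_plate_diagnostic(raw)
        report["plate_silhouette_before"] = diag_before.silhouette
        diag_before.coordinates.to_csv(out / "pca_before.csv")
    except Exception as err:  # diagnostic is advisory, never fatal
        logger.warning("PCA diagnostic (before) unavailable: %s", err)

    corrected = _stage(
        "spatial_correct",
        lambda: _load_or(
            out / "features_corrected.csv",
            lambda: spatial_correct(raw, layouts, tol=cfg.polish_tol, max_iter=cfg.polish_max_iter),
        ),
    )
    aligned_path = out / "features_aligned.csv"
    if aligned_path.exists():
        aligned = FeatureTable.read_csv(aligned_path)
        report["stages"]["robust_z_align"] = {"status": "ok", "seconds": 0.0, "reused": True}
    else:
        aligned, stats = _stage(
            "robust_z_align", lambda: robust_z_align(corrected, layouts, mad_floor=cfg.mad_floor)
        )
        aligned.to_csv(aligned_path)
        report["n_floored_features"] = int(stats.floored.to_numpy().sum())

    try:
        diag_after = pca_plate_diagnostic(aligned)
        report["plate_silhouette_after"] = diag_after.silhouette
        diag_after.coordinates.to_csv(out / "pca_after.csv")
    except Exception as err:
        logger.warning("PCA diagnostic (after) unavailable: %s", err)

    # -- hit selection -------------------------------------------------------
    if cfg.mode == "positive":
        result = _stage(
            "select_hits",
            lambda: run_positive_mode(aligned, layouts, hit_fraction=cfg.hit_fraction),
        )
        hits_df = result.per_condition.copy()
        np.save(out / "lda_axis.npy", result.axis)
        report["threshold"] = result.threshold
        report["n_hits"] = len(result.hits)
    else:
        result = _stage(
            "select_hits",
            lambda: run_negative_mode(
                aligned,
                layouts,
                hit_fraction=cfg.hit_fraction,
                k=cfg.k_clusters,
                per_channel=cfg.per_channel,
            ),
        )
        hits_df = result.per_condition.copy()
        hits_df["cluster"] = [result.cluster_labels.get(c, 0) for c in hits_df.index]
        reps = set(result.representatives.values())
        hits_df["representative"] = [c in reps for c in hits_df.index]
        report["threshold"] = result.distance_threshold
        report["n_hits"] = len(result.hits)
        report["clusters"] = {str(k): v for k, v in result.representatives.items()}
        report["covariance"] = {
            "shrinkage": result.model.shrinkage,
            "regularization": result.model.regularization,
            "condition_number": result.model.condition_number,
        }
        if result.per_channel_distances is not None:
            result.per_channel_distances.to_csv(out / "per_channel_distances.csv")
    hits_df.to_csv(out / "hits.csv")

    report["seconds_total"] = round(time.time() - t0, 3)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    logger.info("run complete: %s (%d hits)", out, report.get("n_hits", 0))
    return out


# ---------------------------------------------------------------------------
# Report rendering


def render_report(run_dir: Path) -> list[Path]:
    """Render PNG figures and a markdown summary from a completed run directory.

    Produces whatever the available intermediates allow — score scatter with
    threshold lines, PCA plate plots before/after alignment, per-plate
    heatmaps of the first feature raw vs corrected — and lists anything
    missing rather than failing.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    run_dir = Path(run_dir)
    produced: list[Path] = []
    missing: list[str] = []
    report = {}
    if (run_dir / "report.json").exists():
        report = json.loads((run_dir / "report.json").read_text())

    def _save(fig, name: str) -> None:
        path = run_dir / name
        fig.savefig(path, dpi=110)
        plt.close(fig)
        produced.append(path)

    # score / distance scatter with threshold line
    hits_path = run_dir / "hits.csv"
    if hits_path.exists():
        hits = pd.read_csv(hits_path, index_col=0)
        score_col = "display_score" if "display_score" in hits.columns else "distance"
        fig, ax = plt.subplots(figsize=(7, 4))
        order = np.argsort(hits[score_col].to_numpy())
        colors = np.where(hits["hit"].to_numpy()[order], "crimson", "steelblue")
        ax.scatter(np.arange(len(hits)), hits[score_col].to_numpy()[order], s=8, c=colors)
        thr = report.get("threshold")
        if thr is not None:
            ax.axhline(thr, ls="--", color="k", lw=1, label=f"threshold = {thr:.3g}")
            ax.legend()
        ax.set_xlabel("condition (ranked)")
        ax.set_ylabel(score_col.replace("_", " "))
        _save(fig, "scores.png")
    else:
        missing.append("hits.csv")

    # PCA plate plots
    for tag in ("before", "after"):
        path = run_dir / f"pca_{tag}.csv"
        if not path.exists():
            missing.append(path.name)
            continue
        coords = pd.read_csv(path)
        labels = coords["plate_id"].astype(str) + "/" + coords["replicate_id"].astype(str)
        fig, ax = plt.subplots(figsize=(5, 4))
        for lab in sorted(labels.unique()):
            sub = coords[labels == lab]
            ax.scatter(sub["pc1"], sub["pc2"], s=6, label=lab, alpha=0.6)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        sil = report.get(f"plate_silhouette_{tag}")
        ax.set_title(f"plates {tag} alignment" + (f" (silhouette {sil:.2f})" if sil is not None else ""))
        ax.legend(fontsize=6, markerscale=2)
        _save(fig, f"pca_{tag}.png")

    # per-plate heatmaps of the first feature, raw vs corrected
    from .plate_model import WellAddress, N_COLS, N_ROWS

    for tag, fname in (("raw", "features_raw.csv"), ("corrected", "features_corrected.csv")):
        path = run_dir / fname
        if not path.exists():
            missing.append(fname)
            continue
        table = FeatureTable.read_csv(path)
        plates = list(table.data.groupby(level=["plate_id", "replicate_id"], sort=False))
        fig, axes = plt.subplots(
            1, len(plates), figsize=(3 * len(plates), 2.4), squeeze=False
        )
        for ax, ((plate, rep), block) in zip(axes[0], plates):
            grid = np.full((N_ROWS, N_COLS), np.nan)
            for (_, _, well), val in block.iloc[:, 0].items():
                addr = WellAddress.parse(well)
                grid[addr.row_index, addr.col_index] = val
            im = ax.imshow(grid, aspect="auto", cmap="viridis")
            ax.set_title(f"{plate}/{rep}", fontsize=8)
            ax.set_xticks([])
            ax.set_yticks([])
            fig.colorbar(im, ax=ax, fraction=0.046)
        fig.suptitle(f"{tag}: first feature per plate")
        _save(fig, f"heatmaps_{tag}.png")

    lines = ["# Run summary", ""]
    if report:
        lines += [
            f"- config hash: `{report.get('config_hash')}`",
            f"- mode: {report.get('config', {}).get('mode')}",
            f"- hits: {report.get('n_hits')}",
            f"- threshold: {report.get('threshold')}",
            f"- plate silhouette before/after: "
            f"{report.get('plate_silhouette_before')} / {report.get('plate_silhouette_after')}",
        ]
    lines += ["", "## Figures", *[f"- {p.name}" for p in produced]]
    if missing:
        lines += ["", "## Missing intermediates", *[f"- {m}" for m in missing]]
    summary = run_dir / "report.md"
    summary.write_text("\n".join(lines) + "\n")
    produced.append(summary)
    return produced
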