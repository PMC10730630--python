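"""Synthetic screens with known ground truth.

No public image set accompanies the screening campaigns this pipeline targets,
so every stage is exercised on generated screens that embed the statistical
structure the pipeline assumes: duplicate-replicate multi-plate 384-well
layouts with vehicle-only negative controls (and optionally positive
controls), additive within-plate row/column gradients, per-plate affine
offset/scale misalignment, and planted hit conditions at low prevalence.

Two planted phenotype classes mirror the two kinds of effect a compound
screen read out by deep features typically shows: a *cell-loss* phenotype
that depresses features across all channels (correlated with a cell-count
proxy), and a *brightness* phenotype confined to the cell-channel block.
The two directions have disjoint feature support, hence are orthogonal.

The feature-level generator is the primary test substrate; the image-level
generator renders Gaussian-blob cells into TIFF trees to exercise the
encoding path end-to-end at small scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .plate_model import (
    ControlRole,
    FeatureTable,
    N_COLS,
    N_ROWS,
    PlateLayout,
    ROW_LETTERS,
    TableState,
    WellAddress,
    write_platemap,
)

SAMPLE_COLS = 22  # columns 1..22 hold samples; 23 negative, 24 positive controls
NEG_COL = 23
POS_COL = 24

CELL_LOSS = "cell_loss"
BRIGHTNESS = "brightness"


@dataclass
class ScreenSimConfig:
    """Study design of a simulated screen.

    Defaults mirror a duplicate compound screen: a 1280-compound library over
    four 384-well plates per replicate, 16 negative (and 16 positive) control
    wells per plate, ~1% planted hits displacing each supported feature by
    ``effect_size`` aligned MAD units, unit well-to-well noise, row/column
    gradients and per-plate affine distortions for the correction stages to
    remove.  ``n_features`` defaults to a reduced 64-wide profile (two
    channel blocks of 32) so the whole screen runs at desk scale; all
    statistics are dimension-generic.
    """

    n_plates: int = 4
    n_replicates: int = 2
    channels: int = 2
    fields_per_well: int = 4
    n_features: int = 64
    n_conditions: int = 1280
    n_negative: int = 16
    n_positive: int = 16  # 0 → no-positive-control screen
    hit_prevalence: float = 0.01
    effect_size: float = 5.0
    positive_effect_size: float = 10.0
    phenotype_weights: dict = dc_field(
        default_factory=lambda: {CELL_LOSS: 0.8, BRIGHTNESS: 0.2}
    )
    gradient_amplitude: float = 1.0
    plate_scale_range: tuple[float, float] = (0.7, 1.3)
    plate_offset_range: tuple[float, float] = (-2.0, 2.0)
    noise_scale: float = 1.0
    seed: int = 0
    # image-level parameters
    image_size: int = 448
    cells_per_field: float = 40.0

    def __post_init__(self) -> None:
        if not 0.0 < self.hit_prevalence < 0.2:
            raise ValueError(f"hit_prevalence must be in (0, 0.2), got {self.hit_prevalence}")
        if self.n_features % self.channels:
            raise ValueError("n_features must divide evenly into channel blocks")
        if self.n_conditions > self.n_plates * N_ROWS * SAMPLE_COLS:
            raise ValueError("too many conditions for the plate count")
        if self.n_negative < 1 or self.n_negative > N_ROWS:
            raise ValueError("n_negative must be in 1..16")

    def plate_rng(self, replicate: int, plate: int) -> np.random.Generator:
        """One stream per (replicate, plate): adding plates never perturbs others."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(replicate, plate))
        )

    def screen_rng(self) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(9999,)))


@dataclass
class GroundTruth:
    """Planted truth of a simulated screen, consistent across replicates."""

    conditions: pd.DataFrame  # condition_id × [is_hit, phenotype]
    directions: dict[str, np.ndarray]  # phenotype → unit-max-norm direction
    effect_size: float

    @property
    def hit_ids(self) -> set[str]:
        return set(self.conditions.index[self.conditions["is_hit"]])

    def to_csv(self, path) -> None:
        self.conditions.to_csv(path)


def phenotype_directions(n_features: int, channels: int) -> dict[str, np.ndarray]:
    """Disjoint-support (hence orthogonal) phenotype directions, unit max-norm.

    Cell loss depresses every feature except the brightness sub-block; the
    brightness direction raises the second half of the cell-channel (last)
    block only.
    """
    block = n_features // channels
    bright = np.zeros(n_features)
    start = n_features - block // 2  # upper half of the last channel block
    bright[start:] = 1.0
    loss = -np.ones(n_features)
    loss[start:] = 0.0
    return {CELL_LOSS: loss, BRIGHTNESS: bright}


def _build_layouts(cfg: ScreenSimConfig) -> tuple[list[PlateLayout], list[list[str]]]:
    """Plate layouts plus the per-plate condition assignment (shared by replicates)."""
    per_plate: list[list[str]] = []
    conds = [f"cond_{i + 1:04d}" for i in range(cfg.n_conditions)]
    base = cfg.n_conditions // cfg.n_plates
    extra = cfg.n_conditions % cfg.n_plates
    start = 0
    for p in range(cfg.n_plates):
        n = base + (1 if p < extra else 0)
        per_plate.append(conds[start : start + n])
        start += n

    layouts = []
    for r in range(cfg.n_replicates):
        rep_id = f"R{r + 1}"
        for p in range(cfg.n_plates):
            plate_id = f"P{p + 1:02d}"
            wells: dict[WellAddress, tuple[str, ControlRole]] = {}
            for i in range(cfg.n_negative):
                wells[WellAddress(ROW_LETTERS[i], NEG_COL)] = (f"DMSO_{plate_id}", ControlRole.negative)
            for i in range(cfg.n_positive):
                wells[WellAddress(ROW_LETTERS[i], POS_COL)] = (f"POS_{plate_id}", ControlRole.positive)
            for k, cond in enumerate(per_plate[p]):
                row, col = divmod(k, SAMPLE_COLS)
                wells[WellAddress(ROW_LETTERS[row], col + 1)] = (cond, ControlRole.sample)
            layouts.append(
                PlateLayout(plate_id, rep_id, wells, cfg.fields_per_well, cfg.channels)
            )
    return layouts, per_plate


def _plant_truth(cfg: ScreenSimConfig) -> GroundTruth:
    rng = cfg.screen_rng()
    n_hits = max(1, round(cfg.hit_prevalence * cfg.n_conditions))
    hit_idx = rng.choice(cfg.n_conditions, size=n_hits, replace=False)
    classes = list(cfg.phenotype_weights)
    weights = np.array([cfg.phenotype_weights[c] for c in classes], dtype=float)
    weights /= weights.sum()
    # deterministic class counts (largest remainder), shuffled assignment
    counts = np.floor(weights * n_hits).astype(int)
    for i in np.argsort(-(weights * n_hits - counts)):
        if counts.sum() >= n_hits:
            break
        counts[i] += 1
    assignment = np.repeat(classes, counts)
    rng.shuffle(assignment)
    conds = pd.DataFrame(
        {"is_hit": False, "phenotype": "none"},
        index=pd.Index([f"cond_{i + 1:04d}" for i in range(cfg.n_conditions)], name="condition_id"),
    )
    for idx, cls in zip(hit_idx, assignment):
        conds.iloc[idx] = [True, cls]
    return GroundTruth(
        conditions=conds,
        directions=phenotype_directions(cfg.n_features, cfg.channels),
        effect_size=cfg.effect_size,
    )


def _condition_effect(cond: str, role: ControlRole, truth: GroundTruth, cfg: ScreenSimConfig) -> np.ndarray:
    if role == ControlRole.positive:
        return cfg.positive_effect_size * truth.directions[CELL_LOSS]
    if role == ControlRole.sample and truth.conditions.loc[cond, "is_hit"]:
        cls = truth.conditions.loc[cond, "phenotype"]
        return cfg.effect_size * truth.directions[cls]
    return np.zeros(cfg.n_features)


def generate_feature_screen(
    cfg: ScreenSimConfig,
) -> tuple[FeatureTable, list[PlateLayout], GroundTruth]:
    """Simulate a raw per-well feature table with known planted hits.

    Well profile = condition effect + N(0, noise²) per feature, then per-plate
    row/column gradients (additive, linear) and an affine distortion
    x → a_p·x + b_p.  Replicates share condition effects but draw independent
    noise and artifacts.  Fixed seed → bitwise identical output.
    """
    layouts, _ = _build_layouts(cfg)
    truth = _plant_truth(cfg)
    rows, index = [], []
    for lay in layouts:
        r = int(lay.replicate_id[1:]) - 1
        p = int(lay.plate_id[1:]) - 1
        rng = cfg.plate_rng(r, p)
        g_row = rng.uniform(-cfg.gradient_amplitude, cfg.gradient_amplitude, cfg.n_features)
        g_col = rng.uniform(-cfg.gradient_amplitude, cfg.gradient_amplitude, cfg.n_features)
        a_p = rng.uniform(*cfg.plate_scale_range)
        b_p = rng.uniform(*cfg.plate_offset_range)
        for well in sorted(lay.wells):
            cond, role = lay.wells[well]
            x = _condition_effect(cond, role, truth, cfg)
            x = x + rng.normal(0.0, cfg.noise_scale, cfg.n_features)
            x = x + g_row * (well.row_index - (N_ROWS - 1) / 2) / ((N_ROWS - 1) / 2)
            x = x + g_col * (well.col_index - (N_COLS - 1) / 2) / ((N_COLS - 1) / 2)
            x = a_p * x + b_p
            rows.append(x)
            index.append((lay.plate_id, lay.replicate_id, str(well)))
    table = FeatureTable.from_array(np.stack(rows), index, state=TableState.raw)
    return table, layouts, truth


# ---------------------------------------------------------------------------
# Image-level generator


def _render_field(
    rng: np.random.Generator,
    cfg: ScreenSimConfig,
    channel: int,
    n_cells: int,
    intensity_gain: float,
    background: float,
) -> np.ndarray:
    """One grayscale field: Gaussian-blob cells on a noisy background.

    The nuclei channel (1) shows small bright blobs; the cell channel(s) show
    larger, dimmer ones at the same positions' vicinity.
    """
    size = cfg.image_size
    img = np.full((size, size), background, dtype=float)
    if channel == 1:
        sigma, amp = 4.0, 12000.0
    else:
        sigma, amp = 10.0, 6000.0
    half = int(3 * sigma)
    ax = np.arange(-half, half + 1)
    kernel = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma**2))
    for _ in range(n_cells):
        cy, cx = rng.integers(half, size - half, size=2)
        img[cy - half : cy + half + 1, cx - half : cx + half + 1] += amp * intensity_gain * kernel
    img = rng.poisson(np.clip(img, 0, None)).astype(float)
    return np.clip(img, 0, 65535).astype(np.uint16)


def generate_image_screen(
    cfg: ScreenSimConfig, out_dir: Path
) -> tuple[Path, list[PlateLayout], GroundTruth]:
    """Render a TIFF tree <out>/<replicate>/<plate>/<well>_f<F>_ch<C>.tif.

    Hit phenotypes are expressed optically: cell-loss hits have ~5× fewer
    cells per field; brightness hits have a 3× brighter cell channel.  A
    linear background gradient runs across each plate and every image carries
    shot noise.  Intended for small configs (a couple of plates, a few dozen
    wells); the feature-level generator is the substrate for statistics.
    """
    import tifffile

    if cfg.image_size < 448:
        raise ValueError("image_size must be ≥ 448 (at least a 2×2 tile grid)")
    layouts, _ = _build_layouts(cfg)
    truth = _plant_truth(cfg)
    out_dir = Path(out_dir)
    for lay in layouts:
        r = int(lay.replicate_id[1:]) - 1
        p = int(lay.plate_id[1:]) - 1
        rng = cfg.plate_rng(r, p)
        plate_dir = out_dir / lay.replicate_id / lay.plate_id
        plate_dir.mkdir(parents=True, exist_ok=True)
        for well in sorted(lay.wells):
            cond, role = lay.wells[well]
            count_gain, bright_gain = 1.0, 1.0
            is_hit = role == ControlRole.sample and bool(truth.conditions.loc[cond, "is_hit"])
            phenotype = truth.conditions.loc[cond, "phenotype"] if is_hit else "none"
            if role == ControlRole.positive or phenotype == CELL_LOSS:
                count_gain = 0.2
            elif phenotype == BRIGHTNESS:
                bright_gain = 3.0
            background = 200.0 * (
                1.0
                + cfg.gradient_amplitude * 0.3 * (well.row_index - (N_ROWS - 1) / 2) / N_ROWS
                + cfg.gradient_amplitude * 0.3 * (well.col_index - (N_COLS - 1) / 2) / N_COLS
            )
            for fld in range(1, cfg.fields_per_well + 1):
                n_cells = int(rng.poisson(cfg.cells_per_field * count_gain))
                for ch in range(1, cfg.channels + 1):
                    gain = bright_gain if ch > 1 else 1.0
                    img = _render_field(rng, cfg, ch, n_cells, gain, background)
                    tifffile.imwrite(plate_dir / f"{well}_f{fld}_ch{ch}.tif", img)
    return out_dir, layouts, truth


def write_feature_screen(cfg: ScreenSimConfig, out_dir: Path) -> dict[str, Path]:
    """Generate and serialize a feature screen (features, plate map, truth)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table, layouts, truth = generate_feature_screen(cfg)
    paths = {
        "features": out_dir / "features.csv",
        "platemap": out_dir / "platemap.csv",
        "ground_truth": out_dir / "ground_truth.csv",
    }
    table.to_csv(paths["features"])
    write_platemap(layouts, paths["platemap"])
    truth.to_csv(paths["ground_truth"])
    return paths
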