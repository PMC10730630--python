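"""Plate correction and alignment.

Within-plate positional artifacts (edge evaporation, dispensing gradients) are
removed feature-by-feature with Tukey's two-way median polish on the 16×24
well grid; plates are then aligned by robust Z-scoring every feature against
the plate's own negative-control wells, z = (x − median(neg)) / (1.4826·MAD(neg)).
After alignment every well of every plate lives on a common scale, which is
what licenses pooling perturbations across plates.

A PCA diagnostic quantifies plate separation (mean silhouette of plate labels
in the first two principal axes) before and after alignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate_model import (
    ControlRole,
    FeatureTable,
    N_COLS,
    N_ROWS,
    PlateLayout,
    TableState,
    WellAddress,
)

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # Gaussian-consistency constant
MAD_FLOOR = 1e-8

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 20


class NormalizationError(RuntimeError):
    pass


@dataclass
class PolishDecomposition:
    """Additive decomposition x[i,j] = overall + row[i] + col[j] + residual[i,j].

    For a stack of matrices (one per feature) the fields carry a trailing
    feature axis; reconstruction is exact by construction on every present cell.
    """

    overall: np.ndarray
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    iterations: int
    converged: bool

    def reconstruct(self) -> np.ndarray:
        return (
            self.overall
            + self.row_effects[:, None, ...]
            + self.col_effects[None, :, ...]
            + self.residuals
        )


def median_polish(
    matrix: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PolishDecomposition:
    """Tukey's iterative alternating row/column median sweep.

    Accepts a 2-D matrix or a stack (rows × cols × features) polished
    independently along the trailing axis.  NaN cells are gaps (medians over
    present cells); an all-missing row or column is an error.  Sweeps run
    row-first until the maximum absolute change of any effect drops below
    ``tol`` or ``max_iter`` is reached; the decomposition reconstructs the
    input exactly at every iteration.
    """
    z = np.array(matrix, dtype=float)
    stacked = z.ndim > 2
    if not stacked:
        z = z[:, :, None]
    nr, nc = z.shape[:2]
    present = ~np.isnan(z)
    empty_rows = np.where(~present.any(axis=(1, 2)))[0]
    empty_cols = np.where(~present.any(axis=(0, 2)))[0]
    if empty_rows.size or empty_cols.size:
        raise NormalizationError(
            f"all-missing row(s) {empty_rows.tolist()} / column(s) {empty_cols.tolist()}"
        )

    trailing = z.shape[2:]
    overall = np.zeros(trailing)
    row = np.zeros((nr,) + trailing)
    col = np.zeros((nc,) + trailing)
    converged = False
    it = 0
    with warnings.catch_warnings():
        # all-NaN row/col slices of individual features are tolerated as gaps
        warnings.simplefilter("ignore", RuntimeWarning)
        for it in range(1, max_iter + 1):
            rdelta = np.nanmedian(z, axis=1)
            rdelta = np.nan_to_num(rdelta)
            z -= rdelta[:, None]
            row += rdelta
            cmed = np.median(col, axis=0)
            overall += cmed
            col -= cmed

            cdelta = np.nanmedian(z, axis=0)
            cdelta = np.nan_to_num(cdelta)
            z -= cdelta[None, :]
            col += cdelta
            rmed = np.median(row, axis=0)
            overall += rmed
            row -= rmed

            change = max(
                np.max(np.abs(rdelta)),
                np.max(np.abs(cdelta)),
                np.max(np.abs(rmed)),
                np.max(np.abs(cmed)),
            )
            if change < tol:
                converged = True
                break
    if not stacked:
        overall, row, col, z = overall[0], row[:, 0], col[:, 0], z[:, :, 0]
    return PolishDecomposition(overall, row, col, z, iterations=it, converged=converged)


def _plate_grid(block: pd.DataFrame) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Arrange a plate's rows on the 16×24 grid (NaN = absent well)."""
    grid = np.full((N_ROWS, N_COLS, block.shape[1]), np.nan)
    positions = []
    for k, well_name in enumerate(block.index):
        addr = WellAddress.parse(well_name)
        grid[addr.row_index, addr.col_index] = block.iloc[k].to_numpy()
        positions.append((addr.row_index, addr.col_index))
    return grid, positions


def spatial_correct(
    table: FeatureTable,
    layouts: list[PlateLayout] | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FeatureTable:
    """Remove row/column positional effects from every plate, every feature.

    Each plate (per replicate) is polished independently; the corrected value
    is x − row_effect − col_effect (= overall + residual for polished cells),
    i.e. positional effects are subtracted while the plate's location is
    retained for the subsequent robust Z.

    When ``layouts`` are given, row/column effects are *estimated* from sample
    wells only and then applied to every well.  Control wells routinely occupy
    dedicated plate columns, and a column filled with one control would have
    its entire phenotype absorbed into the column effect; estimating on
    samples (controls and empty wells as gaps) removes the artifact without
    touching the control signal.  Rows/columns holding no estimation wells get
    a zero effect.
    """
    if table.state != TableState.raw:
        raise NormalizationError(f"spatial_correct expects a raw table, got {table.state.value}")
    control_wells: dict[tuple[str, str], set[str]] = {}
    if layouts is not None:
        for lay in layouts:
            control_wells[(lay.plate_id, lay.replicate_id)] = {
                str(w)
                for w, (_, role) in lay.wells.items()
                if role != ControlRole.sample
            }
    out = table.data.copy()
    not_converged: list[str] = []
    for (plate, rep), block in out.groupby(level=["plate_id", "replicate_id"], sort=False):
        plate_block = block.droplevel(["plate_id", "replicate_id"])
        grid, positions = _plate_grid(plate_block)
        estimation = grid.copy()
        for well_name in control_wells.get((plate, rep), ()):
            addr = WellAddress.parse(well_name)
            estimation[addr.row_index, addr.col_index] = np.nan
        # rows/columns holding no estimation wells contribute zero effect
        has_row = ~np.all(np.isnan(estimation), axis=(1, 2))
        has_col = ~np.all(np.isnan(estimation), axis=(0, 2))
        sub = estimation[np.ix_(np.where(has_row)[0], np.where(has_col)[0])]
        try:
            dec = median_polish(sub, tol=tol, max_iter=max_iter)
        except NormalizationError as err:
            raise NormalizationError(f"plate {plate}/{rep}: {err}") from err
        if not dec.converged:
            not_converged.append(f"{plate}/{rep}")
        row_eff = np.zeros((N_ROWS,) + grid.shape[2:])
        col_eff = np.zeros((N_COLS,) + grid.shape[2:])
        row_eff[has_row] = dec.row_effects
        col_eff[has_col] = dec.col_effects
        corrected = grid - row_eff[:, None] - col_eff[None, :]
        values = np.stack([corrected[i, j] for (i, j) in positions])
        out.loc[block.index] = values
    if not_converged:
        logger.info(
            "median polish hit the iteration cap on %d plate(s) (%s); residual effect "
            "drift is below the per-sweep median step",
            len(not_converged), ", ".join(not_converged[:4]),
        )
    result = FeatureTable(out, state=TableState.raw)
    result.advance_state(TableState.spatially_corrected)
    return result


@dataclass
class AlignmentStats:
    """Per-plate, per-feature negative-control statistics used for alignment."""

    negctrl_median: pd.DataFrame  # (plate, replicate) × features
    negctrl_mad_scaled: pd.DataFrame  # same shape, 1.4826·MAD, floored
    floored: pd.DataFrame  # boolean: features whose MAD hit the floor


def robust_z_align(
    table: FeatureTable,
    layouts: list[PlateLayout],
    mad_floor: float = MAD_FLOOR,
) -> tuple[FeatureTable, AlignmentStats]:
    """Align plates by robust Z-scoring against each plate's negative controls.

    Every well of a plate is transformed feature-wise with that plate's
    negative-control median and scaled MAD, so any per-plate affine distortion
    x → a·x + b cancels exactly.  Degenerate (locally constant) features are
    floored at ``mad_floor`` and flagged rather than dividing by zero.
    """
    if table.state != TableState.spatially_corrected:
        raise NormalizationError(
            f"robust_z_align expects a spatially_corrected table, got {table.state.value}"
        )
    by_key = {(lay.plate_id, lay.replicate_id): lay for lay in layouts}
    out = table.data.copy()
    med_rows, mad_rows, floor_rows, keys = [], [], [], []
    for (plate, rep), block in out.groupby(level=["plate_id", "replicate_id"], sort=False):
        lay = by_key.get((plate, rep))
        if lay is None:
            raise NormalizationError(f"no layout for plate {plate}/{rep}")
        neg_wells = [str(w) for w in lay.wells_with_role(ControlRole.negative)]
        neg_idx = [(plate, rep, w) for w in neg_wells if (plate, rep, w) in block.index]
        if not neg_idx:
            raise NormalizationError(f"plate {plate}/{rep} has no negative-control wells")
        if len(neg_idx) < 8:
            logger.warning(
                "plate %s/%s has only %d negative controls; alignment statistics are noisy",
                plate, rep, len(neg_idx),
            )
        neg = block.loc[neg_idx].to_numpy()
        med = np.median(neg, axis=0)
        mad = MAD_SCALE * np.median(np.abs(neg - med), axis=0)
        floored = mad < mad_floor
        if floored.any():
            logger.warning(
                "plate %s/%s: %d feature(s) with near-zero negative-control MAD floored",
                plate, rep, int(floored.sum()),
            )
            mad = np.where(floored, mad_floor, mad)
        out.loc[block.index] = (block.to_numpy() - med) / mad
        keys.append((plate, rep))
        med_rows.append(med)
        mad_rows.append(mad)
        floor_rows.append(floored)
    idx = pd.MultiIndex.from_tuples(keys, names=["plate_id", "replicate_id"])
    stats = AlignmentStats(
        negctrl_median=pd.DataFrame(med_rows, index=idx, columns=table.data.columns),
        negctrl_mad_scaled=pd.DataFrame(mad_rows, index=idx, columns=table.data.columns),
        floored=pd.DataFrame(floor_rows, index=idx, columns=table.data.columns),
    )
    result = FeatureTable(out, state=TableState.spatially_corrected)
    result.advance_state(TableState.aligned)
    return result, stats


@dataclass
class PlateDiagnostic:
    """First two principal axes of the screen with a plate-separation score."""

    coordinates: pd.DataFrame  # (plate, replicate, well) × [pc1, pc2]
    plate_labels: np.ndarray
    silhouette: float
    explained_variance_ratio: tuple[float, float]


def pca_plate_diagnostic(table: FeatureTable) -> PlateDiagnostic:
    """Project all well profiles on the first two principal axes.

    The plate-separation score is the mean silhouette of (plate, replicate)
    labels in the 2-D projection: near 1 when plates form separate clouds
    (strong plate effect), near 0 when plates overlap.  Comparing the score
    before and after alignment quantifies how much plate effect was removed.
    """
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    X = table.data.to_numpy()
    if X.shape[0] < 2:
        raise NormalizationError("PCA diagnostic needs at least 2 wells")
    if np.allclose(X.var(axis=0), 0.0):
        raise NormalizationError("PCA diagnostic rejects a zero-variance table (all rows identical)")
    labels = np.array(
        [f"{p}/{r}" for p, r, _ in table.data.index], dtype=object
    )
    if len(np.unique(labels)) < 2:
        raise NormalizationError("PCA diagnostic needs at least 2 plates")
    coords = PCA(n_components=2, svd_solver="full").fit(X - X.mean(axis=0))
    proj = coords.transform(X - X.mean(axis=0))
    sil = float(silhouette_score(proj, labels))
    return PlateDiagnostic(
        coordinates=pd.DataFrame(proj, index=table.data.index, columns=["pc1", "pc2"]),
        plate_labels=labels,
        silhouette=sil,
        explained_variance_ratio=tuple(coords.explained_variance_ratio_[:2]),
    )
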