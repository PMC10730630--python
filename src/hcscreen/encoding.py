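"""Well encoding: tiles → embeddings → field medians → well profiles.

Each single-channel microscopy field is split into non-overlapping 224×224
tiles, each tile is replicated to a fake-RGB image and normalized with the
encoder's training-corpus constants, the batch of tiles is pushed through the
encoder, and the per-dimension median over tiles gives one embedding per
field.  Per channel, the per-dimension median over the F fields of a well is
taken, and the channel blocks are concatenated into the 512·C well profile.

The encoder is injected: the default is a ResNet-18 with the classification
layer removed; deterministic mock encoders keep the whole pipeline testable
without any pretrained weights.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .plate_model import (
    FeatureTable,
    ManifestEntry,
    PlateLayout,
    TableState,
    WellAddress,
    validate_screen,
)
from .resnet import EMBEDDING_DIM, IMAGENET_MEAN, IMAGENET_STD, ResNet18Encoder

logger = logging.getLogger(__name__)

TILE_SIZE = 224

DEFAULT_FILENAME_REGEX = r"(?P<well>[A-Pa-p]\d{1,2})_f(?P<field>\d+)_ch(?P<channel>\d+)\.tiff?$"


class EncodingError(RuntimeError):
    pass


@dataclass(frozen=True)
class ImageField:
    """One grayscale image: a single channel of one field of one well."""

    pixels: np.ndarray
    well: WellAddress
    field: int
    channel: int
    bit_depth_max: float = 65535.0

    def unit_scaled(self) -> np.ndarray:
        """Intensities divided by the bit-depth maximum (absolute scale kept).

        Per-image min–max rescaling would erase brightness phenotypes, which
        are genuine signal when exposure is held fixed across plates.
        """
        return np.asarray(self.pixels, dtype=np.float64) / self.bit_depth_max


@dataclass(frozen=True)
class Tile:
    pixels: np.ndarray  # 224×224, unit-scaled
    origin: tuple[int, int]


@dataclass(frozen=True)
class EncoderSpec:
    """Contract for a tile encoder: (N, 3, 224, 224) batch → (N, dim) embeddings.

    ``mean``/``std`` are the per-plane normalization constants of the encoder's
    training corpus, applied after fake-RGB replication.
    """

    encode: Callable[[np.ndarray], np.ndarray]
    embedding_dim: int = EMBEDDING_DIM
    mean: tuple[float, float, float] = tuple(IMAGENET_MEAN)
    std: tuple[float, float, float] = tuple(IMAGENET_STD)
    name: str = "encoder"


def default_encoder(weights_path: str | None = None) -> EncoderSpec:
    """ResNet-18 encoder (classification head removed), 512-d output."""
    net = ResNet18Encoder.from_npz(weights_path) if weights_path else ResNet18Encoder()
    return EncoderSpec(encode=net, embedding_dim=EMBEDDING_DIM, name="resnet18")


def mean_intensity_encoder(dim: int = EMBEDDING_DIM) -> EncoderSpec:
    """Mock encoder: mean tile intensity broadcast to every dimension.

    Monotone in brightness, which makes planted intensity phenotypes visible
    end-to-end without any network weights.
    """

    def encode(batch: np.ndarray) -> np.ndarray:
        return np.repeat(batch.mean(axis=(1, 2, 3))[:, None], dim, axis=1)

    return EncoderSpec(encode=encode, embedding_dim=dim, name="mean-intensity")


def constant_encoder(value: float = 1.0, dim: int = EMBEDDING_DIM) -> EncoderSpec:
    def encode(batch: np.ndarray) -> np.ndarray:
        return np.full((batch.shape[0], dim), value)

    return EncoderSpec(encode=encode, embedding_dim=dim, name="constant")


def get_encoder(spec: str) -> EncoderSpec:
    """Resolve an encoder by name: 'default', 'mock', or a path to .npz weights."""
    if spec == "default":
        return default_encoder()
    if spec == "mock":
        return mean_intensity_encoder()
    return default_encoder(weights_path=spec)


# ---------------------------------------------------------------------------
# Tiling and normalization


def split_into_tiles(field: ImageField, pad_to_tile: bool = False) -> list[Tile]:
    """Non-overlapping 224×224 tiles anchored at the top-left of the field.

    The right/bottom remainder strip (width < 224) is discarded.  Fields
    smaller than 224 in either axis are rejected unless ``pad_to_tile`` is set,
    in which case they are zero-padded up to one tile.
    """
    pixels = field.unit_scaled()
    h, w = pixels.shape
    if h < TILE_SIZE or w < TILE_SIZE:
        if not pad_to_tile:
            raise EncodingError(
                f"field {field.well}/f{field.field}/ch{field.channel} is {h}×{w}, "
                f"smaller than {TILE_SIZE}; enable pad_to_tile to zero-pad"
            )
        pixels = np.pad(pixels, ((0, max(0, TILE_SIZE - h)), (0, max(0, TILE_SIZE - w))))
        h, w = pixels.shape
    tiles = []
    for i in range(h // TILE_SIZE):
        for j in range(w // TILE_SIZE):
            r, c = i * TILE_SIZE, j * TILE_SIZE
            tiles.append(Tile(pixels[r : r + TILE_SIZE, c : c + TILE_SIZE], (r, c)))
    return tiles


def replicate_to_rgb(tile: Tile, enc: EncoderSpec) -> np.ndarray:
    """Triple the single channel into a fake-RGB image, then normalize per plane."""
    planes = np.repeat(tile.pixels[None, :, :], 3, axis=0)
    mean = np.asarray(enc.mean, dtype=np.float64)[:, None, None]
    std = np.asarray(enc.std, dtype=np.float64)[:, None, None]
    return (planes - mean) / std


# ---------------------------------------------------------------------------
# Aggregation


def _encode_batched(enc: EncoderSpec, tiles: np.ndarray, batch_size: int) -> np.ndarray:
    outs = [enc.encode(tiles[i : i + batch_size]) for i in range(0, len(tiles), batch_size)]
    return np.concatenate(outs, axis=0)


def encode_field(
    field: ImageField,
    enc: EncoderSpec,
    batch_size: int = 16,
    pad_to_tile: bool = False,
) -> np.ndarray:
    """Per-dimension median over the tile embeddings of one field."""
    tiles = split_into_tiles(field, pad_to_tile=pad_to_tile)
    batch = np.stack([replicate_to_rgb(t, enc) for t in tiles])
    emb = _encode_batched(enc, batch, batch_size)
    if not np.all(np.isfinite(emb)):
        bad = tiles[int(np.argwhere(~np.isfinite(emb))[0][0])]
        raise EncodingError(
            f"non-finite encoder output for {field.well}/f{field.field}/"
            f"ch{field.channel}, tile at {bad.origin}"
        )
    return np.median(emb, axis=0)


def assemble_well_profile(
    field_embeddings: Sequence[Sequence[np.ndarray | None]],
    allow_partial: bool = False,
) -> np.ndarray:
    """Combine a C×F grid of field embeddings into one well profile.

    Per channel, the per-dimension median over the F field embeddings; channel
    blocks are concatenated in channel order.  Missing fields are an error
    unless ``allow_partial`` is set (median over the available fields).
    """
    blocks = []
    for c, per_field in enumerate(field_embeddings, start=1):
        present = [e for e in per_field if e is not None]
        if len(present) != len(per_field) and not allow_partial:
            raise EncodingError(
                f"channel {c}: {len(per_field) - len(present)} field embedding(s) missing "
                "(pass allow_partial to aggregate over available fields)"
            )
        if not present:
            raise EncodingError(f"channel {c}: no field embeddings at all")
        blocks.append(np.median(np.stack(present), axis=0))
    return np.concatenate(blocks)


# ---------------------------------------------------------------------------
# Whole-screen encoding from a TIFF tree


def scan_image_tree(
    root: Path,
    filename_regex: str = DEFAULT_FILENAME_REGEX,
) -> dict[ManifestEntry, Path]:
    """Map (plate, replicate, well, field, channel) → file for a TIFF tree.

    Expected layout: ``root/<replicate_id>/<plate_id>/<well>_f<F>_ch<C>.tif``
    (the filename pattern is configurable).
    """
    pattern = re.compile(filename_regex)
    manifest: dict[ManifestEntry, Path] = {}
    root = Path(root)
    for path in sorted(root.rglob("*.tif")) + sorted(root.rglob("*.tiff")):
        m = pattern.search(path.name)
        if m is None:
            logger.warning("ignoring unrecognized file name %s", path.name)
            continue
        rel = path.relative_to(root)
        if len(rel.parts) != 3:
            raise EncodingError(
                f"{path} not in <replicate>/<plate>/<file> layout (got {rel})"
            )
        replicate_id, plate_id = rel.parts[0], rel.parts[1]
        well = str(WellAddress.parse(m.group("well")))
        entry = (plate_id, replicate_id, well, int(m.group("field")), int(m.group("channel")))
        manifest[entry] = path
    return manifest


def encode_screen(
    image_root: Path,
    layouts: list[PlateLayout],
    enc: EncoderSpec,
    batch_size: int = 16,
    filename_regex: str = DEFAULT_FILENAME_REGEX,
    allow_partial: bool = False,
    pad_to_tile: bool = False,
) -> FeatureTable:
    """Encode every well of a screen into a raw feature table.

    The image tree is validated against the layouts before any encoding; the
    output has one row per (plate, replicate, well) and 512·C columns
    (embedding_dim·C for mock encoders), in deterministic well order.
    """
    import tifffile

    manifest = scan_image_tree(image_root, filename_regex)
    report = validate_screen(layouts, manifest.keys())
    problems = [r for r in report if not allow_partial or not r.startswith("missing")]
    if problems:
        raise EncodingError(
            "image tree does not match layouts:\n  " + "\n  ".join(problems[:20])
        )

    rows, index = [], []
    for lay in layouts:
        logger.info("encoding plate %s replicate %s (%d wells)", lay.plate_id, lay.replicate_id, lay.n_wells)
        for well in sorted(lay.wells):
            grid: list[list[np.ndarray | None]] = []
            for ch in range(1, lay.channels + 1):
                per_field: list[np.ndarray | None] = []
                for fld in range(1, lay.fields_per_well + 1):
                    path = manifest.get((lay.plate_id, lay.replicate_id, str(well), fld, ch))
                    if path is None:
                        per_field.append(None)
                        continue
                    pixels = tifffile.imread(path)
                    bit_max = 65535.0 if pixels.dtype.itemsize > 1 else 255.0
                    field = ImageField(pixels, well, fld, ch, bit_depth_max=bit_max)
                    per_field.append(
                        encode_field(field, enc, batch_size=batch_size, pad_to_tile=pad_to_tile)
                    )
                grid.append(per_field)
            rows.append(assemble_well_profile(grid, allow_partial=allow_partial))
            index.append((lay.plate_id, lay.replicate_id, str(well)))
    return FeatureTable.from_array(np.stack(rows), index, state=TableState.raw)
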