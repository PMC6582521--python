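"""Rendering molecules as fixed-size Kekulé structure images plus augmentation.

Molecules are depicted with explicit alternating single/double bonds
(kekulized), dark bond lines and element-coloured heteroatom labels on a white
background, rasterized directly at the backbone input size (224x224 RGB).
Training-time augmentation applies horizontal/vertical flips and a +/-90
degree rotation, each independently with 50% probability per epoch — the
label-preserving dihedral transforms.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from rdkit import Chem
from rdkit.Chem import rdDepictor
from rdkit.Chem.Draw import rdMolDraw2D

from .chem_data import CompoundRecord

#: Per-channel normalization constants of the ImageNet input distribution that
#: the pretrained backbone families expect (RGB, on the 0-1 scale).
CHANNEL_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float64)
CHANNEL_STD = np.array([0.229, 0.224, 0.225], dtype=np.float64)

DEFAULT_SIZE = 224


class RenderError(RuntimeError):
    """A molecule could not be depicted (e.g. kekulization failure)."""


@dataclass
class RenderedImage:
    """A rasterized depiction of one compound.

    ``pixels`` is (size, size, 3) uint8; ``provenance`` hashes the renderer
    settings so images are only comparable within one depiction style.
    """

    compound_id: str
    pixels: np.ndarray
    provenance: str


@dataclass
class AugmentationPolicy:
    """Stochastic flip/rotation policy applied afresh at every training epoch."""

    horizontal_flip_prob: float = 0.5
    vertical_flip_prob: float = 0.5
    rot90_prob: float = 0.5
    enabled: bool = True

    def __post_init__(self) -> None:
        for p in (self.horizontal_flip_prob, self.vertical_flip_prob, self.rot90_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


_RENDER_SETTINGS = {
    "renderer": "rdkit-MolDraw2DCairo",
    "kekulize": True,
    "background": "white",
    "coord_gen": "rdDepictor.Compute2DCoords",
}


def render_settings_hash(size: int = DEFAULT_SIZE) -> str:
    """Stable fingerprint of the depiction style (renderer + size)."""
    payload = json.dumps({**_RENDER_SETTINGS, "size": size}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def render_kekule(
    record: CompoundRecord | str, size: int = DEFAULT_SIZE, compound_id: str | None = None
) -> RenderedImage:
    """Render a standardized molecule as a Kekulé depiction raster.

    Deterministic: identical structure and settings give byte-identical pixels.
    Sizes other than 224 are allowed (the backbones expect 224; callers resize
    or accept the mismatch knowingly).
    """
    if isinstance(record, CompoundRecord):
        smiles, cid = record.canonical_structure, record.compound_id
    else:
        smiles, cid = record, compound_id or "unnamed"
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise RenderError(f"cannot parse structure for {cid}")
    try:
        rdDepictor.Compute2DCoords(mol)
        drawer = rdMolDraw2D.MolDraw2DCairo(size, size)
        opts = drawer.drawOptions()
        opts.useBWAtomPalette = False
        rdMolDraw2D.PrepareAndDrawMolecule(drawer, mol, kekulize=True)
        drawer.FinishDrawing()
        png_bytes = drawer.GetDrawingText()
    except Exception as exc:  # rdkit raises various exception types here
        raise RenderError(f"depiction failed for {cid}: {exc}") from exc
    with Image.open(io.BytesIO(png_bytes)) as im:
        pixels = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return RenderedImage(cid, pixels, render_settings_hash(size))


def augment(
    image: RenderedImage | np.ndarray,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply the stochastic dihedral transforms; returns a pixel array.

    Each transform fires independently with its policy probability; the 90
    degree rotation direction is drawn uniformly from {+90, -90}.
    """
    pixels = image.pixels if isinstance(image, RenderedImage) else image
    if not policy.enabled:
        return pixels
    out = pixels
    if rng.random() < policy.horizontal_flip_prob:
        out = out[:, ::-1]
    if rng.random() < policy.vertical_flip_prob:
        out = out[::-1, :]
    if rng.random() < policy.rot90_prob:
        k = 1 if rng.random() < 0.5 else 3
        out = np.rot90(out, k=k)
    return np.ascontiguousarray(out)


def normalize_for_backbone(pixels: np.ndarray) -> np.ndarray:
    """uint8 HWC image -> float CHW tensor on the backbone input scale."""
    x = pixels.astype(np.float64) / 255.0
    x = (x - CHANNEL_MEAN) / CHANNEL_STD
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def denormalize_from_backbone(tensor: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize_for_backbone` (float HWC on the 0-255 scale)."""
    x = tensor.transpose(1, 2, 0) * CHANNEL_STD + CHANNEL_MEAN
    return x * 255.0


def content_hash(image: RenderedImage) -> str:
    """SHA-256 of the raw pixel bytes; used for determinism checks and caching."""
    return hashlib.sha256(
        np.ascontiguousarray(image.pixels).tobytes()
    ).hexdigest()


def render_library(
    records, out_dir: str | Path, size: int = DEFAULT_SIZE
) -> pd.DataFrame:
    """Render all records to <compound_id>.png, reusing cached files.

    The cache key is (compound_id, provenance hash): changing renderer settings
    invalidates previously written images. Returns the manifest
    (compound_id, path, provenance).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = render_settings_hash(size)
    manifest_path = out_dir / "manifest.csv"
    cached: dict[str, str] = {}
    if manifest_path.exists():
        old = pd.read_csv(manifest_path)
        cached = {
            str(r.compound_id): str(r.path)
            for r in old.itertuples(index=False)
            if r.provenance == prov and Path(r.path).exists()
        }
    rows = []
    for rec in records:
        path = cached.get(rec.compound_id)
        if path is None:
            img = render_kekule(rec, size=size)
            path = str(out_dir / f"{rec.compound_id}.png")
            Image.fromarray(img.pixels).save(path)
        rows.append({"compound_id": rec.compound_id, "path": path, "provenance": prov})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, index=False)
    return manifest


def load_rendered(manifest: pd.DataFrame) -> list[RenderedImage]:
    """Load images referenced by a manifest produced by :func:`render_library`."""
    images = []
    for r in manifest.itertuples(index=False):
        with Image.open(r.path) as im:
            pixels = np.asarray(im.convert("RGB"), dtype=np.uint8)
        images.append(RenderedImage(str(r.compound_id), pixels, str(r.provenance)))
    return images
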