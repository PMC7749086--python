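"""Array-archive persistence: .npz files with JSON sidecar manifests.

Descriptor stacks, Gram matrices and WAID matrices are saved as numpy
archives; the sidecar ``<name>.manifest.json`` records provenance
(config hash, source ids, measure/gamma, ...) so any artifact can be
traced back to the settings that produced it.
"""

from __future__ import annotations

import io
import json
import warnings
import zipfile
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["save_array_archive", "load_array_archive", "load_image", "save_image"]


def save_array_archive(path: str | Path, arrays: dict[str, np.ndarray],
                       manifest: dict | None = None) -> Path:
    """Write arrays to ``path`` (.npz) and the manifest to a JSON sidecar.

    The archive is written with fixed zip timestamps so identical arrays
    always produce byte-identical files (reproducibility guarantee).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        for name, arr in arrays.items():
            buf = io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arr))
            info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())
    if manifest is not None:
        sidecar = path.with_suffix(path.suffix + ".manifest.json")
        sidecar.write_text(json.dumps(manifest, sort_keys=True, indent=2))
    return path


def load_array_archive(path: str | Path) -> tuple[dict[str, np.ndarray], dict | None]:
    """Load an archive and its manifest (None when no sidecar exists)."""
    path = Path(path)
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    sidecar = path.with_suffix(path.suffix + ".manifest.json")
    manifest = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return arrays, manifest


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG/TIFF); alpha is dropped with a warning."""
    with Image.open(path) as im:
        if im.mode in ("RGBA", "LA", "PA"):
            warnings.warn(f"{path}: dropping alpha channel", stacklevel=2)
        if im.mode != "RGB":
            im = im.convert("RGB")
        return np.asarray(im, dtype=np.uint8)


def save_image(path: str | Path, pixels: np.ndarray) -> Path:
    """Write an 8-bit RGB (or grayscale mask) array as PNG/TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(pixels)).save(path)
    return path
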