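"""Frame stack I/O: multi-page TIFF or numbered PNG sequences."""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence

import numpy as np

from .errors import HemorheoError


def read_frames(path) -> List[np.ndarray]:
    """Load frames from a multi-page TIFF file or a directory of PNGs."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(path.glob("*.png")) or sorted(path.glob("*.tif*"))
        if not files:
            raise HemorheoError(f"no PNG or TIFF frames found in {path}")
        return [np.asarray(iio.imread(f), dtype=float) for f in files]
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
        if arr.ndim == 2:
            return [np.asarray(arr, dtype=float)]
        return [np.asarray(a, dtype=float) for a in arr]
    raise HemorheoError(f"unsupported frame source {path}")


def write_frames(frames: Sequence[np.ndarray], path) -> None:
    """Write frames as one multi-page TIFF (float32)."""
    import tifffile

    tifffile.imwrite(Path(path),
                     np.stack([np.asarray(f, dtype=np.float32)
                               for f in frames]),
                     photometric="minisblack")
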