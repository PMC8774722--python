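"""File output: deterministic CSVs, plain array dumps, raster images, and run
manifests.

CSV dialect is fixed for cross-platform diffability: comma-separated, header
row, '.' decimal separator, LF line endings.  Raster rendering maps occupied
sites to a dark color and empty sites to white with no interpolation, so the
image is a pixel-exact function of the grid.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

OCCUPIED_COLOR = "#1a3a8f"
EMPTY_COLOR = "#ffffff"


def write_csv(df: pd.DataFrame, path: Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def write_json(obj: dict[str, Any], path: Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def write_grid_text(grid: np.ndarray, path: Path) -> Path:
    """Plain 0/1 integer array dump, one lattice row per line."""
    path = Path(path)
    np.savetxt(path, np.asarray(grid, dtype=np.int8), fmt="%d")
    return path


def write_grid_png(grid: np.ndarray, path: Path) -> Path:
    """Two-color raster image of an occupancy grid (occupied dark, empty
    light), one pixel per site."""
    from matplotlib.colors import ListedColormap
    from matplotlib.image import imsave

    path = Path(path)
    cmap = ListedColormap([EMPTY_COLOR, OCCUPIED_COLOR])
    imsave(path, np.asarray(grid, dtype=np.uint8), cmap=cmap, vmin=0, vmax=1)
    return path


def write_curve_png(summary: pd.DataFrame, fit, path: Path) -> Path:
    """Scatter of mean p_c against r with the fitted line and standard-error
    bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        summary["r"], summary["mean_pc"], yerr=summary["se"],
        fmt="o", color=OCCUPIED_COLOR, capsize=3, label="ensemble mean",
    )
    if fit is not None:
        rr = np.linspace(summary["r"].min(), summary["r"].max(), 50)
        ax.plot(
            rr, fit.intercept + fit.slope * rr, "k--",
            label=f"fit: slope {fit.slope:.3f}",
        )
    ax.set_xlabel("reduction rate r")
    ax.set_ylabel(r"critical density $p_c$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    out_dir: Path, command: str, params: dict[str, Any], files: list[Path]
) -> Path:
    """Record everything needed to bit-reproduce a run: full parameter echo,
    package version, output files with SHA-256 digests, and a timestamp."""
    from . import __version__

    manifest = {
        "command": command,
        "version": __version__,
        "params": params,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "files": {str(Path(f).name): _sha256(f) for f in files},
    }
    return write_json(manifest, Path(out_dir) / "manifest.json")
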