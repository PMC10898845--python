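"""Readers, writers and renderers for the pipeline's interchange formats.

* paint events and cohorts: plain CSV;
* templates: binary PNG (255 = in-mask) plus a JSON sidecar listing the
  landmark pixel indices;
* map bundles: compressed ``.npz`` holding an (n_in_mask x n_stimuli)
  matrix plus a JSON header (template hash, smoothing sigma, provenance);
* rendered maps and matrices: PNG via matplotlib (diverging palette,
  optional significant-only masking).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .template import BodyTemplate

EVENT_COLUMNS = ["subject_id", "stimulus", "polarity", "row", "col", "intensity"]

#: Format used for floats in CSV artifacts so that reruns are byte-identical.
CSV_FLOAT_FORMAT = "%.10g"


def template_hash(template: BodyTemplate) -> str:
    """A short stable digest of a template's mask."""
    h = hashlib.sha256()
    h.update(np.asarray(template.in_mask, dtype=np.uint8).tobytes())
    h.update(f"{template.height}x{template.width}".encode())
    return h.hexdigest()[:16]


def save_template(template: BodyTemplate, png_path: str | Path) -> None:
    """Write a template as a binary PNG plus a JSON landmark sidecar."""
    from PIL import Image

    png_path = Path(png_path)
    img = Image.fromarray((template.in_mask.astype(np.uint8)) * 255, mode="L")
    img.save(png_path)
    sidecar = {
        "height": template.height,
        "width": template.width,
        "hash": template_hash(template),
        "landmarks": {k: v.tolist() for k, v in template.landmarks.items()},
    }
    png_path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_template(png_path: str | Path) -> BodyTemplate:
    """Read a template written by :func:`save_template`."""
    from PIL import Image

    png_path = Path(png_path)
    mask = np.asarray(Image.open(png_path).convert("L")) >= 128
    meta = json.loads(png_path.with_suffix(".json").read_text())
    landmarks = {k: np.asarray(v, dtype=int) for k, v in meta["landmarks"].items()}
    return BodyTemplate(
        height=meta["height"], width=meta["width"], in_mask=mask, landmarks=landmarks
    )


def write_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    events[EVENT_COLUMNS].to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event CSV is missing columns: {sorted(missing)}")
    return events


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a statistics table deterministically (fixed float format)."""
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def save_map_bundle(
    path: str | Path,
    matrix: np.ndarray,
    labels: list[str],
    template: BodyTemplate,
    sigma: float | None = None,
    extra_header: dict | None = None,
) -> None:
    """Write a set of in-mask map vectors as a compressed bundle.

    ``matrix`` is (n_in_mask, n_labels), column order following ``labels``.
    A JSON header with the template hash and parameters is written next to
    the ``.npz``.
    """
    path = Path(path)
    if matrix.shape != (template.n_in_mask, len(labels)):
        raise ValueError("matrix shape must be (n_in_mask, n_labels)")
    np.savez_compressed(path, maps=matrix, labels=np.asarray(labels))
    header = {
        "template_hash": template_hash(template),
        "n_in_mask": template.n_in_mask,
        "sigma": sigma,
        "labels": list(labels),
    }
    if extra_header:
        header.update(extra_header)
    path.with_suffix(".json").write_text(json.dumps(header))


def load_map_bundle(path: str | Path) -> tuple[np.ndarray, list[str], dict]:
    path = Path(path)
    with np.load(path.with_suffix(".npz"), allow_pickle=False) as npz:
        matrix = npz["maps"]
        labels = [str(x) for x in npz["labels"]]
    header = json.loads(path.with_suffix(".json").read_text())
    return matrix, labels, header


def render_map_png(
    vector: np.ndarray,
    template: BodyTemplate,
    path: str | Path,
    sig_mask: np.ndarray | None = None,
    title: str = "",
    vmax: float | None = None,
) -> None:
    """Render an in-mask map vector as a diverging-palette PNG.

    With ``sig_mask`` given, non-significant pixels are blanked (the
    significant-only display used for thresholded group maps).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = np.asarray(vector, dtype=float).copy()
    values = np.where(np.isfinite(values), values, 0.0)
    if sig_mask is not None:
        values = np.where(sig_mask, values, 0.0)
    grid = template.to_grid(values)
    grid[~template.in_mask] = np.nan
    if vmax is None:
        finite = np.abs(values[np.isfinite(values)])
        vmax = float(finite.max()) if finite.size and finite.max() > 0 else 1.0
    fig, ax = plt.subplots(figsize=(3, 5))
    ax.imshow(grid, cmap="RdBu_r", vmin=-vmax, vmax=vmax, interpolation="nearest")
    ax.set_title(title, fontsize=8)
    ax.axis("off")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


def render_matrix_png(
    values: np.ndarray,
    labels: list[str],
    path: str | Path,
    title: str = "",
    cmap: str = "RdBu_r",
    center_zero: bool = True,
) -> None:
    """Render a labelled square matrix (similarity or confusion) as a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    if center_zero:
        vmax = float(np.abs(values).max()) or 1.0
        im = ax.imshow(values, cmap=cmap, vmin=-vmax, vmax=vmax)
    else:
        im = ax.imshow(values, cmap=cmap)
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(labels)), labels, fontsize=6)
    ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
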