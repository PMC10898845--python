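"""Per-subject BSM reconstruction.

Paint events (pixel, polarity, intensity) are rasterized into separate
activation and deactivation grids, masked to the body outline, combined
(activation minus deactivation) and smoothed with a truncated 2-D Gaussian
kernel. Extent is quantified as the proportion of in-mask pixels painted
(PPP) on the *unsmoothed* maps, separately per polarity, and subjects with
too few completed maps are dropped by a completion-rate QC step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .template import BodyTemplate

#: Minimum number of completed maps (out of 21) for a subject to be retained.
DEFAULT_MIN_MAPS = 17

#: Gaussian smoothing sigma in pixels used for the combined maps.
DEFAULT_SIGMA = 5.0


@dataclass
class SubjectBSM:
    """One subject's signed, smoothed map for one stimulus."""

    subject_id: str
    stimulus: str
    raw_activation: np.ndarray  # (H, W) nonnegative, zero outside mask
    raw_deactivation: np.ndarray  # (H, W) nonnegative, zero outside mask
    combined_smoothed: np.ndarray  # flat vector over in-mask pixels
    smoothing_sigma: float


RawMaps = dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]


def rasterize_events(
    events: pd.DataFrame,
    template: BodyTemplate,
    brush_radius: float = 0.0,
    known_stimuli: tuple[str, ...] | None = None,
) -> RawMaps:
    """Rasterize a paint-event table into per-(subject, stimulus) raw grids.

    Each event deposits its intensity on every pixel within ``brush_radius``
    (Euclidean distance) of its coordinate; where deposits overlap, the
    maximum wins, capped at 1. Pixels outside the body outline are zeroed.

    Parameters
    ----------
    events
        Table with columns ``subject_id, stimulus, polarity, row, col,
        intensity`` (0-based pixel coordinates, row-major origin top-left).
    template
        The body template whose mask is applied.
    brush_radius
        Deposit radius in pixels; 0 paints single pixels (the synthetic
        generator emits per-pixel events).
    known_stimuli
        If given, stimulus labels outside this set raise a ``ValueError``.

    Returns
    -------
    dict
        ``(subject_id, stimulus) -> (activation_grid, deactivation_grid)``.
    """
    required = {"subject_id", "stimulus", "polarity", "row", "col", "intensity"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event table is missing columns: {sorted(missing)}")
    if len(events) == 0:
        return {}
    if known_stimuli is not None:
        unknown = set(events["stimulus"].unique()) - set(known_stimuli)
        if unknown:
            raise ValueError(f"unknown stimulus labels: {sorted(unknown)}")
    if (events["intensity"] < 0).any():
        raise ValueError("negative paint intensity")
    if not events["polarity"].isin([1, -1]).all():
        raise ValueError("polarity must be +1 or -1")
    rows = events["row"].to_numpy()
    cols = events["col"].to_numpy()
    if (
        (rows < 0).any()
        or (rows >= template.height).any()
        or (cols < 0).any()
        or (cols >= template.width).any()
    ):
        raise ValueError("event coordinates outside the template grid")

    # brush footprint: pixel offsets within the Euclidean radius
    r = int(np.floor(brush_radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy**2 + dx**2 <= brush_radius**2
    dy, dx = dy[keep], dx[keep]

    out: RawMaps = {}
    H, W = template.height, template.width
    for (sid, stim), sub in events.groupby(["subject_id", "stimulus"], sort=True):
        act = np.zeros((H, W), dtype=float)
        deact = np.zeros((H, W), dtype=float)
        for pol, grid in ((1, act), (-1, deact)):
            pol_rows = sub[sub["polarity"] == pol]
            if len(pol_rows) == 0:
                continue
            rr = pol_rows["row"].to_numpy()[:, None] + dy[None, :]
            cc = pol_rows["col"].to_numpy()[:, None] + dx[None, :]
            ii = np.broadcast_to(
                pol_rows["intensity"].to_numpy()[:, None], rr.shape
            )
            ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            np.maximum.at(grid, (rr[ok], cc[ok]), ii[ok])
        np.minimum(act, 1.0, out=act)
        np.minimum(deact, 1.0, out=deact)
        act[~template.in_mask] = 0.0
        deact[~template.in_mask] = 0.0
        out[(str(sid), str(stim))] = (act, deact)
    return out


def gaussian_smooth(grid: np.ndarray, sigma: float) -> np.ndarray:
    """Smooth a 2-D grid with a normalized Gaussian kernel.

    The kernel is truncated at radius ``ceil(3*sigma)`` and borders are
    zero-padded, so an activation's total mass is preserved whenever its
    support is at least 3 sigma away from the grid edge.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    radius = int(np.ceil(3.0 * sigma))
    return ndimage.gaussian_filter(
        grid.astype(float), sigma=sigma, mode="constant", cval=0.0, radius=radius
    )


def combine_and_smooth(
    raw_activation: np.ndarray,
    raw_deactivation: np.ndarray,
    sigma: float,
    template: BodyTemplate,
    order: str = "combine_then_smooth",
) -> np.ndarray:
    """Combine polarity grids into one signed map, smooth, and re-mask.

    The default follows the convention of combining first (activation minus
    deactivation) and smoothing the combined map; ``order=
    "smooth_then_combine"`` smooths each polarity separately before
    subtracting, as a sensitivity check.

    Returns the flat signed vector over in-mask pixels (row-major order).
    """
    if raw_activation.shape != (template.height, template.width):
        raise ValueError("activation grid shape does not match template")
    if raw_deactivation.shape != raw_activation.shape:
        raise ValueError("polarity grids have different shapes")
    if order == "combine_then_smooth":
        smoothed = gaussian_smooth(raw_activation - raw_deactivation, sigma)
    elif order == "smooth_then_combine":
        smoothed = gaussian_smooth(raw_activation, sigma) - gaussian_smooth(
            raw_deactivation, sigma
        )
    else:
        raise ValueError(f"unknown combination order '{order}'")
    return template.to_vector(smoothed)


def build_subject_bsms(
    raw_maps: RawMaps, template: BodyTemplate, sigma: float = DEFAULT_SIGMA,
    order: str = "combine_then_smooth",
) -> list[SubjectBSM]:
    """Convenience: combine+smooth every raw map into a :class:`SubjectBSM`."""
    out = []
    for (sid, stim), (act, deact) in raw_maps.items():
        vec = combine_and_smooth(act, deact, sigma, template, order=order)
        out.append(
            SubjectBSM(
                subject_id=sid,
                stimulus=stim,
                raw_activation=act,
                raw_deactivation=deact,
                combined_smoothed=vec,
                smoothing_sigma=sigma,
            )
        )
    return out


def _looks_anomalous(act: np.ndarray, deact: np.ndarray) -> bool:
    """Heuristic flag for glyph-like drawings: the painted support forms a
    perfect filled rectangle (a screenshot-style artifact), which genuine
    painting essentially never produces."""
    support = (act > 0) | (deact > 0)
    n = int(support.sum())
    if n < 12:
        return False
    rows, cols = np.nonzero(support)
    area = (rows.max() - rows.min() + 1) * (cols.max() - cols.min() + 1)
    return n == area


def qc_filter(
    raw_maps: RawMaps,
    min_maps: int = DEFAULT_MIN_MAPS,
    flagged_subjects: tuple[str, ...] = (),
    warn_anomalous: bool = True,
) -> tuple[pd.DataFrame, RawMaps]:
    """Completion-rate QC: drop subjects with fewer than ``min_maps``
    completed maps, plus any subject on the injected flag list.

    The flag list stands in for manual visual screening of anomalous
    drawings; a rectangle-support heuristic additionally *warns* about
    suspicious maps but never auto-excludes.

    Returns
    -------
    (report, retained)
        ``report`` has one row per subject: ``subject_id,
        n_maps_completed, excluded, reason``; ``retained`` contains only
        the maps of non-excluded subjects.
    """
    if not (1 <= min_maps <= 21):
        raise ValueError("min_maps must be in [1, 21]")
    counts: dict[str, int] = {}
    for (sid, _stim) in raw_maps:
        counts[sid] = counts.get(sid, 0) + 1
    flagged = set(flagged_subjects)
    rows = []
    excluded = set()
    for sid in sorted(counts):
        n = counts[sid]
        if sid in flagged:
            reason = "flagged_anomalous"
        elif n < min_maps:
            reason = "insufficient_maps"
        else:
            reason = "none"
        if reason != "none":
            excluded.add(sid)
        rows.append(
            {
                "subject_id": sid,
                "n_maps_completed": n,
                "excluded": reason != "none",
                "reason": reason,
            }
        )
    if warn_anomalous:
        for (sid, stim), (act, deact) in raw_maps.items():
            if sid not in excluded and _looks_anomalous(act, deact):
                warnings.warn(
                    f"map ({sid}, {stim}) has rectangle-like painted support; "
                    "consider visual screening",
                    stacklevel=2,
                )
    report = pd.DataFrame(rows, columns=["subject_id", "n_maps_completed", "excluded", "reason"])
    retained = {k: v for k, v in raw_maps.items() if k[0] not in excluded}
    return report, retained


def compute_ppp(raw_maps: RawMaps, template: BodyTemplate) -> pd.DataFrame:
    """Proportion of pixels painted, per subject x stimulus and polarity.

    Computed on the unsmoothed maps: the fraction of in-mask pixels with
    intensity > 0, separately for activations and deactivations.
    """
    n = template.n_in_mask
    mask = template.in_mask
    rows = []
    for (sid, stim), (act, deact) in raw_maps.items():
        rows.append(
            {
                "subject_id": sid,
                "stimulus": stim,
                "ppp_activation": float((act[mask] > 0).sum()) / n,
                "ppp_deactivation": float((deact[mask] > 0).sum()) / n,
            }
        )
    return pd.DataFrame(
        rows, columns=["subject_id", "stimulus", "ppp_activation", "ppp_deactivation"]
    )
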