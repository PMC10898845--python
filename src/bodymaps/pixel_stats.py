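"""Mass-univariate pixelwise statistics.

Group-level maps are obtained by running a scalar t-test independently at
every in-mask pixel: a one-sample test against zero within a group (the
group-level BSM), or a pooled-variance two-sample test contrasting groups.
Each map's p-values are corrected with the Benjamini–Hochberg false
discovery rate over the pixels of that map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class TMap:
    """Per-pixel statistics of one map.

    All arrays are flat vectors over in-mask pixels. ``degenerate`` marks
    pixels with zero variance but nonzero mean (p set to 0 and flagged
    rather than dropped).
    """

    mean: np.ndarray
    sd: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    kind: str  # "one_sample" | "two_sample"
    alpha: float = 0.05
    sig_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sig_mask is None:
            self.sig_mask = fdr_mask(self.p, self.alpha)
        if self.degenerate is None:
            self.degenerate = np.zeros(self.p.shape, dtype=bool)

    @property
    def n_significant(self) -> int:
        return int(self.sig_mask.sum())


def one_sample_tmap(maps: np.ndarray, alpha: float = 0.05) -> TMap:
    """One-sample t-test against zero at every pixel.

    Parameters
    ----------
    maps
        ``(n_subjects, n_pixels)`` array of subject map vectors.
    alpha
        FDR level for the significance mask.

    Notes
    -----
    Zero-variance pixels are handled explicitly: if the mean is also zero
    the pixel is a clean null (t=0, p=1); if the mean is nonzero the test
    is degenerate (p=0, flagged in ``degenerate``).
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 2:
        raise ValueError("one_sample_tmap needs a 2-D array with >= 2 subjects")
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    df = n - 1
    zero_sd = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = np.empty_like(mean)
    ok = ~zero_sd
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df)
    degenerate = zero_sd & (mean != 0)
    t[zero_sd & (mean == 0)] = 0.0
    p[zero_sd & (mean == 0)] = 1.0
    t[degenerate] = np.sign(mean[degenerate]) * np.inf
    p[degenerate] = 0.0
    tmap = TMap(mean=mean, sd=sd, t=t, p=p, df=df, kind="one_sample", alpha=alpha)
    tmap.degenerate = degenerate
    return tmap


def two_sample_tmap(
    maps_group_a: np.ndarray,
    maps_group_b: np.ndarray,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> TMap:
    """Pixelwise two-sample t-test, positive t meaning group A > group B.

    The default is the pooled-variance Student test with
    ``df = n1 + n2 - 2``; ``equal_var=False`` switches to Welch. The
    ``mean``/``sd`` fields hold the mean difference and the pooled SD.
    """
    a = np.asarray(maps_group_a, dtype=float)
    b = np.asarray(maps_group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be 2-D arrays over the same pixels")
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 subjects")
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    diff = m1 - m2
    if equal_var:
        df = n1 + n2 - 2
        sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / df)
        denom = sp * np.sqrt(1.0 / n1 + 1.0 / n2)
        df_vec = np.full(diff.shape, float(df))
    else:
        se2 = v1 / n1 + v2 / n2
        denom = np.sqrt(se2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df_vec = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        df_vec = np.where(np.isfinite(df_vec), df_vec, 1.0)
        sp = np.sqrt((v1 + v2) / 2.0)
        df = int(round(float(np.nanmean(df_vec))))
    zero_sd = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    p = np.empty_like(diff)
    ok = ~zero_sd
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_vec[ok])
    degenerate = zero_sd & (diff != 0)
    t[zero_sd & (diff == 0)] = 0.0
    p[zero_sd & (diff == 0)] = 1.0
    t[degenerate] = np.sign(diff[degenerate]) * np.inf
    p[degenerate] = 0.0
    tmap = TMap(
        mean=diff,
        sd=sp,
        t=t,
        p=p,
        df=(n1 + n2 - 2) if equal_var else df,
        kind="two_sample",
        alpha=alpha,
    )
    tmap.degenerate = degenerate
    tmap.sig_mask = fdr_mask(p, alpha)
    return tmap


def fdr_mask(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask.

    Sorts the supplied p-values, finds the largest rank ``k`` with
    ``p_(k) <= (k/m) * alpha`` and rejects every hypothesis with
    ``p <= p_(k)``. Returns a boolean mask in input order; an empty input
    yields an empty mask.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be a 1-D vector")
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    thresh = alpha * (np.arange(1, m + 1) / m)
    passed = p[order] <= thresh
    if not passed.any():
        return np.zeros(m, dtype=bool)
    k = int(np.nonzero(passed)[0].max())
    return p <= p[order][k]
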