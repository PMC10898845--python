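"""Synthetic body-mapping cohorts.

Generates paint-event tables and questionnaire data with the statistical
structure the downstream analysis is designed to detect:

* each stimulus has a canonical topography (a set of signed Gaussian
  sensation blobs anchored to body landmarks);
* "high" drinkers paint with an extent gain ``kappa`` (activations scaled
  up) and with their stimulus-specific topography partially blended toward
  a shared head+chest template by a confusion weight ``w`` — less specific,
  more mutually similar maps;
* questionnaire totals are drawn per group from clamped normals whose
  default targets are the published group means/SDs (low drinkers
  AUDIT ~ 2.6, high drinkers ~ 10.5, etc.).

The generator is fully reproducible from a single integer seed, and the
per-subject random streams depend on the subject's rank within its group
rather than on the group itself, so that with ``w = 0``, ``kappa = 1`` and
zero noise the two groups paint identical maps — the null configuration
used in parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimuli import StimulusSet
from .template import BodyTemplate

# Stream tags for seed derivation (kept < 2**16; combined with the master
# seed through numpy's SeedSequence spawn keys).
_STREAM_TOPO = 1
_STREAM_MAPS = 2
_STREAM_QUEST = 3


@dataclass(frozen=True)
class Blob:
    """One signed Gaussian sensation blob anchored to a landmark."""

    landmark: str
    center: tuple[int, int]  # (row, col), inside the landmark pixel set
    jitter_scale: float  # SD in pixels of per-subject center jitter
    sigma: float  # spatial spread in pixels
    sign: int  # +1 activation, -1 deactivation
    amplitude: float  # in (0, 1]

    def __post_init__(self) -> None:
        if not (0.0 < self.amplitude <= 1.0):
            raise ValueError("blob amplitude must be in (0, 1]")
        if self.sign not in (-1, 1):
            raise ValueError("blob sign must be +1 or -1")


@dataclass(frozen=True)
class CanonicalTopography:
    """The canonical blob set of one stimulus."""

    stimulus: str
    blobs: tuple[Blob, ...]

    def __post_init__(self) -> None:
        if len(self.blobs) == 0:
            raise ValueError("a topography needs at least one blob")


# (landmark, jitter_scale, sigma, sign, amplitude) in units of a 160-pixel
# tall template; scaled to the actual template at construction time. Shapes
# follow the qualitative group-level map conventions of body-mapping studies:
# happiness whole-body positive, sadness limb deactivation with chest
# activation, hunger abdominal, racing heart chest-focal, and a neutral
# state with the lowest total amplitude of the emotion block.
_BLUEPRINT: dict[str, list[tuple[str, float, float, int, float]]] = {
    "fear": [("chest", 3, 8, 1, 0.90), ("head", 2, 6, 1, 0.60),
             ("left_leg", 3, 8, -1, 0.40), ("right_leg", 3, 8, -1, 0.40)],
    "anger": [("head", 2, 7, 1, 0.90), ("chest", 3, 9, 1, 0.80),
              ("left_arm", 2, 7, 1, 0.60), ("right_arm", 2, 7, 1, 0.60)],
    "disgust": [("head", 2, 6, 1, 0.70), ("abdomen", 3, 8, 1, 0.80)],
    "sadness": [("chest", 3, 9, 1, 0.70),
                ("left_arm", 2, 8, -1, 0.50), ("right_arm", 2, 8, -1, 0.50),
                ("left_leg", 3, 9, -1, 0.50), ("right_leg", 3, 9, -1, 0.50)],
    "happiness": [("full_body", 4, 30, 1, 0.50), ("head", 2, 8, 1, 0.80),
                  ("chest", 3, 10, 1, 0.80)],
    "surprise": [("head", 2, 7, 1, 0.80), ("chest", 3, 8, 1, 0.70)],
    "anxiety": [("chest", 3, 10, 1, 0.95), ("abdomen", 3, 8, 1, 0.50)],
    "hope": [("chest", 3, 9, 1, 0.60), ("head", 2, 7, 1, 0.50)],
    "contempt": [("head", 2, 7, 1, 0.60), ("chest", 3, 8, 1, 0.30)],
    "confusion": [("head", 2, 8, 1, 0.75)],
    "neutral": [("chest", 3, 8, 1, 0.12), ("head", 2, 6, 1, 0.10)],
    "nausea": [("abdomen", 3, 9, 1, 0.90), ("head", 2, 6, 1, 0.50),
               ("chest", 3, 7, 1, 0.30)],
    "hunger": [("abdomen", 3, 10, 1, 0.95)],
    "thirst": [("head", 2, 5, 1, 0.80)],
    "physical_fatigue": [("full_body", 4, 30, -1, 0.40),
                         ("left_arm", 2, 8, -1, 0.60), ("right_arm", 2, 8, -1, 0.60),
                         ("head", 2, 6, 1, 0.30)],
    "shortness_of_breath": [("chest", 3, 8, 1, 0.90), ("head", 2, 6, 1, 0.40)],
    "racing_heart": [("chest", 2, 7, 1, 1.00)],
    "numbness": [("left_arm", 2, 8, -1, 0.70), ("right_arm", 2, 8, -1, 0.70),
                 ("left_leg", 3, 9, -1, 0.60), ("right_leg", 3, 9, -1, 0.60)],
    "skin_tingling": [("left_arm", 2, 7, 1, 0.50), ("right_arm", 2, 7, 1, 0.50),
                      ("full_body", 4, 25, 1, 0.25)],
    "tipsy": [("head", 2, 8, 1, 0.80),
              ("left_leg", 3, 9, -1, 0.45), ("right_leg", 3, 9, -1, 0.45)],
    "hangover": [("head", 2, 8, 1, 0.95), ("abdomen", 3, 8, 1, 0.70),
                 ("full_body", 4, 25, -1, 0.30)],
}

# Questionnaire target (mean, sd) per group, at the published group values,
# plus the instrument range used for clamping.
DEFAULT_QUESTIONNAIRE_TARGETS: dict[str, dict] = {
    "audit": {"low": (2.62, 1.18), "high": (10.53, 3.59), "range": (0, 40)},
    "task_difficulty": {"low": (5.57, 2.41), "high": (6.30, 2.29), "range": (1, 10)},
    "tas_ddf": {"low": (10.62, 4.24), "high": (12.10, 4.68), "range": (5, 25)},
    "tas_dif": {"low": (17.03, 6.40), "high": (19.52, 5.83), "range": (7, 35)},
    "tas_eot": {"low": (11.76, 4.21), "high": (12.45, 3.85), "range": (8, 40)},
    "tas_total": {"low": (39.41, 11.99), "high": (44.07, 11.31), "range": (20, 100)},
    "maia": {"low": (98.29, 23.59), "high": (94.35, 23.73), "range": (0, 160)},
    "isq": {"low": (15.53, 5.50), "high": (17.43, 6.20), "range": (8, 40)},
    "age": {"low": (23.34, 3.52), "high": (22.67, 3.30), "range": (18, 30)},
}

#: Proportion of female participants per group (remaining probability is
#: split between male and a third gender category).
DEFAULT_FEMALE_PROP = {"low": 0.8667, "high": 0.9011}
_OTHER_GENDER_PROP = 0.02


@dataclass
class GeneratorConfig:
    """Configuration of a synthetic cohort.

    Defaults reproduce the published study conditions: two groups of 90/91
    subjects whose questionnaire totals match the printed group means/SDs,
    a high group with a 1.3x activation extent gain and a 0.5 blend toward
    the shared head+chest template, and a per-map dropout rate giving a
    mean completion of roughly 20.4 of 21 maps.
    """

    n_low: int = 90
    n_high: int = 91
    extent_gain: float = 1.3
    confusion_weight: float = 0.5
    subject_noise_sd: float = 0.03
    style_sd: float = 0.12
    map_noise_sd: float = 0.18
    noise_smooth_sigma: float = 6.0
    amp_jitter_sd: float = 0.3
    paint_threshold: float = 0.15
    map_dropout_prob: float = 0.03
    questionnaire_targets: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_QUESTIONNAIRE_TARGETS.items()}
    )
    female_prop: dict = field(default_factory=lambda: dict(DEFAULT_FEMALE_PROP))
    seed: int = 0

    def validate(self) -> None:
        if self.n_low < 2 or self.n_high < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.extent_gain < 1.0:
            raise ValueError("extent_gain must be >= 1")
        if not (0.0 <= self.confusion_weight <= 1.0):
            raise ValueError("confusion_weight must be in [0, 1]")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be >= 0")
        if self.style_sd < 0 or self.map_noise_sd < 0 or self.amp_jitter_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if not (0.0 < self.paint_threshold < 1.0):
            raise ValueError("paint_threshold must be in (0, 1)")
        if not (0.0 <= self.map_dropout_prob < 1.0):
            raise ValueError("map_dropout_prob must be in [0, 1)")


def _project_to_landmark(
    template: BodyTemplate, landmark: str, row: float, col: float
) -> tuple[int, int]:
    """Snap a (possibly off-landmark) point to the nearest landmark pixel."""
    idx = template.landmarks[landmark]
    rows, cols = np.unravel_index(idx, (template.height, template.width))
    d2 = (rows - row) ** 2 + (cols - col) ** 2
    k = int(np.argmin(d2))
    return int(rows[k]), int(cols[k])


def make_canonical_topographies(
    template: BodyTemplate, stimuli: StimulusSet, seed: int
) -> list[CanonicalTopography]:
    """Assign every stimulus a distinct blob set on the given template.

    Blob centers are drawn near the centroid of their landmark region
    (seeded, then snapped onto the landmark pixel set); spatial scales in
    the blueprint are expressed for a 160-pixel-tall body and rescaled to
    the actual template height.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM_TOPO,)))
    unit = template.height / 160.0
    topos: list[CanonicalTopography] = []
    for stim in stimuli.labels:
        spec_blobs = _BLUEPRINT.get(stim)
        if spec_blobs is None:
            # unknown custom label: fall back to a chest blob
            spec_blobs = [("chest", 3, 8, 1, 0.5)]
        blobs = []
        for landmark, jit, sig, sign, amp in spec_blobs:
            idx = template.landmarks[landmark]
            rows, cols = np.unravel_index(idx, (template.height, template.width))
            cy, cx = float(rows.mean()), float(cols.mean())
            cy += rng.normal(0, jit * unit)
            cx += rng.normal(0, jit * unit)
            center = _project_to_landmark(template, landmark, cy, cx)
            blobs.append(
                Blob(
                    landmark=landmark,
                    center=center,
                    jitter_scale=jit * unit,
                    sigma=max(sig * unit, 1.0),
                    sign=sign,
                    amplitude=amp,
                )
            )
        topos.append(CanonicalTopography(stimulus=stim, blobs=tuple(blobs)))
    return topos


def render_blobs(template: BodyTemplate, blobs: tuple[Blob, ...] | list[Blob]) -> np.ndarray:
    """Render signed Gaussian blobs onto the masked grid, clipped to [-1, 1]."""
    H, W = template.height, template.width
    field_grid = np.zeros((H, W), dtype=float)
    for blob in blobs:
        r0, c0 = blob.center
        rad = int(np.ceil(4 * blob.sigma))
        rlo, rhi = max(r0 - rad, 0), min(r0 + rad + 1, H)
        clo, chi = max(c0 - rad, 0), min(c0 + rad + 1, W)
        rows = np.arange(rlo, rhi)[:, None]
        cols = np.arange(clo, chi)[None, :]
        d2 = (rows - r0) ** 2 + (cols - c0) ** 2
        field_grid[rlo:rhi, clo:chi] += (
            blob.sign * blob.amplitude * np.exp(-d2 / (2.0 * blob.sigma**2))
        )
    field_grid = np.clip(field_grid, -1.0, 1.0)
    field_grid[~template.in_mask] = 0.0
    return field_grid


def shared_head_chest_template(template: BodyTemplate) -> np.ndarray:
    """The shared activation pattern confused maps are blended toward.

    A fixed positive head + chest field: the common locus where
    less-differentiated painters report most sensations.
    """
    unit = template.height / 160.0
    blobs = []
    for landmark, sig, amp in (("head", 9, 0.9), ("chest", 11, 0.9)):
        idx = template.landmarks[landmark]
        rows, cols = np.unravel_index(idx, (template.height, template.width))
        center = _project_to_landmark(template, landmark, float(rows.mean()), float(cols.mean()))
        blobs.append(
            Blob(
                landmark=landmark,
                center=center,
                jitter_scale=0.0,
                sigma=max(sig * unit, 1.0),
                sign=1,
                amplitude=amp,
            )
        )
    return render_blobs(template, blobs)


def _jitter_blobs(
    template: BodyTemplate,
    topo: CanonicalTopography,
    rng: np.random.Generator,
    amp_jitter_sd: float = 0.0,
) -> list[Blob]:
    out = []
    for blob in topo.blobs:
        r = blob.center[0] + rng.normal(0, blob.jitter_scale)
        c = blob.center[1] + rng.normal(0, blob.jitter_scale)
        center = _project_to_landmark(template, blob.landmark, r, c)
        amp = blob.amplitude
        amp_draw = rng.normal(0, 1.0)
        if amp_jitter_sd > 0:
            amp = min(amp * float(np.exp(amp_jitter_sd * amp_draw)), 1.0)
        out.append(
            Blob(
                landmark=blob.landmark,
                center=center,
                jitter_scale=blob.jitter_scale,
                sigma=blob.sigma,
                sign=blob.sign,
                amplitude=amp,
            )
        )
    return out


def _smooth_noise(
    rng: np.random.Generator, shape: tuple[int, int], sd: float, smooth_sigma: float
) -> np.ndarray:
    """A spatially correlated Gaussian field with pixelwise SD ``sd``.

    Smooth fields emulate stroke-scale idiosyncrasies of real painting;
    unlike iid pixel noise they are not averaged away by the downstream
    Gaussian smoothing. The RNG draw happens even for sd=0 so that random
    streams stay aligned across configurations.
    """
    raw = rng.standard_normal(shape)
    if sd == 0:
        return np.zeros(shape)
    from scipy import ndimage

    sm = ndimage.gaussian_filter(raw, smooth_sigma, mode="constant")
    s = sm.std()
    return sm * (sd / s) if s > 0 else np.zeros(shape)


def _draw_questionnaires(
    config: GeneratorConfig, group: str, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    for measure, target in config.questionnaire_targets.items():
        mean, sd = target[group]
        lo, hi = target["range"]
        vals = rng.normal(mean, sd, size=n)
        # instrument totals are integers; clamp (not resample) to the range
        cols[measure] = np.clip(np.round(vals), lo, hi).astype(int)
    p_f = config.female_prop[group]
    p_other = _OTHER_GENDER_PROP
    p_m = max(1.0 - p_f - p_other, 0.0)
    cols["gender"] = rng.choice(
        np.array(["female", "male", "other"]), size=n, p=[p_f, p_m, p_other]
    )
    return cols


def simulate_cohort(
    config: GeneratorConfig, template: BodyTemplate, stimuli: StimulusSet
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate paint events, a cohort table and a ground-truth record.

    For each retained subject x stimulus the latent intensity field is

    ``(1 - w * is_high) * topography + w * is_high * shared_template``

    with the activation (positive) part additionally scaled by ``kappa``
    for high-group subjects, plus iid Gaussian pixel noise. Pixels whose
    latent activation (deactivation) exceeds ``paint_threshold`` become
    paint events of polarity +1 (-1) with intensity ``min(|latent|, 1)``.
    Each subject x stimulus map is independently dropped with probability
    ``map_dropout_prob`` (an unfinished map).

    Returns
    -------
    events : pandas.DataFrame
        Columns ``subject_id, stimulus, polarity, row, col, intensity``.
    cohort : pandas.DataFrame
        One row per subject with group and questionnaire totals.
    truth : dict
        Generating parameters and per-subject latent confusion weights.
    """
    config.validate()
    topos = make_canonical_topographies(template, stimuli, config.seed)
    topo_by_stim = {t.stimulus: t for t in topos}
    shared = shared_head_chest_template(template)
    w = config.confusion_weight
    kappa = config.extent_gain

    ev_subject: list[str] = []
    ev_stim: list[str] = []
    ev_pol: list[int] = []
    ev_row: list[np.ndarray] = []
    ev_col: list[np.ndarray] = []
    ev_int: list[np.ndarray] = []
    truth_subjects: dict[str, dict] = {}
    cohort_rows: list[dict] = []

    for group, n in (("low", config.n_low), ("high", config.n_high)):
        is_high = group == "high"
        qrng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(_STREAM_QUEST, int(is_high)))
        )
        qcols = _draw_questionnaires(config, group, n, qrng)
        group_has_maps = False
        for rank in range(n):
            sid = f"{group}_{rank + 1:03d}"
            # per-rank stream: identical across groups so that the null
            # configuration (w=0, kappa=1, no noise) paints identical maps
            srng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(_STREAM_MAPS, rank))
            )
            shape = (template.height, template.width)
            style = _smooth_noise(srng, shape, config.style_sd, config.noise_smooth_sigma)
            n_completed = 0
            for stim in stimuli.labels:
                drop = srng.random() < config.map_dropout_prob
                jittered = _jitter_blobs(
                    template, topo_by_stim[stim], srng, config.amp_jitter_sd
                )
                map_noise = _smooth_noise(
                    srng, shape, config.map_noise_sd, config.noise_smooth_sigma
                )
                pixel_noise = (
                    srng.normal(0.0, config.subject_noise_sd, size=shape)
                    if config.subject_noise_sd > 0
                    else 0.0
                )
                if drop:
                    continue
                latent = render_blobs(template, jittered)
                if is_high and w > 0:
                    latent = (1.0 - w) * latent + w * shared
                if is_high and kappa != 1.0:
                    latent = np.where(latent > 0, latent * kappa, latent)
                latent = latent + style + map_noise + pixel_noise
                latent[~template.in_mask] = 0.0
                n_completed += 1
                group_has_maps = True
                for pol in (1, -1):
                    signed = latent if pol == 1 else -latent
                    hit = signed > config.paint_threshold
                    if not hit.any():
                        continue
                    rows, cols_ = np.nonzero(hit)
                    ev_subject.append(sid)
                    ev_stim.append(stim)
                    ev_pol.append(pol)
                    ev_row.append(rows)
                    ev_col.append(cols_)
                    ev_int.append(np.minimum(signed[hit], 1.0))
            truth_subjects[sid] = {
                "group": group,
                "rank": rank,
                "latent_confusion": w if is_high else 0.0,
                "n_maps_completed": n_completed,
            }
            row = {"subject_id": sid, "group": group}
            for measure in qcols:
                row[measure] = qcols[measure][rank]
            cohort_rows.append(row)
        if not group_has_maps:
            raise ValueError(f"group '{group}' is empty after map dropout")

    parts = []
    for sid, stim, pol, rows, cols_, inten in zip(
        ev_subject, ev_stim, ev_pol, ev_row, ev_col, ev_int
    ):
        parts.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "stimulus": stim,
                    "polarity": pol,
                    "row": rows.astype(int),
                    "col": cols_.astype(int),
                    "intensity": inten,
                }
            )
        )
    if parts:
        events = pd.concat(parts, ignore_index=True)
    else:
        events = pd.DataFrame(
            columns=["subject_id", "stimulus", "polarity", "row", "col", "intensity"]
        )
    cohort = pd.DataFrame(cohort_rows)
    truth = {
        "confusion_weight": w,
        "extent_gain": kappa,
        "subject_noise_sd": config.subject_noise_sd,
        "paint_threshold": config.paint_threshold,
        "map_dropout_prob": config.map_dropout_prob,
        "seed": config.seed,
        "subjects": truth_subjects,
    }
    return events, cohort, truth
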