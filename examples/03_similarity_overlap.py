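"""Confusion between maps: cosine similarity and significance overlap.

Computes per-group cosine-similarity matrices of the 21 group-level
t-maps, their high-minus-low difference, and the per-pixel overlap of
FDR-significant maps — the analyses that quantify how undifferentiated
the high group's bodily sensations are.
"""

import numpy as np

from bodymaps import (
    GeneratorConfig,
    build_subject_bsms,
    default_stimulus_set,
    make_body_template,
    matrix_difference,
    one_sample_tmap,
    overlap_counts,
    rasterize_events,
    similarity_matrix,
    simulate_cohort,
)

template = make_body_template(80, 32)
stimuli = default_stimulus_set()
events, _, _ = simulate_cohort(
    GeneratorConfig(n_low=12, n_high=12, seed=3), template, stimuli
)
raw = rasterize_events(events, template)
bsms = build_subject_bsms(raw, template, sigma=3.0)

sims, masks = {}, {}
for g in ("low", "high"):
    tmaps = {}
    for stim in stimuli.labels:
        stack = np.array([b.combined_smoothed for b in bsms
                          if b.stimulus == stim and b.subject_id.startswith(g)])
        tmaps[stim] = one_sample_tmap(stack)
    sims[g] = similarity_matrix(tmaps, labels=stimuli.labels)
    masks[g] = {s: tmaps[s].sig_mask for s in stimuli.labels}
    print(f"{g}: mean off-diagonal similarity, emotions block = "
          f"{sims[g].mean_offdiagonal(stimuli.emotion_block):.3f}")

diff = matrix_difference(sims["high"], sims["low"])
print(f"largest similarity increase (high-low): {diff.values.max():.3f}")

for g in ("low", "high"):
    om = overlap_counts(masks[g], stimuli.emotion_block, "emotions", group=g)
    print(f"{g}: max overlap count (emotions) = {om.counts.max()} of 11")
print(
    "-> higher off-diagonal similarity and deeper overlap in the high "
    "group mean its emotion maps collapse onto a shared pattern"
)
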