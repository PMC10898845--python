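"""Group-level pixelwise t-maps with FDR thresholding.

Reconstructs smoothed subject maps for one stimulus, runs the one-sample
t-test against zero at every in-mask pixel, applies Benjamini-Hochberg
FDR (alpha = 0.05), and contrasts the groups with a pooled two-sample
t-map.
"""

import numpy as np

from bodymaps import (
    GeneratorConfig,
    build_subject_bsms,
    default_stimulus_set,
    make_body_template,
    one_sample_tmap,
    rasterize_events,
    simulate_cohort,
    two_sample_tmap,
)

template = make_body_template(80, 32)
stimuli = default_stimulus_set()
events, _, _ = simulate_cohort(
    GeneratorConfig(n_low=12, n_high=12, seed=2), template, stimuli
)
raw = rasterize_events(events, template)
bsms = build_subject_bsms(raw, template, sigma=3.0)

stim = "racing_heart"
stacks = {
    g: np.array([b.combined_smoothed for b in bsms
                 if b.stimulus == stim and b.subject_id.startswith(g)])
    for g in ("low", "high")
}
for g, stack in stacks.items():
    tm = one_sample_tmap(stack)
    print(f"{stim} ({g}): {tm.n_significant}/{template.n_in_mask} significant px "
          f"(df={tm.df}, max |t|={np.nanmax(np.abs(tm.t[np.isfinite(tm.t)])):.1f})")

contrast = two_sample_tmap(stacks["high"], stacks["low"])  # positive = high > low
print(f"high-low contrast: {contrast.n_significant} significant px, df={contrast.df}")
print(
    "-> the one-sample maps localize the chest blob; the contrast shows "
    "where the high group's activation is reliably stronger"
)
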