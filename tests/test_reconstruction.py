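import numpy as np
import pandas as pd
import pytest

from bodymaps import (
    combine_and_smooth,
    compute_ppp,
    gaussian_smooth,
    qc_filter,
    rasterize_events,
)


def _event(template, row, col, polarity=1, intensity=1.0, sid="s1", stim="fear"):
    return pd.DataFrame(
        [{"subject_id": sid, "stimulus": stim, "polarity": polarity,
          "row": row, "col": col, "intensity": intensity}]
    )


def _an_inmask_pixel(template):
    r, c = np.argwhere(template.in_mask)[len(np.argwhere(template.in_mask)) // 2]
    return int(r), int(c)


def _an_outmask_pixel(template):
    r, c = np.argwhere(~template.in_mask)[0]
    return int(r), int(c)


class TestRasterize:
    def test_single_event_zero_brush_paints_one_pixel(self, template):
        r, c = _an_inmask_pixel(template)
        raw = rasterize_events(_event(template, r, c), template, brush_radius=0)
        act, deact = raw[("s1", "fear")]
        assert act[r, c] == 1.0
        assert np.count_nonzero(act) == 1
        assert np.count_nonzero(deact) == 0

    def test_out_of_mask_event_is_masked_out(self, template):
        r, c = _an_outmask_pixel(template)
        raw = rasterize_events(_event(template, r, c), template)
        act, deact = raw[("s1", "fear")]
        assert not act.any() and not deact.any()

    def test_overlapping_deposits_take_maximum(self, template):
        r, c = _an_inmask_pixel(template)
        events = pd.concat([
            _event(template, r, c, intensity=0.4),
            _event(template, r, c, intensity=0.9),
        ])
        raw = rasterize_events(events, template)
        act, _ = raw[("s1", "fear")]
        assert act[r, c] == pytest.approx(0.9)

    def test_brush_radius_footprint_is_euclidean_disc(self, template):
        r, c = _an_inmask_pixel(template)
        raw = rasterize_events(_event(template, r, c), template, brush_radius=2.0)
        act, _ = raw[("s1", "fear")]
        painted = {(pr, pc) for pr, pc in zip(*np.nonzero(act))}
        expected = {
            (r + dr, c + dc)
            for dr in range(-2, 3)
            for dc in range(-2, 3)
            if dr**2 + dc**2 <= 4 and template.in_mask[r + dr, c + dc]
        }
        assert painted == expected

    def test_unknown_stimulus_and_bad_inputs_rejected(self, template, stimuli):
        r, c = _an_inmask_pixel(template)
        with pytest.raises(ValueError, match="unknown stimulus"):
            rasterize_events(
                _event(template, r, c, stim="boredom"), template,
                known_stimuli=stimuli.labels,
            )
        with pytest.raises(ValueError, match="negative"):
            rasterize_events(_event(template, r, c, intensity=-0.1), template)
        with pytest.raises(ValueError, match="coordinates"):
            rasterize_events(_event(template, template.height, c), template)
        with pytest.raises(ValueError, match="polarity"):
            rasterize_events(_event(template, r, c, polarity=2), template)


class TestSmoothing:
    def test_all_zero_input_stays_zero(self, template):
        zero = np.zeros((template.height, template.width))
        out = combine_and_smooth(zero, zero, sigma=3.0, template=template)
        assert not out.any()

    def test_single_pixel_matches_closed_form_kernel(self):
        """Impulse response equals the truncated discrete Gaussian
        normalized to unit sum (radius ceil(3 sigma))."""
        sigma = 2.0
        n = 41
        grid = np.zeros((n, n))
        grid[n // 2, n // 2] = 1.0
        out = gaussian_smooth(grid, sigma)
        rad = int(np.ceil(3 * sigma))
        ax = np.arange(-rad, rad + 1)
        k1 = np.exp(-(ax**2) / (2 * sigma**2))
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        np.testing.assert_allclose(
            out[n // 2 - rad : n // 2 + rad + 1, n // 2 - rad : n // 2 + rad + 1],
            kernel,
            atol=1e-12,
        )

    def test_mass_preserved_away_from_borders(self):
        rng = np.random.default_rng(0)
        sigma = 2.5
        grid = np.zeros((60, 60))
        grid[25:35, 25:35] = rng.random((10, 10))
        out = gaussian_smooth(grid, sigma)
        assert out.sum() == pytest.approx(grid.sum(), rel=1e-6)

    def test_smoothing_is_linear(self, template, rng):
        a = rng.random((template.height, template.width)) * template.in_mask
        b = rng.random((template.height, template.width)) * template.in_mask
        z = np.zeros_like(a)
        s_ab = combine_and_smooth(a + b, z, 4.0, template)
        s_a = combine_and_smooth(a, z, 4.0, template)
        s_b = combine_and_smooth(b, z, 4.0, template)
        np.testing.assert_allclose(s_ab, s_a + s_b, atol=1e-9)

    def test_combined_map_is_activation_minus_deactivation(self, template, rng):
        act = rng.random((template.height, template.width)) * template.in_mask
        deact = rng.random((template.height, template.width)) * template.in_mask
        combined = combine_and_smooth(act, deact, 3.0, template)
        expected = combine_and_smooth(act, np.zeros_like(act), 3.0, template) - \
            combine_and_smooth(deact, np.zeros_like(act), 3.0, template)
        np.testing.assert_allclose(combined, expected, atol=1e-9)

    def test_masking_idempotent(self, template, rng):
        grid = rng.random((template.height, template.width))
        masked = grid * template.in_mask
        np.testing.assert_array_equal(masked * template.in_mask, masked)

    def test_nonpositive_sigma_rejected(self, template):
        zero = np.zeros((template.height, template.width))
        with pytest.raises(ValueError):
            combine_and_smooth(zero, zero, 0.0, template)


class TestQC:
    def _maps(self, template, n_maps_by_subject):
        zero = np.zeros((template.height, template.width))
        raw = {}
        for sid, n in n_maps_by_subject.items():
            for i in range(n):
                raw[(sid, f"stim{i}")] = (zero, zero)
        return raw

    def test_threshold_is_strict_less_than_17(self, template):
        raw = self._maps(template, {"a": 16, "b": 17, "c": 21})
        report, retained = qc_filter(raw, min_maps=17)
        rep = report.set_index("subject_id")
        assert rep.loc["a", "excluded"] and rep.loc["a", "reason"] == "insufficient_maps"
        assert not rep.loc["b", "excluded"]
        assert not rep.loc["c", "excluded"]
        assert {sid for sid, _ in retained} == {"b", "c"}

    def test_flag_list_excludes_with_reason(self, template):
        raw = self._maps(template, {"a": 21, "b": 21})
        report, retained = qc_filter(raw, flagged_subjects=("b",))
        rep = report.set_index("subject_id")
        assert rep.loc["b", "reason"] == "flagged_anomalous"
        assert {sid for sid, _ in retained} == {"a"}

    def test_no_exclusions_when_all_complete(self, template):
        raw = self._maps(template, {"a": 21, "b": 21})
        report, retained = qc_filter(raw)
        assert not report["excluded"].any()
        assert (report["reason"] == "none").all()
        assert len(retained) == len(raw)

    def test_rectangle_support_warns_but_keeps(self, template):
        # paint a perfect 4x4 rectangle inside the chest (itself rectangular)
        rows, cols = np.unravel_index(
            template.landmarks["chest"], (template.height, template.width)
        )
        r0, c0 = int(np.median(rows)), int(np.median(cols))
        act = np.zeros((template.height, template.width))
        act[r0 : r0 + 4, c0 : c0 + 4] = 0.5
        act *= template.in_mask
        assert np.count_nonzero(act) == 16
        raw = {("a", f"stim{i}"): (act, np.zeros_like(act)) for i in range(21)}
        with pytest.warns(UserWarning, match="rectangle"):
            report, retained = qc_filter(raw)
        assert not report["excluded"].any()


class TestPPP:
    def test_fraction_of_painted_pixels(self, template):
        act = np.zeros((template.height, template.width))
        idx = np.argwhere(template.in_mask)[:100]
        act[idx[:, 0], idx[:, 1]] = 0.5
        deact = np.zeros_like(act)
        ppp = compute_ppp({("s", "fear"): (act, deact)}, template)
        assert ppp.loc[0, "ppp_activation"] == pytest.approx(100 / template.n_in_mask)
        assert ppp.loc[0, "ppp_deactivation"] == 0.0

    def test_empty_map_gives_zero(self, template):
        zero = np.zeros((template.height, template.width))
        ppp = compute_ppp({("s", "fear"): (zero, zero)}, template)
        assert ppp.loc[0, "ppp_activation"] == 0.0

    def test_matches_bruteforce_count_on_random_maps(self, template, rng):
        act = (rng.random((template.height, template.width)) > 0.7) * rng.random(
            (template.height, template.width)
        )
        deact = (rng.random((template.height, template.width)) > 0.9) * rng.random(
            (template.height, template.width)
        )
        act *= template.in_mask
        deact *= template.in_mask
        ppp = compute_ppp({("s", "x"): (act, deact)}, template)
        brute_act = sum(
            1
            for r in range(template.height)
            for c in range(template.width)
            if template.in_mask[r, c] and act[r, c] > 0
        )
        assert ppp.loc[0, "ppp_activation"] == pytest.approx(
            brute_act / template.n_in_mask
        )

    def test_ppp_unaffected_by_smoothing_parameters(self, template, rng):
        # PPP is defined on raw maps: smoothing sigma never enters
        act = rng.random((template.height, template.width)) * template.in_mask
        deact = np.zeros_like(act)
        before = compute_ppp({("s", "x"): (act, deact)}, template)
        combine_and_smooth(act, deact, 5.0, template)
        after = compute_ppp({("s", "x"): (act, deact)}, template)
        pd.testing.assert_frame_equal(before, after)
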