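"""End-to-end body-map workflow.

Runs the full analysis in order: (optional) cohort simulation, BSM
reconstruction and completion-rate QC, percentile group assignment,
pixelwise one- and two-sample t-maps with FDR thresholding, PPP extent
metrics with the mixed group-by-BSM ANOVA, cosine-similarity matrices and
their group difference, significance-overlap maps and their subtraction,
PCA+LDA cross-validated classification with the accuracy ANOVA, and
questionnaire group comparisons. All artifacts are written to the output
directory together with a JSON + Markdown report; statistics tables are
written with a fixed float format so identical seeds give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from . import scalar_stats
from .classification import (
    ClassificationConfig,
    accuracy_anova,
    assemble_features,
    chance_level,
    cv_lda_accuracy,
)
from .pixel_stats import one_sample_tmap, two_sample_tmap
from .reconstruction import (
    DEFAULT_MIN_MAPS,
    DEFAULT_SIGMA,
    build_subject_bsms,
    compute_ppp,
    qc_filter,
    rasterize_events,
)
from .similarity import (
    matrix_difference,
    overlap_counts,
    overlap_difference,
    similarity_matrix,
)
from .stimuli import StimulusSet, default_stimulus_set
from .synthetic import GeneratorConfig, simulate_cohort
from .template import BodyTemplate, make_body_template

logger = logging.getLogger("bodymaps")

#: Questionnaire columns compared between groups in the cohort table.
QUESTIONNAIRE_MEASURES = [
    "age",
    "audit",
    "task_difficulty",
    "tas_ddf",
    "tas_dif",
    "tas_eot",
    "tas_total",
    "maia",
    "isq",
]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Either ``simulate`` is set (a synthetic cohort is generated) or
    ``events_path``/``cohort_path``/``template_path`` point to existing
    inputs.
    """

    out_dir: str | Path = "bodymaps_out"
    simulate: GeneratorConfig | None = None
    template_height: int = 160
    template_width: int = 64
    events_path: str | Path | None = None
    cohort_path: str | Path | None = None
    template_path: str | Path | None = None
    sigma: float = DEFAULT_SIGMA
    fdr_alpha: float = 0.05
    min_maps: int = DEFAULT_MIN_MAPS
    low_pct: float = 33.0
    high_pct: float = 66.0
    brush_radius: float = 0.0
    flagged_subjects: tuple[str, ...] = ()
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    render: bool = True
    seed: int = 0


def _stage(name: str):
    """Decorator-free stage timer used inside run_pipeline."""

    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: started", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                logger.info("stage %s: done in %.2fs", name, dt)
            else:
                logger.error("stage %s: FAILED after %.2fs (%s)", name, dt, exc)
            return False

    return _Timer()


def _seed_fanout(seed: int) -> dict[str, int]:
    """Derive named sub-seeds from the master seed (all < 2**31)."""
    base = int(seed) % (2**31 - 1)
    return {
        "simulation": base,
        "classify_low": (base * 7919 + 1) % (2**31 - 1),
        "classify_high": (base * 7919 + 2) % (2**31 - 1),
        "permutation": (base * 7919 + 3) % (2**31 - 1),
    }


def run_pipeline(config: RunConfig, stimuli: StimulusSet | None = None) -> dict:
    """Execute the full workflow; returns the report dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stimuli = stimuli or default_stimulus_set()
    seeds = _seed_fanout(config.seed)
    report: dict = {
        "parameters": {
            "sigma": config.sigma,
            "fdr_alpha": config.fdr_alpha,
            "min_maps": config.min_maps,
            "percentiles": [config.low_pct, config.high_pct],
            "brush_radius": config.brush_radius,
            "classification": dataclasses.asdict(config.classification),
            "seed": config.seed,
            "sub_seeds": seeds,
        }
    }

    with _stage("inputs"):
        if config.simulate is not None:
            template = make_body_template(config.template_height, config.template_width)
            sim = dataclasses.replace(config.simulate, seed=seeds["simulation"])
            events, cohort, truth = simulate_cohort(sim, template, stimuli)
            bio.save_template(template, out / "template.png")
            bio.write_events_csv(events, out / "events.csv")
            bio.write_table(cohort, out / "cohort.csv")
            (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
            report["parameters"]["generator"] = {
                k: v
                for k, v in dataclasses.asdict(sim).items()
                if not isinstance(v, dict)
            }
        else:
            if not (config.events_path and config.cohort_path and config.template_path):
                raise ValueError(
                    "either set config.simulate or provide events/cohort/template paths"
                )
            template = bio.load_template(config.template_path)
            events = bio.read_events_csv(config.events_path)
            cohort = pd.read_csv(config.cohort_path)
        report["template"] = {
            "height": template.height,
            "width": template.width,
            "n_in_mask": template.n_in_mask,
            "hash": bio.template_hash(template),
        }

    with _stage("reconstruct_qc"):
        raw_maps = rasterize_events(
            events, template, brush_radius=config.brush_radius,
            known_stimuli=stimuli.labels,
        )
        qc_report, retained = qc_filter(
            raw_maps, min_maps=config.min_maps, flagged_subjects=config.flagged_subjects
        )
        bio.write_table(qc_report, out / "qc_report.csv")
        report["qc"] = {
            "n_subjects": int(len(qc_report)),
            "n_excluded": int(qc_report["excluded"].sum()),
            "excluded_reasons": qc_report[qc_report["excluded"]]["reason"]
            .value_counts()
            .to_dict(),
        }

    with _stage("group_assign"):
        retained_subjects = sorted({sid for sid, _ in retained})
        cohort = cohort.set_index("subject_id", drop=False)
        cohort_r = cohort.loc[retained_subjects].copy()
        labels = scalar_stats.percentile_group_assign(
            cohort_r["audit"].to_numpy(), config.low_pct, config.high_pct
        )
        cohort_r["group_assigned"] = labels
        bio.write_table(cohort_r.reset_index(drop=True), out / "cohort_assigned.csv")
        group_of = dict(zip(cohort_r["subject_id"], cohort_r["group_assigned"]))
        subjects_by_group = {
            g: [s for s in retained_subjects if group_of[s] == g] for g in ("low", "high")
        }
        report["groups"] = {
            "cutpoint_percentiles": [config.low_pct, config.high_pct],
            "n_low": len(subjects_by_group["low"]),
            "n_high": len(subjects_by_group["high"]),
            "n_middle": int((labels == "middle").sum()),
        }
        for g in ("low", "high"):
            if len(subjects_by_group[g]) < 2:
                raise ValueError(f"assigned group '{g}' has fewer than 2 subjects")

    with _stage("smooth"):
        bsms = build_subject_bsms(retained, template, sigma=config.sigma)
        vec_by_key = {(b.subject_id, b.stimulus): b.combined_smoothed for b in bsms}

    with _stage("pixel_stats"):
        tmaps: dict[str, dict[str, object]] = {"low": {}, "high": {}}
        pixel_rows = []
        for g in ("low", "high"):
            gsubs = set(subjects_by_group[g])
            for stim in stimuli.labels:
                stack = np.array(
                    [
                        vec_by_key[(s, stim)]
                        for s in subjects_by_group[g]
                        if (s, stim) in vec_by_key
                    ]
                )
                tm = one_sample_tmap(stack, alpha=config.fdr_alpha)
                tmaps[g][stim] = tm
                pixel_rows.append(
                    {"group": g, "stimulus": stim, "kind": "one_sample",
                     "n_subjects": stack.shape[0], "df": tm.df,
                     "n_significant": tm.n_significant,
                     "n_degenerate": int(tm.degenerate.sum())}
                )
        contrasts = {}
        for stim in stimuli.labels:
            a = np.array([vec_by_key[(s, stim)] for s in subjects_by_group["high"]
                          if (s, stim) in vec_by_key])
            b = np.array([vec_by_key[(s, stim)] for s in subjects_by_group["low"]
                          if (s, stim) in vec_by_key])
            tm = two_sample_tmap(a, b, alpha=config.fdr_alpha)  # high - low
            contrasts[stim] = tm
            pixel_rows.append(
                {"group": "high-low", "stimulus": stim, "kind": "two_sample",
                 "n_subjects": a.shape[0] + b.shape[0], "df": tm.df,
                 "n_significant": tm.n_significant,
                 "n_degenerate": int(tm.degenerate.sum())}
            )
        pixel_summary = pd.DataFrame(pixel_rows)
        bio.write_table(pixel_summary, out / "pixel_summary.csv")
        for g in ("low", "high"):
            tmat = np.column_stack([tmaps[g][s].t for s in stimuli.labels])
            smat = np.column_stack(
                [tmaps[g][s].sig_mask.astype(float) for s in stimuli.labels]
            )
            bio.save_map_bundle(out / f"tmaps_{g}", np.nan_to_num(tmat, posinf=0, neginf=0),
                                list(stimuli.labels), template, sigma=config.sigma,
                                extra_header={"kind": "one_sample_t", "group": g})
            bio.save_map_bundle(out / f"sig_{g}", smat, list(stimuli.labels), template,
                                sigma=config.sigma,
                                extra_header={"kind": "fdr_sig", "group": g})
        cmat = np.column_stack(
            [np.nan_to_num(contrasts[s].t, posinf=0, neginf=0) for s in stimuli.labels]
        )
        bio.save_map_bundle(out / "contrast_t", cmat, list(stimuli.labels), template,
                            sigma=config.sigma,
                            extra_header={"kind": "two_sample_t_high_minus_low"})
        report["pixel_stats"] = {
            "n_significant_total": {
                g: int(sum(tmaps[g][s].n_significant for s in stimuli.labels))
                for g in ("low", "high")
            }
        }
        if config.render:
            for g in ("low", "high"):
                for stim in stimuli.labels:
                    tm = tmaps[g][stim]
                    bio.render_map_png(
                        np.nan_to_num(tm.t, posinf=0, neginf=0), template,
                        out / f"tmap_{g}_{stim}.png", sig_mask=tm.sig_mask,
                        title=f"{stim} ({g})",
                    )

    with _stage("ppp_anova"):
        ppp = compute_ppp(retained, template)
        ppp["group"] = ppp["subject_id"].map(group_of)
        bio.write_table(ppp, out / "ppp.csv")
        ppp_lh = ppp[ppp["group"].isin(["low", "high"])]
        anova_frames = []
        ppp_effects = {}
        for polarity in ("activation", "deactivation"):
            res = scalar_stats.mixed_anova(
                ppp_lh, dv=f"ppp_{polarity}", within="stimulus",
                subject="subject_id", between="group",
            )
            frame = res.to_frame()
            frame.insert(0, "polarity", polarity)
            anova_frames.append(frame)
            ppp_effects[polarity] = res
        bio.write_table(pd.concat(anova_frames, ignore_index=True),
                        out / "ppp_anova.csv")
        report["ppp"] = {
            pol: {
                "group_F": res["group"].F,
                "group_p": res["group"].p,
                "group_direction_high_minus_low": float(
                    ppp_lh[ppp_lh["group"] == "high"][f"ppp_{pol}"].mean()
                    - ppp_lh[ppp_lh["group"] == "low"][f"ppp_{pol}"].mean()
                ),
                "bsm_F": res["stimulus"].F,
                "bsm_p": res["stimulus"].p,
                "gg_epsilon": res.gg_epsilon,
                "sphericity_p": res.sphericity_p,
                "gg_applied": res.gg_applied,
            }
            for pol, res in ppp_effects.items()
        }

    with _stage("similarity"):
        sims = {}
        for g in ("low", "high"):
            sims[g] = similarity_matrix(tmaps[g], labels=stimuli.labels)
            bio.write_table(
                sims[g].to_frame().reset_index(names="stimulus"),
                out / f"similarity_{g}.csv",
            )
        diff = matrix_difference(sims["high"], sims["low"])
        bio.write_table(diff.to_frame().reset_index(names="stimulus"),
                        out / "similarity_diff.csv")
        emo = stimuli.emotion_block
        report["similarity"] = {
            "mean_offdiag_emotions": {
                g: sims[g].mean_offdiagonal(emo) for g in ("low", "high")
            },
            "mean_offdiag_all": {g: sims[g].mean_offdiagonal() for g in ("low", "high")},
        }
        if config.render:
            for g in ("low", "high"):
                bio.render_matrix_png(sims[g].values, list(stimuli.labels),
                                      out / f"similarity_{g}.png",
                                      title=f"cosine similarity ({g})")
            bio.render_matrix_png(diff.values, list(stimuli.labels),
                                  out / "similarity_diff.png",
                                  title="cosine similarity (high - low)")

    with _stage("overlap"):
        overlap_mats = {}
        for g in ("low", "high"):
            masks = {s: tmaps[g][s].sig_mask for s in stimuli.labels}
            for subset in ("all", "emotions", "physiological"):
                om = overlap_counts(masks, stimuli.subset(subset), subset, group=g)
                overlap_mats[(g, subset)] = om
        cols, labels_o = [], []
        for (g, subset), om in overlap_mats.items():
            cols.append(om.counts.astype(float))
            labels_o.append(f"{g}_{subset}")
        for subset in ("all", "emotions", "physiological"):
            d = overlap_difference(overlap_mats[("high", subset)],
                                   overlap_mats[("low", subset)])
            cols.append(d.astype(float))
            labels_o.append(f"diff_{subset}")
        bio.save_map_bundle(out / "overlap", np.column_stack(cols), labels_o,
                            template, extra_header={"kind": "overlap_counts"})
        report["overlap"] = {
            f"{g}_{subset}": {
                "max_count": int(om.counts.max()),
                "mean_count": float(om.counts.mean()),
            }
            for (g, subset), om in overlap_mats.items()
        }
        if config.render:
            for (g, subset), om in overlap_mats.items():
                bio.render_map_png(om.counts.astype(float), template,
                                   out / f"overlap_{g}_{subset}.png",
                                   title=f"overlap {g} {subset}")

    with _stage("classification"):
        runs = {}
        for g, seed_key in (("low", "classify_low"), ("high", "classify_high")):
            sub_maps = {
                (s, stim): vec_by_key[(s, stim)]
                for s in subjects_by_group[g]
                for stim in stimuli.labels
                if (s, stim) in vec_by_key
            }
            X, y, subj = assemble_features(sub_maps, n_folds=config.classification.n_folds)
            cfg = dataclasses.replace(config.classification, seed=seeds[seed_key])
            runs[g] = cv_lda_accuracy(X, y, cfg, group=g, subjects=subj)
        comparison = accuracy_anova(runs["low"], runs["high"],
                                    seed=seeds["permutation"])
        acc_frames = [runs[g].accuracy_frame() for g in ("low", "high")]
        bio.write_table(pd.concat(acc_frames, ignore_index=True), out / "accuracy.csv")
        for g in ("low", "high"):
            conf = pd.DataFrame(runs[g].confusion,
                                index=[str(c) for c in runs[g].classes],
                                columns=[str(c) for c in runs[g].classes])
            bio.write_table(conf.reset_index(names="true_class"),
                            out / f"confusion_{g}.csv")
            if config.render:
                bio.render_matrix_png(runs[g].confusion,
                                      [str(c) for c in runs[g].classes],
                                      out / f"confusion_{g}.png",
                                      title=f"confusion ({g}, %)",
                                      cmap="viridis", center_zero=False)
        eff_frame = comparison.full_model.to_frame()
        eff_frame.insert(0, "model", "mixed_group_by_bsm")
        overall_frame = pd.DataFrame(
            [{"model": "overall_one_way", "effect": "group",
              "df_num": comparison.overall.df_num, "df_den": comparison.overall.df_den,
              "F": comparison.overall.F, "p": comparison.overall.p,
              "eta_sq": comparison.overall.eta_sq, "epsilon": 1.0,
              "sphericity_p": float("nan"), "ss": comparison.overall.ss}]
        )
        bio.write_table(pd.concat([overall_frame, eff_frame], ignore_index=True),
                        out / "classification_effects.csv")
        bio.write_table(comparison.per_bsm, out / "classification_per_bsm.csv")
        report["classification"] = {
            "chance_level_pct": chance_level(len(stimuli.labels)),
            "mean_accuracy_pct": {g: runs[g].mean_accuracy for g in ("low", "high")},
            "sd_accuracy_pct": {
                g: float(runs[g].overall_accuracy.std(ddof=1)) for g in ("low", "high")
            },
            "overall_F": comparison.overall.F,
            "overall_df": [comparison.overall.df_num, comparison.overall.df_den],
            "overall_p": comparison.overall.p,
            "permutation_p": comparison.permutation_p,
            "anticonservative_caveat": (
                "iteration-level ANOVA treats CV iterations as independent "
                "observations; see permutation_p for a conservative check"
            ),
        }

    with _stage("table1"):
        rows = []
        low = cohort_r[cohort_r["group_assigned"] == "low"]
        high = cohort_r[cohort_r["group_assigned"] == "high"]
        for measure in QUESTIONNAIRE_MEASURES:
            if measure not in cohort_r.columns:
                continue
            res = scalar_stats.two_sample_from_raw(
                low[measure].to_numpy(float), high[measure].to_numpy(float), "pooled"
            )
            rows.append(
                {"measure": measure,
                 "mean_low": float(low[measure].mean()),
                 "sd_low": float(low[measure].std(ddof=1)),
                 "mean_high": float(high[measure].mean()),
                 "sd_high": float(high[measure].std(ddof=1)),
                 "statistic": res.t, "df": res.df, "p": res.p,
                 "cohens_d": res.cohens_d, "method": res.method}
            )
        if "gender" in cohort_r.columns:
            tab = pd.crosstab(cohort_r["group_assigned"].isin(["high"]),
                              cohort_r["gender"])
            tab = tab.loc[:, (tab.sum(axis=0) > 0)]
            if tab.shape[1] >= 2:
                res = scalar_stats.chi_square_contingency(tab.to_numpy())
                rows.append(
                    {"measure": "gender", "mean_low": float("nan"),
                     "sd_low": float("nan"), "mean_high": float("nan"),
                     "sd_high": float("nan"), "statistic": res.t, "df": res.df,
                     "p": res.p, "cohens_d": float("nan"), "method": res.method}
                )
        table1 = pd.DataFrame(rows)
        bio.write_table(table1, out / "table1_comparisons.csv")
        report["table1"] = table1.to_dict(orient="records")

    with _stage("report"):
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, default=float)
        )
        md = ["# Body-map pipeline report", ""]
        md.append(f"- template: {report['template']}")
        md.append(f"- QC: {report['qc']}")
        md.append(f"- groups: {report['groups']}")
        md.append(f"- PPP: {report['ppp']}")
        md.append(f"- similarity: {report['similarity']}")
        md.append(f"- classification: {report['classification']}")
        (out / "report.md").write_text("\n".join(md) + "\n")
    return report
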