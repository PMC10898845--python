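"""Discriminability of bodily maps: PCA + LDA complete classification.

Subject-level smoothed maps are the samples, the 21 stimuli the classes.
Per group, accuracy is estimated with iterated stratified five-fold
cross-validation: in every fold the dimensionality is reduced to 30
principal components fitted on the training rows only, a linear
discriminant classifier is fitted on the projected training data, and the
held-out rows are predicted. Chance level for the complete classification
is 100/21 ~ 5%. Group runs are compared with ANOVAs over iteration-level
accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from . import scalar_stats
from .scalar_stats import AnovaEffect, MixedAnovaResult
from .reconstruction import SubjectBSM


@dataclass
class ClassificationConfig:
    """Cross-validation settings for one group's classification run."""

    n_components: int = 30
    n_folds: int = 5
    n_iterations: int = 1000
    seed: int = 0
    pca_scope: str = "fold"  # "fold" = leakage-free (default) | "global"
    group_by_subject: bool = False
    ridge: float = 1e-6  # trace-scaled shrinkage used if covariance is singular

    def validate(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.pca_scope not in ("fold", "global"):
            raise ValueError("pca_scope must be 'fold' or 'global'")


@dataclass
class ClassificationRun:
    """Results of one group's iterated cross-validated classification."""

    group: str
    classes: tuple[str, ...]
    config: ClassificationConfig
    overall_accuracy: np.ndarray  # (n_iterations,) percent
    per_class_accuracy: np.ndarray  # (n_iterations, n_classes) percent
    confusion: np.ndarray  # (n_classes, n_classes) row-normalized percent

    @property
    def chance_level(self) -> float:
        """Chance accuracy in percent for the complete classification."""
        return 100.0 / len(self.classes)

    @property
    def mean_accuracy(self) -> float:
        return float(self.overall_accuracy.mean())

    def accuracy_frame(self) -> pd.DataFrame:
        """Tidy per-iteration per-class accuracies."""
        rows = []
        for it in range(self.overall_accuracy.size):
            rows.append(
                {"iteration": it, "group": self.group, "bsm": "__overall__",
                 "accuracy_pct": self.overall_accuracy[it]}
            )
            for ci, cls in enumerate(self.classes):
                rows.append(
                    {"iteration": it, "group": self.group, "bsm": cls,
                     "accuracy_pct": self.per_class_accuracy[it, ci]}
                )
        return pd.DataFrame(rows)


def chance_level(n_classes: int = 21) -> float:
    """Chance accuracy (percent) of a complete n-way classification."""
    return 100.0 / n_classes


def assemble_features(
    maps: list[SubjectBSM] | dict[tuple[str, str], np.ndarray],
    n_folds: int = 5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack subject maps into a feature matrix with class labels.

    Each retained subject contributes one row per completed stimulus; the
    features are the smoothed in-mask vectors. Missing subject x stimulus
    maps are simply absent.

    Returns ``(X, labels, subjects)``; raises if any class would have
    fewer samples than ``n_folds``, naming the class.
    """
    feats: list[np.ndarray] = []
    labels: list[str] = []
    subjects: list[str] = []
    if isinstance(maps, dict):
        items = [(sid, stim, vec) for (sid, stim), vec in maps.items()]
    else:
        items = [(m.subject_id, m.stimulus, m.combined_smoothed) for m in maps]
    for sid, stim, vec in items:
        feats.append(np.asarray(vec, dtype=float))
        labels.append(stim)
        subjects.append(sid)
    if not feats:
        raise ValueError("no maps to assemble")
    X = np.vstack(feats)
    y = np.asarray(labels)
    subj = np.asarray(subjects)
    classes, counts = np.unique(y, return_counts=True)
    scarce = classes[counts < n_folds]
    if scarce.size:
        raise ValueError(
            f"class '{scarce[0]}' has fewer samples ({counts[counts < n_folds][0]}) "
            f"than the {n_folds} folds"
        )
    return X, y, subj


def _fit_predict_fold(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    config: ClassificationConfig,
    rs: int,
    pca: PCA | None,
) -> np.ndarray:
    if pca is None:
        if config.n_components >= X_train.shape[0]:
            raise ValueError(
                f"n_components ({config.n_components}) must be < n training rows "
                f"({X_train.shape[0]})"
            )
        pca = PCA(
            n_components=config.n_components, svd_solver="randomized", random_state=rs
        ).fit(X_train)
    Z_train = pca.transform(X_train)
    Z_test = pca.transform(X_test)
    # guard against a singular within-class covariance in the reduced space
    means = {c: Z_train[y_train == c].mean(axis=0) for c in np.unique(y_train)}
    centered = Z_train - np.vstack([means[c] for c in y_train])
    rank = np.linalg.matrix_rank(centered)
    if rank < Z_train.shape[1]:
        warnings.warn(
            "singular within-class covariance; applying trace-scaled ridge",
            stacklevel=2,
        )
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=config.ridge)
    else:
        lda = LinearDiscriminantAnalysis(solver="svd")
    lda.fit(Z_train, y_train)
    return lda.predict(Z_test)


def cv_lda_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    config: ClassificationConfig,
    group: str = "",
    subjects: np.ndarray | None = None,
) -> ClassificationRun:
    """Iterated stratified k-fold PCA+LDA classification.

    Every iteration reshuffles a stratified split (derived deterministically
    from the master seed through an iteration counter); within each fold
    PCA and LDA see training rows only, so no information from the test
    fold leaks into the fit (``pca_scope="global"`` deliberately breaks
    that guard for comparison). The iteration accuracy is the percentage
    of correct predictions pooled over all folds; per-class accuracies are
    percentages within each class's test rows. The confusion matrix pools
    all iterations and is row-normalized to percent.
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = tuple(np.unique(y))
    n_classes = len(classes)
    cls_index = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([cls_index[c] for c in y])

    global_pca = None
    if config.pca_scope == "global":
        global_pca = PCA(
            n_components=config.n_components,
            svd_solver="randomized",
            random_state=config.seed,
        ).fit(X)

    overall = np.zeros(config.n_iterations)
    per_class = np.zeros((config.n_iterations, n_classes))
    confusion = np.zeros((n_classes, n_classes))

    if config.group_by_subject and subjects is None:
        raise ValueError("group_by_subject requires the subjects array")

    for it in range(config.n_iterations):
        rs = (config.seed * 100003 + it) % (2**31 - 1)
        if config.group_by_subject:
            skf = StratifiedGroupKFold(
                n_splits=config.n_folds, shuffle=True, random_state=rs
            )
            splits = skf.split(X, y_idx, groups=subjects)
        else:
            skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=rs)
            splits = skf.split(X, y_idx)
        pred_idx = np.empty(y.size, dtype=int)
        for fold, (tr, te) in enumerate(splits):
            pred = _fit_predict_fold(
                X[tr], y[tr], X[te], config, rs=(rs + fold) % (2**31 - 1),
                pca=global_pca,
            )
            pred_idx[te] = [cls_index[c] for c in pred]
        correct = pred_idx == y_idx
        overall[it] = 100.0 * correct.mean()
        for ci in range(n_classes):
            sel = y_idx == ci
            per_class[it, ci] = 100.0 * correct[sel].mean()
            np.add.at(confusion[ci], pred_idx[sel], 1)
    row_sums = confusion.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        confusion = np.where(row_sums > 0, 100.0 * confusion / row_sums, 0.0)
    return ClassificationRun(
        group=group,
        classes=classes,
        config=config,
        overall_accuracy=overall,
        per_class_accuracy=per_class,
        confusion=confusion,
    )


@dataclass
class AccuracyComparison:
    """Group comparison of two classification runs.

    ``overall`` is the one-way ANOVA on iteration-level overall accuracies
    (between df 1, error df 2n-2). ``full_model`` is the mixed group-by-BSM
    ANOVA treating iterations as sampling units — this replicates the
    published df structure but is anticonservative because iterations
    reuse the same subjects; ``permutation_p`` is a conservative
    label-permutation p-value for the overall group difference.
    """

    overall: AnovaEffect
    full_model: MixedAnovaResult
    per_bsm: pd.DataFrame
    permutation_p: float
    degenerate: bool = False


def _one_way_f(a: np.ndarray, b: np.ndarray) -> AnovaEffect:
    n1, n2 = a.size, b.size
    gm = np.concatenate([a, b]).mean()
    ss_b = n1 * (a.mean() - gm) ** 2 + n2 * (b.mean() - gm) ** 2
    ss_w = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df1, df2 = 1, n1 + n2 - 2
    if ss_w == 0:
        F = 0.0 if ss_b == 0 else float("inf")
        p = 1.0 if ss_b == 0 else 0.0
    else:
        F = float((ss_b / df1) / (ss_w / df2))
        from scipy import stats as _st

        p = float(_st.f.sf(F, df1, df2))
    eta = float(ss_b / (ss_b + ss_w)) if (ss_b + ss_w) > 0 else float("nan")
    return AnovaEffect(name="group", df_num=df1, df_den=df2, F=F, p=p, eta_sq=eta,
                       gg_epsilon=1.0, sphericity_p=float("nan"), ss=float(ss_b))


def accuracy_anova(
    run_low: ClassificationRun,
    run_high: ClassificationRun,
    n_permutations: int = 1000,
    seed: int = 0,
) -> AccuracyComparison:
    """Compare two groups' classification accuracies.

    Requires equal iteration counts. With identical runs the between-group
    sum of squares is zero and F is reported as 0 with a degenerate flag.
    """
    if run_low.overall_accuracy.size != run_high.overall_accuracy.size:
        raise ValueError("runs must have equal n_iterations")
    if run_low.classes != run_high.classes:
        raise ValueError("runs must share the same class set")
    a = run_low.overall_accuracy
    b = run_high.overall_accuracy
    overall = _one_way_f(a, b)
    degenerate = np.array_equal(a, b)

    n_it = a.size
    frames = []
    for run, gname in ((run_low, "low"), (run_high, "high")):
        df = pd.DataFrame(
            run.per_class_accuracy, columns=[str(c) for c in run.classes]
        )
        df["iteration"] = [f"{gname}_{i}" for i in range(n_it)]
        df["group"] = gname
        frames.append(df.melt(id_vars=["iteration", "group"], var_name="bsm",
                              value_name="accuracy_pct"))
    long = pd.concat(frames, ignore_index=True)
    full_model = scalar_stats.mixed_anova(
        long, dv="accuracy_pct", within="bsm", subject="iteration", between="group"
    )

    per_rows = []
    for ci, cls in enumerate(run_low.classes):
        eff = _one_way_f(run_low.per_class_accuracy[:, ci],
                         run_high.per_class_accuracy[:, ci])
        per_rows.append(
            {"bsm": cls, "F": eff.F, "df_num": eff.df_num, "df_den": eff.df_den,
             "p": eff.p,
             "mean_low": float(run_low.per_class_accuracy[:, ci].mean()),
             "mean_high": float(run_high.per_class_accuracy[:, ci].mean())}
        )
    per_bsm = pd.DataFrame(per_rows)

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if abs(perm[:n_it].mean() - perm[n_it:].mean()) >= observed:
            count += 1
    perm_p = (count + 1) / (n_permutations + 1)

    return AccuracyComparison(
        overall=overall,
        full_model=full_model,
        per_bsm=per_bsm,
        permutation_p=float(perm_p),
        degenerate=bool(degenerate),
    )
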