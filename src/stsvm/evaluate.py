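"""Repeated stratified cross-validation harness, AUC and the stability index.

The harness mirrors the evaluation protocol the method is designed for:
10 times repeated 10-fold stratified cross-validation in which *every*
data-dependent step — standardization, t-statistics, permutation selection,
span-rule tuning, SVM training — sees only the training folds.  The kernel
itself depends only on the network, never on expression values or labels,
so it is computed once and shared across folds.

Signature stability is summarized by the stability index: the mean, over
features selected at least once, of their selection frequency normalized by
the maximum possible count (repeats x folds).  SI = 1 means every feature
ever selected was selected in every fold.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import classify, smoothing
from .kernel import SmoothKernel, pstep_rwk
from .netio import ExpressionDataset, Network


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney form; ties count 1/2)."""
    labels = np.asarray(labels)
    if len(set(np.unique(labels))) < 2:
        raise ValueError("AUC needs both classes in the test labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def stability_index(counts: dict[str, int], max_count: int) -> float:
    """Mean normalized selection frequency over ever-selected features.

    SI = (1/|S|) sum_{g in S} c_g / max_count with S = {g : c_g >= 1};
    lies in (0, 1], and equals 1 iff every ever-selected feature was
    selected in all max_count folds.
    """
    selected = {g: c for g, c in counts.items() if c >= 1}
    if not selected:
        raise ValueError("no feature was ever selected")
    if max_count < max(selected.values()):
        raise ValueError("max_count smaller than an observed selection count")
    return float(np.mean([c / max_count for c in selected.values()]))


@dataclass
class CVConfig:
    """Parameters of the cross-validated pipeline."""

    folds: int = 10
    repeats: int = 10
    a: float = 2.0
    p: int = 2
    n_perm: int = 1000
    top_frac: float = 0.10
    fdr: float = 0.05
    c_grid: tuple[float, ...] = classify.DEFAULT_C_GRID
    fixed_C: float | None = None
    row_normalize: bool = False
    fallback_k: int = 10
    keep_fold_details: bool = False


@dataclass
class FoldDetail:
    """Training-side artifacts of one fold (for audits and inspection)."""

    repeat: int
    fold: int
    signature: tuple[str, ...]
    C: float
    means: np.ndarray
    sds: np.ndarray
    dual_coef: np.ndarray
    intercept: float


@dataclass
class CVReport:
    """Result of a repeated stratified cross-validation run."""

    aucs: np.ndarray                      # (repeats, folds)
    selection_counts: dict[str, int]
    signature_sizes: list[int]
    seed: int
    config: CVConfig
    fold_details: list[FoldDetail] = field(default_factory=list)

    @property
    def stability(self) -> float:
        return stability_index(
            self.selection_counts, self.config.repeats * self.config.folds
        )

    @property
    def median_auc(self) -> float:
        return float(np.median(self.aucs))

    def auc_frame(self) -> pd.DataFrame:
        rows = [
            {"repeat": r, "fold": f, "auc": self.aucs[r, f]}
            for r in range(self.aucs.shape[0])
            for f in range(self.aucs.shape[1])
        ]
        return pd.DataFrame(rows)

    def counts_frame(self) -> pd.DataFrame:
        items = sorted(self.selection_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(items, columns=["feature", "count"])

    def summary_frame(self) -> pd.DataFrame:
        q1, q3 = np.percentile(self.aucs, [25, 75])
        return pd.DataFrame(
            [
                {
                    "median_auc": self.median_auc,
                    "auc_iqr": q3 - q1,
                    "stability_index": self.stability,
                    "mean_signature_size": float(np.mean(self.signature_sizes)),
                    "folds": self.config.folds,
                    "repeats": self.config.repeats,
                    "seed": self.seed,
                }
            ]
        )

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.auc_frame().to_csv(os.path.join(outdir, "auc.tsv"), sep="\t", index=False)
        self.counts_frame().to_csv(
            os.path.join(outdir, "selection_counts.tsv"), sep="\t", index=False
        )
        self.summary_frame().to_csv(
            os.path.join(outdir, "summary.tsv"), sep="\t", index=False
        )


def fit_fold(
    train: ExpressionDataset,
    K: SmoothKernel,
    config: CVConfig,
    perm_seed: int,
) -> tuple[classify.TrainedModel, smoothing.SelectionResult]:
    """Train-side pipeline of one fold: selection, standardization, tuning,
    SVM fit.  Sees training samples only."""
    sel = smoothing.run_selection(
        train,
        K,
        n_perm=config.n_perm,
        top_frac=config.top_frac,
        fdr=config.fdr,
        seed=perm_seed,
        row_normalize=config.row_normalize,
        fallback_k=config.fallback_k,
    )
    signature = sorted(sel.signature)
    sub = train.subset_features(signature)
    train_std, _, means, sds = classify.standardize_fit_apply(sub.values)
    X = train_std.T  # sample x feature
    y = train.labels
    if config.fixed_C is not None:
        c = float(config.fixed_C)
    else:
        c = classify.span_select_C(X, y, config.c_grid)
    model = classify.train_svm(X, y, c, signature=signature, means=means, sds=sds)
    return model, sel


def apply_fold(model: classify.TrainedModel, test: ExpressionDataset) -> np.ndarray:
    """Score the test fold with a fold's trained model (training scaling)."""
    sub = test.subset_features(model.signature)
    safe = np.where(model.sds > 0, model.sds, 1.0)
    x = np.where(
        (model.sds > 0)[:, None],
        (sub.values - model.means[:, None]) / safe[:, None],
        0.0,
    )
    return classify.ranking_function(model, x.T)


def _svm_channel(
    train: ExpressionDataset,
    test: ExpressionDataset,
    grid: tuple[float, ...],
) -> tuple[np.ndarray, np.ndarray]:
    """Plain SVM ranking scores for one data channel (standardize on train,
    span-rule C, linear SVM); returns (train scores, test scores)."""
    tr, te, _, _ = classify.standardize_fit_apply(train.values, test.values)
    c = classify.span_select_C(tr.T, train.labels, grid)
    model = classify.train_svm(tr.T, train.labels, c)
    return (
        classify.ranking_function(model, tr.T),
        classify.ranking_function(model, te.T),
    )


def stacked_meta_cv(
    gene_data: ExpressionDataset,
    gene_net: Network,
    mirna_data: ExpressionDataset,
    config: CVConfig | None = None,
    seed: int = 0,
    inner_folds: int = 3,
) -> dict[str, float]:
    """Cross-validated meta-classifier combining a gene and a miRNA channel.

    Per outer fold, the gene channel is the full smoothed-selection SVM
    pipeline and the miRNA channel a plain SVM on all miRNA features.  The
    logistic combiner is fit on *out-of-fold* ranking scores from an inner
    cross-validation of the training fold — fitting it on in-sample scores
    would let an overfit channel (e.g. pure-noise miRNAs) look informative
    and drag down test performance.

    Returns pooled test AUCs: {"auc_meta": ..., "auc_gene": ...}.
    """
    config = config or CVConfig()
    kernel_g = pstep_rwk(gene_net, a=config.a, p=config.p)
    gene_data = gene_data.subset_features(list(kernel_g.nodes))
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(
        n_splits=config.folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    y = gene_data.labels
    gene_scores, meta_scores, y_pool = [], [], []
    for tr_idx, te_idx in skf.split(np.zeros(len(y)), y):
        gtr, gte = gene_data.subset_samples(tr_idx), gene_data.subset_samples(te_idx)
        mtr, mte = mirna_data.subset_samples(tr_idx), mirna_data.subset_samples(te_idx)
        gmodel, _ = fit_fold(gtr, kernel_g, config, int(rng.integers(2**31 - 1)))
        f1_te = apply_fold(gmodel, gte)
        _, f2_te = _svm_channel(mtr, mte, config.c_grid)
        inner = StratifiedKFold(
            n_splits=inner_folds,
            shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        oof1 = np.zeros(gtr.n_samples)
        oof2 = np.zeros(gtr.n_samples)
        for itr, ite in inner.split(np.zeros(gtr.n_samples), gtr.labels):
            g_in, g_out = gtr.subset_samples(itr), gtr.subset_samples(ite)
            m_in, m_out = mtr.subset_samples(itr), mtr.subset_samples(ite)
            gm, _ = fit_fold(g_in, kernel_g, config, int(rng.integers(2**31 - 1)))
            oof1[ite] = apply_fold(gm, g_out)
            _, oof2[ite] = _svm_channel(m_in, m_out, config.c_grid)
        meta = classify.fit_meta(oof1, oof2, gtr.labels)
        meta_scores.append(classify.predict_meta(meta, f1_te, f2_te))
        gene_scores.append(f1_te)
        y_pool.append(gte.labels)
    y_all = np.concatenate(y_pool)
    return {
        "auc_meta": auc(np.concatenate(meta_scores), y_all),
        "auc_gene": auc(np.concatenate(gene_scores), y_all),
    }


def repeated_cv(
    data: ExpressionDataset,
    net: Network,
    config: CVConfig | None = None,
    seed: int = 0,
    kernel: SmoothKernel | None = None,
) -> CVReport:
    """Repeated stratified k-fold cross-validation of the whole pipeline.

    Fold assignments are derived from the labels and the seed only, and a
    fresh stratified split is drawn for each repeat.  Per-fold AUCs,
    selection counts and signature sizes are accumulated into a
    :class:`CVReport`.  Identical inputs and seed give identical output.
    """
    config = config or CVConfig()
    y = data.labels
    n_pos = int((y == 1).sum())
    n_neg = int((y == -1).sum())
    if min(n_pos, n_neg) < config.folds:
        raise ValueError(
            f"smallest class has {min(n_pos, n_neg)} samples, fewer than "
            f"{config.folds} folds; use fewer folds"
        )
    if kernel is None:
        kernel = pstep_rwk(net, a=config.a, p=config.p)
    if list(data.features) != list(kernel.nodes):
        data = data.subset_features(list(kernel.nodes))
    rng = np.random.default_rng(seed)
    aucs = np.zeros((config.repeats, config.folds))
    counts: dict[str, int] = {}
    sizes: list[int] = []
    details: list[FoldDetail] = []
    for r in range(config.repeats):
        split_seed = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(
            n_splits=config.folds, shuffle=True, random_state=split_seed
        )
        for f, (tr_idx, te_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
            perm_seed = int(rng.integers(0, 2**31 - 1))
            train = data.subset_samples(tr_idx)
            test = data.subset_samples(te_idx)
            model, sel = fit_fold(train, kernel, config, perm_seed)
            scores = apply_fold(model, test)
            aucs[r, f] = auc(scores, test.labels)
            sizes.append(len(sel.signature))
            for g in sel.signature:
                counts[g] = counts.get(g, 0) + 1
            if config.keep_fold_details:
                details.append(
                    FoldDetail(
                        repeat=r,
                        fold=f,
                        signature=tuple(sorted(sel.signature)),
                        C=model.C,
                        means=model.means.copy(),
                        sds=model.sds.copy(),
                        dual_coef=model.dual_coef.copy(),
                        intercept=model.intercept,
                    )
                )
    return CVReport(
        aucs=aucs,
        selection_counts=counts,
        signature_sizes=sizes,
        seed=seed,
        config=config,
        fold_details=details,
    )
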