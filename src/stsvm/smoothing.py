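"""Network-smoothed t-statistics and permutation-based feature selection.

Each feature's absolute two-sample t-statistic is smoothed over the network
by a p-step random walk kernel (s = K |t|), so a feature's score aggregates
the differential-expression evidence of its topological neighborhood.  The
smoothed score no longer follows a t-distribution, so significance is
assessed by a label-permutation test (restricted, for runtime, to the top
fraction of features by smoothed score), followed by Benjamini-Hochberg FDR
control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .kernel import SmoothKernel
from .netio import ExpressionDataset

logger = logging.getLogger(__name__)


def abs_tstats(data: ExpressionDataset) -> np.ndarray:
    """Absolute pooled-variance two-sample t-statistic per feature.

    Features with zero pooled variance (constant across all samples) score
    0 rather than NaN.  Requires at least two samples in each class.
    """
    y = data.labels
    return _abs_tstats_matrix(data.values, (y == 1))


def _abs_tstats_matrix(values: np.ndarray, pos_mask: np.ndarray) -> np.ndarray:
    n1 = int(pos_mask.sum())
    n2 = int((~pos_mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"need at least 2 samples per class, got {n1} positive / {n2} negative"
        )
    x1 = values[:, pos_mask]
    x2 = values[:, ~pos_mask]
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x2 - m2[:, None]) ** 2).sum(axis=1)
    pooled = (ss1 + ss2) / (n1 + n2 - 2)
    denom = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / np.where(denom > 0, denom, 1.0), 0.0)
    return np.abs(t)


def _perm_abs_tstats(values: np.ndarray, pos_masks: np.ndarray) -> np.ndarray:
    """|t| for many label permutations at once.

    ``pos_masks`` is (n_perm, n_samples) boolean; returns
    (n_features, n_perm).  Uses the identity sum((x-m)^2) = sum(x^2) - n m^2
    per class so the whole batch reduces to two matrix products.
    """
    x = values
    x2 = values**2
    counts = pos_masks.sum(axis=1).astype(float)  # n1 per permutation
    n = values.shape[1]
    n2 = n - counts
    s1 = x @ pos_masks.T          # class sums, (n_features, n_perm)
    q1 = x2 @ pos_masks.T
    s_tot = x.sum(axis=1)[:, None]
    q_tot = x2.sum(axis=1)[:, None]
    m1 = s1 / counts
    m2 = (s_tot - s1) / n2
    ss1 = q1 - counts * m1**2
    ss2 = (q_tot - q1) - n2 * m2**2
    pooled = (ss1 + ss2) / (n - 2)
    pooled = np.maximum(pooled, 0.0)  # guard float cancellation
    denom = np.sqrt(pooled * (1.0 / counts + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / np.where(denom > 0, denom, 1.0), 0.0)
    return np.abs(t)


def smooth_scores(
    K: SmoothKernel, t: np.ndarray, row_normalize: bool = False
) -> np.ndarray:
    """Smoothed score vector s = K t (t aligned to K's node order, t >= 0).

    With ``row_normalize`` each kernel row is scaled to sum 1, turning the
    score into a weighted neighborhood average instead of an aggregate; the
    default (off) deliberately boosts hub nodes.
    """
    t = np.asarray(t, dtype=float)
    if t.shape != (K.n_nodes,):
        raise ValueError(f"t has shape {t.shape}, kernel has {K.n_nodes} nodes")
    if (t < 0).any():
        raise ValueError("t must be non-negative (absolute t-statistics)")
    m = _kernel_operator(K, row_normalize)
    s = m @ t
    if (s < -1e-10).any():
        raise AssertionError("kernel produced negative smoothed scores")
    return np.maximum(s, 0.0)


def _kernel_operator(K: SmoothKernel, row_normalize: bool) -> np.ndarray:
    if not row_normalize:
        return K.matrix
    rows = K.matrix.sum(axis=1, keepdims=True)
    return K.matrix / np.where(rows > 0, rows, 1.0)


def top_fraction(
    scores: np.ndarray, nodes: tuple[str, ...] | list[str], fraction: float
) -> list[str]:
    """The ceil(fraction*n) nodes with the largest scores.

    Ties at the cutoff are broken by node identifier (lexicographic) so the
    tested set is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(nodes)
    if len(scores) != n:
        raise ValueError("scores and nodes must be aligned")
    k = math.ceil(fraction * n)
    order = sorted(range(n), key=lambda i: (-scores[i], nodes[i]))
    return [nodes[i] for i in order[:k]]


def permutation_test(
    data: ExpressionDataset,
    K: SmoothKernel,
    tested: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    row_normalize: bool = False,
) -> dict[str, float]:
    """Permutation p-values for the smoothed scores of the tested nodes.

    For each of ``n_perm`` random label permutations, |t| and the smoothed
    scores are recomputed over all nodes; the p-value of node g is the
    add-one estimator (1 + #{b : s_g^(b) >= s_g^obs}) / (1 + n_perm), so
    p >= 1/(n_perm+1) and ties count against the observed score.
    Deterministic given the seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not tested:
        raise ValueError("tested node set is empty")
    if list(data.features) != list(K.nodes):
        raise ValueError("dataset features must be aligned to kernel nodes")
    rng = np.random.default_rng(seed)
    y_pos = data.labels == 1
    obs = smooth_scores(K, _abs_tstats_matrix(data.values, y_pos), row_normalize)
    masks = np.empty((n_perm, data.n_samples), dtype=bool)
    for b in range(n_perm):
        masks[b] = rng.permutation(y_pos)
    t_perm = _perm_abs_tstats(data.values, masks)        # (n_feat, n_perm)
    s_perm = _kernel_operator(K, row_normalize) @ t_perm  # (n_feat, n_perm)
    idx = {n: i for i, n in enumerate(K.nodes)}
    pvals: dict[str, float] = {}
    for g in tested:
        i = idx[g]
        exceed = int((s_perm[i] >= obs[i]).sum())
        pvals[g] = (1.0 + exceed) / (1.0 + n_perm)
    return pvals


def bh_fdr(pvalues: dict[str, float]) -> dict[str, float]:
    """Benjamini-Hochberg step-up adjusted values, monotone and capped at 1."""
    if not pvalues:
        return {}
    items = sorted(pvalues.items())
    p = np.array([v for _, v in items])
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    return {g: float(qv) for (g, _), qv in zip(items, q)}


def select_signature(qvalues: dict[str, float], alpha: float = 0.05) -> set[str]:
    """Features with FDR-adjusted value strictly below alpha; may be empty."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return {g for g, q in qvalues.items() if q < alpha}


@dataclass
class SelectionResult:
    """Outcome of the smoothed-score permutation selection.

    ``scores`` cover every node; p- and q-values only the tested subset
    (top fraction by smoothed score); ``signature`` the nodes passing the
    FDR cut (or the top-k fallback when none do, flagged by
    ``used_fallback``).
    """

    nodes: tuple[str, ...]
    scores: np.ndarray
    tested: list[str]
    pvalues: dict[str, float]
    qvalues: dict[str, float]
    signature: set[str]
    n_permutations: int
    seed: int
    used_fallback: bool = False

    def to_table(self) -> "pd.DataFrame":
        import pandas as pd

        rows = []
        for i, g in enumerate(self.nodes):
            rows.append(
                {
                    "feature": g,
                    "score": self.scores[i],
                    "p": self.pvalues.get(g, float("nan")),
                    "q": self.qvalues.get(g, float("nan")),
                    "selected": int(g in self.signature),
                }
            )
        df = pd.DataFrame(rows)
        return df.sort_values(
            ["selected", "score", "feature"], ascending=[False, False, True]
        ).reset_index(drop=True)

    def write(self, path: str) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


def run_selection(
    data: ExpressionDataset,
    K: SmoothKernel,
    n_perm: int = 1000,
    top_frac: float = 0.10,
    fdr: float = 0.05,
    seed: int = 0,
    row_normalize: bool = False,
    fallback_k: int = 10,
) -> SelectionResult:
    """Full selection pipeline: |t| -> smoothing -> restricted permutation
    test -> BH FDR -> signature.

    If no feature passes the FDR cut the top ``fallback_k`` nodes by
    smoothed score are selected instead (with a logged warning) so a
    downstream classifier is always trainable.
    """
    t = abs_tstats(data)
    if list(data.features) != list(K.nodes):
        raise ValueError("dataset features must be aligned to kernel nodes")
    s = smooth_scores(K, t, row_normalize)
    tested = top_fraction(s, K.nodes, top_frac)
    pvals = permutation_test(
        data, K, tested, n_perm=n_perm, seed=seed, row_normalize=row_normalize
    )
    qvals = bh_fdr(pvals)
    signature = select_signature(qvals, fdr)
    used_fallback = False
    if not signature:
        k = min(fallback_k, len(tested))
        signature = set(top_fraction(s, K.nodes, max(k / len(K.nodes), 1e-12))[:k])
        used_fallback = True
        logger.warning(
            "no feature passed FDR < %.3g; falling back to top %d by smoothed score",
            fdr,
            k,
        )
    return SelectionResult(
        nodes=K.nodes,
        scores=s,
        tested=tested,
        pvalues=pvals,
        qvalues=qvals,
        signature=signature,
        n_permutations=n_perm,
        seed=seed,
        used_fallback=used_fallback,
    )
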