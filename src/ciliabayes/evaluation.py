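"""Classifier evaluation: ROC/AUC, rank tests, cross-validation, enrichment.

The headline ROC population is the training genes only (positives versus
negatives), since unlabeled genes carry no truth. AUC is computed with
ties credited 0.5 per tied positive-negative pair, which makes it exactly
the Mann-Whitney U statistic divided by n_pos * n_neg.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .bayes import LikelihoodTable, ScoreTable, estimate_likelihoods, score_genes
from .containers import GeneEvidenceTable, RunConfig, TrainingSets

__all__ = [
    "RocResult",
    "CvResult",
    "EnrichmentResult",
    "roc_auc",
    "mann_whitney",
    "kfold_cv",
    "fisher_enrichment",
    "ciliome_size",
]


@dataclass
class RocResult:
    """ROC points from (0,0) to (1,1) plus trapezoidal AUC."""

    points: list[tuple[float, float]]  # (FPR, TPR)
    auc: float

    def plot(self, ax=None, **kwargs):
        """Draw the ROC curve; returns the matplotlib Axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fpr, tpr = zip(*self.points)
        ax.plot(fpr, tpr, **kwargs)
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.set_title(f"AUC = {self.auc:.3f}")
        return ax


def roc_auc(scores: dict | pd.Series, labels: dict | pd.Series) -> RocResult:
    """ROC curve and AUC for per-gene scores against pos/neg labels.

    ``labels`` maps genes to "pos"/"neg" (or booleans); only genes present
    in ``labels`` enter the curve. Ties in score produce diagonal ROC
    segments, so the trapezoidal area credits 0.5 per tied pair.
    """
    scores = pd.Series(scores)
    labels = pd.Series(labels)
    genes = labels.index.intersection(scores.index)
    if len(genes) != len(labels):
        missing = set(labels.index) - set(genes)
        raise KeyError(f"labeled genes without scores: {sorted(missing)[:5]}")
    y = labels.loc[genes]
    is_pos = (y == "pos") | (y == True)  # noqa: E712 - allow boolean labels
    s = scores.loc[genes].to_numpy(dtype=float)
    pos = is_pos.to_numpy()
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    order = np.argsort(-s, kind="mergesort")
    s_sorted, pos_sorted = s[order], pos[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(s_sorted)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(pos_sorted[i:j].sum())
        fp += (j - i) - int(pos_sorted[i:j].sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(points=points, auc=auc)


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # 1-based midrank
        i = j
    return ranks


def mann_whitney(
    sample_a, sample_b, exact_limit: int = 8, max_enumeration: int = 200_000
) -> tuple[float, float]:
    """Mann-Whitney U of ``sample_a`` over ``sample_b`` with two-sided p.

    Small samples (min size <= ``exact_limit`` and a feasible number of
    label assignments) get an exact permutation p-value computed by
    enumerating which pooled observations belong to the smaller sample —
    this handles ties, unlike textbook exact tables. Larger samples use
    the tie-corrected normal approximation with continuity correction.

    Returns
    -------
    (U, p) : U statistic of ``sample_a`` (number of (a, b) pairs with
        a > b, ties counting 0.5) and the two-sided p-value.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u_a = float(ranks[:n].sum() - n * (n + 1) / 2.0)

    if min(n, m) <= exact_limit and comb(n + m, min(n, m)) <= max_enumeration:
        # enumerate assignments of the smaller sample's positions
        k = min(n, m)
        mu = n * m / 2.0
        obs_dev = abs(u_a - mu)
        hits = total = 0
        for combo in itertools.combinations(range(n + m), k):
            rsum = ranks[list(combo)].sum()
            u_small = rsum - k * (k + 1) / 2.0
            # U of sample a for this assignment
            u = u_small if k == n else n * m - u_small
            total += 1
            if abs(u - mu) >= obs_dev - 1e-12:
                hits += 1
        return u_a, hits / total

    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return u_a, float(res.pvalue)


@dataclass
class CvResult:
    """Stratified k-fold cross-validation of the classifier.

    Every training gene is scored exactly once by a model whose
    likelihoods were estimated without that gene's fold; ``pooled_roc``
    is the ROC over those held-out scores.
    """

    fold_assignments: dict[str, int]
    heldout_scores: pd.Series
    pooled_roc: RocResult
    seed: int


def kfold_cv(
    evidence: GeneEvidenceTable,
    training: TrainingSets,
    config: RunConfig,
) -> CvResult:
    """Stratified k-fold cross-validation of the naive-Bayes classifier.

    Folds stratify by training class using ``config.rng_seed``. Per fold,
    likelihoods are re-estimated on the remaining folds (bait exclusions
    re-applied) and the held-out training genes are scored by that model.
    """
    k = config.cv_folds
    train_genes = sorted(training.positives | training.negatives)
    train_genes = [g for g in train_genes if g in set(evidence.genes)]
    y = np.array(
        ["pos" if g in training.positives else "neg" for g in train_genes]
    )
    n_pos, n_neg = int((y == "pos").sum()), int((y == "neg").sum())
    if min(n_pos, n_neg) < k:
        raise ValueError(
            f"training class smaller than fold count ({n_pos} pos, "
            f"{n_neg} neg, {k} folds)"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.rng_seed)
    fold_of: dict[str, int] = {}
    held: dict[str, float] = {}
    genes_arr = np.array(train_genes)
    for fold, (_, test_idx) in enumerate(skf.split(genes_arr, y)):
        heldout = set(genes_arr[test_idx])
        for g in heldout:
            fold_of[g] = fold
        fold_training = TrainingSets(
            positives=training.positives - heldout,
            negatives=training.negatives - heldout,
            bait_exclusions=training.bait_exclusions,
        )
        lik = estimate_likelihoods(evidence, fold_training, config)
        table = score_genes(evidence, lik, config, training=fold_training)
        sub = table.records.loc[table.records.index.intersection(list(heldout))]
        for g, sc in sub["score"].items():
            held[g] = float(sc)
    heldout_scores = pd.Series(held).loc[train_genes]
    labels = pd.Series(y, index=train_genes)
    roc = roc_auc(heldout_scores, labels)
    return CvResult(
        fold_assignments=fold_of,
        heldout_scores=heldout_scores,
        pooled_roc=roc,
        seed=config.rng_seed,
    )


@dataclass
class EnrichmentResult:
    """Two-sided Fisher exact test of dataset membership vs positive set."""

    dataset_id: str
    tested: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    odds_ratio: float


def fisher_enrichment(
    dataset_flag: set,
    positives: set,
    background: set,
    dataset_id: str = "",
    tested: str = "in_dataset",
) -> EnrichmentResult:
    """Fisher exact enrichment of the positive set within a dataset's hits.

    Builds the 2x2 table (positive / not) x (in dataset / not) over the
    background universe and returns the two-sided exact p.
    """
    if not background:
        raise ValueError("empty background")
    bg = set(background)
    flag = set(dataset_flag) & bg
    pos = set(positives) & bg
    a = len(pos & flag)
    b = len(pos - flag)
    c = len(flag - pos)
    d = len(bg) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(
        dataset_id=dataset_id,
        tested=tested,
        table=((a, b), (c, d)),
        p_value=float(p),
        odds_ratio=float(odds),
    )


def ciliome_size(
    table: ScoreTable,
    validation=None,
    q: float | None = None,
) -> tuple[float, float | None]:
    """Estimate the total number of organelle genes in the genome.

    raw
        Sum of posterior probabilities over all genes — the expected
        number of organelle genes if the posteriors are calibrated.
    adjusted (only with a validation outcome)
        Anchors the posterior mass outside the training set to the
        experimentally observed positive predictive value: the posterior
        mass of the selected novel candidates is rescaled by
        ``PPV_observed / mean posterior of selected novel``, and that
        calibration factor is applied to the whole non-training posterior
        mass, on top of the count of known (training) positives.
    """
    post = table.records["posterior"]
    raw = float(post.sum())
    if validation is None:
        return raw, None
    from .bayes import select_candidates
    from .validation import ppv as _ppv

    q = q if q is not None else table.config.fdr_threshold
    k, n, observed_ppv = _ppv(validation)
    novel = select_candidates(table, q=q, novel_only=True)
    flags = table.records["training_flag"]
    non_training_mass = float(post[flags == "-"].sum())
    sel_mass = float(post.loc[novel].sum())
    n_train_pos = int((flags == "P").sum())
    if sel_mass == 0:
        return raw, None
    calibration = observed_ppv * len(novel) / sel_mass
    adjusted = n_train_pos + calibration * non_training_mass
    return raw, float(adjusted)
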