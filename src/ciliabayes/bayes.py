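"""Naive-Bayes integration of categorical evidence into per-gene log-odds.

For every dataset ``d`` and category ``c`` the class-conditional fractions

    P(c | organelle gene)      and      P(c | non-organelle gene)

are estimated from the positive / negative training sets (with the
dataset's assay baits removed from the positive set, and an optional
pseudocount), and the per-category log2 likelihood ratio is

    llr(d, c) = log2  P(c | positive) / P(c | negative).

Assuming the datasets are independent given the class, a gene's integrated
log-odds score is the prior log-odds plus the sum of its categories' llrs:

    score(g) = log2( prior / (1 - prior) ) + sum_d llr(d, c_g(d)).

A score of 1 means 2:1 odds in favour of organelle membership. The
posterior probability is 2^score / (1 + 2^score); ranking genes by score
and averaging (1 - posterior) down the list yields a cumulative
(posterior-based) false discovery rate used for candidate selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GeneEvidenceTable, RunConfig, TrainingSets

__all__ = [
    "CategoryLikelihood",
    "LikelihoodTable",
    "ScoreTable",
    "estimate_likelihoods",
    "score_genes",
    "fdr_curve",
    "select_candidates",
]


@dataclass(frozen=True)
class CategoryLikelihood:
    """Class-conditional fractions and log2 likelihood ratio for one category."""

    dataset_id: str
    category: str
    n_pos: int
    n_neg: int
    frac_pos: float
    frac_neg: float
    llr: float


@dataclass
class LikelihoodTable:
    """Per-(dataset, category) likelihood estimates plus training summary.

    ``training_summary`` records the effective (bait-excluded) positive and
    negative set sizes used per dataset.
    """

    entries: list[CategoryLikelihood]
    training_summary: dict[str, tuple[int, int]] = field(default_factory=dict)

    def llr(self, dataset_id: str, category: str) -> float:
        key = (dataset_id, category)
        try:
            return self._index[key]
        except AttributeError:
            object.__setattr__(
                self,
                "_index",
                {(e.dataset_id, e.category): e.llr for e in self.entries},
            )
            return self._index[key]
        except KeyError:
            raise KeyError(
                f"no likelihood entry for dataset {dataset_id!r}, "
                f"category {category!r}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "dataset": e.dataset_id,
                    "category": e.category,
                    "n_pos": e.n_pos,
                    "n_neg": e.n_neg,
                    "frac_pos": e.frac_pos,
                    "frac_neg": e.frac_neg,
                    "llr": e.llr,
                }
                for e in self.entries
            ]
        )

    def to_dict(self) -> dict:
        """JSON-serialisable audit record (the per-category log-odds table)."""
        return {
            "entries": self.to_frame().to_dict(orient="records"),
            "training_summary": {
                d: {"n_pos": p, "n_neg": n}
                for d, (p, n) in self.training_summary.items()
            },
        }


@dataclass
class ScoreTable:
    """Ranked per-gene scores, posteriors and cumulative FDR.

    ``records`` is a DataFrame indexed by gene with columns
    ``score``, ``posterior``, ``rank``, ``fdr``, ``training_flag`` sorted by
    rank (descending score, ties broken by ascending gene ID).
    """

    records: pd.DataFrame
    config: RunConfig

    def __len__(self) -> int:
        return len(self.records)


def _category_counts(
    column: pd.Series, categories: tuple[str, ...], members: frozenset[str]
) -> np.ndarray:
    sub = column.loc[column.index.intersection(list(members))]
    vc = sub.value_counts()
    return np.array([int(vc.get(c, 0)) for c in categories])


def estimate_likelihoods(
    evidence: GeneEvidenceTable,
    training: TrainingSets,
    config: RunConfig,
) -> LikelihoodTable:
    """Estimate per-(dataset, category) class-conditional fractions and llrs.

    For each dataset the positive set is first stripped of that dataset's
    bait genes; then with pseudocount ``s = config.smoothing`` and ``k``
    categories,

        frac = (count + s) / (N + s * k)

    separately per class, and ``llr = log2(frac_pos / frac_neg)``.

    Raises
    ------
    ValueError
        If a dataset's effective positive or negative training set is
        empty, or if ``smoothing == 0`` and a category is empty in one
        class (infinite llr).
    """
    entries: list[CategoryLikelihood] = []
    summary: dict[str, tuple[int, int]] = {}
    s = config.smoothing
    for schema in evidence.schemas:
        d = schema.dataset_id
        pos, neg = training.effective(d)
        pos = pos & set(evidence.genes)
        neg = neg & set(evidence.genes)
        if not pos or not neg:
            raise ValueError(
                f"dataset {d!r}: empty effective "
                f"{'positive' if not pos else 'negative'} training set"
            )
        col = evidence.cells[d]
        counts_pos = _category_counts(col, schema.categories, frozenset(pos))
        counts_neg = _category_counts(col, schema.categories, frozenset(neg))
        k = len(schema.categories)
        n_pos, n_neg = counts_pos.sum(), counts_neg.sum()
        frac_pos = (counts_pos + s) / (n_pos + s * k)
        frac_neg = (counts_neg + s) / (n_neg + s * k)
        if np.any(frac_pos <= 0) or np.any(frac_neg <= 0):
            bad = [
                schema.categories[i]
                for i in range(k)
                if frac_pos[i] <= 0 or frac_neg[i] <= 0
            ]
            raise ValueError(
                f"dataset {d!r}: categories {bad} empty in one training "
                f"class with smoothing=0; llr would be infinite "
                f"(raise smoothing or merge categories)"
            )
        llr = np.log2(frac_pos / frac_neg)
        summary[d] = (int(n_pos), int(n_neg))
        for i, c in enumerate(schema.categories):
            entries.append(
                CategoryLikelihood(
                    dataset_id=d,
                    category=c,
                    n_pos=int(counts_pos[i]),
                    n_neg=int(counts_neg[i]),
                    frac_pos=float(frac_pos[i]),
                    frac_neg=float(frac_neg[i]),
                    llr=float(llr[i]),
                )
            )
    return LikelihoodTable(entries=entries, training_summary=summary)


def _posterior_from_score(score: np.ndarray) -> np.ndarray:
    # 2^s/(1+2^s) computed stably as a logistic in natural log space
    return 1.0 / (1.0 + np.exp2(-score))


def score_genes(
    evidence: GeneEvidenceTable,
    lik: LikelihoodTable,
    config: RunConfig,
    training: TrainingSets | None = None,
) -> ScoreTable:
    """Integrate per-dataset llrs into ranked per-gene log-odds scores.

    Training genes are scored and flagged ('P'/'N'), never dropped. Rows
    are ordered by descending score with ties broken by ascending gene ID;
    ``rank`` is 1-based over that order and ``fdr`` is the running mean of
    (1 - posterior).
    """
    prior_logodds = float(np.log2(config.prior / (1.0 - config.prior)))
    total = np.full(len(evidence), prior_logodds)
    for schema in evidence.schemas:
        d = schema.dataset_id
        lut = {c: lik.llr(d, c) for c in schema.categories}
        col = evidence.cells[d]
        missing = set(col.unique()) - set(lut)
        if missing:
            raise KeyError(
                f"dataset {d!r}: no likelihood entry for categories "
                f"{sorted(missing)}"
            )
        total = total + col.map(lut).to_numpy(dtype=float)

    df = pd.DataFrame(index=evidence.cells.index.copy())
    df["score"] = total
    df["posterior"] = _posterior_from_score(total)
    if training is not None:
        df["training_flag"] = [training.flag(g) for g in df.index]
    else:
        df["training_flag"] = "-"
    # deterministic tie-break: descending score, then ascending gene ID
    df = (
        df.assign(_gene=df.index.astype(str))
        .sort_values(["score", "_gene"], ascending=[False, True], kind="mergesort")
        .drop(columns="_gene")
    )
    df["rank"] = np.arange(1, len(df) + 1)
    df["fdr"] = np.cumsum(1.0 - df["posterior"].to_numpy()) / df["rank"].to_numpy()
    return ScoreTable(records=df, config=config)


def fdr_curve(
    table: ScoreTable, exclude_training: bool = False
) -> pd.DataFrame:
    """Cumulative posterior FDR along the ranked gene list.

    ``FDR(k) = mean(1 - posterior)`` over ranks 1..k of the included
    population: all genes, or only unflagged genes when
    ``exclude_training`` is set (ranks are then recomputed over that
    sub-population).
    """
    df = table.records
    if exclude_training:
        df = df[df["training_flag"] == "-"]
    if len(df) == 0:
        raise ValueError("empty population for FDR curve")
    post = df["posterior"].to_numpy()
    k = np.arange(1, len(df) + 1)
    out = pd.DataFrame(
        {
            "rank": k,
            "gene": df.index.to_numpy(),
            "score": df["score"].to_numpy(),
            "fdr": np.cumsum(1.0 - post) / k,
        }
    )
    return out


def select_candidates(
    table: ScoreTable, q: float, novel_only: bool = False
) -> list[str]:
    """Genes above the largest rank whose cumulative FDR is <= ``q``.

    The threshold rank K is always computed over **all** genes; with
    ``novel_only`` the training-flagged genes are removed from the returned
    list afterwards (not from the threshold computation).
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0,1), got {q}")
    df = table.records
    fdr = df["fdr"].to_numpy()
    # boundary-inclusive up to accumulated rounding noise
    below = np.nonzero(fdr <= q + 1e-12)[0]
    if len(below) == 0:
        return []
    K = below.max() + 1
    sel = df.iloc[:K]
    if novel_only:
        sel = sel[sel["training_flag"] == "-"]
    return list(sel.index)
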