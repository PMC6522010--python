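"""Core data containers for categorical evidence integration.

Evidence about organelle (cilium) membership arrives as one categorical
label per gene per dataset — "found"/"not found" interaction calls,
confidence tiers from published proteomics, co-evolution bins, and so on.
These containers hold that evidence together with the training gene sets
and the run configuration that the naive-Bayes integration consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DatasetSchema",
    "GeneEvidenceTable",
    "TrainingSets",
    "RunConfig",
]


@dataclass(frozen=True)
class DatasetSchema:
    """Category space of a single evidence dataset.

    Parameters
    ----------
    dataset_id : str
        Short dataset name, used as the evidence-table column header.
    categories : tuple of str
        Ordered category labels (at least two). Order is meaningful only
        for presentation (e.g. increasing propensity to report organelle
        genes); the classifier treats categories as unordered.
    default_category : str
        Label assigned to genes absent from the dataset (typically
        "not_found").
    merge_map : mapping of str to str, optional
        Collapses raw input labels into ``categories`` (e.g. mapping
        fine-grained co-evolution scores into two bins).
    """

    dataset_id: str
    categories: tuple[str, ...]
    default_category: str
    merge_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", tuple(self.categories))
        object.__setattr__(self, "merge_map", dict(self.merge_map))
        if len(self.categories) < 2:
            raise ValueError(
                f"dataset {self.dataset_id!r}: need >= 2 categories, "
                f"got {self.categories!r}"
            )
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(
                f"dataset {self.dataset_id!r}: duplicate category labels"
            )
        if self.default_category not in self.categories:
            raise ValueError(
                f"dataset {self.dataset_id!r}: default category "
                f"{self.default_category!r} not among categories"
            )
        for raw, target in self.merge_map.items():
            if target not in self.categories:
                raise ValueError(
                    f"dataset {self.dataset_id!r}: merge target {target!r} "
                    f"for raw label {raw!r} not among categories"
                )

    def resolve(self, label: str | None, gene: str = "?") -> str:
        """Map a raw label onto the category space.

        Empty/missing labels become the default category; labels present in
        ``merge_map`` are collapsed; anything else must already be a
        category.
        """
        if label is None or label == "" or (isinstance(label, float) and pd.isna(label)):
            return self.default_category
        label = str(label)
        if label in self.merge_map:
            return self.merge_map[label]
        if label in self.categories:
            return label
        raise ValueError(
            f"gene {gene!r}, dataset {self.dataset_id!r}: "
            f"label {label!r} is not a known category or merge-map key"
        )


class GeneEvidenceTable:
    """Genes x datasets matrix of categorical evidence labels.

    Wraps a :class:`pandas.DataFrame` (index = gene IDs, one column per
    dataset, values = category labels) plus the per-dataset schemas.
    Every cell is guaranteed to hold a label from its dataset's category
    space; genes missing from a dataset carry that dataset's default
    category.
    """

    def __init__(self, cells: pd.DataFrame, schemas: Iterable[DatasetSchema]):
        schemas = list(schemas)
        by_id = {s.dataset_id: s for s in schemas}
        if len(by_id) != len(schemas):
            raise ValueError("duplicate dataset_id among schemas")
        if cells.index.has_duplicates:
            dups = cells.index[cells.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        unknown = [c for c in cells.columns if c not in by_id]
        if unknown:
            raise ValueError(f"datasets without schema: {unknown}")
        # Fill datasets absent from the table entirely with defaults.
        data = cells.copy()
        for s in schemas:
            if s.dataset_id not in data.columns:
                data[s.dataset_id] = s.default_category
        data = data[[s.dataset_id for s in schemas]]
        for s in schemas:
            col = data[s.dataset_id]
            data[s.dataset_id] = [
                s.resolve(v, gene=g) for g, v in zip(data.index, col)
            ]
        self.cells: pd.DataFrame = data
        self.schemas: list[DatasetSchema] = schemas
        self.schema_by_id: dict[str, DatasetSchema] = by_id

    @property
    def genes(self) -> list[str]:
        return list(self.cells.index)

    @property
    def dataset_ids(self) -> list[str]:
        return [s.dataset_id for s in self.schemas]

    def __len__(self) -> int:
        return len(self.cells)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<GeneEvidenceTable: {len(self)} genes x "
            f"{len(self.schemas)} datasets>"
        )


@dataclass
class TrainingSets:
    """Positive / negative training gene sets with optional bait exclusions.

    Overlap between positives and negatives is resolved by removing the
    overlapping genes from the negative set. ``bait_exclusions`` maps a
    dataset id to the genes (assay baits) that must be removed from the
    positive set when estimating that dataset's likelihoods, so that an
    interaction screen is not credited for re-finding its own baits.
    """

    positives: frozenset[str]
    negatives: frozenset[str]
    bait_exclusions: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positives = frozenset(self.positives)
        self.negatives = frozenset(self.negatives) - self.positives
        self.bait_exclusions = {
            k: frozenset(v) for k, v in self.bait_exclusions.items()
        }

    def effective(self, dataset_id: str) -> tuple[frozenset[str], frozenset[str]]:
        """Training sets with the dataset's baits removed from the positives."""
        baits = self.bait_exclusions.get(dataset_id, frozenset())
        return self.positives - baits, self.negatives - baits

    def flag(self, gene: str) -> str:
        """'P', 'N' or '-' for a gene."""
        if gene in self.positives:
            return "P"
        if gene in self.negatives:
            return "N"
        return "-"


@dataclass
class RunConfig:
    """Configuration of a scoring run.

    Parameters
    ----------
    prior : float
        Prior probability that a random gene belongs to the organelle.
        Default 0.05 (roughly 1100 ciliary genes in a 22k-gene genome).
    smoothing : float
        Pseudocount added per (category, class) when estimating
        class-conditional category fractions; keeps log-likelihood ratios
        finite for categories empty in one class.
    fdr_threshold : float
        Cumulative posterior FDR used for candidate selection.
    cv_folds : int
        Number of stratified cross-validation folds.
    rng_seed : int
        Seed for every stochastic step (fold assignment, simulation).
    ddp_threshold : int
        Differential-Dollo-parsimony cut: profiles with DDP <= threshold
        against the organelle profile fall in the co-evolving bin.
    """

    prior: float = 0.05
    smoothing: float = 0.5
    fdr_threshold: float = 0.25
    cv_folds: int = 10
    rng_seed: int = 0
    ddp_threshold: int = 9
    log_base: int = 2  # fixed; a score of 1 means 2:1 odds

    def __post_init__(self) -> None:
        if not 0.0 < self.prior < 1.0:
            raise ValueError(f"prior must be in (0,1), got {self.prior}")
        if self.smoothing < 0:
            raise ValueError("smoothing must be >= 0")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must be in (0,1)")
        if self.log_base != 2:
            raise ValueError("log base is fixed at 2")
        if self.ddp_threshold < 0:
            raise ValueError("ddp_threshold must be >= 0")
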