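"""Model/Results interface over the naive-Bayes evidence integration.

`OrganelleMembershipModel` is constructed from an evidence table, training
gene sets and a run configuration; `fit()` estimates the per-category
likelihood ratios and scores every gene, returning an
`OrganelleMembershipResults` that carries the estimates, rankings,
diagnostics and a text summary, with candidate selection, evaluation,
cross-validation and plotting hanging off it.

Example
-------
>>> from ciliabayes import synthetic
>>> from ciliabayes.model import OrganelleMembershipModel
>>> bundle = synthetic.generate(synthetic.default_paperlike_config(seed=1))
>>> res = OrganelleMembershipModel.from_bundle(bundle).fit()
>>> candidates = res.select_candidates(q=0.25, novel_only=True)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bayes, evaluation
from .containers import GeneEvidenceTable, RunConfig, TrainingSets

__all__ = ["OrganelleMembershipModel", "OrganelleMembershipResults"]


class OrganelleMembershipModel:
    """Naive-Bayes classifier of organelle membership from categorical evidence.

    Parameters
    ----------
    evidence : GeneEvidenceTable
        Genes x datasets categorical evidence.
    training : TrainingSets
        Positive/negative gene sets with optional per-dataset bait
        exclusions.
    config : RunConfig, optional
        Prior, smoothing, FDR threshold, CV folds, seed.
    """

    def __init__(
        self,
        evidence: GeneEvidenceTable,
        training: TrainingSets,
        config: RunConfig | None = None,
    ):
        self.evidence = evidence
        self.training = training
        self.config = config or RunConfig()

    @classmethod
    def from_files(
        cls,
        evidence_path,
        positives_path,
        negatives_path,
        config_path,
        bait_paths: dict | None = None,
    ) -> "OrganelleMembershipModel":
        """Build a model from an evidence TSV, gene lists and a YAML config."""
        from . import io

        config, schemas = io.load_config(config_path)
        evidence = io.read_evidence_table(evidence_path, schemas)
        training = io.read_training_sets(positives_path, negatives_path, bait_paths)
        return cls(evidence, training, config)

    @classmethod
    def from_bundle(cls, bundle, config: RunConfig | None = None):
        """Build a model from a synthetic bundle (uses the bundle's seed)."""
        if config is None:
            config = RunConfig(
                prior=bundle.config.prior_true,
                rng_seed=bundle.config.seed,
                ddp_threshold=bundle.config.ddp_threshold,
            )
        return cls(bundle.evidence, bundle.training, config)

    def fit(self) -> "OrganelleMembershipResults":
        """Estimate likelihood ratios and score every gene."""
        lik = bayes.estimate_likelihoods(self.evidence, self.training, self.config)
        table = bayes.score_genes(self.evidence, lik, self.config, self.training)
        return OrganelleMembershipResults(self, lik, table)


class OrganelleMembershipResults:
    """Fitted per-category likelihood ratios and ranked gene scores."""

    def __init__(self, model, likelihoods, score_table):
        self.model = model
        self.likelihoods: bayes.LikelihoodTable = likelihoods
        self.score_table: bayes.ScoreTable = score_table

    # -- accessors -----------------------------------------------------
    @property
    def scores(self) -> pd.Series:
        return self.score_table.records["score"]

    @property
    def posteriors(self) -> pd.Series:
        return self.score_table.records["posterior"]

    # -- selection and curves ------------------------------------------
    def fdr_curve(self, exclude_training: bool = False) -> pd.DataFrame:
        return bayes.fdr_curve(self.score_table, exclude_training=exclude_training)

    def select_candidates(
        self, q: float | None = None, novel_only: bool = False
    ) -> list[str]:
        q = q if q is not None else self.model.config.fdr_threshold
        return bayes.select_candidates(self.score_table, q=q, novel_only=novel_only)

    # -- evaluation ----------------------------------------------------
    def training_labels(self) -> pd.Series:
        t = self.model.training
        genes = [
            g
            for g in self.score_table.records.index
            if g in t.positives or g in t.negatives
        ]
        return pd.Series(
            ["pos" if g in t.positives else "neg" for g in genes], index=genes
        )

    def roc(self) -> evaluation.RocResult:
        """ROC over training genes (positives vs negatives)."""
        labels = self.training_labels()
        return evaluation.roc_auc(self.scores, labels)

    def mann_whitney(self) -> tuple[float, float]:
        """Separation of positive vs negative training scores."""
        labels = self.training_labels()
        pos = self.scores.loc[labels.index[labels == "pos"]]
        neg = self.scores.loc[labels.index[labels == "neg"]]
        return evaluation.mann_whitney(pos.to_numpy(), neg.to_numpy())

    def cross_validate(self) -> evaluation.CvResult:
        return evaluation.kfold_cv(
            self.model.evidence, self.model.training, self.model.config
        )

    def dataset_enrichment(
        self, found_categories: dict | None = None
    ) -> list[evaluation.EnrichmentResult]:
        """Fisher enrichment of the positive set per dataset.

        ``found_categories`` maps dataset ids to the set of category
        labels counting as "in the dataset"; by default every category
        except the dataset's default counts.
        """
        ev = self.model.evidence
        background = set(ev.genes)
        out = []
        for schema in ev.schemas:
            d = schema.dataset_id
            if found_categories and d in found_categories:
                found = set(found_categories[d])
            else:
                found = set(schema.categories) - {schema.default_category}
            flag = set(ev.cells.index[ev.cells[d].isin(found)])
            out.append(
                evaluation.fisher_enrichment(
                    flag,
                    set(self.model.training.positives),
                    background,
                    dataset_id=d,
                    tested="|".join(sorted(found)),
                )
            )
        return out

    def ciliome_size(self, validation=None, q: float | None = None):
        return evaluation.ciliome_size(self.score_table, validation=validation, q=q)

    # -- presentation --------------------------------------------------
    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary."""
        cfg = self.model.config
        lik = self.likelihoods.to_frame()
        roc = self.roc()
        u, p = self.mann_whitney()
        sel = self.select_candidates()
        sel_novel = self.select_candidates(novel_only=True)
        lines = []
        lines.append("Organelle membership model (naive-Bayes evidence integration)")
        lines.append("=" * 64)
        lines.append(
            f"genes: {len(self.score_table):6d}    datasets: "
            f"{len(self.model.evidence.schemas)}"
        )
        lines.append(
            f"prior: {cfg.prior:.3f}  smoothing: {cfg.smoothing}  "
            f"log base: {cfg.log_base}"
        )
        npos = len(self.model.training.positives)
        nneg = len(self.model.training.negatives)
        lines.append(f"training: {npos} positives / {nneg} negatives")
        lines.append("")
        lines.append("Per-category log2 likelihood ratios")
        lines.append("-" * 64)
        for _, r in lik.iterrows():
            lines.append(
                f"  {r['dataset']:<18s} {r['category']:<12s} "
                f"llr {r['llr']:+7.3f}   (P {r['frac_pos']:.4f} | "
                f"N {r['frac_neg']:.4f})"
            )
        lines.append("")
        lines.append("Diagnostics")
        lines.append("-" * 64)
        lines.append(f"  training ROC AUC:          {roc.auc:.4f}")
        lines.append(f"  Mann-Whitney U, p:         {u:.1f}, {p:.3g}")
        lines.append(
            f"  candidates at FDR<={cfg.fdr_threshold:.2f}:   "
            f"{len(sel)} total, {len(sel_novel)} novel"
        )
        raw, _ = self.ciliome_size()
        lines.append(f"  expected organelle genes:  {raw:.1f} (posterior sum)")
        lines.append("")
        lines.append(f"Top {top} genes")
        lines.append("-" * 64)
        head = self.score_table.records.head(top)
        for g, r in head.iterrows():
            lines.append(
                f"  {int(r['rank']):4d}  {g:<12s} score {r['score']:+8.3f}  "
                f"posterior {r['posterior']:.3f}  fdr {r['fdr']:.3f}  "
                f"[{r['training_flag']}]"
            )
        return "\n".join(lines)

    def plot_score_distributions(self, ax=None, bins: int = 60):
        """Score histograms for positives, negatives and unlabeled genes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.score_table.records
        groups = {"P": "positive set", "N": "negative set", "-": "other genes"}
        rng = (float(df["score"].min()), float(df["score"].max()))
        for flag, label in groups.items():
            vals = df.loc[df["training_flag"] == flag, "score"]
            if len(vals):
                ax.hist(
                    vals, bins=bins, range=rng, density=True, histtype="step",
                    label=label,
                )
        ax.set_xlabel("integrated log2-odds score")
        ax.set_ylabel("density")
        ax.legend()
        return ax
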