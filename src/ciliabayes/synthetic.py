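"""Synthetic benchmark generator for the evidence-integration pipeline.

Generates complete input bundles — a categorical gene-by-dataset evidence
table, positive/negative training sets with bait exclusions, binary
phylogenetic profiles on a species tree, and the ground-truth class of
every gene — with the statistical structure the classifier assumes:
genes are organelle members with a fixed prior probability, and each
dataset's category is drawn independently given the class (optionally
with a copula-style coupling between two datasets to mimic redundant
assays). The co-evolution evidence column is not sampled directly: gene
profiles are noisy copies of the organelle's presence/absence profile
(class-specific flip rates) and the column is derived through the Dollo
module, exactly as in the real pipeline.

The default configuration emulates the published study's conditions: a
22,000-gene genome, a 5% prior, eight evidence datasets whose genome-wide
and gold-standard coverages echo the published per-dataset coverage
table, training sets of 302 positives and 1275 negatives, and a 52-species
tree on which the organelle was lost eight times independently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import DatasetSchema, GeneEvidenceTable, TrainingSets
from .dollo import SpeciesTree, ddp_against_reference

__all__ = [
    "DatasetSpec",
    "SyntheticConfig",
    "SyntheticBundle",
    "generate",
    "default_paperlike_config",
    "build_default_tree",
]


@dataclass(frozen=True)
class DatasetSpec:
    """Class-conditional category distribution of one synthetic dataset.

    ``p_pos`` / ``p_neg`` map category labels to P(category | class); each
    must sum to 1 over ``categories``. ``couple_to`` names another dataset
    whose latent uniform is re-used with probability ``couple_share``
    (a comonotone copula: marginals are preserved, categories become
    positively dependent given the class — mimicking two assays with
    overlapping baits). ``n_baits`` training positives are designated as
    assay baits: they are forced into ``bait_category`` and excluded from
    the positive set when this dataset's likelihoods are estimated.
    """

    dataset_id: str
    categories: tuple[str, ...]
    p_pos: dict
    p_neg: dict
    default_category: str | None = None
    couple_to: str | None = None
    couple_share: float = 0.0
    n_baits: int = 0
    bait_category: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", tuple(self.categories))
        for name, dist in (("p_pos", self.p_pos), ("p_neg", self.p_neg)):
            if set(dist) != set(self.categories):
                raise ValueError(
                    f"dataset {self.dataset_id!r}: {name} keys must match categories"
                )
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"dataset {self.dataset_id!r}: {name} sums to {total}, not 1"
                )
        if not 0.0 <= self.couple_share <= 1.0:
            raise ValueError("couple_share must be in [0,1]")

    def schema(self) -> DatasetSchema:
        default = self.default_category or self.categories[-1]
        return DatasetSchema(
            dataset_id=self.dataset_id,
            categories=self.categories,
            default_category=default,
        )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic bundle."""

    n_genes: int = 22_000
    prior_true: float = 0.05
    dataset_specs: tuple[DatasetSpec, ...] = ()
    n_train_pos: int = 302
    n_train_neg: int = 1275
    tree_newick: str | None = None
    reference_profile: dict | None = None
    profile_flip_pos: float = 0.0
    profile_flip_neg: float = 0.0
    ddp_threshold: int = 9
    ddp_dataset_id: str | None = None  # evidence column derived from profiles
    shared_detectability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prior_true <= 1.0:
            raise ValueError("prior_true must be in [0,1]")
        if not 0.0 <= self.shared_detectability <= 1.0:
            raise ValueError("shared_detectability must be in [0,1]")
        for f in (self.profile_flip_pos, self.profile_flip_neg):
            if not 0.0 <= f <= 0.5:
                raise ValueError("profile flip rates must be in [0, 0.5]")
        ids = [s.dataset_id for s in self.dataset_specs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate dataset_id in dataset_specs")
        for s in self.dataset_specs:
            if s.couple_to is not None and s.couple_to not in ids:
                raise ValueError(
                    f"dataset {s.dataset_id!r} coupled to unknown "
                    f"dataset {s.couple_to!r}"
                )


@dataclass
class SyntheticBundle:
    """A generated benchmark: evidence, training sets, profiles and truth."""

    evidence: GeneEvidenceTable
    training: TrainingSets
    truth: pd.Series  # gene -> "pos"/"neg"
    profiles: pd.DataFrame | None  # genes x species, 0/1
    reference_profile: dict | None
    tree: SpeciesTree | None
    config: SyntheticConfig

    @property
    def n_planted(self) -> int:
        return int((self.truth == "pos").sum())


def _stream(seed: int, k: int) -> np.random.Generator:
    # one bundle-wide stream family, split per purpose by fixed sub-seeds
    return np.random.default_rng([seed, k])


def _sample_categorical(
    u: np.ndarray, is_pos: np.ndarray, spec: DatasetSpec
) -> np.ndarray:
    cats = np.array(spec.categories, dtype=object)
    cum_pos = np.cumsum([spec.p_pos[c] for c in spec.categories])
    cum_neg = np.cumsum([spec.p_neg[c] for c in spec.categories])
    idx_pos = np.searchsorted(cum_pos, u, side="right")
    idx_neg = np.searchsorted(cum_neg, u, side="right")
    idx = np.where(is_pos, idx_pos, idx_neg)
    return cats[np.clip(idx, 0, len(cats) - 1)]


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Draw a complete synthetic bundle; deterministic given ``config.seed``.

    Class labels are Bernoulli(``prior_true``); each categorical dataset's
    column is sampled independently given the class via inverse-CDF on a
    per-column uniform stream (coupled datasets share their partner's
    uniforms with probability ``couple_share``); training sets are uniform
    subsets of each class; phylo-profiles flip the reference profile's
    bits at class-specific rates, and the co-evolution column is the
    thresholded DDP of each profile against the reference.
    """
    seed = config.seed
    n = config.n_genes
    genes = [f"G{i:05d}" for i in range(n)]

    is_pos = _stream(seed, 0).random(n) < config.prior_true
    truth = pd.Series(np.where(is_pos, "pos", "neg"), index=genes)

    # per-column latent uniforms (coupling re-uses the partner's draws)
    uniforms: dict[str, np.ndarray] = {}
    spec_index = {s.dataset_id: i for i, s in enumerate(config.dataset_specs)}
    shared_u = _stream(seed, 50).random(n)  # gene-level detectability latent
    for s in config.dataset_specs:
        i = spec_index[s.dataset_id]
        u = _stream(seed, 100 + i).random(n)
        if config.shared_detectability > 0:
            mask = _stream(seed, 300 + i).random(n) < config.shared_detectability
            u = np.where(mask, shared_u, u)
        uniforms[s.dataset_id] = u
    for s in config.dataset_specs:
        if s.couple_to is not None and s.couple_share > 0:
            mask = (
                _stream(seed, 500 + spec_index[s.dataset_id]).random(n)
                < s.couple_share
            )
            uniforms[s.dataset_id] = np.where(
                mask, uniforms[s.couple_to], uniforms[s.dataset_id]
            )

    cells = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for s in config.dataset_specs:
        cells[s.dataset_id] = _sample_categorical(uniforms[s.dataset_id], is_pos, s)

    # training sets: uniform subsets of each class
    rng_train = _stream(seed, 900)
    pos_idx = np.flatnonzero(is_pos)
    neg_idx = np.flatnonzero(~is_pos)
    if config.n_train_pos > len(pos_idx) or config.n_train_neg > len(neg_idx):
        raise ValueError(
            f"infeasible training sizes: want {config.n_train_pos} of "
            f"{len(pos_idx)} positives, {config.n_train_neg} of "
            f"{len(neg_idx)} negatives"
        )
    train_pos = frozenset(
        genes[i] for i in rng_train.choice(pos_idx, config.n_train_pos, replace=False)
    )
    train_neg = frozenset(
        genes[i] for i in rng_train.choice(neg_idx, config.n_train_neg, replace=False)
    )

    # designate assay baits among the training positives
    rng_bait = _stream(seed, 901)
    bait_exclusions: dict[str, frozenset] = {}
    train_pos_list = sorted(train_pos)
    for s in config.dataset_specs:
        if s.n_baits > 0:
            if s.n_baits > len(train_pos_list):
                raise ValueError(
                    f"dataset {s.dataset_id!r}: more baits than training positives"
                )
            baits = rng_bait.choice(train_pos_list, s.n_baits, replace=False)
            bait_exclusions[s.dataset_id] = frozenset(baits)
            forced = s.bait_category or s.categories[0]
            cells.loc[list(baits), s.dataset_id] = forced

    # phylo-profiles and the derived co-evolution column
    profiles = reference = tree = None
    if config.tree_newick is not None:
        tree = SpeciesTree.from_newick(config.tree_newick)
        reference = dict(config.reference_profile or {})
        if set(reference) != set(tree.leaves):
            raise ValueError("reference profile must cover all tree leaves")
        ref_vec = np.array([reference[l] for l in tree.leaves], dtype=np.int64)
        rng_prof = _stream(seed, 902)
        flip_rate = np.where(is_pos, config.profile_flip_pos, config.profile_flip_neg)
        flips = rng_prof.random((n, len(tree.leaves))) < flip_rate[:, None]
        mat = np.bitwise_xor(ref_vec[None, :], flips.astype(np.int64))
        profiles = pd.DataFrame(mat, index=genes, columns=tree.leaves)
        if config.ddp_dataset_id is not None:
            ddp_vals = ddp_against_reference(tree, profiles, reference)
            t = config.ddp_threshold
            low, high = f"DDP<={t}", f"DDP>{t}"
            cells[config.ddp_dataset_id] = np.where(ddp_vals <= t, low, high)

    schemas = [s.schema() for s in config.dataset_specs]
    if config.ddp_dataset_id is not None and config.tree_newick is not None:
        t = config.ddp_threshold
        schemas.append(
            DatasetSchema(
                dataset_id=config.ddp_dataset_id,
                categories=(f"DDP<={t}", f"DDP>{t}"),
                default_category=f"DDP>{t}",
            )
        )

    evidence = GeneEvidenceTable(cells, schemas)
    training = TrainingSets(
        positives=train_pos, negatives=train_neg, bait_exclusions=bait_exclusions
    )
    return SyntheticBundle(
        evidence=evidence,
        training=training,
        truth=truth,
        profiles=profiles,
        reference_profile=reference,
        tree=tree,
        config=config,
    )


def build_default_tree(
    n_species: int = 52, n_losses: int = 8, seed: int = 715
) -> tuple[str, dict]:
    """Deterministic species tree plus organelle presence/absence profile.

    Random binary coalescent over ``n_species`` named species, then
    ``n_losses`` disjoint clades (2-6 species each) are marked as having
    lost the organelle — echoing the repeated independent loss of the
    cilium across eukaryotes. Returns (newick, reference_profile).
    """
    rng = np.random.default_rng(seed)
    names = [f"sp{i:02d}" for i in range(1, n_species + 1)]
    nodes = [(name, frozenset([name])) for name in names]
    clades: list[frozenset] = []
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        (nwk_i, set_i), (nwk_j, set_j) = nodes[i], nodes[j]
        merged = (f"({nwk_i},{nwk_j})", set_i | set_j)
        clades.append(set_i | set_j)
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(merged)
    newick = nodes[0][0] + ";"
    root = nodes[0][1]
    candidates = [c for c in clades if 2 <= len(c) <= 6 and c != root]
    order = rng.permutation(len(candidates))
    lost: set[str] = set()
    chosen = 0
    for k in order:
        c = candidates[k]
        if chosen >= n_losses:
            break
        if c & lost:
            continue
        # the loss must stay a maximal trait-free subtree: skip clades whose
        # parent would become entirely trait-free (losses would merge)
        parent = min((p for p in clades + [root] if c < p), key=len)
        if not (parent - c - lost):
            continue
        lost |= c
        chosen += 1
    if chosen < n_losses:
        raise ValueError(
            f"could only place {chosen} of {n_losses} independent losses"
        )
    reference = {name: 0 if name in lost else 1 for name in names}
    return newick, reference


def _binary_spec(
    dataset_id: str,
    cov_pos: float,
    cov_genome: float,
    prior: float,
    found: str = "found",
    not_found: str = "not_found",
    **kwargs,
) -> DatasetSpec:
    """Binary found/not dataset hitting the target coverages at ``prior``."""
    cov_neg = (cov_genome - prior * cov_pos) / (1.0 - prior)
    if not 0.0 < cov_neg < 1.0:
        raise ValueError(f"{dataset_id}: inconsistent coverage targets")
    return DatasetSpec(
        dataset_id=dataset_id,
        categories=(found, not_found),
        p_pos={found: cov_pos, not_found: 1 - cov_pos},
        p_neg={found: cov_neg, not_found: 1 - cov_neg},
        default_category=not_found,
        **kwargs,
    )


def _tiered_spec(
    dataset_id: str,
    cov_pos: float,
    cov_genome: float,
    prior: float,
    pos_split=(0.5, 0.3, 0.2),
    neg_split=(0.2, 0.3, 0.5),
) -> DatasetSpec:
    """Confidence-tiered dataset (high/medium/low/not_found).

    The found mass is split across tiers with the positives weighted
    toward the high-confidence tier and the negatives toward the
    low-confidence tier, so the per-tier likelihood ratios decrease with
    confidence as in tiered published datasets.
    """
    cov_neg = (cov_genome - prior * cov_pos) / (1.0 - prior)
    cats = ("high", "medium", "low", "not_found")
    p_pos = {c: cov_pos * w for c, w in zip(cats, pos_split)}
    p_neg = {c: cov_neg * w for c, w in zip(cats, neg_split)}
    p_pos["not_found"] = 1 - cov_pos
    p_neg["not_found"] = 1 - cov_neg
    return DatasetSpec(
        dataset_id=dataset_id,
        categories=cats,
        p_pos=p_pos,
        p_neg=p_neg,
        default_category="not_found",
    )


# Per-class flip rates for the phylo-profiles, chosen once so that the
# derived DDP<=9 column covers roughly 30% of organelle genes and 6-7% of
# the genome on the default 52-species tree (the coverage regime of the
# published co-evolution dataset).
_DEFAULT_FLIP_POS = 0.132
_DEFAULT_FLIP_NEG = 0.213


def default_paperlike_config(seed: int = 0) -> SyntheticConfig:
    """Study-condition defaults: 22k genes, 5% prior, eight datasets.

    The eight evidence columns mirror the published per-dataset coverage
    table: two mass-spectrometry interaction screens, a yeast two-hybrid
    screen, a conserved ciliogenic-TFBS column, an expression screen, two
    published tiered datasets, and the co-evolution column derived from
    phylo-profiles via Dollo parsimony. Class-conditional "found" rates
    are derived from the genome-wide and gold-standard coverages at the
    5% prior. Columns are conditionally independent given the class (the
    naive-Bayes assumption); redundant assays can be emulated through the
    per-dataset copula (``couple_to``) or the gene-level
    ``shared_detectability`` knob, both off here.
    """
    prior = 0.05
    specs = (
        _binary_spec("tap_ms", 0.649, 0.194, prior, n_baits=100),
        _binary_spec("silac", 0.215, 0.062, prior, n_baits=16),
        _binary_spec("y2h", 0.092, 0.015, prior, n_baits=27),
        _binary_spec("tfbs", 0.294, 0.097, prior, found="tfbs", not_found="no_tfbs"),
        _binary_spec(
            "expression", 0.755, 0.240, prior, found="S>=1.5", not_found="S<1.5"
        ),
        _tiered_spec("proteomics_2007", 0.384, 0.092, prior),
        _tiered_spec("expression_2007", 0.262, 0.053, prior),
    )
    newick, reference = build_default_tree()
    return SyntheticConfig(
        n_genes=22_000,
        prior_true=prior,
        dataset_specs=specs,
        n_train_pos=302,
        n_train_neg=1275,
        tree_newick=newick,
        reference_profile=reference,
        profile_flip_pos=_DEFAULT_FLIP_POS,
        profile_flip_neg=_DEFAULT_FLIP_NEG,
        ddp_threshold=9,
        ddp_dataset_id="coevolution",
        seed=seed,
    )


def true_likelihood_table(bundle: SyntheticBundle):
    """Oracle likelihood table from the generator's ground truth.

    Class-conditional category fractions are measured on the whole
    population using the true class of every gene (no training subset, no
    smoothing) — the "true parameters" against which estimator recovery
    and posterior calibration are judged. Columns derived from profiles
    (the DDP bin) get their population-level conditionals the same way.
    """
    from .bayes import CategoryLikelihood, LikelihoodTable

    is_pos = (bundle.truth == "pos").to_numpy()
    entries = []
    summary = {}
    for schema in bundle.evidence.schemas:
        col = bundle.evidence.cells[schema.dataset_id].to_numpy()
        n_pos = int(is_pos.sum())
        n_neg = int((~is_pos).sum())
        summary[schema.dataset_id] = (n_pos, n_neg)
        for c in schema.categories:
            in_c = col == c
            fp = float(in_c[is_pos].mean())
            fn = float(in_c[~is_pos].mean())
            if fp <= 0 or fn <= 0:
                # guard: population-empty category; tiny floor keeps llr finite
                fp = max(fp, 0.5 / max(n_pos, 1))
                fn = max(fn, 0.5 / max(n_neg, 1))
            entries.append(
                CategoryLikelihood(
                    dataset_id=schema.dataset_id,
                    category=c,
                    n_pos=int(in_c[is_pos].sum()),
                    n_neg=int(in_c[~is_pos].sum()),
                    frac_pos=fp,
                    frac_neg=fn,
                    llr=float(np.log2(fp / fn)),
                )
            )
    return LikelihoodTable(entries=entries, training_summary=summary)


def true_llr(spec: DatasetSpec) -> dict:
    """log2 P(c|pos)/P(c|neg) per category — the generator's ground truth."""
    return {
        c: float(np.log2(spec.p_pos[c] / spec.p_neg[c])) for c in spec.categories
    }


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Same study conditions, different random seed."""
    return replace(config, seed=seed)
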