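"""Statistics for judging an experimental validation campaign.

Given the binary outcomes of follow-up experiments on selected candidate
genes (localization and knockdown-phenotype assays collapsed to yes/no),
these functions compute the observed positive predictive value, the
validation count expected from the classifier's FDR, and the significance
of the observed validation rate under hypergeometric and binomial nulls.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "ValidationOutcome",
    "load_packaged_outcomes",
    "read_outcomes",
    "ppv",
    "expected_successes",
    "prob_exact_hypergeom",
    "binom_tail_upper",
    "campaign_report",
]

ASSAY_CLASSES = ("phenotype", "localization")


@dataclass
class ValidationOutcome:
    """Tested candidate genes with binary ciliary-evidence calls.

    ``entries`` is a DataFrame with columns ``gene``, ``rank``,
    ``assay_class`` ("phenotype" | "localization") and ``outcome``
    ("yes" | "no"). Genes are unique.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"gene", "rank", "assay_class", "outcome"}
        missing = req - set(self.entries.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if self.entries["gene"].duplicated().any():
            dups = self.entries.loc[
                self.entries["gene"].duplicated(), "gene"
            ].tolist()
            raise ValueError(f"duplicate genes in outcomes: {dups}")
        bad = set(self.entries["outcome"]) - {"yes", "no"}
        if bad:
            raise ValueError(f"outcomes must be yes/no, got {sorted(bad)}")
        bad = set(self.entries["assay_class"]) - set(ASSAY_CLASSES)
        if bad:
            raise ValueError(f"unknown assay classes {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.entries)


def read_outcomes(path) -> ValidationOutcome:
    """Read an outcome TSV (gene, rank, assay_class, outcome; '#' comments)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str})
    return ValidationOutcome(entries=df)


def load_packaged_outcomes() -> ValidationOutcome:
    """The packaged 36-gene validation outcome table.

    Transcribed outcome calls of the validation campaign: 36 candidates
    tested across six assay types in four model systems, with the final
    per-gene yes/no call and the assay family each gene was tested in.
    """
    ref = resources.files("ciliabayes").joinpath("data/validation_outcomes.tsv")
    with resources.as_file(ref) as path:
        return read_outcomes(path)


def ppv(
    outcomes: ValidationOutcome, assay_filter: str | None = None
) -> tuple[int, int, float]:
    """Positive predictive value from an outcome table.

    Returns ``(k, n, k/n)``: confirmed candidates, candidates tested, and
    their ratio, optionally restricted to one assay class.
    """
    df = outcomes.entries
    if assay_filter is not None:
        if assay_filter not in ASSAY_CLASSES:
            raise ValueError(f"unknown assay class {assay_filter!r}")
        df = df[df["assay_class"] == assay_filter]
    n = len(df)
    if n == 0:
        raise ValueError("no outcomes after filtering")
    k = int((df["outcome"] == "yes").sum())
    return k, n, k / n


def expected_successes(n: int, ppv_: float) -> float:
    """Expected number of confirmed candidates among ``n`` tested at a given PPV."""
    if n < 0 or not 0.0 <= ppv_ <= 1.0:
        raise ValueError("need n >= 0 and ppv in [0,1]")
    return n * ppv_


def prob_exact_hypergeom(pool: int, true_in_pool: int, tested: int, successes: int) -> float:
    """Hypergeometric point mass P(X = x) in log space.

    Probability of drawing exactly ``successes`` true genes when sampling
    ``tested`` genes without replacement from a ``pool`` containing
    ``true_in_pool`` true genes:
    C(K,x) C(N-K, n-x) / C(N,n).
    """
    N, K, n, x = pool, true_in_pool, tested, successes
    if not (0 <= n <= N and 0 <= K <= N and 0 <= x <= n):
        raise ValueError(f"invalid hypergeometric parameters N={N} K={K} n={n} x={x}")
    if x > K or (n - x) > (N - K):
        return 0.0

    def logC(a: int, b: int) -> float:
        return float(gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1))

    return float(np.exp(logC(K, x) + logC(N - K, n - x) - logC(N, n)))


def binom_tail_upper(n: int, p: float, x: int) -> float:
    """Upper tail P(X >= x) under Binomial(n, p), summed in log space."""
    if not (0 <= x <= n) or not 0.0 <= p <= 1.0:
        raise ValueError(f"invalid binomial parameters n={n} p={p} x={x}")
    if x == 0:
        return 1.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    ks = np.arange(x, n + 1)
    logpmf = (
        gammaln(n + 1)
        - gammaln(ks + 1)
        - gammaln(n - ks + 1)
        + ks * np.log(p)
        + (n - ks) * np.log1p(-p)
    )
    return float(np.exp(logsumexp(logpmf)))


def campaign_report(
    outcomes: ValidationOutcome,
    theoretical_ppv: float = 0.67,
    candidate_pool: int | None = None,
    chance_ppv: float = 0.05,
) -> dict:
    """Full validation-campaign summary as a JSON-serialisable dict.

    Reports observed PPV overall and per assay class, the expected
    validation count at the classifier's theoretical PPV, the
    hypergeometric point probability of the observed count when drawing
    from the candidate pool (pool size defaults to the number of selected
    novel candidates if given), and the binomial upper-tail probability of
    doing at least this well by chance at the genome-wide prior.
    """
    k, n, observed = ppv(outcomes)
    per_class = {}
    for cls in ASSAY_CLASSES:
        try:
            ck, cn, cp = ppv(outcomes, assay_filter=cls)
            per_class[cls] = {"k": ck, "n": cn, "ppv": cp}
        except ValueError:
            per_class[cls] = None
    report = {
        "k": k,
        "n": n,
        "ppv_observed": observed,
        "ppv_per_assay_class": per_class,
        "ppv_theoretical": theoretical_ppv,
        "expected_successes": expected_successes(n, theoretical_ppv),
        "chance_ppv": chance_ppv,
        "p_chance_binomial_upper": binom_tail_upper(n, chance_ppv, k),
    }
    if candidate_pool is not None:
        K = round(theoretical_ppv * candidate_pool)
        report["hypergeometric"] = {
            "pool": candidate_pool,
            "true_in_pool": K,
            "p_point": prob_exact_hypergeom(candidate_pool, K, n, k),
        }
    return report
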