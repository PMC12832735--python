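"""Per-feature log-mean abundance and top-K highly-represented sets.

Because EV preparations from different biofluids differ in isolation method,
donor population and library chemistry, absolute expression levels are not
comparable across sources.  The pipeline therefore ranks features *within*
each source by the mean of log-transformed counts,

    mu_g = (1/n) * sum_i log(x_gi + 1),

and takes the K features with the largest mu_g (K = 1000 by default) as that
source's highly-represented set.  Only the *composition* of the two top-K
sets is ever compared downstream.  The ranking is invariant to the log base;
scores are reported in natural-log units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BIOTYPES, CountMatrix, FeatureAnnotation


@dataclass
class AbundanceScores:
    """mu_g per feature (natural-log units unless log_base says otherwise)."""

    scores: pd.Series  # index = feature IDs
    n_samples: int
    log_base: float = math.e

    def __post_init__(self) -> None:
        if (self.scores < 0).any():
            raise ValueError("abundance scores cannot be negative")


@dataclass
class TopKSet:
    """The K features with largest mu_g in one source, in rank order."""

    table: pd.DataFrame  # columns: rank, feature_id, score
    k: int
    source_label: str = ""
    universe: frozenset = frozenset()  # all features that were scored

    def __post_init__(self) -> None:
        scores = self.table["score"].to_numpy()
        if len(scores) > 1 and (np.diff(scores) > 1e-12).any():
            raise ValueError("top-K scores must be non-increasing")

    @property
    def feature_set(self) -> frozenset:
        return frozenset(self.table["feature_id"])

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def log_mean_abundance(
    counts: CountMatrix,
    log_base: float = math.e,
    library_size_normalize: bool = False,
) -> AbundanceScores:
    """Compute mu_g = (1/n) sum_i log(x_gi + 1) for every feature.

    ``library_size_normalize`` rescales each sample's counts to the cohort's
    mean library size before the log transform.  This is an explicit,
    off-by-default deviation from the plain formula; it changes scores but
    can be useful when library sizes vary wildly within a cohort.
    """
    df = counts.counts
    if df.shape[1] == 0:
        raise ValueError("count matrix has zero samples")
    if library_size_normalize:
        libsizes = df.sum(axis=0)
        if (libsizes == 0).any():
            raise ValueError("cannot library-size normalize a sample with zero counts")
        df = df / libsizes * libsizes.mean()
    mu = np.log1p(df).mean(axis=1)
    if log_base != math.e:
        mu = mu / math.log(log_base)
    mu.name = "score"
    return AbundanceScores(scores=mu, n_samples=df.shape[1], log_base=log_base)


def top_k_features(
    scores: AbundanceScores,
    k: int = 1000,
    source_label: str = "",
) -> TopKSet:
    """Select the K highest-scoring features.

    Ties at the boundary are broken by ascending lexicographic feature ID so
    the result is deterministic across runs and platforms.
    """
    if k < 1:
        raise ValueError(f"K must be >= 1, got {k}")
    s = scores.scores
    order = (
        s.rename("score")
        .rename_axis("feature_id")
        .reset_index()
        .sort_values(["score", "feature_id"], ascending=[False, True])
        .head(min(k, len(s)))
        .reset_index(drop=True)
    )
    order.insert(0, "rank", np.arange(1, len(order) + 1))
    return TopKSet(
        table=order,
        k=k,
        source_label=source_label,
        universe=frozenset(s.index),
    )


@dataclass
class RecurrenceResult:
    """Features of one biotype recurrently in the per-sample top-K."""

    table: pd.DataFrame  # columns: feature_id, n_samples_in_topk, fraction, recurrent
    k: int
    min_fraction: float
    n_samples: int

    @property
    def recurrent(self) -> frozenset:
        return frozenset(self.table.loc[self.table["recurrent"], "feature_id"])


def topk_recurrence(
    counts: CountMatrix,
    biotype: str,
    annotation: FeatureAnnotation,
    k: int = 20,
    min_fraction: float = 0.5,
) -> RecurrenceResult:
    """Find features of one biotype that recur in per-sample top-K lists.

    Within each sample, features carrying the requested biotype are ranked by
    that sample's raw count (ties by ascending feature ID).  A feature is
    recurrent if it lands in the per-sample top-K in at least ``min_fraction``
    of samples.  This is the per-individual cargo-similarity summary (e.g.
    which lncRNAs dominate every donor's EV preparation).
    """
    if biotype not in BIOTYPES:
        raise ValueError(f"biotype '{biotype}' not in vocabulary {BIOTYPES}")
    if k < 1:
        raise ValueError("K must be >= 1")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    keep = [
        f for f in counts.feature_ids if annotation.biotype_of(f) == biotype
    ]
    sub = counts.counts.loc[keep]
    n_samples = sub.shape[1]
    hits: dict[str, int] = dict.fromkeys(keep, 0)
    for sample in sub.columns:
        col = sub[sample]
        top = (
            col.rename("count")
            .rename_axis("feature_id")
            .reset_index()
            .sort_values(["count", "feature_id"], ascending=[False, True])
            .head(min(k, len(col)))
        )
        for fid in top["feature_id"]:
            hits[fid] += 1
    rows = pd.DataFrame(
        {
            "feature_id": list(hits),
            "n_samples_in_topk": list(hits.values()),
        }
    )
    rows["fraction"] = rows["n_samples_in_topk"] / n_samples if n_samples else 0.0
    rows["recurrent"] = rows["fraction"] >= min_fraction
    rows = rows.sort_values(
        ["fraction", "feature_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return RecurrenceResult(
        table=rows, k=k, min_fraction=min_fraction, n_samples=n_samples
    )
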