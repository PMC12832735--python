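"""Top-K composition comparison against gene-set collections.

For a pathway with k member genes, the representation of the pathway in a
source is the fraction of those k genes that fall inside the source's top-K
abundance set.  Comparing this fraction between two sources (e.g. saliva EVs
vs blood EVs) asks which biofluid's vesicle cargo over-represents the
pathway, without ever comparing expression levels across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import FeatureAnnotation, GeneSet, GeneSetCollection, harmonize_ids
from .ranking import TopKSet


def _topk_symbols(topk: TopKSet, annotation: FeatureAnnotation | None) -> frozenset:
    ids = list(topk.feature_set)
    if annotation is None:
        normalized, _ = harmonize_ids(ids)
        return frozenset(normalized)
    normalized, _ = harmonize_ids(ids, annotation=annotation, to_symbols=True)
    return frozenset(normalized)


def members_in_topk(
    topk: TopKSet,
    geneset: GeneSet,
    annotation: FeatureAnnotation | None = None,
) -> int:
    """Count pathway members inside the top-K set (after ID harmonization)."""
    if geneset.size == 0:
        raise ValueError(f"gene set '{geneset.set_id}' is empty")
    return len(_topk_symbols(topk, annotation) & geneset.members)


@dataclass
class RepresentationTable:
    """Per-pathway top-K membership counts and percentages for two sources.

    ``percent_a`` / ``percent_b`` hold full precision; the one-decimal
    display values (round-half-even) appear only in :meth:`formatted` and
    the TSV output.  ``measured_a`` / ``measured_b`` count pathway members
    present anywhere in each source's measured feature universe — the
    percentage denominator is always the full pathway size k, so these
    columns expose how much of each pathway was measurable at all.
    """

    table: pd.DataFrame
    k: int
    source_a: str
    source_b: str

    def __post_init__(self) -> None:
        t = self.table
        bound = t["pathway_size"].clip(upper=self.k)  # min(K, pathway size)
        for suffix in ("a", "b"):
            counts = t[f"count_{suffix}"]
            if ((counts < 0) | (counts > bound)).any():
                raise ValueError("representation counts exceed min(K, pathway size)")
            pct = t[f"percent_{suffix}"]
            if ((pct < 0) | (pct > 100)).any():
                raise ValueError("percentages must lie in [0, 100]")

    def formatted(self) -> pd.DataFrame:
        """Display table: 'count (percent)' strings, one decimal, half-even."""
        t = self.table
        out = pd.DataFrame(
            {
                "pathway_id": t["pathway_id"],
                "pathway_name": t["pathway_name"],
                self.source_a or "source_a": [
                    f"{c} ({round(p, 1)})"
                    for c, p in zip(t["count_a"], t["percent_a"])
                ],
                self.source_b or "source_b": [
                    f"{c} ({round(p, 1)})"
                    for c, p in zip(t["count_b"], t["percent_b"])
                ],
                "pathway_size": t["pathway_size"],
            }
        )
        return out

    def to_tsv(self, path) -> None:
        self.formatted().to_csv(path, sep="\t", index=False)

    def to_json(self, path=None, provenance: dict | None = None):
        """JSON twin with unrounded percentages."""
        payload = {
            "k": self.k,
            "source_a": self.source_a,
            "source_b": self.source_b,
            "pathways": self.table.to_dict(orient="records"),
        }
        if provenance is not None:
            payload["provenance"] = provenance
        if path is None:
            return payload
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return payload


def representation_table(
    topk_a: TopKSet,
    topk_b: TopKSet,
    genesets: GeneSetCollection,
    annotation: FeatureAnnotation | None = None,
) -> RepresentationTable:
    """Build the per-pathway representation comparison for two sources.

    Rows follow the gene-set collection's order.  Pathway members missing
    from a source's measured universe still count in the denominator k.
    """
    if topk_a.k != topk_b.k:
        raise ValueError(
            f"top-K sets built with different K: {topk_a.k} vs {topk_b.k}"
        )
    set_a = _topk_symbols(topk_a, annotation)
    set_b = _topk_symbols(topk_b, annotation)
    if annotation is None:
        universe_a, _ = harmonize_ids(topk_a.universe)
        universe_b, _ = harmonize_ids(topk_b.universe)
    else:
        universe_a, _ = harmonize_ids(topk_a.universe, annotation, to_symbols=True)
        universe_b, _ = harmonize_ids(topk_b.universe, annotation, to_symbols=True)
    universe_a, universe_b = frozenset(universe_a), frozenset(universe_b)

    rows = []
    for gs in genesets:
        count_a = len(set_a & gs.members)
        count_b = len(set_b & gs.members)
        rows.append(
            {
                "pathway_id": gs.set_id,
                "pathway_name": gs.name,
                "pathway_size": gs.size,
                "count_a": count_a,
                "percent_a": 100.0 * count_a / gs.size,
                "count_b": count_b,
                "percent_b": 100.0 * count_b / gs.size,
                "measured_a": len(universe_a & gs.members),
                "measured_b": len(universe_b & gs.members),
            }
        )
    return RepresentationTable(
        table=pd.DataFrame(rows),
        k=topk_a.k,
        source_a=topk_a.source_label,
        source_b=topk_b.source_label,
    )


@dataclass
class ProportionTestResult:
    difference: float  # count_a/k - count_b/k
    p_value: float
    odds_ratio: float


def proportion_test(count_a: int, count_b: int, k: int) -> ProportionTestResult:
    """Exact conditional test for a difference in top-K representation.

    Tests the 2x2 table [in-topK vs not] x [source A vs B] with Fisher's
    exact test (two-sided).  This goes beyond plain descriptive reporting of
    the two percentages and is off by default in pipeline reports; the
    hypergeometric conditioning treats the two sources' pathway memberships
    as independent samples, which ignores that the same genes are scored in
    both sources.
    """
    if k == 0:
        raise ValueError("pathway size k must be positive")
    if not (0 <= count_a <= k and 0 <= count_b <= k):
        raise ValueError("counts must lie in [0, k]")
    odds_ratio, p = stats.fisher_exact(
        [[count_a, k - count_a], [count_b, k - count_b]], alternative="two-sided"
    )
    return ProportionTestResult(
        difference=(count_a - count_b) / k,
        p_value=float(p),
        odds_ratio=float(odds_ratio),
    )
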