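"""Presence calling for qPCR arrays and background filtering for miRNA panels.

qPCR arrays report a cycle-threshold (Ct) value per well: the PCR cycle at
which fluorescence crosses threshold, so lower Ct means more template.  A
transcript is called present in a sample only when BOTH duplicate runs give
a Ct inside the assay's dynamic range, [18, 35] by default (bounds
inclusive); a well that never crossed threshold ("Undetermined") is missing
and forces an absent call.

Hybridisation-count miRNA panels carry negative-control probes with no
target.  The background threshold is the control mean + 2 SD computed per
sample and averaged across samples; a miRNA is expressed when its mean count
exceeds that threshold.  Expressed miRNAs at or below a low-expression
cutoff (100 counts by default, strict '>' required to clear) are flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CtTable, MiRNACountTable


@dataclass
class PresenceMatrix:
    """Boolean gene x sample presence calls with their provenance."""

    matrix: pd.DataFrame  # bool, index = genes, columns = samples
    ct_min: float
    ct_max: float
    replicate_policy: str = "both_in_window"

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    def to_tsv(self, path) -> None:
        out = self.matrix.astype(int).copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def qpcr_presence_call(
    ct: CtTable, ct_min: float = 18.0, ct_max: float = 35.0
) -> PresenceMatrix:
    """Call presence per (gene, sample) from duplicate Ct runs.

    Present iff both replicates have ct_min <= Ct <= ct_max; a missing
    replicate (absent row or Undetermined well) forces absent.  The output
    is defined for every gene and sample appearing anywhere in the table.
    """
    t = ct.table
    genes, samples = ct.genes, ct.samples
    in_window = t["ct"].between(ct_min, ct_max, inclusive="both") & t["ct"].notna()
    ok = t.assign(ok=in_window)
    # a (gene, sample) is present iff exactly both replicates exist and pass
    grp = ok.groupby(["gene", "sample"])["ok"].agg(["sum", "count"])
    present = (grp["sum"] == 2) & (grp["count"] == 2)
    grid = present.unstack("sample").reindex(index=genes, columns=samples)
    matrix = grid.notna() & grid.eq(True)  # missing (gene, sample) -> absent
    return PresenceMatrix(matrix=matrix, ct_min=ct_min, ct_max=ct_max)


@dataclass
class PresenceSummary:
    """Genes present in >= m samples, for each threshold m."""

    counts: dict[int, int]  # m -> number of genes with >= m present calls
    universe: int  # assay universe size (number of genes on the array)
    n_samples: int

    def percent(self, m: int) -> float:
        return 100.0 * self.counts[m] / self.universe if self.universe else 0.0

    def percent_display(self, m: int) -> int:
        """Percent rounded to the nearest integer for display."""
        return int(round(self.percent(m)))

    def to_json(self, path=None, provenance: dict | None = None):
        payload = {
            "universe": self.universe,
            "n_samples": self.n_samples,
            "thresholds": {
                str(m): {
                    "genes": c,
                    "percent": self.percent(m),
                    "percent_display": self.percent_display(m),
                }
                for m, c in self.counts.items()
            },
        }
        if provenance is not None:
            payload["provenance"] = provenance
        if path is None:
            return payload
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return payload


def presence_summary(
    p: PresenceMatrix, thresholds: tuple[int, ...] = (1, 10)
) -> PresenceSummary:
    """Count genes detected in at least m samples for each threshold m."""
    per_gene = p.matrix.sum(axis=1)
    counts = {int(m): int((per_gene >= m).sum()) for m in thresholds}
    return PresenceSummary(
        counts=counts, universe=p.matrix.shape[0], n_samples=p.matrix.shape[1]
    )


@dataclass
class ExpressedMiRNASet:
    """miRNAs clearing the negative-control background, with expression flags.

    ``table`` covers every assayed miRNA: mean count across samples, the
    expressed call, and the low-expression flag (mean <= low_cutoff) which
    is only meaningful for expressed miRNAs.
    """

    table: pd.DataFrame  # columns: id, mean_count, expressed, low_flag, rank
    background_threshold: float
    low_cutoff: float
    per_sample_background: pd.Series

    @property
    def expressed(self) -> frozenset:
        return frozenset(self.table.loc[self.table["expressed"], "id"])

    @property
    def low_flagged(self) -> frozenset:
        return frozenset(
            self.table.loc[self.table["expressed"] & self.table["low_flag"], "id"]
        )

    def top(self, n: int = 20) -> pd.DataFrame:
        """The n most abundant expressed miRNAs (by mean count)."""
        return self.table[self.table["expressed"]].nsmallest(n, "rank")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def mirna_expression_filter(
    t: MiRNACountTable,
    low_cutoff: float = 100.0,
    n_sd: float = 2.0,
    top_n: int = 20,
) -> ExpressedMiRNASet:
    """Separate expressed miRNAs from hybridisation background.

    Background per sample = mean + n_sd * SD of that sample's negative
    controls (population SD, so a single control row yields a defined,
    zero-spread threshold); thresholds are then averaged across samples.  A
    miRNA is expressed when its mean count across samples strictly exceeds
    the averaged threshold.  Expressed miRNAs with mean count <= low_cutoff
    are flagged as low expression (strict '>' required to clear the flag).
    """
    controls = t.control_counts
    per_sample_bg = controls.mean(axis=0) + n_sd * controls.std(axis=0, ddof=0)
    background = float(per_sample_bg.mean())

    mirnas = t.mirna_counts
    mean_counts = mirnas.mean(axis=1)
    table = pd.DataFrame(
        {
            "id": mean_counts.index,
            "mean_count": mean_counts.to_numpy(),
        }
    )
    table["expressed"] = table["mean_count"] > background
    table["low_flag"] = table["mean_count"] <= low_cutoff
    table = table.sort_values(
        ["mean_count", "id"], ascending=[False, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    result = ExpressedMiRNASet(
        table=table,
        background_threshold=background,
        low_cutoff=low_cutoff,
        per_sample_background=per_sample_bg,
    )
    # top-N report is derived on demand via .top(top_n); keep default visible
    result.table.attrs["top_n"] = top_n
    return result
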