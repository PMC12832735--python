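"""Transcript-biotype composition and read-mapping summaries.

Answers two descriptive questions about an EV RNA-seq cohort: what fraction
of each sample's reads mapped to the human genome at all (unique + multi),
and, of the transcripts detected in each sample, how many are protein
coding, lncRNA, pseudogene-derived or other.

Two averaging conventions exist for cohort-level biotype percentages and
they generally disagree: the mean of per-sample percentages weights every
sample equally, while the ratio of summed (or mean) counts weights samples
by how many transcripts they detect.  Both are reported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BIOTYPES, CountMatrix, FeatureAnnotation, MappingStats


@dataclass
class CompositionSummary:
    """Per-sample detected-feature tallies by biotype, plus cohort averages.

    ``per_sample`` has one row per (sample, biotype) with the detected count
    and percentage of that sample's detected total; the percentage is NaN
    for a sample with nothing detected.  ``cohort`` carries, per biotype,
    the mean detected count, the mean of the per-sample percentages, and
    the ratio-of-mean-counts percentage.
    """

    per_sample: pd.DataFrame  # columns: sample, biotype, count, percent
    totals: pd.Series  # total detected per sample
    cohort: pd.DataFrame  # index biotype: mean_count, mean_percent, ratio_percent
    detect_threshold: float
    n_unannotated: int = 0

    def to_tsv(self, path) -> None:
        self.per_sample.to_csv(path, sep="\t", index=False)

    def to_json(self, path=None, provenance: dict | None = None):
        payload = {
            "detect_threshold": self.detect_threshold,
            "n_unannotated_features": self.n_unannotated,
            "mean_total_detected": float(self.totals.mean()),
            "per_biotype": self.cohort.round(6).to_dict(orient="index"),
        }
        if provenance is not None:
            payload["provenance"] = provenance
        if path is None:
            return payload
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return payload


def biotype_composition(
    counts: CountMatrix,
    annotation: FeatureAnnotation,
    detect_threshold: float = 1.0,
) -> CompositionSummary:
    """Tally detected features per biotype in every sample.

    A feature is detected in a sample iff its count >= ``detect_threshold``
    (default 1).  Features absent from the annotation are binned as 'other'
    and counted in ``n_unannotated`` with a warning.
    """
    df = counts.counts
    biotypes = pd.Series(
        [annotation.biotype_of(f) for f in df.index], index=df.index, dtype=object
    )
    n_unannotated = int(biotypes.isna().sum())
    if n_unannotated:
        warnings.warn(
            f"{n_unannotated} features missing from annotation; binned as 'other'",
            stacklevel=2,
        )
        biotypes = biotypes.fillna("other")

    detected = df >= detect_threshold
    rows = []
    totals = {}
    for sample in df.columns:
        det = detected[sample]
        total = int(det.sum())
        totals[sample] = total
        tally = biotypes[det].value_counts()
        for bt in BIOTYPES:
            n = int(tally.get(bt, 0))
            pct = 100.0 * n / total if total > 0 else np.nan
            rows.append(
                {"sample": sample, "biotype": bt, "count": n, "percent": pct}
            )
    per_sample = pd.DataFrame(rows)
    totals = pd.Series(totals, name="total_detected")

    cohort = (
        per_sample.groupby("biotype", sort=False)
        .agg(mean_count=("count", "mean"), mean_percent=("percent", "mean"))
        .reindex(list(BIOTYPES))
    )
    grand_mean = totals.mean()
    cohort["ratio_percent"] = (
        100.0 * cohort["mean_count"] / grand_mean if grand_mean > 0 else np.nan
    )
    return CompositionSummary(
        per_sample=per_sample,
        totals=totals,
        cohort=cohort,
        detect_threshold=detect_threshold,
        n_unannotated=n_unannotated,
    )


@dataclass
class MappingSummary:
    """Total-mapped percentage (unique + multi) per sample and its mean."""

    per_sample: pd.DataFrame  # unique/multi/unmapped/total_mapped percent
    means: pd.Series = field(default_factory=pd.Series)

    def to_json(self, path=None, provenance: dict | None = None):
        payload = {
            "per_sample": self.per_sample.round(6).to_dict(orient="index"),
            "mean": self.means.round(6).to_dict(),
        }
        if provenance is not None:
            payload["provenance"] = provenance
        if path is None:
            return payload
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return payload


def mapping_summary(stats: MappingStats) -> MappingSummary:
    """Summarise alignment fractions: total mapped = unique% + multi%.

    Raw-count inputs are converted to percentages of each sample's total
    reads first; a sample with zero total reads is an error.
    """
    if stats.mode == "counts":
        t = stats.table
        total = t[list(MappingStats._COUNT_COLS)].sum(axis=1)
        if (total == 0).any():
            zero = total.index[total == 0][0]
            raise ValueError(f"sample '{zero}' has zero total reads")
        pct = pd.DataFrame(
            {
                "unique_percent": 100.0 * t["unique_reads"] / total,
                "multi_percent": 100.0 * t["multi_reads"] / total,
                "unmapped_percent": 100.0 * t["unmapped_reads"] / total,
            }
        )
    else:
        pct = stats.table[list(MappingStats._PERCENT_COLS)].copy()
    pct["total_mapped_percent"] = pct["unique_percent"] + pct["multi_percent"]
    return MappingSummary(per_sample=pct, means=pct.mean(axis=0))
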