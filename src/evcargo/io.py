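"""Readers, writers and validation for the tabular artifacts of the pipeline.

Every table the pipeline consumes or emits passes through this module:
featureCounts-style count matrices, GMT gene-set collections, feature
annotation tables (biotype + symbol), qPCR Ct tables with duplicate runs,
miRNA count panels with negative-control rows, and per-sample read-mapping
summaries.  All files are UTF-8, tab-delimited (Ct tables are CSV), decimal
point '.', no thousands separators.  Readers validate hard; writers produce
files the readers accept unchanged (round-trip identity).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Closed biotype vocabulary.  Annotation readers canonicalise the richer
#: genome-annotation labels (lincRNA, processed_pseudogene, ...) onto it.
BIOTYPES: tuple[str, ...] = ("protein_coding", "lncRNA", "pseudogene", "other")

_ENSEMBL_VERSIONED = re.compile(r"^(ENS[A-Z0-9]*?\d+)\.(\d+)$")

#: featureCounts emits these metadata columns between the ID and the samples.
_FEATURECOUNTS_META = ("Chr", "Start", "End", "Strand", "Length")


class FormatError(ValueError):
    """A file violates the format contract (bad value, duplicate ID, ...)."""


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Non-negative feature x sample count matrix from one EV source.

    Counts may be fractional: multi-mapping reassignment (e.g. averaged
    reassignment of repetitive-element reads) yields non-integer counts, so
    validation enforces non-negativity only.
    """

    counts: pd.DataFrame  # index = feature IDs, columns = sample IDs
    source_label: str = ""

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise FormatError(
                f"count matrix '{self.source_label}' is empty "
                f"({df.shape[0]} features x {df.shape[1]} samples)"
            )
        dup = df.index[df.index.duplicated()].unique()
        if len(dup):
            raise FormatError(f"duplicate feature IDs: {list(dup[:5])}")
        if df.columns.duplicated().any():
            raise FormatError(
                f"duplicate sample IDs: {list(df.columns[df.columns.duplicated()])}"
            )
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("count matrix contains non-numeric entries")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise FormatError(
                f"missing count at feature '{df.index[r]}', sample '{df.columns[c]}'"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count {values[r, c]} at feature '{df.index[r]}', "
                f"sample '{df.columns[c]}'"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


def read_count_matrix(path, source_label: str = "") -> CountMatrix:
    """Read a featureCounts-style tab-delimited count table.

    First column holds feature IDs; remaining columns are samples.  Comment
    lines starting with '#' are skipped, and the standard featureCounts
    metadata columns (Chr/Start/End/Strand/Length) are dropped if all are
    present.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype={0: str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty count file: {path}") from exc
    if all(c in df.columns for c in _FEATURECOUNTS_META):
        df = df.drop(columns=list(_FEATURECOUNTS_META))
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric count in {path}: {exc}") from exc
    return CountMatrix(counts=df, source_label=source_label)


def write_count_matrix(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Feature annotation
# ---------------------------------------------------------------------------

def canonical_biotype(label: str) -> str:
    """Map a genome-annotation biotype label onto the closed vocabulary."""
    label = label.strip()
    if label in BIOTYPES:
        return label
    if label in ("lincRNA", "lnc_RNA", "antisense", "sense_intronic",
                 "sense_overlapping", "3prime_overlapping_ncRNA"):
        return "lncRNA"
    if label.endswith("pseudogene"):
        return "pseudogene"
    return "other"


@dataclass
class FeatureAnnotation:
    """feature ID -> (canonical biotype, gene symbol)."""

    table: pd.DataFrame  # index = feature IDs, columns: biotype, symbol

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()].unique()
            raise FormatError(f"duplicate annotation feature IDs: {list(dup[:5])}")
        bad = set(self.table["biotype"]) - set(BIOTYPES)
        if bad:
            raise FormatError(f"biotypes outside vocabulary: {sorted(bad)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)

    def biotype_of(self, feature_id: str) -> str | None:
        if feature_id in self.table.index:
            return self.table.at[feature_id, "biotype"]
        return None

    def symbol_of(self, feature_id: str) -> str | None:
        if feature_id in self.table.index:
            return self.table.at[feature_id, "symbol"]
        return None

    @property
    def symbols(self) -> frozenset:
        return frozenset(self.table["symbol"].dropna())


def read_annotation(path) -> FeatureAnnotation:
    """Read an annotation TSV with columns feature_id, biotype, symbol."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    needed = {"feature_id", "biotype", "symbol"}
    if not needed.issubset(df.columns):
        raise FormatError(
            f"annotation file missing columns {sorted(needed - set(df.columns))}"
        )
    df = df.set_index("feature_id")
    df["biotype"] = df["biotype"].map(canonical_biotype)
    return FeatureAnnotation(table=df[["biotype", "symbol"]])


def write_annotation(ann: FeatureAnnotation, path) -> None:
    out = ann.table.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    set_id: str
    name: str
    members: frozenset

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Ordered mapping of pathway ID -> gene set (GMT file contents)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gs in self.sets.values():
            if gs.size < 1:
                raise FormatError(f"gene set '{gs.set_id}' is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB member [TAB member ...].

    Duplicate members within a line are collapsed (set semantics).
    """
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            set_id, name = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            sets[set_id] = GeneSet(set_id=set_id, name=name, members=members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# ID harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizationReport:
    """Accounting of what harmonize_ids did; nothing is dropped silently."""

    n_input: int
    n_output: int
    n_version_stripped: int
    n_dropped: int
    dropped_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "n_version_stripped": self.n_version_stripped,
            "dropped": self.n_dropped,
            "dropped_ids": list(self.dropped_ids),
        }


def strip_version(feature_id: str) -> str:
    """Strip an Ensembl-style version suffix ('ENSG...123.7' -> 'ENSG...123')."""
    m = _ENSEMBL_VERSIONED.match(feature_id)
    return m.group(1) if m else feature_id


def harmonize_ids(
    ids,
    annotation: FeatureAnnotation | None = None,
    to_symbols: bool = False,
) -> tuple[list[str], HarmonizationReport]:
    """Normalise feature IDs into a common namespace.

    Ensembl-style version suffixes are always stripped.  With
    ``to_symbols=True`` the stripped IDs are mapped to gene symbols through
    ``annotation``; IDs without a symbol are excluded and counted in the
    report.  IDs that already are symbols known to the annotation pass
    through unchanged, which makes the operation idempotent.
    """
    ids = list(ids)
    n_stripped = 0
    out: list[str] = []
    dropped: list[str] = []
    known_symbols = annotation.symbols if annotation is not None else frozenset()
    for fid in ids:
        stripped = strip_version(fid)
        if stripped != fid:
            n_stripped += 1
        if not to_symbols:
            out.append(stripped)
            continue
        if annotation is None:
            raise ValueError("to_symbols=True requires an annotation")
        if stripped in known_symbols:
            out.append(stripped)  # already a symbol
            continue
        symbol = annotation.symbol_of(stripped)
        if symbol is None or (isinstance(symbol, float) and np.isnan(symbol)):
            dropped.append(fid)
        else:
            out.append(symbol)
    report = HarmonizationReport(
        n_input=len(ids),
        n_output=len(out),
        n_version_stripped=n_stripped,
        n_dropped=len(dropped),
        dropped_ids=dropped,
    )
    return out, report


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

@dataclass
class CtTable:
    """Long-format qPCR results: one row per (gene, sample, replicate).

    Each assay is run in duplicate; ``ct`` is NaN for wells that did not
    cross threshold ("Undetermined").
    """

    table: pd.DataFrame  # columns: gene, sample, replicate, ct

    def __post_init__(self) -> None:
        t = self.table
        bad_rep = set(t["replicate"].unique()) - {1, 2}
        if bad_rep:
            raise FormatError(f"replicate index outside {{1, 2}}: {sorted(bad_rep)}")
        keys = t[["gene", "sample", "replicate"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise FormatError(
                f"duplicate Ct entry for gene '{dup['gene']}', sample "
                f"'{dup['sample']}', replicate {dup['replicate']}"
            )
        present = t["ct"].dropna()
        if (present <= 0).any():
            raise FormatError("Ct values must be positive when present")

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.table["sample"].unique())


def read_ct_table(path) -> CtTable:
    """Read a Ct CSV with columns gene, sample, replicate, ct.

    Empty cells and the string 'Undetermined' map to missing.
    """
    df = pd.read_csv(path, dtype={"gene": str, "sample": str})
    needed = {"gene", "sample", "replicate", "ct"}
    if not needed.issubset(df.columns):
        raise FormatError(
            f"Ct file missing columns {sorted(needed - set(df.columns))}"
        )
    df["ct"] = pd.to_numeric(
        df["ct"].replace({"Undetermined": np.nan, "undetermined": np.nan}),
        errors="raise",
    )
    df["replicate"] = df["replicate"].astype(int)
    return CtTable(table=df[["gene", "sample", "replicate", "ct"]])


def write_ct_table(ct: CtTable, path) -> None:
    ct.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# miRNA count panels
# ---------------------------------------------------------------------------

@dataclass
class MiRNACountTable:
    """Hybridisation counts per miRNA probe, with negative-control rows.

    Negative-control probes carry no target sequence; their counts estimate
    the non-specific background used by the expression filter.
    """

    counts: pd.DataFrame  # index = probe IDs, columns = samples
    control_ids: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise FormatError("duplicate miRNA probe IDs")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative miRNA counts")
        missing = set(self.control_ids) - set(self.counts.index)
        if missing:
            raise FormatError(f"control IDs absent from table: {sorted(missing)[:5]}")
        if not self.control_ids:
            raise FormatError(
                "at least one negative-control row is required for background estimation"
            )

    @property
    def mirna_ids(self) -> list[str]:
        return [i for i in self.counts.index if i not in self.control_ids]

    @property
    def control_counts(self) -> pd.DataFrame:
        return self.counts.loc[sorted(self.control_ids)]

    @property
    def mirna_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.mirna_ids]


def read_mirna_table(path) -> MiRNACountTable:
    """Read a miRNA count TSV: columns id, control (boolean), then samples."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns or "control" not in df.columns:
        raise FormatError("miRNA table needs 'id' and 'control' columns")
    df = df.set_index("id")
    control_flags = (
        df["control"].astype(str).str.strip().str.lower().isin(("true", "1", "yes"))
    )
    counts = df.drop(columns=["control"]).astype(float)
    return MiRNACountTable(
        counts=counts,
        control_ids=frozenset(counts.index[control_flags]),
    )


def write_mirna_table(t: MiRNACountTable, path) -> None:
    out = t.counts.copy()
    out.insert(0, "control", [i in t.control_ids for i in out.index])
    out.index.name = "id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Read-mapping statistics
# ---------------------------------------------------------------------------

@dataclass
class MappingStats:
    """Per-sample alignment category summary, in percent or raw-read units.

    ``mode`` is 'percent' (columns unique_percent, multi_percent,
    unmapped_percent, each in [0, 100]) or 'counts' (columns unique_reads,
    multi_reads, unmapped_reads summing to each sample's total).
    """

    table: pd.DataFrame  # index = sample IDs
    mode: str = "percent"

    _PERCENT_COLS = ("unique_percent", "multi_percent", "unmapped_percent")
    _COUNT_COLS = ("unique_reads", "multi_reads", "unmapped_reads")

    def __post_init__(self) -> None:
        if self.mode == "percent":
            cols = list(self._PERCENT_COLS)
            missing = set(cols) - set(self.table.columns)
            if missing:
                raise FormatError(f"mapping stats missing columns {sorted(missing)}")
            vals = self.table[cols].to_numpy()
            if ((vals < 0) | (vals > 100)).any():
                raise FormatError("mapping percentages must lie in [0, 100]")
        elif self.mode == "counts":
            cols = list(self._COUNT_COLS)
            missing = set(cols) - set(self.table.columns)
            if missing:
                raise FormatError(f"mapping stats missing columns {sorted(missing)}")
            if (self.table[cols].to_numpy() < 0).any():
                raise FormatError("read counts must be non-negative")
            if "total_reads" in self.table.columns:
                sums = self.table[cols].sum(axis=1)
                if not np.allclose(sums, self.table["total_reads"]):
                    raise FormatError("mapping categories do not sum to total reads")
        else:
            raise ValueError(f"unknown mapping-stats mode: {self.mode}")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)


def read_mapping_stats(path) -> MappingStats:
    """Read a mapping-stats TSV; mode is inferred from the column names."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str}).set_index("sample")
    if set(MappingStats._PERCENT_COLS).issubset(df.columns):
        return MappingStats(table=df.astype(float), mode="percent")
    if set(MappingStats._COUNT_COLS).issubset(df.columns):
        return MappingStats(table=df.astype(float), mode="counts")
    raise FormatError(
        "mapping-stats file needs either percent columns "
        f"{MappingStats._PERCENT_COLS} or count columns {MappingStats._COUNT_COLS}"
    )


def write_mapping_stats(stats: MappingStats, path) -> None:
    out = stats.table.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")
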