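"""Tabular I/O for 16S amplicon count data.

The pipeline's canonical container is the :class:`CountTable`: a
features x samples matrix of non-negative integer read counts with
unique feature and sample identifiers.  On disk a count table is
tab-separated text, feature identifiers in the first column, sample
identifiers in the header row.  Lines starting with ``#`` are
provenance comments and are ignored on read.

Besides reading and writing, this module provides the three standard
preprocessing steps applied to every table before analysis:

* :func:`aggregate_to_genus` -- collapse ASV rows to genus rows using a
  taxonomy map (the whole analysis is conducted at genus level);
* :func:`rarefy` -- subsample every sample without replacement to a
  common read depth so that detection limits and richness are
  comparable across samples;
* :func:`relative_abundance` -- convert counts to per-sample fractions.

The detection limit implied by rarefaction to depth ``d`` is one read,
i.e. a relative abundance of ``1/d`` (2.5e-5 at the study depth of
40,000 reads); "not detected" (ND) downstream means zero reads after
rarefaction.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "CountTableError",
    "TaxonomyMap",
    "read_count_table",
    "write_count_table",
    "read_sparse_triplets",
    "write_sparse_triplets",
    "aggregate_to_genus",
    "rarefy",
    "relative_abundance",
    "read_metadata",
    "write_metadata",
    "FEEDS",
    "PHASES",
    "REACTOR_FEEDS",
]

#: Feed conditions a sample can carry in the metadata table.
FEEDS = ("syntho_only", "active_solids", "autoclaved_solids", "inoculum", "influent")

#: The three feed conditions that correspond to operated reactors.
REACTOR_FEEDS = ("syntho_only", "active_solids", "autoclaved_solids")

#: Sampling timepoints: start/end of Phase 1, end of Phase 2, end of Phase 3.
PHASES = ("P1S", "P1F", "P2F", "P3F")


class CountTableError(ValueError):
    """Raised when a count table violates its invariants or cannot be parsed."""


def _find_duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


class CountTable:
    """Non-negative integer feature x sample matrix.

    Parameters
    ----------
    data:
        DataFrame with feature identifiers as index and sample
        identifiers as columns.  Values must be integer-valued and
        non-negative; identifiers must be unique.  Row/column order is
        preserved.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            raise CountTableError("count table requires a pandas DataFrame")
        dup_f = _find_duplicates(map(str, data.index))
        if dup_f:
            raise CountTableError(f"duplicated feature id(s): {dup_f}")
        dup_s = _find_duplicates(map(str, data.columns))
        if dup_s:
            raise CountTableError(f"duplicated sample id(s): {dup_s}")
        arr = data.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise CountTableError("count table contains non-numeric values")
        if arr.size:
            if np.isnan(arr.astype(float)).any():
                raise CountTableError("count table contains missing values")
            if (arr < 0).any():
                r, c = np.argwhere(arr < 0)[0]
                raise CountTableError(
                    f"negative count at feature {data.index[r]!r}, sample {data.columns[c]!r}"
                )
            if np.any(arr.astype(float) % 1 != 0):
                r, c = np.argwhere(arr.astype(float) % 1 != 0)[0]
                raise CountTableError(
                    f"non-integer count at feature {data.index[r]!r}, sample {data.columns[c]!r}"
                )
        self.data = data.astype(np.int64)
        self.data.index = self.data.index.map(str)
        self.data.columns = self.data.columns.map(str)
        self.data.index.name = "feature_id"

    # -- convenience ---------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def column_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise CountTableError(f"unknown sample id(s): {missing}")
        return CountTable(self.data.loc[:, list(sample_ids)])

    def drop_empty_features(self) -> "CountTable":
        keep = self.data.sum(axis=1) > 0
        return CountTable(self.data.loc[keep])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountTable) and self.data.equals(other.data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        nf, ns = self.shape
        return f"CountTable({nf} features x {ns} samples)"


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_count_table(path) -> CountTable:
    """Read a tab-separated count table.

    First column holds feature ids, header row holds sample ids; ``#``
    lines are skipped.  Malformed, negative or non-integer cells raise
    :class:`CountTableError` naming the offending row and column.
    """
    header: list[str] | None = None
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            header = line.rstrip("\r\n").split("\t")
            break
    if header is None:
        raise CountTableError(f"{path}: empty count table")
    samples = header[1:]
    dups = _find_duplicates(samples)
    if dups:
        raise CountTableError(f"{path}: duplicated sample header(s): {dups}")

    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    dup_f = _find_duplicates(map(str, df.index))
    if dup_f:
        raise CountTableError(f"{path}: duplicated feature id(s): {dup_f}")

    numeric = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise CountTableError(
                f"{path}: unparseable count at feature {row!r}, sample {col!r}"
            )
        neg = vals < 0
        if neg.any():
            row = df.index[neg.to_numpy().nonzero()[0][0]]
            raise CountTableError(
                f"{path}: negative count at feature {row!r}, sample {col!r}"
            )
        frac = vals % 1 != 0
        if frac.any():
            row = df.index[frac.to_numpy().nonzero()[0][0]]
            raise CountTableError(
                f"{path}: non-integer count at feature {row!r}, sample {col!r}"
            )
        numeric[col] = vals.astype(np.int64)
    out = pd.DataFrame(numeric, index=df.index.map(str))
    out = out.loc[:, samples] if samples else out
    return CountTable(out)


def write_count_table(table: CountTable, path, provenance: Sequence[str] | None = None) -> None:
    """Write ``table`` as canonical TSV.

    ``provenance`` lines, if given, are written first as ``#`` comments
    (skipped by :func:`read_count_table`); without them the output is
    the canonical byte representation, so write/read round trips are
    idempotent.
    """
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        for line in provenance or ():
            fh.write(f"# {line}\n")
        table.data.to_csv(fh, sep="\t", index_label="feature_id", lineterminator="\n")


def write_sparse_triplets(table: CountTable, path, provenance: Sequence[str] | None = None) -> None:
    """Export non-zero cells as ``feature_id  sample_id  count`` triplets.

    Interoperability format only (BIOM-style sparse triplets); all-zero
    rows and columns are not representable, so TSV remains the source
    of truth.
    """
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        for line in provenance or ():
            fh.write(f"# {line}\n")
        fh.write("feature_id\tsample_id\tcount\n")
        arr = table.data.to_numpy()
        rows, cols = np.nonzero(arr)
        for r, c in zip(rows, cols):
            fh.write(f"{table.data.index[r]}\t{table.data.columns[c]}\t{arr[r, c]}\n")


def read_sparse_triplets(path) -> CountTable:
    """Read a sparse-triplet export back into a dense :class:`CountTable`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"feature_id": str, "sample_id": str})
    for col in ("feature_id", "sample_id", "count"):
        if col not in df.columns:
            raise CountTableError(f"{path}: missing column {col!r}")
    dense = df.pivot_table(
        index="feature_id", columns="sample_id", values="count", fill_value=0, sort=False
    )
    dense.columns.name = None
    return CountTable(dense)


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

class TaxonomyMap:
    """Feature id -> lineage map with a genus accessor.

    A lineage is an ordered tuple of rank labels
    (domain, phylum, class, order, family, genus).  Features that are
    unclassified at genus rank get a synthesized placeholder
    ``UC_<lowest classified rank>`` ("UC" = uncultured), so every
    feature always maps to a non-empty genus label.
    """

    #: genus is the 6th rank of a lineage
    GENUS_RANK = 5

    def __init__(self, lineages: Mapping[str, Sequence[str]]):
        self._lineages: dict[str, tuple[str, ...]] = {}
        for fid, ranks in lineages.items():
            ranks = tuple(str(r).strip() for r in ranks)
            if not any(ranks):
                raise CountTableError(f"feature {fid!r} has an empty lineage")
            self._lineages[str(fid)] = ranks

    def __contains__(self, fid: str) -> bool:
        return fid in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    def lineage(self, fid: str) -> tuple[str, ...]:
        return self._lineages[fid]

    def genus(self, fid: str) -> str:
        ranks = self._lineages[fid]
        if len(ranks) > self.GENUS_RANK and ranks[self.GENUS_RANK]:
            return ranks[self.GENUS_RANK]
        lowest = [r for r in ranks if r][-1]
        return f"UC_{lowest}"

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyMap":
        """Read a two-column TSV: feature_id, semicolon-delimited lineage."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if df.shape[1] < 2:
            raise CountTableError(f"{path}: taxonomy file needs two columns")
        fid_col, lin_col = df.columns[:2]
        lineages = {
            str(row[fid_col]): tuple(str(row[lin_col]).split(";"))
            for _, row in df.iterrows()
        }
        return cls(lineages)

    def to_tsv(self, path, provenance: Sequence[str] | None = None) -> None:
        with open(path, "wt", encoding="utf-8", newline="") as fh:
            for line in provenance or ():
                fh.write(f"# {line}\n")
            fh.write("feature_id\tlineage\n")
            for fid, ranks in self._lineages.items():
                fh.write(f"{fid}\t{';'.join(ranks)}\n")


def aggregate_to_genus(table: CountTable, taxonomy: TaxonomyMap) -> CountTable:
    """Collapse ASV rows to genus rows by summing member counts.

    Output features are the distinct genus labels in order of first
    appearance; per-sample column sums are conserved exactly.  Features
    missing from ``taxonomy`` raise an error listing them all.
    """
    missing = [f for f in table.feature_ids if f not in taxonomy]
    if missing:
        raise CountTableError(f"features missing from taxonomy: {missing}")
    genera = pd.Series(
        [taxonomy.genus(f) for f in table.feature_ids], index=table.data.index
    )
    agg = table.data.groupby(genera, sort=False).sum()
    agg.index.name = "feature_id"
    return CountTable(agg)


# ---------------------------------------------------------------------------
# rarefaction / normalisation
# ---------------------------------------------------------------------------

def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each retained sample's reads are drawn by multivariate
    hypergeometric sampling, so no cell can exceed its input count and
    every retained column sums to ``depth`` exactly.  Samples with
    fewer than ``depth`` total reads are dropped and reported through
    ``warnings.warn``.  Deterministic for a given ``seed`` (samples are
    processed in column order).
    """
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for sid in table.sample_ids:
        col = table.data[sid].to_numpy()
        total = int(col.sum())
        if total < depth:
            dropped.append(sid)
            continue
        if total == depth:
            cols[sid] = col
        else:
            cols[sid] = rng.multivariate_hypergeometric(col, depth)
    if dropped:
        warnings.warn(
            f"rarefy: dropped {len(dropped)} sample(s) with fewer than "
            f"{depth} reads: {dropped}",
            UserWarning,
            stacklevel=2,
        )
    out = pd.DataFrame(cols, index=table.data.index)
    return CountTable(out)


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Convert counts to per-sample fractions (each column sums to 1)."""
    sums = table.column_sums()
    zero = sums[sums == 0]
    if len(zero):
        raise CountTableError(f"zero-sum sample(s): {list(zero.index)}")
    return table.data / sums


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

_META_COLUMNS = ("sample_id", "set", "block", "feed", "phase", "replicate")


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV.

    Columns: sample_id, set, block, feed, phase, replicate.  ``feed``
    and ``phase`` are validated against the controlled vocabularies;
    influent/inoculum samples may leave block and replicate empty.
    Returns a DataFrame indexed by sample_id.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise CountTableError(f"{path}: metadata missing column(s) {missing}")
    dups = _find_duplicates(df["sample_id"])
    if dups:
        raise CountTableError(f"{path}: duplicated sample id(s) in metadata: {dups}")
    bad_feed = sorted(set(df["feed"]) - set(FEEDS))
    if bad_feed:
        raise CountTableError(f"{path}: unknown feed value(s) {bad_feed}")
    bad_phase = sorted(set(df["phase"]) - set(PHASES))
    if bad_phase:
        raise CountTableError(f"{path}: unknown phase value(s) {bad_phase}")
    reactors = df["feed"].isin(REACTOR_FEEDS)
    if (df.loc[reactors, "block"] == "").any():
        bad = df.loc[reactors & (df["block"] == ""), "sample_id"].tolist()
        raise CountTableError(f"{path}: reactor sample(s) missing block: {bad}")
    return df.set_index("sample_id")


def write_metadata(meta: pd.DataFrame, path, provenance: Sequence[str] | None = None) -> None:
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        for line in provenance or ():
            fh.write(f"# {line}\n")
        meta.to_csv(fh, sep="\t", index_label="sample_id", lineterminator="\n")
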