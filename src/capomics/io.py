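"""Tabular input/output shared by all pipeline stages.

Intensity matrices are features x samples delimited text; sample metadata is a
CSV with one row per sample; gene sets use the standard GMT format. All readers
accept gzip-compressed files transparently.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("CON", "NS_CAP", "S_CAP")
COHORTS = ("train", "validation")
ANNOTATION_FLAGS = frozenset({"immunity", "infection", "death_related"})

DEFAULT_NA_SENTINELS = ("", "NA", "NaN", "nan")


class OmicsIOError(ValueError):
    """Raised when an input table violates its invariants."""


@dataclass
class IntensityTable:
    """A features x samples matrix of positive intensities with missing cells.

    Parameters
    ----------
    layer : str
        Omics layer name (e.g. ``"protein"`` or ``"metabolite"``).
    values : pandas.DataFrame
        Rows indexed by feature id, columns by sample id; missing cells are
        NaN; all present values must be strictly positive.
    """

    layer: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        dup_f = idx[idx.duplicated()].unique()
        if len(dup_f):
            raise OmicsIOError(
                f"duplicate feature id(s) in layer {self.layer!r}: {list(map(str, dup_f))}"
            )
        dup_s = cols[cols.duplicated()].unique()
        if len(dup_s):
            raise OmicsIOError(f"duplicate sample id(s): {list(map(str, dup_s))}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            # locate the offending cell for a useful message
            for j, c in enumerate(cols):
                col = self.values.iloc[:, j]
                bad = col[~col.map(lambda v: isinstance(v, (int, float)) or pd.isna(v))]
                if len(bad):
                    raise OmicsIOError(
                        f"non-numeric cell at feature {bad.index[0]!r}, sample {c!r}: {bad.iloc[0]!r}"
                    )
            raise OmicsIOError("non-numeric values in intensity table")
        nonpos = np.asarray((arr <= 0) & ~np.isnan(arr)).nonzero()
        if len(nonpos[0]):
            i, j = nonpos[0][0], nonpos[1][0]
            raise OmicsIOError(
                f"non-positive intensity {arr[i, j]!r} at feature {idx[i]!r}, sample {cols[j]!r}"
            )

    # -- properties ------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    # -- io --------------------------------------------------------------
    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        layer: str,
        na_sentinels: Sequence[str] = DEFAULT_NA_SENTINELS,
    ) -> "IntensityTable":
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=list(na_sentinels),
            keep_default_na=False,
            compression="infer",
        )
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        # coerce object columns so the validator can name the bad cell
        for c in df.columns:
            if df[c].dtype == object:
                coerced = pd.to_numeric(df[c], errors="coerce")
                bad = df[c][coerced.isna() & df[c].notna()]
                if len(bad):
                    raise OmicsIOError(
                        f"non-numeric cell at feature {bad.index[0]!r}, "
                        f"sample {c!r}: {bad.iloc[0]!r}"
                    )
                df[c] = coerced
        return cls(layer=layer, values=df.astype(float))

    def to_tsv(self, path: str | Path, na_rep: str = "NA") -> None:
        self.values.to_csv(path, sep="\t", na_rep=na_rep)

    # -- transforms ------------------------------------------------------
    def total_intensity_scaled(self) -> "IntensityTable":
        """Scale each sample to the median total intensity (optional step)."""
        totals = self.values.sum(axis=0, skipna=True)
        target = float(np.median(totals))
        return IntensityTable(self.layer, self.values * (target / totals))


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-metadata invariants and return the frame unchanged."""
    for col in ("sample_id", "group", "cohort"):
        if col not in meta.columns:
            raise OmicsIOError(f"metadata missing required column {col!r}")
    dup = meta["sample_id"][meta["sample_id"].duplicated()]
    if len(dup):
        raise OmicsIOError(f"duplicate sample id(s) in metadata: {list(dup)}")
    bad_g = set(meta["group"]) - set(GROUPS)
    if bad_g:
        raise OmicsIOError(f"unknown group label(s): {sorted(bad_g)}; allowed: {GROUPS}")
    bad_c = set(meta["cohort"]) - set(COHORTS)
    if bad_c:
        raise OmicsIOError(f"unknown cohort label(s): {sorted(bad_c)}; allowed: {COHORTS}")
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, compression="infer")
    meta["sample_id"] = meta["sample_id"].astype(str)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(meta).to_csv(path, index=False)


def align(
    table: IntensityTable,
    metadata: pd.DataFrame,
    groups: Iterable[str] | None = None,
    cohort: str | None = None,
) -> IntensityTable:
    """Restrict and order a table's columns to a metadata subset.

    Columns follow metadata row order, so repeated alignment is idempotent
    and order-stable. Raises on samples absent from the metadata and on an
    empty selection.
    """
    validate_metadata(metadata)
    known = set(metadata["sample_id"])
    missing = [s for s in table.sample_ids if s not in known]
    if missing:
        raise OmicsIOError(f"sample(s) missing from metadata: {missing}")
    sel = metadata
    if groups is not None:
        sel = sel[sel["group"].isin(list(groups))]
    if cohort is not None:
        sel = sel[sel["cohort"] == cohort]
    ids = [s for s in sel["sample_id"] if s in set(table.sample_ids)]
    if not ids:
        raise OmicsIOError("empty selection: no samples match the requested subset")
    return IntensityTable(table.layer, table.values.loc[:, ids])


@dataclass
class GeneSetCollection:
    """Named feature sets: set name -> (description, unique member ids)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise OmicsIOError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return _io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name TAB description TAB member ids.

    Duplicate members within a line are deduplicated (set semantics); two
    lines sharing a name make the collection ambiguous and are rejected.
    """
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise OmicsIOError(f"GMT line {lineno}: expected >= 3 fields, got {len(fields)}")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise OmicsIOError(f"GMT line {lineno}: duplicate set name {name!r}")
            members = tuple(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise OmicsIOError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read feature annotations: feature_id, display_name, flags.

    ``flags`` is a semicolon-separated subset of
    ``{immunity, infection, death_related}``.
    """
    df = pd.read_csv(path, sep="\t", compression="infer", dtype=str).fillna("")
    for col in ("feature_id", "display_name", "flags"):
        if col not in df.columns:
            raise OmicsIOError(f"annotation file missing column {col!r}")
    parsed = []
    for _, row in df.iterrows():
        flags = frozenset(f for f in row["flags"].split(";") if f)
        bad = flags - ANNOTATION_FLAGS
        if bad:
            raise OmicsIOError(
                f"feature {row['feature_id']!r}: unknown flag(s) {sorted(bad)}; "
                f"allowed: {sorted(ANNOTATION_FLAGS)}"
            )
        parsed.append(flags)
    out = df[["feature_id", "display_name"]].copy()
    out["flags"] = parsed
    return out
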