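"""Reading, validation and serialization of community tables and result records.

The universal input is a taxa-by-sample matrix of non-negative integer counts
(:class:`CommunityTable`) plus a sample-to-group mapping. All downstream
stages consume this type; transforms shared by several stages (relative
abundance, top-N filtering) live here as well.

File conventions: tab-separated, UTF-8, ``.`` decimal, no quoting of ids;
the first header cell of a count table is ignored. Result records serialize
to JSON (any record) or TSV (per-OTU records) with a schema-version key and
round-trip all floats losslessly.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

#: registry used by :func:`write_results` / :func:`read_results`
_RESULT_REGISTRY: dict[str, type] = {}


class TableValidationError(ValueError):
    """A community table or metadata file violates a structural invariant."""


def register_result(cls):
    """Class decorator marking a dataclass as a serializable result record."""
    _RESULT_REGISTRY[cls.__name__] = cls
    return cls


@dataclass(frozen=True)
class CommunityTable:
    """Taxa-by-sample count matrix with group labels.

    Parameters
    ----------
    counts : ndarray of shape (n_otus, n_samples)
        Non-negative integer counts.
    otu_ids, sample_ids : sequence of str
        Unique row / column identifiers.
    groups : mapping of sample_id -> group label
        Must cover every sample.
    """

    counts: np.ndarray
    otu_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    groups: Mapping[str, str]

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise TableValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise TableValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "otu_ids", tuple(str(o) for o in self.otu_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "groups", dict(self.groups))
        self._validate()

    def _validate(self):
        n_otus, n_samples = self.counts.shape
        if len(self.otu_ids) != n_otus or len(self.sample_ids) != n_samples:
            raise TableValidationError(
                f"id lengths ({len(self.otu_ids)}, {len(self.sample_ids)}) do not "
                f"match counts shape {self.counts.shape}"
            )
        if n_otus < 2 or n_samples < 2:
            raise TableValidationError("need at least 2 OTUs and 2 samples")
        if len(set(self.otu_ids)) != n_otus:
            dupes = {o for o in self.otu_ids if self.otu_ids.count(o) > 1}
            raise TableValidationError(f"duplicate OTU ids: {sorted(dupes)}")
        if len(set(self.sample_ids)) != n_samples:
            dupes = {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            raise TableValidationError(f"duplicate sample ids: {sorted(dupes)}")
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise TableValidationError(
                f"negative count at OTU {self.otu_ids[i]!r}, sample "
                f"{self.sample_ids[j]!r}"
            )
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise TableValidationError(f"samples missing a group label: {missing}")
        zero = [s for s, t in zip(self.sample_ids, self.counts.sum(axis=0)) if t == 0]
        if zero:
            raise TableValidationError(f"samples with zero library size: {zero}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, CommunityTable):
            return NotImplemented
        return (
            self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and self.groups == other.groups
            and np.array_equal(self.counts, other.counts)
        )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def group_labels(self) -> tuple[str, ...]:
        """Distinct group labels in first-appearance order over samples."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.groups[s], None)
        return tuple(seen)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    def subset(
        self,
        otus: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
        drop_empty_samples: bool = False,
    ) -> "CommunityTable":
        """Restrict to the given OTUs and/or samples (order preserved as given).

        With ``drop_empty_samples`` samples whose restricted library size is
        zero are removed instead of failing validation.
        """
        otus = list(self.otu_ids) if otus is None else list(otus)
        samples = list(self.sample_ids) if samples is None else list(samples)
        unknown = [o for o in otus if o not in set(self.otu_ids)]
        if unknown:
            raise KeyError(f"unknown OTU ids: {unknown}")
        unknown = [s for s in samples if s not in set(self.sample_ids)]
        if unknown:
            raise KeyError(f"unknown sample ids: {unknown}")
        ridx = [self.otu_ids.index(o) for o in otus]
        cidx = [self.sample_ids.index(s) for s in samples]
        counts = self.counts[np.ix_(ridx, cidx)]
        if drop_empty_samples:
            keep = counts.sum(axis=0) > 0
            counts = counts[:, keep]
            samples = [s for s, k in zip(samples, keep) if k]
        return CommunityTable(
            counts=counts,
            otu_ids=tuple(otus),
            sample_ids=tuple(samples),
            groups={s: self.groups[s] for s in samples},
        )

    def group_table(self, group: str, drop_absent_otus: bool = True) -> "CommunityTable":
        """Samples of one group; OTUs absent from every sample of the group
        are dropped by default (they carry no information in group-restricted
        computations)."""
        samples = self.samples_in_group(group)
        if not samples:
            raise KeyError(f"unknown group: {group!r}")
        sub = self.subset(samples=samples)
        if drop_absent_otus:
            keep = [o for o, t in zip(sub.otu_ids, sub.counts.sum(axis=1)) if t > 0]
            sub = sub.subset(otus=keep)
        return sub


@dataclass(frozen=True)
class RelativeAbundanceTable:
    """Proportional abundances with the same ids/groups as the source table.

    ``axis`` records the normalization: ``per_sample`` columns sum to 1,
    ``per_otu`` rows sum to 1.
    """

    proportions: np.ndarray
    otu_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    groups: Mapping[str, str]
    axis: str = "per_sample"

    def __post_init__(self):
        props = np.asarray(self.proportions, dtype=float)
        object.__setattr__(self, "proportions", props)
        object.__setattr__(self, "otu_ids", tuple(self.otu_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if (props < 0).any() or (props > 1 + 1e-9).any():
            raise TableValidationError("proportions must lie in [0, 1]")
        sums = props.sum(axis=0 if self.axis == "per_sample" else 1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise TableValidationError(f"{self.axis} sums deviate from 1: {sums}")


@dataclass(frozen=True)
class Taxonomy:
    """Ranked lineage labels per OTU; missing ranks are None."""

    lineages: Mapping[str, tuple[str | None, ...]]
    ranks: tuple[str, ...] = (
        "domain", "phylum", "class", "order", "family", "genus",
    )

    def validate_against(self, table: CommunityTable) -> None:
        extra = set(self.lineages) - set(table.otu_ids)
        if extra:
            raise TableValidationError(
                f"taxonomy contains OTUs not in the table: {sorted(extra)[:5]}"
            )


# -- readers -------------------------------------------------------------------


def read_community_table(path: str | Path, metadata_path: str | Path) -> CommunityTable:
    """Read a taxa-by-sample TSV plus a ``sample_id<TAB>group`` metadata TSV.

    The count table's header row holds sample ids (first cell ignored) and the
    first column holds OTU ids. Samples absent from the metadata are rejected.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message is informative
        raise TableValidationError(f"cannot parse count table {path}: {exc}") from exc
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise TableValidationError(
                f"metadata {metadata_path} lacks required column {col!r}"
            )
    groups = dict(zip(meta["sample_id"], meta["group"]))

    values = np.empty(df.shape, dtype=np.int64)
    for i, (otu, row) in enumerate(df.iterrows()):
        for j, raw in enumerate(row):
            try:
                v = float(raw)
            except (TypeError, ValueError):
                raise TableValidationError(
                    f"non-numeric count {raw!r} at OTU {otu!r}, sample "
                    f"{df.columns[j]!r}"
                ) from None
            if v < 0:
                raise TableValidationError(
                    f"negative count {raw} at OTU {otu!r}, sample {df.columns[j]!r}"
                )
            if v != int(v):
                raise TableValidationError(
                    f"non-integer count {raw} at OTU {otu!r}, sample "
                    f"{df.columns[j]!r}"
                )
            values[i, j] = int(v)

    unmapped = [s for s in df.columns if s not in groups]
    if unmapped:
        raise TableValidationError(f"samples absent from metadata: {unmapped}")
    return CommunityTable(
        counts=values,
        otu_ids=tuple(df.index),
        sample_ids=tuple(df.columns),
        groups={s: groups[s] for s in df.columns},
    )


def write_community_table(
    table: CommunityTable, path: str | Path, metadata_path: str | Path
) -> None:
    """Inverse of :func:`read_community_table` (identity on round-trip)."""
    df = pd.DataFrame(table.counts, index=table.otu_ids, columns=table.sample_ids)
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")
    meta = pd.DataFrame(
        {"sample_id": table.sample_ids, "group": [table.groups[s] for s in table.sample_ids]}
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> Taxonomy:
    """Read an ``otu_id<TAB>rank1;rank2;...`` lineage TSV."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    lineages = {}
    for _, row in df.iterrows():
        parts = [p.strip() or None for p in str(row.iloc[1]).split(";")]
        lineages[row.iloc[0]] = tuple(parts)
    return Taxonomy(lineages=lineages)


# -- transforms ----------------------------------------------------------------


def to_relative_abundance(
    table: CommunityTable, axis: str = "per_sample"
) -> RelativeAbundanceTable:
    """Normalize counts to proportions.

    ``per_sample``: each column sums to 1 (library sizes must be positive).
    ``per_otu``: each row sums to 1; rows with zero total are dropped with a
    warning.
    """
    if axis not in ("per_sample", "per_otu"):
        raise ValueError(f"unknown axis {axis!r}")
    counts = table.counts.astype(float)
    if axis == "per_sample":
        totals = counts.sum(axis=0)
        if (totals == 0).any():
            bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
            raise TableValidationError(f"all-zero sample columns: {bad}")
        return RelativeAbundanceTable(
            proportions=counts / totals,
            otu_ids=table.otu_ids,
            sample_ids=table.sample_ids,
            groups=table.groups,
            axis="per_sample",
        )
    totals = counts.sum(axis=1)
    dropped = [o for o, t in zip(table.otu_ids, totals) if t == 0]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} all-zero OTU rows from per-OTU "
            f"normalization: {dropped[:5]}",
            stacklevel=2,
        )
    keep = totals > 0
    return RelativeAbundanceTable(
        proportions=counts[keep] / totals[keep, None],
        otu_ids=tuple(o for o, k in zip(table.otu_ids, keep) if k),
        sample_ids=table.sample_ids,
        groups=table.groups,
        axis="per_otu",
    )


def filter_top_n(table: CommunityTable, n: int) -> CommunityTable:
    """Keep the ``n`` OTUs with the largest total counts.

    Ties are broken by lexicographic otu_id for cross-platform
    reproducibility. If fewer than ``n`` OTUs exist, all are kept with a
    warning.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if table.n_otus <= n:
        if table.n_otus < n:
            warnings.warn(
                f"requested top {n} of only {table.n_otus} OTUs; keeping all",
                stacklevel=2,
            )
        return table
    totals = table.counts.sum(axis=1)
    order = sorted(range(table.n_otus), key=lambda i: (-totals[i], table.otu_ids[i]))
    chosen = sorted(order[:n])  # preserve original row order
    return table.subset(otus=[table.otu_ids[i] for i in chosen])


# -- result serialization ------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def result_to_dict(record) -> dict:
    """Dataclass result -> plain JSON-safe dict with schema/type keys."""
    cls = type(record)
    if cls.__name__ not in _RESULT_REGISTRY:
        raise TypeError(f"{cls.__name__} is not a registered result type")
    payload = _jsonable(dataclasses.asdict(record))
    return {"schema_version": SCHEMA_VERSION, "record_type": cls.__name__, **payload}


def result_from_dict(data: dict):
    name = data.get("record_type")
    if name not in _RESULT_REGISTRY:
        raise TypeError(f"unknown record type {name!r}")
    cls = _RESULT_REGISTRY[name]
    kwargs = {
        f.name: data[f.name] for f in dataclasses.fields(cls) if f.name in data
    }
    return cls(**kwargs)


def write_results(record, path: str | Path, format: str = "JSON") -> None:
    """Serialize a result record to ``path``.

    JSON works for every registered record type and round-trips all numerics
    at full float precision. TSV is available for per-OTU records
    (GuildClassification) whose natural shape is one row per OTU.
    """
    fmt = format.upper()
    path = Path(path)
    if fmt == "JSON":
        payload = result_to_dict(record)
        path.write_text(json.dumps(payload, indent=1))
        return
    if fmt == "TSV":
        frame = _result_to_frame(record)
        frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
        return
    raise ValueError(f"unknown format {format!r}")


def read_results(path: str | Path):
    """Read back a JSON result written by :func:`write_results`."""
    data = json.loads(Path(path).read_text())
    if data.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported schema version {data.get('schema_version')!r}"
        )
    return result_from_dict(data)


def _result_to_frame(record) -> pd.DataFrame:
    cls_name = type(record).__name__
    if cls_name not in _RESULT_REGISTRY:
        raise TypeError(f"{cls_name} is not a registered result type")
    if cls_name == "GuildClassification":
        return pd.DataFrame(
            {
                "otu_id": list(record.otu_ids),
                "B_obs": list(record.b_obs),
                "low_ci": list(record.low_ci),
                "upp_ci": list(record.upp_ci),
                "guild": list(record.guild),
            }
        )
    raise TypeError(f"no TSV schema defined for {cls_name}; use JSON")
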