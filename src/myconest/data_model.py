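"""Core data types and I/O for OTU count tables and paired sampling designs.

Matrix orientation is fixed everywhere: rows are OTUs, columns are samples.
All tabular files are tab-separated UTF-8 with a header row and no quoting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "CountTable",
    "SampleMetadata",
    "PairedDesign",
    "TREATMENTS",
    "HABITATS",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "standardize_depth",
    "combine_paired",
    "presence_absence",
]

TREATMENTS = ("intact", "disturbed")
HABITATS = ("grassland", "gully", "slope")

#: metadata columns that must be present in every metadata TSV
REQUIRED_METADATA_COLUMNS = (
    "sample_id",
    "plant_id",
    "treatment",
    "habitat",
    "elevation",
    "collection_year",
)

#: optional numeric covariates recognised as first-class fields
SOIL_COLUMNS = (
    "colony_diameter",
    "ph",
    "truog_p",
    "ca",
    "mg",
    "k",
    "cec",
    "nh3_n",
    "no3_n",
    "total_n",
)


class DataError(ValueError):
    """Raised for malformed input files or invariant violations."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise DataError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class CountTable:
    """Non-negative integer OTU-by-sample matrix with ordered unique ids.

    Parameters
    ----------
    otu_ids : sequence of str
        Row labels, unique, order preserved.
    sample_ids : sequence of str
        Column labels, unique, order preserved.
    counts : ndarray of shape (n_otus, n_samples)
        Non-negative integers.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.otu_ids = [str(i) for i in self.otu_ids]
        self.sample_ids = [str(i) for i in self.sample_ids]
        _check_unique(self.otu_ids, "OTU")
        _check_unique(self.sample_ids, "sample")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise DataError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            frac, _ = np.modf(counts.astype(float))
            if np.any(frac != 0) or np.any(~np.isfinite(counts.astype(float))):
                r, c = np.argwhere((frac != 0) | ~np.isfinite(counts.astype(float)))[0]
                raise DataError(
                    f"non-integer count {counts[r, c]!r} at OTU {self.otu_ids[r]!r}, "
                    f"sample {self.sample_ids[c]!r}"
                )
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            r, c = np.argwhere(counts < 0)[0]
            raise DataError(
                f"negative count {counts[r, c]} at OTU {self.otu_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )
        self.counts = counts.astype(np.int64)

    # -- convenience -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise DataError(f"unknown sample id: {sample_id!r}") from None

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample_id)]

    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return CountTable(list(self.otu_ids), list(sample_ids), self.counts[:, idx].copy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SampleMetadata:
    """Per-sample design factors and environmental covariates."""

    sample_id: str
    plant_id: str
    treatment: str
    habitat: str
    elevation: float
    collection_year: int
    colony_diameter: float | None = None
    ph: float | None = None
    truog_p: float | None = None
    ca: float | None = None
    mg: float | None = None
    k: float | None = None
    cec: float | None = None
    nh3_n: float | None = None
    no3_n: float | None = None
    total_n: float | None = None
    extras: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise DataError(
                f"sample {self.sample_id!r}: treatment {self.treatment!r} "
                f"not in {TREATMENTS}"
            )
        if self.habitat not in HABITATS:
            raise DataError(
                f"sample {self.sample_id!r}: habitat {self.habitat!r} not in {HABITATS}"
            )
        self.elevation = float(self.elevation)
        if not np.isfinite(self.elevation):
            raise DataError(f"sample {self.sample_id!r}: elevation must be finite")
        self.collection_year = int(self.collection_year)

    def numeric_factors(self) -> dict[str, float]:
        """All finite numeric covariates, named, for correlation/Mantel sweeps."""
        out: dict[str, float] = {"elevation": self.elevation}
        for name in SOIL_COLUMNS:
            v = getattr(self, name)
            if v is not None and np.isfinite(v):
                out[name] = float(v)
        for name, v in self.extras.items():
            try:
                fv = float(v)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                continue
            if np.isfinite(fv):
                out[name] = fv
        return out


@dataclass
class PairedDesign:
    """Mapping plant_id -> (intact_sample_id, disturbed_sample_id)."""

    pairs: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for plant, pair in self.pairs.items():
            if len(pair) != 2:
                raise DataError(f"plant {plant!r}: pair must have exactly two samples")
            for s in pair:
                if s in seen:
                    raise DataError(f"sample {s!r} appears in more than one pair")
                seen.add(s)

    @property
    def plant_ids(self) -> list[str]:
        return list(self.pairs)

    @property
    def sample_ids(self) -> list[str]:
        out = []
        for i, d in self.pairs.values():
            out.extend((i, d))
        return out

    def intact_ids(self) -> list[str]:
        return [i for i, _ in self.pairs.values()]

    def disturbed_ids(self) -> list[str]:
        return [d for _, d in self.pairs.values()]

    @classmethod
    def from_metadata(cls, metadata: Iterable[SampleMetadata]) -> "PairedDesign":
        """Build the design by grouping samples on plant_id.

        Requires exactly one intact and one disturbed sample per plant; pair
        members must agree on habitat and elevation.
        """
        by_plant: dict[str, dict[str, SampleMetadata]] = {}
        for m in metadata:
            slot = by_plant.setdefault(m.plant_id, {})
            if m.treatment in slot:
                raise DataError(
                    f"plant {m.plant_id!r} has more than one {m.treatment} sample"
                )
            slot[m.treatment] = m
        pairs: dict[str, tuple[str, str]] = {}
        for plant, slot in by_plant.items():
            if set(slot) != set(TREATMENTS):
                missing = set(TREATMENTS) - set(slot)
                raise DataError(f"plant {plant!r} is missing treatment(s): {sorted(missing)}")
            i, d = slot["intact"], slot["disturbed"]
            if i.habitat != d.habitat or i.elevation != d.elevation:
                raise DataError(
                    f"plant {plant!r}: paired samples disagree on habitat/elevation"
                )
            pairs[plant] = (i.sample_id, d.sample_id)
        return cls(pairs)

    def validate_against(self, metadata: Iterable[SampleMetadata]) -> None:
        known = {m.sample_id for m in metadata}
        for plant, pair in self.pairs.items():
            for s in pair:
                if s not in known:
                    raise DataError(f"plant {plant!r} references unknown sample {s!r}")


# ---------------------------------------------------------------------------
# count-table I/O
# ---------------------------------------------------------------------------


def read_count_table(path: str | Path, format: str = "tsv") -> CountTable:
    """Read an OTU x sample count table from TSV or BIOM-style JSON.

    TSV layout: first column OTU ids, header row sample ids. Input row and
    column order are preserved. Negative, non-integer, or non-numeric cells
    raise :class:`DataError` naming the offending OTU and sample.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        otu_ids = [str(i) for i in df.index]
        sample_ids = [str(c) for c in df.columns]
        _check_unique(otu_ids, "OTU")
        _check_unique(sample_ids, "sample")
        counts = np.zeros(df.shape, dtype=np.int64)
        raw = df.to_numpy()
        for r in range(df.shape[0]):
            for c in range(df.shape[1]):
                cell = raw[r, c]
                try:
                    v = int(str(cell))
                except (TypeError, ValueError):
                    raise DataError(
                        f"{path}: non-integer count {cell!r} at OTU {otu_ids[r]!r}, "
                        f"sample {sample_ids[c]!r}"
                    ) from None
                if v < 0:
                    raise DataError(
                        f"{path}: negative count {v} at OTU {otu_ids[r]!r}, "
                        f"sample {sample_ids[c]!r}"
                    )
                counts[r, c] = v
        return CountTable(otu_ids, sample_ids, counts)
    if format == "biom_json":
        with open(path) as fh:
            doc = json.load(fh)
        otu_ids = [str(row["id"]) for row in doc["rows"]]
        sample_ids = [str(col["id"]) for col in doc["columns"]]
        _check_unique(otu_ids, "OTU")
        _check_unique(sample_ids, "sample")
        counts = np.zeros((len(otu_ids), len(sample_ids)), dtype=np.int64)
        if doc.get("matrix_type", "sparse") == "dense":
            data = np.asarray(doc["data"])
            for r in range(data.shape[0]):
                for c in range(data.shape[1]):
                    counts[r, c] = _int_cell(data[r, c], otu_ids[r], sample_ids[c], path)
        else:
            for r, c, v in doc["data"]:
                counts[int(r), int(c)] = _int_cell(v, otu_ids[int(r)], sample_ids[int(c)], path)
        return CountTable(otu_ids, sample_ids, counts)
    raise DataError(f"unknown count-table format: {format!r}")


def _int_cell(v: object, otu: str, sample: str, path: Path) -> int:
    fv = float(v)  # type: ignore[arg-type]
    if not fv.is_integer():
        raise DataError(f"{path}: non-integer count {v!r} at OTU {otu!r}, sample {sample!r}")
    iv = int(fv)
    if iv < 0:
        raise DataError(f"{path}: negative count {iv} at OTU {otu!r}, sample {sample!r}")
    return iv


def write_count_table(table: CountTable, path: str | Path, format: str = "tsv") -> None:
    """Write a count table in a form :func:`read_count_table` reproduces exactly."""
    path = Path(path)
    if format == "tsv":
        table.to_dataframe().to_csv(path, sep="\t", index_label="otu_id")
        return
    if format == "biom_json":
        rows, cols = np.nonzero(table.counts)
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "type": "OTU table",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": list(table.shape),
            "rows": [{"id": i, "metadata": None} for i in table.otu_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": [
                [int(r), int(c), int(table.counts[r, c])] for r, c in zip(rows, cols)
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
        return
    raise DataError(f"unknown count-table format: {format!r}")


# ---------------------------------------------------------------------------
# metadata I/O
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read sample metadata from TSV; unknown columns are kept in ``extras``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required metadata column(s): {missing}")
    known = set(REQUIRED_METADATA_COLUMNS) | set(SOIL_COLUMNS)
    records: list[SampleMetadata] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        if sid in seen:
            raise DataError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        kwargs: dict[str, object] = {
            "sample_id": sid,
            "plant_id": str(row["plant_id"]),
            "treatment": str(row["treatment"]),
            "habitat": str(row["habitat"]),
            "elevation": float(row["elevation"]),
            "collection_year": int(float(row["collection_year"])),
        }
        for name in SOIL_COLUMNS:
            if name in df.columns and pd.notna(row[name]) and str(row[name]) != "":
                kwargs[name] = float(row[name])
        extras = {
            c: row[c]
            for c in df.columns
            if c not in known and pd.notna(row[c])
        }
        records.append(SampleMetadata(extras=extras, **kwargs))  # type: ignore[arg-type]
    return records


def write_metadata(records: Sequence[SampleMetadata], path: str | Path) -> None:
    rows = []
    for m in records:
        row: dict[str, object] = {
            "sample_id": m.sample_id,
            "plant_id": m.plant_id,
            "treatment": m.treatment,
            "habitat": m.habitat,
            "elevation": m.elevation,
            "collection_year": m.collection_year,
        }
        for name in SOIL_COLUMNS:
            v = getattr(m, name)
            if v is not None:
                row[name] = v
        row.update(m.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------


def standardize_depth(
    table: CountTable,
    depth: int = 10_000,
    seed: int | np.random.Generator | None = None,
    on_shortfall: str = "error",
) -> CountTable:
    """Rarefy every sample to exactly ``depth`` reads without replacement.

    Each column is subsampled by a multivariate hypergeometric draw, so each
    output cell is at most its input cell and every column sums exactly to
    ``depth``. Deterministic given ``seed``.

    Parameters
    ----------
    on_shortfall : {"error", "drop"}
        Samples with fewer than ``depth`` reads abort by default; ``"drop"``
        removes them with a warning instead.
    """
    if depth <= 0:
        raise DataError(f"depth must be positive, got {depth}")
    sums = table.column_sums()
    short = [
        (s, int(n)) for s, n in zip(table.sample_ids, sums) if n < depth
    ]
    keep = list(range(len(table.sample_ids)))
    if short:
        if on_shortfall == "drop":
            import warnings

            for s, n in short:
                warnings.warn(
                    f"dropping sample {s!r}: {n} reads < depth {depth}", stacklevel=2
                )
            short_ids = {s for s, _ in short}
            keep = [i for i, s in enumerate(table.sample_ids) if s not in short_ids]
            if not keep:
                raise DataError(f"all samples fall below depth {depth}")
        elif on_shortfall == "error":
            detail = ", ".join(f"{s!r} ({n} < {depth})" for s, n in short)
            raise DataError(f"sample(s) below target depth: {detail}")
        else:
            raise DataError(f"unknown shortfall policy: {on_shortfall!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.zeros((len(table.otu_ids), len(keep)), dtype=np.int64)
    for j, col_idx in enumerate(keep):
        col = table.counts[:, col_idx]
        out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return CountTable(
        list(table.otu_ids), [table.sample_ids[i] for i in keep], out
    )


def combine_paired(table: CountTable, design: PairedDesign) -> CountTable:
    """Sum the intact and disturbed columns of each pair into one plant column."""
    if not design.pairs:
        raise DataError("empty paired design")
    present = set(table.sample_ids)
    paired: set[str] = set()
    cols = []
    for plant, (i, d) in design.pairs.items():
        for s in (i, d):
            if s not in present:
                raise DataError(f"plant {plant!r}: sample {s!r} not in count table")
            paired.add(s)
        cols.append(table.column(i) + table.column(d))
    orphans = [s for s in table.sample_ids if s not in paired]
    if orphans:
        raise DataError(f"unpaired sample(s) in count table: {orphans}")
    return CountTable(
        list(table.otu_ids), list(design.pairs), np.column_stack(cols)
    )


def presence_absence(table: CountTable) -> CountTable:
    """Binary view: 1 where a count is positive, else 0."""
    return CountTable(
        list(table.otu_ids), list(table.sample_ids), (table.counts > 0).astype(np.int64)
    )
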