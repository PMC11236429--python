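"""Readers, writers and containers for OTU count tables and sample metadata.

Everything downstream operates on two plain containers: :class:`OtuTable`
(samples x OTUs integer counts) and :class:`SampleMetadata` (per-sample land
use, coordinates and soil chemistry).  TSV is the canonical on-disk format;
a BIOM-style export (OTUs as rows, optional trailing taxonomy column) is
accepted via the ``orientation`` flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical metadata column names (soil chemistry measured per sample).
ENV_VARIABLES = ["moisture", "pH", "TP", "TC", "TN", "CN"]

#: Mandatory metadata columns besides the sample-id index.
METADATA_COLUMNS = ["land_use", "lon", "lat"] + ENV_VARIABLES


class FormatError(ValueError):
    """A cell or header in an input file is malformed."""


class ValidationError(ValueError):
    """A structurally valid file violates a container invariant."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} identifiers: {dup}")


@dataclass
class OtuTable:
    """Samples x OTUs non-negative integer count matrix.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers (rows).
    otu_ids : list of str
        Unique OTU identifiers (columns).
    counts : ndarray of shape (n_samples, n_otus)
        Non-negative integer read counts.
    taxonomy : dict, optional
        OTU id -> lineage string.
    """

    sample_ids: list
    otu_ids: list
    counts: np.ndarray
    taxonomy: dict | None = field(default=None)

    def __post_init__(self):
        self.sample_ids = list(map(str, self.sample_ids))
        self.otu_ids = list(map(str, self.otu_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            frac = counts != np.floor(counts)
            if frac.any():
                i, j = np.argwhere(frac)[0]
                raise FormatError(
                    f"non-integer count {counts[i, j]!r} at sample "
                    f"{self.sample_ids[i]!r}, OTU {self.otu_ids[j]!r}"
                )
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count at sample {self.sample_ids[i]!r}, OTU {self.otu_ids[j]!r}"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        self.counts = counts.astype(np.int64, copy=False)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def select_otus(self, otu_ids) -> "OtuTable":
        idx = [self.otu_ids.index(o) for o in otu_ids]
        tax = None
        if self.taxonomy is not None:
            tax = {o: self.taxonomy[o] for o in otu_ids if o in self.taxonomy}
        return OtuTable(self.sample_ids, list(otu_ids), self.counts[:, idx], tax)

    def select_samples(self, sample_ids) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(list(sample_ids), self.otu_ids, self.counts[idx], self.taxonomy)


@dataclass
class SampleMetadata:
    """Per-sample land use, geographic coordinates and soil chemistry."""

    sample_ids: list
    land_use: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    env: pd.DataFrame
    extra: pd.DataFrame | None = None

    def __post_init__(self):
        self.sample_ids = list(map(str, self.sample_ids))
        _check_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        self.land_use = np.asarray(self.land_use, dtype=object)
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        for name, arr in [("land_use", self.land_use), ("lon", self.lon), ("lat", self.lat)]:
            if len(arr) != n:
                raise ValidationError(f"{name} has {len(arr)} entries for {n} samples")
        if np.any(np.abs(self.lat) > 90):
            raise ValidationError("latitude outside [-90, 90]")
        if np.any(np.abs(self.lon) > 180):
            raise ValidationError("longitude outside [-180, 180]")
        self.env = pd.DataFrame(self.env)
        missing = [v for v in ENV_VARIABLES if v not in self.env.columns]
        if missing:
            raise ValidationError(f"missing environmental variables: {missing}")
        self.env = self.env.loc[:, ENV_VARIABLES].astype(float)
        self.env.index = pd.Index(self.sample_ids)
        if not np.isfinite(self.env.to_numpy()).all():
            raise ValidationError("non-finite environmental values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"land_use": self.land_use, "lon": self.lon, "lat": self.lat},
            index=self.sample_ids,
        )
        df = pd.concat([df, self.env], axis=1)
        if self.extra is not None and len(self.extra.columns):
            df = pd.concat([df, self.extra.set_axis(df.index)], axis=1)
        return df

    def select_samples(self, sample_ids) -> "SampleMetadata":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        extra = self.extra.iloc[idx] if self.extra is not None else None
        return SampleMetadata(
            list(sample_ids),
            self.land_use[idx],
            self.lon[idx],
            self.lat[idx],
            self.env.iloc[idx],
            extra,
        )


@dataclass
class DistanceMatrix:
    """Square symmetric pairwise distance or similarity matrix.

    ``kind`` records whether entries are dissimilarities (zero diagonal) or
    similarities (unit diagonal); several tests convert between the two and
    need to know which they hold.
    """

    ids: list
    values: np.ndarray
    kind: str = "dissimilarity"

    def __post_init__(self):
        self.ids = list(map(str, self.ids))
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError(f"matrix shape {v.shape} does not match {n} ids")
        if self.kind not in ("dissimilarity", "similarity"):
            raise ValidationError(f"unknown kind {self.kind!r}")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValidationError("matrix is not symmetric within 1e-12")
        target = 0.0 if self.kind == "dissimilarity" else 1.0
        if n and np.abs(np.diag(v) - target).max() > 0:
            raise ValidationError(f"diagonal must be exactly {target} for {self.kind}")
        if self.kind == "dissimilarity" and v.min(initial=0.0) < 0:
            raise ValidationError("negative dissimilarities")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries in row-major order."""
        i, j = np.tril_indices(self.n, -1)
        return self.values[i, j]

    def to_dissimilarity(self) -> "DistanceMatrix":
        if self.kind == "dissimilarity":
            return self
        logger.info("converting similarity matrix to dissimilarity (1 - s)")
        v = 1.0 - self.values
        np.fill_diagonal(v, 0.0)
        return DistanceMatrix(self.ids, v, "dissimilarity")

    def to_similarity(self) -> "DistanceMatrix":
        if self.kind == "similarity":
            return self
        v = 1.0 - self.values
        np.fill_diagonal(v, 1.0)
        return DistanceMatrix(self.ids, v, "similarity")


# ---------------------------------------------------------------------------
# readers / writers


def read_otu_table(path, orientation: str = "samples_as_rows") -> OtuTable:
    """Read a TSV count table.

    ``orientation='otus_as_rows'`` accepts the common BIOM-style export with
    OTUs as rows and an optional trailing ``taxonomy`` column.
    """
    if orientation not in ("samples_as_rows", "otus_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index = df.index.astype(str)
    taxonomy = None
    if orientation == "otus_as_rows":
        tax_cols = [c for c in df.columns if str(c).lower() == "taxonomy"]
        if tax_cols:
            taxonomy = df[tax_cols[0]].astype(str).to_dict()
            df = df.drop(columns=tax_cols)
        df = df.T
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"non-numeric count {df.loc[row, col]!r} at sample {row!r}, OTU {col!r}"
            )
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise FormatError(f"missing count at sample {df.index[i]!r}, OTU {df.columns[j]!r}")
    return OtuTable(df.index.tolist(), [str(c) for c in df.columns], values, taxonomy)


def write_otu_table(table: OtuTable, path, orientation: str = "samples_as_rows") -> None:
    df = table.to_dataframe()
    if orientation == "otus_as_rows":
        df = df.T
        if table.taxonomy:
            df["taxonomy"] = [table.taxonomy.get(o, "") for o in df.index]
        df.index.name = "otu_id"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    """Read a sample-metadata TSV (id, land use, lon/lat, six soil variables)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata is missing mandatory columns: {missing}")
    extra_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    if extra_cols:
        logger.warning("metadata has extra columns (preserved): %s", extra_cols)
    for col in ["lon", "lat"] + ENV_VARIABLES:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna().to_numpy().nonzero()[0][0]]
            raise FormatError(f"non-numeric value in column {col!r} at sample {row!r}")
        df[col] = vals
    return SampleMetadata(
        df.index.tolist(),
        df["land_use"].to_numpy(),
        df["lon"].to_numpy(),
        df["lat"].to_numpy(),
        df[ENV_VARIABLES],
        df[extra_cols] if extra_cols else None,
    )


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def align(table: OtuTable, meta: SampleMetadata) -> tuple[OtuTable, SampleMetadata]:
    """Restrict table and metadata to their common samples, in table order."""
    common = [s for s in table.sample_ids if s in set(meta.sample_ids)]
    if not common:
        raise ValidationError("OTU table and metadata share no sample ids")
    dropped = sorted(
        (set(table.sample_ids) | set(meta.sample_ids)) - set(common)
    )
    if dropped:
        logger.warning("align dropped samples absent from one input: %s", dropped)
    t = table if common == table.sample_ids else table.select_samples(common)
    m = meta if common == meta.sample_ids else meta.select_samples(common)
    return t, m
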