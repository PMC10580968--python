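"""OTU count tables, sample metadata, and abundance transforms.

The central container is :class:`OTUTable`, an integer count matrix with
samples as rows and OTUs as columns.  Readers accept the "classic" OTU-table
TSV layout (rows = OTUs, columns = samples, first column the OTU id) as well
as BIOM-JSON, and record which orientation was detected.  Rarefaction is
without-replacement (multivariate hypergeometric) subsampling to a fixed
depth, mirroring the single-rarefaction step of standard amplicon pipelines.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("sample_id", "latitude", "longitude", "location",
                    "MAT", "MAP", "MDTR", "region")

PATHWAYS = ("CBB", "WL", "ASR", "DSR", "SOX", "nitrogen_fixation",
            "dissimilatory_nitrite_reduction")


class TableError(ValueError):
    """Raised for malformed OTU tables or metadata."""


@dataclass
class OTUTable:
    """Integer count matrix, samples x OTUs.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with OTU ids as columns.  Values must
        be non-negative integers (fractional counts are rejected).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()].tolist()
            raise TableError(f"duplicate sample ids: {dup}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()].tolist()
            raise TableError(f"duplicate OTU ids: {dup}")
        values = c.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise TableError("counts must be numeric")
        if np.isnan(values.astype(float)).any():
            raise TableError("counts contain missing values")
        if (values < 0).any():
            raise TableError("negative count")
        if not np.allclose(values, np.round(values)):
            raise TableError("fractional counts are not allowed")
        self.counts = c.astype(np.int64)
        self.counts.index = c.index.astype(str)
        self.counts.columns = c.columns.astype(str)

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def zero_otus(self) -> list[str]:
        """OTU ids with zero total count (retained but flagged)."""
        totals = self.counts.sum(axis=0)
        return list(totals.index[totals == 0])

    def drop_zero_otus(self) -> "OTUTable":
        totals = self.counts.sum(axis=0)
        return OTUTable(self.counts.loc[:, totals > 0].copy())


def relative_abundance(table: OTUTable) -> pd.DataFrame:
    """Per-sample proportions; every row sums to 1.

    Raises
    ------
    TableError
        If any sample has zero total count.
    """
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise TableError(f"zero-sum samples: {bad}")
    return table.counts.div(totals, axis=0)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path, format: str = "tsv",
                   orientation: str = "auto") -> OTUTable:
    """Read an OTU table from TSV (classic layout) or BIOM-JSON.

    In the classic layout rows are OTUs and columns are samples; the internal
    convention is samples-as-rows, so the matrix is transposed on read.
    ``orientation`` may be ``"otus_as_rows"`` (classic), ``"samples_as_rows"``
    or ``"auto"``; auto assumes the classic layout unless the first header
    field names a sample axis (``sample_id``).
    """
    path = Path(path)
    if format == "biom-json":
        return _read_biom_json(path)
    if format != "tsv":
        raise TableError(f"unknown format: {format!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    first = str(df.index.name or "")
    if orientation == "auto":
        orientation = ("samples_as_rows"
                       if first.lower() in {"sample_id", "sample", "samples"}
                       else "otus_as_rows")
        logger.info("orientation detected: %s", orientation)
    if orientation == "otus_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise TableError(f"unknown orientation: {orientation!r}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise TableError("counts must be numeric")
    return OTUTable(df)


def write_otu_table(table: OTUTable, path: str | Path,
                    format: str = "tsv") -> None:
    """Write in the classic layout (rows = OTUs, first column = OTU id)."""
    path = Path(path)
    if format == "biom-json":
        _write_biom_json(table, path)
        return
    if format != "tsv":
        raise TableError(f"unknown format: {format!r}")
    out = table.counts.T
    out.index.name = "#OTU ID"
    out.to_csv(path, sep="\t")


def _read_biom_json(path: Path) -> OTUTable:
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [row["id"] for row in doc["rows"]]
    sample_ids = [col["id"] for col in doc["columns"]]
    n_rows, n_cols = doc["shape"]
    mat = np.zeros((n_rows, n_cols))
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"])
    else:  # sparse [row, col, value] triplets
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    df = pd.DataFrame(mat.T, index=sample_ids, columns=otu_ids)
    return OTUTable(df)


def _write_biom_json(table: OTUTable, path: Path) -> None:
    mat = table.counts.to_numpy().T  # BIOM rows are observations
    rows, cols = np.nonzero(mat)
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "microassembly",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [table.n_otus, table.n_samples],
        "rows": [{"id": o, "metadata": None} for o in table.otu_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": [[int(i), int(j), int(mat[i, j])] for i, j in zip(rows, cols)],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV and validate coordinates.

    Required columns: sample_id, latitude, longitude, location, MAT, MAP,
    MDTR, region.  Returns a DataFrame indexed by sample_id.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise TableError(f"metadata missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise TableError("duplicate sample_id in metadata")
    lat, lon = df["latitude"], df["longitude"]
    if ((lat < -90) | (lat > 90)).any():
        raise TableError("latitude out of range [-90, 90]")
    if ((lon < -180) | (lon > 180)).any():
        raise TableError("longitude out of range [-180, 180]")
    return df.set_index(df["sample_id"].astype(str)).drop(columns=["sample_id"])


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_function_table(path: str | Path) -> pd.DataFrame:
    """Read an OTU -> pathway annotation table (otu_id, pathway, present)."""
    df = pd.read_csv(path, sep="\t", dtype={"otu_id": str, "pathway": str})
    for col in ("otu_id", "pathway", "present"):
        if col not in df.columns:
            raise TableError(f"function table missing column {col!r}")
    unknown = set(df["pathway"]) - set(PATHWAYS)
    if unknown:
        raise TableError(f"unknown pathways: {sorted(unknown)}")
    if df.duplicated(subset=["otu_id", "pathway"]).any():
        raise TableError("duplicate (otu_id, pathway) pairs")
    df["present"] = df["present"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: OTUTable, depth: int, seed: int,
           return_dropped: bool = False):
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (ids logged, and
    returned when ``return_dropped`` is set).  Subsampling is multivariate
    hypergeometric and deterministic given ``seed``.
    """
    if depth < 1:
        raise TableError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals >= depth
    dropped = list(totals.index[~keep])
    if dropped:
        logger.warning("rarefy: dropping %d samples below depth %d: %s",
                       len(dropped), depth, dropped)
    if not keep.any():
        raise TableError("no samples retained at this depth")
    counts = table.counts.loc[keep].to_numpy()
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    rarefied = OTUTable(pd.DataFrame(out, index=table.counts.index[keep],
                                     columns=table.counts.columns))
    if return_dropped:
        return rarefied, dropped
    return rarefied
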