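"""Community tables, sample metadata, and the latitude/depth strata.

The two core containers used throughout the package are :class:`OtuTable`
(a samples x OTUs abundance matrix, either sequencing read counts or
relative fingerprint peak heights) and a metadata :class:`pandas.DataFrame`
with one row per sample (geography, hydrography, covariates).

Stations are binned into six latitudinal ocean provinces (banded Longhurst
regions as used for an Atlantic pole-to-pole transect) and samples into four
depth layers (epipelagic, mesopelagic, upper and lower bathypelagic).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OtuTable",
    "PROVINCES",
    "LAYERS",
    "METADATA_COLUMNS",
    "assign_province",
    "assign_layer",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "align_samples",
]

#: Latitudinal province bands, listed north to south.  Each entry is
#: (name, south_edge, north_edge); intervals are half-open and north-favouring
#: (a boundary latitude belongs to the more northern province), except the
#: overall domain ends which are closed.
PROVINCES = (
    ("ARCT", 55.0, 70.0),   # North Atlantic Arctic
    ("NADR", 40.0, 55.0),   # North Atlantic Drift
    ("NAG", 12.0, 40.0),    # North Atlantic Gyral (tropical + subtropical gyre)
    ("WTRA", -6.0, 12.0),   # Western Tropical Atlantic
    ("SATL", -40.0, -6.0),  # South Atlantic Gyral
    ("SANT", -55.0, -40.0), # Subantarctic (incl. Subtropical Convergence)
)

#: Depth layers: (name, top, bottom).  Top-inclusive; the upper/lower
#: bathypelagic boundary at 2000 m belongs to the upper layer.
LAYERS = (
    ("EPI", 0.0, 200.0),
    ("MESO", 200.0, 1000.0),
    ("UPPER_BATHY", 1000.0, 2000.0),
    ("LOWER_BATHY", 2000.0, float("inf")),
)

PROVINCE_NAMES = tuple(p[0] for p in PROVINCES)
LAYER_NAMES = tuple(l[0] for l in LAYERS)

METADATA_COLUMNS = (
    "sample_id",
    "latitude",
    "longitude",
    "depth_m",
    "temperature_c",
    "salinity",
    "oxygen_umol_kg",
    "nitrite_umol_l",
    "date_iso",
    "thaum_16s_per_ml",
    "lac_hac_ratio",
    "province",
    "layer",
)


class FormatError(ValueError):
    """Malformed input table (duplicate ids, ragged/negative/non-integer cells)."""


class JoinError(ValueError):
    """Sample ids of table and metadata do not overlap."""


def assign_province(latitude: float) -> str:
    """Map a latitude (degrees N positive) to its ocean province band.

    Bands tile [-55, 70]; a latitude exactly on an interior boundary belongs
    to the more northern province.  Latitudes outside the transect domain
    raise ``ValueError`` (no province defined there).
    """
    lat = float(latitude)
    if not -55.0 <= lat <= 70.0:
        raise ValueError(
            f"latitude {lat} outside the transect domain [-55, 70]; no province defined"
        )
    for name, south, north in PROVINCES:
        if lat >= south:
            return name
    raise AssertionError("unreachable: province bands tile the domain")


def assign_layer(depth_m: float) -> str:
    """Map a sampling depth (metres) to its depth layer.

    EPI [0, 200), MESO [200, 1000), UPPER_BATHY [1000, 2000],
    LOWER_BATHY (2000, inf).  Negative depths raise ``ValueError``.
    """
    d = float(depth_m)
    if d < 0:
        raise ValueError(f"negative depth {d} m")
    if d < 200.0:
        return "EPI"
    if d < 1000.0:
        return "MESO"
    if d <= 2000.0:
        return "UPPER_BATHY"
    return "LOWER_BATHY"


@dataclass
class OtuTable:
    """Samples x OTUs abundance matrix.

    Parameters
    ----------
    sample_ids, otu_ids
        Ordered, unique identifiers for rows and columns.
    values
        Non-negative matrix, shape (n_samples, n_otus).  In ``counts`` mode
        the entries must be integers (sequencing reads); in ``relative`` mode
        each row sums to 1 (within 1e-6) or is all zero (normalized
        fingerprint peak heights).
    """

    sample_ids: list = field(default_factory=list)
    otu_ids: list = field(default_factory=list)
    values: np.ndarray = None
    mode: str = "counts"

    def __post_init__(self):
        self.sample_ids = list(map(str, self.sample_ids))
        self.otu_ids = list(map(str, self.otu_ids))
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise FormatError("duplicate OTU ids")
        if self.values.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"OTU {self.otu_ids[j]!r}"
            )
        if self.mode == "counts":
            if not np.allclose(self.values, np.round(self.values), atol=0):
                i, j = np.argwhere(self.values != np.round(self.values))[0]
                raise FormatError(
                    f"non-integer count {self.values[i, j]} at sample "
                    f"{self.sample_ids[i]!r}, OTU {self.otu_ids[j]!r}"
                )
        else:
            sums = self.values.sum(axis=1)
            bad = ~(np.isclose(sums, 1.0, atol=1e-6) | (sums == 0))
            if np.any(bad):
                i = int(np.argmax(bad))
                raise FormatError(
                    f"relative-mode row {self.sample_ids[i]!r} sums to {sums[i]}, "
                    "expected 1 (or all-zero)"
                )

    @property
    def shape(self):
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, mode: str) -> "OtuTable":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(), mode)

    def relative(self) -> "OtuTable":
        """Row-normalized copy (counts -> relative abundances)."""
        totals = self.values.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            i = int(np.argmax(totals[:, 0] == 0))
            raise ValueError(f"all-zero sample {self.sample_ids[i]!r}")
        return OtuTable(self.sample_ids, self.otu_ids, self.values / totals, "relative")

    def subset_samples(self, keep) -> "OtuTable":
        keep = list(keep)
        idx = [self.sample_ids.index(s) for s in keep]
        return OtuTable(keep, self.otu_ids, self.values[idx], self.mode)

    def to_biom_json(self) -> str:
        """Minimal BIOM-style JSON export (dense, documented dialect)."""
        return json.dumps(
            {
                "format": "aoamacro-biom-minimal-1.0",
                "matrix_type": "dense",
                "shape": list(self.values.shape),
                "rows": self.sample_ids,
                "columns": self.otu_ids,
                "mode": self.mode,
                "data": self.values.tolist(),
            }
        )


def write_otu_table(table: OtuTable, path) -> None:
    """Write an OtuTable as TSV: samples as rows, OTUs as columns."""
    table.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_otu_table(path, mode: str = "counts") -> OtuTable:
    """Read a delimited OTU table (TSV/CSV, sniffed delimiter) and validate it.

    Raises :class:`FormatError` naming the offending cell/line for duplicate
    ids, ragged rows, negative abundances, or non-integer counts in
    ``counts`` mode.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    delim = "\t" if "\t" in lines[0] else ","
    header = lines[0].split(delim)
    otu_ids = header[1:]
    sample_ids, rows = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split(delim)
        if len(parts) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        sample_ids.append(parts[0])
        try:
            row = [float(x) for x in parts[1:]]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from None
        for j, v in enumerate(row):
            if v < 0:
                raise FormatError(
                    f"{path}:{lineno}: negative abundance {v} in column {otu_ids[j]!r}"
                )
        rows.append(row)
    try:
        return OtuTable(sample_ids, otu_ids, np.array(rows, dtype=float), mode)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV and validate latitudes, depths and strata."""
    meta = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in ("sample_id", "latitude", "depth_m") if c not in meta.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    if (meta["latitude"].abs() > 90).any():
        raise FormatError(f"{path}: latitude out of [-90, 90]")
    if (meta["depth_m"] < 0).any():
        raise FormatError(f"{path}: negative depth")
    return meta


def align_samples(table: OtuTable, meta: pd.DataFrame):
    """Intersect table and metadata on sample id, in table order.

    Returns ``(table_view, meta_view)`` restricted to the shared samples;
    dropped ids are logged.  Raises :class:`JoinError` if the id sets are
    disjoint.
    """
    meta_ids = set(meta["sample_id"].astype(str))
    shared = [s for s in table.sample_ids if s in meta_ids]
    if not shared:
        raise JoinError("no shared sample ids between table and metadata")
    dropped_t = [s for s in table.sample_ids if s not in meta_ids]
    dropped_m = sorted(meta_ids - set(table.sample_ids))
    if dropped_t:
        logger.info("align_samples: dropped %d table samples: %s", len(dropped_t), dropped_t)
    if dropped_m:
        logger.info("align_samples: dropped %d metadata samples: %s", len(dropped_m), dropped_m)
    sub = table.subset_samples(shared)
    meta_sub = (
        meta.assign(sample_id=meta["sample_id"].astype(str))
        .set_index("sample_id")
        .loc[shared]
        .reset_index()
    )
    return sub, meta_sub
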