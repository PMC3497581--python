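"""Reading isotope sample tables and computing centroid-standardized vectors.

The atomic record is one specimen's (δ13C, δ15N) signature labelled by
species, genus and assemblage (site).  Species means are taken per
(species, site); each site's centroid is the *unweighted* mean of its
species means, so that heavily sampled species do not drag the centroid;
every specimen is then expressed as a vector (dx, dy, angle, magnitude)
from its local centroid.

Collections are plain :class:`pandas.DataFrame` objects with documented
columns; angles use the mathematical convention (0° = +δ13C axis,
counterclockwise, [0, 360)) and are NaN where the magnitude is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParseError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "IsotopeSample",
    "REQUIRED_COLUMNS",
    "read_samples",
    "species_means",
    "assemblage_centroids",
    "assemblage_centroid",
    "individual_vectors",
    "write_vectors",
]

REQUIRED_COLUMNS = ("specimen_id", "species", "genus", "site", "d13C", "d15N")


@dataclass(frozen=True)
class IsotopeSample:
    """One specimen's isotope signature."""

    specimen_id: str
    species: str
    genus: str
    site: str
    d13C: float
    d15N: float


def _validate(df: pd.DataFrame) -> None:
    dup = df["specimen_id"][df["specimen_id"].duplicated()]
    if not dup.empty:
        raise DataError(f"duplicate specimen_id values: {sorted(set(dup))[:5]}")
    genus_per_species = df.groupby("species")["genus"].nunique()
    bad = genus_per_species[genus_per_species > 1]
    if not bad.empty:
        raise DataError(
            f"species mapped to more than one genus: {list(bad.index)[:5]}"
        )


def read_samples(
    path,
    schema: Optional[Mapping[str, str]] = None,
    *,
    delimiter: Optional[str] = None,
) -> pd.DataFrame:
    """Read a sample table (CSV/TSV, UTF-8, header row).

    ``schema`` maps canonical names (``specimen_id``, ``species``,
    ``genus``, ``site``, ``d13C``, ``d15N``) to the file's column names.
    Rows with blank isotope cells are dropped with a logged count;
    non-numeric non-blank isotope cells raise :class:`ParseError` with the
    offending row number (1-based, excluding the header).
    """
    sep = delimiter
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    mapping = dict(schema) if schema else {}
    rename = {mapping.get(k, k): k for k in REQUIRED_COLUMNS}
    missing = [mapping.get(k, k) for k in REQUIRED_COLUMNS if mapping.get(k, k) not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.rename(columns=rename)[list(REQUIRED_COLUMNS)]

    for col in ("d13C", "d15N"):
        raw = df[col].str.strip()
        blank = (raw == "") | raw.str.lower().isin({"na", "nan", "null"})
        numeric = pd.to_numeric(raw.where(~blank), errors="coerce")
        bad = (~blank) & numeric.isna()
        if bad.any():
            row = int(df.index[bad][0]) + 1
            raise ParseError(
                f"non-numeric {col} value {raw[bad].iloc[0]!r} at data row {row}"
            )
        df[col] = numeric

    n0 = len(df)
    df = df.dropna(subset=["d13C", "d15N"]).reset_index(drop=True)
    rejected = n0 - len(df)
    if rejected:
        logger.warning("rejected %d row(s) with missing isotope values", rejected)
    for col in ("specimen_id", "species", "genus", "site"):
        df[col] = df[col].str.strip()
    _validate(df)
    return df


def species_means(samples: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean signature per (species, site).

    Columns: species, genus, site, mean_d13C, mean_d15N, n.
    """
    if len(samples) == 0:
        raise DataError("no samples")
    out = (
        samples.groupby(["species", "site"], as_index=False, sort=True)
        .agg(
            genus=("genus", "first"),
            mean_d13C=("d13C", "mean"),
            mean_d15N=("d15N", "mean"),
            n=("specimen_id", "size"),
        )
    )
    return out[["species", "genus", "site", "mean_d13C", "mean_d15N", "n"]]


def assemblage_centroids(means: pd.DataFrame) -> pd.DataFrame:
    """Per-site centroid: unweighted mean of species means, plus richness.

    Columns: site, c13, c15, species_richness.
    """
    out = (
        means.groupby("site", as_index=False, sort=True)
        .agg(
            c13=("mean_d13C", "mean"),
            c15=("mean_d15N", "mean"),
            species_richness=("species", "nunique"),
        )
    )
    return out


def assemblage_centroid(means: pd.DataFrame, site: str) -> pd.Series:
    """Centroid of one site; raises :class:`DataError` for an unknown site."""
    cents = assemblage_centroids(means)
    row = cents[cents["site"] == site]
    if row.empty:
        raise DataError(f"unknown site: {site!r}")
    return row.iloc[0]


def vector_components(dx: np.ndarray, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Angle in [0, 360) (NaN at zero magnitude) and Euclidean magnitude."""
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    magnitude = np.hypot(dx, dy)
    with np.errstate(invalid="ignore"):
        angle = np.degrees(np.arctan2(dy, dx)) % 360.0
    angle = np.where(angle >= 360.0, 0.0, angle)
    angle = np.where(magnitude == 0.0, np.nan, angle)
    return angle, magnitude


def individual_vectors(samples: pd.DataFrame, centroids: pd.DataFrame) -> pd.DataFrame:
    """One centroid-standardized vector per specimen.

    Columns: owner, species, genus, site, dx, dy, angle_deg, magnitude.
    ``angle_deg`` is NaN for zero-magnitude vectors (direction undefined).
    """
    orphans = set(samples["site"]) - set(centroids["site"])
    if orphans:
        raise DataError(f"sample site(s) without centroid: {sorted(orphans)}")
    merged = samples.merge(centroids[["site", "c13", "c15"]], on="site", how="left")
    dx = (merged["d13C"] - merged["c13"]).to_numpy()
    dy = (merged["d15N"] - merged["c15"]).to_numpy()
    angle, magnitude = vector_components(dx, dy)
    n_zero = int(np.count_nonzero(magnitude == 0.0))
    if n_zero:
        logger.warning("%d vector(s) have zero magnitude; angle undefined", n_zero)
    return pd.DataFrame(
        {
            "owner": merged["specimen_id"],
            "species": merged["species"],
            "genus": merged["genus"],
            "site": merged["site"],
            "dx": dx,
            "dy": dy,
            "angle_deg": angle,
            "magnitude": magnitude,
        }
    )


def write_vectors(vectors: pd.DataFrame, path) -> None:
    """Write the vector table as TSV (owner, site, dx, dy, angle_deg, magnitude)."""
    cols = ["owner", "site", "dx", "dy", "angle_deg", "magnitude"]
    vectors[cols].to_csv(path, sep="\t", index=False, float_format="%.6f")
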