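"""Orchestration of the two analysis partitions.

Partition 1 summarizes each genus from its individual vectors pooled
across sites; partition 2 first collapses each (genus, site) cell to a
single mean direction and then summarizes each genus from those site
means.  Both feed the same circular-summary machinery.  Group means are
unit-vector resultants: per-individual ‰ magnitudes never enter the
circular statistics (they are kept for reporting and for the linear half
of the richness-bias tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import circular_stats as cs
from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "GenusSummaryRow",
    "apply_genus_splits",
    "genus_individual_summary",
    "genus_site_means",
    "genus_site_summary",
    "richness_bias_tests",
]


@dataclass(frozen=True)
class GenusSummaryRow:
    genus: str
    n_individuals: int
    n_assemblages: int
    summary: cs.CircularSummary


def apply_genus_splits(
    vectors: pd.DataFrame, splits: Optional[Mapping[str, str]]
) -> pd.DataFrame:
    """Override the genus label for selected species.

    ``splits`` maps species name -> operational group label (e.g. splitting
    one large genus into named species groups).  Unmapped species keep
    their genus column.
    """
    if not splits:
        return vectors
    out = vectors.copy()
    mapped = out["species"].map(splits)
    out["genus"] = mapped.fillna(out["genus"])
    return out


def _defined(vectors: pd.DataFrame) -> pd.DataFrame:
    bad = vectors["angle_deg"].isna()
    if bad.any():
        logger.warning("excluding %d zero-magnitude vector(s)", int(bad.sum()))
    return vectors[~bad]


def genus_individual_summary(
    vectors: pd.DataFrame, **summary_kwargs
) -> list[GenusSummaryRow]:
    """Partition 1: one row per genus over its individual vector angles."""
    vec = _defined(vectors)
    rows = []
    for genus, grp in vec.groupby("genus", sort=True):
        if len(grp) == 0:
            continue
        rows.append(
            GenusSummaryRow(
                genus=str(genus),
                n_individuals=int(len(grp)),
                n_assemblages=int(grp["site"].nunique()),
                summary=cs.summarize(grp["angle_deg"].to_numpy(), **summary_kwargs),
            )
        )
    dropped = set(vectors["genus"]) - {r.genus for r in rows}
    if dropped:
        logger.warning("genus/genera with no defined vectors dropped: %s", sorted(dropped))
    return rows


def genus_site_means(vectors: pd.DataFrame) -> pd.DataFrame:
    """Unit-vector mean direction per (genus, site) cell.

    Columns: genus, site, mu_deg, r, n.  Cells whose resultant vanishes
    get NaN ``mu_deg`` and are excluded downstream.
    """
    vec = _defined(vectors)
    recs = []
    for (genus, site), grp in vec.groupby(["genus", "site"], sort=True):
        mu, r = cs.circular_mean(grp["angle_deg"].to_numpy())
        recs.append(
            {
                "genus": genus,
                "site": site,
                "mu_deg": np.nan if mu is None else mu,
                "r": r,
                "n": len(grp),
            }
        )
    return pd.DataFrame.from_records(
        recs, columns=["genus", "site", "mu_deg", "r", "n"]
    )


def genus_site_summary(
    site_means: pd.DataFrame, **summary_kwargs
) -> list[GenusSummaryRow]:
    """Partition 2: one row per genus over its site mean angles.

    Site-level resultant lengths are discarded; only the angles enter
    (unit-vector convention).
    """
    means = site_means[site_means["mu_deg"].notna()]
    rows = []
    for genus, grp in means.groupby("genus", sort=True):
        rows.append(
            GenusSummaryRow(
                genus=str(genus),
                n_individuals=int(grp["n"].sum()),
                n_assemblages=int(len(grp)),
                summary=cs.summarize(grp["mu_deg"].to_numpy(), **summary_kwargs),
            )
        )
    return rows


def richness_bias_tests(
    vectors: pd.DataFrame,
    centroids: pd.DataFrame,
    genera: Optional[Sequence[str]] = None,
    *,
    min_n: int = 4,
) -> pd.DataFrame:
    """Correlate vector direction/length with assemblage species richness.

    Test 1 uses individual vectors (direction vs richness circularly,
    ‰ magnitude vs richness linearly); Test 2 repeats it on the (genus,
    site) mean vectors, where the linear variable is the cell resultant
    length.  Genera with fewer than ``min_n`` usable records in a test are
    skipped with a log entry.

    Returns one row per (genus, test) with columns
    genus, test, n, circ_R2, circ_P, lin_R2, lin_P.
    """
    if "species_richness" not in centroids.columns:
        raise DataError("centroids must carry species_richness")
    richness = centroids.set_index("site")["species_richness"]
    missing = set(vectors["site"]) - set(richness.index)
    if missing:
        raise DataError(f"site(s) without richness value: {sorted(missing)}")

    vec = _defined(vectors)
    if genera is None:
        genera = sorted(vec["genus"].unique())
    site_means = genus_site_means(vectors)

    rows = []
    for genus in genera:
        ind = vec[vec["genus"] == genus]
        if len(ind) >= min_n:
            x = richness.loc[ind["site"]].to_numpy(dtype=float)
            circ = cs.circ_linear_correlation(ind["angle_deg"].to_numpy(), x)
            lin_R2, lin_P = cs.linear_correlation(ind["magnitude"].to_numpy(), x)
            rows.append(
                {
                    "genus": genus,
                    "test": 1,
                    "n": len(ind),
                    "circ_R2": circ.circ_R2,
                    "circ_P": circ.circ_P,
                    "lin_R2": lin_R2,
                    "lin_P": lin_P,
                }
            )
        else:
            logger.info("test 1 skipped for %s (n=%d < %d)", genus, len(ind), min_n)
        gm = site_means[(site_means["genus"] == genus) & site_means["mu_deg"].notna()]
        if len(gm) >= min_n:
            x = richness.loc[gm["site"]].to_numpy(dtype=float)
            circ = cs.circ_linear_correlation(gm["mu_deg"].to_numpy(), x)
            lin_R2, lin_P = cs.linear_correlation(gm["r"].to_numpy(), x)
            rows.append(
                {
                    "genus": genus,
                    "test": 2,
                    "n": len(gm),
                    "circ_R2": circ.circ_R2,
                    "circ_P": circ.circ_P,
                    "lin_R2": lin_R2,
                    "lin_P": lin_P,
                }
            )
        else:
            logger.info("test 2 skipped for %s (n=%d < %d)", genus, len(gm), min_n)
    return pd.DataFrame.from_records(
        rows, columns=["genus", "test", "n", "circ_R2", "circ_P", "lin_R2", "lin_P"]
    )
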