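"""Publication-shaped TSV/JSON writers.

Formatting conventions follow the summary tables: angles as integer
degrees, r / variance / concentration to 2 decimals, probabilities to 3
decimals, a dash for undefined cells, and significance marks appended to
the genus label ("*" for Rayleigh P < 0.05, "†" for 0.10 > P > 0.05).
"""

from __future__ import annotations

import json
import math
from typing import Optional, Sequence

import pandas as pd

from .circular_stats import CircularSummary, RaoBracket
from .pipeline import GenusSummaryRow

__all__ = [
    "DASH",
    "significance_mark",
    "table1_frame",
    "table2_frame",
    "table3_frame",
    "write_tsv",
    "summaries_to_json",
]

DASH = "–"  # en dash, as printed for undefined cells
STAR_P = 0.05
DAGGER_P = 0.10

TABLE1_COLUMNS = [
    "genus",
    "individuals",
    "assemblages",
    "mean_vector_mu",
    "mean_vector_r",
    "concentration",
    "circular_variance",
    "circular_sd",
    "rayleigh_p",
    "rao_p",
]
TABLE2_COLUMNS = [c for c in TABLE1_COLUMNS if c not in ("individuals", "assemblages")]
TABLE3_COLUMNS = [
    "genus",
    "test1_n", "test1_circ_R2", "test1_circ_P", "test1_lin_R2", "test1_lin_P",
    "test2_n", "test2_circ_R2", "test2_circ_P", "test2_lin_R2", "test2_lin_P",
]


def significance_mark(rayleigh_p: float) -> str:
    if rayleigh_p < STAR_P:
        return "*"
    if rayleigh_p < DAGGER_P:
        return "†"
    return ""


def _fmt_angle(v: Optional[float]) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return DASH
    return f"{round(v) % 360:d}°"


def _fmt(v: Optional[float], nd: int) -> str:
    if v is None or (isinstance(v, float) and (math.isnan(v) or math.isinf(v))):
        return DASH
    return f"{v:.{nd}f}"


def _summary_cells(s: CircularSummary) -> dict:
    kappa = DASH if s.kappa is None else _fmt(s.kappa, 2)
    if s.n == 1:
        # singletons print only the direction and the Rayleigh constant
        return {
            "mean_vector_mu": _fmt_angle(s.mu_deg),
            "mean_vector_r": _fmt(s.r, 2),
            "concentration": DASH,
            "circular_variance": DASH,
            "circular_sd": DASH,
            "rayleigh_p": _fmt(s.rayleigh_P, 3),
            "rao_p": DASH,
        }
    return {
        "mean_vector_mu": _fmt_angle(s.mu_deg),
        "mean_vector_r": _fmt(s.r, 2),
        "concentration": kappa,
        "circular_variance": _fmt(s.circ_variance, 2),
        "circular_sd": _fmt_angle(s.circ_sd_deg if math.isfinite(s.circ_sd_deg) else None),
        "rayleigh_p": _fmt(s.rayleigh_P, 3),
        "rao_p": DASH if s.rao_P is None else str(s.rao_P),
    }


def table1_frame(rows: Sequence[GenusSummaryRow]) -> pd.DataFrame:
    recs = []
    for row in rows:
        cells = _summary_cells(row.summary)
        recs.append(
            {
                "genus": row.genus + significance_mark(row.summary.rayleigh_P),
                "individuals": row.n_individuals,
                "assemblages": row.n_assemblages,
                **cells,
            }
        )
    return pd.DataFrame.from_records(recs, columns=TABLE1_COLUMNS)


def table2_frame(rows: Sequence[GenusSummaryRow]) -> pd.DataFrame:
    recs = []
    for row in rows:
        cells = _summary_cells(row.summary)
        recs.append(
            {"genus": row.genus + significance_mark(row.summary.rayleigh_P), **cells}
        )
    return pd.DataFrame.from_records(recs, columns=TABLE2_COLUMNS)


def table3_frame(tests: pd.DataFrame) -> pd.DataFrame:
    """Wide Table-3-shaped frame from the long richness-bias test output."""
    recs = {}
    for _, r in tests.iterrows():
        rec = recs.setdefault(r["genus"], {"genus": r["genus"]})
        p = f"test{int(r['test'])}"
        rec[f"{p}_n"] = str(int(r["n"]))
        rec[f"{p}_circ_R2"] = _fmt(r["circ_R2"], 2)
        rec[f"{p}_circ_P"] = _fmt(r["circ_P"], 3)
        rec[f"{p}_lin_R2"] = _fmt(r["lin_R2"], 2)
        rec[f"{p}_lin_P"] = _fmt(r["lin_P"], 3)
    frame = pd.DataFrame.from_records(list(recs.values()), columns=TABLE3_COLUMNS)
    return frame.fillna(DASH)


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def summaries_to_json(rows: Sequence[GenusSummaryRow]) -> str:
    def enc(row: GenusSummaryRow) -> dict:
        s = row.summary
        return {
            "genus": row.genus,
            "n_individuals": row.n_individuals,
            "n_assemblages": row.n_assemblages,
            "n": s.n,
            "mu_deg": s.mu_deg,
            "r": s.r,
            "kappa": None if s.kappa is None or not math.isfinite(s.kappa) else s.kappa,
            "circ_variance": s.circ_variance,
            "circ_sd_deg": s.circ_sd_deg if math.isfinite(s.circ_sd_deg) else None,
            "rayleigh_Z": s.rayleigh_Z,
            "rayleigh_P": s.rayleigh_P,
            "rao_U": s.rao_U,
            "rao_P": None if s.rao_P is None else str(s.rao_P),
        }

    return json.dumps([enc(r) for r in rows], indent=2)
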