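"""Report tables: shape annual risk summaries like the published tables.

Rounding follows the published precision: 4 decimals for concentrations,
3 for relative risks, 2 for per-100,000 risks; ELCR is kept in scientific
notation.  Internal computation is always full precision - rounding happens
only here, at the presentation boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .endpoints import AnnualRiskSummary

LUNG_COLUMNS = [
    "mean_exposure",
    "cumulative_exposure",
    "rr_be",
    "rr_ub",
    "c_avg",
    "lung_mortality_be",
    "lung_mortality_ub",
    "elcr_mean",
]

MESO_COLUMNS = [
    "mean_exposure",
    "cumulative_exposure",
    "meso_incidence_be",
    "meso_incidence_ub",
    "c_avg",
    "meso_mortality_be",
    "meso_mortality_ub",
]

_ROUNDING = {
    "mean_exposure": 4,
    "cumulative_exposure": 4,
    "c_avg": 4,
    "rr_be": 3,
    "rr_ub": 3,
    "lung_mortality_be": 2,
    "lung_mortality_ub": 2,
    "meso_incidence_be": 2,
    "meso_incidence_ub": 2,
    "meso_mortality_be": 2,
    "meso_mortality_ub": 2,
}


def summary_frame(rows: Iterable[AnnualRiskSummary]) -> pd.DataFrame:
    """Full-precision DataFrame of all computed columns, indexed by year."""
    data = [vars(r) for r in rows]
    return pd.DataFrame(data).set_index("year").sort_index()


def _rounded(frame: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    out = frame[list(columns)].copy()
    for col in out.columns:
        if col in _ROUNDING:
            out[col] = out[col].round(_ROUNDING[col])
    return out


def lung_table(rows: Iterable[AnnualRiskSummary]) -> pd.DataFrame:
    """Lung-cancer report table (RR, Cavg, lifetime mortality, mean ELCR)."""
    return _rounded(summary_frame(rows), LUNG_COLUMNS)


def mesothelioma_table(rows: Iterable[AnnualRiskSummary]) -> pd.DataFrame:
    """Mesothelioma report table (incidence and lifetime mortality)."""
    return _rounded(summary_frame(rows), MESO_COLUMNS)


def to_markdown(frame: pd.DataFrame, float_fmt: str = "{:g}") -> str:
    """Render a DataFrame as a GitHub-style markdown table."""
    frame = frame.reset_index()

    def fmt(v: object) -> str:
        if isinstance(v, float):
            return "{:.3e}".format(v) if v != 0 and abs(v) < 1e-3 else float_fmt.format(v)
        return str(v)

    header = [str(c) for c in frame.columns]
    body = [[fmt(v) for v in row] for row in frame.itertuples(index=False)]
    widths = [
        max(len(header[i]), *(len(r[i]) for r in body)) if body else len(header[i])
        for i in range(len(header))
    ]
    lines = [
        "| " + " | ".join(h.ljust(w) for h, w in zip(header, widths)) + " |",
        "|" + "|".join("-" * (w + 2) for w in widths) + "|",
    ]
    lines += [
        "| " + " | ".join(v.ljust(w) for v, w in zip(row, widths)) + " |"
        for row in body
    ]
    return "\n".join(lines) + "\n"


def write_table(frame: pd.DataFrame, path: str | Path, fmt: str = "csv") -> None:
    """Write a report table as csv, md, or json."""
    path = Path(path)
    if fmt == "csv":
        frame.to_csv(path)
    elif fmt == "md":
        path.write_text(to_markdown(frame), encoding="utf-8")
    elif fmt == "json":
        frame.reset_index().to_json(path, orient="records", indent=2)
    else:
        raise ValueError(f"unknown table format {fmt!r}")
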