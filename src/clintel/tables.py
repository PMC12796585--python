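"""Suppression-aware tabular results.

Every analytics operation returns a :class:`ResultTable`: a DataFrame plus
metadata naming which columns hold patient counts and which percentage/
statistic columns are derived from them.  Statistical disclosure control
masks any count strictly between 0 and the threshold, together with its
derived percentages, before anything is rendered or serialized.  Zero is
never masked (it reveals only absence), and masking is idempotent and
monotone in the threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: default minimum publishable cell count (common disclosure-control floor)
DEFAULT_SUPPRESSION_THRESHOLD = 5


@dataclass
class ResultTable:
    """Tabular analytics output with small-cell suppression bookkeeping.

    ``count_columns`` name the columns holding raw patient counts;
    ``derived`` maps each derived column (e.g. a percentage) to the count
    column it reveals.  ``suppressed`` is a boolean frame aligned with
    ``data`` marking masked cells; masked cells keep no recoverable value
    once rendered.
    """

    title: str
    data: pd.DataFrame
    count_columns: tuple[str, ...] = ()
    derived: dict[str, str] = field(default_factory=dict)
    threshold: int = 0  # threshold already applied (0 = none)
    suppressed: pd.DataFrame | None = None
    footnotes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.suppressed is None:
            self.suppressed = pd.DataFrame(
                False, index=self.data.index, columns=self.data.columns
            )

    def copy(self) -> "ResultTable":
        return ResultTable(
            title=self.title,
            data=self.data.copy(),
            count_columns=self.count_columns,
            derived=dict(self.derived),
            threshold=self.threshold,
            suppressed=self.suppressed.copy(),
            footnotes=list(self.footnotes),
        )

    # -- rendering -----------------------------------------------------
    def rendered(self) -> pd.DataFrame:
        """String frame with masked cells shown as ``<threshold``."""
        out = self.data.astype(object).copy()
        marker = f"<{self.threshold}" if self.threshold else "*"
        for col in out.columns:
            col_vals = []
            for i in out.index:
                if bool(self.suppressed.at[i, col]):
                    col_vals.append(marker)
                else:
                    v = out.at[i, col]
                    if isinstance(v, float):
                        v = "" if np.isnan(v) else f"{v:.10g}"
                    col_vals.append(str(v))
            out[col] = col_vals
        return out

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.rendered().to_csv(path, index=False)
        return path

    def to_json(self) -> str:
        return json.dumps(
            {
                "title": self.title,
                "threshold": self.threshold,
                "columns": list(self.data.columns),
                "rows": self.rendered().to_dict(orient="records"),
                "footnotes": self.footnotes,
            },
            indent=2,
        )


def suppress_small_counts(table: ResultTable, threshold: int) -> ResultTable:
    """Mask every count in 1..threshold-1 and its derived cells; idempotent."""
    out = table.copy()
    out.threshold = max(out.threshold, int(threshold))
    for col in out.count_columns:
        if col not in out.data.columns:
            continue
        vals = pd.to_numeric(out.data[col], errors="coerce")
        mask = (vals > 0) & (vals < out.threshold)
        out.suppressed[col] = out.suppressed[col] | mask.fillna(False)
    for dcol, ccol in out.derived.items():
        if dcol in out.data.columns and ccol in out.suppressed.columns:
            out.suppressed[dcol] = out.suppressed[dcol] | out.suppressed[ccol]
    return out


__all__ = ["ResultTable", "suppress_small_counts", "DEFAULT_SUPPRESSION_THRESHOLD"]
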