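"""Reading, validating and writing delimited two-wave PROM datasets."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("auxmic")

__all__ = ["ColumnMapping", "DataError", "read_dataset", "write_dataset"]


class DataError(ValueError):
    pass


@dataclass
class ColumnMapping:
    """Maps user column names onto the canonical indicator roles.

    ``aux_t1``/``aux_t2`` may each name a single column (an item or a
    precomputed sum score) or a list of item columns, which are summed.
    ``trs`` names either a binary improved indicator (``trs_is_binary``) or
    an ordered multi-level anchor dichotomized at ``trs_cut``.
    """

    sim_t1: str = "sim_t1"
    sim_t2: str = "sim_t2"
    aux_t1: str | list[str] = "aux_sum_t1"
    aux_t2: str | list[str] = "aux_sum_t2"
    trs: str = "trs_improved"
    trs_is_binary: bool = True
    trs_cut: int = 5
    sim_range: tuple[float, float] | None = None

    def required_columns(self) -> list[str]:
        cols = [self.sim_t1, self.sim_t2, self.trs]
        for a in (self.aux_t1, self.aux_t2):
            cols.extend(a if isinstance(a, list) else [a])
        return cols


def read_dataset(
    path: str | Path, mapping: ColumnMapping | None = None, sep: str | None = None
) -> pd.DataFrame:
    """Load a delimited dataset and map it onto the canonical columns.

    Rows with missing values in any mapped column are dropped (logged);
    non-numeric cells raise an error naming the row and column.  Returns a
    frame with columns sim_t1, sim_t2, aux_t1, aux_t2, trs_improved (and
    trs7 when the anchor is multi-level).
    """
    mapping = mapping or ColumnMapping()
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in mapping.required_columns() if c not in raw.columns]
    if missing:
        raise DataError(f"unmapped/absent required columns: {missing}")

    use = raw[mapping.required_columns()].copy()
    for col in use.columns:
        coerced = pd.to_numeric(use[col], errors="coerce")
        bad = coerced.isna() & use[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"non-numeric value {use[col].iloc[row]!r} in column {col!r} at row {row}"
            )
        use[col] = coerced
    n0 = len(use)
    use = use.dropna()
    dropped = n0 - len(use)
    if dropped:
        logger.info("dropped %d of %d rows with missing mapped values", dropped, n0)

    out = pd.DataFrame(index=use.index)
    out["sim_t1"] = use[mapping.sim_t1]
    out["sim_t2"] = use[mapping.sim_t2]
    for role, src in (("aux_t1", mapping.aux_t1), ("aux_t2", mapping.aux_t2)):
        out[role] = use[src].sum(axis=1) if isinstance(src, list) else use[src]
    trs = use[mapping.trs]
    if mapping.trs_is_binary:
        vals = set(np.unique(trs))
        if not vals <= {0, 1}:
            raise DataError(f"binary anchor column {mapping.trs!r} has values {sorted(vals)}")
        out["trs_improved"] = trs.astype(int)
    else:
        from .mic import dichotomize_trs

        out["trs7"] = trs.astype(int)
        out["trs_improved"], _ = dichotomize_trs(trs.to_numpy(), mapping.trs_cut)
    if mapping.sim_range is not None:
        lo, hi = mapping.sim_range
        obs_lo, obs_hi = float(out["sim_t1"].min()), float(out["sim_t1"].max())
        if obs_lo < lo or obs_hi > hi:
            raise DataError(
                f"SIM scores outside the declared range [{lo}, {hi}]"
            )
    return out.reset_index(drop=True)


def write_dataset(data: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write an observed-data table as delimited text with header."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    data.to_csv(path, sep=sep, index=False)
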