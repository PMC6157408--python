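"""Round-robin data container and CSV input/output.

Canonical on-disk format is a wide CSV with one row per four-member family:
``family_id``, the 12 dyadic columns ``x_MF`` ... ``x_ST`` (actor-major
order), then optional role-specific outcome columns ``y_M``..``y_S`` and
family-level predictor columns ``z_1``..``z_K``.  Missing values are empty
fields (``NA`` is also accepted on read).  A long format
(family_id, actor, partner, value) importer is provided and converted on
read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DYADS, ROLES

log = logging.getLogger(__name__)

__all__ = ["DYAD_COLUMNS", "RoundRobinData", "read_round_robin_csv",
           "read_round_robin_long", "write_round_robin_csv", "SchemaError"]

#: Mandatory dyadic measurement columns, actor-major order.
DYAD_COLUMNS: tuple[str, ...] = tuple(f"x_{d}" for d in DYADS)

OUTCOME_COLUMNS: tuple[str, ...] = tuple(f"y_{r}" for r in ROLES)


class SchemaError(ValueError):
    """Raised when an input table does not match the round-robin schema."""


@dataclass
class RoundRobinData:
    """Per-family dyadic measurements plus optional outcomes and predictors.

    ``table`` holds one row per family.  Dyadic values are floats with NaN
    marking missing entries; the mask is derived, never stored separately.
    """

    table: pd.DataFrame
    latent: pd.DataFrame | None = field(default=None, repr=False, compare=False)
    """Optional true latent effects (generator output only; 9 columns)."""

    def __post_init__(self) -> None:
        t = self.table
        if "family_id" not in t.columns:
            raise SchemaError("missing mandatory column family_id")
        for c in DYAD_COLUMNS:
            if c not in t.columns:
                raise SchemaError(f"missing mandatory dyad column {c}")
        unknown = [c for c in t.columns if c.startswith("x_") and c not in DYAD_COLUMNS]
        if unknown:
            raise SchemaError(f"unknown dyad column(s): {', '.join(unknown)}")
        if len(t) == 0:
            raise SchemaError("at least one family required")
        if t["family_id"].duplicated().any():
            dup = t.loc[t["family_id"].duplicated(), "family_id"].iloc[0]
            raise SchemaError(f"duplicate family_id {dup!r}")
        for c in DYAD_COLUMNS + tuple(self.outcome_columns) + tuple(self.predictor_columns):
            if not pd.api.types.is_numeric_dtype(t[c]):
                bad = t.index[pd.to_numeric(t[c], errors="coerce").isna() & t[c].notna()]
                row = bad[0] if len(bad) else "?"
                raise SchemaError(f"non-numeric cell in column {c}, row {row}")
        self.table = t.reset_index(drop=True)

    # ------------------------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        outcomes: dict[str, np.ndarray] | None = None,
        predictors: np.ndarray | None = None,
        family_ids: list | None = None,
        latent: np.ndarray | None = None,
    ) -> "RoundRobinData":
        """Assemble from an (n, 12) dyadic array plus optional extras."""
        values = np.asarray(values, dtype=float)
        n = values.shape[0]
        if values.shape != (n, 12):
            raise SchemaError("dyadic value array must be (n, 12)")
        tab = pd.DataFrame(values, columns=list(DYAD_COLUMNS))
        tab.insert(0, "family_id", family_ids if family_ids is not None else np.arange(1, n + 1))
        if outcomes:
            for r, y in outcomes.items():
                tab[f"y_{r}"] = np.asarray(y, dtype=float)
        if predictors is not None:
            predictors = np.atleast_2d(np.asarray(predictors, dtype=float))
            if predictors.shape[0] != n:
                predictors = predictors.T
            for k in range(predictors.shape[1]):
                tab[f"z_{k + 1}"] = predictors[:, k]
        lat = None
        if latent is not None:
            from .core import FACTORS

            lat = pd.DataFrame(np.asarray(latent, dtype=float), columns=list(FACTORS))
        return cls(tab, latent=lat)

    # ------------------------------------------------------------------
    @property
    def n_families(self) -> int:
        return len(self.table)

    @property
    def values(self) -> np.ndarray:
        """(n, 12) dyadic measurements with NaN for missing."""
        return self.table[list(DYAD_COLUMNS)].to_numpy(dtype=float)

    @property
    def mask(self) -> np.ndarray:
        """(n, 12) boolean, True where observed."""
        return ~np.isnan(self.values)

    @property
    def outcome_columns(self) -> list[str]:
        return [c for c in self.table.columns if c in OUTCOME_COLUMNS]

    @property
    def predictor_columns(self) -> list[str]:
        cols = [c for c in self.table.columns if c.startswith("z_")]
        return sorted(cols, key=lambda c: int(c.split("_", 1)[1]))

    def outcome(self, role: str) -> np.ndarray:
        col = f"y_{role}"
        if col not in self.table.columns:
            raise SchemaError(f"outcome column {col} not present")
        return self.table[col].to_numpy(dtype=float)

    def predictors(self) -> np.ndarray:
        """(n, K) predictor matrix z_1..z_K."""
        cols = self.predictor_columns
        if not cols:
            raise SchemaError("no predictor columns z_* present")
        return self.table[cols].to_numpy(dtype=float)

    def complete_rows(self) -> np.ndarray:
        """Boolean index of families with all 12 dyads observed."""
        return self.mask.all(axis=1)

    def missing_census(self) -> dict:
        """Counts of missing cells and of families with any missing dyad."""
        m = self.mask
        n_incomplete = int((~m.all(axis=1)).sum())
        return {
            "n_families": self.n_families,
            "n_missing_cells": int((~m).sum()),
            "n_incomplete_families": n_incomplete,
            "incomplete_family_rate": n_incomplete / self.n_families,
        }

    def subset(self, idx: np.ndarray) -> "RoundRobinData":
        lat = self.latent.iloc[idx].reset_index(drop=True) if self.latent is not None else None
        tab = self.table.iloc[idx].reset_index(drop=True)
        tab = tab.copy()
        # resampling may duplicate ids; keep originals in a side column
        if tab["family_id"].duplicated().any():
            tab["source_family_id"] = tab["family_id"]
            tab["family_id"] = np.arange(1, len(tab) + 1)
        return RoundRobinData(tab, latent=lat)


def read_round_robin_csv(path) -> RoundRobinData:
    """Read the canonical wide CSV; empty fields and ``NA`` are missing."""
    raw = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    for c in raw.columns:
        if c == "family_id":
            continue
        try:
            raw[c] = pd.to_numeric(raw[c])
        except (ValueError, TypeError):
            bad = raw.index[pd.to_numeric(raw[c], errors="coerce").isna() & raw[c].notna()]
            raise SchemaError(
                f"non-numeric cell in column {c}, row {bad[0] if len(bad) else '?'}"
            ) from None
    data = RoundRobinData(raw)
    census = data.missing_census()
    log.info(
        "read %d families from %s (%d incomplete, %.1f%%)",
        data.n_families, path, census["n_incomplete_families"],
        100 * census["incomplete_family_rate"],
    )
    return data


def read_round_robin_long(path) -> RoundRobinData:
    """Read a long CSV (family_id, actor, partner, value) and pivot to wide.

    Dyads absent from the file are treated as missing.  Extra wide columns
    (y_*, z_*) are not representable in long form.
    """
    raw = pd.read_csv(path, na_values=["NA"])
    for col in ("family_id", "actor", "partner", "value"):
        if col not in raw.columns:
            raise SchemaError(f"long format requires column {col}")
    raw["dyad"] = raw["actor"].astype(str).str.strip() + raw["partner"].astype(str).str.strip()
    bad = set(raw["dyad"]) - set(DYADS)
    if bad:
        raise SchemaError(f"invalid actor/partner pair(s): {sorted(bad)}")
    if raw.duplicated(["family_id", "dyad"]).any():
        raise SchemaError("duplicate (family_id, actor, partner) rows")
    wide = raw.pivot(index="family_id", columns="dyad", values="value")
    wide = wide.reindex(columns=list(DYADS))
    wide.columns = [f"x_{d}" for d in wide.columns]
    wide = wide.reset_index()
    return RoundRobinData(wide)


def write_round_robin_csv(data: RoundRobinData, path) -> None:
    """Write the canonical wide CSV (missing as empty fields)."""
    data.table.to_csv(path, index=False, na_rep="")
    log.info("wrote %d families to %s", data.n_families, path)
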