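"""Validated in-memory containers for the circulating-miRNA pipeline.

Count matrices are held feature x sample (miRNA rows, sample columns), the
orientation in which small-RNA count tables are distributed.  Sample metadata,
miRNA target tables and gene-set collections are thin validated wrappers
around pandas objects / plain sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("circmir")

CASE_LABEL = "DR"
CONTROL_LABEL = "NDR"


class ValidationError(ValueError):
    """Raised when an input object violates a container invariant."""


@dataclass
class CountMatrix:
    """Integer read-count matrix, mature (or precursor) miRNAs x samples.

    Parameters
    ----------
    counts
        DataFrame indexed by feature ID with one column per sample ID.
        Values must be non-negative integers (integral floats are rejected,
        not coerced).
    mature_map
        Optional precursor -> mature ID mapping carried along when the
        matrix is precursor-level (see :func:`circmir.io.read_count_matrix`).
    """

    counts: pd.DataFrame
    mature_map: dict[str, str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        df = self.counts
        if not isinstance(df, pd.DataFrame):
            raise ValidationError("counts must be a pandas DataFrame")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature IDs: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        if df.isna().any().any():
            r, c = np.argwhere(df.isna().values)[0]
            raise ValidationError(
                f"missing count at feature {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(values < 0):
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at feature {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if not np.allclose(values, np.round(values), rtol=0, atol=0):
            r, c = np.argwhere(values != np.round(values))[0]
            raise ValidationError(
                f"non-integer count at feature {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        self.counts = df.astype(np.int64)

    # -- accessors ---------------------------------------------------------
    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_features(self, keep: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[keep], mature_map=self.mature_map)


def validate_sample_table(
    table: pd.DataFrame,
    samples: list[str] | None = None,
    case_label: str = CASE_LABEL,
    control_label: str = CONTROL_LABEL,
) -> pd.DataFrame:
    """Validate a sample-metadata table (index = sample ID).

    Required columns: ``group`` (case/control label) and ``age`` (years).
    Optional: ``sex``, ``bmi``.  When ``samples`` is given, every sample of
    the count matrix must have exactly one metadata row; the table is
    reordered to match.
    """
    if "group" not in table.columns or "age" not in table.columns:
        raise ValidationError("sample table requires 'group' and 'age' columns")
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample IDs in metadata: {dups}")
    allowed = {case_label, control_label}
    bad = sorted(set(table["group"]) - allowed)
    if bad:
        raise ValidationError(f"unknown group labels {bad}; expected {sorted(allowed)}")
    if not np.issubdtype(np.asarray(table["age"]).dtype, np.number):
        raise ValidationError("age column must be numeric")
    if samples is not None:
        missing = [s for s in samples if s not in table.index]
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")
        table = table.loc[samples]
    n_case = int((table["group"] == case_label).sum())
    n_control = int((table["group"] == control_label).sum())
    if n_case == 0 or n_control == 0:
        raise ValidationError(
            f"both groups must be non-empty (got {case_label}={n_case}, "
            f"{control_label}={n_control})"
        )
    logger.info("sample metadata: %s=%d, %s=%d", case_label, n_case, control_label, n_control)
    return table


@dataclass
class GeneSetCollection:
    """Named gene sets plus a declared background universe size.

    ``background_size`` defaults to 20,000 (approximate protein-coding
    universe) and must cover every set when an explicit universe is given.
    """

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set[str] | None = None
    background_size: int = 20_000

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            if self.universe is not None:
                extra = members - self.universe
                if extra:
                    raise ValidationError(
                        f"gene set {name!r} has members outside the universe: "
                        f"{sorted(extra)[:5]}"
                    )
        if self.universe is not None:
            self.background_size = len(self.universe)
        if self.background_size < max((len(s) for s in self.sets.values()), default=0):
            raise ValidationError("background size smaller than largest gene set")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def validate_target_table(table: pd.DataFrame) -> pd.DataFrame:
    """Normalise and deduplicate a miRNA -> validated-target-gene table.

    Columns: ``mirna``, ``gene`` and optional ``evidence``.  Gene symbols and
    miRNA IDs are whitespace-stripped; duplicate (miRNA, gene) pairs after
    upper-casing gene symbols are dropped (count logged).
    """
    for col in ("mirna", "gene"):
        if col not in table.columns:
            raise ValidationError(f"target table requires a {col!r} column")
    out = table.copy()
    out["mirna"] = out["mirna"].astype(str).str.strip()
    out["gene"] = out["gene"].astype(str).str.strip().str.upper()
    if "evidence" not in out.columns:
        out["evidence"] = "validated"
    n_before = len(out)
    out = out.drop_duplicates(subset=["mirna", "gene"]).reset_index(drop=True)
    n_dropped = n_before - len(out)
    if n_dropped:
        logger.info("target table: dropped %d duplicate (miRNA, gene) pairs", n_dropped)
    return out
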