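"""Readers/writers for count tables, metadata, target tables and GMT gene sets,
plus mature-level merging and the abundance filter.

All tabular formats are TSV with a header row (UTF-8).  Readers validate and
reject malformed input rather than coercing it.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CountMatrix,
    GeneSetCollection,
    ValidationError,
    validate_sample_table,
    validate_target_table,
)

logger = logging.getLogger("circmir")


def read_count_matrix(path: str | Path, precursor_column: str | None = None) -> CountMatrix:
    """Read a TSV count table (first column = feature IDs, remaining = samples).

    If ``precursor_column`` names a column of the table, rows are taken to be
    precursor-level: the first column holds precursor (hairpin) IDs and
    ``precursor_column`` holds the mature miRNA each precursor produces.  The
    returned matrix is then precursor-level with the precursor->mature mapping
    attached as ``mature_map``, ready for :func:`merge_mature_counts`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    dups = sorted({h for h in header if h in seen or seen.add(h)})
    if dups:
        raise ValidationError(f"duplicate sample columns in {path.name}: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)

    mature_map = None
    if precursor_column is not None:
        if precursor_column not in df.columns:
            raise ValidationError(
                f"precursor column {precursor_column!r} not found in {path.name}"
            )
        mature_map = dict(zip(df.index, df[precursor_column]))
        df = df.drop(columns=[precursor_column])

    for col in df.columns:
        raw = df[col]
        if raw.isna().any():
            feat = raw.index[raw.isna()][0]
            raise ValidationError(
                f"missing value at feature {feat!r}, sample {col!r} in {path.name}"
            )
        try:
            df[col] = pd.to_numeric(raw)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric value in sample column {col!r}") from exc
    cm = CountMatrix(df, mature_map=mature_map)
    logger.info("read %d features x %d samples from %s", *cm.shape, path.name)
    return cm


def write_count_matrix(cm: CountMatrix, path: str | Path, index_label: str = "mirna") -> None:
    cm.counts.to_csv(path, sep="\t", index_label=index_label)


# keep the generic name used by round-trip callers
write_table = write_count_matrix


def merge_mature_counts(cm: CountMatrix, mapping: dict[str, str] | None = None) -> CountMatrix:
    """Sum counts of precursors that produce the same mature miRNA.

    A mature miRNA can be excised from several genomic hairpins; counts
    attributed to different precursors of the same mature form are summed per
    sample.  Output feature order is first-appearance order of mature IDs.
    """
    if mapping is None:
        mapping = cm.mature_map
    if mapping is None:
        raise ValidationError("no precursor->mature mapping supplied or attached")
    unmapped = [f for f in cm.features if f not in mapping]
    if unmapped:
        raise ValidationError(f"precursors missing from mapping: {unmapped}")

    mature_ids = [mapping[f] for f in cm.features]
    # groupby(sort=False) keeps first-appearance order of mature IDs
    merged = cm.counts.groupby(pd.Index(mature_ids, name=cm.counts.index.name), sort=False).sum()
    logger.info("merged %d precursors into %d mature miRNAs", cm.shape[0], merged.shape[0])
    return CountMatrix(merged)


def filter_low_abundance(cm: CountMatrix, min_total: int = 200) -> CountMatrix:
    """Drop miRNAs of insufficient abundance: total count (over all samples)
    strictly below ``min_total`` is excluded; the boundary total == min_total
    is retained.  Feature order is preserved."""
    totals = cm.row_totals()
    keep = totals[totals >= min_total].index.tolist()
    if not keep:
        raise ValidationError(
            f"abundance filter removed every feature (min_total={min_total}); "
            "review the threshold"
        )
    n_dropped = cm.shape[0] - len(keep)
    logger.info(
        "abundance filter (total >= %d): kept %d / %d features (%d excluded)",
        min_total, len(keep), cm.shape[0], n_dropped,
    )
    return cm.subset_features(keep)


def read_sample_metadata(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read sample metadata TSV: sample_id, group, age[, sex, bmi]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [c.strip().lower() for c in df.columns]
    return validate_sample_table(df, **kwargs)


def write_sample_metadata(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_target_table(path: str | Path) -> pd.DataFrame:
    """Read a miRNA -> validated target gene TSV (columns mirna, gene[, evidence])."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    return validate_target_table(df)


def write_target_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path, background_size: int = 20_000) -> GeneSetCollection:
    """Read a GMT gene-set file: name <TAB> description <TAB> member genes."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path.name}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(got {len(fields)})"
                )
            name, desc, *members = fields
            members = [m.strip().upper() for m in members if m.strip()]
            if name in sets:
                raise ValidationError(f"{path.name}:{lineno}: duplicate gene set {name!r}")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions, background_size=background_size)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
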