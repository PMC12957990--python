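"""CSV ingestion and validation for paired ratings tables.

Two dialects are supported, since clinics export both shapes:

* ``long`` -- one row per respondent-item:
  ``respondent_id,item,impaired,bothered``
* ``wide`` -- one row per respondent:
  ``respondent_id,impaired_home,bothered_home,...,impaired_work,bothered_work``

Item labels are the canonical tokens ``home, private_leisure, relationships,
social_leisure, work``; ratings are bare integers 0-8.  Strict mode raises on
the first violation, naming the row and the reason; lenient mode drops
invalid records and logs how many were excluded, leaving downstream analyses
pairwise-complete per item.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import RATING_MAX, RATING_MIN, ItemId, RatingsTable

logger = logging.getLogger(__name__)

LONG_COLUMNS = ["respondent_id", "item", "impaired", "bothered"]


def _wide_columns() -> list[str]:
    cols = ["respondent_id"]
    for item in ItemId:
        cols += [f"impaired_{item.value}", f"bothered_{item.value}"]
    return cols


class DialectError(ValueError):
    pass


class StrictModeError(ValueError):
    """A validation failure while reading in strict mode; names row and reason."""


def _parse_rating(raw, row_no: int, col: str, strict: bool) -> float:
    """Return the rating as float.

    Lenient mode keeps out-of-range integers (so validation can count them)
    and maps missing/non-integer entries to NaN.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
        if strict:
            raise StrictModeError(f"row {row_no}: missing {col} rating")
        return np.nan
    s = str(raw).strip()
    try:
        value = int(s)
    except ValueError:
        if strict:
            raise StrictModeError(f"row {row_no}: {col} rating {raw!r} is not an integer") from None
        return np.nan
    if strict and not RATING_MIN <= value <= RATING_MAX:
        raise StrictModeError(
            f"row {row_no}: {col} rating {value} outside the "
            f"{RATING_MIN}-{RATING_MAX} range"
        )
    return float(value)


def _read_long(frame: pd.DataFrame, strict: bool) -> pd.DataFrame:
    rows = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # 1 = header
        try:
            item = ItemId.from_token(str(row.item))
        except ValueError as exc:
            if strict:
                raise StrictModeError(f"row {i}: {exc}") from None
            continue
        rows.append(
            (
                str(row.respondent_id).strip(),
                item.value,
                _parse_rating(row.impaired, i, "impaired", strict),
                _parse_rating(row.bothered, i, "bothered", strict),
            )
        )
    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def _read_wide(frame: pd.DataFrame, strict: bool) -> pd.DataFrame:
    rows = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        rid = str(row.respondent_id).strip()
        for item in ItemId:
            imp = _parse_rating(getattr(row, f"impaired_{item.value}"), i, "impaired", strict)
            bot = _parse_rating(getattr(row, f"bothered_{item.value}"), i, "bothered", strict)
            rows.append((rid, item.value, imp, bot))
    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def scan_ratings(path, dialect: str = "long") -> RatingsTable:
    """Parse a ratings CSV leniently, keeping violations in the frame.

    Out-of-range values, duplicates and missing ratings are preserved so that
    :func:`wsas_audit.model.validate` can count them; analysis code should
    use :func:`read_ratings` instead.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise OSError(f"cannot read ratings file {path}: {exc}") from exc

    if dialect == "long":
        expected = LONG_COLUMNS
    elif dialect == "wide":
        expected = _wide_columns()
    else:
        raise DialectError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")
    if list(raw.columns) != expected:
        raise DialectError(
            f"{path}: header {list(raw.columns)} does not match the {dialect} "
            f"dialect {expected}"
        )
    frame = _read_long(raw, False) if dialect == "long" else _read_wide(raw, False)
    return RatingsTable(frame, provenance=str(path))


def read_ratings(path, dialect: str = "long", strict: bool = True) -> RatingsTable:
    """Read and validate a paired-ratings CSV into a RatingsTable."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise OSError(f"cannot read ratings file {path}: {exc}") from exc

    if dialect == "long":
        expected = LONG_COLUMNS
    elif dialect == "wide":
        expected = _wide_columns()
    else:
        raise DialectError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")
    if list(raw.columns) != expected:
        raise DialectError(
            f"{path}: header {list(raw.columns)} does not match the {dialect} "
            f"dialect {expected}"
        )

    frame = _read_long(raw, strict) if dialect == "long" else _read_wide(raw, strict)

    if not strict:
        bad = (
            (frame["impaired"] < RATING_MIN)
            | (frame["impaired"] > RATING_MAX)
            | (frame["bothered"] < RATING_MIN)
            | (frame["bothered"] > RATING_MAX)
        )
        if bad.any():
            logger.warning("dropping %d out-of-range records", int(bad.sum()))
            frame = frame[~bad]

    dup_mask = frame.duplicated(subset=["respondent_id", "item"], keep="first")
    if dup_mask.any():
        first = frame[dup_mask].iloc[0]
        if strict:
            raise StrictModeError(
                f"duplicate ratings for respondent {first.respondent_id!r}, "
                f"item {first.item!r}"
            )
        logger.warning("dropping %d duplicate respondent-item rows", int(dup_mask.sum()))
        frame = frame[~dup_mask]

    incomplete = frame[["impaired", "bothered"]].isna().any(axis=1)
    if incomplete.any():
        # strict mode already raised row-by-row; only reachable when lenient
        logger.warning("dropping %d records with missing/invalid ratings", int(incomplete.sum()))
        frame = frame[~incomplete]

    frame = frame.copy()
    frame[["impaired", "bothered"]] = frame[["impaired", "bothered"]].astype(np.int64)

    if strict:
        per_resp = frame.groupby("respondent_id")["item"].count()
        short = per_resp[per_resp != len(ItemId)]
        if len(short):
            rid = short.index[0]
            raise StrictModeError(
                f"respondent {rid!r} has {short.iloc[0]} items; strict mode "
                f"requires all {len(ItemId)}"
            )
    return RatingsTable(frame, provenance=str(path))


def write_ratings(table: RatingsTable, path, dialect: str = "long") -> None:
    """Write a ratings table as CSV in the named dialect."""
    path = Path(path)
    frame = table.frame.dropna(subset=["impaired", "bothered"]).copy()
    frame[["impaired", "bothered"]] = frame[["impaired", "bothered"]].astype(np.int64)
    if dialect == "long":
        frame.to_csv(path, index=False)
        return
    if dialect == "wide":
        wide = frame.pivot(index="respondent_id", columns="item")
        cols = _wide_columns()[1:]
        wide.columns = [f"{kind}_{item}" for kind, item in wide.columns]
        wide = wide.reindex(columns=cols).astype("Int64")  # keeps bare ints despite gaps
        wide.reset_index().to_csv(path, index=False)
        return
    raise DialectError(f"unknown dialect {dialect!r}")
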