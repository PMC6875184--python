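"""Canonical in-memory representation of administrative-claims study data.

A :class:`ClaimsDataset` bundles four tables — members, enrollment spans,
medical claims and chart-adjudication labels — as pandas DataFrames with a
fixed, validated schema. CSV readers/writers round-trip the dataset
losslessly up to row order.

CSV schemas (UTF-8, comma-delimited, RFC-4180 quoting, header row required):

* ``members.csv``:      member_id, sex, birth_year
* ``enrollment.csv``:   member_id, start_date, end_date
* ``claims.csv``:       claim_id, member_id, service_date, setting,
                        provider_id, principal_dx_flag, dx_codes
* ``adjudication.csv``: member_id, reviewer_id, label, alternative_dx

Dates are ISO-8601; enrollment span endpoints are inclusive. ``dx_codes`` is
a semicolon-delimited list of ICD-9-CM codes, stored dot-stripped internally.
``principal_dx_flag`` marks the first-listed code as the principal diagnosis.
Overlapping or abutting enrollment spans are merged into maximal disjoint
spans at load time; spans separated by one or more uncovered days are kept
apart (any gap tolerance is applied later, by the screening engine).
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .codes import normalize_dx_code
from .errors import ReferentialIntegrityError, RowParseError, SchemaError

logger = logging.getLogger(__name__)

ONE_DAY = pd.Timedelta(days=1)

SEXES = frozenset({"F", "M"})
SETTINGS = frozenset({"inpatient", "outpatient"})
ADJUDICATION_LABELS = ("confirmed", "not_endometrial", "non_evaluable")

MEMBER_COLUMNS = ["member_id", "sex", "birth_year"]
ENROLLMENT_COLUMNS = ["member_id", "start_date", "end_date"]
CLAIM_COLUMNS = [
    "claim_id",
    "member_id",
    "service_date",
    "setting",
    "provider_id",
    "principal_dx_flag",
    "dx_codes",
]
ADJUDICATION_COLUMNS = ["member_id", "reviewer_id", "label", "alternative_dx"]

_TABLE_FILES = {
    "members": "members.csv",
    "enrollment": "enrollment.csv",
    "claims": "claims.csv",
    "adjudication": "adjudication.csv",
}


@dataclass
class ClaimsDataset:
    """Joined member / enrollment / claims / adjudication tables.

    Every ``member_id`` referenced by the three satellite tables must exist
    in ``members``; :meth:`validate` enforces this and all per-table
    invariants and is run automatically by :func:`read_dataset`.
    """

    members: pd.DataFrame
    enrollment: pd.DataFrame
    claims: pd.DataFrame
    adjudication: pd.DataFrame = field(default_factory=lambda: empty_table("adjudication"))

    def validate(self) -> "ClaimsDataset":
        _validate_members(self.members)
        _validate_enrollment(self.enrollment)
        _validate_claims(self.claims)
        _validate_adjudication(self.adjudication)
        self._check_referential_integrity()
        return self

    def _check_referential_integrity(self) -> None:
        known = set(self.members["member_id"])
        for name, table in (
            ("claims", self.claims),
            ("enrollment", self.enrollment),
            ("adjudication", self.adjudication),
        ):
            dangling = sorted(set(table["member_id"]) - known)
            if dangling:
                raise ReferentialIntegrityError(
                    f"{name} references unknown member_id(s): {', '.join(dangling)}",
                    offenders=dangling,
                )

    def sorted(self) -> "ClaimsDataset":
        """Canonically row-ordered copy (used for order-insensitive comparison)."""
        return ClaimsDataset(
            members=self.members.sort_values("member_id", ignore_index=True),
            enrollment=self.enrollment.sort_values(
                ["member_id", "start_date"], ignore_index=True
            ),
            claims=self.claims.sort_values(
                ["member_id", "service_date", "claim_id"], ignore_index=True
            ),
            adjudication=self.adjudication.sort_values(
                ["member_id", "reviewer_id"], ignore_index=True
            ),
        )


def empty_table(name: str) -> pd.DataFrame:
    columns = {
        "members": MEMBER_COLUMNS,
        "enrollment": ENROLLMENT_COLUMNS,
        "claims": CLAIM_COLUMNS,
        "adjudication": ADJUDICATION_COLUMNS,
    }[name]
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


def empty_dataset() -> ClaimsDataset:
    return ClaimsDataset(
        members=empty_table("members"),
        enrollment=empty_table("enrollment"),
        claims=empty_table("claims"),
        adjudication=empty_table("adjudication"),
    )


# ---------------------------------------------------------------------------
# reading


def read_dataset(paths: Mapping[str, Path | str] | Path | str) -> ClaimsDataset:
    """Read, validate and normalize a dataset from per-table CSV files.

    ``paths`` is either a directory containing the four standard file names
    or a mapping with keys ``members``, ``enrollment``, ``claims`` and
    (optionally) ``adjudication``. Returns a validated dataset with merged
    enrollment spans and normalized diagnosis codes.
    """
    if isinstance(paths, (str, Path)):
        directory = Path(paths)
        paths = {
            name: directory / fname
            for name, fname in _TABLE_FILES.items()
            if name != "adjudication" or (directory / fname).exists()
        }
    for required in ("members", "enrollment", "claims"):
        if required not in paths:
            raise SchemaError(f"no path given for required table '{required}'")

    members = _read_members(Path(paths["members"]))
    enrollment = _read_enrollment(Path(paths["enrollment"]))
    claims = _read_claims(Path(paths["claims"]))
    if "adjudication" in paths:
        adjudication = _read_adjudication(Path(paths["adjudication"]))
    else:
        adjudication = empty_table("adjudication")

    return ClaimsDataset(members, enrollment, claims, adjudication).validate()


def _read_csv(path: Path, expected: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in expected]
    if extra:
        logger.warning("%s: ignoring unknown column(s): %s", path.name, ", ".join(extra))
    return df[expected]


def _parse_dates(series: pd.Series, path: Path, column: str) -> pd.Series:
    parsed = pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & series.astype(str).str.len().gt(0)
    bad |= series.astype(str).str.len().eq(0)
    if bad.any():
        row = int(bad.idxmax())
        raise RowParseError(
            f"unparseable ISO-8601 date {series.iloc[row]!r} in column '{column}'",
            path=str(path),
            line=row + 2,  # 1-based, after header
        )
    return parsed


def _read_members(path: Path) -> pd.DataFrame:
    df = _read_csv(path, MEMBER_COLUMNS)
    years = pd.to_numeric(df["birth_year"], errors="coerce")
    if years.isna().any():
        row = int(years.isna().idxmax())
        raise RowParseError(
            f"unparseable birth_year {df['birth_year'].iloc[row]!r}",
            path=str(path), line=row + 2,
        )
    df["birth_year"] = years.astype(int)
    return df


def _read_enrollment(path: Path) -> pd.DataFrame:
    df = _read_csv(path, ENROLLMENT_COLUMNS)
    for col in ("start_date", "end_date"):
        df[col] = _parse_dates(df[col], path, col)
    return merge_enrollment_spans(df)


def _read_claims(path: Path) -> pd.DataFrame:
    df = _read_csv(path, CLAIM_COLUMNS)
    df["service_date"] = _parse_dates(df["service_date"], path, "service_date")
    df["provider_id"] = df["provider_id"].replace("", None)
    df["principal_dx_flag"] = df["principal_dx_flag"].map(_parse_optional_bool)
    dx = []
    for i, raw in enumerate(df["dx_codes"]):
        parts = [p for p in str(raw).split(";") if p.strip()]
        if not parts:
            raise RowParseError("empty dx_codes", path=str(path), line=i + 2)
        dx.append(tuple(normalize_dx_code(p) for p in parts))
    df["dx_codes"] = dx
    return df


def _parse_optional_bool(raw: str):
    value = str(raw).strip().lower()
    if value in ("", "na", "none"):
        return None
    if value in ("true", "1", "t", "yes"):
        return True
    if value in ("false", "0", "f", "no"):
        return False
    raise RowParseError(f"unparseable boolean {raw!r} in principal_dx_flag")


def _read_adjudication(path: Path) -> pd.DataFrame:
    df = _read_csv(path, ADJUDICATION_COLUMNS)
    df["alternative_dx"] = df["alternative_dx"].replace("", None)
    return df


# ---------------------------------------------------------------------------
# per-table invariants


def _validate_members(df: pd.DataFrame) -> None:
    if df["member_id"].duplicated().any():
        dupes = sorted(df.loc[df["member_id"].duplicated(), "member_id"].unique())
        raise SchemaError(f"duplicate member_id(s): {', '.join(map(str, dupes))}")
    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        raise SchemaError(f"invalid sex value(s): {sorted(df.loc[bad_sex, 'sex'].unique())}")
    if len(df) and not df["birth_year"].between(1890, 2014).all():
        raise SchemaError("birth_year outside [1890, 2014]")


def _validate_enrollment(df: pd.DataFrame) -> None:
    if len(df) and (df["start_date"] > df["end_date"]).any():
        raise SchemaError("enrollment span with start_date > end_date")


def _validate_claims(df: pd.DataFrame) -> None:
    bad = ~df["setting"].isin(SETTINGS)
    if bad.any():
        raise SchemaError(f"invalid setting value(s): {sorted(df.loc[bad, 'setting'].unique())}")
    if any(len(codes) == 0 for codes in df["dx_codes"]):
        raise SchemaError("claim with empty dx_codes")


def _validate_adjudication(df: pd.DataFrame) -> None:
    bad = ~df["label"].isin(ADJUDICATION_LABELS)
    if bad.any():
        raise SchemaError(f"invalid adjudication label(s): {sorted(df.loc[bad, 'label'].unique())}")
    if df.duplicated(subset=["member_id", "reviewer_id"]).any():
        raise SchemaError("more than one adjudication record per (member_id, reviewer_id)")


# ---------------------------------------------------------------------------
# enrollment-span merging


def merge_enrollment_spans(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping and abutting spans into maximal disjoint spans.

    Abutting means the next span starts the day after the previous ends;
    spans separated by at least one uncovered day stay distinct. Total
    covered days are preserved.
    """
    if df.empty:
        return df.reset_index(drop=True)
    df = df.sort_values(["member_id", "start_date", "end_date"])
    rows: list[tuple] = []
    for member_id, group in df.groupby("member_id", sort=True):
        cur_start = cur_end = None
        for start, end in zip(group["start_date"], group["end_date"]):
            if cur_start is None:
                cur_start, cur_end = start, end
            elif start <= cur_end + ONE_DAY:
                cur_end = max(cur_end, end)
            else:
                rows.append((member_id, cur_start, cur_end))
                cur_start, cur_end = start, end
        rows.append((member_id, cur_start, cur_end))
    return pd.DataFrame(rows, columns=ENROLLMENT_COLUMNS)


# ---------------------------------------------------------------------------
# writing


def write_dataset(dataset: ClaimsDataset, paths: Mapping[str, Path | str] | Path | str) -> dict[str, Path]:
    """Write the four tables as CSV files; inverse of :func:`read_dataset`.

    Returns the mapping of table name to written path. Empty tables produce
    header-only files.
    """
    if isinstance(paths, (str, Path)):
        directory = Path(paths)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {name: directory / fname for name, fname in _TABLE_FILES.items()}
    written: dict[str, Path] = {}

    out = dataset.members.copy()
    written["members"] = _write_csv(out, Path(paths["members"]))

    out = dataset.enrollment.copy()
    for col in ("start_date", "end_date"):
        out[col] = _format_dates(out[col])
    written["enrollment"] = _write_csv(out, Path(paths["enrollment"]))

    out = dataset.claims.copy()
    out["service_date"] = _format_dates(out["service_date"])
    out["provider_id"] = out["provider_id"].map(lambda v: "" if v is None else v)
    out["principal_dx_flag"] = out["principal_dx_flag"].map(
        lambda v: "" if v is None else ("true" if v else "false")
    )
    out["dx_codes"] = out["dx_codes"].map(";".join)
    written["claims"] = _write_csv(out, Path(paths["claims"]))

    out = dataset.adjudication.copy()
    out["alternative_dx"] = out["alternative_dx"].map(lambda v: "" if v is None else v)
    written["adjudication"] = _write_csv(out, Path(paths["adjudication"]))
    return written


def _format_dates(series: pd.Series) -> pd.Series:
    if series.empty:
        return series
    return pd.to_datetime(series).dt.strftime("%Y-%m-%d")


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def datasets_equal(a: ClaimsDataset, b: ClaimsDataset) -> bool:
    """Order-insensitive dataset equality (the round-trip contract)."""
    a, b = a.sorted(), b.sorted()
    for name in ("members", "enrollment", "claims", "adjudication"):
        ta, tb = getattr(a, name), getattr(b, name)
        if len(ta) != len(tb):
            return False
        if len(ta) == 0:
            continue
        try:
            pd.testing.assert_frame_equal(ta, tb, check_dtype=False)
        except AssertionError:
            return False
    return True
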