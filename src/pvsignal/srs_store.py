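"""Load, validate, deduplicate and filter JADER-style spontaneous-report tables.

A spontaneous reporting system (SRS) extract arrives as four relational CSV
tables keyed by a case identifier and a version number:

* ``DEMO`` — one row per report version: sex, age band, body-weight band.
* ``DRUG`` — drug entries: name, role (suspected / concomitant /
  interacting), administration route, start and end dates.
* ``REAC`` — adverse-event entries: MedDRA preferred-term (PT) code and
  onset date.
* ``HIST`` — comorbidity terms; carried through but unused by the
  statistics.

Dates are ISO ``YYYY-MM-DD``; a ``YYYY-MM`` value is retained but flagged
incomplete (usable for counting, never for time-to-onset). All category
fields are closed vocabularies validated at load time.

The in-memory container, :class:`ReportSet`, wraps the four tables as
pandas DataFrames with a synthetic ``report_id`` (``case.vN``) so that
pre-deduplication versions stay distinguishable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = frozenset({"male", "female", "unspecified"})
AGE_BANDS = frozenset({"<20", "20-59", ">=60", "unspecified"})
WEIGHT_BANDS = frozenset({"<40", "40-69", ">=70", "unspecified"})
ROLES = frozenset({"suspected", "concomitant", "interacting"})
ROUTES = frozenset({"intravenous", "oral", "other", "unspecified"})

DEMO_COLUMNS = ["case_id", "version", "sex", "age_band", "weight_band"]
DRUG_COLUMNS = ["case_id", "version", "drug_name", "role", "route",
                "start_date", "end_date"]
REAC_COLUMNS = ["case_id", "version", "pt_code", "onset_date"]
HIST_COLUMNS = ["case_id", "version", "term"]


class SchemaError(ValueError):
    """A required column is missing or a closed-vocabulary field is violated."""


class LoadError(ValueError):
    """The table content is structurally invalid (e.g. duplicated key rows)."""


def parse_partial_date(value) -> tuple[pd.Timestamp, bool]:
    """Parse an ISO date that may be truncated to year-month.

    Returns ``(timestamp, complete)``. ``YYYY-MM`` parses to the first of
    the month with ``complete=False``; an empty/missing value returns
    ``(NaT, False)``. Anything else must be a full ``YYYY-MM-DD``.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return pd.NaT, False
    s = str(value).strip()
    if not s or s.lower() in {"nan", "na"}:
        return pd.NaT, False
    parts = s.split("-")
    if len(parts) == 2:
        return pd.Timestamp(int(parts[0]), int(parts[1]), 1), False
    if len(parts) == 3:
        return pd.Timestamp(int(parts[0]), int(parts[1]), int(parts[2])), True
    raise ValueError(f"unparseable date {value!r}; expected YYYY-MM-DD or YYYY-MM")


def _parse_date_column(frame: pd.DataFrame, column: str) -> None:
    # vectorised equivalent of parse_partial_date over a whole column
    s = frame[column].astype(str).str.strip()
    s = s.mask(s.str.lower().isin({"nan", "na", "none"}), "")
    length = s.str.len()
    unknown = ~length.isin([0, 7, 10])
    if unknown.any():
        raise ValueError(f"unparseable date {s[unknown].iloc[0]!r} in "
                         f"{column}; expected YYYY-MM-DD or YYYY-MM")
    full = pd.to_datetime(s.where(length == 10), format="%Y-%m-%d")
    partial = pd.to_datetime(s.where(length == 7), format="%Y-%m")
    frame[column] = full.fillna(partial)
    frame[column + "_complete"] = (length == 10).to_numpy()


def _require_columns(frame: pd.DataFrame, columns: Iterable[str], table: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{table} table is missing required column(s): "
                          + ", ".join(missing))


def _check_vocabulary(frame: pd.DataFrame, column: str, allowed: frozenset,
                      table: str) -> None:
    bad = set(frame[column].unique()) - allowed
    if bad:
        raise SchemaError(
            f"{table}.{column} contains value(s) outside the closed vocabulary "
            f"{sorted(allowed)}: {sorted(map(str, bad))}")


@dataclass
class ReportSet:
    """Normalised relational view of the four SRS tables.

    Each table carries ``report_id`` (= ``{case_id}.v{version}``) so entries
    in DRUG/REAC/HIST unambiguously reference a DEMO row even before
    deduplication.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    hist: pd.DataFrame
    deduplicated: bool = False
    incomplete_date_rows: int = 0

    @property
    def report_ids(self) -> frozenset:
        return frozenset(self.demo["report_id"])

    def __len__(self) -> int:
        return len(self.demo)

    @classmethod
    def from_frames(cls, demo: pd.DataFrame, drug: pd.DataFrame,
                    reac: pd.DataFrame, hist: pd.DataFrame,
                    alias_map: Mapping[str, str] | None = None) -> "ReportSet":
        """Validate raw tables (strings, pre-parsing) and build a ReportSet."""
        demo = demo.copy()
        drug = drug.copy()
        reac = reac.copy()
        hist = hist.copy()

        _require_columns(demo, DEMO_COLUMNS, "DEMO")
        _require_columns(drug, DRUG_COLUMNS, "DRUG")
        _require_columns(reac, REAC_COLUMNS, "REAC")
        _require_columns(hist, HIST_COLUMNS, "HIST")

        # reject rows whose key is unparseable rather than failing the load
        for name, frame in (("DEMO", demo), ("DRUG", drug),
                            ("REAC", reac), ("HIST", hist)):
            case = frame["case_id"].astype(str).str.strip()
            version = pd.to_numeric(frame["version"], errors="coerce")
            ok = (case != "") & version.notna()
            rejected = int((~ok).sum())
            if rejected:
                logger.warning("%s: rejected %d row(s) with unparseable report id",
                               name, rejected)
            frame.drop(index=frame.index[~ok], inplace=True)
            frame["case_id"] = case[ok]
            frame["version"] = version[ok].astype(int)
            frame["report_id"] = (frame["case_id"] + ".v"
                                  + frame["version"].astype(str))

        if demo.duplicated(subset=["case_id", "version"]).any():
            dup = demo[demo.duplicated(subset=["case_id", "version"])]
            raise LoadError("DEMO contains duplicated (case_id, version) rows: "
                            + ", ".join(dup["report_id"].head(5)))

        for col, vocab in (("sex", SEXES), ("age_band", AGE_BANDS),
                           ("weight_band", WEIGHT_BANDS)):
            demo[col] = demo[col].astype(str).str.strip()
            _check_vocabulary(demo, col, vocab, "DEMO")

        alias = {str(k).strip().lower(): str(v).strip().lower()
                 for k, v in (alias_map or {}).items()}
        names = drug["drug_name"].astype(str).str.strip().str.lower()
        drug["drug_name"] = names.map(lambda n: alias.get(n, n))
        drug["role"] = drug["role"].astype(str).str.strip().str.lower()
        drug["route"] = drug["route"].astype(str).str.strip().str.lower()
        _check_vocabulary(drug, "role", ROLES, "DRUG")
        _check_vocabulary(drug, "route", ROUTES, "DRUG")

        reac["pt_code"] = reac["pt_code"].astype(str).str.strip()
        if (reac["pt_code"] == "").any():
            raise SchemaError("REAC.pt_code contains empty values")

        _parse_date_column(drug, "start_date")
        _parse_date_column(drug, "end_date")
        _parse_date_column(reac, "onset_date")

        bad_interval = (drug["start_date"].notna() & drug["end_date"].notna()
                        & drug["start_date_complete"] & drug["end_date_complete"]
                        & (drug["end_date"] < drug["start_date"]))
        if bad_interval.any():
            logger.warning("DRUG: %d entr(ies) with end_date < start_date kept "
                           "but will be treated as inconsistent downstream",
                           int(bad_interval.sum()))

        incomplete = int((drug["start_date"].notna() & ~drug["start_date_complete"]).sum()
                         + (reac["onset_date"].notna() & ~reac["onset_date_complete"]).sum())
        if incomplete:
            logger.info("retained %d partial (year-month) date value(s); "
                        "flagged incomplete", incomplete)

        return cls(demo=demo, drug=drug, reac=reac, hist=hist,
                   incomplete_date_rows=incomplete)


def load_tables(demo_path, drug_path, reac_path, hist_path,
                alias_map: Mapping[str, str] | str | Path | None = None) -> ReportSet:
    """Load the four SRS CSV tables into a validated :class:`ReportSet`.

    ``alias_map`` maps brand / salt-form names to one canonical active
    ingredient; it may be a mapping or a path to a two-column CSV
    ``alias,canonical``.
    """
    if isinstance(alias_map, (str, Path)):
        alias_map = load_alias_map(alias_map)
    frames = {}
    for name, path in (("DEMO", demo_path), ("DRUG", drug_path),
                       ("REAC", reac_path), ("HIST", hist_path)):
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"{name} table not found: {path}")
        frames[name] = pd.read_csv(path, dtype=str, keep_default_na=False)
    logger.info("loaded DEMO=%d DRUG=%d REAC=%d HIST=%d rows",
                *(len(frames[k]) for k in ("DEMO", "DRUG", "REAC", "HIST")))
    return ReportSet.from_frames(frames["DEMO"], frames["DRUG"],
                                 frames["REAC"], frames["HIST"], alias_map)


def load_alias_map(path) -> dict[str, str]:
    frame = pd.read_csv(path, dtype=str)
    _require_columns(frame, ["alias", "canonical"], "alias map")
    return dict(zip(frame["alias"], frame["canonical"]))


def deduplicate(rs: ReportSet) -> ReportSet:
    """Keep only the highest version of each case number.

    JADER distributes successive versions of a case as separate report
    rows; the latest version supersedes earlier ones. Idempotent; the
    number of removed report versions is logged.
    """
    demo = rs.demo
    keep = demo.groupby("case_id")["version"].transform("max") == demo["version"]
    removed = int((~keep).sum())
    if removed:
        logger.info("deduplicate: removed %d superseded report version(s)", removed)
    kept_ids = set(demo.loc[keep, "report_id"])
    return ReportSet(
        demo=demo[keep].reset_index(drop=True),
        drug=rs.drug[rs.drug["report_id"].isin(kept_ids)].reset_index(drop=True),
        reac=rs.reac[rs.reac["report_id"].isin(kept_ids)].reset_index(drop=True),
        hist=rs.hist[rs.hist["report_id"].isin(kept_ids)].reset_index(drop=True),
        deduplicated=True,
        incomplete_date_rows=rs.incomplete_date_rows,
    )


def eligible_reports(rs: ReportSet, drug: str,
                     allowed_routes: Iterable[str] = ROUTES,
                     include_unspecified_route: bool = True) -> frozenset:
    """Report ids in which ``drug`` is a *suspected* drug given by an allowed route.

    A report qualifies iff it has at least one entry for the drug with
    role ``suspected`` and route in ``allowed_routes``. Route fields are
    frequently blank in SRS data, so ``unspecified`` is admitted by
    default (a missing route never excludes a suspected-drug report); set
    ``include_unspecified_route=False`` for the strict rule. Reports where
    the drug appears only as concomitant/interacting do not qualify.
    """
    drug = str(drug).strip().lower()
    d = rs.drug
    if not (d["drug_name"] == drug).any():
        logger.warning("eligible_reports: drug %r not present in DRUG table", drug)
        return frozenset()
    routes = set(allowed_routes)
    if include_unspecified_route:
        routes |= {"unspecified"}
    bad = routes - ROUTES
    if bad:
        raise ValueError(f"unknown route(s): {sorted(bad)}")
    mask = ((d["drug_name"] == drug) & (d["role"] == "suspected")
            & d["route"].isin(routes))
    return frozenset(d.loc[mask, "report_id"])


def demographic_summary(rs: ReportSet, report_ids: Iterable[str]) -> pd.DataFrame:
    """Count-and-percent table by sex, age band and weight band.

    Returns a tidy frame ``(axis, band, count, percent)``; within each
    axis the counts sum to ``len(report_ids)`` and percentages are taken
    against that total (0.0 for an empty id set).
    """
    ids = set(report_ids)
    sub = rs.demo[rs.demo["report_id"].isin(ids)]
    total = len(ids)
    rows = []
    for axis, bands in (("sex", SEXES), ("age_band", AGE_BANDS),
                        ("weight_band", WEIGHT_BANDS)):
        counts = sub[axis].value_counts()
        for band in sorted(bands):
            n = int(counts.get(band, 0))
            pct = 100.0 * n / total if total else 0.0
            rows.append({"axis": axis, "band": band, "count": n,
                         "percent": pct})
    return pd.DataFrame(rows, columns=["axis", "band", "count", "percent"])
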