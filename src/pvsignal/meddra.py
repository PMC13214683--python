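"""PT → SMQ aggregation with a user-supplied term dictionary.

MedDRA content is licensed and cannot be redistributed, so the mapping
from preferred terms (PTs) to Standardized MedDRA Queries (SMQs) is an
input artifact: a CSV with columns ``pt_code, smq_id, scope, smq_name``
where ``scope`` is ``narrow`` or ``broad``. Mappings are many-to-many.

Aggregation follows the once-per-report rule: an adverse-event term
contributes at most one count per report, and a report belongs to an SMQ
iff at least one of its PTs maps into it with the requested scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .srs_store import ReportSet

logger = logging.getLogger(__name__)

SCOPES = frozenset({"narrow", "broad"})


class DictionaryError(ValueError):
    """The term dictionary violates its schema (scope enum, duplicate pairs)."""


@dataclass
class TermDictionary:
    """Set of (pt_code, smq_id, scope) mappings plus SMQ display names."""

    entries: pd.DataFrame           # columns: pt_code, smq_id, scope
    smq_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in ("pt_code", "smq_id", "scope")
                   if c not in self.entries.columns]
        if missing:
            raise DictionaryError("dictionary is missing column(s): "
                                  + ", ".join(missing))
        bad = set(self.entries["scope"]) - SCOPES
        if bad:
            raise DictionaryError(f"invalid scope value(s): {sorted(bad)}; "
                                  "scope must be 'narrow' or 'broad'")
        if self.entries.duplicated(subset=["pt_code", "smq_id"]).any():
            dup = self.entries[self.entries.duplicated(subset=["pt_code", "smq_id"])]
            raise DictionaryError(
                "duplicate (pt_code, smq_id) pair(s): "
                + ", ".join(dup["pt_code"].astype(str).head(5)))
        for smq in self.entries["smq_id"].unique():
            self.smq_names.setdefault(smq, smq)

    def mapping(self, scope: str = "narrow") -> dict[str, frozenset]:
        """pt_code → frozenset of smq_ids, restricted to one scope."""
        if scope not in SCOPES:
            raise ValueError(f"scope must be one of {sorted(SCOPES)}")
        sub = self.entries[self.entries["scope"] == scope]
        return {pt: frozenset(g) for pt, g in sub.groupby("pt_code")["smq_id"]}

    def __len__(self) -> int:
        return len(self.entries)


def load_dictionary(path) -> TermDictionary:
    """Load a PT→SMQ dictionary CSV (pt_code, smq_id, scope, smq_name)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("pt_code", "smq_id", "scope", "smq_name"):
        if col not in frame.columns:
            raise DictionaryError(f"dictionary is missing column(s): {col}")
    frame["scope"] = frame["scope"].str.strip().str.lower()
    names = dict(zip(frame["smq_id"], frame["smq_name"]))
    return TermDictionary(entries=frame[["pt_code", "smq_id", "scope"]],
                          smq_names=names)


@dataclass
class EventMatrix:
    """Report → set-of-terms membership at PT or SMQ level.

    ``membership`` maps each report id to the (duplicate-free) set of term
    ids recorded for it; reports with no qualifying term are absent.
    """

    level: str                               # "PT" or "SMQ"
    membership: dict[str, frozenset]
    term_names: dict[str, str] = field(default_factory=dict)

    def reports_by_term(self) -> dict[str, frozenset]:
        """Invert the membership map: term id → set of report ids."""
        inverted: dict[str, set] = {}
        for rid, terms in self.membership.items():
            for t in terms:
                inverted.setdefault(t, set()).add(rid)
        return {t: frozenset(s) for t, s in inverted.items()}

    def terms(self) -> frozenset:
        out: set = set()
        for terms in self.membership.values():
            out |= terms
        return frozenset(out)

    def to_pairs(self) -> pd.DataFrame:
        """Sparse (report_id, term_id) pair list, sorted for reproducibility."""
        rows = [(rid, t) for rid, terms in self.membership.items()
                for t in sorted(terms)]
        rows.sort()
        return pd.DataFrame(rows, columns=["report_id", "term_id"])


def build_event_matrix(rs: ReportSet, dictionary: TermDictionary | None = None,
                       level: str = "PT", scope: str = "narrow") -> EventMatrix:
    """Aggregate REAC rows into once-per-report term membership.

    At PT level the membership is simply the distinct PT codes of each
    report. At SMQ level each PT is mapped through the dictionary entries
    with the requested scope; a report with several qualifying PTs inside
    one SMQ still contributes exactly one membership. PTs absent from the
    dictionary are silently unmapped; their count is logged as coverage.
    """
    if level not in {"PT", "SMQ"}:
        raise ValueError("level must be 'PT' or 'SMQ'")
    reac = rs.reac
    if level == "PT":
        membership = {rid: frozenset(g)
                      for rid, g in reac.groupby("report_id")["pt_code"]}
        return EventMatrix(level="PT", membership=membership,
                           term_names={t: t for ts in membership.values()
                                       for t in ts})

    if dictionary is None:
        raise ValueError("SMQ level requires a term dictionary")
    pt_to_smq = dictionary.mapping(scope=scope)
    unmapped: set[str] = set()
    membership = {}
    for rid, pts in reac.groupby("report_id")["pt_code"]:
        smqs: set = set()
        for pt in set(pts):
            groups = pt_to_smq.get(pt)
            if groups is None:
                unmapped.add(pt)
            else:
                smqs |= groups
        if smqs:
            membership[rid] = frozenset(smqs)
    if unmapped:
        logger.info("build_event_matrix: %d PT code(s) not covered by the "
                    "%s-scope dictionary", len(unmapped), scope)
    return EventMatrix(level="SMQ", membership=membership,
                       term_names=dict(dictionary.smq_names))
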