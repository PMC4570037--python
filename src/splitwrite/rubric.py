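"""Rubric data model, file I/O, and dual-rater consensus.

Completeness of reporting is judged against per-protocol rubrics: for each
of the six methods domains a list of pre-specified keywords (expected
content phrases), each carrying a positive weight and an optional
"essential element" flag.  Two independent raters record keyword presence;
disagreements are resolved by consensus.

Serialization formats
---------------------
* JSON: one document per protocol, ``{"protocol_id": ..., "domains":
  {domain: [keyword, ...]}}`` (a list of such documents for several
  protocols).
* CSV: flat table with columns ``protocol_id, domain, keyword_id, text,
  weight, essential`` (optional ``synonyms``, pipe-separated).
* Ratings CSV: ``protocol_id, domain, rater_id, keyword_id, present,
  flagged_missing`` with 0/1 indicators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .design import DOMAINS

__all__ = [
    "Keyword",
    "DomainRubric",
    "ProtocolRubric",
    "RatingRecord",
    "ConsensusRating",
    "Disagreement",
    "ConsensusResult",
    "RubricError",
    "RubricStructureError",
    "RubricValidationError",
    "ConsensusError",
    "load_rubric",
    "load_rubrics",
    "save_rubrics",
    "load_ratings",
    "save_ratings",
    "merge_consensus",
]


class RubricError(ValueError):
    """Base class for rubric problems."""


class RubricStructureError(RubricError):
    """File structure invalid: missing or duplicate domains, unknown fields."""


class RubricValidationError(RubricError):
    """A keyword or weight violates an invariant."""


class ConsensusError(ValueError):
    """Rater coverage or cardinality problem during consensus merge."""


@dataclass(frozen=True)
class Keyword:
    """One pre-specified content element with its scoring weight."""

    id: str
    text: str
    weight: float
    essential: bool = False
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise RubricValidationError("keyword id must be non-empty")
        if not self.text:
            raise RubricValidationError(f"keyword {self.id!r}: text must be non-empty")
        if not self.weight > 0:
            raise RubricValidationError(
                f"keyword {self.id!r}: weight must be > 0, got {self.weight}"
            )


@dataclass(frozen=True)
class DomainRubric:
    """Weighted keyword checklist for one methods domain of one protocol."""

    protocol_id: str
    domain: str
    keywords: tuple[Keyword, ...]

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise RubricStructureError(
                f"unknown domain {self.domain!r}; expected one of {DOMAINS}"
            )
        if not self.keywords:
            raise RubricValidationError(
                f"{self.protocol_id}/{self.domain}: at least one keyword required"
            )
        ids = [k.id for k in self.keywords]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RubricValidationError(
                f"{self.protocol_id}/{self.domain}: duplicate keyword ids {dupes}"
            )

    @property
    def total_weight(self) -> float:
        return sum(k.weight for k in self.keywords)

    @property
    def essential_keywords(self) -> tuple[Keyword, ...]:
        return tuple(k for k in self.keywords if k.essential)

    def scaled(self, c: float) -> "DomainRubric":
        """Copy with every weight multiplied by ``c`` (c > 0)."""
        return replace(
            self, keywords=tuple(replace(k, weight=k.weight * c) for k in self.keywords)
        )


@dataclass(frozen=True)
class ProtocolRubric:
    """The six domain rubrics of one protocol."""

    protocol_id: str
    domains: tuple[DomainRubric, ...]

    def __post_init__(self) -> None:
        names = [d.domain for d in self.domains]
        missing = [d for d in DOMAINS if d not in names]
        if missing:
            raise RubricStructureError(
                f"protocol {self.protocol_id!r}: missing domain(s) {missing}"
            )
        if len(names) != len(set(names)):
            raise RubricStructureError(
                f"protocol {self.protocol_id!r}: duplicate domains"
            )
        for d in self.domains:
            if d.protocol_id != self.protocol_id:
                raise RubricStructureError(
                    f"domain rubric {d.domain} belongs to {d.protocol_id!r}, "
                    f"not {self.protocol_id!r}"
                )

    def domain(self, name: str) -> DomainRubric:
        for d in self.domains:
            if d.domain == name:
                return d
        raise KeyError(name)

    def __getitem__(self, name: str) -> DomainRubric:
        return self.domain(name)


@dataclass(frozen=True)
class RatingRecord:
    """One rater's verdict on one keyword.

    ``present`` is the raw presence indicator; ``flagged_missing`` records
    that the writer explicitly noted the information as absent from the
    source protocol (which counts as completely reported when scoring).
    """

    protocol_id: str
    domain: str
    rater_id: str
    keyword_id: str
    present: bool
    flagged_missing: bool = False

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.protocol_id, self.domain, self.keyword_id)


@dataclass(frozen=True)
class ConsensusRating:
    """Post-consensus verdict on one keyword (rater identity dropped)."""

    protocol_id: str
    domain: str
    keyword_id: str
    present: bool
    flagged_missing: bool = False
    resolved: bool = False  # True when the value came from explicit resolution

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.protocol_id, self.domain, self.keyword_id)

    @property
    def effective_present(self) -> bool:
        """Presence for scoring: present OR flagged as missing-from-protocol."""
        return self.present or self.flagged_missing


@dataclass(frozen=True)
class Disagreement:
    """An unresolved rater disagreement on one keyword."""

    protocol_id: str
    domain: str
    keyword_id: str
    verdicts: tuple[tuple[str, bool, bool], ...]  # (rater_id, present, flagged)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.protocol_id, self.domain, self.keyword_id)


@dataclass
class ConsensusResult:
    consensus: list[ConsensusRating]
    disagreements: list[Disagreement]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _split_synonyms(value) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ()
    return tuple(s for s in str(value).split("|") if s)


def _keyword_from_dict(d: Mapping) -> Keyword:
    return Keyword(
        id=str(d["id"]),
        text=str(d["text"]),
        weight=float(d["weight"]),
        essential=bool(d.get("essential", False)),
        synonyms=tuple(d.get("synonyms", ())),
    )


def _keyword_to_dict(k: Keyword) -> dict:
    d = {"id": k.id, "text": k.text, "weight": k.weight, "essential": k.essential}
    if k.synonyms:
        d["synonyms"] = list(k.synonyms)
    return d


def _protocol_from_dict(doc: Mapping) -> ProtocolRubric:
    pid = str(doc["protocol_id"])
    domains_map = doc.get("domains")
    if not isinstance(domains_map, Mapping):
        raise RubricStructureError(f"protocol {pid!r}: missing 'domains' map")
    domains = []
    for name, kws in domains_map.items():
        domains.append(
            DomainRubric(
                protocol_id=pid,
                domain=str(name),
                keywords=tuple(_keyword_from_dict(k) for k in kws),
            )
        )
    return ProtocolRubric(protocol_id=pid, domains=tuple(domains))


def load_rubrics(path: str | Path) -> dict[str, ProtocolRubric]:
    """Load one or more protocol rubrics from a JSON or CSV file.

    Returns a mapping protocol_id -> :class:`ProtocolRubric`, preserving
    keyword order as given in the file.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        docs = doc if isinstance(doc, list) else [doc]
        rubrics = [_protocol_from_dict(d) for d in docs]
    elif path.suffix.lower() == ".csv":
        frame = pd.read_csv(path, dtype={"protocol_id": str, "keyword_id": str})
        required = {"protocol_id", "domain", "keyword_id", "text", "weight", "essential"}
        missing_cols = required - set(frame.columns)
        if missing_cols:
            raise RubricStructureError(
                f"rubric CSV missing columns: {sorted(missing_cols)}"
            )
        rubrics = []
        for pid, pgroup in frame.groupby("protocol_id", sort=False):
            domains = []
            for name, dgroup in pgroup.groupby("domain", sort=False):
                keywords = tuple(
                    Keyword(
                        id=str(r.keyword_id),
                        text=str(r.text),
                        weight=float(r.weight),
                        essential=bool(int(r.essential)),
                        synonyms=_split_synonyms(getattr(r, "synonyms", None)),
                    )
                    for r in dgroup.itertuples()
                )
                domains.append(
                    DomainRubric(protocol_id=str(pid), domain=str(name), keywords=keywords)
                )
            rubrics.append(ProtocolRubric(protocol_id=str(pid), domains=tuple(domains)))
    else:
        raise RubricStructureError(f"unsupported rubric format: {path.suffix!r}")
    return {r.protocol_id: r for r in rubrics}


def load_rubric(path: str | Path) -> ProtocolRubric:
    """Load a single-protocol rubric file (error if it holds several)."""
    rubrics = load_rubrics(path)
    if len(rubrics) != 1:
        raise RubricStructureError(
            f"expected exactly one protocol in {path}, found {len(rubrics)}"
        )
    return next(iter(rubrics.values()))


def save_rubrics(
    rubrics: ProtocolRubric | Iterable[ProtocolRubric], path: str | Path
) -> None:
    """Write rubric(s) to JSON or CSV, preserving keyword order and weights."""
    if isinstance(rubrics, ProtocolRubric):
        rubrics = [rubrics]
    rubrics = list(rubrics)
    path = Path(path)
    if path.suffix.lower() == ".json":
        docs = [
            {
                "protocol_id": r.protocol_id,
                "domains": {
                    d.domain: [_keyword_to_dict(k) for k in d.keywords]
                    for d in r.domains
                },
            }
            for r in rubrics
        ]
        with open(path, "w") as fh:
            json.dump(docs[0] if len(docs) == 1 else docs, fh, indent=1)
            fh.write("\n")
    elif path.suffix.lower() == ".csv":
        rows = []
        any_syn = any(k.synonyms for r in rubrics for d in r.domains for k in d.keywords)
        for r in rubrics:
            for d in r.domains:
                for k in d.keywords:
                    row = [r.protocol_id, d.domain, k.id, k.text, k.weight, int(k.essential)]
                    if any_syn:
                        row.append("|".join(k.synonyms))
                    rows.append(row)
        cols = ["protocol_id", "domain", "keyword_id", "text", "weight", "essential"]
        if any_syn:
            cols.append("synonyms")
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    else:
        raise RubricStructureError(f"unsupported rubric format: {path.suffix!r}")


def load_ratings(path: str | Path) -> list[RatingRecord]:
    """Read a ratings CSV into :class:`RatingRecord` objects."""
    frame = pd.read_csv(path, dtype={"protocol_id": str, "rater_id": str, "keyword_id": str})
    return [
        RatingRecord(
            protocol_id=r.protocol_id,
            domain=r.domain,
            rater_id=r.rater_id,
            keyword_id=r.keyword_id,
            present=bool(int(r.present)),
            flagged_missing=bool(int(r.flagged_missing)),
        )
        for r in frame.itertuples()
    ]


def save_ratings(records: Iterable[RatingRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.protocol_id, r.domain, r.rater_id, r.keyword_id,
             int(r.present), int(r.flagged_missing))
            for r in records
        ],
        columns=["protocol_id", "domain", "rater_id", "keyword_id",
                 "present", "flagged_missing"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

Resolution = bool | tuple[bool, bool]


def merge_consensus(
    ratings: Iterable[RatingRecord],
    resolutions: Mapping[tuple[str, str, str], Resolution] | None = None,
) -> ConsensusResult:
    """Merge the records of exactly two raters into consensus ratings.

    Where the raters agree (on both ``present`` and ``flagged_missing``) the
    shared value is copied with ``resolved=False``.  Where they disagree and
    ``resolutions`` provides an override for the (protocol, domain, keyword)
    key, the override is used with ``resolved=True``; an override may be a
    bare bool (``present``, flagged_missing=False) or a
    ``(present, flagged_missing)`` pair.  Remaining disagreements are listed
    in the report and excluded from the consensus output.

    Raises :class:`ConsensusError` if the records do not come from exactly
    two raters or the raters do not cover identical keys.
    """
    resolutions = dict(resolutions or {})
    by_key: dict[tuple[str, str, str], dict[str, RatingRecord]] = {}
    raters: set[str] = set()
    for rec in ratings:
        raters.add(rec.rater_id)
        slot = by_key.setdefault(rec.key, {})
        if rec.rater_id in slot:
            raise ConsensusError(f"duplicate record for {rec.key} by {rec.rater_id!r}")
        slot[rec.rater_id] = rec
    if len(raters) != 2:
        raise ConsensusError(f"consensus requires exactly 2 raters, got {sorted(raters)}")
    missing = sorted(
        (key, rater)
        for key, slot in by_key.items()
        for rater in raters - set(slot)
    )
    if missing:
        raise ConsensusError(f"rater coverage mismatch; missing records: {missing}")

    consensus: list[ConsensusRating] = []
    disagreements: list[Disagreement] = []
    for key in by_key:  # insertion order = input order
        a, b = (by_key[key][r] for r in sorted(raters))
        if (a.present, a.flagged_missing) == (b.present, b.flagged_missing):
            consensus.append(
                ConsensusRating(*key, present=a.present,
                                flagged_missing=a.flagged_missing, resolved=False)
            )
        elif key in resolutions:
            override = resolutions[key]
            if isinstance(override, bool):
                present, flagged = override, False
            else:
                present, flagged = override
            consensus.append(
                ConsensusRating(*key, present=bool(present),
                                flagged_missing=bool(flagged), resolved=True)
            )
        else:
            disagreements.append(
                Disagreement(
                    *key,
                    verdicts=tuple(
                        (r, by_key[key][r].present, by_key[key][r].flagged_missing)
                        for r in sorted(raters)
                    ),
                )
            )
    return ConsensusResult(consensus=consensus, disagreements=disagreements)
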