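"""Standardized 0-10 completeness-of-reporting scores.

The domain score is the weighted fraction of rubric keywords credited as
reported, rescaled to 0-10:

    S = 10 * sum(w_i * x_i) / sum(w_i)

where ``x_i = 1`` iff keyword i is present in the written domain *or* the
writer explicitly flagged the information as missing from the source
protocol (the missing-information rule: such a keyword counts as
completely reported).  Because keyword counts vary across domains and
protocols, the rescaling makes domain scores comparable; they are the unit
of analysis.  The essential-elements subscore applies the same formula to
the keywords flagged essential, and is undefined (``None``) when a domain
has no essential keywords.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .design import CONDITIONS, DOMAINS, participant_label
from .rubric import (
    ConsensusRating,
    DomainRubric,
    ProtocolRubric,
    RatingRecord,
)

__all__ = [
    "ScoreRecord",
    "ScoreTable",
    "ScoringError",
    "domain_score",
    "essential_score",
    "condition_means",
    "ConditionMeans",
    "auto_match",
    "score_trial",
]


class ScoringError(ValueError):
    """Rubric/consensus mismatch or malformed score table."""


@dataclass
class ScoreRecord:
    """One domain-level completeness score for one participant."""

    participant_id: str
    protocol_id: str
    domain: str
    condition: str
    score: float
    essential_score: float | None = None


class ScoreTable:
    """Balanced table of domain-level scores.

    Each participant contributes exactly six records: three domains written
    under the tool condition and three under control.  Backed by a pandas
    DataFrame with columns ``participant_id, protocol_id, domain, condition,
    score, essential_score``.

    Scores produced from rubrics always lie in [0, 10]; synthetic scores
    generated on the unbounded normal scale may exit that range unless
    truncation is requested, so the table validates balance but not range.
    """

    COLUMNS = ("participant_id", "protocol_id", "domain",
               "condition", "score", "essential_score")

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        frame = frame.copy()
        if "essential_score" not in frame.columns:
            frame["essential_score"] = np.nan
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ScoringError(f"score table missing columns: {sorted(missing)}")
        self.frame = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if validate:
            self.validate()

    def validate(self) -> None:
        """Check the 3-tool + 3-control balance for every participant."""
        bad_cond = set(self.frame["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ScoringError(f"unknown condition labels: {sorted(bad_cond)}")
        bad_dom = set(self.frame["domain"]) - set(DOMAINS)
        if bad_dom:
            raise ScoringError(f"unknown domains: {sorted(bad_dom)}")
        counts = (
            self.frame.groupby(["participant_id", "condition"], observed=True)
            .size()
            .unstack(fill_value=0)
        )
        for cond in CONDITIONS:
            if cond not in counts.columns:
                counts[cond] = 0
        bad = counts[(counts["tool"] != 3) | (counts["control"] != 3)]
        if len(bad):
            raise ScoringError(
                "unbalanced participants (need exactly 3 tool + 3 control): "
                f"{list(bad.index)}"
            )
        dup = self.frame.duplicated(["participant_id", "domain"])
        if dup.any():
            dupes = self.frame.loc[dup, ["participant_id", "domain"]]
            raise ScoringError(f"duplicate participant-domain rows: {dupes.values.tolist()}")

    @classmethod
    def from_records(cls, records: Iterable[ScoreRecord]) -> "ScoreTable":
        return cls(
            pd.DataFrame(
                [
                    (r.participant_id, r.protocol_id, r.domain, r.condition,
                     r.score, np.nan if r.essential_score is None else r.essential_score)
                    for r in records
                ],
                columns=list(cls.COLUMNS),
            )
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "ScoreTable":
        return cls(pd.read_csv(path, dtype={"participant_id": str, "protocol_id": str}))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def participants(self) -> list[str]:
        return list(dict.fromkeys(self.frame["participant_id"]))

    def __len__(self) -> int:
        return len(self.frame)

    def pivot_means(self) -> pd.DataFrame:
        """Per-participant condition means: rows participants, columns tool/control."""
        piv = self.frame.pivot_table(
            index="participant_id", columns="condition", values="score",
            aggfunc="mean", observed=True,
        )
        return piv.loc[self.participants, list(CONDITIONS)]


def _consensus_map(
    rubric: DomainRubric, consensus: Iterable[ConsensusRating]
) -> dict[str, ConsensusRating]:
    """Index consensus records of this rubric's protocol+domain by keyword id."""
    known = {k.id for k in rubric.keywords}
    out: dict[str, ConsensusRating] = {}
    for rec in consensus:
        if rec.protocol_id != rubric.protocol_id or rec.domain != rubric.domain:
            continue
        if rec.keyword_id not in known:
            raise ScoringError(
                f"consensus record for unknown keyword {rec.keyword_id!r} in "
                f"{rubric.protocol_id}/{rubric.domain}"
            )
        out[rec.keyword_id] = rec
    return out


def _weighted_score(keywords, cmap: Mapping[str, ConsensusRating],
                    rubric: DomainRubric) -> float:
    total = 0.0
    credited = 0.0
    for kw in keywords:
        if kw.id not in cmap:
            raise ScoringError(
                f"keyword {kw.id!r} of {rubric.protocol_id}/{rubric.domain} "
                "not covered by consensus ratings"
            )
        total += kw.weight
        if cmap[kw.id].effective_present:
            credited += kw.weight
    # divide before scaling so a fully credited rubric yields exactly 10.0
    return 10.0 * (credited / total)


def domain_score(
    rubric: DomainRubric, consensus: Iterable[ConsensusRating]
) -> float:
    """Standardized completeness score S = 10 * sum(w_i x_i) / sum(w_i)."""
    cmap = _consensus_map(rubric, consensus)
    return _weighted_score(rubric.keywords, cmap, rubric)


def essential_score(
    rubric: DomainRubric, consensus: Iterable[ConsensusRating]
) -> float | None:
    """Same formula restricted to essential keywords; None when there are none."""
    essential = rubric.essential_keywords
    if not essential:
        return None
    cmap = _consensus_map(rubric, consensus)
    return _weighted_score(essential, cmap, rubric)


@dataclass
class ConditionMeans:
    """Per-participant and overall mean scores by writing condition."""

    per_participant: pd.DataFrame  # index participant_id, columns tool/control
    overall_tool: float
    overall_control: float


def condition_means(table: ScoreTable) -> ConditionMeans:
    """Mean of each participant's three scores per condition, plus overall means.

    The overall condition mean is the mean over participants of the
    per-participant condition means (each participant weighted equally).
    """
    piv = table.pivot_means()
    return ConditionMeans(
        per_participant=piv,
        overall_tool=float(piv["tool"].mean()),
        overall_control=float(piv["control"].mean()),
    )


_MISSING_MARKER = re.compile(r"\[\s*missing\s*:\s*([^\]]+)\]", re.IGNORECASE)
_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


def _normalize(text: str) -> str:
    """Case-fold, strip punctuation to spaces, collapse whitespace."""
    return " ".join(text.casefold().translate(_PUNCT_TABLE).split())


def auto_match(
    rubric: DomainRubric, text: str, rater_id: str = "auto"
) -> list[RatingRecord]:
    """Deterministic keyword matcher for demos and synthetic pipelines.

    A keyword is present iff its normalized text (or any normalized synonym)
    occurs as a substring of the normalized input.  A keyword is flagged
    missing iff its id appears inside an explicit ``[MISSING: ...]`` marker
    in the raw text.  The study itself used human raters; this matcher only
    stands in for them in synthetic end-to-end runs.
    """
    norm_text = _normalize(text)
    flagged_ids: set[str] = set()
    for m in _MISSING_MARKER.finditer(text):
        for token in re.split(r"[,\s]+", m.group(1).strip()):
            if token:
                flagged_ids.add(token.casefold())
    records = []
    for kw in rubric.keywords:
        candidates = (kw.text, *kw.synonyms)
        present = any(
            _normalize(c) and _normalize(c) in norm_text for c in candidates
        )
        records.append(
            RatingRecord(
                protocol_id=rubric.protocol_id,
                domain=rubric.domain,
                rater_id=rater_id,
                keyword_id=kw.id,
                present=present,
                flagged_missing=kw.id.casefold() in flagged_ids,
            )
        )
    return records


def score_trial(
    rubrics: Mapping[str, ProtocolRubric],
    consensus: Iterable[ConsensusRating],
    allocation: pd.DataFrame,
) -> ScoreTable:
    """Score every participant-domain of a trial from keyword-level consensus.

    ``allocation`` is the long allocation table (columns participant_index,
    protocol_id, domain, condition) produced by the design module; consensus
    records are matched through each participant's protocol.
    """
    consensus = list(consensus)
    records = []
    for (idx, pid), group in allocation.groupby(
        ["participant_index", "protocol_id"], sort=True
    ):
        if pid not in rubrics:
            raise ScoringError(f"no rubric for protocol {pid!r}")
        rubric = rubrics[pid]
        for row in group.itertuples():
            dom = rubric.domain(row.domain)
            records.append(
                ScoreRecord(
                    participant_id=participant_label(int(idx)),
                    protocol_id=str(pid),
                    domain=row.domain,
                    condition=row.condition,
                    score=domain_score(dom, consensus),
                    essential_score=essential_score(dom, consensus),
                )
            )
    return ScoreTable.from_records(records)
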