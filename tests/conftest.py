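"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from splitwrite import (
    DOMAINS,
    ConsensusRating,
    DomainRubric,
    Keyword,
    ProtocolRubric,
    ScoreRecord,
    ScoreTable,
    enumerate_patterns,
)


def make_rubric(
    protocol_id: str = "P1",
    domain: str = "randomization",
    weights=(2.0, 1.0, 1.0),
    essential=None,
    texts=None,
) -> DomainRubric:
    """Small domain rubric with keyword ids k1, k2, ..."""
    n = len(weights)
    essential = essential if essential is not None else [False] * n
    texts = texts if texts is not None else [f"phrase {i + 1}" for i in range(n)]
    return DomainRubric(
        protocol_id=protocol_id,
        domain=domain,
        keywords=tuple(
            Keyword(id=f"k{i + 1}", text=texts[i], weight=float(weights[i]),
                    essential=bool(essential[i]))
            for i in range(n)
        ),
    )


def consensus_for(rubric: DomainRubric, present, flagged=None) -> list[ConsensusRating]:
    """Consensus records covering the rubric with the given presence vector."""
    n = len(rubric.keywords)
    flagged = flagged if flagged is not None else [False] * n
    return [
        ConsensusRating(
            protocol_id=rubric.protocol_id,
            domain=rubric.domain,
            keyword_id=kw.id,
            present=bool(present[i]),
            flagged_missing=bool(flagged[i]),
        )
        for i, kw in enumerate(rubric.keywords)
    ]


def make_protocol_rubric(protocol_id: str = "P1", weights=(2.0, 1.0, 1.0)) -> ProtocolRubric:
    return ProtocolRubric(
        protocol_id=protocol_id,
        domains=tuple(
            make_rubric(protocol_id, dom, weights=weights) for dom in DOMAINS
        ),
    )


def table_from_contrasts(d_values, base: float = 5.0) -> ScoreTable:
    """Balanced table where participant p's tool scores all sit d_p above base.

    The paired contrast of condition means is then exactly ``d_values``.
    """
    pattern = enumerate_patterns()[0]
    records = []
    for p, d in enumerate(d_values, start=1):
        for dom in DOMAINS:
            cond = pattern.condition(dom)
            records.append(
                ScoreRecord(
                    participant_id=f"P{p:03d}",
                    protocol_id=f"PROT{p:03d}",
                    domain=dom,
                    condition=cond,
                    score=base + (d if cond == "tool" else 0.0),
                )
            )
    return ScoreTable.from_records(records)


def random_rubric(rng: np.random.Generator, protocol_id="P1",
                  domain="randomization", max_kw=8) -> DomainRubric:
    """Random rubric: 1..max_kw keywords, continuous weights in (0.1, 5]."""
    n = int(rng.integers(1, max_kw + 1))
    weights = rng.uniform(0.1, 5.0, size=n)
    essential = rng.random(n) < 0.5
    return make_rubric(protocol_id, domain, weights=weights, essential=essential)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
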