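"""Trial design: allocation patterns, permuted-block randomization, sample size.

A split-manuscript trial randomizes the six methods-section domains of a
single manuscript *within* each participant: three domains are written with
the writing aid tool, the other three without.  The data structure is the
one found in split-mouth dental trials and cluster randomized cross-over
trials, so the sample-size calculation uses the cluster-crossover design
effect ("inflation factor")

    IF = 1 + (m - 1) * rho - m * rho_prime

where ``m`` is the number of domains per participant per condition, ``rho``
the within-condition intraclass correlation and ``rho_prime`` the
cross-condition correlation between two domain scores of the same
participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import ceil, sqrt
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: The six methods-section domains, in canonical order.
DOMAINS: tuple[str, ...] = (
    "trial_design",
    "randomization",
    "blinding",
    "participants",
    "interventions",
    "outcomes",
)

#: Number of domains allocated to the tool condition per participant.
TOOL_DOMAINS_PER_PARTICIPANT = 3

#: One permuted block holds each of the C(6,3)=20 allocation patterns once.
DEFAULT_BLOCK_SIZE = 20

CONDITIONS = ("tool", "control")


class DesignError(ValueError):
    """Invalid design parameters or degenerate design."""


@dataclass(frozen=True)
class AllocationPattern:
    """One participant's assignment of exactly 3 of the 6 domains to the tool.

    The complement of ``tool_domains`` implicitly forms the control set.
    """

    tool_domains: frozenset[str]

    def __post_init__(self) -> None:
        unknown = set(self.tool_domains) - set(DOMAINS)
        if unknown:
            raise DesignError(f"unknown domains: {sorted(unknown)}")
        if len(self.tool_domains) != TOOL_DOMAINS_PER_PARTICIPANT:
            raise DesignError(
                f"a pattern must assign exactly {TOOL_DOMAINS_PER_PARTICIPANT} "
                f"domains to the tool, got {len(self.tool_domains)}"
            )

    @property
    def control_domains(self) -> frozenset[str]:
        return frozenset(DOMAINS) - self.tool_domains

    def condition(self, domain: str) -> str:
        """Condition ('tool' or 'control') of ``domain`` under this pattern."""
        if domain not in DOMAINS:
            raise DesignError(f"unknown domain: {domain!r}")
        return "tool" if domain in self.tool_domains else "control"

    def sorted_tool(self) -> tuple[str, ...]:
        """Tool domains in canonical domain order (stable key for the pattern)."""
        return tuple(d for d in DOMAINS if d in self.tool_domains)


def enumerate_patterns() -> tuple[AllocationPattern, ...]:
    """All 20 distinct 3-of-6 allocation patterns, lexicographic in domain order.

    Deterministic: the same tuple on every call.
    """
    return tuple(
        AllocationPattern(frozenset(combo)) for combo in combinations(DOMAINS, 3)
    )


def participant_label(index: int) -> str:
    """Human-readable participant id for a 1-based participant index."""
    return f"P{index:03d}"


@dataclass
class AllocationSequence:
    """Ordered allocation of participants to 3-of-6 patterns.

    Within each complete block of ``block_size`` participants every distinct
    pattern occurs exactly once (permuted-block randomization).
    """

    patterns: list[AllocationPattern]
    block_size: int = DEFAULT_BLOCK_SIZE
    seed: int | None = None

    @property
    def n_participants(self) -> int:
        return len(self.patterns)

    def block_index(self, participant_index: int) -> int:
        """0-based block of a 1-based participant index."""
        return (participant_index - 1) // self.block_size

    def condition(self, participant_index: int, domain: str) -> str:
        return self.patterns[participant_index - 1].condition(domain)

    def __iter__(self) -> Iterator[tuple[int, AllocationPattern]]:
        return ((i + 1, p) for i, p in enumerate(self.patterns))

    def tool_indicator(self) -> np.ndarray:
        """Boolean matrix (n_participants, 6): True where the domain is tool."""
        return np.array(
            [[d in p.tool_domains for d in DOMAINS] for p in self.patterns]
        )

    def to_frame(self, protocol_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Long allocation table: one row per participant-domain.

        Columns: participant_index, protocol_id, domain, condition,
        block_index, seed.
        """
        if protocol_ids is None:
            protocol_ids = [f"PROT{i:03d}" for i in range(1, self.n_participants + 1)]
        if len(protocol_ids) != self.n_participants:
            raise DesignError(
                f"need {self.n_participants} protocol ids, got {len(protocol_ids)}"
            )
        rows = []
        for i, pattern in self:
            for domain in DOMAINS:
                rows.append(
                    (
                        i,
                        protocol_ids[i - 1],
                        domain,
                        pattern.condition(domain),
                        self.block_index(i),
                        self.seed,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "participant_index",
                "protocol_id",
                "domain",
                "condition",
                "block_index",
                "seed",
            ],
        )


def generate_sequence(n_participants: int, seed: int | None = None) -> AllocationSequence:
    """Permuted-block randomization sequence for ``n_participants``.

    ceil(n/20) independently permuted blocks of the 20 patterns are
    concatenated and truncated to ``n_participants``.  Reproducible given
    ``seed``.
    """
    if n_participants < 1:
        raise DesignError(f"n_participants must be >= 1, got {n_participants}")
    rng = np.random.default_rng(seed)
    patterns = enumerate_patterns()
    block_size = len(patterns)
    n_blocks = ceil(n_participants / block_size)
    seq: list[AllocationPattern] = []
    for _ in range(n_blocks):
        order = rng.permutation(block_size)
        seq.extend(patterns[j] for j in order)
    return AllocationSequence(seq[:n_participants], block_size=block_size, seed=seed)


def assign_protocols(
    protocol_ids: Sequence[str], seed: int | None = None
) -> list[str]:
    """Seeded random permutation of a protocol list (one protocol per participant)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(protocol_ids))
    return [protocol_ids[j] for j in order]


@dataclass(frozen=True)
class DesignParams:
    """Parameters of the sample-size calculation and power analysis.

    Defaults are the study's planning assumptions: two-sided alpha 5%,
    power 90%, minimal difference 2 score points, per-domain SD 4, ICC 0.8,
    cross-condition correlation 0.4, m=3 domains per participant per
    condition.
    """

    alpha: float = 0.05
    power: float = 0.90
    delta: float = 2.0
    sigma: float = 4.0
    rho: float = 0.8
    rho_prime: float = 0.4
    m: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DesignError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 < self.power < 1:
            raise DesignError(f"power must be in (0,1), got {self.power}")
        if self.delta <= 0:
            raise DesignError(f"delta must be > 0, got {self.delta}")
        if self.sigma <= 0:
            raise DesignError(f"sigma must be > 0, got {self.sigma}")
        if not 0 <= self.rho_prime <= self.rho <= 1:
            raise DesignError(
                f"need 0 <= rho_prime <= rho <= 1, got rho={self.rho}, "
                f"rho_prime={self.rho_prime}"
            )
        if self.m < 1:
            raise DesignError(f"m must be >= 1, got {self.m}")


def inflation_factor(params: DesignParams) -> float:
    """Cluster-crossover design effect IF = 1 + (m-1)*rho - m*rho_prime.

    Raises :class:`DesignError` if the implied factor is not positive
    (degenerate design).
    """
    factor = 1.0 + (params.m - 1) * params.rho - params.m * params.rho_prime
    if factor <= 0:
        raise DesignError(f"degenerate design: inflation factor {factor} <= 0")
    return factor


@dataclass(frozen=True)
class SampleSize:
    """Result of the cluster-crossover sample-size calculation."""

    domains_per_group: int
    participants: int
    n_unrounded: float  # IF * independent-observations requirement, before rounding
    inflation_factor: float
    n_independent: float  # two-sample normal-approximation requirement per group


def required_sample_size(params: DesignParams) -> SampleSize:
    """Domains per group and participants needed under the correlated design.

    The independent-observations two-sample requirement per group,

        n0 = 2 * (z_{1-alpha/2} + z_{power})^2 * sigma^2 / delta^2,

    is inflated by the design effect and rounded up to the nearest multiple
    of m so that it maps onto whole participants (each contributes m domains
    per group).
    """
    z_alpha = stats.norm.ppf(1 - params.alpha / 2)
    z_power = stats.norm.ppf(params.power)
    n0 = 2 * (z_alpha + z_power) ** 2 * params.sigma**2 / params.delta**2
    factor = inflation_factor(params)
    n_unrounded = factor * n0
    domains_per_group = int(ceil(n_unrounded / params.m) * params.m)
    return SampleSize(
        domains_per_group=domains_per_group,
        participants=domains_per_group // params.m,
        n_unrounded=n_unrounded,
        inflation_factor=factor,
        n_independent=n0,
    )
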