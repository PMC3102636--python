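"""The Gillespie loop for a single branch.

One iteration: draw the waiting time to the next event from an exponential
with rate equal to the sum of all event rates; stop if it overruns the
branch; otherwise select an event with probability proportional to its rate,
accept/reject it if it is an indel proposal, apply it, update the rates, and
repeat.  Selection is hierarchical — site proportional to its cached total
rate, then a binding within the site, then the concrete change — which gives
every concrete event probability rate / total_rate.

The pseudo-random draw order is frozen (waiting time, site, binding,
within-binding target/length, acceptance uniform) so a fixed seed gives an
identical trajectory.  Rejected indel proposals consume their Gillespie step
and are logged with ``accepted=False``; this is what makes the fast-field
rescaling a pure efficiency gain.  Cached rates are recomputed from scratch
every ``audit_interval`` events (and at branch start) to bound
floating-point drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .indels import (
    DeletionSpan,
    InsertionProposal,
    accept_or_reject,
    deletion_acceptance_probability,
    insertion_acceptance_probability,
    propose_deletion,
    propose_insertion,
)
from .sequence import EvolvingSequence, RateAuditError, process_kind

__all__ = [
    "Event",
    "BranchResult",
    "InsertOp",
    "DeleteOp",
    "EngineError",
    "next_event_time",
    "select_event",
    "apply_event",
    "evolve_branch",
]


class EngineError(RuntimeError):
    pass


@dataclass
class Event:
    """One selected Gillespie event.

    ``site`` is the 0-based initiating index at selection time; logs print
    it 1-based.  ``accepted`` is always True for substitutions and records
    the accept/reject outcome for indel proposals.
    """

    kind: str  # substitution | insertion | deletion
    site: int
    rate: float
    time: float = 0.0
    accepted: bool = True
    # substitution payload
    from_state: str | None = None
    to_state: str | None = None
    process_label: str = ""
    # indel payload
    span: DeletionSpan | None = None
    proposal: InsertionProposal | None = None
    acceptance_probability: float = 1.0

    def detail(self) -> str:
        if self.kind == "substitution":
            return f"{self.from_state}->{self.to_state}"
        if self.kind == "deletion":
            s = self.span
            return f"del[{s.start + 1},{s.stop + 1}) p={self.acceptance_probability:.4g}"
        p = self.proposal
        return f"ins+{p.proposed_length}@{p.position + 1} p={self.acceptance_probability:.4g}"


@dataclass(frozen=True)
class InsertOp:
    """New homology columns appear before ``before_uid`` (None: at the end),
    anchored right of ``anchor_uid``."""

    anchor_uid: int
    new_uids: tuple
    before_uid: int | None
    partitions: tuple = ()


@dataclass(frozen=True)
class DeleteOp:
    uids: tuple


@dataclass
class BranchResult:
    sequence: EvolvingSequence
    events: list[Event] = field(default_factory=list)
    alignment_ops: list = field(default_factory=list)
    branch_id: str = ""

    def applied_events(self) -> list[Event]:
        return [e for e in self.events if e.accepted]


def next_event_time(total_rate: float, rng: np.random.Generator) -> float | None:
    """Exponential waiting time with mean 1/total_rate; None if no event is
    possible."""
    if total_rate < 0:
        raise EngineError(f"negative total rate {total_rate}")
    if total_rate == 0:
        return None
    return float(rng.exponential(1.0 / total_rate))


def _pick_index(weights: Sequence[float], u: float) -> int:
    acc = 0.0
    for j, w in enumerate(weights):
        acc += w
        if u < acc:
            return j
    return len(weights) - 1


def select_event(seq: EvolvingSequence, rng: np.random.Generator) -> Event:
    """Hierarchical selection: site ∝ cached rate, binding ∝ its rate within
    the site, then the concrete change."""
    rates = seq.cached_site_rates
    cum = np.cumsum(rates)
    total = float(cum[-1])
    if total <= 0:
        raise EngineError("select_event called with zero total rate")
    i = int(np.searchsorted(cum, rng.random() * total, side="right"))
    if i >= len(rates):
        i = len(rates) - 1
    while rates[i] <= 0 and i > 0:  # numerically possible only at boundaries
        i -= 1
    brates = seq.binding_rates(i)
    site_total = sum(brates)
    if not np.isclose(site_total, rates[i], rtol=1e-9, atol=1e-12):
        raise RateAuditError(
            f"site {i}: cached rate {rates[i]!r} != sum of binding rates {site_total!r}"
        )
    j = _pick_index(brates, rng.random() * site_total)
    binding = seq.sites[i].bindings[j]
    proc = binding.process
    kind = process_kind(proc)
    if kind == "substitution":
        state = seq.sites[i].state
        si = proc.alphabet.index[state]
        row = proc.Q[si].copy()
        row[si] = 0.0
        leave = row.sum()
        k = _pick_index(row, rng.random() * leave)
        return Event(
            "substitution",
            site=i,
            rate=brates[j],
            from_state=state,
            to_state=proc.alphabet.symbols[k],
            process_label=proc.label,
        )
    if kind == "deletion":
        span = propose_deletion(seq, proc, i, rng)
        p = deletion_acceptance_probability(seq, span, proc)
        return Event(
            "deletion", site=i, rate=brates[j], span=span,
            acceptance_probability=p, process_label=proc.label,
        )
    proposal = propose_insertion(seq, proc, i, rng)
    p = insertion_acceptance_probability(seq, proc, i)
    return Event(
        "insertion", site=i, rate=brates[j], proposal=proposal,
        acceptance_probability=p, process_label=proc.label,
    )


def apply_event(seq: EvolvingSequence, event: Event, alignment_ops: list) -> None:
    """Mutate the sequence according to an accepted event; rejected indel
    proposals mutate nothing (they are only logged)."""
    if not event.accepted:
        return
    if event.kind == "substitution":
        seq.set_state(event.site, event.to_state)
        return
    if event.kind == "deletion":
        span = event.span
        if span.stop > len(seq) or seq.sites[span.start].uid is None:
            raise EngineError("deletion span is stale (sequence changed since proposal)")
        removed = seq.delete_span(span.start, span.stop)
        alignment_ops.append(DeleteOp(tuple(s.uid for s in removed)))
        return
    # insertion
    proposal = event.proposal
    pos = proposal.position
    if pos < 1 or pos > len(seq):
        raise EngineError("insertion point is stale (sequence changed since proposal)")
    anchor_uid = seq.sites[pos - 1].uid
    before_uid = seq.sites[pos].uid if pos < len(seq) else None
    inserted = seq.insert_sites(pos, list(proposal.new_sites))
    alignment_ops.append(
        InsertOp(
            anchor_uid,
            tuple(s.uid for s in inserted),
            before_uid,
            partitions=tuple(s.partition for s in inserted),
        )
    )


def evolve_branch(
    seq: EvolvingSequence,
    branch_length: float,
    rng: np.random.Generator,
    branch_id: str = "",
    audit_interval: int = 1000,
) -> BranchResult:
    """Run the Gillespie loop on ``seq`` (mutated in place) for
    ``branch_length`` units of expected-substitutions-per-site time."""
    if branch_length < 0:
        raise EngineError("branch length must be nonnegative")
    seq.audit()
    result = BranchResult(seq, branch_id=branch_id)
    t = 0.0
    while True:
        dt = next_event_time(seq.cached_total_rate, rng)
        if dt is None or t + dt > branch_length:
            break
        t += dt
        event = select_event(seq, rng)
        if event.kind != "substitution":
            event.accepted = accept_or_reject(event.acceptance_probability, rng)
        event.time = t
        apply_event(seq, event, result.alignment_ops)
        result.events.append(event)
        if len(result.events) % audit_interval == 0:
            seq.audit()
    return result
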