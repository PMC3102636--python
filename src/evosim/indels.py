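"""Insertion and deletion processes with field-model selective constraints.

A deletion process proposes deletions at a per-site initiation rate with
lengths from an arbitrary discrete distribution; the span starts at the
initiating site and extends rightward, truncated at the sequence end.  Each
site i carries a deletion tolerance d_i in [0, 1] and the proposal is
accepted with probability prod(d_i) over the span, so d_i = 1 sites are
deleted at the background rate and d_i = 0 sites are never deleted ("field
deletion" model).  A rejected proposal still consumes its Gillespie step.

In ``fast_field`` mode the process is rescaled: proposals initiate at the
rate the sequence would have if every site were as tolerant as its most
tolerant site (rate x D with D = max d_i over bound sites), and acceptance
is compensated to prod(d_i) / D.  The realized per-span deletion rate,
proposal rate x acceptance, is rate x prod(d_i) in both modes — fast_field
is a pure speed-up that wastes fewer rejected proposals, not a different
model.

Insertions use the insertion tolerance of the initiating site alone; the
inserted sites are produced by a pluggable generator that sees the flanking
context (enabling e.g. duplications).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .models import SiteRateModel, SubstitutionModel, draw_site_rates
from .sequence import EvolvingSequence, ProcessBinding, Site

__all__ = [
    "IndelError",
    "LengthDistribution",
    "DeletionProcess",
    "InsertionProcess",
    "DeletionSpan",
    "InsertionContext",
    "SiteTemplate",
    "sample_indel_length",
    "propose_deletion",
    "deletion_acceptance_probability",
    "effective_deletion_proposal_rate",
    "accept_or_reject",
    "propose_insertion",
    "insertion_acceptance_probability",
    "default_insert_generator",
    "duplication_generator",
    "InsertionProposal",
    "FIXED_ONE",
]


class IndelError(ValueError):
    pass


@dataclass(frozen=True)
class LengthDistribution:
    """Discrete distribution on positive integers for indel lengths.

    kinds: ``fixed`` (params: value), ``geometric`` (params: p — number of
    trials, support >= 1), ``poisson_shifted`` (params: lam — 1 + Poisson),
    ``user_table`` (params: table mapping length -> probability) and
    ``callable`` (params: fn(rng) -> length).
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k, p = self.kind, self.params
        if k == "fixed":
            if int(p["value"]) < 1:
                raise IndelError("fixed length must be >= 1")
        elif k == "geometric":
            if not 0 < p["p"] <= 1:
                raise IndelError("geometric p must lie in (0, 1]")
        elif k == "poisson_shifted":
            if p["lam"] < 0:
                raise IndelError("poisson lam must be nonnegative")
        elif k == "user_table":
            table = dict(p["table"])
            if not table or any(int(length) < 1 for length in table):
                raise IndelError("user_table support must be positive integers")
            if any(prob < 0 for prob in table.values()):
                raise IndelError("user_table probabilities must be nonnegative")
            if abs(sum(table.values()) - 1.0) > 1e-9:
                raise IndelError("user_table probabilities must sum to 1")
        elif k == "callable":
            if not callable(p.get("fn")):
                raise IndelError("callable kind needs params['fn']")
        else:
            raise IndelError(f"unknown length distribution kind {k!r}")

    def sample(self, rng: np.random.Generator) -> int:
        return sample_indel_length(self, rng)

    def mean(self) -> float:
        k, p = self.kind, self.params
        if k == "fixed":
            return float(p["value"])
        if k == "geometric":
            return 1.0 / p["p"]
        if k == "poisson_shifted":
            return 1.0 + p["lam"]
        if k == "user_table":
            return float(sum(int(l) * w for l, w in p["table"].items()))
        raise IndelError("mean of a callable length distribution is unknown")


FIXED_ONE = LengthDistribution("fixed", {"value": 1})


def sample_indel_length(dist: LengthDistribution, rng: np.random.Generator) -> int:
    k, p = dist.kind, dist.params
    if k == "fixed":
        return int(p["value"])
    if k == "geometric":
        return int(rng.geometric(p["p"]))
    if k == "poisson_shifted":
        return 1 + int(rng.poisson(p["lam"]))
    if k == "user_table":
        lengths = sorted(int(l) for l in p["table"])
        probs = np.array([p["table"][l] for l in lengths], dtype=float)
        return int(lengths[rng.choice(len(lengths), p=probs / probs.sum())])
    # callable
    length = int(p["fn"](rng))
    if length < 1:
        raise IndelError(f"length callable returned {length}; lengths must be >= 1")
    return length


@dataclass(frozen=True)
class SiteTemplate:
    """Default make-up of newly inserted sites: a substitution model whose
    equilibrium supplies the states, extra processes to bind (e.g. the indel
    processes themselves), a rate-multiplier distribution, and tolerances."""

    model: SubstitutionModel | None = None
    extra_processes: tuple = ()
    rate_model: SiteRateModel | None = None
    deletion_tolerance: float = 1.0
    insertion_tolerance: float = 1.0
    partition: str | None = None


@dataclass(eq=False)
class DeletionProcess:
    rate: float
    lengths: LengthDistribution = FIXED_ONE
    mode: str = "plain_field"
    label: str = "deletion"
    kind = "deletion"

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise IndelError("deletion rate must be nonnegative")
        if self.mode not in ("plain_field", "fast_field"):
            raise IndelError(f"unknown deletion mode {self.mode!r}")


@dataclass(eq=False)
class InsertionProcess:
    rate: float
    lengths: LengthDistribution = FIXED_ONE
    generator: Callable | None = None  # (length, context, rng) -> list[Site]
    template: SiteTemplate = field(default_factory=SiteTemplate)
    label: str = "insertion"
    kind = "insertion"

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise IndelError("insertion rate must be nonnegative")


@dataclass(frozen=True)
class DeletionSpan:
    """Half-open interval [start, stop) proposed for removal."""

    start: int
    stop: int
    initiating_site: int
    proposed_length: int
    truncated: bool

    def __post_init__(self) -> None:
        if not self.start <= self.initiating_site < self.stop:
            raise IndelError("initiating site must lie inside the span")

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class InsertionContext:
    """Flanking context handed to insert generators."""

    sequence: EvolvingSequence
    position: int  # new sites go before this index

    def left_states(self, k: int) -> list[str]:
        return [s.state for s in self.sequence.sites[max(0, self.position - k):self.position]]

    def right_states(self, k: int) -> list[str]:
        return [s.state for s in self.sequence.sites[self.position:self.position + k]]


def _binding_to(seq: EvolvingSequence, i: int, proc) -> ProcessBinding | None:
    for b in seq.sites[i].bindings:
        if b.process is proc:
            return b
    return None


def propose_deletion(
    seq: EvolvingSequence, proc: DeletionProcess, initiating_site: int, rng: np.random.Generator
) -> DeletionSpan:
    """Anchor a proposed deletion at ``initiating_site`` (its leftmost site)
    and extend rightward by the drawn length, truncating at the sequence end.
    Truncation (rather than rejection) avoids edge artifacts; acceptance then
    uses only the surviving sites' tolerances."""
    if _binding_to(seq, initiating_site, proc) is None:
        raise IndelError(f"site {initiating_site} is not bound to {proc.label!r}")
    length = sample_indel_length(proc.lengths, rng)
    stop = initiating_site + length
    truncated = stop > len(seq)
    if truncated:
        stop = len(seq)
    return DeletionSpan(initiating_site, stop, initiating_site, length, truncated)


def deletion_acceptance_probability(
    seq: EvolvingSequence, span: DeletionSpan, proc: DeletionProcess
) -> float:
    """prod(d_i) over the span (plain field), or prod(d_i) / D (fast field).

    A span site not bound to ``proc`` — a deletion reaching across a
    partition boundary — contributes the neutral tolerance 1.
    """
    p = 1.0
    for i in range(span.start, span.stop):
        b = _binding_to(seq, i, proc)
        if b is not None:
            p *= b.deletion_tolerance
    if proc.mode == "fast_field":
        D = seq.max_tolerance(proc)
        if D <= 0.0:
            return 0.0
        p /= D
    return min(p, 1.0)


def effective_deletion_proposal_rate(seq: EvolvingSequence, proc: DeletionProcess, i: int) -> float:
    """Per-site proposal initiation rate; in fast_field mode scaled by the
    current maximum tolerance D among bound sites."""
    b = _binding_to(seq, i, proc)
    if b is None:
        raise IndelError(f"site {i} is not bound to {proc.label!r}")
    r = proc.rate * b.rate_multiplier
    if proc.mode == "fast_field":
        r *= seq.max_tolerance(proc)
    return r


def accept_or_reject(probability: float, rng: np.random.Generator) -> bool:
    if not 0.0 <= probability <= 1.0:
        raise IndelError(f"acceptance probability {probability} outside [0, 1]")
    if probability >= 1.0:
        return True
    if probability <= 0.0:
        return False
    return bool(rng.random() < probability)


def default_insert_generator(
    proc: InsertionProcess, length: int, context: InsertionContext, rng: np.random.Generator
) -> list[Site]:
    """States drawn from the template model's equilibrium; bindings copied
    from the process template (fresh rate multipliers per site)."""
    t = proc.template
    if t.model is None:
        raise IndelError(f"insertion process {proc.label!r} has no template model and no generator")
    idx = rng.choice(len(t.model.alphabet), size=length, p=t.model.pi)
    if t.rate_model is not None:
        mults = draw_site_rates(t.rate_model, length, rng)
    else:
        mults = np.ones(length)
    sites = []
    for j, m in zip(idx, mults):
        bindings = [ProcessBinding(t.model, rate_multiplier=float(m))]
        for extra in t.extra_processes:
            bindings.append(
                ProcessBinding(
                    extra,
                    deletion_tolerance=t.deletion_tolerance,
                    insertion_tolerance=t.insertion_tolerance,
                )
            )
        sites.append(Site(t.model.alphabet.symbols[j], bindings, partition=t.partition))
    return sites


def duplication_generator(proc: InsertionProcess, length: int, context: InsertionContext,
                          rng: np.random.Generator) -> list[Site]:
    """Tandem duplication: copy the ``length`` sites left of the insertion
    point (states and bindings)."""
    flank = context.sequence.sites[max(0, context.position - length):context.position]
    if len(flank) < length:
        raise IndelError("duplication flank shorter than the drawn length")
    return [Site(s.state, [b.copy() for b in s.bindings], partition=s.partition) for s in flank]


@dataclass(frozen=True)
class InsertionProposal:
    position: int  # insertion point: new sites go before this index
    new_sites: tuple
    proposed_length: int


def propose_insertion(
    seq: EvolvingSequence, proc: InsertionProcess, initiating_site: int, rng: np.random.Generator
) -> InsertionProposal:
    """Draw a length, invoke the generator with the flanking context and
    place the insert immediately right of the initiating site."""
    if _binding_to(seq, initiating_site, proc) is None:
        raise IndelError(f"site {initiating_site} is not bound to {proc.label!r}")
    length = sample_indel_length(proc.lengths, rng)
    position = initiating_site + 1
    context = InsertionContext(seq, position)
    gen = proc.generator
    if gen is None:
        new_sites = default_insert_generator(proc, length, context, rng)
    else:
        new_sites = gen(length, context, rng)
    new_sites = list(new_sites)
    if len(new_sites) != length or not all(isinstance(s, Site) for s in new_sites):
        name = getattr(gen, "__name__", repr(gen)) if gen else "default"
        raise IndelError(f"insert generator {name} returned an invalid payload")
    return InsertionProposal(position, tuple(new_sites), length)


def insertion_acceptance_probability(seq: EvolvingSequence, proc: InsertionProcess,
                                     initiating_site: int) -> float:
    """Insertions are gated by the initiating site's tolerance only."""
    b = _binding_to(seq, initiating_site, proc)
    if b is None:
        raise IndelError(f"site {initiating_site} is not bound to {proc.label!r}")
    return b.insertion_tolerance
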