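"""The evolving-sequence data model.

A sequence is an ordered list of sites.  Each site carries a state token and
an ordered list of process bindings; a binding attaches a substitution,
insertion or deletion process to the site together with the site- and
process-specific parameters (rate multiplier, deletion/insertion tolerance).
Sites with no substitution binding never change state (fixed motifs); indel
processes may still act on them.

Every site's total event-initiation rate is cached, as is the sequence
total; the caches are refreshed incrementally by mutators and verified
against a from-scratch recomputation by :meth:`EvolvingSequence.audit`
(the engine audits periodically to catch floating-point drift).

Sites are 0-based internally; logs and annotation tracks are 1-based.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence as TSequence

import numpy as np

from .models import SubstitutionModel

__all__ = [
    "ProcessBinding",
    "Site",
    "EvolvingSequence",
    "SequenceError",
    "RateAuditError",
    "make_root_sequence",
    "make_root_from_string",
    "attach_process",
    "site_event_rate",
    "set_site_property",
]


class SequenceError(ValueError):
    pass


class RateAuditError(RuntimeError):
    """Cached rates drifted from a from-scratch recomputation."""


_PROPERTY_KEYS = ("rate_multiplier", "deletion_tolerance", "insertion_tolerance")


def process_kind(process) -> str:
    """'substitution' | 'insertion' | 'deletion'."""
    kind = getattr(process, "kind", None)
    if kind is None and isinstance(process, SubstitutionModel):
        kind = "substitution"
    if kind not in ("substitution", "insertion", "deletion"):
        raise SequenceError(f"object {process!r} is not a usable process")
    return kind


class ProcessBinding:
    """Attachment of one process to one site, with per-site parameters."""

    __slots__ = ("process", "rate_multiplier", "deletion_tolerance", "insertion_tolerance")

    def __init__(
        self,
        process,
        rate_multiplier: float = 1.0,
        deletion_tolerance: float = 1.0,
        insertion_tolerance: float = 1.0,
    ):
        if rate_multiplier < 0:
            raise SequenceError("rate_multiplier must be nonnegative")
        if not 0.0 <= deletion_tolerance <= 1.0:
            raise SequenceError("deletion_tolerance must lie in [0, 1]")
        if not 0.0 <= insertion_tolerance <= 1.0:
            raise SequenceError("insertion_tolerance must lie in [0, 1]")
        self.process = process
        self.rate_multiplier = rate_multiplier
        self.deletion_tolerance = deletion_tolerance
        self.insertion_tolerance = insertion_tolerance

    def copy(self) -> "ProcessBinding":
        return ProcessBinding(
            self.process, self.rate_multiplier, self.deletion_tolerance, self.insertion_tolerance
        )


class Site:
    __slots__ = ("state", "bindings", "uid", "partition")

    def __init__(self, state: str, bindings: Iterable[ProcessBinding] = (), uid=None, partition=None):
        self.state = state
        self.bindings = list(bindings)
        self.uid = uid
        self.partition = partition

    def copy(self) -> "Site":
        return Site(self.state, [b.copy() for b in self.bindings], self.uid, self.partition)

    def substitution_bindings(self):
        return [b for b in self.bindings if process_kind(b.process) == "substitution"]


class EvolvingSequence:
    """Ordered sites plus cached per-site and total event rates."""

    def __init__(self, sites: Iterable[Site], uid_counter: itertools.count | None = None):
        self.sites: list[Site] = list(sites)
        if uid_counter is None:
            start = 0
            for s in self.sites:
                if s.uid is None:
                    s.uid = start
                    start += 1
                else:
                    start = max(start, s.uid + 1)
            uid_counter = itertools.count(start)
        self._uid_counter = uid_counter
        self._dmax: dict = {}
        self._validate_states()
        self._rates = np.array([self._site_rate(s) for s in self.sites], dtype=float)
        self.cached_total_rate = float(self._rates.sum())

    # -- basics ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def cached_site_rates(self) -> np.ndarray:
        return self._rates

    def states(self) -> list[str]:
        return [s.state for s in self.sites]

    def text(self) -> str:
        return "".join(s.state for s in self.sites)

    def copy(self) -> "EvolvingSequence":
        """Independent copy sharing the process objects and the uid counter
        (so sibling branches never reuse a site identity)."""
        new = EvolvingSequence.__new__(EvolvingSequence)
        new.sites = [s.copy() for s in self.sites]
        new._uid_counter = self._uid_counter
        new._dmax = {}
        new._rates = self._rates.copy()
        new.cached_total_rate = self.cached_total_rate
        return new

    def new_uid(self):
        return next(self._uid_counter)

    def _validate_states(self) -> None:
        for i, s in enumerate(self.sites):
            for b in s.bindings:
                if process_kind(b.process) == "substitution" and s.state not in b.process.alphabet:
                    raise SequenceError(
                        f"site {i}: state {s.state!r} not in alphabet of {b.process.label!r}"
                    )

    # -- rate bookkeeping --------------------------------------------------

    def max_tolerance(self, proc) -> float:
        """Largest deletion tolerance among sites bound to ``proc``
        (the fast-field proposal scale D); cached lazily."""
        D = self._dmax.get(id(proc))
        if D is None:
            D = 0.0
            for s in self.sites:
                for b in s.bindings:
                    if b.process is proc and b.deletion_tolerance > D:
                        D = b.deletion_tolerance
            self._dmax[id(proc)] = D
        return D

    def _binding_rate(self, site: Site, b: ProcessBinding) -> float:
        kind = process_kind(b.process)
        if kind == "substitution":
            return b.rate_multiplier * b.process.leave_rate(site.state)
        if kind == "insertion":
            return b.rate_multiplier * b.process.rate
        # deletion
        r = b.rate_multiplier * b.process.rate
        if b.process.mode == "fast_field":
            r *= self.max_tolerance(b.process)
        return r

    def _site_rate(self, site: Site) -> float:
        return sum(self._binding_rate(site, b) for b in site.bindings)

    def binding_rates(self, i: int) -> list[float]:
        """Per-binding event-initiation rates at site ``i`` (engine level 2)."""
        s = self.sites[i]
        return [self._binding_rate(s, b) for b in s.bindings]

    def refresh_site(self, i: int) -> None:
        new = self._site_rate(self.sites[i])
        self.cached_total_rate += new - self._rates[i]
        self._rates[i] = new

    def _refresh_deletion_scale(self, proc) -> None:
        """Recompute D for a fast-field deletion process and refresh the
        cached rates of every site bound to it if D changed."""
        if getattr(proc, "mode", None) != "fast_field":
            return
        old = self._dmax.pop(id(proc), None)
        new = self.max_tolerance(proc)
        if old is not None and old == new:
            return
        for i, s in enumerate(self.sites):
            if any(b.process is proc for b in s.bindings):
                self.refresh_site(i)

    def _fast_deletion_procs(self, sites: Iterable[Site]):
        procs = []
        for s in sites:
            for b in s.bindings:
                if getattr(b.process, "mode", None) == "fast_field" and not any(
                    p is b.process for p in procs
                ):
                    procs.append(b.process)
        return procs

    def audit(self, rel_tol: float = 1e-9) -> None:
        """Recompute every cached rate from scratch; raise on drift."""
        self._dmax.clear()
        fresh = np.array([self._site_rate(s) for s in self.sites], dtype=float)
        total = float(fresh.sum())
        if not np.isclose(total, self.cached_total_rate, rtol=rel_tol, atol=1e-12):
            raise RateAuditError(
                f"cached total rate {self.cached_total_rate!r} != recomputed {total!r}"
            )
        self._rates = fresh
        self.cached_total_rate = total

    # -- mutators ----------------------------------------------------------

    def set_state(self, i: int, token: str) -> None:
        s = self.sites[i]
        for b in s.bindings:
            if process_kind(b.process) == "substitution" and token not in b.process.alphabet:
                raise SequenceError(
                    f"site {i}: token {token!r} not in alphabet of {b.process.label!r}"
                )
        s.state = token
        self.refresh_site(i)

    def delete_span(self, start: int, stop: int) -> list[Site]:
        """Remove sites[start:stop]; returns the removed sites."""
        removed = self.sites[start:stop]
        fast = self._fast_deletion_procs(removed)
        del self.sites[start:stop]
        self._rates = np.delete(self._rates, np.s_[start:stop])
        self.cached_total_rate = float(self._rates.sum())
        for proc in fast:
            self._refresh_deletion_scale(proc)
        return removed

    def insert_sites(self, pos: int, new_sites: TSequence[Site]) -> list[Site]:
        """Splice ``new_sites`` in before index ``pos``; assigns uids."""
        for s in new_sites:
            if s.uid is None:
                s.uid = self.new_uid()
        for s in new_sites:
            for b in s.bindings:
                if process_kind(b.process) == "substitution" and s.state not in b.process.alphabet:
                    raise SequenceError(
                        f"inserted state {s.state!r} not in alphabet of {b.process.label!r}"
                    )
        self.sites[pos:pos] = list(new_sites)
        rates = [self._site_rate(s) for s in new_sites]
        self._rates = np.insert(self._rates, pos, rates)
        self.cached_total_rate = float(self._rates.sum())
        for proc in self._fast_deletion_procs(new_sites):
            self._refresh_deletion_scale(proc)
        return list(new_sites)


# --------------------------------------------------------------------------
# Module-level operations
# --------------------------------------------------------------------------


def make_root_sequence(
    length: int,
    model: SubstitutionModel,
    rng: np.random.Generator,
    rate_multipliers: np.ndarray | None = None,
) -> EvolvingSequence:
    """Equilibrium root: states drawn iid from ``model.pi``, one binding per
    site to ``model`` (optionally with per-site rate multipliers)."""
    if length < 1:
        raise SequenceError("length must be >= 1")
    idx = rng.choice(len(model.alphabet), size=length, p=model.pi)
    if rate_multipliers is None:
        rate_multipliers = np.ones(length)
    sites = [
        Site(model.alphabet.symbols[j], [ProcessBinding(model, rate_multiplier=float(m))])
        for j, m in zip(idx, rate_multipliers)
    ]
    return EvolvingSequence(sites)


def make_root_from_string(
    tokens: TSequence[str],
    attachments: TSequence[tuple[int, int, object]] = (),
) -> EvolvingSequence:
    """Root with explicit states.

    ``tokens`` is a string (one character per site) or a list of tokens
    (needed for codon sites).  ``attachments`` is a list of
    ``(start, stop, process)`` half-open ranges; sites left unbound carry any
    token and stay fixed (motifs).
    """
    sites = [Site(t) for t in tokens]
    for start, stop, process in attachments:
        if process_kind(process) == "substitution":
            for i in range(start, stop):
                if sites[i].state not in process.alphabet:
                    raise SequenceError(
                        f"site {i}: token {sites[i].state!r} not in alphabet of "
                        f"{process.label!r}"
                    )
        for i in range(start, stop):
            sites[i].bindings.append(ProcessBinding(process))
    return EvolvingSequence(sites)


def attach_process(
    seq: EvolvingSequence,
    site_range: tuple[int, int],
    process,
    params: dict | None = None,
) -> None:
    """Bind ``process`` to every site in the half-open ``site_range``.

    ``params`` may give ``rate_multiplier`` / ``deletion_tolerance`` /
    ``insertion_tolerance`` as scalars or per-site arrays over the range.
    """
    start, stop = site_range
    if start < 0 or stop > len(seq):
        raise SequenceError(f"range [{start}, {stop}) outside sequence of length {len(seq)}")
    if stop <= start:
        return
    params = params or {}
    for key in params:
        if key not in _PROPERTY_KEYS:
            raise SequenceError(f"unknown binding parameter {key!r}")
    kind = process_kind(process)
    if kind == "substitution":
        for i in range(start, stop):
            site = seq.sites[i]
            if site.state not in process.alphabet:
                raise SequenceError(
                    f"site {i}: state {site.state!r} not in alphabet of {process.label!r}"
                )
            for b in site.substitution_bindings():
                if b.process.alphabet is not process.alphabet and (
                    b.process.alphabet.symbols != process.alphabet.symbols
                ):
                    raise SequenceError(
                        f"site {i}: overlapping substitution processes with "
                        "different alphabets"
                    )

    def pick(key, i):
        v = params.get(key)
        if v is None:
            return 1.0
        if np.isscalar(v):
            return float(v)
        return float(v[i - start])

    for i in range(start, stop):
        seq.sites[i].bindings.append(
            ProcessBinding(
                process,
                rate_multiplier=pick("rate_multiplier", i),
                deletion_tolerance=pick("deletion_tolerance", i),
                insertion_tolerance=pick("insertion_tolerance", i),
            )
        )
        seq.refresh_site(i)
    if kind == "deletion":
        seq._refresh_deletion_scale(process)


def site_event_rate(seq: EvolvingSequence, i: int) -> float:
    """Total event-initiation rate at site ``i``, recomputed from bindings."""
    return seq._site_rate(seq.sites[i])


def set_site_property(seq: EvolvingSequence, i: int, process, key: str, value: float) -> None:
    """Update one per-(site, process) parameter and refresh caches."""
    if key not in _PROPERTY_KEYS:
        raise SequenceError(f"unknown property {key!r}")
    if key == "rate_multiplier":
        if value < 0:
            raise SequenceError("rate_multiplier must be nonnegative")
    elif not 0.0 <= value <= 1.0:
        raise SequenceError(f"{key} must lie in [0, 1]")
    site = seq.sites[i]
    for b in site.bindings:
        if b.process is process:
            setattr(b, key, float(value))
            break
    else:
        raise SequenceError(f"site {i} has no binding to {process!r}")
    if key == "deletion_tolerance":
        seq._refresh_deletion_scale(process)
    seq.refresh_site(i)
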