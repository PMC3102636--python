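"""Parameter-recovery diagnostics.

The simulator is validated internally: simulate under known parameters,
then recover them with closed-form estimators (p-distance, the Kimura
two-parameter distance and transition/transversion ratio) and exact event
tallies, without any external inference software.
"""

from __future__ import annotations

import math
import re
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import evolve_branch
from .models import STANDARD_GENETIC_CODE, SubstitutionModel
from .sequence import make_root_sequence

__all__ = [
    "DiagnosticsError",
    "p_distance",
    "transition_transversion_fractions",
    "k80_estimates",
    "k80_estimates_from_pair",
    "count_events",
    "end_state_counts",
]

GAP = "-"

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


class DiagnosticsError(ValueError):
    pass


def _comparable(seq_a: Sequence[str], seq_b: Sequence[str]):
    if len(seq_a) != len(seq_b):
        raise DiagnosticsError("sequences must be compared over equal-length rows")
    pairs = [(a, b) for a, b in zip(seq_a, seq_b) if a != GAP and b != GAP]
    if not pairs:
        raise DiagnosticsError("no comparable (ungapped) sites")
    return pairs


def p_distance(seq_a: Sequence[str], seq_b: Sequence[str]) -> float:
    """Fraction of differing sites among shared ungapped columns."""
    pairs = _comparable(seq_a, seq_b)
    return sum(a != b for a, b in pairs) / len(pairs)


def transition_transversion_fractions(seq_a: Sequence[str], seq_b: Sequence[str]):
    """(P, Q): fractions of comparable sites differing by a transition and by
    a transversion, respectively."""
    pairs = _comparable(seq_a, seq_b)
    n = len(pairs)
    P = sum(
        1 for a, b in pairs
        if a != b and ({a, b} <= _PURINES or {a, b} <= _PYRIMIDINES)
    )
    Q = sum(
        1 for a, b in pairs
        if a != b and not ({a, b} <= _PURINES or {a, b} <= _PYRIMIDINES)
    )
    return P / n, Q / n


def k80_estimates(P: float, Q: float) -> tuple[float, float]:
    """Kimura (1980) two-parameter estimators.

    With w1 = 1 - 2P - Q and w2 = 1 - 2Q,
    ``d = -1/2 ln w1 - 1/4 ln w2`` (expected substitutions per site) and
    ``kappa_hat = 2 * (-1/2 ln w1 + 1/4 ln w2) / (-1/2 ln w2)``, the
    instantaneous transition/transversion rate ratio.
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise DiagnosticsError("sequences too diverged for the K80 estimator (saturation)")
    a = -0.5 * math.log(w1)  # (alpha + beta) t
    b = -0.25 * math.log(w2)  # beta t
    d = a + b
    if Q == 0:
        return d, math.inf if P > 0 else float("nan")
    kappa_hat = 2.0 * (a - b) / (-0.5 * math.log(w2))
    return d, kappa_hat


def k80_estimates_from_pair(seq_a: Sequence[str], seq_b: Sequence[str]) -> tuple[float, float]:
    P, Q = transition_transversion_fractions(seq_a, seq_b)
    return k80_estimates(P, Q)


_DETAIL_SUB = re.compile(r"^(\S+)->(\S+)$")


def _classify_codon(from_state: str, to_state: str, code: Mapping[str, str]) -> str:
    return "synonymous" if code.get(from_state) == code.get(to_state) else "nonsynonymous"


def count_events(
    events: Iterable | pd.DataFrame,
    genetic_code: Mapping[str, str] | None = None,
) -> dict:
    """Tally an event log.

    Accepts the in-memory ``SimulationResult.events()`` list of
    ``(branch, Event)`` pairs (or bare Events) or a DataFrame read from the
    events TSV.  Substitutions between triplet tokens are additionally
    classified as synonymous/nonsynonymous under ``genetic_code`` (standard
    code by default).
    """
    code = STANDARD_GENETIC_CODE if genetic_code is None else genetic_code
    by_kind: dict[str, int] = {}
    by_process: dict[str, int] = {}
    rejected: dict[str, int] = {}
    syn = nonsyn = 0
    if isinstance(events, pd.DataFrame):
        rows = events.itertuples()
        for r in rows:
            kind, accepted, detail = r.kind, bool(r.accepted), str(r.detail)
            proc = getattr(r, "process", "")
            if not accepted:
                rejected[kind] = rejected.get(kind, 0) + 1
                continue
            by_kind[kind] = by_kind.get(kind, 0) + 1
            if proc:
                by_process[proc] = by_process.get(proc, 0) + 1
            m = _DETAIL_SUB.match(detail)
            if kind == "substitution" and m and len(m.group(1)) == 3:
                if _classify_codon(m.group(1), m.group(2), code) == "synonymous":
                    syn += 1
                else:
                    nonsyn += 1
    else:
        for item in events:
            ev = item[1] if isinstance(item, tuple) else item
            if not ev.accepted:
                rejected[ev.kind] = rejected.get(ev.kind, 0) + 1
                continue
            by_kind[ev.kind] = by_kind.get(ev.kind, 0) + 1
            if ev.process_label:
                by_process[ev.process_label] = by_process.get(ev.process_label, 0) + 1
            if ev.kind == "substitution" and ev.from_state and len(ev.from_state) == 3:
                if _classify_codon(ev.from_state, ev.to_state, code) == "synonymous":
                    syn += 1
                else:
                    nonsyn += 1
    return {
        "by_kind": by_kind,
        "by_process": by_process,
        "rejected": rejected,
        "synonymous": syn,
        "nonsynonymous": nonsyn,
    }


def end_state_counts(
    model: SubstitutionModel,
    start_state: str,
    t: float,
    n_replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve one site from ``start_state`` for time ``t``, ``n_replicates``
    times; returns end-state counts in alphabet order.  Compare against the
    matching row of the matrix exponential for a jump-chain correctness
    check."""
    counts = np.zeros(len(model.alphabet), dtype=int)
    seq = make_root_sequence(1, model, rng)
    idx = model.alphabet.index
    for _ in range(n_replicates):
        seq.set_state(0, start_state)
        evolve_branch(seq, t, rng)
        counts[idx[seq.sites[0].state]] += 1
    return counts
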