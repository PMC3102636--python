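"""Substitution models over arbitrary alphabets and among-site rate variation.

A substitution model is a continuous-time Markov chain on a finite alphabet,
specified by an instantaneous rate matrix ``Q`` (off-diagonals >= 0, rows
summing to zero) and its stationary distribution ``pi``.  Time is measured in
expected substitutions per site: every constructor rescales ``Q`` so that one
unit of branch length produces one expected substitution per site at
equilibrium (``sum_i pi_i * -Q_ii == 1``).  Special motif processes whose
rates are meant relative to that time unit can opt out with
``normalize=False``.

Among-site rate variation is expressed as per-site nonnegative multipliers
drawn from a :class:`SiteRateModel` (constant, discrete/continuous gamma,
invariant sites plus gamma, or an arbitrary user rule).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import linalg, sparse, stats

__all__ = [
    "Alphabet",
    "SubstitutionModel",
    "SiteRateModel",
    "DNA",
    "AMINO_ACIDS",
    "STANDARD_GENETIC_CODE",
    "sense_codons",
    "build_general_model",
    "build_k80",
    "build_gtr",
    "build_unrest",
    "build_gy94",
    "load_empirical_aa",
    "write_empirical_aa",
    "codon_freqs_f3x4",
    "transition_probabilities",
    "discrete_gamma_rates",
    "draw_site_rates",
]

NUCLEOTIDES = ("A", "C", "G", "T")
AA_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")

# transition pairs (purine<->purine, pyrimidine<->pyrimidine)
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _is_transition(a: str, b: str) -> bool:
    return frozenset((a, b)) in _TRANSITIONS


class ModelError(ValueError):
    """Raised for invalid model specifications."""


# --------------------------------------------------------------------------
# Alphabets and the genetic code
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of distinct state tokens.

    Tokens are single characters for nucleotides and amino acids, and
    triplets for codons; any hashable string works.
    """

    symbols: tuple[str, ...]
    index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise ModelError("alphabet needs at least 2 symbols")
        if len(set(self.symbols)) != len(self.symbols):
            raise ModelError("alphabet symbols must be unique")
        object.__setattr__(self, "index", {s: i for i, s in enumerate(self.symbols)})

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, token: str) -> bool:
        return token in self.index


DNA = Alphabet(NUCLEOTIDES)
AMINO_ACIDS = Alphabet(AA_ORDER)


def _standard_code() -> dict[str, str]:
    aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    code = {}
    k = 0
    for b1 in "TCAG":
        for b2 in "TCAG":
            for b3 in "TCAG":
                code[b1 + b2 + b3] = aas[k]
                k += 1
    return code


#: Codon -> amino-acid letter ('*' = stop), standard nuclear code.
STANDARD_GENETIC_CODE: dict[str, str] = _standard_code()


def sense_codons(genetic_code: Mapping[str, str] | None = None) -> tuple[str, ...]:
    """Non-stop codons of a genetic code, in TCAG nested order."""
    code = STANDARD_GENETIC_CODE if genetic_code is None else genetic_code
    return tuple(c for c in code if code[c] != "*")


# --------------------------------------------------------------------------
# SubstitutionModel
# --------------------------------------------------------------------------


@dataclass
class SubstitutionModel:
    """A normalized continuous-time Markov substitution process.

    Attributes
    ----------
    alphabet : Alphabet
    Q : (n, n) ndarray
        Instantaneous rates; rows sum to zero.  Unless built with
        ``normalize=False`` the matrix satisfies
        ``sum_i pi_i * sum_{j!=i} Q_ij == 1``.
    pi : (n,) ndarray
        Stationary distribution of Q.
    scale : float
        Factor the raw matrix was divided by to reach normalization
        (1.0 for unnormalized models).
    label : str
    """

    alphabet: Alphabet
    Q: np.ndarray
    pi: np.ndarray
    scale: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        n = len(self.alphabet)
        self.Q = np.asarray(self.Q, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.Q.shape != (n, n):
            raise ModelError(f"Q must be {n}x{n}, got {self.Q.shape}")
        off = self.Q.copy()
        np.fill_diagonal(off, 0.0)
        if (off < 0).any():
            raise ModelError("off-diagonal rates must be nonnegative")
        if np.abs(self.Q.sum(axis=1)).max() > 1e-10:
            raise ModelError("rows of Q must sum to zero")
        if (self.pi < 0).any() or abs(self.pi.sum() - 1.0) > 1e-10:
            raise ModelError("pi must be a probability vector")
        if np.abs(self.pi @ self.Q).max() > 1e-8:
            raise ModelError("pi is not stationary for Q")

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def leave_rate(self, token: str) -> float:
        """Total rate of leaving ``token`` (the negated diagonal entry)."""
        i = self.alphabet.index[token]
        return -self.Q[i, i]

    def expected_rate(self) -> float:
        """Expected substitutions per site per unit time at equilibrium."""
        return float(-(self.pi * np.diag(self.Q)).sum())


def _check_irreducible(rates: np.ndarray, symbols: Sequence[str]) -> None:
    n = rates.shape[0]
    adj = sparse.csr_matrix((rates > 0).astype(int))
    n_comp, labels = sparse.csgraph.connected_components(adj, connection="strong")
    if n_comp > 1:
        # name states outside the component of state 0
        stranded = [symbols[i] for i in range(n) if labels[i] != labels[0]]
        raise ModelError(
            "rate matrix is reducible; states not mutually reachable from "
            f"{symbols[0]!r}: {stranded}"
        )


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Solve pi Q = 0, sum(pi) = 1 as an augmented linear system."""
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def build_general_model(
    alphabet: Alphabet,
    off_diagonal_rates: np.ndarray,
    pi: np.ndarray | None = None,
    *,
    normalize: bool = True,
    label: str = "general",
    require_irreducible: bool = True,
) -> SubstitutionModel:
    """Build a model from an arbitrary matrix of off-diagonal rates.

    The diagonal is filled so rows sum to zero.  If ``pi`` is omitted it is
    computed as the stationary vector of Q; if given, it must be stationary
    within tolerance.  With ``normalize=True`` (default) Q is rescaled to one
    expected substitution per site per unit time.  ``require_irreducible``
    may only be relaxed when ``pi`` is supplied (a reducible chain has no
    unique stationary vector).
    """
    n = len(alphabet)
    R = np.array(off_diagonal_rates, dtype=float)
    if R.shape != (n, n):
        raise ModelError(f"rate matrix must be {n}x{n} for this alphabet")
    np.fill_diagonal(R, 0.0)
    if (R < 0).any():
        raise ModelError("off-diagonal rates must be nonnegative")
    if require_irreducible or pi is None:
        _check_irreducible(R, alphabet.symbols)
    Q = R.copy()
    np.fill_diagonal(Q, -R.sum(axis=1))
    if pi is None:
        pi = stationary_distribution(Q)
    else:
        pi = np.asarray(pi, dtype=float)
        if pi.shape != (n,):
            raise ModelError(f"pi must have length {n}")
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ModelError("pi must sum to 1")
        if np.abs(pi @ Q).max() > 1e-8 * max(1.0, np.abs(Q).max()):
            raise ModelError("supplied pi is not stationary for Q")
        pi = pi / pi.sum()
    scale = 1.0
    if normalize:
        scale = float(-(pi * np.diag(Q)).sum())
        if scale <= 0:
            raise ModelError("cannot normalize a zero-rate matrix")
        Q = Q / scale
    return SubstitutionModel(alphabet, Q, pi, scale=scale, label=label)


def build_k80(kappa: float) -> SubstitutionModel:
    """Kimura two-parameter nucleotide model: uniform frequencies,
    transition/transversion rate ratio ``kappa``."""
    if kappa <= 0:
        raise ModelError("kappa must be positive")
    R = np.zeros((4, 4))
    for i, a in enumerate(NUCLEOTIDES):
        for j, b in enumerate(NUCLEOTIDES):
            if i != j:
                R[i, j] = kappa if _is_transition(a, b) else 1.0
    return build_general_model(DNA, R, np.full(4, 0.25), label=f"K80(kappa={kappa:g})")


def build_gtr(exchangeabilities: Sequence[float], base_freqs: Sequence[float]) -> SubstitutionModel:
    """General time-reversible nucleotide model.

    ``exchangeabilities`` are the six symmetric terms in the order
    (AC, AG, AT, CG, CT, GT); ``Q_ij = s_ij * pi_j``.
    """
    s = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(base_freqs, dtype=float)
    if s.shape != (6,):
        raise ModelError("GTR needs exactly 6 exchangeabilities (AC, AG, AT, CG, CT, GT)")
    if pi.shape != (4,):
        raise ModelError("GTR needs 4 base frequencies")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ModelError("base frequencies must sum to 1")
    if (s < 0).any():
        raise ModelError("exchangeabilities must be nonnegative")
    S = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for val, (i, j) in zip(s, pairs):
        S[i, j] = S[j, i] = val
    R = S * pi[None, :]
    return build_general_model(DNA, R, pi, label="GTR")


def build_unrest(off_diagonal_rates: Sequence[float]) -> SubstitutionModel:
    """Unrestricted 12-parameter nucleotide model.

    Rates are given row-major over off-diagonal cells:
    (A>C, A>G, A>T, C>A, C>G, C>T, G>A, G>C, G>T, T>A, T>C, T>G).
    The stationary distribution is computed numerically.
    """
    r = np.asarray(off_diagonal_rates, dtype=float)
    if r.shape != (12,):
        raise ModelError("UNREST needs exactly 12 off-diagonal rates")
    R = np.zeros((4, 4))
    k = 0
    for i in range(4):
        for j in range(4):
            if i != j:
                R[i, j] = r[k]
                k += 1
    return build_general_model(DNA, R, label="UNREST")


def build_gy94(
    kappa: float,
    omega: float,
    codon_freqs: Sequence[float] | str = "equal",
    genetic_code: Mapping[str, str] | None = None,
) -> SubstitutionModel:
    """Goldman-Yang codon model on the sense codons of a genetic code.

    Codons differing at more than one nucleotide position never interchange
    directly.  A single-nucleotide change from codon i to codon j has rate
    ``pi_j`` multiplied by ``kappa`` if the change is a transition and by
    ``omega`` if it alters the encoded amino acid (nonsynonymous).
    """
    if kappa <= 0:
        raise ModelError("kappa must be positive")
    if omega < 0:
        raise ModelError("omega must be nonnegative")
    code = STANDARD_GENETIC_CODE if genetic_code is None else dict(genetic_code)
    codons = sense_codons(code)
    n = len(codons)
    if isinstance(codon_freqs, str):
        if codon_freqs != "equal":
            raise ModelError(f"unknown codon frequency option {codon_freqs!r}")
        pi = np.full(n, 1.0 / n)
    else:
        pi = np.asarray(codon_freqs, dtype=float)
        if pi.shape != (n,):
            raise ModelError(
                f"codon_freqs must have length {n} (sense codons only; "
                "stop codons are excluded from the state space)"
            )
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ModelError("codon frequencies must sum to 1")
    alphabet = Alphabet(codons)
    R = np.zeros((n, n))
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            a, b = diffs[0]
            rate = pi[j]
            if _is_transition(a, b):
                rate *= kappa
            if code[ci] != code[cj]:
                rate *= omega
            R[i, j] = rate
    # omega = 0 forbids all nonsynonymous moves, so the chain is reducible
    # into synonymous classes; pi is still stationary (reversible within
    # each class), so the model is assembled with the check relaxed.
    return build_general_model(
        alphabet, R, pi,
        label=f"GY94(kappa={kappa:g},omega={omega:g})",
        require_irreducible=omega > 0,
    )


def codon_freqs_f3x4(
    nt_freqs_by_position: Sequence[Sequence[float]],
    genetic_code: Mapping[str, str] | None = None,
) -> np.ndarray:
    """F3x4 codon frequencies from per-codon-position nucleotide frequencies,
    renormalized over the sense codons."""
    F = np.asarray(nt_freqs_by_position, dtype=float)
    if F.shape != (3, 4):
        raise ModelError("need a 3x4 array of per-position ACGT frequencies")
    codons = sense_codons(genetic_code)
    idx = {b: i for i, b in enumerate(NUCLEOTIDES)}
    pi = np.array([F[0, idx[c[0]]] * F[1, idx[c[1]]] * F[2, idx[c[2]]] for c in codons])
    total = pi.sum()
    if total <= 0:
        raise ModelError("F3x4 frequencies put zero mass on all sense codons")
    return pi / total


# --------------------------------------------------------------------------
# Empirical amino-acid models
# --------------------------------------------------------------------------

_PACKAGED_AA = {"WAG": "wag.dat", "JTT": "jtt.dat", "LG": "lg.dat"}


def _parse_exchangeability_text(lines: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    values: list[float] = []
    for lineno, raw in enumerate(lines, start=1):
        text = raw.split("#", 1)[0].strip()
        if not text:
            continue
        for tok in text.split():
            try:
                values.append(float(tok))
            except ValueError:
                raise ModelError(f"line {lineno}: cannot parse {tok!r} as a number") from None
    if len(values) != 210:
        raise ModelError(
            "malformed exchangeability file: expected 190 lower-triangle entries "
            f"plus 20 frequencies (210 numbers), found {len(values)}"
        )
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = values[k]
            k += 1
    freqs = np.asarray(values[190:], dtype=float)
    if (freqs < 0).any():
        raise ModelError("negative equilibrium frequency in exchangeability file")
    if abs(freqs.sum() - 1.0) > 1e-4:
        warnings.warn(
            f"amino-acid frequencies sum to {freqs.sum():.6f}; renormalizing",
            stacklevel=3,
        )
    freqs = freqs / freqs.sum()
    return S, freqs


def load_empirical_aa(source: str) -> SubstitutionModel:
    """Load an empirical amino-acid model.

    ``source`` is either a packaged name (``"WAG"``, ``"JTT"``, ``"LG"``) or
    a path to a file in the standard plain-text layout: a 19-row
    lower-triangular block of exchangeabilities followed by 20 equilibrium
    frequencies, in ARNDCQEGHILKMFPSTWYV order; ``#`` starts a comment.
    """
    name = source.upper()
    if name in _PACKAGED_AA:
        text = (
            importlib.resources.files("evosim.data")
            .joinpath(_PACKAGED_AA[name])
            .read_text()
        )
        label = name
    else:
        with open(source) as fh:
            text = fh.read()
        label = f"empirical({source})"
    S, freqs = _parse_exchangeability_text(text.splitlines())
    R = S * freqs[None, :]
    return build_general_model(AMINO_ACIDS, R, freqs, label=label)


def write_empirical_aa(model: SubstitutionModel, path: str) -> None:
    """Write a reversible 20-state model back to the exchangeability layout.

    Exchangeabilities are recovered as ``Q_ij / pi_j`` (defined up to the
    normalization scale).
    """
    if len(model.alphabet) != 20:
        raise ModelError("write_empirical_aa expects a 20-state model")
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(model.pi[None, :] > 0, model.Q / model.pi[None, :], 0.0)
    with open(path, "w") as fh:
        for i in range(1, 20):
            fh.write(" ".join(f"{S[i, j]:.10g}" for j in range(i)) + "\n")
        fh.write("\n" + " ".join(f"{p:.10g}" for p in model.pi) + "\n")


# --------------------------------------------------------------------------
# Transition probabilities (oracle for the stochastic engine)
# --------------------------------------------------------------------------


def transition_probabilities(model: SubstitutionModel, t: float) -> np.ndarray:
    """P(t) = expm(Q t); row-stochastic."""
    if t < 0:
        raise ModelError("time must be nonnegative")
    return linalg.expm(model.Q * t)


# --------------------------------------------------------------------------
# Among-site rate variation
# --------------------------------------------------------------------------


@dataclass
class SiteRateModel:
    """Distribution of per-site rate multipliers.

    kind:
      - ``constant``: all multipliers 1.
      - ``discrete_gamma``: +G with ``n_categories`` equal-probability
        categories of Gamma(alpha, mean 1), each represented by its
        category mean so the average multiplier is exactly 1.
      - ``continuous_gamma``: one Gamma(alpha, mean 1) draw per site.
      - ``invariant_plus_gamma``: +I+G; a site is invariant (rate 0) with
        probability ``p_inv``, otherwise gamma with mean 1/(1 - p_inv),
        keeping the marginal mean at 1.
      - ``custom``: ``custom_rule(site_index, rng) -> multiplier``.
    """

    kind: str = "constant"
    alpha: float | None = None
    n_categories: int = 4
    p_inv: float = 0.0
    custom_rule: Callable[[int, np.random.Generator], float] | None = None

    _KINDS = ("constant", "discrete_gamma", "continuous_gamma", "invariant_plus_gamma", "custom")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ModelError(f"unknown rate model kind {self.kind!r}")
        if self.kind in ("discrete_gamma", "continuous_gamma", "invariant_plus_gamma"):
            if self.alpha is None or self.alpha <= 0:
                raise ModelError("gamma rate models need alpha > 0")
        if not 0.0 <= self.p_inv <= 1.0:
            raise ModelError("p_inv must lie in [0, 1]")
        if self.kind == "discrete_gamma" and self.n_categories < 1:
            raise ModelError("n_categories must be >= 1")
        if self.kind == "custom" and self.custom_rule is None:
            raise ModelError("custom rate model needs custom_rule")


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean rates of ``n_categories`` equal-probability categories of
    Gamma(alpha, mean 1), renormalized so their average is exactly 1."""
    if alpha <= 0:
        raise ModelError("alpha must be positive")
    k = n_categories
    edges = stats.gamma.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    # E[X | a < X < b] * P(a < X < b) = F_{alpha+1}(b) - F_{alpha+1}(a)
    # for Gamma(alpha, mean 1); each category has probability 1/k.
    cdf_hi = stats.gamma.cdf(edges[1:], a=alpha + 1, scale=1.0 / alpha)
    cdf_lo = stats.gamma.cdf(edges[:-1], a=alpha + 1, scale=1.0 / alpha)
    rates = k * (cdf_hi - cdf_lo)
    return rates / rates.mean()


def draw_site_rates(rate_model: SiteRateModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` per-site rate multipliers; deterministic given the rng state."""
    if n < 1:
        raise ModelError("need at least one site")
    m = rate_model
    if m.kind == "constant":
        return np.ones(n)
    if m.kind == "discrete_gamma":
        cats = discrete_gamma_rates(m.alpha, m.n_categories)
        return cats[rng.integers(0, m.n_categories, size=n)]
    if m.kind == "continuous_gamma":
        return rng.gamma(shape=m.alpha, scale=1.0 / m.alpha, size=n)
    if m.kind == "invariant_plus_gamma":
        invariant = rng.random(n) < m.p_inv
        if m.p_inv >= 1.0:
            return np.zeros(n)
        rates = rng.gamma(shape=m.alpha, scale=1.0 / m.alpha, size=n) / (1.0 - m.p_inv)
        rates[invariant] = 0.0
        return rates
    # custom
    out = np.empty(n)
    for i in range(n):
        r = float(m.custom_rule(i, rng))
        if r < 0:
            raise ModelError(f"custom rate rule returned a negative multiplier at site {i}")
        out[i] = r
    return out
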