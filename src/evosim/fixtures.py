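"""Deterministic synthetic inputs for tests and demos.

Three fixture kinds:

``random_tree``
    A random rooted binary tree plus a two-partition nucleotide config with
    substitution, insertion and deletion processes (both field modes).

``coding_region``
    A miniature genomic region: noncoding flanks and an intron under K80
    with indels, two exons under a GY94 codon model, a fixed start codon and
    splice-site motifs, and a stop codon interchanging among TAA/TAG/TGA by
    a dedicated three-state substitution process.

``domain_protein``
    A protein with a conserved domain (WAG, nearly indel-intolerant) and a
    permissive linker (LG, indel-tolerant) evolving under different
    empirical models.
"""

from __future__ import annotations

import numpy as np

from .io import RunConfig

__all__ = ["generate_fixture", "random_tree_newick"]


def random_tree_newick(n_tips: int, rng: np.random.Generator,
                       min_len: float = 0.02, max_len: float = 0.25) -> str:
    """Random rooted binary topology by sequential pairwise joining, with
    uniform branch lengths."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    nodes = [f"t{i + 1}" for i in range(n_tips)]

    def blen() -> str:
        return f"{rng.uniform(min_len, max_len):.4f}"

    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        joined = f"({a}:{blen()},{b}:{blen()})"
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [joined]
    return nodes[0] + ";"


def _random_tree_fixture(params: dict, seed: int) -> tuple[str, RunConfig]:
    rng = np.random.default_rng(seed)
    n_tips = int(params.get("n", 6))
    length = int(params.get("length", 200))
    with_indels = bool(params.get("with_indels", True))
    newick = random_tree_newick(n_tips, rng)
    half = length // 2
    left = ["jc"]
    right = ["k80"]
    processes = {
        "jc": {"type": "jc"},
        "k80": {"type": "k80", "kappa": 2.0},
    }
    if with_indels:
        left += ["del_plain", "ins"]
        right += ["del_fast"]
        processes.update(
            {
                "del_plain": {
                    "type": "deletion",
                    "rate": 0.02,
                    "mode": "plain_field",
                    "length": {"kind": "geometric", "p": 0.5},
                },
                "del_fast": {
                    "type": "deletion",
                    "rate": 0.02,
                    "mode": "fast_field",
                    "length": {"kind": "user_table", "table": {1: 0.6, 2: 0.3, 3: 0.1}},
                },
                "ins": {
                    "type": "insertion",
                    "rate": 0.02,
                    "length": {"kind": "geometric", "p": 0.7},
                    "template": {
                        "model": "jc",
                        "extra_processes": ["del_plain", "ins"],
                        "deletion_tolerance": 0.6,
                        "insertion_tolerance": 1.0,
                        "partition": "left",
                    },
                },
            }
        )
    config = RunConfig.from_dict(
        {
            "seed": seed,
            "tree": {"newick": newick},
            "root": {"length": length},
            "partitions": [
                {
                    "name": "left",
                    "range": [0, half],
                    "processes": left,
                    "rates": {"kind": "discrete_gamma", "alpha": 1.0, "n_categories": 4},
                    "deletion_tolerance": 0.6,
                },
                {
                    "name": "right",
                    "range": [half, length],
                    "processes": right,
                    "deletion_tolerance": 0.3,
                },
            ],
            "processes": processes,
        }
    )
    return newick, config


_MAMMAL_TREE = (
    "((((human:0.06,chimp:0.06):0.04,macaque:0.10):0.05,"
    "(mouse:0.18,rat:0.18):0.12):0.03,(cow:0.15,(dog:0.12,cat:0.12):0.04):0.05,"
    "opossum:0.30);"
)


def _coding_region_fixture(params: dict, seed: int) -> tuple[str, RunConfig]:
    n_exon = int(params.get("exon_codons", 10))
    n_flank = int(params.get("flank", 30))
    n_intron = int(params.get("intron", 20))
    newick = params.get("newick", _MAMMAL_TREE)
    # site layout (codon sites count as one site each)
    a = 0
    layout = []
    for name, n in [
        ("flank5", n_flank),
        ("start", 1),
        ("exon1", n_exon),
        ("donor", 2),
        ("intron", n_intron),
        ("acceptor", 2),
        ("exon2", n_exon),
        ("stop", 1),
        ("flank3", n_flank),
    ]:
        layout.append((name, a, a + n))
        a += n
    length = a
    spans = {name: [s, e] for name, s, e in layout}
    config = RunConfig.from_dict(
        {
            "seed": seed,
            "tree": {"newick": newick},
            "root": {"length": length},
            # coding sites and motifs carry the deletion process with
            # tolerance 0 (never deleted, even by spans starting in the
            # flanks) and initiation multiplier 0 (no proposals start there)
            "partitions": [
                {"name": "flank5", "range": spans["flank5"],
                 "processes": ["k80nc", "del_nc", "ins_nc"], "deletion_tolerance": 0.8},
                {"name": "start", "range": spans["start"], "processes": ["del_nc"],
                 "states": ["ATG"], "deletion_tolerance": 0.0, "indel_rate_multiplier": 0.0},
                {"name": "exon1", "range": spans["exon1"], "processes": ["gy94", "del_nc"],
                 "deletion_tolerance": 0.0, "indel_rate_multiplier": 0.0},
                {"name": "donor", "range": spans["donor"], "processes": ["del_nc"],
                 "states": "GT", "deletion_tolerance": 0.0, "indel_rate_multiplier": 0.0},
                {"name": "intron", "range": spans["intron"],
                 "processes": ["k80nc", "del_nc", "ins_nc"], "deletion_tolerance": 0.8},
                {"name": "acceptor", "range": spans["acceptor"], "processes": ["del_nc"],
                 "states": "AG", "deletion_tolerance": 0.0, "indel_rate_multiplier": 0.0},
                {"name": "exon2", "range": spans["exon2"], "processes": ["gy94", "del_nc"],
                 "deletion_tolerance": 0.0, "indel_rate_multiplier": 0.0},
                {"name": "stop", "range": spans["stop"], "processes": ["stopproc", "del_nc"],
                 "states": ["TAA"], "deletion_tolerance": 0.0, "indel_rate_multiplier": 0.0},
                {"name": "flank3", "range": spans["flank3"],
                 "processes": ["k80nc", "del_nc", "ins_nc"], "deletion_tolerance": 0.8},
            ],
            "processes": {
                "k80nc": {"type": "k80", "kappa": 2.0},
                "gy94": {"type": "gy94", "kappa": 2.0, "omega": 0.2},
                # the three functionally equivalent stop codons interchange
                # by their own process (states are codon triplets)
                "stopproc": {
                    "type": "general",
                    "alphabet": ["TAA", "TAG", "TGA"],
                    "rates": [[0, 1, 1], [1, 0, 1], [1, 1, 0]],
                    "normalize": True,
                },
                "del_nc": {
                    "type": "deletion",
                    "rate": 0.02,
                    "mode": "fast_field",
                    "length": {"kind": "geometric", "p": 0.5},
                },
                "ins_nc": {
                    "type": "insertion",
                    "rate": 0.02,
                    "length": {"kind": "geometric", "p": 0.5},
                    "template": {
                        "model": "k80nc",
                        "extra_processes": ["del_nc", "ins_nc"],
                        "deletion_tolerance": 0.8,
                        "partition": "flank5",
                    },
                },
            },
        }
    )
    return newick, config


def _domain_protein_fixture(params: dict, seed: int) -> tuple[str, RunConfig]:
    rng = np.random.default_rng(seed)
    n_domain = int(params.get("domain", 60))
    n_linker = int(params.get("linker", 40))
    newick = params.get("newick", random_tree_newick(int(params.get("n", 5)), rng))
    config = RunConfig.from_dict(
        {
            "seed": seed,
            "tree": {"newick": newick},
            "root": {"length": n_domain + n_linker},
            "partitions": [
                {
                    "name": "domain",
                    "range": [0, n_domain],
                    "processes": ["wag", "del"],
                    "rates": {"kind": "discrete_gamma", "alpha": 0.8, "n_categories": 4},
                    "deletion_tolerance": 0.05,
                },
                {
                    "name": "linker",
                    "range": [n_domain, n_domain + n_linker],
                    "processes": ["lg", "del", "ins"],
                    "rates": {"kind": "continuous_gamma", "alpha": 1.5},
                    "deletion_tolerance": 0.9,
                },
            ],
            "processes": {
                "wag": {"type": "empirical_aa", "source": "WAG"},
                "lg": {"type": "empirical_aa", "source": "LG"},
                "del": {
                    "type": "deletion",
                    "rate": 0.03,
                    "mode": "fast_field",
                    "length": {"kind": "geometric", "p": 0.6},
                },
                "ins": {
                    "type": "insertion",
                    "rate": 0.03,
                    "length": {"kind": "geometric", "p": 0.6},
                    "template": {
                        "model": "lg",
                        "extra_processes": ["del", "ins"],
                        "deletion_tolerance": 0.9,
                        "partition": "linker",
                    },
                },
            },
        }
    )
    return newick, config


_KINDS = {
    "random_tree": _random_tree_fixture,
    "coding_region": _coding_region_fixture,
    "domain_protein": _domain_protein_fixture,
}


def generate_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Build a deterministic (newick, RunConfig) pair for one fixture kind."""
    if kind not in _KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {sorted(_KINDS)}")
    return _KINDS[kind](params or {}, seed)
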