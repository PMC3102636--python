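"""Tree recursion, node hooks and true-alignment assembly.

Evolution proceeds by pre-order traversal of a rooted tree with branch
lengths in expected substitutions per site.  At each node, hooks targeting
that node run first (property-only mutators: rate multipliers, tolerances —
heterotachy and other time-non-homogeneous scenarios), then every child
branch evolves an independent copy of the node's sequence.

Homology is tracked by threading unique site identities (uids) through the
simulation: the root's uids seed the column structure, each insertion
splices fresh columns in, and deletions simply leave a lineage without
residues in the affected columns.  New columns land immediately before the
initiating site's right neighbour (at the end if there is none), which keeps
every row's residues in sequence order; simultaneous non-homologous
insertions at the same flank on different branches get distinct columns,
ordered by traversal.

Each child branch evolves under a generator seeded from (global seed, child
label), so adding outputs or reordering unrelated work never perturbs the
realized trajectories.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import dendropy
import numpy as np

from .engine import BranchResult, DeleteOp, Event, InsertOp, evolve_branch
from .sequence import EvolvingSequence

__all__ = [
    "Phylogeny",
    "PhyloNode",
    "NodeHook",
    "TrueAlignment",
    "SimulationResult",
    "TreeError",
    "HookError",
    "read_newick",
    "simulate",
    "build_true_alignment",
    "replay_columns",
]

GAP = "-"


class TreeError(ValueError):
    pass


class HookError(RuntimeError):
    pass


@dataclass
class PhyloNode:
    label: str
    length: float  # branch length to parent; 0 for the root
    children: list["PhyloNode"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


@dataclass
class Phylogeny:
    root: PhyloNode

    def preorder(self) -> Iterable[PhyloNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[PhyloNode]:
        return [n for n in self.preorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def find(self, label: str) -> PhyloNode | None:
        for n in self.preorder():
            if n.label == label:
                return n
        return None


def read_newick(text: str) -> Phylogeny:
    """Parse a rooted Newick tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"cannot parse Newick: {exc}") from exc
    counter = [0]
    seen: set[str] = set()

    def convert(dnode, is_root: bool = False) -> PhyloNode:
        label = None
        if dnode.taxon is not None and dnode.taxon.label:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        if label is None:
            counter[0] += 1
            label = f"node{counter[0]}"
        if label in seen:
            raise TreeError(f"duplicate node label {label!r}")
        seen.add(label)
        length = dnode.edge.length
        if length is None:
            if not is_root:
                raise TreeError(f"missing branch length on {label!r}")
            length = 0.0
        if length < 0:
            raise TreeError(f"negative branch length on {label!r}")
        node = PhyloNode(label=label, length=float(length))
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    root = convert(tree.seed_node, is_root=True)
    if not root.children:
        raise TreeError("tree has no branches")
    return Phylogeny(root)


@dataclass
class NodeHook:
    """Property-only mutator run at a node before its child branches evolve.

    ``target`` is a node label or a predicate on labels; ``action`` receives
    the node's EvolvingSequence and may only change per-(site, process)
    parameters — never states or length (enforced).
    """

    target: str | Callable[[str], bool]
    action: Callable[[EvolvingSequence], None]
    name: str = ""

    def matches(self, label: str) -> bool:
        if callable(self.target):
            return bool(self.target(label))
        return self.target == label


@dataclass
class SimulationResult:
    tree: Phylogeny
    node_sequences: dict  # label -> EvolvingSequence
    branch_results: dict  # child label -> BranchResult (traversal order)
    columns: list  # homology column uids, in alignment order
    column_partitions: dict  # uid -> partition label or None
    root_uids: list

    def events(self) -> list[tuple[str, Event]]:
        out = []
        for label, br in self.branch_results.items():
            out.extend((label, e) for e in br.events)
        return out


def _branch_rng(seed: int, label: str) -> np.random.Generator:
    sub = zlib.crc32(label.encode("utf-8"))
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, sub])))


def _apply_ops_to_columns(columns: list, ops: Sequence, partitions: dict) -> None:
    for op in ops:
        if isinstance(op, InsertOp):
            if op.before_uid is None:
                pos = len(columns)
            else:
                pos = columns.index(op.before_uid)
            columns[pos:pos] = list(op.new_uids)
            for uid, part in zip(op.new_uids, op.partitions):
                partitions[uid] = part
        elif not isinstance(op, DeleteOp):
            raise TypeError(f"unknown alignment op {op!r}")


def simulate(
    tree: Phylogeny,
    root: EvolvingSequence,
    hooks: Sequence[NodeHook] = (),
    seed: int = 0,
    audit_interval: int = 1000,
) -> SimulationResult:
    """Evolve ``root`` over ``tree``; returns per-node sequences, per-branch
    event logs and the threaded homology-column structure."""
    columns = [s.uid for s in root.sites]
    partitions = {s.uid: s.partition for s in root.sites}
    node_sequences: dict[str, EvolvingSequence] = {}
    branch_results: dict[str, BranchResult] = {}

    def run_hooks(node: PhyloNode, seq: EvolvingSequence) -> None:
        for hook in hooks:
            if not hook.matches(node.label):
                continue
            before = (len(seq), tuple(s.state for s in seq.sites))
            hook.action(seq)
            after = (len(seq), tuple(s.state for s in seq.sites))
            if before != after:
                name = hook.name or getattr(hook.action, "__name__", repr(hook.action))
                raise HookError(
                    f"hook {name!r} at node {node.label!r} changed sequence "
                    "states or length; hooks may only alter site properties"
                )

    def visit(node: PhyloNode, seq: EvolvingSequence) -> None:
        run_hooks(node, seq)
        node_sequences[node.label] = seq
        for child in node.children:
            child_seq = seq.copy()
            rng = _branch_rng(seed, child.label)
            res = evolve_branch(
                child_seq, child.length, rng, branch_id=child.label,
                audit_interval=audit_interval,
            )
            branch_results[child.label] = res
            _apply_ops_to_columns(columns, res.alignment_ops, partitions)
            visit(child, res.sequence)

    visit(tree.root, root)
    return SimulationResult(
        tree=tree,
        node_sequences=node_sequences,
        branch_results=branch_results,
        columns=columns,
        column_partitions=partitions,
        root_uids=[s.uid for s in root.sites],
    )


def replay_columns(result: SimulationResult) -> list:
    """Rebuild the homology columns purely from the logged per-branch
    alignment ops (traversal order); must equal the online structure."""
    columns = list(result.root_uids)
    partitions: dict = {}
    for br in result.branch_results.values():
        _apply_ops_to_columns(columns, br.alignment_ops, partitions)
    return columns


@dataclass
class TrueAlignment:
    """The gapped homology matrix implied by the realized indel history."""

    labels: list  # row order
    rows: dict  # label -> list of tokens / GAP
    columns: list  # column uids kept
    annotations: list  # per-column partition label (None -> ".")

    @property
    def width(self) -> int:
        return len(self.columns)

    def row_text(self, label: str) -> str:
        return "".join(self.rows[label])

    def degapped(self, label: str) -> str:
        return "".join(t for t in self.rows[label] if set(t) != {GAP})

    def track_rows(self) -> list[tuple[int, str]]:
        """(1-based column index, partition label) pairs for the TSV track."""
        return [(i + 1, a if a is not None else ".") for i, a in enumerate(self.annotations)]


def build_true_alignment(
    result: SimulationResult,
    include_internal: bool = False,
    drop_all_gap_columns: bool = True,
) -> TrueAlignment:
    """Project every requested node's sequence onto the homology columns.

    Gap characters mark columns whose residue is absent from a lineage.
    With ``drop_all_gap_columns`` (default), columns with no residue in any
    included row are removed — e.g. an insertion on an internal branch later
    deleted in every surviving lineage leaves no evidence at the tips.
    """
    labels = result.tree.tip_labels()
    if include_internal:
        labels = labels + [
            n.label for n in result.tree.preorder() if not n.is_tip
        ]
    maps = {}
    for label in labels:
        seq = result.node_sequences[label]
        maps[label] = {s.uid: s.state for s in seq.sites}
    columns = list(result.columns)
    if drop_all_gap_columns:
        columns = [uid for uid in columns if any(uid in m for m in maps.values())]
    # gap marks are padded to the column's residue width so codon columns
    # ('AAG' vs '---') stay flush in the gapped FASTA
    widths = {
        uid: max((len(m[uid]) for m in maps.values() if uid in m), default=1)
        for uid in columns
    }
    rows = {
        label: [maps[label].get(uid, GAP * widths[uid]) for uid in columns]
        for label in labels
    }
    annotations = [result.column_partitions.get(uid) for uid in columns]
    return TrueAlignment(labels=labels, rows=rows, columns=columns, annotations=annotations)
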