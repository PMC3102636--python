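"""Run configuration, file I/O and the end-to-end driver.

A run is described by a YAML document::

    seed: 1
    tree: {newick: "(A:0.2,B:0.2);"}       # or {file: tree.nwk}
    root: {length: 120}                    # optionally tokens: "ACGT..."
    partitions:
      - name: left
        range: [0, 60]                     # half-open, in sites
        processes: [jc, del1]
        rates: {kind: discrete_gamma, alpha: 0.5, n_categories: 4}
        deletion_tolerance: 0.5            # scalar or per-site list
      - name: motif
        range: [60, 63]
        processes: []                      # no processes: a fixed motif
        states: "ATG"
    processes:
      jc:   {type: k80, kappa: 1.0}
      del1: {type: deletion, rate: 0.1, mode: fast_field,
             length: {kind: geometric, p: 0.5}}
    hooks:
      - {node: A, action: scale_rate_multipliers, factor: 0.5}

One global seed governs everything; the root state and every branch evolve
under substreams derived from (seed, label), so runs are reproducible
byte-for-byte.
"""

from __future__ import annotations

import importlib
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .indels import DeletionProcess, InsertionProcess, LengthDistribution, SiteTemplate
from .models import (
    SiteRateModel,
    SubstitutionModel,
    Alphabet,
    build_general_model,
    build_gtr,
    build_gy94,
    build_k80,
    build_unrest,
    draw_site_rates,
    load_empirical_aa,
)
from .phylogeny import (
    NodeHook,
    build_true_alignment,
    read_newick,
    simulate,
)
from .sequence import EvolvingSequence, Site, attach_process, set_site_property

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "write_config",
    "build_processes",
    "build_root_sequence",
    "build_hooks",
    "run",
    "substream",
]


class ConfigError(ValueError):
    pass


def substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic generator for one labelled component of a run."""
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([seed, zlib.crc32(label.encode())]))
    )


@dataclass
class RunConfig:
    """Validated, plain-data run description (round-trips through YAML)."""

    seed: int
    tree: dict
    root: dict
    partitions: list
    processes: dict
    hooks: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - {"seed", "tree", "root", "partitions", "processes", "hooks"}
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        cfg = cls(
            seed=data.get("seed", 0),
            tree=data.get("tree") or {},
            root=data.get("root") or {},
            partitions=list(data.get("partitions") or []),
            processes=dict(data.get("processes") or {}),
            hooks=list(data.get("hooks") or []),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError("seed: must be a nonnegative integer")
        if not ("newick" in self.tree or "file" in self.tree):
            raise ConfigError("tree: needs 'newick' or 'file'")
        length = self.root.get("length")
        if length is None and "tokens" in self.root:
            length = len(self.root["tokens"])
        if length is None:
            raise ConfigError("root: needs 'length' (or explicit 'tokens')")
        if not isinstance(length, int) or length < 1:
            raise ConfigError("root.length: must be a positive integer")
        for k, part in enumerate(self.partitions):
            where = f"partitions[{k}]"
            rng = part.get("range")
            if (
                not isinstance(rng, (list, tuple))
                or len(rng) != 2
                or not all(isinstance(x, int) for x in rng)
            ):
                raise ConfigError(f"{where}.range: needs [start, stop] integers")
            a, b = rng
            if not (0 <= a <= b <= length):
                raise ConfigError(
                    f"{where}.range: [{a}, {b}) outside root length {length}"
                )
            for name in part.get("processes", []):
                if name not in self.processes:
                    raise ConfigError(
                        f"{where}.processes: undefined process {name!r}"
                    )
            for key in ("deletion_tolerance", "insertion_tolerance"):
                v = part.get(key)
                if v is None:
                    continue
                vals = v if isinstance(v, (list, tuple)) else [v]
                if any(not 0.0 <= x <= 1.0 for x in vals):
                    raise ConfigError(f"{where}.{key}: values must lie in [0, 1]")
        for h, hook in enumerate(self.hooks):
            if "node" not in hook or "action" not in hook:
                raise ConfigError(f"hooks[{h}]: needs 'node' and 'action'")


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: not a mapping")
    return RunConfig.from_dict(data)


def write_config(config: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# --------------------------------------------------------------------------
# Building simulation objects from a config
# --------------------------------------------------------------------------


def _resolve_dotted(name: str):
    mod, _, attr = name.partition(":")
    if not attr:
        raise ConfigError(f"dotted reference {name!r} must look like 'pkg.mod:attr'")
    return getattr(importlib.import_module(mod), attr)


def _length_dist(spec: dict, where: str) -> LengthDistribution:
    if not isinstance(spec, dict) or "kind" not in spec:
        raise ConfigError(f"{where}: length distribution needs a 'kind'")
    params = {k: v for k, v in spec.items() if k != "kind"}
    if spec["kind"] == "callable" and isinstance(params.get("fn"), str):
        params["fn"] = _resolve_dotted(params["fn"])
    if spec["kind"] == "user_table":
        params["table"] = {int(k): float(v) for k, v in params["table"].items()}
    try:
        return LengthDistribution(spec["kind"], params)
    except Exception as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def _rate_model(spec: dict | None, where: str) -> SiteRateModel | None:
    if spec is None:
        return None
    try:
        return SiteRateModel(**spec)
    except Exception as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def build_processes(config: RunConfig) -> dict:
    """Instantiate every named process; insertion templates may reference
    other processes by name, so they are built last."""
    out: dict = {}
    deferred = []
    for name, spec in config.processes.items():
        where = f"processes.{name}"
        t = spec.get("type")
        if t in ("k80", "jc"):
            obj = build_k80(1.0 if t == "jc" else spec["kappa"])
        elif t == "gtr":
            obj = build_gtr(spec["exchangeabilities"], spec["base_freqs"])
        elif t == "unrest":
            obj = build_unrest(spec["rates"])
        elif t == "gy94":
            obj = build_gy94(
                spec["kappa"], spec["omega"], spec.get("codon_freqs", "equal")
            )
        elif t == "empirical_aa":
            obj = load_empirical_aa(spec["source"])
        elif t == "general":
            obj = build_general_model(
                Alphabet(tuple(spec["alphabet"])),
                np.asarray(spec["rates"], dtype=float),
                None if spec.get("pi") is None else np.asarray(spec["pi"], dtype=float),
                normalize=spec.get("normalize", True),
            )
        elif t == "deletion":
            obj = DeletionProcess(
                rate=float(spec["rate"]),
                lengths=_length_dist(spec.get("length", {"kind": "fixed", "value": 1}), where),
                mode=spec.get("mode", "plain_field"),
                label=name,
            )
        elif t == "insertion":
            deferred.append((name, spec))
            continue
        else:
            raise ConfigError(f"{where}.type: unknown process type {t!r}")
        if isinstance(obj, SubstitutionModel):
            obj.label = name
        out[name] = obj
    for name, spec in deferred:
        where = f"processes.{name}"
        tspec = spec.get("template") or {}
        model = None
        if tspec.get("model") is not None:
            ref = tspec["model"]
            if ref not in out:
                raise ConfigError(f"{where}.template.model: undefined process {ref!r}")
            model = out[ref]
        extras = []
        for ref in tspec.get("extra_processes", []):
            if ref not in out and ref != name:
                raise ConfigError(f"{where}.template.extra_processes: undefined {ref!r}")
            extras.append(ref)
        gen = spec.get("generator")
        if gen in (None, "default"):
            generator = None
        elif gen == "duplication":
            generator = None  # bound below with the process itself
        else:
            generator = _resolve_dotted(gen)
        proc = InsertionProcess(
            rate=float(spec["rate"]),
            lengths=_length_dist(spec.get("length", {"kind": "fixed", "value": 1}), where),
            generator=generator,
            template=SiteTemplate(
                model=model,
                extra_processes=(),  # filled after all procs exist
                rate_model=_rate_model(tspec.get("rates"), f"{where}.template.rates"),
                deletion_tolerance=float(tspec.get("deletion_tolerance", 1.0)),
                insertion_tolerance=float(tspec.get("insertion_tolerance", 1.0)),
                partition=tspec.get("partition"),
            ),
            label=name,
        )
        out[name] = proc
        if gen == "duplication":
            from .indels import duplication_generator as _dup

            proc.generator = lambda length, ctx, rng, _d=_dup, _p=proc: _d(_p, length, ctx, rng)
        proc.template = SiteTemplate(
            model=proc.template.model,
            extra_processes=tuple(out[r] if r != name else proc for r in extras),
            rate_model=proc.template.rate_model,
            deletion_tolerance=proc.template.deletion_tolerance,
            insertion_tolerance=proc.template.insertion_tolerance,
            partition=proc.template.partition,
        )
    return out


def _partition_tokens(part: dict, n: int, subst, root_tokens, a: int, rng) -> list:
    states = part.get("states")
    if states is not None:
        tokens = list(states)
        if len(tokens) != n:
            raise ConfigError(
                f"partition {part.get('name')!r}: {len(tokens)} states for {n} sites"
            )
        return tokens
    if root_tokens is not None:
        return list(root_tokens[a:a + n])
    if subst is not None:
        idx = rng.choice(len(subst.alphabet), size=n, p=subst.pi)
        return [subst.alphabet.symbols[j] for j in idx]
    raise ConfigError(
        f"partition {part.get('name')!r}: no states, no root tokens and no "
        "substitution process to draw from"
    )


def build_root_sequence(config: RunConfig, processes: dict) -> EvolvingSequence:
    """Assemble the root: per-partition states, bindings and site parameters."""
    rng = substream(config.seed, "root")
    length = config.root.get("length")
    root_tokens = config.root.get("tokens")
    if length is None:
        length = len(root_tokens)
    sites: list = [None] * length
    plans = []
    for part in config.partitions:
        a, b = part["range"]
        procs = [processes[nm] for nm in part.get("processes", [])]
        subst = next((p for p in procs if isinstance(p, SubstitutionModel)), None)
        tokens = _partition_tokens(part, b - a, subst, root_tokens, a, rng)
        for i, tok in zip(range(a, b), tokens):
            if sites[i] is not None:
                raise ConfigError(
                    f"partition {part.get('name')!r}: site {i} covered twice"
                )
            sites[i] = Site(tok, [], partition=part.get("name"))
        mults = None
        rm = _rate_model(part.get("rates"), f"partition {part.get('name')!r}.rates")
        if rm is not None and b > a:
            mults = draw_site_rates(rm, b - a, rng)
        plans.append((part, procs, mults))
    for i, s in enumerate(sites):
        if s is None:
            if root_tokens is None:
                raise ConfigError(
                    f"site {i} is covered by no partition and root has no tokens"
                )
            sites[i] = Site(root_tokens[i], [])
    seq = EvolvingSequence(sites)
    for part, procs, mults in plans:
        a, b = part["range"]
        for proc in procs:
            params: dict = {}
            if isinstance(proc, SubstitutionModel):
                if mults is not None:
                    params["rate_multiplier"] = mults
            else:
                if part.get("indel_rate_multiplier") is not None:
                    params["rate_multiplier"] = part["indel_rate_multiplier"]
                if part.get("deletion_tolerance") is not None:
                    params["deletion_tolerance"] = part["deletion_tolerance"]
                if part.get("insertion_tolerance") is not None:
                    params["insertion_tolerance"] = part["insertion_tolerance"]
            attach_process(seq, (a, b), proc, params)
    return seq


# -- builtin hook actions ---------------------------------------------------


def _matching_bindings(seq, proc_filter):
    for i, site in enumerate(seq.sites):
        for b in site.bindings:
            if proc_filter is None or getattr(b.process, "label", None) == proc_filter:
                yield i, b


def scale_rate_multipliers(factor: float, process: str | None = None):
    def action(seq):
        for i, b in _matching_bindings(seq, process):
            set_site_property(seq, i, b.process, "rate_multiplier", b.rate_multiplier * factor)

    action.__name__ = f"scale_rate_multipliers({factor})"
    return action


def set_binding_property(key: str, value: float, process: str | None = None):
    def action(seq):
        for i, b in _matching_bindings(seq, process):
            set_site_property(seq, i, b.process, key, value)

    action.__name__ = f"set_{key}({value})"
    return action


def build_hooks(config: RunConfig) -> list[NodeHook]:
    hooks = []
    for k, spec in enumerate(config.hooks):
        action_name = spec["action"]
        proc = spec.get("process")
        if action_name == "scale_rate_multipliers":
            action = scale_rate_multipliers(float(spec["factor"]), proc)
        elif action_name in ("set_rate_multiplier", "set_deletion_tolerance", "set_insertion_tolerance"):
            action = set_binding_property(action_name.removeprefix("set_"), float(spec["value"]), proc)
        elif ":" in action_name:
            action = _resolve_dotted(action_name)
        else:
            raise ConfigError(f"hooks[{k}].action: unknown action {action_name!r}")
        hooks.append(NodeHook(target=spec["node"], action=action, name=action_name))
    return hooks


# --------------------------------------------------------------------------
# The driver
# --------------------------------------------------------------------------


def _fasta_records(names, texts):
    return [SeqRecord(Seq(t), id=n, description="") for n, t in zip(names, texts)]


def run(
    config: RunConfig,
    out_prefix: str,
    include_internal: bool = False,
    keep_all_gap_columns: bool = False,
) -> dict:
    """Execute a configured simulation and write the output files.

    Writes ``<prefix>_tips.fasta``, ``<prefix>_alignment.fasta``,
    ``<prefix>_tracks.tsv``, ``<prefix>_events.tsv`` and
    ``<prefix>_manifest.yaml``; returns the paths plus the in-memory
    :class:`SimulationResult` under ``"result"``.
    """
    import pandas as pd

    if "newick" in config.tree:
        newick = config.tree["newick"]
    else:
        with open(config.tree["file"]) as fh:
            newick = fh.read()
    tree = read_newick(newick)
    processes = build_processes(config)
    root = build_root_sequence(config, processes)
    hooks = build_hooks(config)
    result = simulate(tree, root, hooks, seed=config.seed)
    aln = build_true_alignment(
        result,
        include_internal=include_internal,
        drop_all_gap_columns=not keep_all_gap_columns,
    )

    paths = {
        "tips": f"{out_prefix}_tips.fasta",
        "alignment": f"{out_prefix}_alignment.fasta",
        "tracks": f"{out_prefix}_tracks.tsv",
        "events": f"{out_prefix}_events.tsv",
        "manifest": f"{out_prefix}_manifest.yaml",
    }
    tip_labels = result.tree.tip_labels()
    SeqIO.write(
        _fasta_records(tip_labels, [result.node_sequences[l].text() for l in tip_labels]),
        paths["tips"],
        "fasta",
    )
    SeqIO.write(
        _fasta_records(aln.labels, [aln.row_text(l) for l in aln.labels]),
        paths["alignment"],
        "fasta",
    )
    pd.DataFrame(aln.track_rows(), columns=["column", "partition"]).to_csv(
        paths["tracks"], sep="\t", index=False
    )
    rows = [
        {
            "branch": branch,
            "time": f"{ev.time:.9f}",
            "kind": ev.kind,
            "site": ev.site + 1,
            "process": ev.process_label,
            "detail": ev.detail(),
            "accepted": int(ev.accepted),
        }
        for branch, ev in result.events()
    ]
    pd.DataFrame(
        rows, columns=["branch", "time", "kind", "site", "process", "detail", "accepted"]
    ).to_csv(paths["events"], sep="\t", index=False)
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(
            {
                "package": "evosim",
                "version": __version__,
                "seed": config.seed,
                "include_internal": include_internal,
                "keep_all_gap_columns": keep_all_gap_columns,
                "config": config.to_dict(),
            },
            fh,
            sort_keys=False,
        )
    paths["result"] = result
    paths["alignment_obj"] = aln
    return paths
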