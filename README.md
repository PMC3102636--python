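# evosim

Forward-time Monte Carlo simulation of biological sequence evolution along a
rooted phylogeny, for people who benchmark multiple-alignment tools,
phylogenetic inference methods and annotation pipelines against a known
ground truth. Substitutions, insertions and deletions act as concurrent
Poisson processes integrated exactly by the Gillespie algorithm, and the
realized indel history is threaded through the tree so every run yields the
**true multiple alignment** alongside the tip sequences.

## The model

Sequences evolve under continuous-time Markov substitution processes with
arbitrary rate matrices over arbitrary alphabets — built-ins cover K80, GTR,
the non-reversible UNREST, empirical amino-acid models (WAG, JTT and LG are
packaged; any lower-triangle exchangeability file loads) and the GY94 codon
model with transition/transversion ratio κ and nonsynonymous/synonymous
ratio ω. Every matrix is normalized so one unit of branch length equals one
expected substitution per site at equilibrium; indel rates are specified
relative to that time unit. Among-site rate variation (+Γ discrete or
continuous, +I+Γ, or any user rule) applies per site to substitution *and*
indel initiation.

Along each branch of length *L* the engine repeats two steps: draw the
waiting time to the next event from an exponential with rate equal to the
sum of all event rates (stopping when it overruns *L*), then pick one event
with probability proportional to its rate and apply it.

Selective constraints on indels use the **field model**: each site *i*
carries a deletion tolerance *d<sub>i</sub>* ∈ [0, 1], and a proposed
deletion spanning sites ℐ is accepted with probability
∏<sub>*i*∈ℐ</sub> *d<sub>i</sub>* — sites with *d<sub>i</sub>* = 1 are
deleted at the background rate, sites with *d<sub>i</sub>* = 0 never. This
captures undeletable motifs and deletion hotspots with one parameter per
site, and because deletions are free to cross partition boundaries there is
no "edge effect" at partition joins. When a sequence is strongly
intolerant, the **fast field** mode rescales proposals by the maximum
tolerance *D* and compensates the acceptance to ∏*d<sub>i</sub>*/*D*: the
realized deletion rate per span is identical, but almost no proposals are
wasted on rejection. Insertions are gated by the initiating site's
insertion tolerance and built by pluggable generators (equilibrium draws by
default; tandem duplication ships as an example).

Partitions give every site its own processes and parameters; "node hooks"
mutate site properties (rates, tolerances) at internal nodes for
heterotachy and other time-non-homogeneous scenarios.

## Worked example

Simulate a miniature genomic region — noncoding flanks and an intron under
K80 with field-model indels, two 10-codon exons under GY94(κ=2, ω=0.2), a
fixed start codon and splice sites, and a stop codon wandering among
TAA/TAG/TGA under its own three-state process — along a nine-mammal tree:

```sh
evosim fixture --kind coding_region --seed 1 --out demo
evosim run --config demo/coding_region.yaml --out demo/region --seed 1
evosim diagnose demo/region
```

which prints (abridged):

```
applied events by kind:
  deletion: 1
  insertion: 1
  substitution: 177
codon substitutions: synonymous=28 nonsynonymous=11
pairwise p-distances (shared ungapped columns):
  human vs chimp: p=0.1000  K80 d=0.1080 kappa=3.182
  human vs mouse: p=0.2867  K80 d=0.3639 kappa=1.975
  human vs opossum: p=0.2467  K80 d=0.3033 kappa=2.719
```

177 substitutions were applied across the tree, the exons' ω = 0.2 shows up
as a strong synonymous excess (28 vs 11 despite ~3× more nonsynonymous
targets), and the K80 distances grow with divergence from human while κ̂
scatters around the simulated transition/transversion ratio of 2. The run
writes `region_tips.fasta` (ungapped tip sequences), `region_alignment.fasta`
(the true alignment, gap `-`, codon columns padded to `---`),
`region_tracks.tsv` (per-column partition annotation: flank5, start, exon1,
…), `region_events.tsv` (branch, time, kind, 1-based site, detail,
accepted flag) and a manifest echoing the seed and config.

The same machinery is available as a library:

```python
import numpy as np, evosim as ev

m = ev.build_k80(2.0)
root = ev.make_root_sequence(50_000, m, np.random.default_rng(1))
tree = ev.read_newick("(A:0.25,B:0.25);")
res = ev.simulate(tree, root, seed=2)
d, k = ev.k80_estimates_from_pair(res.node_sequences["A"].text(),
                                  res.node_sequences["B"].text())
# d ≈ 0.5, k ≈ 2.0
```

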