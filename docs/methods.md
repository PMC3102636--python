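# Methods

## Model and algorithm

A sequence is an ordered list of sites. Each site holds a state token and a
list of *process bindings*; a binding attaches one process — a substitution
model, an insertion process or a deletion process — together with the
site- and process-specific parameters: a nonnegative rate multiplier
(default 1), a deletion tolerance and an insertion tolerance (defaults 1,
i.e. neutral). Sites with no substitution binding never change state; this
is how fixed motifs (start codons, splice sites) are represented, and indel
processes may still act on them. Sites are 0-based in the API and 1-based
in every log and annotation track.

Evolution along a branch is exact Gillespie simulation. The total event
rate is the sum over sites and bindings of

- substitution: multiplier × (−Q[s,s]), the model's leave rate from the
  current state s;
- insertion: multiplier × insertion initiation rate;
- deletion: multiplier × deletion proposal rate (× D in fast-field mode,
  below).

Waiting times are exponential at the total rate; the branch ends when the
next waiting time would overrun the branch length. Event selection is
hierarchical — site ∝ cached site rate, binding within the site ∝ its
contribution, then the concrete change (substitution target ∝ the Q row's
off-diagonals; indel length from the process's length distribution) — which
yields exactly the flat per-event law rate/total. The pseudo-random draw
order is frozen (time, site, binding, within-binding target, acceptance
uniform), so a fixed seed reproduces a trajectory exactly.

Substitution matrices are normalized at construction so the expected
equilibrium flux Σᵢ πᵢ Σ_{j≠i} Q_{ij} equals 1: branch lengths read as
expected substitutions per site, and indel rates are interpreted relative
to that unit. A `normalize=False` escape hatch exists for special motif
processes (e.g. the three-state stop-codon process) whose rate is meant
relative to the time unit directly. The stationary vector of a general
matrix is solved from the augmented linear system (Qᵀ stacked with the
Σπ = 1 constraint) rather than an eigendecomposition — deterministic and
robust at these alphabet sizes. Irreducibility is checked with a
strongly-connected-components pass and errors name the unreachable states.
GY94 with ω = 0 is deliberately exempt: forbidding all nonsynonymous moves
makes the chain reducible into synonymous classes, but the supplied codon
frequencies remain stationary, so the model is assembled with the check
relaxed.

## Indels and the field models

Deletions are proposed per site at a background rate with a length drawn
from one of: fixed, geometric, shifted Poisson, an explicit table, or a
user callable. The proposed span is anchored at the initiating site (its
leftmost position) and extends rightward; spans overrunning the sequence
end are truncated, not rejected — rejection would reintroduce exactly the
kind of edge artifact the field model is meant to remove — and acceptance
then uses only the surviving sites' tolerances (the event records a
`truncated` flag). Acceptance probability is ∏ d_i over the span. A span
site not bound to the deleting process (a deletion reaching across a
partition boundary) contributes the neutral tolerance 1: deletions cross
partitions freely.

The fast-field mode rescales proposals by D, the maximum deletion tolerance
among sites currently bound to the process, and divides the acceptance
product by D exactly once. Dividing each site's tolerance by D instead
would give ∏d_i/Dᵏ for a k-site span and change multi-site dynamics; the
single division keeps the realized per-span rate identical to the plain
mode — (rate·D)·(∏d/D) = rate·∏d — for every span length, making the fast
mode a pure efficiency gain. ∏d_i/D ≤ 1 always holds because every d_i ≤ D.
D is cached and recomputed whenever a bound tolerance changes or sites are
inserted or deleted; correctness is preferred over micro-optimization here.

Rejected proposals consume their Gillespie step (the event fires, then is
rejected and logged). This matches the proposal/acceptance framing and is
what the fast field saves: on an all-d=0.05 sequence the plain mode rejects
~95% of proposals while the fast mode rejects essentially none, with
identical accepted-deletion statistics (verified by χ² in the acceptance
battery).

Insertions are gated by the initiating site's insertion tolerance only; no
interaction rule across the flank is imposed. Insert content comes from a
generator receiving (length, flanking context, rng); the default draws
states from a template substitution model's equilibrium and binds the
template's processes with fresh rate multipliers, and a tandem-duplication
generator is included as the canonical example of a custom insert process.
Insertions are placed immediately right of the initiating site, so nothing
can be inserted before the first site. A sequence deleted down to length 0
has zero total rate and simply coasts to the end of the branch; insertions
cannot restart an empty sequence (no virtual origin site) — a documented
limitation.

## Rate caching and numerical hygiene

Per-site total rates and their sum are cached and updated incrementally by
every mutator. The engine recomputes everything from scratch at branch
start and every 1,000 events and aborts if the cached total deviates beyond
a relative 1e-9 (`RateAuditError`); the same tolerance guards the
site-versus-binding consistency check inside event selection. Discrete
gamma categories are equal-probability categories represented by their
category *mean* (computed from the incomplete-gamma identity), so the
mean-1 normalization is exact rather than approximate as with medians;
whether the historical R implementation used means or medians is not
documented, so comparisons across simulators should fix α and category
count. +I+Γ draws rate 0 with probability p_inv and otherwise gamma with
mean 1/(1−p_inv), keeping the marginal mean at 1.

## Trees, hooks and the true alignment

Trees are rooted Newick with branch lengths (dendropy parser); unlabeled
internal nodes get deterministic labels. Traversal is pre-order; at each
node, hooks targeting it run first and all descendant branches inherit the
change. Hooks are property-only mutators — they may change multipliers and
tolerances but never states or length (enforced by snapshotting); arbitrary
state edits would silently break homology tracking, which is the one
substantive restriction relative to fully general callback hooks.

Each child branch evolves under a generator seeded from (global seed,
crc32(child label)), so adding outputs or extra tips never perturbs an
existing branch's trajectory.

Homology is tracked by threading unique site identities through the
simulation. The root's identities seed the column list; an insertion
splices fresh columns immediately before the initiating site's right
neighbour (at the list end when inserting at the sequence end), which keeps
every row's residues in sequence order and gives simultaneous
non-homologous insertions at the same flank on sibling branches distinct
columns ordered by traversal. Deletions leave columns in place; the lineage
simply has no residue there. Per-branch alignment operations are logged,
and replaying them from the root reproduces the online column structure
exactly (asserted in tests). Alignment rows degap to their node's sequence
by construction; with `drop_all_gap_columns` (default) columns with no
residue in any included row are removed — an insertion on an internal
branch later deleted everywhere leaves no evidence at the tips. Gap marks
are padded to the column's token width so codon columns stay flush
(`---`). Column annotations carry the partition name of the site that
created the column.

## Configuration, seeds and outputs

Runs are described by a YAML config (tree, root, partitions, named
processes, hooks, seed). A single nonnegative integer seed governs
everything; the root state, every branch and every fixture derive
independent substreams from it. Outputs are FASTA (60-column wrapped,
written with Biopython; ungapped tips, gapped alignment), TSV (events,
per-column tracks) and a YAML manifest echoing seed, version and config.
Identical config + seed gives byte-identical outputs.

The fixture module generates the test/demo scenarios: `random_tree`
(random 6-tip topology with uniform branch lengths 0.02–0.25, a 200-site
two-partition nucleotide sequence with +Γ rate variation, plain- and
fast-field deletions and an insertion process — sized so a simulation runs
in well under a second while still exercising every event type),
`coding_region` (a ~166-site genomic miniature: 30-nt flanks and a 20-nt
intron under K80 κ=2 with field indels, two 10-codon GY94 κ=2/ω=0.2
exons, fixed ATG/GT/AG motifs, and a stop codon under a three-state
process; coding sites carry deletion tolerance 0 so flank-initiated spans
can never eat the gene) and `domain_protein` (WAG domain with deletion
tolerance 0.05 vs LG linker at 0.9). These emulate the composition and
constraint structure of real loci but not, e.g., context-dependent
mutation, CpG effects or selection on the substitution process itself —
passing tests demonstrate the simulator's internal correctness, not
realism of any particular parameter set.

## Validation

There is no external ground truth for a simulator, so validation is
parameter recovery against closed forms computed inside the package:
end-state distributions of single-site runs against the matrix exponential
(χ², reversible and non-reversible models), Poisson event budgets,
Kimura's K80 distance and κ estimators (self-consistent to 1e-6 on exact
P, Q; recovering d = 0.5 ± 0.05 and κ = 2 ± 0.2 from 50,000 simulated
sites), exact syn/nonsyn tallies under ω = 0, the ∏d acceptance law at
100,000 proposals, fast≡plain field equivalence over 500 replicates per
mode, and alignment soundness over 50 random indel simulations. Problem
sizes were chosen so each check has sharp statistical power yet the whole
battery completes in well under a minute on one core.

## Known limitations

- No approximate acceleration (tau-leaping); the algorithm is exact only.
- No pairwise interaction terms between neighbouring sites' tolerances;
  that is precisely the specification burden the field model avoids.
- Hooks cannot edit states or length (see above).
- Empty sequences stay empty.
- Unrooted trees and per-branch model switching via Newick comments are
  out of scope; non-homogeneity is expressed through config-declared hooks.
- The events TSV stores site indices valid at event time; after indels they
  are not positions in the final sequence (the alignment ops, not the site
  indices, carry homology).
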