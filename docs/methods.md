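# Methods

## The model

`domrec` jointly infers gene duplication/loss and domain fusion/fission
events for a gene family whose members occur in two architectures: a
composite receptor kinase (**FUSED** — extracellular S domain,
transmembrane segment, intracellular kinase domain) and a kinase-only
cytoplasmic form (**SPLIT**). The motivating system is the S-domain
receptor-like kinase (SRLK) family of land plants, where the composite
SRLKs coexist with split SRLCKs and the question is when the S domain was
recruited onto the kinase.

The pipeline has three layers, each exact and deterministic:

1. **Duplication–loss reconciliation (LCA mapping).** Every gene-tree
   node `v` is mapped to `M(v)`, the most recent common ancestor in the
   species tree of the species of its descendant genes. `v` is a
   duplication when `M(v)` equals a child's mapping, a speciation
   otherwise. On a gene edge `(v, c)` the lineage descends from `M(v)`
   to `M(c)`; every species branch it bypasses along the way carries one
   loss (one extra when `v` is a duplication, since the duplicate copy
   exists above the speciation at `M(v)`). The LCA mapping simultaneously
   minimizes duplications and losses over all valid reconciliations; the
   test suite re-verifies this against exhaustive enumeration of
   reconciliation maps.

2. **Ancestral architecture parsimony.** With the reconciliation fixed,
   leaf architectures are propagated to ancestors by weighted two-state
   parsimony. A SPLIT→FUSED change along an edge is a gene fusion
   (cost `c_fusion`), FUSED→SPLIT a fission (`c_fission`). Every event is
   charged on top of the node's duplication/speciation cost, so an
   event-bearing node costs 2 at the default unit costs. All five costs
   default to 1 to avoid prior bias about relative event frequencies. The
   optimum is found by the Sankoff dynamic program over the two-state
   space (up pass: minimal subtree cost per node per state with
   asymmetric transition costs; down pass: state selection), which is
   exact — equality with the 2^n enumeration minimum is asserted over
   hundreds of random instances with random positive costs.

3. **Dating and accounting.** Dating is categorical: a duplication (or
   the fusion/fission attached to a node) mapped to species node `s` is
   dated to the species branch entering `s`; a mapping to the species
   root dates to a virtual *root stem*. Branch lengths are carried
   through I/O but never used by inference — the event model is
   topology-only. The per-branch ledger tallies gains, losses, fusions
   and fissions per species branch and the number of gene lineages
   crossing each speciation ("ancestor counts"), split by architecture
   class, and verifies the bookkeeping identity

       count(s) = count(parent(s)) + gains(s) − losses(s)

   (class-wise additionally ±fusions/fissions) as an internal audit on
   every ledger it produces. When the family's inferred origin `M(root)`
   sits below the species root, the ledger additionally books one
   implied loss on each branch skipped between the species root and
   `M(root)`; these conditioning losses keep the identity exact but are
   not part of the reconciliation's parsimony `loss_count`.

### Tie-breaking

Two-state parsimony frequently has co-optimal assignments. Ties are
resolved deterministically and configurably: the root prefers SPLIT (the
split component proteins are the ancestral form in this family — the
basal lineages are cytoplasmic kinases, and fusions, not fissions, are
the expected direction), a tied non-root node inherits its parent's
selected state (avoiding spurious boundary changes), and residual ties
resolve to SPLIT. A `fused-root` policy is exposed via configuration and
the command line so the opposite convention is reachable.

## The coarse family tree

The headline analysis does not require sequences. The observed group
structure of the family — 17 basal SPLIT lineages; one clade of 390
FUSED receptor kinases spanning all five species (moss included); one
clade of 79 SPLIT cytoplasmic kinases containing a nested FUSED cherry
of 2 moss genes — is encoded directly as a 488-leaf tree
(`presets.coarse_srlk_family`). Fusion/fission calls depend only on the
leaf-state pattern and topology, and their dates only on the species
composition of the clades, so this structural stand-in reproduces the
event inference exactly: 2 fusions, 0 fissions, the major fusion dated to
the land-plant root stem and the minor one to the moss terminal branch.
Within-clade topology is an arbitrary ladder and species are assigned
cyclically; duplication/loss totals on this stand-in are therefore
artifacts of the arbitrary resolution and are *not* estimates of the real
family's counts — reproducing those requires the real
maximum-likelihood tree, which is upstream of this package.

## The simulator

`simulate.simulate` evolves gene lineages down a dated species tree by a
continuous-time Markov process (Gillespie waiting times): duplication
copies a lineage in place, loss kills it, fusion flips SPLIT→FUSED,
fission flips back; at each speciation every surviving lineage enters
both daughters. The truth log records every event (including losses in
subtrees that later go extinct) with its branch and absolute time, and a
ground-truth branch ledger is built from the realized lineage counts and
audited with the same bookkeeping identity as inferred ledgers. The seed
fully determines the output, and rescaling time (all rates ×k, all
branch lengths ÷k) reproduces the identical event sequence seed-by-seed.

What it emulates: lineage-specific expansion, clade-restricted fused
groups, rare architecture switches. What it does not: sequence
evolution and thus gene-tree estimation error (the inferred tree is the
true pruned tree), gene conversion, transfer, and correlated rates.
Passing recovery tests therefore demonstrates correctness of the
inference given a correct gene tree, not robustness to tree error.

### Study regimes

* **Low-rate regime** (recovery and bookkeeping studies): unit-length
  five-species tree, per-lineage rates `dup 0.03, loss 0.02, fusion
  0.03, fission 0.01` (expected total events per lineage per branch
  0.09), one SPLIT root lineage. One root lineage keeps the duplication
  parsimony bound exact (with k starting lineages the reconciliation
  must posit k−1 root-stem duplications that no event log contains).
* **Planted-event regime**: loss and fission off, a near-certain fusion
  planted on a chosen branch through a locally elevated rate
  (`rate_overrides`); inference recovers exactly one fusion on that
  branch in 100/100 seeds in the tests.
* **Demo preset** (`presets.demo_params`): the five-species
  tree dated in millions of years (moss split 450, lycophyte 420,
  monocot 150, poplar/Arabidopsis 100) with rates chosen so a typical
  draw shows a large fused clade and rare fissions. Demo only.

## Known limitations

* **Per-kind event bounds are not theorems.** Duplication and loss
  counts inferred by LCA parsimony never exceed the truth (proved by the
  embedding argument and observed 0/486 families). Fusion and fission
  counts individually carry no such guarantee: when a true fusion is
  later reversed by a fission, solutions with {2 fusions} and
  {1 fusion + 1 fission} tie at equal cost, and the deterministic
  inherit-parent tie-break picks the two-fusion solution; leaf patterns
  such as a fused leaf on each side of a split leaf can even make a
  single spurious fission strictly optimal. In the low-rate study this
  affects 2 of 486 surviving families (both over-calling fusions by
  one); pooled fusion recall is 0.94.
* **Duplication-loss parsimony is not monotone in the leaf set.** Adding
  a leaf can *reduce* the optimal dup+loss cost by turning a duplication
  node into a speciation (a brute-force-verified counterexample is kept
  as a regression test). Cross-family cost comparisons should therefore
  not be read as nested.
* **Ancestor counts are conditional on the parsimony history.** They
  count lineages crossing each speciation in the *minimum-event*
  history; true counts are under-estimated whenever losses erase
  evidence of earlier lineages.
* **Polytomies are rejected, never resolved implicitly.** A left-
  ladderization utility exists for explicit preprocessing, but inference
  requires strictly binary rooted trees (the event grammar is defined on
  bifurcations). Unrooted inputs are likewise rejected at binding.
* **Genome-size-normalized expansion ratios** are computed from
  user-supplied sizes only; the package bundles no genome-size
  constants, so published ratio values are reproducible exactly when the
  sizes used to produce them are supplied.

## Numerical choices

Costs are floats with exact comparisons on sums of unit-scale values;
ties are detected by equality, which is safe for the rational default
costs and for the enumeration cross-checks. Problem sizes in the tests —
200-instance oracle sweeps with ≤ 12 internal nodes, 500-family
simulation studies — were chosen to exercise every code path at
desk scale; the full acceptance sweep runs in well under a minute.
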