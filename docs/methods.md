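# Methods

## Contact network construction

A structure is reduced to an ordered list of nodes: amino-acid residues plus
one node per retained HETATM group (a nucleotide, phosphomimic, or other
ligand).  A bound peptide chain is ordinary amino-acid nodes.  Hydrogens and
deuteriums are always dropped — the crystallographic inputs this method is
designed for rarely carry them, and including them only when present would
make contact counts incomparable across structures.  Waters and common
crystallographic ions are excluded by default (the exclusion list is a
visible parameter).  Altloc conflicts keep the highest-occupancy conformer,
ties resolved to the alphabetically first altloc code; only the first model
of a multi-model file is read unless asked otherwise.

Contacts are atom pairs closer than r₀ = 3.4 Å, with two conventions fixed
here because the boundary cases are otherwise undefined:

* a distance exactly equal to r₀ is *not* a contact (strict inequality; a
  measure-zero case for real coordinates, but a fixed convention makes the
  arithmetic exactly testable);
* the backbone set is {N, CA, C, O}; OXT is treated as side-chain.

Backbone–backbone pairs of *sequence-adjacent* residues are excluded.
Adjacency means consecutive node index within the same chain — not
consecutive residue numbers — because the exclusion targets covalently
bonded backbone neighbours, and insertion codes or numbering gaps do not
change who is bonded to whom.  Inter-chain pairs are never adjacent, and
intra-node contacts are ignored.  Without this exclusion, perturbations run
almost deterministically along the backbone and pathway identification
degenerates; with it, transmission reflects tertiary packing.

Averaged contacts N_ij = C_ij / C_i (C_i = heavy atoms in residue i) and
probabilities P_ij = 1 − exp(−α·N_ij) follow directly.  α (default 3.0)
amplifies or damps transmission; low values (0.5–3) are preferred because
high α saturates every edge towards 1 and flattens the coupling landscape.
Rows of P are intentionally not normalised to 1 — a residue can transmit to
several neighbours at once, or to none, which is exactly what distinguishes
this percolation process from Markov-propagation models.

## The propagation process

One round is a first-arrival breadth-first percolation: sources start
perturbed; a perturbed node, popped FIFO, gives each still-unvisited
neighbour (ascending node order) one Bernoulli trial with probability P_ij;
successes join the frontier.  Every node is visited at most once per round,
by the first perturbed node to reach it, and only perturbed nodes propagate
further.  The round ends when the perturbed frontier is empty.  Two readings
of the process description were possible; we terminate on frontier
exhaustion rather than "all nodes visited" because the latter is unreachable
in disconnected graphs, and we do not let unperturbed-but-visited nodes
continue the walk because a residue cannot transmit a perturbation that
never reached it.

ACI is the per-node perturbation frequency over n_rounds (default 10⁴)
draws from a single seeded PCG64 stream; source nodes count as perturbed in
every round, so their ACI is exactly 1.  The binomial sampling error at 10⁴
rounds is ≤ 0.005 per node, negligible for ranking; `convergence_report`
quantifies it empirically with sub-seeds derived by `SeedSequence.spawn`.
Fixed seed, fixed node order ⇒ bit-exact reproducibility; this is a tested
contract, including byte-identical CSV/PDB outputs.

For tiny graphs, `exact_aci` enumerates every branch of the ordered
Bernoulli trials under the *same* frontier discipline (the distribution of
outcomes depends on test order in cyclic graphs, so the reference must
replicate the discipline, not generic independent-edge percolation).  It is
exponential in tested edges and guarded by a depth cap; the Monte-Carlo
engine is validated against it on cyclic topologies and against closed-form
edge-probability products on trees.

## Pathways and importance

When both a source and a target site are known, each round in which the
target is perturbed contributes exactly one path: the parent-pointer chain
of the earliest-perturbed target node, read back to its source.  The parent
chain is the perturbation's actual transmission route — the branching
process has no unique walk, so recording anything else would be arbitrary.
Identical node sequences aggregate; a pathway's weight is its frequency
(count / rounds), hence Σ weights = reach frequency ≤ 1, and the reach
frequency agrees with the target's ACI by construction (tested).  Pathway
identity is the exact node sequence, not the node set.

Residue importance folds pathway weights with p_a ← p_a + p_i − p_a·p_i,
which is the order-independent union 1 − Π(1 − p_i) over all pathways
through the residue.  Pathway weight is the only quantity attached to a
pathway, so it serves as p_i.

## Hotspot clustering and evaluation

Residue–residue distance is the minimum inter-atomic distance; neighbours
are pairs within 4.5 Å.  Each non-excluded residue points to its
strictly-higher-ACI neighbour of maximal ACI (ties by lower index); a
residue with no higher neighbour is a cluster center.  Steepest ascent with
strict inequality guarantees an acyclic pointer graph and deterministic
clusters.  Equal-ACI plateaus therefore do not merge — a documented
limitation visible only on degenerate synthetic profiles (real profiles have
no exact ties; a uniform profile makes every residue its own center).  The
propagation source (the active site) is excluded from clustering, since it
trivially carries ACI 1.

Evaluation keeps the field's verbal metric definitions: a predicted hotspot
is *true* if any member lies within the match radius (4.5 Å, same neighbour
notion — the match criterion is not otherwise specified) of any true-site
residue; TPR = true hotspots / predicted hotspots.  PPV counts the true-site
residues recovered by matched hotspots / all true-site residues.  The
literal reading "site residues inside any cluster" would always give PPV = 1
because gradient clustering partitions all residues; restricting to matched
hotspots is the reading consistent with the metric's intent and its
boundary cases (no hotspot near the site ⇒ TPR = PPV = 0).  Note these
names are precision-like and recall-like respectively, not the standard
ROC quantities.

## All-pairs coupling and chemical-shift comparison

The all-pairs map runs one ACI computation per source residue, restarting
the seeded stream per row so that row i equals a single-source run at the
same seed.  Default per-source rounds drop to 2000 in this mode (recorded in
metadata) — the error per entry rises to ~0.011, still far below the
contrasts of interest, and a ~130-residue protein stays in the minutes
range.  The matrix is generally asymmetric because N_ij ≠ N_ji; both the raw
and the elementwise-mean symmetrised variants are emitted, flagged in
metadata, since either may be wanted for comparison with symmetric
experimental maps.

The experimental side mirrors chemical-shift covariance analysis: combined
chemical shifts CCS = δH + 0.15·δN per residue per variant, then the
absolute Pearson correlation of residue CCS vectors across ≥ 3 variants.
Residues missing shifts are dropped with a warning, or optionally filled
from a designated reference variant (wild type); zero-variance residues are
flagged and masked NaN.  The Gaussian low-pass filter (default σ = 1.0
residue — a visible parameter, as no canonical value exists) uses
missing-data-aware normalisation: values and the presence mask are filtered
separately and divided, which excludes NaN cells from the kernel and
simultaneously handles matrix edges; output values therefore stay inside the
input range, and symmetric input stays symmetric.

The top-k comparison ranks unordered residue pairs by predicted coupling
(ties lexicographic) and reports the fraction of the first k whose reference
correlation exceeds 0.5.  Sequence-adjacent pairs are excluded by default
(switchable): they are trivially coupled and would crowd out the long-range
couplings the comparison is about.  The metric is invariant under any
strictly monotone transform of the predictions (tested).

## Synthetic study conditions

The fixtures are geometric toys, not proteins: 4 pseudo-atoms per residue on
an ideal helical trace (rise 1.5 Å, twist 100°, CA radius 2.3 Å, atom
offsets tuned so the 3.4 Å cutoff reproduces the helical i→i+2..4 contact
band), and a two-domain structure (two 6-residue compact clusters, 3 Å
packing, joined by a 4-residue single-file linker) whose unique inter-domain
route makes pathway claims provable by a graph cut.  The synthetic
chemical-shift panel drives each domain with a shared latent factor across 8
variants (loadings 0.30 ppm on ¹H, 2.0 ppm on ¹⁵N, noise 0.01/0.05 ppm), so
its correlation structure follows the domain architecture by construction.
What passing tests show is that the machinery is correct — counting,
probabilities, percolation statistics, clustering, metrics — against
independent oracles (brute-force loops, closed forms, exact enumeration,
hand counts).  What they do not show is predictive accuracy on real
proteins: side-chain packing heterogeneity, ligand chemistry, and real NMR
noise are outside the fixtures.  Benchmark checks against published
crystal-structure behaviour are included in the test suite but require the
corresponding PDB files locally (`scratch/pdb/`).

## Problem sizes and numerical choices

Defaults: cutoff 3.4 Å, α 3.0, neighbour/match radius 4.5 Å, 10⁴ rounds
(2000 per source in all-pairs mode).  Monte-Carlo assertions in the tests
use 4 binomial standard errors (≈ 1 in 16 000 false-failure odds per
comparison); oracle enumerations stay at ≤ 6 nodes / ≤ 8 edges where the
outcome tree is small.  Degenerate inputs are defined, not special-cased:
cutoff 0 gives an empty network, an unreachable target gives an empty
ensemble with reach frequency 0, a disconnected component has ACI 0, and a
fully excluded clustering input is an error.

## Known limitations

* Single static structure in, no conformational ensembles; the probability
  map ignores interaction energies and chemistry (contacts only).
* Hotspot clustering on near-saturated ACI landscapes (high α, or dense toy
  fixtures) fragments on sampling noise; prefer low α and more rounds.
* PDB input only (no mmCIF); no structure repair, protonation, or
  symmetry-mate expansion.
* Exact enumeration is a validation tool, not an analysis path — it is
  exponential by nature.
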