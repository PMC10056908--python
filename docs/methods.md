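# Methods

## Data

The packaged matrix (`morphoclad.load_aphrodini_matrix`) is the published
character-state table for the tribe Aphrodini: 23 taxa × 39 discrete,
unordered, equally weighted male morphological characters with states
0–6, `?` for unobserved and `-` for inapplicable cells. Roles
(`load_taxon_roles`): 16 ingroup *Planaphrodes* species, six non-
*Planaphrodes* aphrodine outgroups, and *Xestocephalus asper* as the root
outgroup. A checksum test pins the fixture cell-for-cell.

`?` and `-` are both scored as the full state set {0..6}. This is the
standard behaviour of parsimony programs for unordered analysis; the
distinction is preserved notationally through all file formats but never
affects scores.

### Area coding

The four biogeographic regions are (A) Europe, (B) Middle East and
Western Asia, (C) Central Asia including western China, (D) Eastern Asia
including central and eastern China, Korea and Japan. No taxon-by-area
matrix is published; the packaged coding (`load_area_matrix`) was
reconstructed from the species' published distribution statements with
these rules, applied once and shipped as data:

- every country is mapped to the region containing its relevant territory
  (Iran, Azerbaijan, Georgia, Turkey, Syria, Israel → B; Kazakhstan,
  Kyrgyzstan, Uzbekistan, Mongolia → C; China (Sichuan/Hubei), Japan,
  Korea → D; European countries → A);
- "Russia" counts as European Russia (A) except for the two East Asian
  species (*P. sahlbergii*, *P. nigricans*) where it denotes the Far East
  (D);
- widespread outgroup species are coded by their core Palearctic ranges.

The coding is overridable per taxon via a YAML mapping
(`load_area_matrix(overrides=...)`). *Xestocephalus* carries no coding
and is excluded from biogeographic analysis by default; tests of the
reconstruction assert only coarse, data-forced outcomes (the East Asian
trio reconstructs in D, the European subclade in A), which are robust to
the judgement calls above.

## Parsimony engine

Characters are packed into seven 64-character "state planes" per taxon,
so a Fitch set operation on a whole matrix block is a handful of 64-bit
AND/OR/popcount instructions; kernels are numba-compiled. Tree length is
the Fitch downpass count from an arbitrary rooting (scores are
root-invariant; a property test checks this and a brute-force
enumeration oracle fixes the semantics on trees of ≤ 8 leaves).

Per-character bookkeeping uses directed Sankoff cost vectors (unit
costs), computed by an up/down pass. These give, exactly: per-character
lengths sᵢ; the minimum number of changes on each branch over all
most-parsimonious reconstructions (the collapse criterion); and the
parent/child state sets achievable at an optimum (the change map).
mᵢ = (distinct observed states − 1) and gᵢ = (observed taxa − most
frequent observed state count) come from observed frequencies only.

CI and RI are ensemble indices over all 39 characters, including
parsimony-uninformative ones (the convention of the common parsimony
programs); informative-only variants are reported alongside in the
pipeline output. Reported values are rounded half-up to two decimals.

Change maps are reported three ways: `unambiguous` (changes present in
every MPR; from/to sets may be multivalued), and full `acctran` /
`deltran` resolutions obtained by backtracking the Sankoff vectors with
ties broken toward (away from) early changes. A change is flagged
`unique` when its character is homoplasy-free on the tree (sᵢ = mᵢ).

## Tree search

`exhaustive_search` enumerates all unrooted binary topologies (guarded to
≤ 9 taxa) by stepwise addition; `branch_and_bound_search` prunes partial
trees whose length exceeds the incumbent (≤ 16 taxa; partial length is a
valid bound because adding taxa never shortens a tree). Both collect all
optimal trees; they are verified identical on random matrices, and
against a fully independent Python topology enumerator.

`heuristic_search` follows the traditional protocol: each replicate draws
a random addition sequence, greedily inserts taxa at minimum-cost edges,
then swaps to a TBR local optimum (first-improvement passes over all
bisections until none improves). The central identity — for a bisection
into components A and B, the length of any reconnection equals
len(A) + len(B) + #{characters whose Fitch edge sets on the two
reconnection edges are disjoint} — makes every TBR candidate exact and
O(blocks) to score; edge sets come from one up/down pass per component.
TBR subsumes SPR and NNI, so only TBR is implemented; requesting the
others warns and uses TBR. Searches are deterministic for a fixed seed
(an internal xorshift generator drives addition order and tie-breaks).

Optima from all replicates are pooled, deduplicated by unrooted
bipartition set, optionally closed under zero-cost TBR moves
(`close_island=True`; off by default), collapsed under "rule 1" (contract
every branch whose minimum length over all MPRs is zero — the default
collapsing of the major parsimony programs), deduplicated again, and
capped at `trees_to_save`. Reverse-constraint variants of both the
heuristic and branch-and-bound searches (used for Bremer decay) reject
any tree containing a named split; start trees are perturbed across the
forbidden edge by an NNI when necessary.

## Support

**Bootstrap.** Characters are resampled with replacement; each
pseudo-replicate runs a reduced-effort search (10 random-addition
replicates, TBR, up to 5 distinct best trees — reduced because 1000
pseudo-replicates each repeat the search) and contributes its
strict-consensus splits. Headline support defaults to the **frequency
difference** (a group's frequency minus the frequency of its
best-supported contradicting group), the default resampling summary of
the programs these analyses are usually run in, and demonstrably what the
published "bb" values are: raw frequencies run ~7 points higher across
every per-replicate effort tried, while frequency differences land within
~4 points. Raw frequencies are always reported alongside.

**Bremer decay.** decay(S) = (length of the shortest tree lacking S) −
(optimal length). The default route is reverse-constraint search (exact
branch-and-bound below 17 taxa, constrained TBR descent above); a
suboptimal-buffer sweep (replicate finals plus their TBR neighbourhoods
within `max_decay` of the optimum) is available as `route="buffer"` and
agrees with the exact route on small instances by test. Decay exceeding
`max_decay` (default 10) is reported as `max_decay + 1`.

## Discrepancies with the published values

Three published numbers cannot be derived from the published matrix; the
package computes and reports the correct values and the acceptance tests
for the published ones are deliberately left failing:

- **"Four most parsimonious trees."** The 110-step optimum (length
  independently confirmed with R/phangorn) contains ~176 distinct binary
  trees — roughly two dozen after rule-1 collapsing — connected by
  zero-cost TBR moves. A tree buffer of 10 per replicate cannot represent
  this set; the published count reflects retention settings, not the data.
- **"Three branches collapse in the strict consensus."** Against the full
  optimum, eight branches of a binary MP tree collapse, including the
  *P. vallicola*-sister branch and parts of the East Asian subclade.
- **Bremer = 3 for *Planaphrodes*.** The shortest tree lacking
  *Planaphrodes* monophyly has length 114 (decay 4), by constrained
  searches from several seeds and by a complete sweep of >10⁵ trees within
  +3 of the optimum. Conversely the *P. vallicola*-sister branch, also
  printed as 3, has decay 0 (some MP trees lack it). The printed decays —
  all exactly 3, the maximum value printed anywhere — are consistent with
  a suboptimal sweep bounded at +3 over an incomplete buffer.

The *Aphrodes* + *Planaphrodes* decay (3) verifies exactly, as do length
110, CI 0.79, RI 0.82, and (within a few points) both bootstrap values.

## Ancestral areas

Each area evolves independently as a two-state (absent/present) CTMC with
gain rate g and loss rate l on the fixed, possibly multifurcating, rooted
tree; cladograms carry no branch lengths, so branches default to unit
length (`branch_lengths="tree"` uses the stored lengths). The root prior
is the stationary distribution g/(g+l). A Metropolis–Hastings sampler
moves (log g, log l) with Gaussian proposals (sd 0.4) under a uniform
prior on [log 10⁻³, log 10] (events per unit branch length — wide enough
to cover near-static to saturated regimes on a unit-branch cladogram);
defaults: 20 000 iterations, 25% burn-in, thinning 10. For each retained
sample the marginal presence probability at every node is computed
exactly by pruning with an up-down pass (verified against brute-force
joint-state summation on small trees); the table reports posterior means,
per-parameter effective sample sizes, and MAP ranges (areas with
probability > 0.5; an empty MAP range is flagged ambiguous). Areas with
no variance among tips are handled analytically. Runs are deterministic
per seed.

This is a self-contained implementation of the binary ancestral-range
model, not a wrapper around any external program; chain settings are
deliberately modest because the per-sample reconstruction is exact and
the two-parameter posterior mixes quickly (ESS is reported so users can
judge).

## Synthetic data

`simulate_matrix` evolves unordered k-state characters (k = 2..7) under
the symmetric Mk model along a Yule tree (birth rate 1, exponential
branch lengths) or a user tree, with independent per-cell masking by `?`
and `-`. Defaults (8 taxa, 100 binary characters, rate 0.5/unit) give
matrices with moderate homoplasy, comparable in information content to a
morphological study matrix. `simulate_area_history` draws binary area
histories root-to-tips at the CTMC's exact endpoint probabilities,
returning latent node states for recovery scoring; a tip drawn with an
empty range is redrawn conditional on its parent (matching the area-
matrix invariant), which slightly enriches tip presence relative to the
unconditional process — a deliberate, documented bias.

What the simulations do not emulate: correlated characters,
ascertainment ("only variable characters scored") bias, state-dependent
rates, and non-independent area gain/loss. Passing recovery and
calibration tests therefore demonstrates algorithmic correctness under
the stated models, not robustness of parsimony or the range model to
real-data violations.

## Problem sizes in the tests

The suite runs exhaustive oracles at ≤ 8 taxa, heuristic-vs-exact
cross-checks on 100 random 8-taxon matrices, bootstrap tests at 30–1000
replicates, and BBM calibration on 25-tip trees with 3000-iteration
chains; the full published protocol (1000 search replicates; 1000
bootstrap replicates averaged over five seeds) runs in the acceptance
suite and `scripts/acceptance.py`. These sizes were chosen so the entire
analysis reruns from scratch in minutes on a single core.
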