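# Methods

## Selectivity model

A compound assayed against two targets K and S is summarized by its
selectivity ratio, SR = max(IC50_K, IC50_S) / min(IC50_K, IC50_S), always
quoted for the more potent target so SR ≥ 1. SR is computed from the raw
IC50 ratio rather than a pIC50 difference; the two are identical
(SR = 10^|ΔpIC50|) and the ratio avoids an unnecessary log/antilog round
trip. Ties give SR = 1 with no favored target.

Set assignment partitions [1, ∞): SR ≥ `selective_min` → selective for the
favored target (K/S or S/K); SR < `nonselective_max` → non-selective (KS);
the band in between → `ambiguous`. Defaults are `selective_min = 50`,
`nonselective_max = 10`. Two conventions coexist in this field — a strict
50-fold rule and a lax 10-fold rule under which, e.g., an SR of 25 counts as
selective — so both thresholds are explicit parameters and the 10-fold
profile ships as `TENFOLD_THRESHOLDS`. The in-between band is surfaced as
`ambiguous` rather than silently binned so that neither convention is
imposed by default.

## Fingerprints

* **MACCS (166 bits).** The public 166-key substructure dictionary as
  exposed by RDKit. RDKit returns a 167-slot vector whose slot 0 is unused;
  that slot is stripped, so emitted bit *i* corresponds to public MACCS key
  *i + 1*.
* **BAPS (117 bits).** Each key describes one bond: two atom classes joined
  in a ring (`@`) or non-ring (`!@`) context. The historical 117-key list is
  not publicly deposited, so the package ships a versioned, user-replaceable
  default (`resources/baps_keys.tsv`): all 55 unordered pairs over the ten
  atom classes {C, c, N, n, O, o, S, s, P, halogen `[G7]`} in both bond
  contexts (110 keys) plus seven generic keys (`a-@a`, `a-!@a`, `A-@A`,
  `A-!@A`, `a-@A`, `a-!@A`, `a-[G7]`), exactly 117. Keys are evaluated as
  SMARTS bond queries; a bare `!@` bond primitive matches a bond of any
  order outside a ring, which is the intended grammar (the `!@` = acyclic
  convention is standard, and the package follows it even though some
  informal glosses of patterns like `C-!@O` say "cyclic"). A few pair keys
  (e.g. halogen–halogen in a ring) can never match; they are retained so the
  vocabulary stays the documented closure of the class set. Downstream code
  reads all lengths from the table, so a replacement table of a different
  size propagates cleanly.
* **Combined (283 bits).** Concatenation, MACCS at 0–165, BAPS at 166–282.

Hydrogens are implicit; molecules are treated as 2D graphs (no conformers).
Fingerprints are invariant to atom renumbering because every key is a
substructure query.

## Emergent SOM

Online Kohonen training on a rows × cols toroidal grid (default 50 × 82 =
4100 neurons, honoring the ≥ 4000-neuron emergent-map convention; every test
and the reproduction protocol use smaller grids, stated below). Per
presented sample the best-matching unit (BMU) minimizes the configured
distance — Euclidean by default, continuous Tanimoto dissimilarity as an
option — with ties broken to the lowest (row, col). Every neuron within 3σ
of the BMU (toroidal grid distance) moves by α·exp(−g²/2σ²)·(x − w); α and
σ decay linearly over epochs (defaults α 0.5 → 0.05, σ max(rows, cols)/2 →
1, 30 epochs). Weights initialize uniformly inside the per-dimension data
range; initialization and per-epoch shuffling derive from one seed, so equal
seed + config + data gives bit-identical maps. The quantization-error trace
(mean sample-to-BMU distance before training and after each epoch) is
stored. On clustered data the final error is below the initial one; on
structureless uniform data the neighborhood-smoothness term can dominate
pure quantization, so no such guarantee is claimed there.

* **U-matrix**: per neuron, the sum of distances from its weight to its
  eight Moore neighbors (toroidal wrap), divided by the grid maximum; an
  all-flat map returns zeros (the maximum is taken as 1 to avoid 0/0).
* **P-matrix**: per neuron, the count of data points within the Pareto
  radius of its weight. The default radius is the 20th percentile of the
  data's pairwise distance distribution, subsampled to ≤ 2000 points with a
  seeded draw for tractability.

Projection of held-out compounds is a pure BMU lookup; the weights never
change. A seeded stratified splitter supports 50/50 train/projection
protocols (the reference protocol does not state how its split was made, so
stratified-by-set-label random is used).

## Cluster extraction and scoring

Occupied neurons (BMU of ≥ 1 projected compound) with U-height ≤ θ form
nodes; toroidally Moore-adjacent nodes are joined; connected components are
clusters, and compounds whose BMU exceeds θ stay `unclustered`. This is a
deterministic stand-in for the interactive coloring of U-matrix basins.

**Default θ is the 90th percentile of the U-matrix.** On sparse emergent
maps (several-fold more neurons than compounds) nearly all separation comes
from occupancy adjacency: distinct compound families rarely occupy adjacent
neurons, so the threshold only needs to cut the steepest ridges. Empirically
(8 seeds, 20 × 25 grid, 353 compounds) a median threshold strands 10–27 % of
compounds on basin-border neurons while producing the *same* mixed-cluster
structure as θ = 0.7 or 1.0; the stricter default lost coverage without
gaining purity. On dense maps (more compounds than neurons) a lower θ is
appropriate; it is a plain argument everywhere.

Scoring conventions: cluster purity = round(100 · majority-set count /
library members), half-up, decoys excluded from the denominator but any
decoy presence disqualifies a cluster from being a *pure selectivity
cluster* (exactly one set, zero decoys). Global rates over a panel of N
library compounds: coverage = clustered/N, correct = Σ majority counts / N,
error = coverage − correct; exact values satisfy the identity, and the
half-up integer percents are rounded per term — which is why a printed
coverage can differ by 1 from printed correct + error (e.g. 93.46 % exact
prints as 76 + 18 = 94 after per-term rounding).

## Selectivity markers

Per-bit in-cluster frequency is compared with the rest of the library
(decoys excluded — the "rest of the database" is the selectivity database).
A bit is a marker when freq_in ≥ `min_in` (default 0.5) **and**
freq_in − freq_rest ≥ `min_diff` (default 0.5, i.e. 50 percentage points).
Two readings of the informal rule circulate — pure in-cluster occurrence and
pure differential enrichment; the conjunction is implemented because only
differential bits can explain discrimination, and `min_diff = 0` restores
the occurrence-only reading. Both frequencies are reported per marker so
either reading can be audited. Markers sort by descending difference, ties
by bit index; the rule is scale-free (duplicating all members changes
nothing). Marker bits map to atoms through their key's SMARTS; the two
MACCS keys without a substructure definition yield no atom maps.

`pooled_set_markers` gives the per-set view: library members of all
100 %-purity clusters of a set are pooled and the same rule is applied
against the remaining library. Purity-100 (rather than decoy-free) pooling
is used because decoys are excluded from purity by convention and a planted
decoy sitting inside an otherwise clean set cluster should not silence that
set's markers.

## Screening

Decoys merge after the library (id collisions prefixed), the merged panel is
re-mapped, and clusters holding ≥ 1 decoy plus library compounds of exactly
one set become hit sources: each such decoy is scored by its maximum
Tanimoto similarity to the cluster's library members and the global top-k
(default 5, ties by id) form the hit list, each carrying the cluster's set
as predicted selectivity. When activities exist for hits they are annotated
with measured SR and the set label under a configurable threshold profile
(screening follow-ups often use the 10-fold profile).

## Synthetic panel generator

Emulates the undeposited reference panel: sets of 46 (K/S), 49 (KS) and
58 (S/K) compounds, all pIC50 in [3.9, 9.7], selective SR log-uniform in
[50, 250000], non-selective SR log-uniform in [1, 10), plus a decoy pool
(default 1000; the scaled reproduction uses 200) of which 1 % carry a
planted class signature and serve as recoverable hits. On-target pIC50 is
drawn uniformly from [3.9 + log10(SR), 9.7] and the off-target value is
on-target − log10(SR), so both bounds hold by construction and set
assignment recovers the generating class exactly.

Structures come from a fragment grammar (versioned TSV): a core ring with
substituent slots, an amide / ester / carbamate linker to a second ring, and
shared decorations. Class signatures: K/S = thiophene core (aromatic S, a
feature associated with K-selective chemotypes) + nitrile (the electrophilic
warhead of covalent cysteine-protease inhibitors) + thioether; S/K =
pyridine core (aromatic ring N) + aryl chloride; KS = pyridine core +
thioether — a mix of the two selective signatures with no fragment exclusive
to the non-selective set. Signatures attach to every member of their set;
all other grammar choices are shared across sets and decoys, so signature
bits have in-set frequency 1 and everything else is either universal or
rare. The library's second ring is fixed (benzene) so that within-set
structural variance stays below between-set signature separation — the
regime the method assumes and the reference panel's reported accuracy
implies; decoy cores instead draw from {benzene, cyclohexane, furan,
thiophene}, which also exercises the aromatic O/S atom classes of the BAPS
vocabulary. `planted_marker_bits` applies the marker rule to the *true*
class partition and is the ground truth against which cluster-recovered
markers are scored. With `signatures_enabled=False` the class structure
vanishes (negative control: no planted bits, near-chance pure clusters).

What the generator does **not** emulate: real medicinal-chemistry property
distributions (MW, logP), scaffold diversity of curated panels, assay noise,
and activity cliffs. Passing end-to-end tests therefore demonstrates that
the pipeline recovers planted structure-selectivity signal through the full
map/cluster/marker/screen chain, not that it would reach the same accuracy
on a real panel.

## Problem sizes and numerical choices

* Reproduction protocol: 20 × 25 grid (500 neurons), 60 epochs, radius
  12.5 → 2.0 (a final radius above the package default of 1, keeping
  regions smooth on sparse grids), combined 283-bit fingerprints,
  153 + 200 compounds; about 35 s on one CPU. Chosen as the smallest setup
  at which recovery is seed-stable.
* Rounding of printed percentages: half-up (matches the benchmark tables).
* BMU ties: lowest (row, col); cluster ids: components sorted by size then
  smallest member id — both make outputs order-independent and rerunnable
  byte-identically.
* Degenerate inputs: empty projections, empty marker inputs, non-positive
  potencies, mismatched schemes and malformed key tables raise immediately
  with named errors rather than propagating NaNs.

## Known limitations

* The default BAPS vocabulary is a documented reconstruction, not the
  historical list; absolute bit indices are not comparable with legacy
  tools, though the grammar is.
* The published combined-fingerprint benchmark table is internally
  inconsistent (row totals disagree with member counts) and is not used as
  an anchor; the BAPS table and the consistent head of the MACCS table are.
* U-threshold connected components approximate, but do not reproduce,
  interactive watershed/basin coloring; very dense maps need a manual θ.
* Online (not batch) training only; no spherical topology; no GPU path.
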