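# Methods

## Scope and data model

`graphfp` computes fingerprints on the hydrogen-depleted molecular graph:
heavy atoms with element, formal charge, attached-hydrogen count, nominal
mass, ring flags and optional 3D coordinates, plus bonds with order 1/2/3
and an aromatic flag. Depletion happens at parse time, before any typing.
SD input (V2000) is parsed with RDKit; ring membership and aromaticity are
taken from RDKit's default sanitization model. Different perception models
(notably for borderline aromatic systems) can change ring-aware labels, so
cross-toolkit string identity is only guaranteed for perception-independent
schemes (element, element+neighbor, Daylight invariants with ring flag on
unambiguous systems). Heavy atoms keep input order; every encoder is
invariant under permutation of that order (tested).

Unparseable SD records are skipped with a warning rather than aborting a
batch conversion; a file whose records all fail raises an explicit
empty-input error, while a zero-record file yields an empty list.

## Distances

* Topological: shortest-path bond counts via Floyd–Warshall
  (`scipy.sparse.csgraph`); disconnected pairs hold `inf` and features never
  span fragments.
* Geometrical: `g_ij = floor(|c_i - c_j| * s)`. The floor keeps bin 0 for
  sub-threshold contacts and makes the bins integer, so geometric features
  are discrete and comparable by exact equality. The default scaling `s = 1`
  gives Ångström-resolution bins; it should be raised for small rigid
  compounds and lowered for large ones.
* All pair-like encoders include only distances in `[1, d]`; the CATS
  distance-0 cells are populated separately from single atoms (see below).

## Canonicalization

Path patterns render as label/bond-symbol alternations with `-` for single
*and* aromatic bonds (so aromaticity perception cannot change path strings),
`=` for double, `#` for triple. A path is stored under the lexicographically
greater of its two reading directions (raw code-point order); an atom
triplet under the lexicographic maximum of its six rendering orders. The
historical alternative — comparing platform hash codes of the two strings —
picks different representatives of the same equivalence class; membership
checks across implementations should therefore canonicalize before
comparing, which is what the acceptance tests do.

## Encoders

* **DFS** — exhaustive enumeration of simple paths (no atom revisits) of
  1..d bonds from every root; each generated path increments the count of
  its canonical string, so a non-palindromic path contributes once per
  direction. Worst case O(n·3^d); organic branching factors keep it small.
* **ASP** — the DFS subset with `|p_ij| = t_ij`; all distinct shortest paths
  are kept explicitly. On trees ASP equals DFS (paths are unique); on rings
  the around-the-long-way paths are dropped.
* **AP2D/AP3D, AT2D/AT3D** — pairs `label-distance-label` from the upper
  half of the distance matrix; triplets over unordered atom triples with all
  three distances in `[1, d]`, rendered `l_i-d_ij-l_j-d_jk-l_k-d_ki`.
* **PHAP2PT/PHAP3PT (2D/3D)** — as atom pairs/triplets but iterating over
  every PPP of every atom, so one atom pair can contribute several
  pharmacophore pairs. Contradictory PPP combinations never co-occur on one
  atom and thus simply never appear.
* **CATS2D/CATS3D** — fixed vector of `(d+1)*15` counts; block order
  AA, AD, AL, AN, AP, DD, DL, DN, DP, LL, LN, LP, NN, NP, PP; flat index =
  `block*(d+1) + distance`. The distance-0 cell of a block counts single
  atoms bearing both PPPs of the pair — for AA this is simply the number of
  acceptors, which is what the worked example requires (5 for Oxaceprol).
* **SHED** — for each pair block, the counts over distances 1..d form a
  probability distribution whose Shannon entropy H (nats) is stored as
  `exp(H)`, i.e. the perplexity: 1.0 for a single observed distance, k for a
  k-uniform spectrum, 0 for a never-observed pair type. The perplexity form
  is fixed by the worked example: the acceptor–acceptor spectrum
  {2:2, 3:3, 5:5} has H = 1.0297 and the tabulated value is
  exp(1.0297) = 2.800 (likewise AL = 3.596, AN = 2.872).
* **ECFP** — explicit-substructure circular fingerprint: iteration 0 emits
  the atom's initial identifier (its label under the configured scheme,
  Daylight invariants by default); iteration k renders the subgraph induced
  by all atoms within k bonds of the center, keeping all bonds between
  layers, marking unfilled attachment points `([*])` and ring closures with
  paired `%k` markers. Growth stops per center when the sphere saturates.
  Branch order in the renderer is fixed by bond symbol and an
  iterative-refinement rank computed inside the substructure, so the string
  depends only on the substructure, not on atom input order; atoms left tied
  by refinement are structurally interchangeable, so the rendering is
  unambiguous for molecules of this size class. String identity with other
  ECFP implementations is not promised — substructure equivalence is.
* **RAD2D/RAD3D** — per atom and l in 1..d, the cumulative shell feature
  `0[center]1[...]...l[...]` with each shell the sorted labels of atoms at
  that exact distance; empty shells are retained as `l[]` so cumulative
  features stay aligned. Exactly n·d features per molecule.
* **LSTAR** — per root and length l, one bracketed feature holding the
  lexicographically sorted root-anchored strings of all paths of exactly l
  bonds. Root-anchored rendering (rather than two-direction
  canonicalization) keeps the root's label leading, which is the natural
  reading for a radial environment; shells with no paths are skipped.

Defaults (depth, typing) per encoding: DFS/ASP/AP2D d=8 EN, AT2D d=5 EN,
CATS2D/CATS3D d=9 PPP, PHAP2PT2D d=8, PHAP3PT2D d=5, SHED d=8, ECFP d=4
Daylight invariants, RAD2D d=3 EN, LSTAR d=6 EN, AP3D d=10 EN, AT3D d=6 EN,
PHAP2PT3D d=10, PHAP3PT3D d=6, RAD3D d=4 EN (EN = element+neighbor count).

## Pharmacophore rules

Donor: O of OH, N of NH/NH2. Acceptor: any O; N with no attached H.
Positive: positive formal charge, or NH2 nitrogen (deliberately overlapping
with D). Negative: negative formal charge, or the central C/S/P of a
COOH/SOOH/POOH group found by direct neighborhood search (=O plus −OH on the
same center). Lipophilic: Cl/Br/I; S with exactly two carbon neighbors; and
any carbon whose heavy neighbors are at least one and all carbon. The
lipophilic-carbon rule is what makes an acetyl CH3 and an all-carbon ring
CH2 lipophilic while leaving isolated methane carbons without PPPs, and it
reproduces the worked example's AL entry exactly. Aromatic ring O/N are not
excluded from the acceptor rule (the printed rules are followed literally).

## Feature identity, hashing, similarity

Feature id = polynomial rolling hash of the pattern string (multiplier 31,
32-bit wraparound) — portable and platform-independent, so ids and all
downstream bits are byte-identical across runs and machines. Folding places
a feature at bit `((id * 2654435761) mod 2^32) mod h` for a power-of-two
hash space h (default 2^14): a fixed multiplicative scrambling of the seed
id, chosen over a stateful RNG so the position function is specifiable in
one line. MinMax similarity = Σ min(counts)/Σ max(counts) over the union of
patterns (the max in the denominator is required for self-similarity 1);
Tanimoto operates on the distinct-id sets; two empty maps score 0 by
convention (0/0 in the formulas). Folded-fingerprint Tanimoto converges to
exact feature-map Tanimoto as h grows (collision bias shrinks; spot-checked
at 2^10 vs 2^20).

## Exporters and CLI

Sparse SVM lines are written with strictly ascending 1-based indices and
value 1, streaming one feature map at a time. The precomputed-kernel dialect
writes `label 0:i j:K_ij`; it holds all maps in memory. ARFF output is
sparse with h binary attributes and a class attribute that is nominal when
the number of distinct labels is at most five (inclusive, configurable) and
numeric otherwise. CSV comes in a string-feature layout (label, then quoted
`nom:count` cells) and a dense hashed 0/1 layout. Fixed-vector encodings
(CATS, SHED) are exported positionally (`index+1:value`) rather than hashed,
since their fixed layout is the point; ARFF export for them is declined with
an error. Missing labels export as 0 with a warning. Format codes beyond
`-ff 0` (sparse SVM, the default) are an artifact of this package: 1 kernel
matrix, 2 ARFF, 3 CSV string, 4 CSV hashed.

## Fixtures and what the tests show

Oxaceprol (N-acetyl-4-hydroxyproline) ships as an embedded SD text block
with a fixed MMFF-relaxed conformer. Topology, typing and pharmacophore
assignments are exact and asserted; geometric-encoder tests assert
structural properties (shell composition at distance 1, 2D/3D coincidence on
a calibrated chain) rather than conformer-specific bins, because the
tabulated reference conformer is not available — a different reasonable
geometry shifts individual G-matrix bins without touching any topological
result. Parametric all-carbon chains and rings (1.54 Å edges) cover the
generic graph shapes; random test molecules are spanning trees plus chords
with random elements, which exercises the combinatorics but does not emulate
real chemistry (valence rules, charge placement, tautomers), so passing
property tests demonstrate algorithmic correctness, not chemical realism.

Problem sizes used by the default suite: 200 random graphs (n ≤ 12) for the
distance-matrix oracle and the shortest-path-subset property, 20–50 random
molecules (n ≤ 10) per other property, brute-force pair/triplet oracles at
n ≤ 8 — sizes at which the independent oracles are exact and the whole suite
runs in seconds.

## Known limitations

* Ring/aromaticity perception is RDKit's; expert-system atom types are
  approximated by the hybridization-based HYBRID scheme, not replicated.
* No SMILES/InChI input, no V3000, no stereochemistry, no 3D coordinate
  generation (coordinates are consumed, never produced).
* ECFP renderings are canonical for the tested size class but the renderer
  is not a full graph-canonization algorithm; pathological
  refinement-indistinguishable substructures could in principle share a
  string.
* Tabulated example counts from historical implementations annotate each
  emission; this package reports aggregated multiset counts, so a pattern
  generated in both reading directions carries count 2, not 1.
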