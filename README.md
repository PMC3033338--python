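# graphfp

Chemical graph fingerprints for machine learning and similarity searching.

`graphfp` decomposes small-molecule graphs (read from MDL SD files with
explicit hydrogens) into exactly defined multisets of discrete features, the
way QSAR and virtual-screening pipelines consume them: depth-first-search
path fingerprints, all-shortest-path fingerprints, topological and
geometrical atom pairs and triplets, pharmacophore pair/triplet fingerprints,
CATS autocorrelation vectors, SHED keys, an explicit-substructure variant of
the extended connectivity fingerprint (ECFP), and Molprint-like radial
environments. Feature multisets can be compared directly with MinMax or
Tanimoto similarity, folded into hashed binary fingerprints, and exported to
sparse SVM-light/LIBSVM, precomputed-kernel, WEKA ARFF and CSV formats — from
the Python API or from a command-line tool.

## The model

A compound is a hydrogen-depleted molecular graph *C* with *n* heavy atoms;
explicit hydrogens are folded into a per-atom H count at parse time. Every
encoding *F* maps *C* to a feature multiset *F(C) = {f₁, …, f_m}*, where each
feature has a pattern string *f.nom* and a 32-bit id that is a deterministic
hash of the string; features are equal iff their ids are equal, and
regenerating a pattern increments its count.

Two fundamental matrices drive the encoders: the topological distance matrix
*T* of shortest-path bond counts (Floyd–Warshall), and the binned geometrical
matrix *G* with *g_ij = ⌊|c_i − c_j|·s⌋* for a scaling factor *s* (default
1 Å bins). Atoms are typed by a labeling function (element, element+neighbor
count, ring-aware variants, Daylight invariants, or a hybridization-based
scheme), or by potential pharmacophore points (PPP): donor, acceptor,
positive, negative, lipophilic — of which an atom may carry several.

Fixed-vector encodings: the CATS vector has *(d+1)·15* cells (15 unordered
PPP pair blocks × distances 0…d); the SHED key stores, per pair block, the
exponential of the Shannon entropy (the perplexity) of that pair's distance
spectrum.

Defaults per encoding (depth *d*, typing) follow the established
parameterizations, e.g. DFS *d*=8 with element+neighbor labels, ECFP *d*=4
with Daylight invariants, CATS2D *d*=9.

## Worked example

The test fixture Oxaceprol (N-acetyl-4-hydroxyproline, 12 heavy atoms) has
five acceptor atoms (amide N, hydroxyl O, acetyl O, both carboxyl O), two
lipophilic carbons and one acidic carbon:

```python
>>> from graphfp import encode
>>> from graphfp.fixtures import oxaceprol
>>> mol = oxaceprol()
>>> shed = encode(mol, "SHED")          # 15-entry SHED key, d = 8
>>> round(float(shed.block("AA")[0]), 3)
2.8
>>> round(float(shed.block("AL")[0]), 3)
3.596
>>> cats = encode(mol, "CATS2D")        # 150-entry CATS vector, d = 9
>>> int(cats[0])                        # acceptor-acceptor cell, distance 0
5
>>> pairs = encode(mol, "AP2D")         # topological atom pairs
>>> pairs["O.1-2-N.3"]                  # acetyl O two bonds from the amide N
1
```

The SHED AA entry 2.8 is the perplexity of the acceptor–acceptor distance
spectrum {2 bonds: 2 pairs, 3: 3, 5: 5}; the CATS cell 5 counts the acceptor
atoms themselves (distance-0 self-pairs).

From the shell, encoding an SD file with a learning label into hashed sparse
SVM lines (here a three-record toy file written by the fixtures module):

```
$ python -c "from graphfp.fixtures import chain_sdf_text; \
    open('toy.sdf','w').write(chain_sdf_text([2,3,4], labels=['0.5','1.5','2.5'], label_property='act'))"
$ graphfp -f toy.sdf -l act
graphfp: 3 molecules encoded with DFS (d=8)
graphfp: average number of features per molecule: 2.3
graphfp: output written to toy.DFS.LIBSVM_SPARSE
```

`-e` selects the encoding, `-d`/`-s`/`-a` override depth, geometric scaling
and atom typing, `-hs k` sets the hash space to 2^k, `-ff` picks the output
format (0 sparse SVM, 1 kernel matrix, 2 ARFF, 3 CSV string features,
4 CSV hashed), and `-m MINMAX|TANIMOTO` switches to similarity-matrix mode.

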