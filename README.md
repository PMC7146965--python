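# macroforge

Combinatorial enumeration of glycosylated macrolactone (macrolide) virtual
libraries, built for cheminformatics and drug-discovery groups who want
screening-ready macrolide analogues assembled the way biosynthetic
engineering would: a fixed macrolactone core with designated substitution
points, decorated with structural motifs and sugars drawn from known
bioactive macrolides.

## The method

A **core template** is a SMILES string with marked slots — `[*]` (optionally
digit-labelled `[1*]`, `[2*]`, ...) for structural-motif (SM) positions and
`[*sugar*]` for sugar positions, e.g. the erythromycin core

```
CC[C@H]1OC(=O)[*][*sugar*][C@H](C)[*sugar*][*]C[*]C(=O)[*][C@@H](O)[*]1
```

with five SM slots and two sugar slots. Fragments come from plain-text
files, one per line, wrapped in `[R]` connection anchors. The engine:

1. **Stereo-expands** fragments whose *joining atom* (the first body atom)
   carries a defined tetrahedral tag into both parity configurations
   (`@`/`@@`) — both are kept; no CIP assignment is attempted.
2. Builds **sugar-slot plans** realizing the minimum-sugar constraint:
   unfilled sugar slots receive an in-chain hydroxyl unit `C(O)`. The
   default *disjoint* plan family partitions the arrangements with
   ≥ `min_sugars` sugars exactly, so the engine's raw count matches
   `Σ_{k=s..p} C(p,k)·m^k`.
3. Streams the **cartesian product** of all slot choice lists in
   deterministic order, skipping products in which any single SM occurs
   more than `max_sm_repeats` times, splicing fragments textually into the
   core, validating each product with RDKit, and stopping at the requested
   library size. Memory use is constant, so arbitrarily large libraries
   stream to chunked `.smiles` files (≤ 10⁶ records each by default).

The companion space-size arithmetic counts the enumerable space. For
`n` expanded SMs at `p` slots with at most `r` repeats and `m` expanded
sugars in at least `s` of `q` sugar slots, the reporting convention is

```
[ n^r · (n−1)(n−2)···(n−(p−r)) ] · [ Σ_{k=s..q} C(q,k)·m^k ]
```

alongside an exact constrained count (generating-function based) used as
the engine's correctness oracle. A stratified sampler (fixed draw per chunk
file) and a profiler for the six standard 2D descriptors — MW, MolLogP,
TPSA, HBA, HBD, NRB — with Lipinski/Veber rule accounting complete the
pipeline.

## Worked example

```python
from macroforge import SpaceSizeParams, coverage_fraction
from macroforge.enumerator import exact_space_size, formula_space_size

params = SpaceSizeParams(n_sm=24, p_sm=5, r=3, m_sugar=14, p_sugar=2, s=1)
print(formula_space_size(params))   # 1566867456
print(exact_space_size(params))     # 1783004160
print(coverage_fraction(1e9, params))  # 63.8
```

24 stereo-expanded SMs at five slots with three repeats allowed, and 14
stereo-expanded sugars in at least one of two slots, span a formula-
convention space of 1,566,867,456 compounds; a 10⁹-record library covers
63.8% of it. The exact constrained count is larger (1,783,004,160) because
the convention's falling factors undercount tuples that revisit early
symbols.

Enumerating end to end (see `examples/` for complete scripts):

```python
import macroforge as mf

core = mf.parse_core_template("CC1OC(=O)[*]C[*sugar*]CC[*]C(=O)C1")
config = mf.EnumerationConfig(
    core=core,
    sm_library=mf.make_toy_fragments(mf.ToyLibrarySpec(3, 2, "SM")),
    sugar_library=mf.make_toy_fragments(mf.ToyLibrarySpec(2, 2, "SUGAR")),
    library_size=50, max_sm_repeats=2, min_sugars=1,
    chunk_size=20, out_dir="out",
)
report = mf.run_enumeration(config)
# emitted 50 macrolides into 3 files
```

Each output line is a fully assembled macrolide, e.g.
`CC1OC(=O)[C@@H](C)NC[C@H](OCC(O)C(O)CO)CCCC[C@@H](C)NC(=O)C1` — the core
ring with a motif at each SM slot and a glycosyl-like unit at the sugar
slot, both stereo variants of every tagged joining atom appearing across
the stream.

A thin CLI mirrors the library: `macroforge enumerate`, `space-size`,
`coverage`, `sample` and `profile` (see `macroforge --help`).

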