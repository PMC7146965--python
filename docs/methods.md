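# Methods

## Model

The package treats macrolide design as constrained slot-filling on a fixed
macrolactone scaffold. A core SMILES string carries two marker types:
`[*]` (or digit-labelled `[n*]`) for structural-motif (SM) slots and
`[*sugar*]` for sugar slots. Parsing splits the string into fixed segments
and an ordered slot list; digit labels are normalized away and slot
identity is purely positional. Products are assembled by *textual
splicing* — each fragment body replaces its marker between the neighbouring
segments — and only then parsed and sanitized with RDKit. This mirrors how
the input format is defined (fragments are SMILES substrings wrapped in
`[R]` anchors, with no bond-order syntax at the anchor), keeps the
assembly exactly reproducible, and still guarantees that every emitted
record is a chemically valid molecule: unparseable splices are reported
with full per-slot provenance, never silently dropped, and never counted
against the library-size budget.

Assumptions inherited from the format: anchor junctions are single bonds
(the file format cannot express anything else; configurable splicing of
other bond orders is deliberately out of scope), and fragment bodies must
not reuse a ring-closure digit that the core holds open across the splice
region — this is validated up front and treated as an input error, not
repaired.

## Stereo enumeration at joining atoms

The joining atom is the first atom of a fragment body — the one bonded
into the macrocycle through the leading anchor. Stereo status is
classified on the body capped with a dummy atom `*` at each anchor
position, so chirality perception sees the correct neighbour count:

* **DEFINED** — the atom carries a tetrahedral tag and survives RDKit
  perception as an assigned stereocenter: the fragment is expanded into
  both parities (the original and a tag-flipped copy, differing only in
  the joining atom's `@`/`@@`).
* **UNDEFINED** — a perceivable stereocenter without a tag: left
  unchanged.
* **NONE** — not a stereocenter (including tagged atoms that become
  achiral after capping, e.g. a one-atom body bonded to both anchors):
  left unchanged.

No CIP R/S labels are assigned; both configurations are always generated
when expansion is enabled, because which configuration is biosynthetically
accessible is an open question. Only the leading joining atom is expanded;
interior stereocenters and the trailing anchor's neighbour are untouched —
symmetric expansion would inflate a 13-motif/11-defined library beyond the
expected 24 = 2·11 + 2 choices (and 7 all-defined sugars beyond 14).

## Sugar-slot plans and the minimum-sugar constraint

Unfilled sugar slots receive a hydroxyl filler, by default the in-chain
unit `C(O)` (a backbone carbon bearing –OH). A bare `O` would sever the
macrocycle, since sugar slots sit in-chain in the reference cores; the
body is configurable for exocyclic templates.

The constraint "at least `s` of `p` sugar slots hold a real sugar" is
realized by a family of per-slot role assignments:

* **disjoint** (default): one plan per choice of the positions of the
  first `s` sugars — those slots draw from sugars only, earlier gaps are
  forced to hydroxyl, and all later slots draw from sugars + hydroxyl.
  The induced concrete arrangements partition the valid set exactly, so
  the engine's raw emission count equals
  `Σ_{k=s..p} C(p,k)·m^k` (verified by brute force for all `p ≤ 3`,
  `m ≤ 3`, `s ≤ p`).
* **paper_literal**: the historical rotation scheme
  (`(SUGARS, Full_List)`, `(Full_List, SUGARS)` for `p = 2, s = 1`),
  retained behind a flag for fidelity comparisons. It over-covers the
  all-sugar region (420 raw vs 224 distinct arrangements at `m = 14`);
  after canonical-SMILES deduplication it yields the same chemical set as
  disjoint mode, which the tests assert.

Disjoint is the default because it makes the engine's counting agree with
the closed-form space arithmetic; the duplication in the literal scheme is
a property of the scheme, not of the chemistry.

## Enumeration order and constraints

Within a run, plans are visited in order; within a plan, the nested
cartesian product iterates with the rightmost slot varying fastest and
fragments in library (file line) order. This makes output order — and the
meaning of "the first N records" — deterministic and byte-reproducible.
The max-repeat check counts expanded-fragment identity by default (the two
parities of one motif are distinct symbols, matching how the space-size
arithmetic treats the 24 expanded SMs); `count_repeats_by_parent=True`
switches to counting per parent motif. Violators and invalid splices are
skip-and-continue: they consume none of the library-size budget.
Enumeration is a constant-memory stream with no global duplicate tracking
(infeasible at 10⁹ scale); canonical-SMILES deduplication is available at
desk scale through the test oracle path.

## Space-size arithmetic

Two conventions are implemented and deliberately kept distinct:

* `formula_space_size` — the reporting convention
  `n^r · Π_{i=1..p−r}(n−i)` for the SM term times
  `Σ_{k=s..q} C(q,k)·m^k` for sugars. For `n=24, p=5, r=3, m=14, q=2, s=1`
  this gives 1,566,867,456, and a 10⁹-record library covers 63.8% of it.
  It is *not* claimed to equal the constrained count; it exists because
  coverage figures are quoted against it (precondition `n > p − r`).
* `exact_space_size` — the true number of SM tuples with no symbol used
  more than `r` times, computed exactly as
  `p!·[x^p](Σ_{j≤r} x^j/j!)^n` with integer-exact Fraction arithmetic,
  times the sugar term. For the parameters above the SM term is 7,959,840
  (vs the convention's 6,994,944); tests verify it against full
  enumeration of all 24⁵ tuples and against tiny-n brute force.

`coverage_fraction` reports `100·N/space` to one decimal against the
formula convention.

## Sampling and property profiling

`stratified_sample` draws `k` records uniformly without replacement from
every chunk file with one seeded generator (`numpy` PCG64), recording file
name and 1-based row — the provenance convention used to name compounds in
billion-scale builds. A file shorter than `k` is sampled in full with a
warning.

The profiler computes MW, Wildman–Crippen MolLogP, TPSA, HBA, HBD and NRB
with RDKit's standard 2D definitions. HBA/HBD default to Lipinski-style
N/O and NH/OH counts (the counting the rule-of-five thresholds were
calibrated against); RDKit's pharmacophore-style definitions sit behind
`acceptor_definition="rdkit"`. Rule violations use strict `>` (MW > 500,
TPSA > 140, HBA > 10, HBD > 5, NRB > 10, logP > 5): boundary values are
compliant. Summary sd is the sample sd (`ddof=1`) by default and
configurable, since the convention behind published "± x" values is
usually unstated. `compare_property_tables` emits per-property range-
containment flags, Gaussian-KDE curves on a shared grid (CSV-ready for
density plots) and an overlap coefficient; a zero-variance column degrades
to a narrow analytic bump rather than failing the KDE.

## Synthetic fixtures and what tests show

`fixtures` generates deterministic toy inputs: small macrocyclic cores and
fragment libraries whose bodies come from fixed whitelists of short
in-chain units, re-verified against the stereo classifier at generation
time so the requested DEFINED count is guaranteed rather than assumed.
Toy sugar bodies are polyol-ether chains each adding > 100 g/mol, which
lets tests assert the mass monotonicity that real glycosylation imposes.
The whitelists intentionally avoid ring-closure digits and exotic valence,
so engine tests isolate combinatorial logic; chemistry failure modes get
their own negative tests. Toy libraries emulate the *structure* of real
motif/sugar collections (stereo composition, in-chain attachment), not
their chemistry: passing tests demonstrate correctness of assembly,
constraint handling, counting and reproducibility — they say nothing about
the biological plausibility of any particular fragment set.

`brute_force_enumerate` is the independent oracle: it re-splits the core
with its own regex, materializes the full unconstrained product, filters,
splices, canonicalizes and deduplicates, sharing no code with the
streaming engine. The test matrix (all configs with ≤ 3 SMs, ≤ 2 sugars,
≤ 3 SM slots, ≤ 2 sugar slots, every repeat/min-sugar combination — 120
configurations) asserts set equality between engine and oracle and raw-
count equality with `exact_space_size`.

## Problem sizes and numerical choices

Test and example runs use desk-scale libraries (tens to hundreds of
records, chunk sizes of 20–100) — the engine is the same streaming code
path that writes million-record chunks, so scale changes only the number
of iterations. The exact-count cross-check enumerates all 24⁵ ≈ 8·10⁶ SM
tuples vectorized in numpy. Timestamps in output filenames use
`%Y-%m-%d-%H-%M-%S`; passing a fixed timestamp makes reruns byte-identical,
which is how determinism is tested. Full-scale distribution statistics of
a specific published billion-record library are not recomputed here: they
require that library's million-record sample file as input; the profiler
applied to any such file reproduces the pipeline exactly (a deterministic
descriptor pass plus summary).

## Known limitations

* Fragments with more than two anchors, SDF/MOL output, and reaction-SMARTS
  based assembly are out of scope.
* E/Z double-bond enumeration and interior stereocenter expansion are not
  performed.
* The engine does not deduplicate globally at scale; symmetric cores can
  therefore emit chemically identical records under distinct provenance.
* Anchor junctions are always single bonds.
* 2D descriptors ignore conformational effects; for macrocycles, logP and
  TPSA computed this way are trend-level quantities.
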