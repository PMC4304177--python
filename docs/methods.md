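# Methods

This note records the exact procedures implemented in `pdbkernel`, the
parameter choices, and the boundaries of what the synthetic generators
are meant to exercise.

## 1. Parsing (`pdb_io`)

The parser consumes legacy fixed-column PDB text and produces one
`ChainRecord` per chain:

- **HEADER** supplies the 4-character entry id and the deposition date in
  `dd-MMM-yy` form. Two-digit years are resolved with pivot 71: `71–99`
  map to 1971–1999, `00–70` to 2000–2070.
- **EXPDTA** is reduced to `XRAY`, `NMR`, or `OTHER`. NMR entries never
  carry a resolution; a REMARK 2 resolution of `NOT APPLICABLE` maps to
  `None`.
- **SEQRES** yields the reference sequence via three-letter → one-letter
  translation; unknown codes become `X`.
- **MODRES** records are collected as `(position → (modified code,
  standard code))`. A HETATM residue is retained only when its position
  is covered by a MODRES record *and* the chain has SEQRES records;
  all other heterogens (waters, ligands) are dropped at parse time.
- For multi-model (NMR) files only `MODEL 1` is read.

The writer emits HEADER/EXPDTA/REMARK 2/SOURCE/SEQRES/ATOM/TER/END with
coordinates formatted `%8.3f`, so `parse ∘ write ∘ parse` is the identity
on cleaned chains (sequences, numbering, coordinates to 3 decimals, and
metadata). Duplicate atom names within a residue are a write-time error.

## 2. Cleaning (`chain_clean`)

Pipeline order (each stage is pure; the input record is never mutated):

1. **restore_modres** — residues at MODRES positions are renamed to the
   standard parent code and flagged `is_modified`.
2. **select_altloc** — for atoms with alternate-location indicators, the
   first conformer *in file order* is kept and its altLoc blanked. This
   is deliberately simpler than occupancy-based selection; it is
   deterministic for any input and independent of ties in occupancy.
3. **prune_atoms** — atoms outside the standard heavy-atom composition of
   the (restored) residue type are removed; `OXT` is allowed on the final
   residue only; residues of unknown type keep at most the backbone
   (N, CA, C, O).
4. **align_ref_coord** — reconciliation of the reference sequence with
   the coordinate-part sequence (below).
5. **reindex** — residues are renumbered to their reference positions
   (1-based); insertion codes are cleared.
6. **apply_filters** — verdicts, not deletions: `CA_ONLY` (every residue
   is exactly one CA atom), `TOO_SHORT` (reference length < 30; length 30
   is kept), `TOO_MANY_X` (unknown fraction > 0.10; exactly 10% is kept).
   The cleaned chain is returned regardless, with the verdict attached.

### Reconciliation algorithm

Let `n = len(ref)`, `m = len(coord)`, `m ≤ n` (a longer coordinate part
is a hard error). We maximize matches over monotone placements of the
coordinate letters onto reference positions; gaps are permitted only in
the coordinate sequence. Scoring is match +1, mismatch 0, gap −0.5, but
because every placement threads *all* of `coord`, all placements have the
same total gap penalty, so maximizing score is exactly maximizing
matches. The suffix dynamic program is

```
S[i, j] = max( S[i+1, j+1] + [ref[i] == coord[j]],   # place c_j at r_i
               S[i+1, j] )                            # skip r_i
```

with traceback preferring the diagonal on ties, which yields the
lexicographically smallest optimal position tuple (leftmost placement).
Unplaced reference positions, grouped into maximal runs, are the missing
regions. A zero-match optimum is flagged (`flagged_zero_match`) since it
indicates the coordinate part does not belong to this SEQRES. The
implementation is checked against an oracle that enumerates all
`C(n, m)` placements.

## 3. Redundancy reduction (`redundancy`)

**Similarity.** `pairwise_similarity(a, b) = identities / ((|a|+|b|)/2)`,
with identities counted in the best local alignment under match +2,
mismatch −1, gap open −2, gap extend −1 (Biopython `PairwiseAligner`).
Because co-optimal alignments can differ in identity count and the
aligner's enumeration order depends on argument order, the pair is
canonicalized (lexicographically sorted) before aligning — this makes the
score exactly symmetric.

**Priority.** Between two chains: a length difference ≥ 10 residues is
decisive (longer wins); otherwise better (numerically smaller) X-ray
resolution wins, with X-ray outranking NMR/unknown; then later deposit
date; then smaller chain id. This pairwise relation is not transitive
across length windows; ordering a set uses a stable comparison sort,
which is deterministic for a given input order. For *selecting a
representative* within a cluster, the windowed total rule is used
instead: among members within 10 residues of the longest, pick best
resolution, then latest date, then smallest id. The two rules coincide
on two-element sets.

**Clustering.** Greedy incremental clustering at each identity level in
{0.90, 0.80, 0.70, 0.60, 0.50, 0.40, 0.30}: chains are visited in
decreasing priority; each joins the first existing cluster whose
representative's similarity is ≥ the level, else founds a new cluster.
Member→representative similarity ≥ level therefore holds by
construction; member→member similarity within a cluster may be lower.

## 4. Domain assignment (`domain_assign`)

`assign_domains(seq, seq_backend, struct_backend, params)` implements a
recursive protocol over opaque search backends with the contract
`search(query, start, end) -> [SearchHit]`, all spans global and 1-based
(clipped to the queried interval):

1. Query the sequence backend; keep hits with `E < 0.01` **and**
   `Z > 4.5` (both strict).
2. If none survive, query the structure backend; keep hits with
   `Z > 4.5`.
3. Pick the best survivor by highest Z, then longest target, then
   smallest target id, and assign its span the hit's hierarchical
   address (`class.fold.superfamily.family`).
4. Recurse on each unassigned flanking interval of length > 30.
5. After recursion, unassigned runs of length ≤ 30 are merged into the
   neighbor whose adjacent assigned segment is longer (tie → the
   preceding segment); terminal runs merge into their only neighbor.

The result is a validated partition of `1..len(seq)` into labelled
segments. Backend exceptions are wrapped in `BackendError` naming the
stage. Correctness is established against a separately coded simulator
that operates on a per-residue address array.

## 5. Missing-region model selection (`loop_fill`)

For each missing region, a candidate generator proposes `n_candidates`
full-chain conformations. Selection is:

1. **Filter** — discard candidates with `rmsd_rest > 0.1 Å`; exactly
   0.1 Å survives. `rmsd_rest` is the RMSD over all heavy atoms of
   residues *outside* the missing regions, computed directly with **no
   superposition** (the non-loop part must be reproduced in the original
   frame). Atom-set mismatches are an error naming the offending residue.
2. **Select** — the lowest-energy survivor (ties → earliest generated).
   If no candidate survives, `NoModelError` reports the region and the
   number generated.
3. **Flag** — regions of length ≥ 7, and any terminal region, are marked
   low-confidence.

The built-in `StubGenerator` interpolates backbone positions linearly
between the anchor residues' CA atoms (3.8 Å steps for terminal
extensions) plus seeded jitter; per-region streams derive from
`SeedSequence([seed, start, end])` so results are reproducible and
independent across regions. Its `stub_energy` (summed squared consecutive
CA distances) is a stand-in for a statistical potential: *lower is
better* is the only property the selection logic uses, and both the
generator and the scorer are injection points for real backends.

## 6. Annotation (`annotate`)

- 8-state → 3-state reduction: H, G, I → H; E, B → E; T, S, blank/`-` → C.
- RSA = absolute accessibility / residue-type maximum (Rost–Sander
  table), clamped to 1.0 with a warning when the backend reports more
  than the maximum.
- Classes: exposed `RSA > 0.37`, buried `RSA < 0.069`, intermediate
  otherwise — both breakpoints strict, so 0.37 and 0.069 are
  intermediate.
- `annotate_chain` consumes a backend returning `(position, ss8,
  abs_acc)` rows on reference numbering; uncovered positions render as
  `-` in both tracks.

## 7. Synthetic fixtures (`fixtures`)

Chain fixtures lay residues along a line (3.8 Å CA spacing, idealized
backbone offsets, small seeded jitter) — realism is a non-goal; only the
bookkeeping the cleaning rules inspect matters. A `DefectSpec` plants
missing regions, MODRES residues, altLoc duplicates, extra atoms,
CA-only traces, or unknown residues, and the generator emits both the
file and the ground truth cleaning must recover.

Planted missing regions are only valid ground truth when they are the
*unique leftmost optimal* reconciliation. Because every full-threading
placement has maximal matches, the leftmost optimum equals the greedy
leftmost threading of the coordinate sequence; the generator verifies the
planted positions against an independent greedy threading and raises
`AmbiguousFixtureError` otherwise (the random generator redraws).

Family fixtures realize a target identity matrix by mutating each member
from its most-similar predecessor, bisecting on the substitution rate as
measured by the package's own aligner (18 iterations); the realized
matrix is recorded as ground truth and parent-pair targets must land
within ±3 identity points (`InfeasibleFamilyError` otherwise). Scripted
search backends replay planted hits clipped to the queried interval.

## Parameters and defaults

| Parameter | Default | Rationale |
|---|---|---|
| minimum chain length | 30 (strictly below removed) | shortest chain worth structural curation; 30 kept |
| maximum unknown fraction | 0.10 (strictly above removed) | tolerate sparse sequencing artifacts, not unknown-dominated chains |
| alignment gap penalty | −0.5 per skipped reference position | any negative value gives the same optimum (see §2); −0.5 keeps scores half-integral |
| identity levels | 0.90 … 0.30 in steps of 0.10 | standard culling ladder |
| length window | 10 residues | length differences below this are noise relative to resolution quality |
| sequence gates | E < 0.01 and Z > 4.5 | conservative sequence-homology acceptance |
| structure gate | Z > 4.5 | structure-alignment significance |
| recursion minimum | interval > 30 | below domain size; shorter leftovers are linker-like and merged |
| rmsd_rest bound | 0.1 Å (≤ kept) | candidate must reproduce the experimental part essentially exactly |
| low-confidence length | ≥ 7 | interpolation degrades with span; terminal regions always flagged |
| RSA breakpoints | 0.37 / 0.069 (strict) | exposed/buried thresholds on the Rost–Sander normalization |
| candidate budget | 500 per region | verification default; real generators may need more |

## Numerical choices

- The alignment DP table holds half-integer scores in float64, which are
  exactly representable, so score comparisons during traceback are exact.
- `rmsd_rest` accumulates in float64 with no superposition step, so it
  matches the direct formula to ~1e-16.
- Similarity values are exact IEEE quotients of integers
  (`identities / avg_len`), so cases like 50/75 are reproducible
  bit-for-bit.
- All randomness flows through `numpy.random.Generator` seeded
  explicitly; per-region loop streams use `SeedSequence` spawning. Seeds
  stay below 2³¹.

## Verification approach and problem sizes

Every nontrivial computation is checked against an independently coded
oracle rather than stored expectations: exhaustive monotone-placement
enumeration for the aligner (all small cases plus 10,000 random pairs,
reference length ≤ 12 — chosen so the `C(n, m)` enumeration stays
trivially fast), an insertion-sort re-derivation of the windowed priority
rule (all member sets of size ≤ 5 over a metadata grid, 12,615 cases), a
per-residue simulator for the domain protocol (500 random scripts, ≤ 4
hits, query ≤ 60 — small enough that scripts exercise every merge/recurse
branch), direct-formula RMSD, and planted ground truth for cleaning
(200 randomized fixtures) and clustering. These sizes are this package's
own verification budget, selected to finish in seconds on one CPU while
covering every branch; they are not tied to any external corpus.

## Limitations and open decisions

- The altLoc policy (first in file order) ignores occupancy; occupancy-
  or energy-based selection would need a policy extension point.
- The pairwise priority relation is non-transitive by design (length
  window); set ordering is therefore defined as the outcome of a stable
  comparison sort over the given input order rather than a total order.
- The stub loop generator produces physically meaningless but
  deterministic conformations; it exists to verify the selection
  protocol, not to model loops. DOPE-like scoring and fragment-based
  generation are intended as injected backends.
- Secondary-structure and accessibility values are consumed from a
  backend, never computed; the package only reduces and classifies them.
- Similarity uses a pure identity matrix rather than a substitution
  matrix; clustering levels are interpreted as identity fractions, not
  evolutionary distances.
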