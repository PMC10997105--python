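# Methods

## The amplification model

A template sequence is considered amplified by a primer pair when both
primers find binding sites with at most `max_mismatches` mismatches **each**
(the budget is per primer, not summed; default 3, matching ecoPCR's `-e`
semantics), and the region between the two footprints falls within the
pair's length bounds. Matching is ungapped: a mismatch is a position at
which the IUPAC base sets of the primer character and the template character
do not intersect, so a degenerate primer base matches any base in its set,
and a template `N` never contributes a mismatch (set-intersection matching
is symmetric and keeps the hit set monotone in the budget). Both strands are
scanned — the reverse strand by scanning the reverse complement and mapping
coordinates back — and every valid site pairing is enumerated.

All amplicon lengths in the package exclude the primer footprints: the
*metabarcode* is the inter-primer region only, oriented 5'→3' relative to
the forward primer, and the per-pair `min_len`/`max_len` bounds apply to it.

Assumptions and deliberate omissions: no thermodynamic annealing model, no
indel-tolerant matching, no amplification-bias simulation, and no special
prohibition of 3'-terminal mismatches in the engine (3' weighting belongs to
the refinement scan, where it expresses design preference rather than a
binding model).

### Multiple hits per record

When a record yields several valid site pairings, all are reported, but the
metrics use one *designated* hit per record: the shortest amplicon, ties
broken by smallest forward-site start, then strand `+` before `-`. This is a
deterministic stand-in for the preferential amplification of shorter
fragments in real PCR. How multi-hit templates ought to feed a resolution
metric is genuinely open; using all hits would let one sequence contribute
several metabarcodes and overweight repetitive templates.

## Metrics

- **Coverage** = records with ≥ 1 hit / records in the database.
- **Resolution at rank r**: designated metabarcodes are grouped by exact
  string; a group is *resolved* at r when all member lineages carry the same
  name there. Resolution = resolved groups / groups with a definite verdict.
  Each unique metabarcode counts once, regardless of how many sequences
  produce it. Groups containing a member with no annotation at r are, by
  default, excluded from numerator **and** denominator at that rank:
  reference databases legitimately contain family-only records, and an
  annotation gap is not evidence that a primer fails to discriminate. The
  stricter convention (count such groups as unresolved) is available via the
  `incomplete` argument / `--count-incomplete-as-unresolved`. Because
  lineages are required to be prefix-complete below family (species implies
  genus implies family), resolution is monotone: species ≤ genus ≤ family.
- **Specificity** is computed on a mixed-phylum database after retaining one
  sequence per species (seeded random draw, default seed 20240405, recorded
  in the run manifest) so over-sequenced model species cannot dominate:
  specificity = amplified target-phylum sequences / all amplified sequences,
  reported together with the number of distinct target species amplified.
  Records with no species annotation are kept as their own singletons.

## Conservation matrices (sequence logos)

For each designated hit the template region under a primer footprint is
collected, oriented 5'→3' as the primer reads it. Per position, nucleotide
frequencies are computed over {A, C, G, T}; template ambiguity codes are
dropped from that position's count (they encode uncertainty, not an
observed base). Information content is 2 − H with H the base-2 Shannon
entropy (0·log 0 = 0): exactly 0 bits for a uniform position, exactly 2 for
a perfectly conserved one. No small-sample correction is applied by default
— it would break the exact 0–2 range semantics — but the classic
e_n = 3/(2 ln 2 · n) correction is available behind a flag for parity with
logo-rendering tools. The matrix TSV (`position, A, C, G, T, bits, n`) is
the contract; stacked-letter rendering is a cosmetic extra.

## Primer-refinement scan

Windows are collected with a flank (default 10 bases each side) so that
positions just outside the current footprint can be examined. Per position
the scan reports target and non-target information content and
`delta = H_nontarget − H_target`: positive where the target is conserved and
the non-target variable, i.e. where a primer base would discriminate. A
linear weight ramp from 1.0 (5' end) to 3.0 (3' end) encodes the greater
disruptiveness of 3'-proximal mismatches; both endpoints are configurable,
and any non-decreasing ramp preserves the ranking semantics.

`propose_variants` enumerates footprint shifts up to `max_shift` (≤ flank)
and up to `max_edits` re-specifications of primer positions to the minimal
IUPAC code covering target bases with frequency ≥ 5 % (the cutoff bounds
degeneracy inflation). Candidates are ranked by (estimated target coverage,
weighted-delta sum over the footprint), compared lexicographically; ties
break toward fewer edits, then lexicographically smaller sequence. This is a
defined, reproducible refinement procedure — the published optimisations it
resembles do not state an objective function or stopping rule, so no attempt
is made to reconstruct any particular primer.

## Resolution-vs-length regression

Ordinary least squares of species-level resolution on the natural log of
mean metabarcode length, via statsmodels. R², F and P are invariant to the
log base. df = (1, n − 2), and F = R²(n−2)/(1−R²) is asserted as an internal
consistency check (skipped at a numerically perfect fit). Reports with no
amplification are dropped; fewer than three usable points is an error.
On the packaged 15-pair panel metrics the fit is R² = 0.479,
F(1,13) = 11.93, P = 0.0043 — the values the tests and the `regress`
subcommand print. Note that the packaged metrics are rounded to the
precision at which they were reported (resolutions to 2 d.p., lengths to
1 d.p.), so regression statistics computed from them carry that rounding.

## Synthetic databases and what they show

The generator emulates the structure the evaluation assumes, not real 18S
biology. Each record is

    left flank + forward site + variable region + revcomp(reverse site) + right flank

with deterministic taxonomy names (`Fam001`, `Gen001_01`, `Sp001_01_02`).
Defaults (one choice, fixed): 8 families × 3 genera × 4 species × 2
sequences = 192 records, mirroring the shape ratios of a curated nematode
18S database (≈ 3 genera/family, ≈ 4 species/genus, ≈ 2 sequences/species)
at desk scale; variable region 150–380 bp; flanks 20–60 bp; per-site
substitution probability 0.05 genus-level and 0.02 species-level down a
family → genus → species tree.

Binding sites are the primer with degeneracies resolved to concrete bases
and exactly *k* positions mutated to bases **outside** the primer's IUPAC
set at that position, so a sampled mismatch count is always fully realised.
The counts are drawn from the configured distribution ({0,1,2,3,≥4} →
probability, separate target and non-target maps) by largest-remainder
quota, so the configured fractions hold exactly on every instance, and are
drawn per *species* — all sequences of a species share their sites and
variable region — with the forward and reverse draws paired comonotonically
(rank-aligned). Consequences: a clade's amplifiable fraction equals exactly
the probability mass on counts ≤ 3; two clades with identical distributions
amplify identically; and amplifiability is a species property, making
post-dedup specificity independent of the dedup seed and exactly
bookkeepable. A configurable fraction of within-genus species pairs is
forced to share a variable region, giving known species-level resolution
deficits. Default mismatch distributions: target {0: .55, 1: .2, 2: .1,
3: .05, ≥4: .1} (coverage 0.9, in the range reported for well-matched 18S
primers), non-target {0: .05, 1: .05, 2: .1, 3: .1, ≥4: .7}.

The ground-truth object recomputes expected coverage, per-rank resolution
and specificity by pure bookkeeping, independently of the scanning engine,
and the tests additionally validate it against a naive brute-force scan.
What passing these tests shows: the engine and metrics compute exactly what
they claim on data matching their assumptions. What they do not show:
performance on real databases, where lineage annotation is incomplete,
binding-site variation is phylogenetically structured rather than planted,
sequences contain ambiguity codes and partial gene copies, and primers may
bind at unplanned loci. There is a small, seed-dependent possibility of a
coincidental binding site in random flank or inter-primer sequence; at the
fixed test seeds no such collision occurs, and the brute-force
cross-check would surface one.

## Numerical and I/O conventions

- Coordinates are 0-based half-open internally, 1-based inclusive in
  human-facing tables.
- Sequences are uppercased on read and U → T; lineages come as
  `record_id<TAB>rank=name;...` or a 7-column fixed-rank TSV.
- Records failing structural validation (non-IUPAC characters, empty
  sequence, lineage not prefix-complete below family) and records outside
  the target phylum are excluded with machine-readable reason codes, never
  silently; kept + excluded always partition the input.
- Degenerate inputs: empty database → error for coverage; zero amplification
  → coverage 0 with undefined (None/`NA`) resolutions and lengths; a rank at
  which every group is incomplete → undefined with a warning; an all-ambiguous
  logo column → NaN row.
- All randomness (generator, dedup draw) is seeded and surfaced in run
  manifests; identical seed + config reproduce byte-identical outputs.

## Known limitations

- No indels in primer matching; a bulged-primer hit that real PCR might
  tolerate is missed.
- The engine treats all mismatch positions equally; 3' weighting exists only
  in the design scan.
- Resolution depends entirely on the reference database: a genus represented
  by one species trivially shows species-level resolution.
- The variant proposer explores a bounded neighbourhood (shift + consensus
  edits) of an existing primer; it does not design primers de novo.
- Synthetic phylogenies use star-like divergence within ranks, not realistic
  branch lengths or rate heterogeneity.
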