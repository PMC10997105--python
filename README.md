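# primerval

In silico evaluation of metabarcoding primer pairs.

DNA metabarcoding of nematode communities (and of eukaryotes generally)
depends on choosing a primer pair that amplifies most of the target group
(**taxonomic coverage**), yields amplicons that distinguish closely related
taxa (**taxonomic resolution**), and amplifies as little non-target DNA as
possible (**specificity**). `primerval` implements the computational side of
that assessment as a reusable library and command-line tool:

- an ecoPCR-style **in silico PCR engine**: degenerate IUPAC primer matching
  with a per-primer mismatch budget (default 3), amplicon length bounds, and
  both strands scanned; the metabarcode is the inter-primer region excluding
  the primer footprints;
- **metrics** over a reference database (FASTA + lineage table): coverage =
  amplified sequences / total; resolution at rank *r* = the proportion of
  unique metabarcodes whose producing taxa all share one taxon name at *r*
  (species, genus, family); specificity = target-phylum fraction of amplified
  sequences after retaining one sequence per species;
- per-position **conservation matrices** (sequence logos): information
  content 2 − *H* in bits, from 0 (uniform) to 2 (perfectly conserved);
- a **primer-refinement scan** comparing target vs non-target variability in
  and around a primer's binding region (3'-weighted), with ranked variant
  proposals;
- the **resolution-vs-length regression**: OLS of species-level resolution
  on log mean metabarcode length, reported as R², F(1, n−2) and P;
- a **synthetic reference-database generator** with exact per-record ground
  truth for every metric, used throughout the test suite.

A packaged panel of 15 published 18S rDNA primer pairs for nematode
metabarcoding (with literature amplicon-length bounds) and their reported
evaluation metrics ship as fixtures.

## Worked example

```python
from primerval import (SyntheticConfig, generate_db, amplify_db, build_report,
                       load_default_primer_panel, load_reference_panel_metrics,
                       resolution_length_regression)

panel = load_default_primer_panel()
euka02 = next(p for p in panel if p.name == "Euka02")

config = SyntheticConfig(seed=7, shared_metabarcode_fraction=0.2)
records, truth = generate_db(config, euka02)
report = build_report(amplify_db(records, euka02, max_mismatches=3), records)
print(f"coverage          {report.coverage:.3f}  (ground truth {truth.expected_coverage():.3f})")
print(f"mean length       {report.mean_len:.1f} bp")
print(f"resolution  sp/ge/fa  {report.resolution_species:.3f} / "
      f"{report.resolution_genus:.3f} / {report.resolution_family:.3f}")

fit = resolution_length_regression(load_reference_panel_metrics())
print(f"panel regression  R^2={fit.r_squared:.3f}  "
      f"F(1,{fit.df[1]})={fit.f_stat:.2f}  P={fit.p_value:.4f}  slope={fit.slope:.4f}")
```

prints

```
coverage          0.906  (ground truth 0.906)
mean length       244.4 bp
resolution  sp/ge/fa  0.899 / 1.000 / 1.000
panel regression  R^2=0.479  F(1,13)=11.93  P=0.0043  slope=0.0547
```

The synthetic database (192 sequences, 8 families × 3 genera × 4 species ×
2 sequences) was built so that a known fraction of binding sites carries
more than 3 mismatches — the engine's coverage matches the generator's
bookkeeping exactly. 20 % of within-genus species pairs were forced to share
a metabarcode, which depresses species-level resolution (0.899) while genus-
and family-level resolution stay perfect. The regression over the packaged
panel metrics confirms the positive association between species-level
resolution and log mean metabarcode length (longer markers resolve species
better).

## Command line

Every stage is exposed as a subcommand of `primerval`; each writes its
tables plus a `manifest.json` (version, parameters, seeds, input checksums)
sufficient to reproduce the outputs bit-identically:

```bash
primerval simulate --seed 7 --mixed --out sim/
primerval pcr --db sim/db.fasta --lineage sim/lineage.tsv --max-mismatches 3 --out pcr/
primerval report --db sim/db.fasta --lineage sim/lineage.tsv \
    --target-phylum Nematoda --out bundle/
primerval logo --db sim/db.fasta --lineage sim/lineage.tsv \
    --primer Euka02 --side forward --target-phylum Nematoda --out logos/
primerval regress --reports bundle/report.tsv --out regression.json
```

Subcommands: `pcr`, `coverage`, `resolution`, `specificity`, `logo`,
`design-scan`, `regress`, `simulate`, `report`.

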