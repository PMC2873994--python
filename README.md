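# hlassp

A toolkit for real-time PCR-SSP (sequence-specific primer) class I HLA
genotyping, built around a published East-African typing panel addressing the
49 most common HLA-A, -B, and -C alleles of the region.

The package covers the full computational side of the assay:

- **`hlassp.panel_model`** — machine-readable panel (107 primers, 7 probes, 81
  reactions across the three loci) with loading, canonical serialization, an
  invariant audit, and the allele × reaction reactivity matrices. Primer
  sequences keep the bracketed locked-nucleic-acid notation of the source
  tables on disk.
- **`hlassp.typing_engine`** — genotype union-pattern enumeration and
  uniqueness audit (105 unique HLA-A patterns, 273/276 distinct HLA-B
  patterns with exactly three collision groups, 78 unique HLA-C patterns),
  ΔCt reactivity calling with per-reaction cutoffs and internal-standard
  failure handling, pattern decoding with mismatch tolerance, and
  carrier-level sensitivity/specificity/PPV/NPV.
- **`hlassp.insilico_ssp`** — binary reactivity prediction from allele
  template sequences: IUPAC-degenerate primer matching with strict 3'-end
  and LNA rules, amplicon-length bound (<250 bp), and probe containment.
- **`hlassp.popgen`** — allele/carrier frequencies, addressed-allele
  coverage, a Monte-Carlo exact Hardy–Weinberg test, Cavalli-Sforza–Bodmer
  chord distances, neighbor-joining dendrograms (Newick), principal
  coordinates analysis, allele aliasing, and Fisher exact /
  Freeman–Halton contingency tests.
- **`hlassp.synthetic_data`** — seeded simulators: genotype tables under
  Hardy–Weinberg equilibrium, Ct plates with a configurable noise model, and
  synthetic allele templates realizing arbitrary target reactivity matrices.
- **`hlassp.cli_io`** — the `hlassp` command-line interface and the CSV/TSV/
  FASTA/Newick format glue.

## Command-line usage

```sh
# panel census, invariant audit, and genotype-pattern uniqueness report
hlassp audit
hlassp audit --locus HLA-B --json audit.json

# simulate 100 samples per locus under HWE plus matching Ct plates
hlassp simulate --n 100 --seed 7 -o sim/

# reactivity calls and genotype decoding from a Ct plate CSV
hlassp call --plate sim/plate_a.csv -o calls.tsv
hlassp decode --plate sim/plate_a.csv --locus HLA-A -o genotypes.tsv

# carrier-level validation metrics against a reference genotype table
hlassp validate --plate sim/plate_a.csv --truth sim/genotypes.tsv \
    --locus HLA-A -o metrics.tsv

# population genetics: frequencies, coverage, HWE; distances/NJ/PCoA
hlassp popgen --genotypes sim/genotypes.tsv -o pop/
hlassp popgen --freqs many_populations.tsv -o dist/

# in-silico reactivity prediction from FASTA templates
hlassp predict --fasta templates.fa --locus HLA-A -o predicted.tsv
```

Ct plate CSVs have columns `sample_id, reaction_id, ct_specific, ct_internal`;
`Undetermined` is read as the maximum Ct of 60. Genotype and truth tables are
TSV with `sample_id, locus, allele_1, allele_2`.

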