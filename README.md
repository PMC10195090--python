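# hybridreg

Allele-specific expression (ASE) analysis of F1 hybrids between two
diverged lineages, built for the *Anastrepha fraterculus* / *A. obliqua*
style of cross design: two parental lines, reciprocal hybrids OF and FO
(female parent listed first) where the FO direction yields only female
progeny, three biological replicates per cross, and hybrid RNA-seq reads
assigned to their parental allele of origin via fixed inter-specific SNPs.

Given a transcript × sample count matrix in which every hybrid library is
split into two allele columns, the package

* classifies **gene-expression inheritance** (conserved, additive,
  dominant for either parent, over-/underdominant) from three
  negative-binomial contrasts of total expression;
* classifies **cis/trans regulatory divergence** (conserved, cis-only,
  trans-only, cis + trans, cis × trans, compensatory, ambiguous) from
  parental expression divergence (ED), allelic imbalance in hybrids (AI)
  and a binomial ratio test of hybrid vs parental allele ratios;
* computes the **cis index** and flags transcripts whose male ASE pattern
  is consistent with X linkage;
* estimates **molecular divergence**: per-SNP differentiation *d*, the
  fixed-SNP fraction *d*<sub>xy</sub>, and Ka/Ks by Nei–Gojobori (1986)
  counting with Jukes–Cantor correction;
* relates divergence and the cis index to the expression categories with
  square-root-scale linear models honouring the incomplete (no FO male)
  design;
* ships a **synthetic-data generator** with known cis/trans ground truth,
  a power analysis, and a mapping-bias diagnostic.

## The model in brief

Because both alleles of an F1 hybrid share a single trans-acting
environment, the hybrid allele ratio isolates the cis component of
regulatory divergence:

    Rh = log2(A1/A2)          cis component (hybrid allele ratio)
    Rp = log2(P1/P2)          total divergence (parental ratio)
    T  = Rp − Rh              trans component
    I_cis = |Rh| / (|Rh| + |T|)

Counts are filtered at 3 cpm in ≥ 2 of 3 replicates per comparable group,
remaining zeros are raised to one, libraries are TMM-normalized, and all
NB tests share a common dispersion estimated by conditional maximum
likelihood.  A transcript is significant in a contrast when its BH-FDR
q < 0.05 **and** |log2FC| > 1.25 (both thresholds configurable).

## Worked example

```sh
hybridreg simulate --n-transcripts 1000 --effect 3 --seed 7 --out-dir sim
cat > run.yaml <<EOF
counts: sim/counts.tsv
sample_sheet: sim/samples.tsv
out_dir: out
stat:
  dispersion: 0.05
EOF
hybridreg run --config run.yaml
```

prints `done: 1000/1000 transcripts analyzed -> out`, and `out/report.md`
begins:

```
## Regulatory categories
- OF F (n=1000): conserved 250 (25.0%), trans_only 250 (25.0%),
  cis_only 249 (24.9%), cis_x_trans 125 (12.5%), compensatory 125 (12.5%),
  cis_plus_trans 1 (0.1%)
```

The simulated mix was 25% conserved / 25% cis-only / 25% trans-only /
12.5% cis×trans / 12.5% compensatory, so the classifier recovered the
generating architecture almost exactly (one cis-only transcript leaked
into cis + trans).  The output directory also holds per-contrast test
tables (`test_*.tsv`), `inheritance.tsv`, `regulatory.tsv` (with Rh, Rp,
T, I_cis and the X-linkage flag), `category_tallies.tsv`, the association
GLM coefficient tables, and `manifest.json`, which records everything
needed to reproduce the run byte-for-byte.

The same analyses are available as a library:

```python
import hybridreg as hr
specs = hr.architecture_mix(1000, {"conserved": .5, "cis_only": .5})
m, sheet, truth = hr.simulate_counts(specs, hr.SimConfig(seed=1))
bundle = hr.analyze(m, sheet)
bundle.regulatory.head()
```

## Input formats

* counts: TSV, header `transcript_id<TAB><sample_id>...`, integer reads.
* sample sheet: TSV/CSV with columns `sample_id, line, sex, replicate,
  allele` (`line` ∈ {frat, obliq, OF, FO}; `allele` ∈ {frat, obliq, none}).
* aligned CDS pairs: FASTA with ids `<transcript>_frat` / `<transcript>_obliq`.
* SNP table: TSV with `transcript_id, position, freq_frat, freq_obliq`.

All outputs are TSV with the column orders shown in the respective module
docstrings; see `docs/methods.md` for the statistical details and design
choices.
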