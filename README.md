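# opsinkit

A toolkit for the analytical chain of a color-vision study of dim-light
mammals: spectrophotometric lambda-max estimation of visual pigments,
tuning-site-based lambda-max prediction from opsin coding sequences,
per-branch dN/dS purifying-selection tests, and 24-h ethogram/activity
analysis. A synthetic-data module generates inputs with the statistical
structure each stage assumes, so the whole pipeline is testable offline.

## Modules

| module | what it does |
|---|---|
| `opsinkit.synthgen` | Govardovskii-template pigment scans (dark/bleached, replicated, noisy), accept/reject codon evolution on a rooted 3-taxon tree, two-state persistent activity tables |
| `opsinkit.spectra` | replicate averaging, difference spectra, natural cubic smoothing splines (knots at every point, effective-df smoothness control), per-replicate lambda-max with mean +/- SD, Welch's t-test |
| `opsinkit.tuning` | tuning-site extraction by global alignment to a numbering reference, additive five-site LWS lambda-max prediction, SWS2 key-site comparison, IUPAC-ambiguity haplotype expansion |
| `opsinkit.molevol` | Fitch parsimony ancestral codons, Nei-Gojobori site/difference counting, per-branch one-sided Fisher's exact test of pN vs pS |
| `opsinkit.behavior` | light/dark + day-type annotation, multi-label ethogram activity budgets, paired Wilcoxon light-vs-dark tests with Bonferroni correction, day-type chi-squared tests |

## Command-line interface

Each module installs a console script:

```bash
# simulate a replicated dark/light measurement and estimate lambda-max
synthgen spectra --seed 1 --lambda-max 443 --out scan.csv
spectra lambdamax scan.csv --method dark --window 380,520 --out est.json
spectra compare estA.json estB.json          # Welch's t-test

# simulate codon evolution and run the branch test
synthgen codons --seed 1 --n-codons 300 --omega 0.1 --out aln.fasta
molevol branchtest aln.fasta aln.nwk --outgroup C --out-tsv branches.tsv

# tuning sites and five-site-rule prediction
tuning predict lws.fasta --gene LWS
tuning sites sws2.fasta --gene SWS2 --tsv
tuning compare a.fasta b.fasta --gene SWS2

# simulate activity and analyze it
synthgen activity --seed 1 --days 27 --out activity.csv
behavior lightdark activity.csv
behavior daytype activity.csv --bin-hours 3
behavior budget activity.csv
```

## Notes

- The packaged numbering references (`opsinkit/data/*.fasta`) are
  synthetic scaffolds that define site numbering for tests and examples;
  substitute authoritative reference proteins for production analyses.
- The LWS shift table (`opsinkit/data/lws_shift_table.json`) is data,
  not code: base 560 nm with additive single-substitution shifts after
  Yokoyama and colleagues' five-site rule.
- Smoothing uses an effective-degrees-of-freedom target (default 10% of
  the point count), a documented approximation to R's `smooth.spline`
  with `spar = 1`, not a bit-exact port.
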