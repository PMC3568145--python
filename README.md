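# oncocis

Rank cancer genes by the *in cis* expression impact of their copy-number
alterations.

Recurrence-based methods for calling copy-number drivers (GISTIC-style) miss
low-recurrence events and ignore whether an alteration actually moves the
gene's expression. `oncocis` takes the complementary view: a gene whose
amplifications (or deletions) consistently push its expression up (or down)
— relative to both normal tissue and diploid tumors — is a better driver
candidate than a bystander riding along in an altered region, however
frequent the alteration.

## The statistic

For gene *i* and each tumor *j* carrying a multi-copy amplification (status
+2) or homozygous deletion (−2), an expression impact score is computed
against a reference group R:

    EIS_ij = (exp_ij − M_R) / (IQR_A + IQR_R)

where `M_R` is the reference median of the gene's expression and `IQR_A`,
`IQR_R` are the interquartile ranges of the altered and reference groups.
Two references are used: the normal samples (→ `EIS_NORMAL`) and the tumors
diploid for that gene (→ `EIS_TUMOR`). The observed per-gene score is the
median EIS over its `n` altered tumors, standardised against an internal
null: the mean and SD of medians of `n` values resampled (10,000×, with
replacement) from the pool of all EIS values of the same direction and
reference,

    Z = (EIS_obs − mean_bg) / sd_bg .

The two standard scores are combined with equal weights by Stouffer's
method, `Z_COMB = (Z_NORMAL + Z_TUMOR)/√2` (just `Z_TUMOR` if no normals
exist), converted to a one-sided normal p-value (upper tail for
amplifications, lower for deletions) and Benjamini–Hochberg corrected within
each alteration set. Amplifications and deletions are ranked separately —
`Z_COMB` descending and ascending respectively — because deletions move
expression less than multi-copy gains.

The package also bundles:

* a **circular binary segmentation** (CBS) caller turning probe-ordered
  log-ratio profiles into constant-mean segments (permutation/Monte-Carlo
  significance) and discrete gene calls at ±0.2;
* a **synthetic-data generator** (10,000 genes, 90 CNV genes in clustered
  regions, 54 expression-coupled true positives, linear/stepwise/sigmoid
  dosage→expression models, wave-like baseline artifacts);
* a **benchmark harness** computing sensitivity, specificity and Matthews
  correlation over repeated simulate → segment → score trials.

## Worked example

```sh
python examples/rank_altered_genes.py
```

builds a 2,000-gene cohort (40 tumors, 8 normals, 60 CNV genes of which 20
are dosage-coupled) and prints both ranked lists; the top of the
amplification output:

```
AMP: 36 genes scored, 9 significant
        gene  n_altered  eis_normal  eis_tumor  z_normal  z_tumor  z_comb  p_value  corrected_p
rank
1     g00815          8       2.362      1.497     7.698    5.709   9.480      0.0          0.0
2     g00810          8       2.131      1.305     6.872    4.895   8.320      0.0          0.0
...
-> 9/9 significant genes are true dosage-coupled genes
```

Gene `g00815` is amplified in 8 tumors whose expression sits ~2.4 combined
IQRs above the normal-sample median and ~1.5 above the diploid-tumor median;
both biases are far beyond the resampled null (Z 7.7 and 5.7), so the
combined score 9.48 puts it at the top of the list. All nine genes passing
corrected p ≤ 0.05 are true positives of the simulation.

Other entry points: `examples/segment_and_call.py` (CBS on a noisy profile),
`examples/benchmark_trial.py` (one full 10,000-gene pipeline trial), and the
`oncocis` command with `run`, `segment`, `simulate` and `benchmark`
subcommands, e.g.

```sh
oncocis run --expr expr.tsv --cna cna.tsv --annot annot.tsv --out-dir out \
    --samplings 10000 --seed 1
```

which writes `amplifications.tsv` and `deletions.tsv`.

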