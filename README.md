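# selocus

Killer-protector transmission genetics of the rice *Se* hybrid-sterility
locus: predict gamete viability and offspring genotype distributions, infer
killing parameters from segregation counts, classify pollen-fertility
phenotypes, and type *Se*-locus sequences into their evolutionary classes.

## The problem

Hybrids between the two subspecies of Asian cultivated rice, *indica* and
*japonica*, are often semi-sterile, which blocks the use of their strong
heterosis in breeding. A major cause is the *Se* locus on chromosome 12: a
large presence-absence variation (PAV) carrying two adjacent genes, a
**sporophytic pollen killer** (ORF3) and a **gametophytic protector**
(ORF4). In a heterozygote between a PAV-present haplotype *E* and the
PAV-absent *japonica* haplotype *T*, the killer — expressed by the diploid
plant — attacks *all* gametes, and only those carrying the protector
survive. Pollen carrying *T* has no protector and is aborted, so a *T/E*
plant shows ~50% pollen fertility and transmits no *T* allele through
pollen.

The model: a gamete's survival is `1 − k·A·(1−P)`, where `A` is the
sporophyte's killer activity, `P` the gamete's own protection, and `k` the
sex-specific killing efficiency (`km` for pollen, default 1; `kf` for
ovules, default 0 and estimable from testcross data). The surviving
male-pool mass is the predicted pollen fertility; offspring distributions
are the outer product of the selected female and male gamete pools. A
female *T/E* × *E/E* testcross yields *T/E* : *E/E* in proportions
`(1−kf) : 1`, so observed counts 54:74 give `k̂f = 1 − 54/74 ≈ 0.270`.

This package is aimed at quantitative and population geneticists working on
transmission ratio distortion, selfish genetic elements and hybrid-sterility
loci, and at breeders evaluating *Se* haplotypes for compatible-line design.

## Worked example

Self a *T/E* heterozygote under complete pollen killing — the *T/T* class
disappears and segregation is 0 : 1 : 1 instead of Mendelian 1 : 2 : 1:

```
$ selocus predict-cross --female T/E --male T/E --km 1
class   probability
E/E     0.5
T/E     0.5
```

Fit the female killing efficiency to the observed 54:74 testcross table
(`counts.tsv` with columns cross_id, class, count):

```
$ selocus fit --counts counts.tsv --female T/E --male E/E --free kf --km 1
{
  "results": {
    "estimates": { "kf": 0.27027027401509895 },
    "loglik": -87.1539183701316,
    "ci95": { "kf": [0.0, 0.48828403745968474] },
    "identifiable": { "kf": true },
    "n_obs": 128,
    "lrt_vs_mendelian": {
      "statistic": 3.1378414830827808, "df": 1, "p_value": 0.0764949814518334
    }
  },
  ...
}
```

The point estimate is the closed form `1 − 54/74 = 10/37`; the confidence
interval includes 0, consistent with the Pearson test of the same table
(χ² = 3.125 < 3.84 at df 1), so female distortion is suggestive but not
significant at this sample size — milder, in any case, than the complete
male distortion. The likelihood machinery, not the χ² table, is what
scales to joint (km, kf) fits over multiple crosses.

From the library, the transgene-rescue predictions and the 8-class F2
expectation (240 progeny of a selfed *T/E* plant hemizygous for a
protector transgene *G*):

```python
>>> from selocus import parse_genotype, pollen_viability, cross, expected_counts
>>> from selocus import TransmissionParams
>>> params = TransmissionParams(km=1, kf=0)
>>> pollen_viability(parse_genotype("T/E"), params)
0.5
>>> pollen_viability(parse_genotype("T/E;G/-"), params)   # one protector copy
0.75
>>> f2 = cross(parse_genotype("T/E;G/-"), parse_genotype("T/E;G/-"), params)
>>> import pprint; pprint.pprint(expected_counts(f2, 240))
{'E/E;-/-': 20.0,
 'E/E;G/-': 40.0,
 'E/E;G/G': 20.0,
 'T/E;-/-': 20.0,
 'T/E;G/-': 60.0,
 'T/E;G/G': 40.0,
 'T/T;G/-': 20.0,
 'T/T;G/G': 20.0}
```

Eight classes (df 7), including the *T/T* classes that only the transgene
makes recoverable. End-to-end synthetic pipeline:

```sh
selocus simulate-panel --out-fasta panel.fasta --out-truth truth.tsv \
        --out-annotation locus.yaml --seed 1
selocus se-type --fasta panel.fasta --annotation locus.yaml --taxa truth.tsv \
        --out typed.tsv
selocus compat --type-a Type3 --type-b noPAV   # 1.0: the neutral haplotype
```

## Layout

- `src/selocus/transmission.py` — gamete pools, viability, crosses
- `src/selocus/fertility.py` — pollen-fertility classification and histograms
- `src/selocus/inference.py` — χ² tests, MLE of (km, kf), likelihood-ratio test
- `src/selocus/setyping.py` — in-silico PCR, ORF translation, Se-type rules
- `src/selocus/synth.py` — synthetic loci, panels, progeny, fertility data
- `src/selocus/io.py`, `config.py`, `cli.py` — formats, config, CLI
- `docs/methods.md` — model assumptions, defaults and limitations
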