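# mortcode

Automated coding of the **underlying cause of death (UCD)** from
ICD-10-coded death certificates, for epidemiologists and mortality
statisticians who work with multiple-cause-of-death data.

A death certificate lists the causal chain of death in Part I (up to four
lines, immediate cause first, underlying cause on the last used line) and
other significant conditions in Part II (two lines), each line a sequence
of ICD-10 codes. National statistics offices reduce every certificate to a
single UCD by applying WHO selection rules — a process handled by
rule-based expert systems that reject complex certificates to human
coders. `mortcode` implements the statistical alternative: treat UCD
selection as conditional density estimation,

```
P(UCD | CCD, A, Y, G; Θ) = f_Θ(CCD, A, Y, G)
```

where *CCD* is the causal chain encoded as a padded 6×20 grid of code
indices (Part I on rows 0–3, Part II on rows 4–5), *A* the age at death in
25 bins, *Y* the year of death (16 states), *G* the gender, and *f_Θ* a
convolutional network: one shared linear projection (embedding) of every
grid cell's code, demographic projections added to all non-padding cells, a
ReLU convolution stack, global max pooling, and a softmax regression over
the observed code vocabulary, trained with Adam on cross-entropy. The
model outputs a full probability distribution per certificate, so top-k
accuracy and confidence calibration come for free, and it needs no reject
option.

Because real multiple-cause mortality microdata are restricted, the
package includes a **synthetic certificate simulator** with a
deterministic **rule-based coding oracle** (general principle over an
acyclic causal-transition graph, Part II promotion à la HIV/Kaposi,
neonatal rules, year-dependent rule changes, rejects on competing causal
origins). The oracle provides exact, verifiable ground truth, which makes
the whole pipeline testable end to end at desk scale. The package also
implements the **reject-aware evaluation suite** (bootstrap CIs, dual
baseline accuracy, per-chapter error/prevalence, chapter confusion on
errors, top-k, calibration) and **year-harmonized recoding**: re-predict
an entire corpus with the year covariate fixed to one reference year,
removing coding-rule drift from cause-specific time series (e.g. the
published overdose grouping F11–F12, F14–F16, F19, X42, X62, Y12 is built
in as `overdose_groups()`).

See `docs/methods.md` for the model, the simulator's design and its
limitations.

## Worked example

`examples/train_and_evaluate.py` simulates a 200-code corpus (3,600
training certificates), trains a narrow coder for 30 epochs (~2 min on one
CPU core) and evaluates it against the rule oracle:

```
corpus: 3600 train / 400 val / 800 test, 200-code vocabulary

n = 800
accuracy = 0.9750  (95% CI 0.9625-0.9850)
top-1 accuracy = 0.9750
top-2 accuracy = 0.9875
second-choice accuracy on errors = 0.5000
mean argmax confidence: correct 0.9845, incorrect 0.6800

rule-based baseline on the same certificates:
  overall accuracy (rejects counted as errors) = 0.8675
  accuracy on nonrejected certificates         = 1.0000
  reject fraction                              = 0.1325
```

Reading this: the learned coder agrees with the deterministic rule system
on 97.5% of held-out certificates (the CI is a seeded percentile bootstrap,
B=1000). The rule-based baseline rejects 13% of certificates as too
complex; counting those as errors its accuracy is 0.87, excluding them it
is (by construction of the simulator) 1.0. Half of the coder's errors
still rank the correct code second, and its argmax confidence is much
higher when it is right than when it is wrong — the calibration behaviour
that lets predictions carry a usable confidence score.

Other examples, one per capability:

- `examples/simulate_and_code.py` — sample certificates, show oracle rule
  traces (general principle, promotion, neonatal/year remaps, rejects);
- `examples/grid_encoding.py` — the 6×20 grid encoding and age binning;
- `examples/harmonized_recoding.py` — a cause group remapped by a
  simulated 2012 rule change: the original-coding time series jumps at the
  threshold, the series recoded at fixed year 2015 does not.

A thin CLI drives the same pipeline from the shell
(`mortcode simulate | train | evaluate | recode`, configured by one YAML
file; see `mortcode --help`).

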