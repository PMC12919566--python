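# somnostate

Hidden-Markov-model inference of sleep/wake states from *Drosophila*
activity-monitor data.

Fruit-fly sleep is classically scored with a single rule — any run of five
or more minutes without an infrared beam crossing counts as sleep — which
collapses everything from quiet wakefulness to deep sleep into one state.
`somnostate` instead treats the per-minute beam-crossing counts of a
Drosophila Activity Monitor (DAM) as noisy emissions of a hidden Markov
chain over k discrete sleep/wake states, and infers the state sequence
minute by minute.  It is aimed at sleep and circadian researchers working
with Trikinetics DAM2 recordings, and at quantitative geneticists who want
state-duration phenotypes for panels of inbred lines.

## The model

For one fly and one day, raw counts are normalized to percent of the
daily total, giving observations $y_1,\dots,y_{1440}$.  A k-state HMM
with initial distribution $\pi$, row-stochastic transition matrix
$A = (a_{ij})$, and state-specific Gaussian emissions
$y_t \mid s_t = j \sim \mathcal N(\mu_j, \sigma_j^2)$ is fitted by
Baum–Welch EM (convergence at a relative log-likelihood change of
$10^{-8}$), decoded with the Viterbi algorithm, and relabeled so state 0
has the highest activity (wake) and state k−1 the lowest (deep sleep).

Because the EM surface has local maxima, each fly-day is fitted T times:
the first fit constrains direct transitions between the two extreme
states to $10^{-5}$, and every later fit redraws $\pi$ from a flat
Dirichlet.  The per-minute modal state across converged fits is the
consensus sequence, and the **ambiguity score** $(1 - n/T)\cdot 100$ —
with $n$ the multiplicity of the most frequent whole-day sequence —
quantifies restart disagreement.  The number of states is chosen by
fitting $k = 2,\dots,10$ and minimizing
$\mathrm{BIC} = p\ln n - 2\ell$ with $p = k^2 + 2k - 1$ free parameters
and $n = 1440$.

Downstream, per-state minutes (24 h, day, night) become phenotypes:
broad-sense heritability
$H^2 = (\sigma^2_L + \sigma^2_{SL})/(\sigma^2_L + \sigma^2_{SL} + \sigma^2_E)$
from among-line, line×sex and residual variance components, genetic
correlations $r_G = \mathrm{cov}_{ab}/\sqrt{\sigma^2_{La}\sigma^2_{Lb}}$
between traits, hypergeometric tests of 1-Mb genomic windows for
enrichment of trait-associated polymorphisms (BH-FDR adjusted), and
state-conditional arousal thresholds from mechanical-stimulus
experiments.

## Worked example

Simulate a small monitor, run the iterated fit, and quantify:

```sh
somnostate simulate --out-dir demo --flies 2 --days 3 --seed 4
somnostate fit --monitor demo/Monitor1.txt --meta demo/metadata.csv \
    --out demo/consensus.csv --k 4 --iterations 100 --n-days 2 --seed 1
somnostate quantify --consensus demo/consensus.csv --out demo/durations.csv
```

The `fit` step prints

```
wrote demo/consensus.csv (4 fly-days, 0 excluded)
```

meaning both flies contributed both analysis days (none were excluded for
failed convergence or missing minutes).  `demo/consensus.csv` holds one
row per fly-day-minute with the consensus state, its vote support out of
T = 100 restarts, and the day's ambiguity score; `demo/durations.csv`
aggregates to minutes per state per phase, e.g.

```
fly_id,state,phase,minutes
Monitor1_ch01,0,day,118.5
Monitor1_ch01,0,night,91.0
Monitor1_ch01,0,24h,209.5
Monitor1_ch01,1,day,91.5
...
```

Per fly the 24 h rows always total 1440 minutes.  The same library calls
are available in Python (`somnostate.fit_fly`, `somnostate.time_in_state`,
…) for scripted analyses.

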