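# posturemep

Analysis pipeline for **corticospinal presetting before postural
perturbations**: quantification of TMS-evoked motor potentials (MEPs) and
perturbation-evoked EMG responses from multi-channel surface EMG, with the
standard trial-exclusion and normalization rules of the paradigm and a
repeated-measures statistical battery.  Because human EMG from this protocol
is not redistributable, the package bundles a calibrated synthetic trial
generator that emulates the experiment's structure, so every stage is
testable end to end — and user data in the documented CSV-plus-sidecar layout
can be analyzed with the same pipelines.

## Who this is for

Motor-control and posture researchers who measure corticospinal excitability
with TMS around support-surface translations, and anyone who needs a
reference implementation of the standard analysis rules of that literature:

* **MEP**: peak-to-peak amplitude within 40 ms post-TMS, background-activity
  (BGA) RMS over the 50 ms pre-TMS, exclusion of trials with BGA > mean + 2 SD,
  1.5 × IQR outlier rejection, normalization by the maximal M-wave (M-max);
* **EMG response**: rectification and DC subtraction, ensemble averaging
  aligned on perturbation onset, amplitude normalization by a reference
  condition (0–250 ms post-onset), burst-onset detection by a sustained
  (10 ms) crossing of mean + 2 SD of background, and integrated EMG (iEMG)
  over 100 ms from onset;
* **statistics**: one- and two-way within-subject ANOVAs with per-effect
  error terms, Mauchly-gated Greenhouse–Geisser correction
  (ε = (Σλ)²/((k−1)Σλ²)), partial eta squared, and Bonferroni-corrected
  paired post hocs (per-test α = 0.005 for five conditions).

The protocol model is the five-condition design — NoPerturbation, Low
(anterior 3.5 cm / 10 cm/s), High (anterior 7.0 cm / 25 cm/s), Posterior
(posterior 7.0 cm / 25 cm/s) and Random (all three interleaved) — with 15
trials per condition (10 TMS "MEP" trials, TMS at 50 ms before perturbation
onset, and 5 no-TMS "catch" trials), recorded from tibialis anterior (TA),
soleus (SOL) and medial gastrocnemius (MG) at 4 kHz.

See `docs/methods.md` for the generator's model, calibrated defaults, and
every numerical convention.

## Worked example

Run the full chain — simulate a 12-subject cohort, quantify MEPs and
responses, run the statistics — with the packaged defaults:

```bash
posturemep run-all --seed 2019 --out results/demo
```

(equivalently `python -m posturemep.cli …`, or `run_all(default_config(), …)`
from Python).  The report begins:

```
MEP amplitude (% M-max), group mean +/- SE
  ...
  TA:
    NoPerturbation    6.66 +/- 1.31
    Low               8.10 +/- 1.24
    High             12.96 +/- 1.96
    Posterior         5.09 +/- 0.95
    Random           11.45 +/- 1.42
```

These are one cohort's TA MEP condition means: corticospinal drive is preset
highest before a predictable large anterior translation (High), intermediate
when the perturbation is unpredictable (Random), and near quiet-standing
levels before a posterior translation — the ordering the paradigm predicts,
with sampling scatter of a 12-subject draw around the calibrated population
means (9.7 / 14.8 / 7.3 / 11.5 % M-max for Low / High / Posterior / Random).
The ANOVA section shows what a well-powered cohort should show — a TA
condition effect and a TA predictability effect on the iEMG, and no
systematic SOL/MG modulation:

```
TA MEP        condition       F(4,44) = 10.74, p = 0.0002, pes = 0.494, eps = 0.605
TA iEMG 2-way predictability  F(1,11) = 32.46, p = 0.0001, pes = 0.747, eps = 1.000
SOL MEP       condition       F(4,44) = 0.84,  p = 0.5044, pes = 0.071, eps = 0.651
```

(`pes` = partial eta squared; `eps` = Greenhouse–Geisser epsilon; p-values
use ε-scaled degrees of freedom whenever Mauchly's test rejects sphericity.)
The output directory also contains `mep_trials.csv`, `mep_summary.csv`,
`response_trials.csv`, `response_onsets.csv`, `anova.csv`, `pairwise.csv` and
the exact `config.yaml` that reproduces the run.

Other subcommands: `simulate` (write a cohort dataset to disk), `mep` /
`response` / `stats` (stage-wise analysis of a dataset directory), and
`validate` (structural checks: manifest completeness, the 50-ms TMS-lead
geometry, sample-rate and channel-length consistency).

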