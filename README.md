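# nestmark

Peptide-marker authentication of edible bird's nest (EBN) from LC-QTOF-MS/MS
data.

EBN — the swiftlet nest sold as a high-value health food — is widely
adulterated with agar, gelatin, pork skin, tremella fungus, egg white, milk,
rice, starch or swim bladder, and low-grade grass nest is passed off as
high-grade white nest. Because EBN proteins are heavily glycosylated and
mostly insoluble, generic protein assays discriminate poorly; tryptic
peptide markers measured by high-resolution LC-MS do much better. `nestmark`
implements that workflow for analysts building or auditing such an assay:

- **Peptide chemistry** — monoisotopic masses, precursor m/z
  `(M + z·m_H)/z`, in-silico trypsin digestion (cleave after K/R, not
  before P), b/y fragment ladders, ppm comparison, and a fixed modification
  list (oxidation +15.994915 on M/W, deamidation +0.984016 on N/Q).
- **Cross-run alignment** — greedy agglomeration of centroided features
  under m/z (ppm) and retention-time tolerances, yielding per-class
  presence fractions and per-batch consistency fractions.
- **Marker selection** — the three-criterion rule: a marker peak must
  (1) appear only in digested EBN, never in an adulterant, (2) be a
  peptide, and (3) be consistently present across batches of its target
  class. Markers split into EBN-specific (E), white-specific (W) and
  grass-specific (G) panels, coded in retention-time order.
- **MS/MS confirmation** — candidate sequences are verified against
  spectra by singly-charged b/y-ion matching, with a one-modification
  hypothesis search to reconcile the precursor.
- **Quantification and verdicts** — ordinary-least-squares calibration
  `area = a·mg + b` with `R²`, LOD = 3σ/|a|, LOQ = 10σ/|a|, inverse
  quantification, intra/inter-day RSD and spike recovery, and a three-way
  product classifier: no marker detected → *fake*; any grass marker →
  *adulteration*; otherwise → *authentic*.
- **Synthetic data** — a ground-truthed generator emulating the study
  cohort (60 white + 10 grass EBN batches, nine adulterant classes, a
  planted 10 E + 13 W + 3 G panel, RT jitter, ppm m/z error, log-normal
  areas, dropout, noisy calibration lines and designed product panels).

## Worked example

```sh
$ nestmark simulate --seed 7 --out-features cohort.csv \
      --out-spectra spectra.mgf --out-truth truth.json
wrote 5805 features across 121 runs

$ nestmark select-markers --features cohort.csv --spectra spectra.mgf --out panel.csv
selected 26 markers (E=10, W=13, G=3)
```

The simulated cohort (121 injections: 60 white EBN, 10 grass EBN, 51
adulterant runs) carries a planted panel of 26 marker peptides. Alignment
groups the ~5800 peaks across runs; the selector recovers exactly the
planted panel — 10 markers shared by both EBN types, 13 found only in white
EBN, 3 only in grass EBN — and `panel.csv` lists each marker's code,
category, consensus m/z and retention time with its selection flags.

The same machinery runs on real data: any CSV with columns
`run_id,class,batch,mz,rt_min,area[,charge]` (plus MGF spectra and
`amount_mg,area` calibration tables) flows through `align`,
`select-markers`, `confirm`, `calibrate`, `quantify` and `classify`.

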