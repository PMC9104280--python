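# Methods

## The analytical problem

Edible bird's nest (EBN) authentication asks three nested questions of a
sample: does it contain EBN at all, is any of it low-grade grass nest, and
how much material is present? The measurement is a tryptic digest of the
whole sample (soluble and insoluble protein together) analysed by
LC-QTOF-MS in positive mode; the analysis reduces each injection to a list
of centroided features (m/z, retention time, peak area, optional charge).
`nestmark` operates entirely on such feature lists plus MS/MS peak lists —
it does no peak picking and no vendor-format decoding beyond a minimal
centroid-mzML reader.

## Peptide chemistry

Masses are monoisotopic throughout, appropriate for high-resolution QTOF
data: residue masses to five decimals, water 18.010565 Da, proton
1.0072765 Da. A peptide's neutral mass is the residue sum plus water plus
any modification deltas; the z-protonated precursor sits at
`(M + z·m_H)/z`. Trypsin cleaves C-terminal to K/R except before P.
Fragment ladders cover b₁..b_{n−1} and y₁..y_{n−1}; b_i carries the first
i residues plus z protons, y_i the last i residues plus water and z
protons, so complementary pairs satisfy
`mz(b_i) + mz(y_{n−i}) = M + 2·m_H` at 1+.

Modifications are explicit per-position annotations, never search-time
variables; the only enumeration is a deliberately tiny hypothesis space
(≤1 oxidation on M/W, ≤1 deamidation on N/Q, and their combination) used
to reconcile observed precursors during confirmation. This is the
smallest space that explains the observed marker masses — the grass
marker SDDSLWR only matches its observed precursor (447.6996, 2+) with
one oxidation, and the white marker AMESINSR approaches its observed
precursor only when deamidated. One printed variant of the white marker
(454.6704) is irreconcilable under this space; the package records all
printed variants side by side and does not guess which is a typo.

## Alignment and presence

Cross-run grouping is greedy agglomeration in descending area order: each
feature joins the existing group whose intensity-weighted consensus lies
within both tolerances (nearest in ppm wins, RT breaks ties), else it
seeds a new group, with at most one member per run per group. The result
is a partition of the input — every feature belongs to exactly one
aligned group — and is deterministic given the ordering rule. Defaults
are 20 ppm and 0.3 min: wide enough to absorb between-block drift of the
same peptide (the published screen itself prints the same marker ~14 ppm
and 0.13 min apart in different acquisitions), tight enough to keep
distinct tryptic peptides separate. There is no RT warping; cohorts whose
drift exceeds the RT tolerance need external correction first.

Presence is `area ≥ min_area` (default effectively any positive area,
because "high-sensitivity ion" has no published operational threshold and
the threshold is exposed as a parameter). Class presence fraction =
present runs / class runs; batch consistency = batches containing the
feature / batches of the class.

## Marker selection

A feature becomes a marker when it is absent from every adulterant class
(maximum tolerated adulterant presence fraction defaults to 0), is a
peptide, and is batch-consistent in its target class (default consistency
1.0 — present in every batch, relaxable for noisy data). Categories are
exclusive: E = present in both white and grass EBN, W = white only,
G = grass only; for E the consistency requirement is satisfied by either
EBN class, matching the published screen's "either 60 white or 10 grass
batches" convention. Codes are assigned in ascending RT within category
(m/z breaks ties), reproducing the published numbering. Tightening any
criterion can only shrink the panel.

Peptide-ness uses the best available evidence per feature: an associated
MS/MS spectrum in which ≥3 fragment peaks participate in pairwise mass
differences equal to residue masses (20 ppm); otherwise a charge call,
where ≥2 says peptide and a bare 1+ call says not (multiply charged
precursors are the signature of tryptic peptides under ESI, while
singly charged small ions are dominated by non-peptide background);
otherwise a configured default — permissive for encoded presence/absence
tables whose peptide column reflects manual curation.

The encoded 58-feature reference screen contains one row whose printed
adulterant flag contradicts its printed marker code; the canonical
encoding follows the code and logs the deviation, and a strict-flag mode
keeps the printed flag instead (yielding 25 rather than 26 markers). The
package reports the conflict rather than silently correcting it anywhere
else.

## Confirmation

`confirm_sequence` picks the modification hypothesis minimising the
absolute precursor ppm error, then counts singly-charged b/y ions matched
within an absolute fragment tolerance (default 0.05 Th — absolute rather
than relative because QTOF fragment accuracy is roughly constant across
the fragment range). Pass requires precursor |ppm| ≤ 25 and matched
fraction ≥ 0.5. Candidates come from outside (database search, de novo
sequencing, literature); the package performs no database-wide search,
protein inference or FDR estimation.

## Quantification and classification

Calibration is unweighted ordinary least squares of peak area on analyte
amount, requiring ≥3 distinct levels; `R² = 1 − SS_res/SS_tot`. Because
the S/N-based detection-limit definitions leave the noise recipe open,
the package operationalises them as LOD = 3σ/|a| and LOQ = 10σ/|a| with σ
the noise SD in area units, estimated from blank replicates or a baseline
window — so LOQ/LOD = 10/3 exactly. Quantification inverts the line;
estimates below the LOD report "not detected" (the LOD boundary itself is
inclusive) and estimates outside the calibrated range are flagged.
Published LODs cannot be recomputed without the original noise traces and
are treated as reference metadata only.

The product verdict depends on detection flags only: every marker ND →
fake; any grass marker detected → adulteration (grass dominates even when
white markers are present, since its presence already falsifies a
"pure white EBN" claim); otherwise authentic. The white/grass split keys
on the white- and grass-specific markers; the shared EBN marker is
reported alongside because its quantity tracks the white marker closely
in practice but is not additive over white + grass content.

Validation statistics follow convention: RSD = 100·SD/mean (sample SD),
intra-day RSD as the mean of within-day RSDs, inter-day RSD as the RSD of
day means, and spike recovery = 100·(measured_spiked − measured_unspiked)
/ amount_spiked with its RSD over replicates.

## Synthetic data

The generator's defaults mirror the real cohort design: 60 white and 10
grass EBN batches; adulterant runs agar 10, egg white 5, gelatin 8, cow
milk 8, pork skin 4, tremella 6, rice 4, starch 3, swim bladder 3; a
planted panel of 10 E + 13 W + 3 G marker peptides; calibration truth
`area = 169511·mg − 106601` over 0.5–40 mg with 2% proportional Gaussian
noise; and a 46-product design of 14 white-only, 11 mixed and 21
EBN-free products. Planted markers are real tryptic peptides — the three
identified assay sequences plus digests of bundled synthetic decoy
proteins — so their MS/MS ladders are chemically consistent. Noise
defaults are QTOF-realistic: 3 ppm m/z error SD (the published precursor
errors are ~3–4 ppm), 0.05 min RT jitter SD, log-normal area spread 0.3,
dropout 0. Background consists of peaks shared between EBN and
adulterants (exercising the specificity criterion) and per-class singly
charged peaks present in a random 70% of runs (exercising the peptide and
consistency criteria). Marker positions are spaced ≥0.4 min apart so
distinct planted markers can never merge at default tolerances.

What the generator does *not* emulate: chromatographic peak shapes,
isotope envelopes, co-elution interference, RT drift beyond white noise,
matrix-dependent ionisation suppression, and real biological variation in
marker abundance. Passing tests therefore demonstrate the correctness of
the pipeline's logic and numerics under the stated noise model, not
robustness on real instrument data.

## Problem sizes and numerical choices

The default cohort is 121 runs and ~5,800 features, aligned in well under
a second; stochastic checks use 200 seeds for calibration recovery and
100 seeds for the peptide-ness null, sizes at which the binomial/mean
estimates are stable to well inside the asserted bounds. Floating-point
comparisons in tests use absolute tolerances of 5e-5 Da on masses
(printed-precision scale), 1e-9 on exact identities, and the documented
ppm bounds elsewhere. Ties in greedy alignment break by nearest m/z, then
nearest RT, then lexical run id, making every pipeline stage bit-stable
for a given seed.

## Known limitations

- Greedy alignment is order-dependent by design; adversarial inputs can
  split a group that a global optimiser would keep (the small-instance
  brute-force comparison in the tests covers the separated-cluster case
  only).
- The peptide-ness spectrum test uses pairwise residue-mass differences
  at 20 ppm, which is strict for noisy MS/MS; real spectra may need the
  tolerance widened or the charge-call route.
- Confirmation scores count singly-charged b/y ions only; peptides whose
  fragmentation is dominated by multiply charged or internal ions will
  score low.
- The classifier is purely qualitative; it never weighs quantities
  against label claims.
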