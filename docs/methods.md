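# Methods

## The procedure

`coenrich` re-implements the computational pipeline of a two-route
co-enrichment experiment for bait-complex discovery from shotgun (MudPIT)
proteomics.  The input is a protein sequence database (FASTA) and, per run,
a table of peptide-spectrum matches (PSMs) carrying the SEQUEST quality
attributes XCorr and DeltCn.  Spectrum scoring itself is out of scope:
XCorr/DeltCn are treated as given per-PSM attributes, and the pipeline
starts where a database search ends.

The stages are:

1. **Search database.**  Targets plus optional contaminants are
   concatenated with exactly one decoy per non-decoy entry.  Decoys are
   uniform random permutations of their source's residues, so length and
   composition — the properties the downstream statistics depend on — are
   preserved.  Decoy accessions carry the `DECOY_` prefix.  Contaminants
   behave as targets in search and quantification and keep their own
   category so reports can flag them.
2. **Digestion and mapping.**  Lys-C-followed-by-trypsin is modelled as a
   single trypsin-like rule (cleave after K or R, never before P; both cut
   after K, and no separate rule is defined for the two-enzyme sequence).
   Protein termini count as valid tryptic termini.  Peptides are mapped to
   every database protein containing them as a substring, with tryptic
   status (`fully` / `half` / `non`) judged per occurrence from the
   flanking residues.
3. **PSM filtering.**  A PSM is accepted iff DeltCn ≥ 0.08, XCorr ≥ the
   charge-specific minimum (1.8 / 2.0 / 3.0 for charges 1–3), the peptide
   is ≥ 7 residues, and at least one parent occurrence is fully tryptic.
   All thresholds are inclusive ("at least" semantics).  Charges above 3
   reuse the charge-3 threshold (a conservative extension, configurable).
   A peptide shared between a target and a decoy is tie-broken to target,
   the standard concatenated-search convention.  Proteins are accepted if,
   pooling all runs, they carry ≥ 2 distinct accepted peptides or 1 peptide
   with ≥ 2 independent spectra.
4. **FDR.**  Among accepted PSMs the estimator is the classical
   concatenated-search ratio D/T (decoy over target counts); the symmetric
   variant 2D/(T+D) is reported alongside, overall and per run.  The
   estimate is reported, not used as an acceptance gate: the filtering
   criteria above are fixed score thresholds, not an FDR-controlled cut.
5. **Quantification.**  Per run, each accepted protein's unique spectral
   count uSpC sums spectra of peptides unique to it; shared-peptide spectra
   are distributed in proportion to the sharers' unique counts to give
   dSpC, and dSpC/length is normalized across the run's proteins to give
   dNSAF (sums to 1 per run).  Spectra whose peptides map only to
   non-accepted proteins are excluded from counting and from the
   conservation total — only detected proteins are quantified.  When every
   sharer of a peptide has zero unique counts, its spectra are split
   equally (the one degenerate case the proportional rule leaves open;
   equal split preserves count conservation).  Decoy entries are FDR
   bookkeeping only and never enter quantification or classification.
   Per-run columns are never summed across conditions — the classifier
   needs per-fraction values.  Display-format tables round dSpC to
   integers; all computation is on the unrounded values.
6. **Classification.**  Fractionation-positive: dSpC = 0 in the 210 mM
   fraction, > 0 in 290 mM, and c290 ≥ 5 × c350.  "Absent" means zero
   dSpC after filtering and protein acceptance.  A zero 350 mM count with a
   positive 290 mM count passes: a protein seen only in the bait-enriched
   fraction is maximally enriched, and the published calls require this
   convention (a bait scaffold row with a single 290 mM spectrum and an
   empty 350 mM cell is positive).  IP-positive: present in ≥ 1 bait-IP
   replicate and absent from every control-IgG replicate (the published
   calls treat single-replicate presence as presence).  The fold threshold,
   the bait-replicate policy (any/all) and the zero-denominator policy are
   all config-exposed.  The 5-fold criterion is applied to distributed
   spectral counts, the quantity the candidate table reports; on the
   packaged table, reading it as distinct peptides instead changes no call.

## Synthetic data: what it emulates, and what it does not

The simulator generates the experiment the classifier assumes, at the PSM
level (no raw spectra — the pipeline's own computation starts at PSMs):

* A proteome of random sequences (default 200 targets, lengths 150–600)
  with combined K+R frequency 0.11, so tryptic peptide lengths are
  realistic (~9 residues mean).  A configurable number of tryptic segments
  (default 20) is copied between proteins so that shared-peptide
  distribution is genuinely exercised.
* Background proteins draw one log-normal(0, 1) abundance used in all seven
  conditions: they co-fractionate and stick to both IPs, so they fail both
  criteria — the contaminant behaviour the dual criteria are designed to
  reject.
* Planted complex members (default 5) draw log-normal(1.5, 0.5) abundance —
  bait-complex proteins are biochemically enriched, so they sit in the
  upper abundance range, giving 290 mM counts in the published table's
  range (~10–40) — present in the 290 mM fraction and both bait IPs, absent
  from 210 mM and the controls, and depleted in 350 mM by a fold gap drawn
  uniformly from [8, 25]: comfortably above the 5-fold criterion in
  expectation but not immune to sampling noise at the low end.
* Each run draws 2000 spectra multinomially over proteins with probability
  ∝ abundance × observable-peptide count, then uniformly over the protein's
  observable peptides (fully tryptic, ≥ 7 residues — very short peptides
  are not observed as correct identifications).  Scores are Gaussians
  truncated at zero.  XCorr is parameterized as an offset from the charge's
  acceptance threshold (correct: +0.8 ± 0.5, ≈ 95% above threshold;
  incorrect: 0.0 ± 0.4, straddling it), because a single absolute score
  scale cannot sit in the same relation to three different charge-specific
  thresholds.  DeltCn: correct 0.25 ± 0.08, incorrect 0.08 ± 0.04.
* A 5% fraction of spectra (binomially drawn) are incorrect matches,
  implemented as decoy-peptide PSMs: a uniformly random decoy entry, then a
  uniformly random digest peptide of any length.  This mirrors what the
  decoy half of a concatenated search measures.  Incorrect matches are
  deliberately *not* scattered over target entries: with a few hundred
  simulated entries instead of the tens of thousands in a real search
  space, uniform incorrect target matches would plant spurious
  presence/absence flips on individual proteins orders of magnitude more
  often than in real data, which is an artifact of the scaled-down database
  rather than a property of the method.

Consequently, passing the recovery tests shows the pipeline arithmetic and
set logic are correct under the assumed data-generating process; it does
not certify behaviour under real-data pathologies the simulator omits —
correlated contamination between runs, incorrect matches that hit target
proteins, intensity-dependent identification bias, or modified peptides.

The image simulator renders puncta as hard disks (radius 3 px, amplitude
3000) on Gaussian noise (background 100 ± 10) at jittered grid positions
that keep puncta separated, with reference-channel membership (60% of
marker puncta) and third-channel membership (Bernoulli per punctum, default
0.75 for reference-positive and 0.40 for reference-negative puncta)
planted per punctum.  Real micrographs have touching puncta, uneven
background, and out-of-focus light; none of these are modelled, so the
image tests validate the scoring logic, not segmentation robustness.

## Punctum scoring

Channels are thresholded (`fixed`, `percentile`, or `otsu`; the original
cell-scoring software's rule is undocumented, so the method is
config-exposed), stacks are max-projected first, and marker puncta are
8-connected components of ≥ 4 px (noise suppression; configurable).  A
punctum is reference-positive if it shares ≥ 1 pixel with the reference
mask (a fractional-overlap rule is available).  Fractions of
third-channel-positive puncta are computed per group per image; the
statistical unit is the image, and the two groups are compared with a
paired two-sided t-test across images, with images lacking a group
excluded from the pairing.  For synthetic images the paired scoring uses a
fixed threshold at 1600 — halfway between background and spot level —
which recovers rendered spot areas exactly; percentile thresholds mark a
fixed pixel fraction regardless of content and would hallucinate puncta in
empty channels.

## Numerical and design choices

* dSpC distribution is exact floating-point arithmetic; conservation of
  counted spectra per run holds to ≤ 1e-6 relative (observed ~1e-16).
* dNSAF of a run with zero counted spectra is undefined; run-level
  quantification reports zeros for such runs and the low-level
  normalization raises on an all-zero run.
* Candidate reports order combined positives first, then
  fractionation-only, then IP-only, each by descending 290 mM dSpC with
  accession as tie-break, so reruns are byte-identical.
* The pipeline manifest hashes the analysis parameters (not the output
  directory or log level), records per-stage row counts, and the seed is
  threaded from one config value through every random component
  (simulation streams are spawned per run from a root seed sequence).
* Database totals: decoys are strictly 1:1 with non-decoy entries.
* Half-tryptic status is assigned when exactly one terminus conforms to the
  cleavage rule (standard convention); only `fully` matters to the default
  filter.

## Problem sizes

The test suite and the acceptance script use 20 simulated replicates at the
default conditions (200 proteins, 5 members, 7 × 2000 spectra), a 10-image
× 100-punctum colocalization set, and 100-instance randomized oracles for
the counting arithmetic — sizes at which every statistical check is
well-powered while a full run stays around a minute.

## Known limitations

* The FDR estimator is reported at the PSM level only; no protein-level
  FDR is computed.
* No modification handling, no peptide masses, no spectrum-level modelling;
  I and L are treated as distinct residues (lossless, but a search engine
  may conflate them).
* The classifier is deterministic set logic, as the procedure defines it;
  it provides no probabilistic interactor score and no uncertainty on the
  calls.
* The colocalization module does no deconvolution, registration, or 3-D
  segmentation.
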