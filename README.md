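# coenrich

Co-enrichment calling from MudPIT spectral-count proteomics.

When a large scaffold protein (for example the presynaptic active-zone
proteins Piccolo and Bassoon) is purified by two orthogonal routes —
salt-step anion-exchange fractionation and antibody co-immunoprecipitation —
the proteins that track the bait through *both* routes are strong candidate
complex members, while abundant co-fractionating contaminants and sticky IP
background each fail one of the two routes.  `coenrich` implements the full
computational side of that experiment for shotgun (MudPIT) data:

* **Search-database handling** — FASTA IO, per-entry shuffled decoy
  databases, in-silico tryptic digestion (cleave after K/R, not before P),
  and peptide-to-protein mapping with per-occurrence tryptic status.
* **PSM filtering** — DTASelect-style acceptance: DeltCn ≥ 0.08, XCorr ≥
  1.8 / 2.0 / 3.0 for 1+ / 2+ / 3+ spectra, fully tryptic peptides of ≥ 7
  residues; protein acceptance with ≥ 2 peptides or 1 peptide with 2
  independent spectra, pooled over runs; decoy-based FDR (D/T, with
  2D/(T+D) reported alongside).
* **Distributed spectral counting** — shared-peptide spectra are
  apportioned in proportion to unique counts,

      dSpC_k = uSpC_k + Σ_j SpC_j · uSpC_k / Σ_{i ∈ parents(j)} uSpC_i ,

  and length-normalized into distributed Normalized Spectral Abundance
  Factors,

      dNSAF_k = (dSpC_k / L_k) / Σ_i (dSpC_i / L_i) ,

  which sum to 1 within a run and estimate relative abundance.
* **Dual-criteria classification** — a protein is *fractionation-positive*
  if it is absent from the 210 mM NaCl fraction, present in the 290 mM
  (bait-enriched) fraction, and has ≥ 5-fold more spectra in 290 mM than
  350 mM; it is *IP-positive* if present in ≥ 1 bait-antibody IP and absent
  from every control-IgG IP.  Candidates must satisfy both.
* **Ground-truthed simulation** — multi-condition PSM tables with planted
  complex members, shared peptides, and near-threshold decoy matches, plus
  three-channel punctum images with planted colocalization, for end-to-end
  validation of every stage.
* **Object-based colocalization** — threshold / segment / mask-partition /
  score workflow for fluorescence puncta, with a paired t-test across
  images.

## Worked example

The package ships the published candidate table of the Piccolo/Bassoon
co-enrichment experiment as a fixture (per-protein dSpC across the three
salt fractions, two bait IPs, and two control IPs).  Classifying it:

```python
from coenrich import load_table1, ExperimentDesign, make_report

report = make_report(load_table1(), ExperimentDesign())
print(report[["accession", "f210", "f290", "f350", "bait1", "bait2",
              "ctrl1", "ctrl2", "combined_positive", "reasons"]].to_string(index=False))
```

```
    accession  f210  f290  f350  bait1  bait2  ctrl1  ctrl2  combined_positive                           reasons
      Piccolo   0.0  12.0   0.0  159.0   10.0    0.0    0.0               True                     frac-ok;ip-ok
         Trio   0.0   7.0   0.0    2.0    0.0    0.0    0.0               True                     frac-ok;ip-ok
      Bassoon   0.0   1.0   0.0    2.0    1.0    0.0    0.0               True                     frac-ok;ip-ok
         Git1   0.0  24.0   0.0    0.0    0.0    0.0    0.0              False         frac-ok;no-bait-detection
         Git2   0.0   3.0   0.0    0.0    0.0    0.0    0.0              False         frac-ok;no-bait-detection
         CASK   0.0   2.0   0.0    0.0    0.0    0.0    0.0              False         frac-ok;no-bait-detection
        Daam1   1.0   0.0   0.0    0.0    3.0    0.0    0.0              False              present-in-210;ip-ok
   CAST2/ELKS  31.0  35.0   0.0    0.0    0.0    0.0    0.0              False  present-in-210;no-bait-detection
      Munc-18   9.0   3.0   0.0    0.0    0.0    1.0    0.0              False present-in-210;present-in-control
Liprin alpha2   1.0   2.0   1.0    0.0    0.0    0.0    0.0              False  present-in-210;no-bait-detection
```

Exactly three proteins — the bait scaffolds Piccolo and Bassoon and the
Rho-GEF Trio — satisfy both criteria.  Every other protein fails for a
machine-readable reason: Git1/Git2/CASK co-elute with the bait on the
column but never appear in the IPs; Daam1 co-precipitates but leaks into
the 210 mM fraction; the ELKS isoforms and Munc-18 are abundant in the
low-salt wash.

The same analysis runs from the shell, end to end, on simulated or real
inputs:

```sh
coenrich simulate --seed 7 --outdir sim/
coenrich filter --fasta sim/database.fasta --psms sim/psms_F290.tsv --out filtered.tsv
coenrich run-all --config pipeline.yaml
```

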