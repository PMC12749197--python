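# budmrna

Analyses of bud-localized mRNA in budding yeast: zipcode discovery, a
reaction–diffusion model of bud enrichment, single-molecule spot
statistics, and time-lapse lineage analytics.

In *S. cerevisiae*, transcripts such as *ASH1* and the mitotic cyclin
*CLB2* are carried into the growing bud by the She2–She3–Myo4 complex,
guided by structured *zipcode* elements in the mRNA.  This package is for
computational biologists working on such localization data.  It provides:

* **`budmrna.zipcode`** — a two-stage search for She2-type elements: a
  combinatorial scan for two nested inverted-repeat stems (≥ 4 bp) framing
  an asymmetric bulge with a CGA motif and a lone unpaired cytosine 6 nt
  away, followed by a ViennaRNA folding filter at 28 °C (the candidate's
  stems must appear in the 80-nt window's MFE structure, and forcing them
  may cost at most 20 % extra free energy, |ΔG_c − ΔG_f| ≤ 0.2·|ΔG_f|).
  `synonymize_zipcode` destroys a hit by synonymous codon substitutions
  that preserve the protein and the codon-usage index.
* **`budmrna.rdmodel`** — the steady state of

      0 = D ∇²c − k_d c + k_p − k_on c + k_off b
      0 = k_on c − k_off b − k_d b

  on a mother–bud two-sphere domain with reflecting walls: free mRNA c
  diffuses, decays (k_d = ln 2/240 s⁻¹), is produced near the bud centre
  (smooth radial step k_p, volume integral normalized to 1) and exchanges
  with an immobile bound pool b (k_off = 1/90 s⁻¹,
  k_on = 0.25 (k_off + k_d); the *anchored* scenario raises k_on 125-fold).
  Solved by finite differences on a masked Cartesian grid and direct
  sparse LU.
* **`budmrna.spatial`** — mother/bud ellipsoid cell models, compartment
  assignment, 250-nm mRNA–protein colocalization (several proteins near one
  mRNA count as one translation complex) and nascent-RNA counting at
  transcription sites.
* **`budmrna.lineage`** — minimum-total-distance detection linking
  (200 px gate), budded-phase durations from septin-neck tracks, Bayesian
  parent–bud assignment (area, overlap and nuclear-marker factors), and
  bootstrap / t-test comparison of duration distributions.
* **`budmrna.synth`** — seeded generators for all of the above: implanted
  zipcode sequences, spot clouds with known bud and colocalization
  fractions, Poisson expression counts, and time-lapse neck streams with
  known durations.

## Worked example

```sh
python examples/enrichment_model.py
```

```
scenario   bud_fraction bound_fraction  total_mass
free_slow         0.501          0.200       346.0
free_fast         0.362          0.200       346.0
anchored          0.929          0.969       346.0
```

With free diffusion alone (0.1 or 0.4 µm²/s) only 36–50 % of the mRNA sits
in the bud at steady state — diffusion out of the bud beats localized
production.  Adding a high-affinity anchoring factor (k_on × 125, bound
fraction 97 %) retains 93 % in the bud: efficient enrichment requires
anchoring, not just delivery.

```sh
python examples/colocalization.py
```

```
3030 mRNAs in 300 cells
bud fraction: estimated 0.594 vs generated 0.6
mRNAs with a protein focus within 250 nm: 0.246 raw, 0.007 by chance, 0.240 corrected vs generated 0.25
```

The estimators recover the generating bud fraction and colocalization
fraction; the matched null run (no true complexes) quantifies chance
proximity.  `examples/zipcode_search.py` and `examples/budded_phase.py`
demonstrate the other two pipelines, and the same functionality is exposed
as a CLI (`budmrna zipscan|rdsim|coloc|lineage|simulate`).

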