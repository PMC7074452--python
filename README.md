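# chemoclock

Chemotaxonomy from untargeted LC-MS metabolomics: does the metabolome of a
microalgal strain carry the same evolutionary signal as its DNA?

`chemoclock` is built for comparative metabolomics of marine phytoplankton
cultures (picoalgae such as the Mamiellales, plus stramenopile/haptophyte
outgroups), where strains are profiled by UHPLC-ESI⁺-HRMS² and compared
against an 18S phylogeny. It provides four things:

1. **Rule-based MS² annotation** of the polar lipids and pigments that
   dominate algal extracts — galactolipids (MGDG, MGMG), the sulfolipid
   SQDG, betaine lipids (DGTS, DGTA, lyso-DGTS, DGCC), ceramide, and
   xanthophylls/chlorophylls. Annotation uses exact-mass matching of the
   precursor against class templates (chains C12–C24, 0–6 double bonds, 3 ppm),
   then class-specific fragmentation rules:
   * *sn*-regiochemistry from the relative intensity of the two acyl-loss
     fragments [M+X−RCO₂H]⁺ — the *sn*-1 loss dominates for protonated SQDG
     and sodiated MGDG; the *sn*-2 loss dominates for sodiated betaines;
   * betaine confirmation by the 59 Da trimethylamine neutral loss, with the
     mass-isomeric DGTS/DGTA pair resolved by a lineage prior (DGTS in the
     green lineage, DGTA in brown algae);
   * xanthophyll isomers split by a dehydration series (prasinoxanthin),
     a nominal 80 Da epoxide loss (violaxanthin), and diagnostic fragments
     *m/z* 109.1014 / 581.3975 / 641.4207 (fucoxanthin).
2. **Feature-matrix construction** mirroring a standard untargeted workflow:
   2–18 min retention window, greedy centroid grouping at 0.1 min / 3 ppm,
   2×10⁶ intensity floor, blank hiding, zero gap-filling with provenance,
   per-species sharing summaries, and the top-10 "major-metabolite" matrix.
3. **Genotype–metabolome congruence**: Spearman distances between strain
   profiles, complete-linkage HCA, scaled PCA, patristic distances from a
   newick tree, and a permutation Mantel test
   (Pearson *r* on the strictly-upper-triangle distance vectors, one-sided,
   p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1)).
4. **A synthetic-data generator** — metabolite presence evolves by Poisson
   gain/loss along the tree, log-abundance by Brownian motion, measurement by
   lognormal noise with blanks, replicates and bacterial-contamination
   admixture — so the whole pipeline is testable without instrument data.

## Worked example

Simulate a 12-strain study on the built-in fixture phylogeny, run the full
pipeline, and test metabolome–phylogeny congruence:

```bash
chemoclock all --seed 1 --out demo
```

prints the two Mantel results

```json
{"major": {"n_perm": 999, "p": 0.001, "r": 0.880488},
 "whole": {"n_perm": 999, "p": 0.001, "r": 0.990919}}
```

meaning: across the 66 strain pairs, whole-metabolome Spearman distance is
almost perfectly rank-correlated with patristic distance (*r* = 0.99), the
top-10 major-metabolite matrix nearly as strongly (*r* = 0.88), and neither
correlation is ever reached among 999 label permutations (p = 0.001, the
smallest achievable value). `demo/report.json` additionally records the
feature counts (here 340 grouped features, 308 after the intensity floor and
blank hiding removed the 30 simulated medium-background ions, of which 4 are
unique to one strain and 304 shared), the PC1/PC2 explained-variance
fractions of both matrices, and the paths of all artifacts (feature and
presence matrices, annotation TSV, dendrograms, distance matrices).

The stages are also available separately — `chemoclock simulate`,
`features`, `annotate`, `chemotax` — and as a library:

```python
from chemoclock import *

cfg = load_config()
sp = LipidSpecies(cfg.templates["MGDG"], AcylChain(18, 3), AcylChain(16, 4))
spectrum = generate_ms2_fixture(sp, config=cfg)   # or read_mgf("spectra.mgf")
ann = annotate(spectrum, "O_tauri_1", LineagePrior({"O_tauri_1": "green"}), cfg)
print(ann.label, ann.regio_status, ann.tier)      # MGDG 18:3/16:4 assigned 3
```

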