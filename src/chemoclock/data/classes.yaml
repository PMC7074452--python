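# Lipid class templates and pigment catalog.
#
# Backbone = headgroup + glycerol (or sphingoid base) with a free hydroxyl at
# every acyl position; the species formula is backbone + free fatty acids
# minus one H2O per esterified position. Backbones are never printed in the
# source literature for these strains; each one here was reconstructed from
# the standard structure (SMILES given) and its formula cross-checked with
# RDKit (see tests). Regio rules: for SQDG protonated and MGDG sodiated
# adducts the sn-1 acyl-loss fragment [M+X-R1CO2H]+ is the more intense of
# the pair; for betaine sodiated adducts the sn-2 loss dominates.

classes:
  - name: MGDG            # monogalactosyl diacylglycerol
    backbone: C9H18O8     # galactosylglycerol
    smiles: "OCC(O)COC1OC(CO)C(O)C(O)C1O"
    acyl_positions: 2
    regio_rule: {adduct: "[M+Na]+", more_intense: sn1}

  - name: MGMG            # monogalactosyl monoacylglycerol (lyso-MGDG)
    backbone: C9H18O8
    smiles: "OCC(O)COC1OC(CO)C(O)C(O)C1O"
    acyl_positions: 1

  - name: SQDG            # sulfoquinovosyl diacylglycerol
    backbone: C9H18O10S   # sulfoquinovosylglycerol
    smiles: "OCC(O)COC1OC(CS(=O)(=O)O)C(O)C(O)C1O"
    acyl_positions: 2
    regio_rule: {adduct: "[M+H]+", more_intense: sn1}

  - name: DGTS            # diacylglyceryl-trimethylhomoserine (green lineage)
    backbone: C10H21NO5
    smiles: "OCC(O)COCCC([N+](C)(C)C)C(=O)[O-]"
    acyl_positions: 2
    lineage: green
    regio_rule: {adduct: "[M+Na]+", more_intense: sn2}
    neutral_losses:
      - {name: trimethylamine, formula: C3H9N}          # 59 Da, required
      - {name: betaine_87, nominal_mass: 87.0, required: false}  # catalogued, not observed

  - name: DGTA            # diacylglyceryl-hydroxymethyl-trimethyl-beta-alanine (brown)
    backbone: C10H21NO5   # mass-isomeric with DGTS
    smiles: "OCC(O)COCC([N+](C)(C)C)CC(=O)[O-]"
    acyl_positions: 2
    lineage: brown
    regio_rule: {adduct: "[M+Na]+", more_intense: sn2}
    neutral_losses:
      - {name: trimethylamine, formula: C3H9N}

  - name: lyso-DGTS
    backbone: C10H21NO5
    smiles: "OCC(O)COCCC([N+](C)(C)C)C(=O)[O-]"
    acyl_positions: 1
    lineage: green
    neutral_losses:
      - {name: trimethylamine, formula: C3H9N}

  - name: DGCC            # diacylglyceryl-carboxy-hydroxymethyl-choline
    # Least certain backbone of the set: reconstructed as DGTS + O from the
    # carboxy(hydroxymethyl)choline headgroup; flagged for review against an
    # authenticated standard.
    backbone: C10H21NO6
    smiles: "OCC(O)COCC(C[N+](C)(C)C)(O)C(=O)[O-]"
    acyl_positions: 2
    regio_rule: {adduct: "[M+Na]+", more_intense: sn2}
    neutral_losses:
      - {name: trimethylamine, formula: C3H9N}

  - name: Cer             # ceramide, non-hydroxy fatty acid + sphingosine d18:1
    backbone: C18H37NO2   # sphingosine; the single "acyl position" is the amide
    smiles: "CCCCCCCCCCCCC/C=C/C(O)C(N)CO"
    acyl_positions: 1

pigments:
  # Chlorophylls and xanthophylls are individual named compounds, not chain
  # families. Isomer discrimination rules: prasinoxanthin shows a successive
  # dehydration series (precursor - n*18.0106); the epoxycarotenoid
  # violaxanthin shows a nominal 80 Da neutral loss; fucoxanthin is pinned by
  # diagnostic fragments m/z 109.1014, 581.3975, 641.4207 (>= 2 required).
  - {name: chlorophyll a, formula: C55H72MgN4O5}
  - {name: chlorophyll b, formula: C55H70MgN4O6}
  - {name: pheophytin a, formula: C55H74N4O5}
  - {name: prasinoxanthin, formula: C40H56O4, rule: dehydration_series}
  - {name: violaxanthin, formula: C40H56O4, rule: loss_80}
  - {name: fucoxanthin, formula: C42H58O6, rule: diagnostics,
     diagnostic_mz: [109.1014, 581.3975, 641.4207]}
  - {name: siphonaxanthin, formula: C40H56O5}
  - {name: siphonein, formula: C52H78O6}            # siphonaxanthin laurate
  - {name: dihydrolutein, formula: C40H58O2, unverified: true}
  # Catalog stubs without pinned formulas (supply one to enable matching):
  - {name: uriolide, formula: null}
  - {name: micromonal, formula: null}

parameters:
  chain_carbons: [12, 24]
  chain_double_bonds: [0, 6]
  precursor_tol_ppm: 3.0       # MS1 grouping / composition tolerance
  fragment_tol_ppm: 10.0       # MS2 resolution is coarser than MS1
  fragment_tol_da: 0.005
  regio_ratio_threshold: 1.2   # larger/smaller acyl-loss intensity ratio
  nominal_loss_window_da: 0.5  # window for the nominal 80 Da loss
  dehydration_min_losses: 2
  diagnostics_min_matches: 2
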