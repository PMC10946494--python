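# Default registry: the 16 serum/plasma 1H NMR spin systems modelled by this package.
# nominal_delta are standard 600 MHz serum/plasma positions (pH 7.4 phosphate buffer, TMSP
# reference), in ppm. Per-sample positions drift around these by up to ~0.05 ppm.
# Note: formate is recorded as a one-proton CH singlet (its formyl proton); some sources
# mislabel the group as -CH2.
systems:
  - id: valine_CH3
    metabolite: valine
    group: "-CH3"
    multiplicity: doublet
    nominal_delta: 0.9860
    chemical_class: amino_acid
  - id: alanine_CH3
    metabolite: alanine
    group: "-CH3"
    multiplicity: doublet
    nominal_delta: 1.4780
    chemical_class: amino_acid
  - id: leucine_CH3
    metabolite: leucine
    group: "(-CH3)2"
    multiplicity: triplet
    nominal_delta: 0.9610
    chemical_class: amino_acid
  - id: isoleucine_CH3
    metabolite: isoleucine
    group: "-CH3"
    multiplicity: doublet
    nominal_delta: 1.0110
    chemical_class: amino_acid
  - id: tyrosine_CH
    metabolite: tyrosine
    group: "(-CH)2"
    multiplicity: multiplet
    nominal_delta: 6.9020
    chemical_class: amino_acid
  - id: phenylalanine_CH
    metabolite: phenylalanine
    group: "(-CH)2"
    multiplicity: doublet
    nominal_delta: 7.3300
    chemical_class: amino_acid
  - id: glycine_CH2
    metabolite: glycine
    group: "-CH2"
    multiplicity: singlet
    nominal_delta: 3.5620
    chemical_class: amino_acid
  - id: histidine_CH
    metabolite: histidine
    group: "-CH"
    multiplicity: singlet
    nominal_delta: 7.7850
    chemical_class: amino_acid
  - id: lactate_CH3
    metabolite: lactate
    group: "-CH3"
    multiplicity: doublet
    nominal_delta: 1.3310
    chemical_class: carboxylic_acid
  - id: acetate_CH3
    metabolite: acetate
    group: "-CH3"
    multiplicity: singlet
    nominal_delta: 1.9210
    chemical_class: carboxylic_acid
  - id: pyruvate_CH3
    metabolite: pyruvate
    group: "-CH3"
    multiplicity: singlet
    nominal_delta: 2.3700
    chemical_class: carboxylic_acid
  - id: formate_CH
    metabolite: formate
    group: "-CH"
    multiplicity: singlet
    nominal_delta: 8.4520
    chemical_class: carboxylic_acid
  - id: hydroxybutyrate_CH3
    metabolite: 3-hydroxybutyrate
    group: "-CH3"
    multiplicity: doublet
    nominal_delta: 1.2040
    chemical_class: carboxylic_acid
  - id: glucose_anomeric
    metabolite: glucose
    group: "anomeric CH"
    multiplicity: doublet
    nominal_delta: 5.2430
    chemical_class: sugar
  - id: ethanol_CH3
    metabolite: ethanol
    group: "-CH3"
    multiplicity: triplet
    nominal_delta: 1.1860
    chemical_class: alcohol
  - id: acetone_CH3
    metabolite: acetone
    group: "(-CH3)2"
    multiplicity: singlet
    nominal_delta: 2.2370
    chemical_class: ketone
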