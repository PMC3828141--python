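# Laminar cortical-column template (editable configuration).
#
# NOTE: the numeric tables below are package placeholders that preserve
# the qualitative laminar structure (denser within-layer connectivity,
# L4 -> L2/3 -> L5 feedforward excitation, strong local inhibition) and
# were tuned only for the default activity band.  Background-current
# values and input-stream target probabilities are likewise placeholder
# reconstructions.  Transcribe data-based values here to reproduce a
# specific published column quantitatively.
background_current:
  L23E: 0.1
  L23I: 0.08
  L4E: 0.1
  L4I: 0.08
  L5E: 0.11
  L5I: 0.08
conn_delay:
  L23E->L23E: 1.0
  L23E->L23I: 1.0
  L23E->L4E: 1.0
  L23E->L5E: 1.0
  L23E->L5I: 1.0
  L23I->L23E: 1.0
  L23I->L23I: 1.0
  L23I->L4E: 1.0
  L4E->L23E: 1.0
  L4E->L23I: 1.0
  L4E->L4E: 1.0
  L4E->L4I: 1.0
  L4E->L5E: 1.0
  L4I->L23E: 1.0
  L4I->L4E: 1.0
  L4I->L4I: 1.0
  L5E->L23E: 1.0
  L5E->L4E: 1.0
  L5E->L5E: 1.0
  L5E->L5I: 1.0
  L5I->L5E: 1.0
  L5I->L5I: 1.0
conn_prob:
  L23E->L23E: 0.15
  L23E->L23I: 0.3
  L23E->L4E: 0.03
  L23E->L5E: 0.25
  L23E->L5I: 0.08
  L23I->L23E: 0.35
  L23I->L23I: 0.25
  L23I->L4E: 0.05
  L4E->L23E: 0.28
  L4E->L23I: 0.1
  L4E->L4E: 0.15
  L4E->L4I: 0.3
  L4E->L5E: 0.05
  L4I->L23E: 0.05
  L4I->L4E: 0.35
  L4I->L4I: 0.25
  L5E->L23E: 0.03
  L5E->L4E: 0.02
  L5E->L5E: 0.15
  L5E->L5I: 0.3
  L5I->L5E: 0.35
  L5I->L5I: 0.25
conn_weight:
  L23E->L23E:
  - 1.3
  - 0.7
  L23E->L23I:
  - 1.6
  - 0.7
  L23E->L4E:
  - 1.0
  - 0.7
  L23E->L5E:
  - 1.4
  - 0.7
  L23E->L5I:
  - 1.4
  - 0.7
  L23I->L23E:
  - 2.8
  - 0.7
  L23I->L23I:
  - 2.2
  - 0.7
  L23I->L4E:
  - 1.5
  - 0.7
  L4E->L23E:
  - 1.4
  - 0.7
  L4E->L23I:
  - 1.4
  - 0.7
  L4E->L4E:
  - 1.3
  - 0.7
  L4E->L4I:
  - 1.6
  - 0.7
  L4E->L5E:
  - 1.0
  - 0.7
  L4I->L23E:
  - 1.5
  - 0.7
  L4I->L4E:
  - 2.8
  - 0.7
  L4I->L4I:
  - 2.2
  - 0.7
  L5E->L23E:
  - 1.0
  - 0.7
  L5E->L4E:
  - 1.0
  - 0.7
  L5E->L5E:
  - 1.3
  - 0.7
  L5E->L5I:
  - 1.6
  - 0.7
  L5I->L5E:
  - 2.8
  - 0.7
  L5I->L5I:
  - 2.2
  - 0.7
input_streams:
- n: 40
  rate: 0.02
  targets:
    L4E: 0.25
    L4I: 0.15
  weight:
  - 1.8
  - 0.7
- n: 40
  rate: 0.02
  targets:
    L23E: 0.25
    L23I: 0.15
  weight:
  - 1.8
  - 0.7
n_reference: 560
pool_fractions:
  L23E: 0.3
  L23I: 0.1
  L4E: 0.2
  L4I: 0.1
  L5E: 0.2
  L5I: 0.1
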