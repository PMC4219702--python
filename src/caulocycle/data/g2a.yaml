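format: caulocycle-model/1
name: g2a
nodes:
- name: CtrA
  max_level: 1
- name: GcrA
  max_level: 1
- name: DnaA
  max_level: 1
- name: CcrM
  max_level: 1
- name: SciP
  max_level: 1
rules:
  CtrA:
    cases:
    - GcrA>=1 -> 1
    - CcrM==0 & SciP==0 -> 1
    default: 0
  GcrA:
    cases:
    - DnaA>=1 & CtrA==0 -> 1
    default: 0
  DnaA:
    cases:
    - CtrA>=1 & CcrM>=1 & GcrA==0 & DnaA==0 -> 1
    default: 0
  CcrM:
    cases:
    - CtrA>=1 & SciP==0 & CcrM==0 -> 1
    default: 0
  SciP:
    cases:
    - CtrA>=1 & DnaA==0 -> 1
    default: 0
clamps: {}
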