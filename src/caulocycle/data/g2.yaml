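format: caulocycle-model/1
name: g2
nodes:
- name: CtrA
  max_level: 2
- name: GcrA
  max_level: 1
- name: DnaA
  max_level: 1
- name: CcrM
  max_level: 1
- name: SciP
  max_level: 1
- name: DivK
  max_level: 2
- name: DivJ
  max_level: 2
- name: PleC
  max_level: 2
- name: DivL
  max_level: 1
- name: CckA
  max_level: 2
- name: ChpT
  max_level: 2
- name: CpdR
  max_level: 2
- name: ClpXP_RcdA
  max_level: 1
rules:
  CtrA:
    cases:
    - ClpXP_RcdA==1 -> 0
    - GcrA>=1 & ChpT==2 -> 2
    - GcrA>=1 -> 1
    - CcrM==0 & SciP==0 & ChpT==2 -> 2
    - CcrM==0 & SciP==0 -> 1
    default: 0
  GcrA:
    cases:
    - DnaA>=1 & CtrA<=1 -> 1
    default: 0
  DnaA:
    cases:
    - CtrA==2 & CcrM>=1 & GcrA==0 & DnaA==0 -> 1
    default: 0
  CcrM:
    cases:
    - CtrA==2 & SciP==0 & CcrM==0 -> 1
    default: 0
  SciP:
    cases:
    - CtrA==2 & DnaA==0 -> 1
    default: 0
  DivK:
    cases:
    - PleC==2 -> 1
    - DivJ==2 -> 2
    default: 1
  DivJ:
    cases:
    - PleC==2 -> 1
    - DivK==2 -> 2
    default: 1
  PleC:
    cases:
    - DivK==2 -> 1
    default: 2
  DivL:
    cases:
    - DivK==2 -> 0
    default: 1
  CckA:
    cases:
    - DivL==1 -> 2
    default: 1
  ChpT:
    cases:
    - CckA==2 -> 2
    default: 1
  CpdR:
    cases:
    - ChpT==2 -> 2
    default: 1
  ClpXP_RcdA:
    cases:
    - CpdR==1 -> 1
    default: 0
clamps: {}
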