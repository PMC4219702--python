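format: caulocycle-model/1
name: g2b
nodes:
- name: CtrA
  max_level: 2
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
    - ChpT==2 -> 2
    default: 1
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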