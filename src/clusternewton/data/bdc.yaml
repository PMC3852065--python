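schema_version: 1
group: BDC
dosing:
  dose: 1500.0
  infusion_duration: 90.0
  q_liver: 20.7
  v_liver: 24.1
  t_end: 7200.0
  n_bile_transit: 1
parameters:
- id: 1
  name: Kp_liver_CPT11
  unit: '-'
  min: 0.1
  max: 10.0
- id: 2
  name: Kp_liver_SN38
  unit: '-'
  min: 0.1
  max: 10.0
- id: 3
  name: Kp_liver_SN38G
  unit: '-'
  min: 0.1
  max: 10.0
- id: 4
  name: Kp_liver_NPC
  unit: '-'
  min: 0.1
  max: 10.0
- id: 5
  name: Kp_liver_APC
  unit: '-'
  min: 0.1
  max: 10.0
- id: 6
  name: CLr_CPT11
  unit: ml/min/kg
  min: 1.0
  max: 100.0
- id: 7
  name: CLr_SN38
  unit: ml/min/kg
  min: 1.0
  max: 100.0
- id: 8
  name: CLr_SN38G
  unit: ml/min/kg
  min: 1.0
  max: 100.0
- id: 9
  name: CLr_NPC
  unit: ml/min/kg
  min: 1.0
  max: 100.0
- id: 10
  name: CLr_APC
  unit: ml/min/kg
  min: 1.0
  max: 100.0
- id: 11
  name: CLbile_CPT11
  unit: ml/min/kg
  min: 1.0
  max: 100.0
- id: 12
  name: CLbile_SN38
  unit: ml/min/kg
  min: 1.0
  max: 100.0
- id: 13
  name: CLbile_SN38G
  unit: ml/min/kg
  min: 1.0
  max: 100.0
- id: 14
  name: CLbile_NPC
  unit: ml/min/kg
  min: 1.0
  max: 100.0
- id: 15
  name: CLbile_APC
  unit: ml/min/kg
  min: 1.0
  max: 100.0
- id: 16
  name: CL_CES_CPT11
  unit: ml/min/kg
  min: 1.0
  max: 100.0
- id: 17
  name: CL_CES_NPC
  unit: ml/min/kg
  min: 1.0
  max: 100.0
- id: 18
  name: CL_CYP3A4_APC
  unit: ml/min/kg
  min: 1.0
  max: 100.0
- id: 19
  name: CL_CYP3A4_NPC
  unit: ml/min/kg
  min: 1.0
  max: 100.0
- id: 20
  name: CL_UGT_SN38
  unit: ml/min/kg
  min: 1.0
  max: 100.0
- id: 21
  name: kfeces_CPT11
  unit: /min
  min: 0.001
  max: 0.1
- id: 22
  name: kfeces_SN38
  unit: /min
  min: 0.001
  max: 0.1
- id: 23
  name: kfeces_SN38G
  unit: /min
  min: 0.001
  max: 0.1
- id: 24
  name: kfeces_NPC
  unit: /min
  min: 0.001
  max: 0.1
- id: 25
  name: kfeces_APC
  unit: /min
  min: 0.001
  max: 0.1
- id: 26
  name: ka_CPT11
  unit: /min
  min: 0.001
  max: 0.1
- id: 27
  name: ka_SN38
  unit: /min
  min: 0.001
  max: 0.1
- id: 28
  name: ka_SN38G
  unit: /min
  min: 0.001
  max: 0.1
- id: 29
  name: ka_NPC
  unit: /min
  min: 0.001
  max: 0.1
- id: 30
  name: ka_APC
  unit: /min
  min: 0.001
  max: 0.1
- id: 31
  name: kLI_CPT11
  unit: /min
  min: 0.001
  max: 0.1
- id: 32
  name: kLI_SN38
  unit: /min
  min: 0.001
  max: 0.1
- id: 33
  name: kLI_SN38G
  unit: /min
  min: 0.001
  max: 0.1
- id: 34
  name: kLI_NPC
  unit: /min
  min: 0.001
  max: 0.1
- id: 35
  name: kLI_APC
  unit: /min
  min: 0.001
  max: 0.1
- id: 36
  name: ktransit_CPT11
  unit: /min
  min: 0.001
  max: 0.1
- id: 37
  name: ktransit_SN38
  unit: /min
  min: 0.001
  max: 0.1
- id: 38
  name: ktransit_SN38G
  unit: /min
  min: 0.001
  max: 0.1
- id: 39
  name: ktransit_NPC
  unit: /min
  min: 0.001
  max: 0.1
- id: 40
  name: ktransit_APC
  unit: /min
  min: 0.001
  max: 0.1
- id: 41
  name: CL12_CPT11
  unit: ml/min
  min: 1.0
  max: 100.0
- id: 42
  name: CL12_SN38
  unit: ml/min
  min: 1.0
  max: 100.0
- id: 43
  name: CL12_SN38G
  unit: ml/min
  min: 1.0
  max: 100.0
- id: 44
  name: CL12_NPC
  unit: ml/min
  min: 1.0
  max: 100.0
- id: 45
  name: CL12_APC
  unit: ml/min
  min: 1.0
  max: 100.0
- id: 46
  name: k21_CPT11
  unit: /min
  min: 0.1
  max: 10.0
- id: 47
  name: k21_SN38
  unit: /min
  min: 0.1
  max: 10.0
- id: 48
  name: k21_SN38G
  unit: /min
  min: 0.1
  max: 10.0
- id: 49
  name: k21_NPC
  unit: /min
  min: 0.1
  max: 10.0
- id: 50
  name: k21_APC
  unit: /min
  min: 0.1
  max: 10.0
- id: 51
  name: Vrapid_CPT11
  unit: ml/kg
  min: 10.0
  max: 1000.0
- id: 52
  name: Vrapid_SN38
  unit: ml/kg
  min: 10.0
  max: 1000.0
- id: 53
  name: Vrapid_SN38G
  unit: ml/kg
  min: 10.0
  max: 1000.0
- id: 54
  name: Vrapid_NPC
  unit: ml/kg
  min: 10.0
  max: 1000.0
- id: 55
  name: Vrapid_APC
  unit: ml/kg
  min: 10.0
  max: 1000.0
- id: 56
  name: bile_Ttube_ratio
  unit: '-'
  min: 0.1
  max: 10.0
objectives:
- id: 1
  name: urine_CPT11
  value: 412.0
  unit: ug/kg
- id: 2
  name: urine_SN38
  value: 17.0
  unit: ug/kg
- id: 3
  name: urine_SN38G
  value: 227.0
  unit: ug/kg
- id: 4
  name: urine_NPC
  value: 1.7
  unit: ug/kg
- id: 5
  name: urine_APC
  value: 146.0
  unit: ug/kg
- id: 6
  name: feces_CPT11
  value: 118.0
  unit: ug/kg
- id: 7
  name: feces_SN38_SN38G
  value: 52.6
  unit: ug/kg
- id: 8
  name: feces_NPC
  value: 6.05
  unit: ug/kg
- id: 9
  name: feces_APC
  value: 31.4
  unit: ug/kg
- id: 10
  name: bile_CPT11
  value: 349.0
  unit: ug/kg
- id: 11
  name: bile_SN38
  value: 8.32
  unit: ug/kg
- id: 12
  name: bile_SN38G
  value: 50.5
  unit: ug/kg
- id: 13
  name: bile_NPC
  value: 5.68
  unit: ug/kg
- id: 14
  name: bile_APC
  value: 73.8
  unit: ug/kg
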