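effect_table_version: 1
rows:
- drug: aliskiren
  dose: 150.0
  target: DRI
  sign: '-'
  magnitude: emax
- drug: aliskiren
  dose: 300.0
  target: DRI
  sign: '-'
  magnitude: emax
- drug: amlodipine
  dose: 5.0
  target: CCBaa
  sign: '-'
  magnitude: 0.413
- drug: amlodipine
  dose: 5.0
  target: CCBea
  sign: '-'
  magnitude: 0.107
- drug: amlodipine
  dose: 5.0
  target: CCBpreglom
  sign: '-'
  magnitude: 0.413
- drug: amlodipine
  dose: 5.0
  target: CCBsys
  sign: '-'
  magnitude: 0.107
- drug: bisoprolol
  dose: 5.0
  target: Bblocker
  sign: '-'
  magnitude: 0.371
- drug: bisoprolol
  dose: 5.0
  target: Bblocker_rs
  sign: '-'
  magnitude: 0.933
- drug: enalapril
  dose: 20.0
  target: ACEi
  sign: '-'
  magnitude: 0.996
- drug: hctz
  dose: 12.5
  target: DiureticInhibition
  sign: '-'
  magnitude: 0.304
- drug: hctz
  dose: 12.5
  target: DiureticStimulation
  sign: +
  magnitude: 1.113
- drug: hctz
  dose: 12.5
  target: Diureticaa
  sign: '-'
  magnitude: 0.469
- drug: hctz
  dose: 12.5
  target: Diureticea
  sign: '-'
  magnitude: 0.302
- drug: hctz
  dose: 12.5
  target: Diureticpreglom
  sign: '-'
  magnitude: 0.581
- drug: hctz
  dose: 12.5
  target: Diureticsys
  sign: '-'
  magnitude: hctz_ramp
- drug: hctz
  dose: 12.5
  target: Diureticstress
  sign: '-'
  magnitude: 0.389
- drug: hctz
  dose: 12.5
  target: Diureticpotassium
  sign: '-'
  magnitude: 0.03
- drug: hctz
  dose: 12.5
  target: Diureticurea
  sign: +
  magnitude: 0.1
- drug: losartan
  dose: 50.0
  target: ARB
  sign: '-'
  magnitude: 0.886
- drug: losartan
  dose: 100.0
  target: ARB
  sign: '-'
  magnitude: 0.954
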