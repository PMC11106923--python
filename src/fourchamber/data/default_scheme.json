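{
  "Left Atrium": 1,
  "Left Ventricle": 2,
  "Right Atrium": 3,
  "Right Ventricle": 4,
  "Interventricular Septum": 5,
  "Interatrial Septum": 6,
  "Left Ventricular Wall": 7,
  "Right Ventricular Wall": 8,
  "Left Lung": 9,
  "Right Lung": 10,
  "Descending Aorta": 11,
  "Spine": 12,
  "RIB": 13,
  "Heart Area": 14,
  "Thorax Area": 15
}
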