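# Fugl-Meyer Assessment of Lower Extremity (FMA-LE), motor domain.
# 17 items in two subscales (E: lower extremity motor, F: coordination/speed),
# each scored 0 (none) / 1 (partial) / 2 (full).  Standard sum scores:
# SUM E II (0-14), SUM E III (0-4), SUM E IV (0-4), SUM E (0-28),
# SUM F (0-6), TOTAL E-F (0-34).
name: fma_le
items:
  - {id: e1_reflex_flexors, label: "Reflex activity: flexors", section: E.I, min: 0, max: 2}
  - {id: e1_reflex_extensors, label: "Reflex activity: extensors", section: E.I, min: 0, max: 2}
  - {id: e2_hip_flexion, label: "Within synergies, supine: hip flexion", section: E.II, min: 0, max: 2}
  - {id: e2_knee_flexion, label: "Within synergies, supine: knee flexion", section: E.II, min: 0, max: 2}
  - {id: e2_ankle_dorsiflexion, label: "Within synergies, supine: ankle dorsiflexion", section: E.II, min: 0, max: 2}
  - {id: e2_hip_extension, label: "Within synergies, supine: hip extension", section: E.II, min: 0, max: 2}
  - {id: e2_hip_adduction, label: "Within synergies, supine: hip adduction", section: E.II, min: 0, max: 2}
  - {id: e2_knee_extension, label: "Within synergies, supine: knee extension", section: E.II, min: 0, max: 2}
  - {id: e2_ankle_plantarflexion, label: "Within synergies, supine: ankle plantar flexion", section: E.II, min: 0, max: 2}
  - {id: e3_knee_flexion, label: "Mixed synergies, sitting: knee flexion", section: E.III, min: 0, max: 2}
  - {id: e3_ankle_dorsiflexion, label: "Mixed synergies, sitting: ankle dorsiflexion", section: E.III, min: 0, max: 2}
  - {id: e4_knee_flexion_90, label: "Little or no synergy, standing: knee flexion to 90 deg", section: E.IV, min: 0, max: 2}
  - {id: e4_ankle_dorsiflexion, label: "Little or no synergy, standing: ankle dorsiflexion", section: E.IV, min: 0, max: 2}
  - {id: e5_normal_reflexes, label: "Normal reflex activity: knee flexors, patellar, Achilles", section: E.V, min: 0, max: 2}
  - {id: f_tremor, label: "Coordination/speed: tremor", section: F, min: 0, max: 2}
  - {id: f_dysmetria, label: "Coordination/speed: dysmetria", section: F, min: 0, max: 2}
  - {id: f_time, label: "Coordination/speed: time", section: F, min: 0, max: 2}
sum_groups:
  SUM E II:
    [e2_hip_flexion, e2_knee_flexion, e2_ankle_dorsiflexion, e2_hip_extension,
     e2_hip_adduction, e2_knee_extension, e2_ankle_plantarflexion]
  SUM E III: [e3_knee_flexion, e3_ankle_dorsiflexion]
  SUM E IV: [e4_knee_flexion_90, e4_ankle_dorsiflexion]
  SUM E:
    [e1_reflex_flexors, e1_reflex_extensors,
     e2_hip_flexion, e2_knee_flexion, e2_ankle_dorsiflexion, e2_hip_extension,
     e2_hip_adduction, e2_knee_extension, e2_ankle_plantarflexion,
     e3_knee_flexion, e3_ankle_dorsiflexion,
     e4_knee_flexion_90, e4_ankle_dorsiflexion,
     e5_normal_reflexes]
  SUM F: [f_tremor, f_dysmetria, f_time]
  TOTAL E-F:
    [e1_reflex_flexors, e1_reflex_extensors,
     e2_hip_flexion, e2_knee_flexion, e2_ankle_dorsiflexion, e2_hip_extension,
     e2_hip_adduction, e2_knee_extension, e2_ankle_plantarflexion,
     e3_knee_flexion, e3_ankle_dorsiflexion,
     e4_knee_flexion_90, e4_ankle_dorsiflexion,
     e5_normal_reflexes,
     f_tremor, f_dysmetria, f_time]
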