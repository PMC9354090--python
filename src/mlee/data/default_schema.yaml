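# Default knowledge-graph schema for pediatric respiratory clinical records.
# Three-level hierarchy: entity type (sentence class) -> entity (segment label)
# -> attributes (sub-span labels).  The reserved "Other" sentence class is
# appended automatically and carries no entities.
version: "pediatric-respiratory-1"
entity_types:
  - name: Symptom
    entities:
      - name: Fever
        attributes: [Body Temperature, Occurrence, Duration]
      - name: Cough
        attributes: [Occurrence, Duration, Aggravating Factor, Relieving Factor,
                     Cough Frequency, Situation]
  - name: Treatment
    entities:
      - name: Medication Treatment
        attributes: [Drug name, Drug dose, Duration of course of treatment]
      - name: Operation
        attributes: [Type of operation, Date of operation, Adverse reactions]
  - name: Laboratory Test
    entities:
      - name: Laboratory Test Entity
        attributes: [Test item, Value]
  - name: Imaging
    entities:
      - name: Computed Tomography
        attributes: [Body part, Abnormal seen]
      - name: Magnetic Resonance Imaging
        attributes: [Body part, Abnormal seen, T1WI, T2WI]
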