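region,composite
TH-01,thalamus
TH-02,thalamus
TH-03,thalamus
TH-04,thalamus
TH-05,thalamus
TH-06,thalamus
TH-07,thalamus
TH-08,thalamus
TH-09,thalamus
TH-10,thalamus
TH-11,thalamus
TH-12,thalamus
TH-13,thalamus
TH-14,thalamus
TH-15,thalamus
TH-16,thalamus
TH-17,thalamus
TH-18,thalamus
TH-19,thalamus
TH-20,thalamus
TH-21,thalamus
TH-22,thalamus
TH-23,thalamus
TH-24,thalamus
TH-25,thalamus
TH-26,thalamus
TH-27,thalamus
TH-28,thalamus
TH-29,thalamus
TH-30,thalamus
SM-01,sensory_motor
SM-02,sensory_motor
SM-03,sensory_motor
SM-04,sensory_motor
SM-05,sensory_motor
SM-06,sensory_motor
SM-07,sensory_motor
SM-08,sensory_motor
SM-09,sensory_motor
SM-10,sensory_motor
SM-11,sensory_motor
SM-12,sensory_motor
SM-13,sensory_motor
SM-14,sensory_motor
SM-15,sensory_motor
SM-16,sensory_motor
SM-17,sensory_motor
SM-18,sensory_motor
SM-19,sensory_motor
SM-20,sensory_motor
PA-01,polymodal_association
PA-02,polymodal_association
PA-03,polymodal_association
PA-04,polymodal_association
PA-05,polymodal_association
PA-06,polymodal_association
PA-07,polymodal_association
PA-08,polymodal_association
PA-09,polymodal_association
PA-10,polymodal_association
PA-11,polymodal_association
PA-12,polymodal_association
PA-13,polymodal_association
PA-14,polymodal_association
PA-15,polymodal_association
PA-16,polymodal_association
PA-17,polymodal_association
PA-18,polymodal_association
PA-19,polymodal_association
PA-20,polymodal_association
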