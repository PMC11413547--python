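# health-related tokens for the covariate percentage
pain
pains
painful
ache
aches
aching
chronic
doctor
doctors
physician
nurse
clinic
hospital
medication
medications
medicine
meds
dose
dosage
prescription
prescribed
pharmacy
treatment
treatments
therapy
therapist
physical
surgery
surgeon
operation
injection
injections
nerve
nerves
spine
spinal
joint
joints
muscle
muscles
back
neck
shoulder
knee
hip
migraine
migraines
headache
headaches
fibromyalgia
arthritis
neuropathy
sciatica
inflammation
symptom
symptoms
diagnosis
diagnosed
condition
disease
illness
injury
injured
disability
disabled
insurance
specialist
appointment
mri
xray
scan
bloodwork
opioid
opioids
ibuprofen
acetaminophen
gabapentin
steroid
steroids
flare
flares
flareup
fatigue
insomnia
nausea
dizziness
health
healthcare
medical
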