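participant_id,sex,age,body_mass,injected_activity,status,sex_dose_tables
MMDM01,female,83,54,377,myeloma,female
MMDM02,male,63,77.1,366,myeloma,male
MMDM03,male,68,136.1,301.2,myeloma,male
MMDN01,female,44,68,257.5,healthy,male
MMDN02,male,30,90.7,357,healthy,male
MMDN03,female,25,61.2,347,healthy,female
MMDN04,female,25,63,370,healthy,female
MMDN05,male,25,77.1,433,healthy,male
MMDN06,female,27,66.7,361.5,healthy,female
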