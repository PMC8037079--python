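patient_id,age,sex,ais_head_neck,ais_face,ais_chest,ais_abdomen,ais_extremities,ais_external,gcs,asa,sbp,prbc_pre_icu,icu_admitted,mechanism,transfer_status,region_of_hospital,died_in_hospital
F01_all_criteria,85,male,5,0,2,0,0,0,3,4,80,true,true,traffic,primary,europe,true
F02_no_criteria,70,female,0,0,3,0,0,0,15,2,140,false,true,low_fall,primary,europe,false
F03_age_only,82,female,0,0,3,0,0,0,15,2,135,false,true,low_fall,primary,europe,false
F04_ais_only,70,male,4,0,0,0,0,0,14,1,130,false,true,traffic,primary,europe,false
F05_prbc_only,68,male,0,0,3,0,0,0,15,2,95,true,true,high_fall,primary,europe,false
F06_asa_only,66,female,0,0,0,0,3,0,14,3,150,false,true,low_fall,primary,europe,false
F07_gcs_only,72,male,3,0,0,0,0,0,12,1,145,false,true,traffic,primary,europe,false
F08_under_65,64,male,5,0,0,0,0,0,6,2,90,true,true,traffic,primary,europe,true
F09_missing_prbc,75,female,0,0,3,0,0,0,15,2,120,,true,low_fall,primary,europe,false
F10_gtos_227,80,male,5,0,4,3,0,0,15,2,85,true,true,traffic,primary,europe,true
F11_minor_no_icu,70,female,0,0,0,0,2,0,15,2,140,false,false,low_fall,primary,europe,false
F12_minor_icu,70,male,0,0,0,0,2,0,15,2,138,false,true,low_fall,primary,europe,false
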