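exam_type,phantom_age,organ,dose_mSv
WB_CT,0,total_body,4.8
NECK_CHEST_CT,0,total_body,2.6
WB_CT,1,total_body,5.7
NECK_CHEST_CT,1,total_body,3.0
WB_CT,5,total_body,6.9
NECK_CHEST_CT,5,total_body,3.3
WB_CT,10,total_body,6.9
NECK_CHEST_CT,10,total_body,3.5
WB_CT,15,total_body,9.0
NECK_CHEST_CT,15,total_body,4.4
WB_CT,adult,total_body,10.7
NECK_CHEST_CT,adult,total_body,5.3
WB_CT,0,effective_dose,5.5
NECK_CHEST_CT,0,effective_dose,3.4
PET,0,effective_dose,3.8
WB_CT,1,effective_dose,6.6
NECK_CHEST_CT,1,effective_dose,4.0
PET,1,effective_dose,2.8
WB_CT,5,effective_dose,8.3
NECK_CHEST_CT,5,effective_dose,4.5
PET,5,effective_dose,3.0
WB_CT,10,effective_dose,8.6
NECK_CHEST_CT,10,effective_dose,5.1
PET,10,effective_dose,3.6
WB_CT,15,effective_dose,11.0
NECK_CHEST_CT,15,effective_dose,6.2
PET,15,effective_dose,4.3
WB_CT,adult,effective_dose,13.3
NECK_CHEST_CT,adult,effective_dose,7.9
PET,adult,effective_dose,4.2
WB_CT,0,bone_marrow,2.2
NECK_CHEST_CT,0,bone_marrow,0.9
PET,0,bone_marrow,3.1
WB_CT,1,bone_marrow,2.7
NECK_CHEST_CT,1,bone_marrow,1.2
PET,1,bone_marrow,1.8
WB_CT,5,bone_marrow,4.1
NECK_CHEST_CT,5,bone_marrow,1.7
PET,5,bone_marrow,1.9
WB_CT,10,bone_marrow,6.2
NECK_CHEST_CT,10,bone_marrow,2.9
PET,10,bone_marrow,2.2
WB_CT,15,bone_marrow,10.4
NECK_CHEST_CT,15,bone_marrow,5.0
PET,15,bone_marrow,2.4
WB_CT,adult,bone_marrow,13.4
NECK_CHEST_CT,adult,bone_marrow,7.0
PET,adult,bone_marrow,2.4
WB_CT,0,stomach,6.2
NECK_CHEST_CT,0,stomach,4.6
PET,0,stomach,2.3
WB_CT,1,stomach,7.5
NECK_CHEST_CT,1,stomach,5.0
PET,1,stomach,2.0
WB_CT,5,stomach,9.3
NECK_CHEST_CT,5,stomach,4.0
PET,5,stomach,2.1
WB_CT,10,stomach,9.4
NECK_CHEST_CT,10,stomach,5.5
PET,10,stomach,2.2
WB_CT,15,stomach,11.8
NECK_CHEST_CT,15,stomach,5.0
PET,15,stomach,2.4
WB_CT,adult,stomach,13.9
NECK_CHEST_CT,adult,stomach,7.3
PET,adult,stomach,2.4
WB_CT,0,colon,6.0
NECK_CHEST_CT,0,colon,0.5
PET,0,colon,2.2
WB_CT,1,colon,7.1
NECK_CHEST_CT,1,colon,0.5
PET,1,colon,2.2
WB_CT,5,colon,8.6
NECK_CHEST_CT,5,colon,0.3
PET,5,colon,2.4
WB_CT,10,colon,8.7
NECK_CHEST_CT,10,colon,0.4
PET,10,colon,2.7
WB_CT,15,colon,10.8
NECK_CHEST_CT,15,colon,0.2
PET,15,colon,2.9
WB_CT,adult,colon,12.7
NECK_CHEST_CT,adult,colon,0.3
PET,adult,colon,2.9
WB_CT,0,liver,6.2
NECK_CHEST_CT,0,liver,4.6
PET,0,liver,4.4
WB_CT,1,liver,7.4
NECK_CHEST_CT,1,liver,5.2
PET,1,liver,2.0
WB_CT,5,liver,9.1
NECK_CHEST_CT,5,liver,4.6
PET,5,liver,2.2
WB_CT,10,liver,9.1
NECK_CHEST_CT,10,liver,6.1
PET,10,liver,2.2
WB_CT,15,liver,11.2
NECK_CHEST_CT,15,liver,6.3
PET,15,liver,2.4
WB_CT,adult,liver,13.0
NECK_CHEST_CT,adult,liver,8.5
PET,adult,liver,2.4
WB_CT,0,lung,6.7
NECK_CHEST_CT,0,lung,6.5
PET,0,lung,2.2
WB_CT,1,lung,8.1
NECK_CHEST_CT,1,lung,7.9
PET,1,lung,1.9
WB_CT,5,lung,10.1
NECK_CHEST_CT,5,lung,9.7
PET,5,lung,2.0
WB_CT,10,lung,10.1
NECK_CHEST_CT,10,lung,9.9
PET,10,lung,2.1
WB_CT,15,lung,12.4
NECK_CHEST_CT,15,lung,12.1
PET,15,lung,2.4
WB_CT,adult,lung,14.8
NECK_CHEST_CT,adult,lung,14.5
PET,adult,lung,2.2
WB_CT,0,breast,5.6
NECK_CHEST_CT,0,breast,5.5
PET,0,breast,2.3
WB_CT,1,breast,6.6
NECK_CHEST_CT,1,breast,6.3
PET,1,breast,1.6
WB_CT,5,breast,8.4
NECK_CHEST_CT,5,breast,8.0
PET,5,breast,1.7
WB_CT,10,breast,8.1
NECK_CHEST_CT,10,breast,8.1
PET,10,breast,1.8
WB_CT,15,breast,9.1
NECK_CHEST_CT,15,breast,9.0
PET,15,breast,1.9
WB_CT,adult,breast,11.1
NECK_CHEST_CT,adult,breast,11.0
PET,adult,breast,1.9
WB_CT,0,prostate,5.3
NECK_CHEST_CT,0,prostate,0.1
PET,0,prostate,2.7
WB_CT,1,prostate,5.9
NECK_CHEST_CT,1,prostate,0.0
PET,1,prostate,2.0
WB_CT,5,prostate,7.1
NECK_CHEST_CT,5,prostate,0.0
PET,5,prostate,2.1
WB_CT,10,prostate,7.0
NECK_CHEST_CT,10,prostate,0.0
PET,10,prostate,2.2
WB_CT,15,prostate,8.6
NECK_CHEST_CT,15,prostate,0.0
PET,15,prostate,2.4
WB_CT,adult,prostate,10.6
NECK_CHEST_CT,adult,prostate,0.0
PET,adult,prostate,2.4
WB_CT,0,uterus,6.1
NECK_CHEST_CT,0,uterus,0.3
PET,0,uterus,4.0
WB_CT,1,uterus,7.3
NECK_CHEST_CT,1,uterus,0.2
PET,1,uterus,2.9
WB_CT,5,uterus,9.0
NECK_CHEST_CT,5,uterus,0.1
PET,5,uterus,3.3
WB_CT,10,uterus,9.1
NECK_CHEST_CT,10,uterus,0.1
PET,10,uterus,3.9
WB_CT,15,uterus,11.6
NECK_CHEST_CT,15,uterus,0.1
PET,15,uterus,4.4
WB_CT,adult,uterus,14.4
NECK_CHEST_CT,adult,uterus,0.1
PET,adult,uterus,4.6
WB_CT,0,ovary,6.0
NECK_CHEST_CT,0,ovary,0.3
PET,0,ovary,3.3
WB_CT,1,ovary,7.0
NECK_CHEST_CT,1,ovary,0.3
PET,1,ovary,2.4
WB_CT,5,ovary,8.5
NECK_CHEST_CT,5,ovary,0.1
PET,5,ovary,2.6
WB_CT,10,ovary,8.6
NECK_CHEST_CT,10,ovary,0.1
PET,10,ovary,3.0
WB_CT,15,ovary,10.6
NECK_CHEST_CT,15,ovary,0.1
PET,15,ovary,3.4
WB_CT,adult,ovary,12.6
NECK_CHEST_CT,adult,ovary,0.1
PET,adult,ovary,3.3
WB_CT,0,bladder,6.0
NECK_CHEST_CT,0,bladder,0.1
PET,0,bladder,11.1
WB_CT,1,bladder,7.2
NECK_CHEST_CT,1,bladder,0.1
PET,1,bladder,17.2
WB_CT,5,bladder,9.0
NECK_CHEST_CT,5,bladder,0.0
PET,5,bladder,19.0
WB_CT,10,bladder,9.3
NECK_CHEST_CT,10,bladder,0.0
PET,10,bladder,27.9
WB_CT,15,bladder,12.2
NECK_CHEST_CT,15,bladder,0.0
PET,15,bladder,35.8
WB_CT,adult,bladder,15.3
NECK_CHEST_CT,adult,bladder,0.0
PET,adult,bladder,35.4
WB_CT,0,other_solid,4.8
NECK_CHEST_CT,0,other_solid,2.6
PET,0,other_solid,3.8
WB_CT,1,other_solid,5.7
NECK_CHEST_CT,1,other_solid,3.0
PET,1,other_solid,2.8
WB_CT,5,other_solid,6.9
NECK_CHEST_CT,5,other_solid,3.3
PET,5,other_solid,3.0
WB_CT,10,other_solid,6.9
NECK_CHEST_CT,10,other_solid,3.5
PET,10,other_solid,3.6
WB_CT,15,other_solid,9.0
NECK_CHEST_CT,15,other_solid,4.4
PET,15,other_solid,4.3
WB_CT,adult,other_solid,10.7
NECK_CHEST_CT,adult,other_solid,5.3
PET,adult,other_solid,4.2
WB_CT,0,thyroid,6.4
NECK_CHEST_CT,0,thyroid,6.4
PET,0,thyroid,2.2
WB_CT,1,thyroid,8.7
NECK_CHEST_CT,1,thyroid,8.6
PET,1,thyroid,2.0
WB_CT,5,thyroid,11.4
NECK_CHEST_CT,5,thyroid,11.3
PET,5,thyroid,2.1
WB_CT,10,thyroid,12.8
NECK_CHEST_CT,10,thyroid,12.7
PET,10,thyroid,2.1
WB_CT,15,thyroid,19.4
NECK_CHEST_CT,15,thyroid,19.5
PET,15,thyroid,2.2
WB_CT,adult,thyroid,24.8
NECK_CHEST_CT,adult,thyroid,24.8
PET,adult,thyroid,2.2
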