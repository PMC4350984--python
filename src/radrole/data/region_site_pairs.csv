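body_region_group,site_group
Chest,Lung
Chest,Breast
Chest,Other GI
Chest,Lymphoid/leukemia
Chest,Hodgkin's disease
Chest,Unspecified group 2
Organs and tissues in pelvis region,Prostate/Testis/Penis
Organs and tissues in pelvis region,Bladder
Organs and tissues in pelvis region,Rectum
Organs and tissues in pelvis region,Other GYN
Organs and tissues in pelvis region,Ovary
Pelvis – single side,Prostate/Testis/Penis
Pelvis – single side,Bladder
Pelvis – single side,Other GYN
Pelvis – single side,Kidney
Pelvis – both sides,Prostate/Testis/Penis
Pelvis – both sides,Rectum
Pelvis – both sides,Bladder
Pelvis – both sides,Other GYN
Pelvis – both sides,Colon/intestines
Brain,CNS
Brain,Lung
Brain,Melanoma
Brain,Unspecified group 2
Neck,Head/neck
Neck,Other head/neck
Neck,Thyroid/Endo
Neck,Lymphoid/leukemia
Neck,Hodgkin's disease
Head,Head/neck
Head,Other head/neck
Head,skin
Head,CNS
"Bone – spine, limb, chest, head",Myeloma
"Bone – spine, limb, chest, head",Breast
"Bone – spine, limb, chest, head",Prostate/Testis/Penis
"Bone – spine, limb, chest, head",Lung
"Bone – spine, limb, chest, head",Kidney
"Bone – spine, limb, chest, head",Bone
"Bone – spine, limb, chest, head",Unspecified group 2
Abdomen,Other GI
Abdomen,Liver
Abdomen,Colon/intestines
Abdomen,Kidney
Abdomen,Ovary
Abdomen,Lymphoid/leukemia
Abdomen,Unspecified group 1
Skin,skin
Skin,Melanoma
Skin,Soft tissue
Other regions,Soft tissue
Other regions,Unspecified group 1
Other regions,Melanoma
Other regions,Lymphoid/leukemia
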