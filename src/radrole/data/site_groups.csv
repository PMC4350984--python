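site_group,icd9_codes
Head/neck,"140-144,146-149,160,161"
Other head/neck,""
Other GI,"150,151,156-159"
Colon/intestines,"152,153"
Rectum,"154"
Liver,"155"
Lung,"162-165"
Bone,"170"
Soft tissue,"171"
Melanoma,"172"
skin,"173"
Breast,"174,175"
Other GYN,"179-182,184"
Ovary,"183"
Prostate/Testis/Penis,"185-187"
Bladder,"188"
Kidney,"189"
CNS,"190-192"
Thyroid/Endo,"193,194"
Unspecified group 1,"195,196"
Unspecified group 2,"197-199"
Lymphoid/leukemia,"200,202,204-208"
Hodgkin's disease,"201"
Myeloma,"203"
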