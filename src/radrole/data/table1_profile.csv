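variable,level,n_curative,n_palliative,pct_curative,pct_palliative
body_region_group,Chest,123378,12144,91,9
body_region_group,Organs and tissues in pelvis region,78220,2211,97,3
body_region_group,Pelvis – single side,1057,1332,44,56
body_region_group,Pelvis – both sides,27902,2685,91,9
body_region_group,Brain,9177,8589,52,48
body_region_group,Neck,16378,1336,92,8
body_region_group,Head,14256,1020,93,7
body_region_group,"Bone – spine, limb, chest, head",3817,14353,21,79
body_region_group,Abdomen,7206,2614,73,27
body_region_group,Skin,983,357,73,27
body_region_group,Other regions,7116,262,96,4
site_group,Head/neck,26090,924,97,3
site_group,Other head/neck,3735,309,92,8
site_group,Colon/intestines,1782,1271,58,42
site_group,Rectum,17585,1709,91,9
site_group,Liver,140,226,38,62
site_group,Other GI,6736,2349,74,26
site_group,Lung,18850,15319,55,45
site_group,Bone,245,114,68,32
site_group,Soft tissue,1942,303,86,14
site_group,Melanoma,1390,1204,54,46
site_group,skin,134,23,85,15
site_group,Breast,97728,6897,93,7
site_group,Ovary,461,541,46,54
site_group,Other GYN,12791,1391,90,10
site_group,Prostate/Testis/Penis,74061,3896,95,5
site_group,Bladder,2206,1075,67,33
site_group,Kidney,464,1504,24,76
site_group,CNS,7524,604,93,7
site_group,Thyroid/Endo,727,318,70,30
site_group,Unspecified group 1,1271,176,88,12
site_group,Unspecified group 2,4152,2153,66,34
site_group,Lymphoid/leukemia,7295,2933,71,29
site_group,Hodgkin's disease,1697,116,94,6
site_group,Myeloma,484,1548,24,76
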