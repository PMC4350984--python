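verbatim,body_region_group
chest,Chest
chest wall,Chest
thorax,Chest
lung,Chest
mediastinum,Chest
breast,Chest
rib,Chest
pelvic organs,Organs and tissues in pelvis region
prostate,Organs and tissues in pelvis region
bladder,Organs and tissues in pelvis region
rectum,Organs and tissues in pelvis region
cervix,Organs and tissues in pelvis region
uterus,Organs and tissues in pelvis region
pelvis,Pelvis – both sides
whole pelvis,Pelvis – both sides
pelvis bilateral,Pelvis – both sides
pelvis left,Pelvis – single side
pelvis right,Pelvis – single side
hip,Pelvis – single side
brain,Brain
whole brain,Brain
cranium,Brain
neck,Neck
cervical nodes,Neck
larynx,Neck
head,Head
face,Head
scalp,Head
sinus,Head
spine,"Bone – spine, limb, chest, head"
lumbar spine,"Bone – spine, limb, chest, head"
thoracic spine,"Bone – spine, limb, chest, head"
cervical spine,"Bone – spine, limb, chest, head"
femur,"Bone – spine, limb, chest, head"
humerus,"Bone – spine, limb, chest, head"
limb,"Bone – spine, limb, chest, head"
sternum,"Bone – spine, limb, chest, head"
skull,"Bone – spine, limb, chest, head"
bone,"Bone – spine, limb, chest, head"
abdomen,Abdomen
whole abdomen,Abdomen
liver,Abdomen
para-aortic nodes,Abdomen
kidney,Abdomen
skin,Skin
skin lesion,Skin
other,Other regions
total body,Other regions
hemibody,Other regions
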