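"""Classify treatments with the shipped Ontario reference tree.

The reference tree encodes the published fragment of the province-wide
Ontario analysis: fraction size splits the root at 277 cGy; large-fraction
treatments to abdomen/chest/brain/bone/neck/pelvis are palliative, while
prostate-to-pelvis, head-and-neck-to-head and skin-to-skin treatments stay
curative (hypo-fractionated cures); endpoints the analysis does not state
are labelled 'unspecified'.
"""

from radrole import extract_rules, ontario_reference_tree, render_rules

tree = ontario_reference_tree()
print(render_rules(extract_rules(tree)))

examples = [
    ("30 x 200 cGy to chest (lung primary)",
     {"fraction_size": 200.0, "days_from_first": 10.0,
      "body_region_group": "Chest", "site_group": "Lung"}),
    ("5 x 400 cGy to spine (breast primary)",
     {"fraction_size": 400.0, "days_from_first": 200.0,
      "body_region_group": "Bone – spine, limb, chest, head", "site_group": "Breast"}),
    ("single 350 cGy fraction to skin (skin primary)",
     {"fraction_size": 350.0, "days_from_first": 0.0,
      "body_region_group": "Skin", "site_group": "skin"}),
]
for description, record in examples:
    label, leaf_id, _ = tree.classify(record)
    print(f"{description}: {label} (endpoint {leaf_id})")
print("\n'unspecified' marks paths whose published label is unknown; "
      "grow your own tree for a fully labelled classifier.")
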