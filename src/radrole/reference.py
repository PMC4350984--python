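"""Partially specified reference classification tree for Ontario data.

The province-wide Ontario analysis of 2005-2008 administrative radiotherapy
records describes its final tree only in part: the root splits on fraction
size at 277 cGy; among large-fraction treatments those aimed at abdomen,
chest, brain, bone, neck or pelvis are predominantly palliative, while
prostate/testis cancers treated to the pelvic organs, head-and-neck cancers
treated to the head, and skin cancers treated to the skin remain curative
despite the large fractions (hypo-fractionated curative regimens); among
small-fraction treatments the next determinant is the time since the first
treatment, with re-treatments starting beyond roughly two and a half months
(75 days) more likely palliative.

This module encodes exactly those stated paths. Endpoints whose label the
source analysis does not state carry the label ``unspecified``; support
counts are unpublished and stored as zero.
"""

from __future__ import annotations

from .chaid import (
    KIND_PARTITION,
    KIND_THRESHOLD,
    UNSPECIFIED,
    ClassificationTree,
    InductionParams,
    SplitCandidate,
    TreeNode,
)
from .records import CURATIVE, PALLIATIVE

#: body-region groups that are predominantly palliative at >= 277 cGy
PALLIATIVE_REGIONS_LARGE_FRACTION = frozenset(
    {
        "Abdomen",
        "Chest",
        "Brain",
        "Bone – spine, limb, chest, head",
        "Neck",
        "Pelvis – single side",
        "Pelvis – both sides",
    }
)

ROOT_FRACTION_THRESHOLD = 277.0  # cGy
RETREATMENT_DAYS_THRESHOLD = 75.0  # ~ two and a half months


def _split(variable, kind, threshold=None, left_categories=None):
    # statistics of the reference splits are unpublished; stored as NaN-free
    # placeholders (chi2 0, p 1, multiplier 1)
    return SplitCandidate(
        variable=variable,
        kind=kind,
        threshold=threshold,
        left_categories=left_categories,
        chi2=0.0,
        p_raw=1.0,
        bonferroni_multiplier=1,
        p_adj=1.0,
        child_sizes=(0, 0),
    )


def _leaf(node_id, label):
    return TreeNode(node_id=node_id, n_curative=0, n_palliative=0, label=label)


def ontario_reference_tree() -> ClassificationTree:
    """Build the partial reference tree (unstated endpoints ``unspecified``)."""
    # right side of the root: fraction_size >= 277 cGy
    site_chain_skin = TreeNode(
        node_id=8,
        n_curative=0,
        n_palliative=0,
        split=_split("site_group", KIND_PARTITION, left_categories=frozenset({"skin"})),
        left=_leaf(9, CURATIVE),
        right=_leaf(10, UNSPECIFIED),
    )
    site_chain_headneck = TreeNode(
        node_id=6,
        n_curative=0,
        n_palliative=0,
        split=_split("site_group", KIND_PARTITION, left_categories=frozenset({"Head/neck"})),
        left=_leaf(7, CURATIVE),
        right=site_chain_skin,
    )
    site_chain_prostate = TreeNode(
        node_id=4,
        n_curative=0,
        n_palliative=0,
        split=_split(
            "site_group", KIND_PARTITION, left_categories=frozenset({"Prostate/Testis/Penis"})
        ),
        left=_leaf(5, CURATIVE),
        right=site_chain_headneck,
    )
    large_fraction = TreeNode(
        node_id=2,
        n_curative=0,
        n_palliative=0,
        split=_split(
            "body_region_group",
            KIND_PARTITION,
            left_categories=PALLIATIVE_REGIONS_LARGE_FRACTION,
        ),
        left=_leaf(3, PALLIATIVE),
        right=site_chain_prostate,
    )
    # left side of the root: fraction_size < 277 cGy, split on treatment time
    small_fraction = TreeNode(
        node_id=11,
        n_curative=0,
        n_palliative=0,
        split=_split("days_from_first", KIND_THRESHOLD, threshold=RETREATMENT_DAYS_THRESHOLD),
        left=_leaf(12, UNSPECIFIED),
        right=_leaf(13, UNSPECIFIED),
    )
    root = TreeNode(
        node_id=0,
        n_curative=0,
        n_palliative=0,
        split=_split("fraction_size", KIND_THRESHOLD, threshold=ROOT_FRACTION_THRESHOLD),
        left=small_fraction,
        right=large_fraction,
    )
    return ClassificationTree(
        root=root,
        params=InductionParams(),
        variables=("fraction_size", "site_group", "body_region_group", "days_from_first"),
        provenance="Ontario 2005-2008 reference tree (partial; unstated endpoints 'unspecified')",
    )
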