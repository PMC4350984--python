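import os
import sys

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, os.path.dirname(__file__))  # for _oracles

from radrole.chaid import (
    ClassificationTree,
    InductionParams,
    SplitCandidate,
    TreeNode,
    KIND_PARTITION,
    KIND_THRESHOLD,
)


@pytest.fixture
def grouping_maps():
    from radrole.records import load_grouping_maps

    return load_grouping_maps()


@pytest.fixture
def small_records_csv(tmp_path):
    path = tmp_path / "records.csv"
    path.write_text(
        "patient_id,cancer_id,treat_date,fraction_size,body_region_group,site_group,intent_raw\n"
        "p1,p1,2006-01-02,200,Chest,Breast,curative\n"
        "p1,p1,2006-01-03,200,Chest,Breast,curative\n"
        "p2,p2,2006-03-01,,Brain,Lung,palliative\n"
    )
    return path


def _placeholder_split(variable, kind, threshold=None, left_categories=None):
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


def make_generative_tree():
    """Known 3-split tree used by the recovery experiments.

    Root: fraction_size >= 277 cGy. Small-fraction side splits on
    days_from_first at 75 days (re-treatments palliative); large-fraction
    side splits on a two-region palliative body-region set. Designed so
    that, under a uniform feature distribution, fraction_size carries the
    strongest marginal chi-square signal at the root.
    """

    def leaf(node_id, label):
        return TreeNode(node_id=node_id, n_curative=0, n_palliative=0, label=label)

    small = TreeNode(
        node_id=1,
        n_curative=0,
        n_palliative=0,
        split=_placeholder_split("days_from_first", KIND_THRESHOLD, threshold=75.0),
        left=leaf(2, "C"),
        right=leaf(3, "P"),
    )
    large = TreeNode(
        node_id=4,
        n_curative=0,
        n_palliative=0,
        split=_placeholder_split(
            "body_region_group",
            KIND_PARTITION,
            left_categories=frozenset({"Bone – spine, limb, chest, head", "Brain"}),
        ),
        left=leaf(5, "P"),
        right=leaf(6, "C"),
    )
    root = TreeNode(
        node_id=0,
        n_curative=0,
        n_palliative=0,
        split=_placeholder_split("fraction_size", KIND_THRESHOLD, threshold=277.0),
        left=small,
        right=large,
    )
    return ClassificationTree(
        root=root,
        params=InductionParams(),
        variables=("fraction_size", "days_from_first", "body_region_group"),
        provenance="generative tree for recovery experiments",
    )


#: feature space matched to the generative tree: the root threshold sits at
#: the midpoint of the fraction-size range, 80% of days exceed 75, and 2 of
#: 10 body regions form the palliative set
GENERATIVE_FEATURE_SPACE = {
    "fraction_size": ("continuous", (50.0, 504.0)),
    "days_from_first": ("continuous", (0.0, 375.0)),
    "body_region_group": (
        "categorical",
        (
            "Chest",
            "Organs and tissues in pelvis region",
            "Pelvis – both sides",
            "Brain",
            "Neck",
            "Head",
            "Bone – spine, limb, chest, head",
            "Abdomen",
            "Skin",
            "Other regions",
        ),
    ),
}


def random_grown_tree(seed, n=1500, min_node=40, alpha=1.0):
    """A valid random tree: grow on random feature data with noisy labels."""
    from radrole.chaid import grow_tree
    from radrole.synthdata import generate_from_tree

    rng = np.random.default_rng(seed)
    base = make_generative_tree()
    purity = float(rng.uniform(0.7, 0.95))
    df = generate_from_tree(base, purity, n, GENERATIVE_FEATURE_SPACE, seed=seed)
    params = InductionParams(alpha=alpha, min_node=min_node)
    return grow_tree(df, base.variables, params), df
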