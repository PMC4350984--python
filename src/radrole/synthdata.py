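"""Synthetic administrative radiotherapy record sets with known truth.

The generator emulates the structure of daily-fraction records extracted
from a record-and-verify system: per patient one (occasionally two) courses
of consecutive weekday fractions, each course delivered with a latent
therapeutic role. Curative courses are long (15-35 fractions) with small
fractions centred at 200 cGy; palliative courses are short (1-10 fractions)
with large fractions, median 300 cGy. Re-treatment courses, when they
occur, are predominantly palliative. Site and body-region frequencies
follow the Ontario reference profile shipped with the package, restricted
to anatomically plausible region/site pairs.

Noise processes, applied independently per record: the recorded intent is
the true role flipped with ``intent_flip_rate`` and then masked with
``intent_missing_rate``; each classification variable is masked at its own
missingness rate. Everything is reproducible from a single seed.

A second generator, :func:`generate_from_tree`, draws records uniformly
over a configurable feature space so that the Bayes-optimal label of each
leaf region of a given tree equals the leaf's label with a chosen purity —
the harness for tree-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chaid import ClassificationTree, UNSPECIFIED
from .records import (
    CURATIVE,
    PALLIATIVE,
    _data_path,
    compute_days_from_first,
    binarize_intent_column,
    table1_profile,
)

#: strings used for the recorded intent of each role
INTENT_STRINGS = {
    CURATIVE: ("curative", "radical", "adjuvant"),
    PALLIATIVE: ("palliative",),
}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the generator.

    Defaults reproduce the reference profile: 14% of records palliative,
    curative/palliative fraction-size medians 200/300 cGy, per-variable
    completeness 99/91/97/100% (fraction size / body region / site / time),
    4% intent flips and 18.8% missing intent.
    """

    n_patients: int = 2000
    palliative_record_fraction: float = 0.14
    curative_fractions: tuple[int, int] = (15, 35)
    curative_dose_mean: float = 200.0
    curative_dose_sd: float = 25.0
    palliative_fractions: tuple[int, int] = (1, 10)
    palliative_doses: tuple[float, ...] = (300.0, 400.0, 500.0, 600.0, 800.0)
    palliative_dose_weights: tuple[float, ...] = (0.55, 0.18, 0.12, 0.10, 0.05)
    missing_rates: dict = field(
        default_factory=lambda: {
            "fraction_size": 0.01,
            "body_region_group": 0.09,
            "site_group": 0.03,
            "days_from_first": 0.0,
        }
    )
    intent_flip_rate: float = 0.04
    intent_missing_rate: float = 0.188
    technique_missing_rate: float = 0.05
    retreat_prob: float = 0.15
    retreat_palliative_prob: float = 0.90
    n_centres: int = 8
    start_date: str = "2004-01-01"
    end_date: str = "2008-06-30"
    seed: int = 0

    def __post_init__(self):
        for name in ("palliative_record_fraction", "intent_flip_rate", "intent_missing_rate",
                     "retreat_prob", "retreat_palliative_prob", "technique_missing_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for v in self.missing_rates.values():
            if not (0 <= v <= 1):
                raise ValueError("missing rates must be in [0, 1]")
        if min(self.palliative_doses) <= 0 or self.curative_dose_mean <= 0:
            raise ValueError("doses must be positive")

    @property
    def course_palliative_prob(self) -> float:
        """Course-level palliative probability that yields the target
        record-level palliative fraction, given the two regimen lengths."""
        e_cur = (self.curative_fractions[0] + self.curative_fractions[1]) / 2.0
        e_pal = (self.palliative_fractions[0] + self.palliative_fractions[1]) / 2.0
        q = self.palliative_record_fraction
        return q * e_cur / (q * e_cur + (1 - q) * e_pal)

    @property
    def first_course_palliative_prob(self) -> float:
        """First-course palliative probability after accounting for the
        (mostly palliative) re-treatment courses."""
        p = self.course_palliative_prob
        r = self.retreat_prob
        return float(np.clip(p * (1 + r) - r * self.retreat_palliative_prob, 0.0, 1.0))


def _role_tables(rng: np.random.Generator):
    """Role-conditional sampling tables for (body region, site group)."""
    profile = table1_profile()
    pairs = pd.read_csv(_data_path("region_site_pairs.csv"))
    region = profile[profile["variable"] == "body_region_group"].set_index("level")
    site = profile[profile["variable"] == "site_group"].set_index("level")
    tables = {}
    for role, col in ((CURATIVE, "n_curative"), (PALLIATIVE, "n_palliative")):
        region_p = region[col] / region[col].sum()
        per_region = {}
        for reg, grp in pairs.groupby("body_region_group"):
            weights = site.loc[grp["site_group"], col].to_numpy(dtype=float)
            if weights.sum() == 0:
                weights = np.ones(len(grp))
            per_region[reg] = (grp["site_group"].to_numpy(), weights / weights.sum())
        tables[role] = (region_p.index.to_numpy(), region_p.to_numpy(), per_region)
    return tables


def generate_records(config: SynthConfig | None = None) -> pd.DataFrame:
    """Generate a record set with a hidden ``true_role`` column.

    Returns a frame in the canonical record schema plus ``record_id``,
    ``true_role``, ``intent_flag`` and ``days_from_first``. The
    ``true_role`` column is the latent truth used only by tests and audits;
    :func:`write_synthetic` separates it into a sidecar file.
    """
    if config is None:
        config = SynthConfig()
    rng = np.random.default_rng(config.seed)
    n_pat = config.n_patients

    # --- courses ----------------------------------------------------------
    start = pd.Timestamp(config.start_date)
    end = pd.Timestamp(config.end_date)
    horizon = (end - start).days - 200
    first_start = start + pd.to_timedelta(rng.integers(0, max(horizon, 1), n_pat), unit="D")
    first_pal = rng.random(n_pat) < config.first_course_palliative_prob
    retreat = rng.random(n_pat) < config.retreat_prob
    retreat_pal = rng.random(n_pat) < config.retreat_palliative_prob
    retreat_start = first_start + pd.to_timedelta(rng.integers(60, 400, n_pat), unit="D")

    course_patient = np.concatenate([np.arange(n_pat), np.nonzero(retreat)[0]])
    course_pal = np.concatenate([first_pal, retreat_pal[retreat]])
    course_start = np.concatenate([first_start.to_numpy(), retreat_start.to_numpy()[retreat]])

    n_courses = len(course_patient)
    lo_c, hi_c = config.curative_fractions
    lo_p, hi_p = config.palliative_fractions
    n_frac = np.where(
        course_pal,
        rng.integers(lo_p, hi_p + 1, n_courses),
        rng.integers(lo_c, hi_c + 1, n_courses),
    )
    dose = np.where(
        course_pal,
        rng.choice(config.palliative_doses, size=n_courses, p=config.palliative_dose_weights),
        np.clip(np.round(rng.normal(config.curative_dose_mean, config.curative_dose_sd, n_courses)), 50, None),
    )

    tables = _role_tables(rng)
    regions = np.empty(n_courses, dtype=object)
    sites = np.empty(n_courses, dtype=object)
    for role, mask in ((CURATIVE, ~course_pal), (PALLIATIVE, course_pal)):
        k = int(mask.sum())
        if k == 0:
            continue
        region_levels, region_p, per_region = tables[role]
        reg = rng.choice(region_levels, size=k, p=region_p)
        regions[mask] = reg
        chosen = np.empty(k, dtype=object)
        for r in np.unique(reg):
            levels, p = per_region[r]
            idx = np.nonzero(reg == r)[0]
            chosen[idx] = rng.choice(levels, size=len(idx), p=p)
        sites[mask] = chosen

    # --- expand courses to daily records ---------------------------------
    rec_course = np.repeat(np.arange(n_courses), n_frac)
    within = np.concatenate([np.arange(k) for k in n_frac])
    n_rec = len(rec_course)
    dates = np.busday_offset(
        course_start[rec_course].astype("datetime64[D]"), within, roll="forward"
    )
    role = np.where(course_pal[rec_course], PALLIATIVE, CURATIVE)

    patient_ids = np.array([f"PT{i:06d}" for i in range(n_pat)])
    centres = np.array([f"C{c + 1}" for c in rng.integers(0, config.n_centres, n_pat)])

    df = pd.DataFrame(
        {
            "record_id": np.arange(n_rec),
            "patient_id": patient_ids[course_patient[rec_course]],
            "cancer_id": patient_ids[course_patient[rec_course]],
            "centre": centres[course_patient[rec_course]],
            "treat_date": pd.to_datetime(dates),
            "fraction_size": dose[rec_course].astype(float),
            "body_region_group": regions[rec_course],
            "site_group": sites[rec_course],
            "technique": np.where(
                rng.random(n_rec) < np.where(role == PALLIATIVE, 0.6, 0.1),
                "single-field",
                "multi-field",
            ),
            "true_role": role,
        }
    )

    # --- intent noise: flip, then mask ------------------------------------
    flipped = np.where(
        rng.random(n_rec) < config.intent_flip_rate,
        np.where(role == CURATIVE, PALLIATIVE, CURATIVE),
        role,
    )
    intent_raw = np.empty(n_rec, dtype=object)
    for r, options in INTENT_STRINGS.items():
        mask = flipped == r
        intent_raw[mask] = rng.choice(options, size=int(mask.sum()))
    intent_raw[rng.random(n_rec) < config.intent_missing_rate] = None
    df["intent_raw"] = intent_raw

    # --- per-variable missingness -----------------------------------------
    for col, rate in config.missing_rates.items():
        if rate <= 0:
            continue
        target = "treat_date" if col == "days_from_first" else col
        mask = rng.random(n_rec) < rate
        df.loc[mask, target] = None
    df.loc[rng.random(n_rec) < config.technique_missing_rate, "technique"] = None

    df["intent_flag"] = binarize_intent_column(df["intent_raw"])
    df = compute_days_from_first(df)
    return df.reset_index(drop=True)


def write_synthetic(df: pd.DataFrame, records_path, truth_path) -> None:
    """Write the records CSV (without truth) and the hidden-truth sidecar."""
    from .records import write_records

    public = df.drop(columns=["true_role"])
    write_records(public, records_path)
    df[["record_id", "true_role"]].to_csv(truth_path, index=False)


# ---------------------------------------------------------------------------
# tree-recovery harness
# ---------------------------------------------------------------------------

DEFAULT_FEATURE_SPACE = {
    "fraction_size": ("continuous", (50.0, 1000.0)),
    "days_from_first": ("continuous", (0.0, 365.0)),
    "body_region_group": ("categorical", None),  # None -> Table-1 vocabulary
    "site_group": ("categorical", None),
}


def generate_from_tree(
    tree: ClassificationTree,
    purity: float,
    n_records: int,
    feature_space: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample records uniformly over the feature space so each leaf region's
    Bayes-optimal label equals the tree's leaf label with the given purity.

    The tree's leaves must all be labelled C or P; ``purity`` must lie in
    (0.5, 1]. The recorded intent equals the (noisy) true role — the
    purity is the only noise, so a perfect inducer can recover the tree.
    """
    if not (0.5 < purity <= 1.0):
        raise ValueError("purity must be in (0.5, 1]")
    for leaf in tree.leaves():
        if leaf.label == UNSPECIFIED or leaf.label not in (CURATIVE, PALLIATIVE):
            raise ValueError(f"leaf {leaf.node_id} has unusable label {leaf.label!r}")
    space = dict(DEFAULT_FEATURE_SPACE)
    if feature_space:
        space.update(feature_space)
    rng = np.random.default_rng(seed)
    profile = table1_profile()
    data = {}
    for var in tree.variables:
        kind, spec = space[var]
        if kind == "continuous":
            lo, hi = spec
            data[var] = rng.uniform(lo, hi, n_records)
        else:
            levels = spec
            if levels is None:
                levels = profile.loc[profile["variable"] == var, "level"].tolist()
            data[var] = rng.choice(np.asarray(levels, dtype=object), size=n_records)
    df = pd.DataFrame(data)
    df.insert(0, "record_id", np.arange(n_records))
    leaf_labels = tree.classify_frame(df)["label"].to_numpy()
    keep = rng.random(n_records) < purity
    other = np.where(leaf_labels == CURATIVE, PALLIATIVE, CURATIVE)
    df["true_role"] = np.where(keep, leaf_labels, other)
    df["intent_flag"] = df["true_role"]
    return df
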