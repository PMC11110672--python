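"""Flowering-habit trait ontology for heterogeneous biennial-vegetable accessions.

A genebank accession of an outcrossing biennial crop such as carrot is a
heterogeneous population: individual plants may be early annual (flowering by
mid-season, ~60 days after sowing), late annual (flowering by end of season,
~100 DAS) or obligate biennial (never flowering without vernalization).  The
ontology implemented here assigns each accession a flowering-habit category
from its estimated marginal mean percent flowering at the two timepoints:

* ``biennial`` — exactly 0% flowering at 100 DAS;
* ``annual`` — more than ``t_high`` (default 85) percent flowering at 100 DAS,
  subdivided by the 60 DAS mean into ``uniformly_early_annual`` (> ``t_high``
  at 60 DAS), ``uniformly_late_annual`` (≤ ``t_low``, default 15, at 60 DAS)
  and ``non_uniform_annual`` (in between);
* ``mixture`` — anything else (flowering strictly between 0 and ``t_high`` at
  100 DAS), subdivided into ``predominantly_biennial`` (≤ ``t_low`` at both
  timepoints) and ``other_mixture``.

A coarser three-category baseline mirroring legacy genebank "life form"
descriptors is also provided: biennial = 0%, annual = 100%, mixture otherwise.
Both schemes agree exactly on the biennial set, which requires literal zero
observed flowering.

Boundary semantics are fixed half-open so the partition of [0, 100]^2 is total
and disjoint; marginal means are rounded to 4 decimals before comparison to
avoid float-boundary flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._utils import round_half_away

CATEGORIES = ("biennial", "mixture", "annual")
SUBCATEGORIES = (
    "none",
    "predominantly_biennial",
    "other_mixture",
    "uniformly_early_annual",
    "uniformly_late_annual",
    "non_uniform_annual",
)
#: leaf labels used as simulation ground truth
LEAF_CATEGORIES = (
    "biennial",
    "predominantly_biennial",
    "other_mixture",
    "uniformly_early_annual",
    "uniformly_late_annual",
    "non_uniform_annual",
)

_SUB_TO_CAT = {
    "predominantly_biennial": "mixture",
    "other_mixture": "mixture",
    "uniformly_early_annual": "annual",
    "uniformly_late_annual": "annual",
    "non_uniform_annual": "annual",
    "none": None,
}


@dataclass(frozen=True)
class Thresholds:
    """Percent-flowering cut points of the ontology (defaults 15 and 85)."""

    t_low: float = 15.0
    t_high: float = 85.0

    def __post_init__(self):
        if not (0.0 < self.t_low < self.t_high < 100.0):
            raise ValueError(
                f"thresholds must satisfy 0 < t_low < t_high < 100, "
                f"got t_low={self.t_low}, t_high={self.t_high}"
            )


@dataclass(frozen=True)
class FloweringHabitCall:
    """Category assignment for one accession under one scheme."""

    accession_id: str
    scheme: str  # "carrotomics" | "grin_baseline"
    category: str
    subcategory: str
    emm60: float
    emm100: float

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.subcategory not in SUBCATEGORIES:
            raise ValueError(f"unknown subcategory {self.subcategory!r}")
        parent = _SUB_TO_CAT[self.subcategory]
        if parent is not None and parent != self.category:
            raise ValueError(
                f"subcategory {self.subcategory} inconsistent with category {self.category}"
            )
        if self.scheme == "grin_baseline" and self.subcategory != "none":
            raise ValueError("grin_baseline scheme carries no subcategory")


def _check_percent(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(np.isnan(x)) or np.any(x < 0) or np.any(x > 100):
        raise ValueError(f"{name} must lie in [0, 100]")
    return np.round(x, 4)


def classify_arrays(
    emm60, emm100, thresholds: Thresholds = Thresholds()
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised ontology classification.

    Returns ``(category, subcategory)`` object arrays over broadcast inputs.
    """
    e60 = _check_percent(emm60, "emm60")
    e100 = _check_percent(emm100, "emm100")
    e60, e100 = np.broadcast_arrays(e60, e100)
    lo, hi = thresholds.t_low, thresholds.t_high

    cat = np.empty(e60.shape, dtype=object)
    sub = np.empty(e60.shape, dtype=object)

    biennial = e100 == 0.0
    annual = e100 > hi
    mixture = ~biennial & ~annual

    cat[biennial] = "biennial"
    sub[biennial] = "none"

    cat[annual] = "annual"
    sub[annual & (e60 > hi)] = "uniformly_early_annual"
    sub[annual & (e60 <= lo)] = "uniformly_late_annual"
    sub[annual & (e60 > lo) & (e60 <= hi)] = "non_uniform_annual"

    cat[mixture] = "mixture"
    pb = mixture & (e100 <= lo) & (e60 <= lo)
    sub[pb] = "predominantly_biennial"
    sub[mixture & ~pb] = "other_mixture"
    return cat, sub


def classify_carrotomics(
    emm60: float,
    emm100: float,
    thresholds: Thresholds = Thresholds(),
    accession_id: str = "",
) -> FloweringHabitCall:
    """Assign the full ontology category + subcategory to one accession."""
    cat, sub = classify_arrays([emm60], [emm100], thresholds)
    return FloweringHabitCall(
        accession_id=accession_id,
        scheme="carrotomics",
        category=str(cat[0]),
        subcategory=str(sub[0]),
        emm60=float(emm60),
        emm100=float(emm100),
    )


def classify_grin_baseline(
    emm100: float, emm60: float = float("nan"), accession_id: str = ""
) -> FloweringHabitCall:
    """Three-category legacy baseline: 0 → biennial, 100 → annual, else mixture."""
    e = _check_percent([emm100], "emm100")[0]
    if e == 0.0:
        category = "biennial"
    elif e == 100.0:
        category = "annual"
    else:
        category = "mixture"
    return FloweringHabitCall(
        accession_id=accession_id,
        scheme="grin_baseline",
        category=category,
        subcategory="none",
        emm60=float(emm60),
        emm100=float(emm100),
    )


class FloweringHabitClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based flowering-habit classifier over (emm60, emm100) pairs.

    A deterministic, threshold-defined classifier exposed through the usual
    estimator interface so it composes with pipelines and model-selection
    tooling.  ``fit`` only validates the thresholds; nothing is learned from
    data.

    Parameters
    ----------
    scheme : {"carrotomics", "grin_baseline"}
        Full two-timepoint ontology, or the legacy 100 DAS-only baseline.
    t_low, t_high : float
        Percent-flowering cut points (defaults 15 and 85); ignored by the
        baseline scheme except for validation.

    Attributes
    ----------
    classes_ : ndarray of str
        The three top-level categories.
    thresholds_ : Thresholds
        Validated threshold pair.
    """

    def __init__(self, scheme: str = "carrotomics", t_low: float = 15.0, t_high: float = 85.0):
        self.scheme = scheme
        self.t_low = t_low
        self.t_high = t_high

    def fit(self, X=None, y=None):
        if self.scheme not in ("carrotomics", "grin_baseline"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        self.thresholds_ = Thresholds(self.t_low, self.t_high)
        self.classes_ = np.asarray(CATEGORIES, dtype=object)
        return self

    def _emm_columns(self, X) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(X, pd.DataFrame):
            e60 = X["emm60"].to_numpy(dtype=float)
            e100 = X["emm100"].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[1] != 2:
                raise ValueError("X must be (n_samples, 2): columns emm60, emm100")
            e60, e100 = X[:, 0], X[:, 1]
        return e60, e100

    def predict(self, X) -> np.ndarray:
        """Top-level category for each (emm60, emm100) row."""
        check_is_fitted(self)
        e60, e100 = self._emm_columns(X)
        if self.scheme == "grin_baseline":
            e100 = _check_percent(e100, "emm100")
            cat = np.where(e100 == 0.0, "biennial", np.where(e100 == 100.0, "annual", "mixture"))
            return cat.astype(object)
        cat, _ = classify_arrays(e60, e100, self.thresholds_)
        return cat

    def predict_subcategory(self, X) -> np.ndarray:
        """Ontology subcategory ("none" for biennials and the baseline scheme)."""
        check_is_fitted(self)
        if self.scheme == "grin_baseline":
            return np.full(len(self._emm_columns(X)[0]), "none", dtype=object)
        e60, e100 = self._emm_columns(X)
        _, sub = classify_arrays(e60, e100, self.thresholds_)
        return sub

    def classify_frame(self, phenotypes: pd.DataFrame) -> pd.DataFrame:
        """Classify an accession-phenotype table (accession_id, emm60, emm100).

        Returns the habit-call table with columns accession_id, scheme,
        category, subcategory, emm60, emm100.
        """
        check_is_fitted(self)
        out = phenotypes.loc[:, ["accession_id", "emm60", "emm100"]].copy()
        out.insert(1, "scheme", self.scheme)
        out["category"] = self.predict(phenotypes)
        out["subcategory"] = self.predict_subcategory(phenotypes)
        return out[["accession_id", "scheme", "category", "subcategory", "emm60", "emm100"]]


@dataclass
class CollectionSummary:
    """Per-category counts and percentages of a classified collection.

    Mirrors the layout of germplasm-collection summary tables: three bold
    top-level categories, their subcategories, and two "entries flowering"
    rows counting accessions with any flowering at each timepoint.
    """

    scheme: str
    denominator: int
    category_counts: dict = field(default_factory=dict)
    subcategory_counts: dict = field(default_factory=dict)
    n_flowering_60: int = 0
    n_flowering_100: int = 0

    def percent(self, count: int) -> float:
        return round_half_away(100.0 * count / self.denominator, 2)

    @property
    def category_percents(self) -> dict:
        return {k: self.percent(v) for k, v in self.category_counts.items()}

    @property
    def subcategory_percents(self) -> dict:
        return {k: self.percent(v) for k, v in self.subcategory_counts.items()}


def summarize_collection(calls: pd.DataFrame | list) -> CollectionSummary:
    """Summarize habit calls into counts and 2-decimal percentages.

    ``calls`` is a habit-call DataFrame (from ``classify_frame``) or a list of
    :class:`FloweringHabitCall`; all calls must share one scheme.
    """
    if not isinstance(calls, pd.DataFrame):
        calls = pd.DataFrame([c.__dict__ for c in calls])
    if calls.empty:
        raise ValueError("cannot summarize an empty call set")
    schemes = calls["scheme"].unique()
    if len(schemes) != 1:
        raise ValueError(f"calls mix schemes {sorted(schemes)}")
    scheme = str(schemes[0])

    denom = len(calls)
    cat_counts = {c: int((calls["category"] == c).sum()) for c in CATEGORIES}
    sub_counts = {
        s: int((calls["subcategory"] == s).sum()) for s in SUBCATEGORIES if s != "none"
    }
    emm60 = calls["emm60"].to_numpy(dtype=float)
    emm100 = calls["emm100"].to_numpy(dtype=float)
    return CollectionSummary(
        scheme=scheme,
        denominator=denom,
        category_counts=cat_counts,
        subcategory_counts=sub_counts,
        n_flowering_60=int(np.sum(np.nan_to_num(emm60) > 0)),
        n_flowering_100=int(np.sum(np.nan_to_num(emm100) > 0)),
    )


def trait_dictionary() -> pd.DataFrame:
    """The ontology as a Crop-Ontology-style trait dictionary table."""
    rows = [
        ("percent_flowering", "Percentage of flowering plants within a plot in the first "
         "growing season, scored on a 5-point scale (0-100% in increments of 25%).",
         "percent {0,25,50,75,100}", "60;100"),
        ("annual_flowering_habit", "More than 85% of plants in the plot flowering during "
         "the first growth season.", "category", "60;100"),
        ("uniformly_early_annual", "More than 85% of plants in the plot with signs of "
         "flowering at mid-season.", "category", "60"),
        ("uniformly_late_annual", "At most 15% of plants flowering at mid-season and more "
         "than 85% flowering at end of season.", "category", "60;100"),
        ("non_uniform_annual", "More than 15% flowering at mid-season and more than 85% "
         "flowering at end of season; not considered a mixture.", "category", "60;100"),
        ("biennial_flowering_habit", "0% of plants in the plot flowering during the first "
         "growth season; roots require vernalization to flower.", "category", "60;100"),
        ("mixed_flowering_habit", "Both annual and biennial plants in various proportions "
         "(flowering in (0%, 85%] at end of season).", "category", "60;100"),
        ("predominantly_biennial", "Mixture with more than 0% and at most 15% flowering "
         "plants in the plot at end of season.", "category", "60;100"),
    ]
    return pd.DataFrame(rows, columns=["trait", "definition", "scale", "timepoints_das"])
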