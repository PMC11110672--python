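"""Per-accession estimated marginal means of percent flowering.

Category assignment is based on model-based accession means, not raw plot
averages: with genotype as the focal fixed term, the estimated marginal mean
is the unweighted average of year-level cell means (each cell mean averaging
the blocks within that year).  Under a fully balanced design this equals the
raw accession mean; under missing plots it equals the least-squares mean of
the genotype term with sum-to-zero coding, weighting each year equally rather
than by its plot count.
"""

from __future__ import annotations

import warnings

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

REQUIRED_COLUMNS = ("accession_id", "year", "block", "pct60", "pct100")


def accession_emmeans(
    observations: pd.DataFrame,
    years=None,
    min_years: int = 1,
    warn_partial: bool = True,
) -> pd.DataFrame:
    """Estimated marginal means of pct60/pct100 per accession.

    Parameters
    ----------
    observations : DataFrame
        Scored plot observations (accession_id, year, block, pct60, pct100).
    years : label, sequence of labels, or None
        A single year label gives within-year means; a sequence (or None = all
        years present) gives across-year means of yearly cell means.
    min_years : int
        Drop accessions observed in fewer than this many of the selected years.
    warn_partial : bool
        Warn (but retain) accessions missing from some selected years.

    Returns
    -------
    DataFrame with columns accession_id, scope, emm60, emm100, n_plots_used,
    n_years_present.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in observations.columns]
    if missing:
        raise ValueError(f"observations missing required columns {missing}")
    if observations.empty:
        raise ValueError("empty observation set")

    present_years = list(pd.unique(observations["year"]))
    if years is None:
        selected = present_years
        scope = "multi_year"
    elif isinstance(years, (list, tuple, set, pd.Index)):
        selected = list(years)
        scope = "multi_year" if len(selected) > 1 else "single_year"
    else:
        selected = [years]
        scope = "single_year"
    absent = [y for y in selected if y not in present_years]
    if absent:
        raise ValueError(f"requested years {absent} absent from data")

    obs = observations[observations["year"].isin(selected)]
    cell = obs.groupby(["accession_id", "year"], sort=True).agg(
        emm60=("pct60", "mean"), emm100=("pct100", "mean"), n_plots=("pct60", "size")
    )
    per_acc = cell.groupby("accession_id", sort=True).agg(
        emm60=("emm60", "mean"),
        emm100=("emm100", "mean"),
        n_plots_used=("n_plots", "sum"),
        n_years_present=("emm60", "size"),
    )
    if warn_partial and scope == "multi_year":
        partial = per_acc[per_acc["n_years_present"] < len(selected)]
        if len(partial):
            warnings.warn(
                f"{len(partial)} accession(s) present in only some of the selected "
                f"years; their means average the years observed",
                stacklevel=2,
            )
    per_acc = per_acc[per_acc["n_years_present"] >= min_years]
    out = per_acc.reset_index()
    out.insert(1, "scope", scope)
    out["n_plots_used"] = out["n_plots_used"].astype(int)
    out["n_years_present"] = out["n_years_present"].astype(int)
    return out


class AccessionMarginalMeans(TransformerMixin, BaseEstimator):
    """Transformer from plot observations to accession marginal means.

    Aggregates a long plot-observation table into one row per accession with
    the estimated marginal means used for flowering-habit classification.

    Parameters
    ----------
    years : label, sequence, or None
        Year scope passed through to :func:`accession_emmeans`.
    min_years : int
        Minimum number of selected years an accession must appear in.
    """

    def __init__(self, years=None, min_years: int = 1):
        self.years = years
        self.min_years = min_years

    def fit(self, X: pd.DataFrame, y=None):
        missing = [c for c in REQUIRED_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"observations missing required columns {missing}")
        self.years_ = (
            list(pd.unique(X["year"])) if self.years is None else self.years
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self)
        return accession_emmeans(X, years=self.years_, min_years=self.min_years)
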