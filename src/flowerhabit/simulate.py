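"""Synthetic germplasm collections and multi-year RCBD flowering trials.

The generator emulates the structure of a field evaluation of a heterogeneous
biennial root-crop collection: each accession is a mixture of early-annual,
late-annual and obligate-biennial plants; plots of ~50 plants are grown in a
randomized complete block design (2 blocks) over several years; per-plot
flowering fractions are observed at mid-season (60 days after sowing) and end
of season (100 DAS).  Genotype, year, genotype-by-year and block-within-year
effects perturb the annual fraction of each plot on the logit (liability)
scale, so probabilities stay in (0, 1); degenerate accessions (annual fraction
exactly 0 or 1) are left untouched, so a true biennial never flowers.

Because every accession is constructed from a known flowering-habit category,
the generator provides exact ground truth for classifier-recovery tests.
Optional stand-loss events thin plots with a bias against early-flowering
plants, reproducing the way a poor-establishment year inflates the apparent
biennial fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._utils import stable_stream_seed
from .ontology import LEAF_CATEGORIES, Thresholds, classify_arrays

_MIX_CATEGORIES = LEAF_CATEGORIES + ("annual",)


@dataclass(frozen=True)
class AccessionProfile:
    """Latent truth for one accession: life-form composition + genotype effect.

    The composition (p_early_annual, p_late_annual, p_biennial) sums to one;
    genotype_effect is a logit-scale shift on the per-plant annual probability.
    """

    accession_id: str
    p_early_annual: float
    p_late_annual: float
    p_biennial: float
    genotype_effect: float = 0.0
    true_category: str = ""

    def __post_init__(self):
        ps = (self.p_early_annual, self.p_late_annual, self.p_biennial)
        if any(p < 0 or p > 1 for p in ps):
            raise ValueError(f"composition probabilities must be in [0,1]: {ps}")
        if abs(sum(ps) - 1.0) > 1e-12:
            raise ValueError(f"composition must sum to 1 within 1e-12, got {sum(ps)!r}")


@dataclass(frozen=True)
class StandLossEvent:
    """Thinning of all plots in one year; early_bias > 0 preferentially removes
    early-flowering plants (logit-scale reduction of their survival)."""

    year: str
    survival_fraction: float
    early_bias: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.survival_fraction <= 1.0:
            raise ValueError("survival_fraction must be in (0, 1]")


@dataclass(frozen=True)
class TrialDesign:
    """Multi-year RCBD layout; default 3 years x 2 blocks x 50 plants."""

    years: tuple = ("Y1", "Y2", "Y3")
    blocks_per_year: int = 2
    plants_per_plot: int = 50
    emergence_rate: float = 1.0
    stand_loss_events: tuple = ()
    senescence_rate: float = 0.0  # per early-annual plant, off by default

    def __post_init__(self):
        if self.blocks_per_year < 1 or self.plants_per_plot < 1:
            raise ValueError("blocks_per_year and plants_per_plot must be >= 1")
        if not 0.0 < self.emergence_rate <= 1.0:
            raise ValueError("emergence_rate must be in (0, 1]")
        if not 0.0 <= self.senescence_rate < 1.0:
            raise ValueError("senescence_rate must be in [0, 1)")
        for ev in self.stand_loss_events:
            if ev.year not in self.years:
                raise ValueError(f"stand_loss_event year {ev.year!r} not in design years")


@dataclass
class EnvironmentEffects:
    """Drawn logit-scale environment effects for one simulated trial."""

    year_effect: dict = field(default_factory=dict)
    gy_effect: dict = field(default_factory=dict)
    block_effect: dict = field(default_factory=dict)
    sd_year: float = 0.0
    sd_gy: float = 0.0
    sd_block: float = 0.0


def _draw_composition(rng: np.random.Generator, category: str, concentration: float,
                      thr: Thresholds) -> tuple[float, float, float]:
    """Rejection-sample a life-form composition inside a category's region.

    Draws from Dirichlet(concentration, concentration, concentration) until the
    true fractions classify into ``category`` (fractions x 100 against the
    ontology thresholds), so truth labels are exact by construction.
    """
    if category == "biennial":
        return 0.0, 0.0, 1.0
    for _ in range(100_000):
        p_early, p_late, p_bien = rng.dirichlet([concentration] * 3)
        cat, sub = classify_arrays([100 * p_early], [100 * (p_early + p_late)], thr)
        label = str(cat[0]) if str(sub[0]) == "none" else str(sub[0])
        if label == category or (category == "annual" and str(cat[0]) == "annual"):
            return float(p_early), float(p_late), float(p_bien)
    raise RuntimeError(f"rejection sampling failed for category {category!r}")


def generate_collection(
    n_accessions: int,
    category_mix: dict[str, float] | None = None,
    concentration: float = 1.0,
    seed: int = 0,
    sd_genotype: float = 0.3,
    thresholds: Thresholds = Thresholds(),
) -> list[AccessionProfile]:
    """Generate accession profiles with known flowering-habit categories.

    ``category_mix`` maps category names (the five ontology leaves, plus
    ``other_mixture`` and the aggregate ``annual``) to target proportions that
    must sum to 1.  Counts per category are allocated deterministically
    (largest-remainder rounding) so empirical frequencies match the targets to
    within 1/n, then the ordering is shuffled.  Compositions are drawn inside
    each category's threshold region; a true biennial has p_biennial = 1
    exactly.  Deterministic given ``seed``.
    """
    if n_accessions < 1:
        raise ValueError("n_accessions must be >= 1")
    if category_mix is None:
        # loosely modelled on a diverse cultivated collection: ~30% biennial,
        # ~24% predominantly biennial, ~37% other mixtures, ~9% annual
        category_mix = {
            "biennial": 0.30,
            "predominantly_biennial": 0.24,
            "other_mixture": 0.37,
            "annual": 0.09,
        }
    for k, v in category_mix.items():
        if k not in _MIX_CATEGORIES:
            raise ValueError(f"unknown category {k!r}")
        if v < 0:
            raise ValueError(f"negative proportion for {k!r}")
    total = sum(category_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"category proportions must sum to 1, got {total}")

    # largest-remainder allocation of counts
    cats = sorted(category_mix)
    quotas = {c: n_accessions * category_mix[c] for c in cats}
    counts = {c: int(np.floor(quotas[c])) for c in cats}
    short = n_accessions - sum(counts.values())
    for c in sorted(cats, key=lambda c: (-(quotas[c] - counts[c]), c))[:short]:
        counts[c] += 1

    labels = [c for c in cats for _ in range(counts[c])]
    rng = np.random.default_rng(stable_stream_seed(seed, "collection"))
    rng.shuffle(labels)

    profiles = []
    for i, category in enumerate(labels):
        acc_id = f"ACC{i:05d}"
        acc_rng = np.random.default_rng(stable_stream_seed(seed, "profile", acc_id))
        p_e, p_l, p_b = _draw_composition(acc_rng, category, concentration, thresholds)
        g = float(acc_rng.normal(0.0, sd_genotype)) if sd_genotype > 0 else 0.0
        if category == "annual":
            cat, sub = classify_arrays([100 * p_e], [100 * (p_e + p_l)], thresholds)
            category = str(sub[0])
        profiles.append(
            AccessionProfile(acc_id, p_e, p_l, p_b, genotype_effect=g, true_category=category)
        )
    return profiles


def truth_table(profiles: list[AccessionProfile]) -> dict[str, str]:
    """The generator's latent category labels, never inferred from data."""
    return {p.accession_id: p.true_category for p in profiles}


def truth_frame(profiles: list[AccessionProfile]) -> pd.DataFrame:
    """Truth labels + compositions as a table (for the truth-label CSV)."""
    return pd.DataFrame(
        [
            {
                "accession_id": p.accession_id,
                "true_category": p.true_category,
                "p_early_annual": p.p_early_annual,
                "p_late_annual": p.p_late_annual,
                "p_biennial": p.p_biennial,
            }
            for p in profiles
        ]
    )


def draw_environment(
    profiles: list[AccessionProfile],
    design: TrialDesign,
    env_sds: tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: int = 0,
) -> EnvironmentEffects:
    """Draw centered normal year / genotype-by-year / block-within-year effects."""
    sd_year, sd_gy, sd_block = env_sds
    eff = EnvironmentEffects(sd_year=sd_year, sd_gy=sd_gy, sd_block=sd_block)
    for y in design.years:
        r = np.random.default_rng(stable_stream_seed(seed, "year_eff", y))
        eff.year_effect[y] = float(r.normal(0, sd_year)) if sd_year > 0 else 0.0
        for b in range(1, design.blocks_per_year + 1):
            r = np.random.default_rng(stable_stream_seed(seed, "block_eff", y, b))
            eff.block_effect[(y, b)] = float(r.normal(0, sd_block)) if sd_block > 0 else 0.0
        for p in profiles:
            r = np.random.default_rng(stable_stream_seed(seed, "gy_eff", p.accession_id, y))
            eff.gy_effect[(p.accession_id, y)] = float(r.normal(0, sd_gy)) if sd_gy > 0 else 0.0
    return eff


def _perturbed_composition(profile: AccessionProfile, delta: float) -> tuple[float, float]:
    """Shift the total annual fraction by ``delta`` on the logit scale.

    The early/late split within annuals is preserved; degenerate fractions
    (0 or 1) are fixed points, so obligate biennials and pure annuals are
    unaffected by environment.
    """
    p_a = profile.p_early_annual + profile.p_late_annual
    if 0.0 < p_a < 1.0 and delta != 0.0:
        p_a_new = float(expit(logit(p_a) + delta))
    else:
        p_a_new = p_a
    early_share = profile.p_early_annual / p_a if p_a > 0 else 0.0
    p_early = p_a_new * early_share
    return p_early, p_a_new - p_early


def simulate_trial(
    profiles: list[AccessionProfile],
    design: TrialDesign = TrialDesign(),
    env_sds: tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate plot-level flowering fractions for a multi-year RCBD trial.

    Each plot draws ``plants_per_plot`` plants (after binomial emergence
    thinning); every plant takes a life form from the accession's composition
    after the plot's logit-scale perturbation (genotype + year + GxY + block
    effects).  Early annuals have flowered by 60 DAS, late annuals by 100 DAS,
    biennials never.  Stand-loss events thin the year's plots, with survival
    of early-flowering plants reduced by ``early_bias`` on the logit scale.

    Returns a DataFrame with columns accession_id, year, block, n_plants,
    frac60, frac100 (fractions of surviving plants in [0, 1]); plots with zero
    surviving plants are dropped.  Byte-identical output for identical inputs
    and seed.
    """
    if not profiles:
        raise ValueError("profile list is empty")
    env = draw_environment(profiles, design, env_sds, seed)
    losses = {ev.year: ev for ev in design.stand_loss_events}

    rows = []
    for p in profiles:
        for y in design.years:
            for b in range(1, design.blocks_per_year + 1):
                rng = np.random.default_rng(
                    stable_stream_seed(seed, "plot", p.accession_id, y, b)
                )
                n = design.plants_per_plot
                if design.emergence_rate < 1.0:
                    n = int(rng.binomial(n, design.emergence_rate))
                if n == 0:
                    continue
                delta = (
                    p.genotype_effect
                    + env.year_effect[y]
                    + env.gy_effect[(p.accession_id, y)]
                    + env.block_effect[(y, b)]
                )
                p_early, p_late = _perturbed_composition(p, delta)
                n_early, n_late, n_bien = rng.multinomial(
                    n, [p_early, p_late, 1.0 - p_early - p_late]
                )
                if y in losses:
                    ev = losses[y]
                    s = ev.survival_fraction
                    if s < 1.0:
                        s_early = float(expit(logit(s) - ev.early_bias))
                        n_early = int(rng.binomial(n_early, s_early))
                        n_late = int(rng.binomial(n_late, s))
                        n_bien = int(rng.binomial(n_bien, s))
                n_total = n_early + n_late + n_bien
                if n_total == 0:
                    continue
                n_senesced = 0
                if design.senescence_rate > 0.0 and n_early > 0:
                    n_senesced = int(rng.binomial(n_early, design.senescence_rate))
                rows.append(
                    {
                        "accession_id": p.accession_id,
                        "year": y,
                        "block": b,
                        "n_plants": n_total,
                        "frac60": n_early / n_total,
                        "frac100": (n_early - n_senesced + n_late) / n_total,
                    }
                )
    return pd.DataFrame(rows, columns=["accession_id", "year", "block", "n_plants", "frac60", "frac100"])


def simulate_gaussian_trial(
    n_accessions: int,
    n_years: int,
    n_blocks: int,
    vg: float,
    vgy: float = 0.0,
    vyear: float = 0.0,
    vblock: float = 0.0,
    verror: float = 1.0,
    mu: float = 50.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced draw from the multi-year variance-components model itself.

    y_ijk = mu + g_i + y_j + (gy)_ij + b_k(j) + e_ijk with independent centered
    normal components; used for estimator parameter-recovery studies, where the
    data-generating model must match the fitted model exactly.  Returns the
    scored-observation layout (accession_id, year, block, pct60=pct100=value).
    """
    rng = np.random.default_rng(stable_stream_seed(seed, "gaussian_trial"))
    g = rng.normal(0, np.sqrt(vg), n_accessions)
    yy = rng.normal(0, np.sqrt(vyear), n_years)
    gy = rng.normal(0, np.sqrt(vgy), (n_accessions, n_years))
    bl = rng.normal(0, np.sqrt(vblock), (n_years, n_blocks))
    e = rng.normal(0, np.sqrt(verror), (n_accessions, n_years, n_blocks))
    vals = (
        mu
        + g[:, None, None]
        + yy[None, :, None]
        + gy[:, :, None]
        + bl[None, :, :]
        + e
    )
    idx = pd.MultiIndex.from_product(
        [
            [f"ACC{i:05d}" for i in range(n_accessions)],
            [f"Y{j+1}" for j in range(n_years)],
            list(range(1, n_blocks + 1)),
        ],
        names=["accession_id", "year", "block"],
    )
    df = pd.DataFrame({"value": vals.ravel()}, index=idx).reset_index()
    df["pct60"] = df["value"]
    df["pct100"] = df["value"]
    return df.drop(columns="value")
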