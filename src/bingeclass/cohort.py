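"""Seeded synthetic cohorts with the four-group drinking structure.

The generator emulates the statistical structure the pipeline assumes: a
mixture of four severity groups whose per-item means follow the published
cluster-mean profiles, group sizes 721/404/106/46 out of 1,277, female
shares falling steeply with severity, and group-level alcohol-demand
parameters (Q0, alpha) spanning the reported range.  It reproduces the
moments downstream stages need — it makes no claim to the real cohort's
full joint distribution.

Item noise model: ordinal AUDIT codes are Gaussian around the group mean,
rounded and clipped to 0..4; the per-10-occasion items are Gaussian clipped
to [0, 10]; speed is Gaussian clipped at 0; the drunkenness count is
negative binomial around the group mean with mild overdispersion (size 50),
keeping each group's counts inside the banding the derived groups exhibit
(group 4 concentrated in 30-50 episodes).  With all dispersions at zero the
generator is deterministic at the (rounded, clipped) profile means.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .survey import ITEM_FIELDS, ORDINAL_ITEMS, PER10_ITEMS

#: Default 17-point price ladder, euros 0-20.
DEFAULT_PRICES: tuple[float, ...] = (
    0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0,
    6.0, 7.0, 8.0, 9.0, 10.0, 12.0, 15.0, 20.0,
)

# Within-group dispersions calibrated to the study's printed per-group item
# distributions (ordinal-code spread, share drinking 4+ drinks/hour) and the
# information content of the published Wald standard errors; drunkenness is
# handled by the negative-binomial count_size.
_DEFAULT_SDS = (0.9, 0.9, 0.9, 1.3, 0.0, 2.0, 2.0)


@dataclass(frozen=True)
class GroupProfile:
    """Generating profile of one severity group.

    ``item_means`` follows :data:`bingeclass.survey.ITEM_FIELDS` order; the
    ``item_sds`` entry for drunkenness_frequency is only consulted as an
    on/off switch (0 = deterministic count), the count's spread being set by
    the negative-binomial ``count_size`` (variance = mu + mu^2/size).
    """

    index: int
    item_means: tuple[float, ...]
    mixing_weight: float
    item_sds: tuple[float, ...] = _DEFAULT_SDS
    count_size: float = 50.0
    female_share: float = 0.5
    q0: float = 10.0
    alpha: float = 0.005

    def __post_init__(self) -> None:
        if len(self.item_means) != len(ITEM_FIELDS):
            raise ValueError("item_means must have one entry per candidate item")
        if len(self.item_sds) != len(ITEM_FIELDS):
            raise ValueError("item_sds must have one entry per candidate item")
        if any(s < 0 for s in self.item_sds):
            raise ValueError("dispersions must be nonnegative")
        if not 0 <= self.female_share <= 1:
            raise ValueError("female_share must lie in [0, 1]")
        if self.mixing_weight <= 0:
            raise ValueError("mixing_weight must be positive")
        if self.q0 <= 0 or self.alpha <= 0:
            raise ValueError("demand parameters q0 and alpha must be positive")


def default_profiles() -> list[GroupProfile]:
    """The four study-condition group profiles.

    Means are the published cluster means; mixing weights the derived group
    sizes 721/404/106/46; female shares the per-group gender counts
    (645/723, 279/402, 51/106, 12/46); demand parameters the group-level
    Q0/alpha means.
    """
    means = [
        (1.79, 0.70, 0.90, 1.47, 0.93, 1.24, 1.23),
        (2.19, 1.54, 1.89, 2.32, 5.82, 4.95, 4.15),
        (2.60, 2.04, 2.66, 2.85, 19.28, 6.10, 4.65),
        (3.02, 2.76, 2.65, 3.17, 39.26, 6.52, 3.94),
    ]
    sizes = [721.0, 404.0, 106.0, 46.0]
    female = [645 / 723, 279 / 402, 51 / 106, 12 / 46]
    demand = [(6.36, 0.014), (10.45, 0.005), (12.37, 0.004), (16.66, 0.005)]
    return [
        GroupProfile(
            index=g + 1,
            item_means=means[g],
            mixing_weight=sizes[g] / sum(sizes),
            female_share=female[g],
            q0=demand[g][0],
            alpha=demand[g][1],
        )
        for g in range(4)
    ]


def zero_dispersion_profiles() -> list[GroupProfile]:
    """Default profiles with all item noise switched off (means pass through)."""
    return [
        replace(p, item_sds=(0.0,) * len(ITEM_FIELDS), count_size=np.inf)
        for p in default_profiles()
    ]


def _draw_items(profile: GroupProfile, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an n x 7 item matrix for one group, per-item noise as documented."""
    out = np.empty((n, len(ITEM_FIELDS)))
    for j, name in enumerate(ITEM_FIELDS):
        mu, sd = profile.item_means[j], profile.item_sds[j]
        if name == "drunkenness_frequency":
            if sd == 0 and not np.isfinite(profile.count_size):
                vals = np.full(n, round(mu))
            else:
                size = profile.count_size
                if np.isfinite(size):
                    # NB(mean mu, size r): p = r/(r+mu)
                    p = size / (size + mu)
                    vals = rng.negative_binomial(size, p, n)
                else:
                    vals = rng.poisson(mu, n)
            out[:, j] = vals
        elif name in ORDINAL_ITEMS:
            vals = rng.normal(mu, sd, n) if sd > 0 else np.full(n, mu)
            out[:, j] = np.clip(np.rint(vals), 0, 4)
        elif name in PER10_ITEMS:
            vals = rng.normal(mu, sd, n) if sd > 0 else np.full(n, mu)
            out[:, j] = np.clip(vals, 0, 10)
        else:  # consumption_speed
            vals = rng.normal(mu, sd, n) if sd > 0 else np.full(n, mu)
            out[:, j] = np.clip(vals, 0, None)
    return out


def generate_cohort(
    profiles: list[GroupProfile] | None = None,
    n: int = 1277,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate ``n`` respondents from a mixture of group profiles.

    Returns
    -------
    cohort : pandas.DataFrame
        Columns ``id``, ``gender``, ``age`` plus the seven item columns in
        :data:`~bingeclass.survey.ITEM_FIELDS` order.
    labels : numpy.ndarray
        Generating group index (1..G) per respondent.
    """
    if profiles is None:
        profiles = default_profiles()
    if not profiles:
        raise ValueError("profiles must be nonempty")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    weights = np.array([p.mixing_weight for p in profiles], float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixing proportions must sum to 1")

    rng = np.random.default_rng(seed)
    assignment = rng.choice(len(profiles), size=n, p=weights)

    items = np.empty((n, len(ITEM_FIELDS)))
    gender = np.empty(n, dtype=object)
    labels = np.empty(n, dtype=int)
    for g, profile in enumerate(profiles):
        mask = assignment == g
        m = int(mask.sum())
        if m == 0:
            continue
        items[mask] = _draw_items(profile, m, rng)
        gender[mask] = np.where(rng.random(m) < profile.female_share, "F", "M")
        labels[mask] = profile.index

    age = np.clip(rng.normal(21.1, 1.8, n), 18, 26)
    cohort = pd.DataFrame(items, columns=list(ITEM_FIELDS))
    for name in ORDINAL_ITEMS + ("drunkenness_frequency",):
        cohort[name] = cohort[name].astype(int)
    cohort.insert(0, "age", np.round(age, 1))
    cohort.insert(0, "gender", gender)
    cohort.insert(0, "id", [f"S{i:05d}" for i in range(n)])
    return cohort, labels


def generate_apt_curve(
    q0: float,
    alpha: float,
    prices: tuple[float, ...] | list[float] = DEFAULT_PRICES,
    noise_sd: float = 0.0,
    seed: int = 0,
    k: float = 3.20,
    round_counts: bool = True,
):
    """Simulate an alcohol purchase task series from exponentiated demand.

    Consumption at each price is the demand-equation value (zero price
    substituted by 0.01 euros, as in fitting) times multiplicative
    lognormal noise with log-scale SD ``noise_sd``, then rounded to a
    nonnegative integer drink count unless ``round_counts`` is False.
    """
    from .apt import DemandCurve, demand_quantity

    if q0 <= 0 or alpha <= 0:
        raise ValueError("q0 and alpha must be positive")
    prices = np.asarray(prices, float)
    if prices.ndim != 1 or np.any(prices < 0) or np.any(np.diff(prices) <= 0):
        raise ValueError("prices must be nonnegative and strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")

    rng = np.random.default_rng(seed)
    from .apt import ZERO_PRICE_SUB

    q = demand_quantity(np.where(prices == 0, ZERO_PRICE_SUB, prices), q0, alpha, k)
    if noise_sd > 0:
        q = q * rng.lognormal(0.0, noise_sd, len(prices))
    if round_counts:
        q = np.clip(np.rint(q), 0, None)
    return DemandCurve(prices=tuple(prices), consumption=tuple(q))
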