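"""Constrained null model for vulnerability and over-redundancy.

FV and FOR depend on S, FE, and how species are spread across entities.
The null hypothesis keeps S and FE fixed and randomizes the spread:
each entity is first seeded with one species (every realized entity must
stay occupied), and the remaining S - FE species are then placed
independently and uniformly at random across the FE entities. Observed
values are compared to the simulated null distribution with a bilateral
Monte-Carlo test (add-one correction, ties count toward both tails) and
a standardized effect size (observed - null mean) / null sd.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .indices import over_redundancy, vulnerability
from .schema import EntityTable

__all__ = [
    "SCHEME",
    "NullModelResult",
    "simulate_occupancy",
    "null_test",
    "run_null_tests",
]

#: Name of the randomization scheme, recorded in every result.
SCHEME = "seed-one-scatter-rest"

STATISTICS = {"FV": vulnerability, "FOR": over_redundancy}


def _statistic_matrix(sims: np.ndarray, statistic: str) -> np.ndarray:
    """Vectorized FV/FOR over a (n_sims, FE) matrix of positive counts."""
    s = sims.sum(axis=1, dtype=float)
    if statistic == "FV":
        return 100.0 * (sims == 1).mean(axis=1)
    fr = s / sims.shape[1]
    excess = np.maximum(sims - fr[:, None], 0.0).sum(axis=1)
    return 100.0 * excess / s


def simulate_occupancy(S: int, FE: int, rng: np.random.Generator) -> np.ndarray:
    """One random occupancy: FE positive integers summing to S.

    Each entity gets one seed species; the remaining S - FE species are
    scattered as iid uniform assignments (a symmetric multinomial).
    """
    if FE < 1 or S < FE:
        raise ValidationError(f"need S >= FE >= 1, got S={S}, FE={FE}")
    return 1 + rng.multinomial(S - FE, np.full(FE, 1.0 / FE))


@dataclass
class NullModelResult:
    """Outcome of one bilateral null-model test."""

    statistic: str
    observed: float
    n_sims: int
    sim_mean: float
    sim_sd: float
    p_two_sided: float
    ses: float
    seed: int | None
    degenerate: bool = False
    scheme: str = SCHEME

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "n_sims": self.n_sims,
            "sim_mean": self.sim_mean,
            "sim_sd": self.sim_sd,
            "p_two_sided": self.p_two_sided,
            "ses": self.ses,
            "seed": self.seed,
            "degenerate": self.degenerate,
            "scheme": self.scheme,
        }


def null_test(
    occupancy,
    statistic: str = "FV",
    n_sims: int = 9999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> NullModelResult:
    """Bilateral Monte-Carlo test of an observed FV or FOR value.

    p = 2 * min over tails of (1 + #{sim on that side of obs}) / (n_sims+1),
    capped at 1; the minimum attainable p is therefore 2/(n_sims+1). When
    the null distribution is degenerate (sd = 0) the SES is undefined and
    the result is flagged.
    """
    if statistic not in STATISTICS:
        raise ValidationError(f"unknown statistic {statistic!r}; use 'FV' or 'FOR'")
    if n_sims < 99:
        raise ValidationError("n_sims must be at least 99")
    occ = np.asarray(occupancy)
    observed = STATISTICS[statistic](occ)
    S, FE = int(occ.sum()), occ.size
    if rng is None:
        rng = np.random.default_rng(seed)
    if S < FE or FE < 1:
        raise ValidationError(f"need S >= FE >= 1, got S={S}, FE={FE}")
    sims = 1 + rng.multinomial(S - FE, np.full(FE, 1.0 / FE), size=n_sims)
    stats = _statistic_matrix(sims, statistic)

    lo = (1 + np.sum(stats <= observed)) / (n_sims + 1)
    hi = (1 + np.sum(stats >= observed)) / (n_sims + 1)
    p = min(1.0, 2.0 * min(lo, hi))
    sim_mean = float(stats.mean())
    sim_sd = float(stats.std(ddof=1))
    degenerate = sim_sd == 0.0
    ses = float("nan") if degenerate else (observed - sim_mean) / sim_sd
    return NullModelResult(
        statistic=statistic,
        observed=float(observed),
        n_sims=n_sims,
        sim_mean=sim_mean,
        sim_sd=sim_sd,
        p_two_sided=float(p),
        ses=float(ses),
        seed=seed,
        degenerate=degenerate,
    )


def run_null_tests(
    entities: EntityTable,
    n_sims: int = 9999,
    seed: int | None = None,
    statistics: tuple[str, ...] = ("FV", "FOR"),
    include_pooled: bool = True,
) -> pd.DataFrame:
    """Null-model tests for every assemblage and statistic, as a tidy table.

    A master seed spawns one independent substream per (assemblage,
    statistic) pair, so any single test can be reproduced in isolation
    from the master seed and the pair's position in the grid.
    """
    names = entities.assemblage_names(include_pooled=include_pooled)
    children = np.random.SeedSequence(seed).spawn(len(names) * len(statistics))
    rows = []
    k = 0
    for name in names:
        occ = entities.occupancy(name)
        for stat in statistics:
            res = null_test(
                occ, statistic=stat, n_sims=n_sims,
                rng=np.random.default_rng(children[k]),
            )
            k += 1
            row = {"assemblage": name, **res.to_dict()}
            row["seed"] = seed
            rows.append(row)
    return pd.DataFrame(rows)
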