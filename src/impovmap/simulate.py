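"""Synthetic household-survey generator with known ground truth.

Emulates a stratified national household survey over 32 districts (a
rook-contiguity lattice, optionally with one isolated island district)
so that every pipeline stage — poverty metrics, Moran's I, and the
spatial multilevel model — can be exercised against latent quantities
the generator records exactly.

Two generation modes:

``outcome_first`` (default)
    District effects u are drawn from the LCAR field at the true
    (lambda, tau2), covariates from the configured margins, and the
    binary impoverishment outcome from logit(pi) = alpha + beta'x + u_j.
    Expenditures and OOP payments are then constructed to be consistent
    with each household's outcome flag (flagged households sit just
    above the poverty line before payments and below it after), so the
    model-fitting ground truth is exact.

``expenditure_first``
    Per-capita expenditure is drawn from a lognormal calibrated so the
    poverty line sits at the target pre-payment head count, OOP payments
    from a two-part model, and the flag is whatever falls out — the mode
    to use when testing the poverty metrics against the closed-form
    lognormal head count Phi((log z - log median)/sigma).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .car import sample_lcar_field
from .poverty import NATIONAL_LINE, PovertyLine
from .weights import SpatialWeights, read_gal, rook_lattice, weights_from_edges, write_gal

__all__ = ["GeneratorConfig", "generate", "write_fixture", "read_fixture", "district_lattice"]


def _default_margins() -> dict:
    # Covariate frequencies of the 2016/17 Malawi integrated household survey
    return {
        "head_age": {
            "lt26": 0.1230,
            "26-35": 0.2666,
            "36-45": 0.2379,
            "46-55": 0.1521,
            "over56": 0.2204,
        },
        "female_head": 1.0 - 0.7112,
        "child_u5": 0.5352,
        "elderly": 0.1975,
        "chronic": 0.2233,
        "hospitalized": 0.1316,
        "rural": 0.8095,
        "facility": {"government": 0.8723, "religious": 0.1068, "private": 0.0209},
        "region_district_share": {"northern": 0.0915, "central": 0.4432, "southern": 0.4653},
        "mean_household_size": 4.29,
        "mean_distance_km": 13.33,
    }


def _default_beta() -> dict[str, float]:
    # Log odds ratios of the study's adjusted estimates (spatial model)
    return {
        "head_age[lt26]": math.log(0.28),
        "head_age[26-35]": math.log(0.53),
        "head_age[36-45]": math.log(0.45),
        "head_age[46-55]": math.log(0.29),
        "female_head": math.log(0.98),
        "household_size": math.log(1.05),
        "ses_higher": math.log(0.34),
        "child_u5": math.log(1.08),
        "elderly": math.log(0.74),
        "chronic": math.log(1.56),
        "hospitalized": math.log(3.63),
        "rural": math.log(2.03),
        "distance_km": math.log(0.99),
        "facility[religious]": math.log(1.36),
        "facility[private]": math.log(0.49),
        "region[central]": math.log(1.33),
        "region[southern]": math.log(0.88),
    }


@dataclass
class GeneratorConfig:
    """Study-condition defaults: 32 districts, ~12.4k households, a weak
    smooth spatial field (lambda 0.5, conditional variance 1/tau2 = 2e-4)
    and a ~1.6% impoverishment rate at the national poverty line."""

    n_districts: int = 32
    households_per_district: int | tuple[int, int] = 389
    island: bool = True  # one isolated district, like Likoma
    true_lambda: float = 0.5
    true_tau2: float = 5000.0
    alpha: float | None = None  # None: calibrated so the mean rate hits target_rate
    target_rate: float = 0.016
    true_beta: dict[str, float] = field(default_factory=_default_beta)
    line: PovertyLine = field(default_factory=lambda: NATIONAL_LINE)
    expenditure_sigma: float = 1.1
    target_head_count: float = 0.515  # pre-payment, at `line`
    oop_p_any: float = 0.6
    oop_median: float = 6000.0
    oop_sigma: float = 1.2
    oop_hospitalized_scale: float = 4.0
    oop_chronic_scale: float = 2.0
    mode: str = "outcome_first"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("outcome_first", "expenditure_first"):
            raise ValueError("mode must be 'outcome_first' or 'expenditure_first'")
        if not 0.0 <= self.true_lambda < 1.0 or self.true_tau2 <= 0:
            raise ValueError("invalid LCAR parameters")
        if not 0.0 < self.target_head_count < 1.0:
            raise ValueError("target head count must be in (0, 1)")
        if not 0.0 < self.target_rate < 1.0:
            raise ValueError("target impoverishment rate must be in (0, 1)")

    @property
    def log_median_expenditure(self) -> float:
        """Per-capita lognormal log-median putting the line at the target
        head count: log z - sigma * Phi^-1(target)."""
        z = self.line.per_year
        return math.log(z) - self.expenditure_sigma * norm.ppf(self.target_head_count)

    @property
    def analytic_head_count(self) -> float:
        """Closed-form pre-payment head count of the lognormal model."""
        z = self.line.per_year
        return float(
            norm.cdf(
                (math.log(z) - self.log_median_expenditure) / self.expenditure_sigma
            )
        )


def district_lattice(n_districts: int, island: bool = True) -> SpatialWeights:
    """Near-square rook lattice over the districts; with ``island`` the last
    district is disconnected (an isolated lake district)."""
    best = (1, n_districts)
    for r in range(1, int(math.sqrt(n_districts)) + 1):
        if n_districts % r == 0:
            best = (r, n_districts // r)
    lat = rook_lattice(*best)
    if not island:
        return lat
    edges = [(a, b) for a, b in lat.edges() if lat.district_ids[-1] not in (a, b)]
    return weights_from_edges(edges, lat.district_ids)


def _draw_covariates(
    cfg: GeneratorConfig, n_per_district: np.ndarray, weights: SpatialWeights, rng
) -> pd.DataFrame:
    m = _default_margins()
    n = int(n_per_district.sum())
    J = weights.n_districts
    district = np.repeat(np.arange(J), n_per_district)

    # districts split into contiguous regional blocks (north/centre/south)
    share = m["region_district_share"]
    n_north = max(1, round(share["northern"] * J))
    n_central = round(share["central"] * J)
    region_of_district = np.array(
        ["northern"] * n_north
        + ["central"] * n_central
        + ["southern"] * (J - n_north - n_central)
    )

    def cat(margins: dict[str, float]) -> np.ndarray:
        labels = list(margins)
        p = np.array([margins[k] for k in labels], dtype=float)
        return rng.choice(labels, size=n, p=p / p.sum())

    df = pd.DataFrame(
        {
            "household_id": [f"H{k:06d}" for k in range(n)],
            "district_id": [weights.district_ids[j] for j in district],
            "head_age": cat(m["head_age"]),
            "female_head": rng.binomial(1, m["female_head"], n),
            "child_u5": rng.binomial(1, m["child_u5"], n),
            "elderly": rng.binomial(1, m["elderly"], n),
            "chronic": rng.binomial(1, m["chronic"], n),
            "hospitalized": rng.binomial(1, m["hospitalized"], n),
            "rural": rng.binomial(1, m["rural"], n),
            "ses_higher": rng.binomial(1, 0.5, n),
            "facility": cat(m["facility"]),
            "region": region_of_district[district],
            "distance_km": rng.gamma(2.0, m["mean_distance_km"] / 2.0, n),
            "household_size": 1 + rng.poisson(m["mean_household_size"] - 1.0, n),
            "survey_weight": np.exp(rng.normal(0.0, 0.3, n)),
        }
    )
    df["_district_index"] = district
    return df


def _linear_predictor(df: pd.DataFrame, beta: dict[str, float]) -> np.ndarray:
    """beta' x with 'name[level]' keys matching categorical levels."""
    eta = np.zeros(len(df))
    for key, b in beta.items():
        if "[" in key:
            name, level = key[:-1].split("[")
            col = (df[name].astype(str) == level).to_numpy(dtype=float)
        else:
            col = df[key].to_numpy(dtype=float)
        eta += b * col
    return eta


def _two_part_oop(df: pd.DataFrame, cfg: GeneratorConfig, rng) -> np.ndarray:
    p_any = expit(
        logit(cfg.oop_p_any)
        + 1.0 * df["hospitalized"].to_numpy()
        + 0.5 * df["chronic"].to_numpy()
    )
    any_oop = rng.binomial(1, p_any)
    amount = np.exp(rng.normal(math.log(cfg.oop_median), cfg.oop_sigma, len(df)))
    amount *= cfg.oop_hospitalized_scale ** df["hospitalized"].to_numpy()
    amount *= cfg.oop_chronic_scale ** df["chronic"].to_numpy()
    return any_oop * amount


def generate(
    cfg: GeneratorConfig,
) -> tuple[pd.DataFrame, SpatialWeights, dict]:
    """Generate (households, weights, truth) under the configured scenario."""
    rng = np.random.default_rng(cfg.seed)
    weights = district_lattice(cfg.n_districts, cfg.island)
    J = weights.n_districts
    if isinstance(cfg.households_per_district, (tuple, list)):
        lo, hi = cfg.households_per_district
        n_per = rng.integers(lo, hi + 1, size=J)
    else:
        n_per = np.full(J, int(cfg.households_per_district))
    df = _draw_covariates(cfg, n_per, weights, rng)
    d = df.pop("_district_index").to_numpy()
    u = sample_lcar_field(cfg.true_lambda, cfg.true_tau2, weights, seed=rng)

    eta = _linear_predictor(df, cfg.true_beta) + u[d]
    if cfg.alpha is None:
        target = cfg.target_rate

        def mean_rate(a: float) -> float:
            return float(expit(a + eta).mean()) - target

        alpha = float(brentq(mean_rate, -30.0, 10.0))
    else:
        alpha = float(cfg.alpha)
    pi = expit(alpha + eta)

    z = cfg.line.per_year
    sigma = cfg.expenditure_sigma
    mu_log = cfg.log_median_expenditure
    size = df["household_size"].to_numpy(dtype=float)
    x_pre = np.exp(rng.normal(mu_log, sigma, len(df)))
    oop = _two_part_oop(df, cfg, rng)

    if cfg.mode == "outcome_first":
        y = rng.binomial(1, pi).astype(int)
        flagged = y == 1
        # flagged households: just above the line before payments, below after
        delta = rng.uniform(0.02, 0.10, flagged.sum())
        eps = rng.uniform(0.1, 1.0, flagged.sum())
        x_pre[flagged] = z * (1.0 + delta)
        oop[flagged] = size[flagged] * delta * z * (1.0 + eps)
        # unflagged households above the line must not cross it
        above = (~flagged) & (x_pre >= z)
        cap = 0.9 * size[above] * (x_pre[above] - z)
        oop[above] = np.minimum(oop[above], cap)
    else:
        y = None  # derived from expenditures below

    total = x_pre * size
    oop = np.minimum(oop, 0.95 * total)  # payments cannot exceed consumption
    df["total_expenditure"] = total
    df["oop_payment"] = oop
    x_post = np.maximum(total - oop, 0.0) / size
    crossing = ((x_pre >= z) & (x_post < z)).astype(int)
    if y is None:
        y = crossing
    df["impoverished"] = y

    truth = {
        "mode": cfg.mode,
        "alpha": alpha,
        "beta": dict(cfg.true_beta),
        "lambda": cfg.true_lambda,
        "tau2": cfg.true_tau2,
        "u": u.tolist(),
        "district_ids": list(weights.district_ids),
        "line_per_year": z,
        "expenditure_sigma": sigma,
        "log_median_expenditure": mu_log,
        "analytic_head_count": (
            cfg.analytic_head_count if cfg.mode == "expenditure_first" else None
        ),
        "crossing": crossing.tolist(),
        "mean_pi": float(pi.mean()),
        "seed": cfg.seed,
    }
    return df, weights, truth


def write_fixture(
    records: pd.DataFrame,
    weights: SpatialWeights,
    truth: dict,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write households.csv + districts.gal + truth.json; read-back round-trips."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "households": outdir / "households.csv",
        "weights": outdir / "districts.gal",
        "truth": outdir / "truth.json",
    }
    records.to_csv(paths["households"], index=False)
    write_gal(weights, paths["weights"])
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return paths


def read_fixture(outdir: str | Path) -> tuple[pd.DataFrame, SpatialWeights, dict]:
    outdir = Path(outdir)
    records = pd.read_csv(outdir / "households.csv")
    weights = read_gal(outdir / "districts.gal")
    truth = json.loads((outdir / "truth.json").read_text())
    return records, weights, truth
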