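"""End-to-end orchestration: metrics -> Moran -> model fits -> report.

One :class:`RunConfig` drives the whole analysis reproducibly: every
source of randomness derives from the single top-level seed through
per-stage spawned seed sequences, and all outputs are plain CSV/JSON so
re-running with the same seed yields byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import generator_config_from_dict, parse_line, read_households
from .model import LcarSpec, build_model_frame, compare_dic, fit, random_effect_map
from .poverty import (
    grouped_report_frame,
    impoverishment,
    impoverishment_by_group,
    validate_households,
)
from .simulate import generate, write_fixture
from .weights import morans_i, read_gal

log = logging.getLogger("impovmap")

DEFAULT_COVARIATES = (
    "head_age",
    "female_head",
    "household_size",
    "ses_higher",
    "child_u5",
    "elderly",
    "chronic",
    "hospitalized",
    "rural",
    "distance_km",
    "facility",
    "region",
)


@dataclass
class RunConfig:
    """Paths, poverty lines, groupings and MCMC settings for one run."""

    output_dir: str
    households_csv: str | None = None
    weights_gal: str | None = None
    synthetic: dict | None = None  # GeneratorConfig fields; generates inputs
    column_map: dict[str, str] | None = None
    lines: Sequence[str | float] = ("national", "usd190", "usd320")
    model_line: str | float = "national"
    groupings: Sequence[str] = ("district_id", "region", "rural", "quintile")
    covariates: Sequence[str] = DEFAULT_COVARIATES
    references: dict[str, str] = field(
        default_factory=lambda: {
            "head_age": "over56",
            "facility": "government",
            "region": "northern",
        }
    )
    moran_permutations: int = 9999
    chains: int = 2
    iterations: int = 4000
    burn_in: int = 1000
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        return cls(**d)


def _stage_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, np.uint32)[0]) % (2**31 - 1)


def run(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis; returns a manifest of outputs.

    Emits per-line impoverishment tables, grouped tables, Moran's I on
    the district head-count change, the three model fits with odds
    ratios and a DIC ranking, the district random-effect map, and a run
    log carrying the seed, version and config hash.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = np.random.SeedSequence(config.seed).spawn(4)
    manifest: dict[str, Any] = {"outputs": [], "warnings": []}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        manifest["outputs"].append(name)

    # --- inputs ------------------------------------------------------------
    stage = "inputs"
    try:
        if config.synthetic is not None:
            gen_cfg = generator_config_from_dict(
                {**config.synthetic, "seed": _stage_seed(stages[0])}
            )
            households, weights, truth = generate(gen_cfg)
            write_fixture(households, weights, truth, out / "fixture")
            manifest["outputs"].extend(
                ["fixture/households.csv", "fixture/districts.gal", "fixture/truth.json"]
            )
        else:
            if config.households_csv is None:
                raise ValueError("either households_csv or synthetic must be given")
            households = read_households(config.households_csv, config.column_map)
            weights = read_gal(config.weights_gal) if config.weights_gal else None
        validate_households(households)

        stage = "impoverishment tables"
        lines = [parse_line(sp) for sp in config.lines]
        district_change: pd.Series | None = None
        for line in lines:
            table = impoverishment(households, line)
            emit(f"impoverishment_{line.label}.csv", table.to_report_frame())
            for grouping in config.groupings:
                tabs = impoverishment_by_group(households, line, grouping)
                emit(
                    f"impoverishment_{line.label}_by_{grouping}.csv",
                    grouped_report_frame(tabs),
                )
                if grouping == "district_id" and line.label == parse_line(
                    config.model_line
                ).label:
                    district_change = pd.Series(
                        {
                            g: t.absolute_diff["head_count_pct"]
                            for g, t in tabs.items()
                        }
                    )

        stage = "Moran's I"
        moran_out: dict[str, Any] | None = None
        if weights is not None and district_change is not None:
            vals = district_change.reindex(weights.district_ids)
            if vals.isna().any():
                missing = vals[vals.isna()].index.tolist()
                raise ValueError(f"no households observed in district(s) {missing}")
            res = morans_i(
                vals.to_numpy(),
                weights,
                n_permutations=config.moran_permutations,
                seed=_stage_seed(stages[1]),
            )
            moran_out = {
                "variable": "absolute head-count change",
                "I": res.I,
                "expected_I": res.expected_I,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
                "standardization": res.standardization,
            }
            (out / "moran.json").write_text(json.dumps(moran_out, indent=1) + "\n")
            manifest["outputs"].append("moran.json")

        stage = "model fits"
        model_line = parse_line(config.model_line)
        posteriors = []
        if households["oop_payment"].max() == 0:
            msg = "all OOP payments are zero: outcome is degenerate, model stage skipped"
            log.warning(msg)
            manifest["warnings"].append(msg)
        elif weights is None:
            msg = "no spatial weights supplied: model stage skipped"
            log.warning(msg)
            manifest["warnings"].append(msg)
        else:
            frame = build_model_frame(
                households,
                [c for c in config.covariates if c in households.columns],
                line=model_line,
                weights=weights,
                references=config.references,
            )
            if frame.y.min() == frame.y.max():
                msg = "outcome has a single level: model stage skipped"
                log.warning(msg)
                manifest["warnings"].append(msg)
            else:
                spec = LcarSpec(weights=weights)
                fit_seed = _stage_seed(stages[2])
                for k, model in enumerate(("single", "multilevel", "spatial")):
                    log.info("fitting %s model", model)
                    post = fit(
                        frame,
                        spec,
                        model=model,
                        chains=config.chains,
                        iterations=config.iterations,
                        burn_in=config.burn_in,
                        seed=fit_seed + k,
                    )
                    posteriors.append(post)
                    manifest["warnings"].extend(
                        f"{model}: {w}" for w in post.warnings
                    )
                    emit(f"model_{model}_odds_ratios.csv", post.odds_ratios)
                    emit(f"model_{model}_summary.csv", post.summaries)
                emit("dic_comparison.csv", compare_dic(posteriors))
                spatial = posteriors[-1]
                emit("random_effects.csv", random_effect_map(spatial, weights))

        stage = "report"
        cfg_dict = asdict(config)
        cfg_dict.pop("output_dir", None)  # hash the analysis, not its location
        cfg_hash = hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        manifest.update(
            {"seed": config.seed, "version": __version__, "config_hash": cfg_hash}
        )
        if moran_out is not None:
            manifest["moran"] = moran_out
        (out / "run.log").write_text(
            "\n".join(
                [
                    f"impovmap {__version__}",
                    f"seed {config.seed}",
                    f"config_hash {cfg_hash}",
                    f"outputs {len(manifest['outputs'])}",
                ]
                + [f"warning {w}" for w in manifest["warnings"]]
            )
            + "\n"
        )
        manifest["outputs"].append("run.log")
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
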