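"""Repeated-run protocol: rebuild, evaluate, aggregate, compare.

Because chimeric-dataset construction is stochastic (menagerie selection
and cross-modality assignment are random permutations), a single run is not
representative. The harness re-executes the whole random process a
configured number of times (default 30), each run with fresh seeds spawned
deterministically from one master seed, evaluates every configured method
(modality subset x fusion rule) in the three scenarios, and reports mean
+/- standard deviation of decidability and EER. Methods are compared with
Welch's two-sample t-test against the lowest-mean-EER method per scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chimera_builder import build
from .errors import IntegrityError, ValidationError
from .modality_store import ModalityDataset
from .verification_eval import (
    SCENARIOS,
    decidability,
    enumerate_pairs,
    eer_from_scores,
    score_pairs,
)
from .zoo_labeling import ZooConfig, label_modality


@dataclass(frozen=True)
class MethodSpec:
    """One evaluated method: a modality subset and an optional fusion rule."""

    modalities: tuple[str, ...]
    rule: str | None = None  # None = unimodal; sum/min/mult/concat otherwise

    def __post_init__(self) -> None:
        if len(self.modalities) == 1 and self.rule is not None:
            raise ValidationError("unimodal methods take no fusion rule")
        if len(self.modalities) > 1 and self.rule is None:
            raise ValidationError("multimodal methods need a fusion rule")

    @property
    def name(self) -> str:
        base = "+".join(self.modalities)
        return f"{base}/{self.rule}" if self.rule else base


@dataclass(frozen=True)
class ExperimentConfig:
    methods: tuple[MethodSpec, ...]
    metrics: Mapping[str, str] | str = "euclidean"
    zoo: ZooConfig = ZooConfig()
    scenarios: tuple[str, ...] = SCENARIOS
    n_runs: int = 30
    pair_limits: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValidationError("need n_runs >= 2")
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ValidationError(f"unknown scenarios {unknown}")


@dataclass
class ExperimentReport:
    """Per-run decidability and EER for every (method, scenario)."""

    methods: list[str]
    scenarios: list[str]
    eer: dict[tuple[str, str], np.ndarray]
    dec: dict[tuple[str, str], np.ndarray]
    run_seeds: list[int]
    master_seed: int

    @property
    def n_runs(self) -> int:
        return len(self.run_seeds)

    def summary(self) -> pd.DataFrame:
        """Mean +/- sd table shaped like a methods-comparison table."""
        rows = []
        for method in self.methods:
            row: dict[str, object] = {"method": method}
            for scen in self.scenarios:
                d = self.dec[(method, scen)]
                e = self.eer[(method, scen)]
                row[f"{scen}_decidability_mean"] = d.mean()
                row[f"{scen}_decidability_sd"] = d.std(ddof=1)
                row[f"{scen}_eer_mean"] = e.mean()
                row[f"{scen}_eer_sd"] = e.std(ddof=1)
            rows.append(row)
        return pd.DataFrame(rows)


def _spawn_run_seeds(master_seed: int, n_runs: int) -> list[int]:
    """Documented scheme: SeedSequence(master).generate_state(n), masked to
    31 bits; collisions (astronomically unlikely) are bumped to uniqueness."""
    state = np.random.SeedSequence(master_seed).generate_state(n_runs)
    seeds: list[int] = []
    for s in state:
        s = int(s) & 0x7FFFFFFF
        while s in seeds:
            s = (s + 1) & 0x7FFFFFFF
        seeds.append(s)
    return seeds


def run_protocol(
    modalities: Mapping[str, ModalityDataset],
    config: ExperimentConfig,
    master_seed: int = 0,
    n_runs: int | None = None,
) -> ExperimentReport:
    """Execute the full stochastic protocol ``n_runs`` times.

    Each run derives zoo/build/pair seeds from its run seed, relabels each
    modality, rebuilds the chimeric dataset, and evaluates every method in
    every scenario. Failures abort with the offending run seed.
    """
    n_runs = n_runs or config.n_runs
    run_seeds = _spawn_run_seeds(master_seed, n_runs)
    metrics = config.metrics
    if isinstance(metrics, str):
        metrics = {mod: metrics for mod in modalities}
    session_order = next(iter(modalities.values())).session_order

    eer: dict[tuple[str, str], list[float]] = {}
    dec: dict[tuple[str, str], list[float]] = {}
    for r, run_seed in enumerate(run_seeds):
        try:
            ss = np.random.SeedSequence(run_seed)
            zoo_seed, build_seed, pair_seed = (
                int(x) & 0x7FFFFFFF for x in ss.generate_state(3)
            )
            mod_seeds = np.random.SeedSequence(zoo_seed).generate_state(len(modalities))
            zoo_maps = {
                mod: label_modality(ds, config.zoo, int(mod_seeds[m]) & 0x7FFFFFFF)
                for m, (mod, ds) in enumerate(modalities.items())
            }
            chimeric = build(modalities, zoo_maps, seed=build_seed)
            for scen in config.scenarios:
                manifest = enumerate_pairs(
                    chimeric, scen, session_order, config.pair_limits, pair_seed
                )
                for method in config.methods:
                    scores = score_pairs(
                        manifest,
                        chimeric,
                        modalities,
                        metrics,
                        modality_subset=method.modalities,
                        fusion=method.rule,
                    )
                    key = (method.name, scen)
                    dec.setdefault(key, []).append(decidability(scores))
                    eer.setdefault(key, []).append(eer_from_scores(scores))
        except Exception as exc:
            raise RuntimeError(f"run {r} (seed {run_seed}) failed: {exc}") from exc

    return ExperimentReport(
        methods=[m.name for m in config.methods],
        scenarios=list(config.scenarios),
        eer={k: np.array(v) for k, v in eer.items()},
        dec={k: np.array(v) for k, v in dec.items()},
        run_seeds=run_seeds,
        master_seed=master_seed,
    )


def compare_methods(report: ExperimentReport, alpha: float = 0.05) -> pd.DataFrame:
    """Welch t-test of every method's per-run EERs against the best method.

    Per scenario, the reference is the method with the lowest mean EER; a
    method is flagged ``equivalent_to_best`` when p >= alpha (no significant
    difference from the best).
    """
    if len(report.methods) < 2:
        raise IntegrityError("need >= 2 methods to compare")
    lengths = {len(v) for v in report.eer.values()}
    if len(lengths) != 1:
        raise IntegrityError("methods have unequal run counts")
    rows = []
    for scen in report.scenarios:
        means = {m: report.eer[(m, scen)].mean() for m in report.methods}
        best = min(means, key=lambda m: (means[m], m))
        ref = report.eer[(best, scen)]
        for method in report.methods:
            cur = report.eer[(method, scen)]
            if np.array_equal(cur, ref):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(cur, ref, equal_var=False)
            rows.append(
                {
                    "scenario": scen,
                    "method": method,
                    "best_method": best,
                    "eer_mean": means[method],
                    "t_stat": float(t),
                    "p_value": float(p),
                    "equivalent_to_best": bool(p >= alpha),
                }
            )
    return pd.DataFrame(rows)
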