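"""Synthetic multi-session feature data with planted menagerie structure.

The generator emulates the situation the protocol is designed for:
per-modality tables of fixed-length embeddings, acquired in two (or more)
sessions, where a small fraction of individuals are *goats* (inflated
intra-class spread) or *lambs* (class center shrunk toward the population
mean, hence unusually close to everyone else).

Model, per modality: each individual j gets a class center
``c_j ~ N(0, sigma_between^2 I_d)`` (multiplied by the shrink factor
``lambda`` if j is a planted lamb); each session adds an individual-specific
drift offset ``N(0, sigma_drift^2 I_d)`` — the "natural noise" that makes
inter-session matching harder; samples are the session center plus
``N(0, sigma_within^2 I_d)`` noise, with sigma_within multiplied by g for
planted goats. Sample counts per (individual, session) are drawn uniformly
from a configured range.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .modality_store import ModalityDataset, SampleRecord
from .zoo_labeling import round_half_up


@dataclass(frozen=True)
class ModalitySpec:
    """Noise geometry of one synthetic modality."""

    modality_id: str
    dimension: int = 16
    sigma_between: float = 1.0
    sigma_within: float = 0.5
    sigma_drift: float = 0.25

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValidationError("dimension must be >= 1")
        if min(self.sigma_between, self.sigma_within) <= 0 or self.sigma_drift < 0:
            raise ValidationError("sigma_between/sigma_within must be > 0, sigma_drift >= 0")


_DEFAULT_SPECS = (
    ModalitySpec("m1"),
    ModalitySpec("m2"),
    ModalitySpec("m3"),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Suite-level knobs: population sizes, menagerie fractions, sessions.

    Defaults mirror a three-modality study whose smallest modality has 56
    individuals, with 10% planted goats and 10% planted lambs, two
    sessions, and 4-6 samples per individual per session.

    The default goat multiplier (2.0) doubles a goat's intra-class noise:
    goats are markedly harder to match yet their genuine scores still lie
    mostly below typical impostor scores, as for real percentile-defined
    goats. (Much larger multipliers turn goats into subjects whose genuine
    comparisons score worse than impostors — outlier/wolf behavior, not
    goat behavior.) Likewise the default lamb shrink (0.5) halves a lamb's
    distance to the population without collapsing lambs onto each other.
    """

    n_individuals: tuple[int, ...] = (56, 60, 70)
    modalities: tuple[ModalitySpec, ...] = _DEFAULT_SPECS
    goat_fraction: float = 0.10
    goat_multiplier: float = 2.0
    lamb_fraction: float = 0.10
    lamb_shrink: float = 0.50
    samples_per_session: tuple[int, int] = (4, 6)
    n_sessions: int = 2
    shared_pool: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.n_individuals, int):
            object.__setattr__(self, "n_individuals", (self.n_individuals,) * len(self.modalities))
        if len(self.n_individuals) != len(self.modalities):
            raise ValidationError("one population size per modality is required")
        if self.goat_fraction + self.lamb_fraction >= 0.5:
            raise ValidationError("goat and lamb fractions must sum to < 0.5")
        if not self.goat_multiplier > 1:
            raise ValidationError("goat_multiplier must be > 1")
        if not (0 < self.lamb_shrink < 1):
            raise ValidationError("lamb_shrink must lie in (0, 1)")
        lo, hi = self.samples_per_session
        if lo < 2 or hi < lo:
            raise ValidationError("samples_per_session range must satisfy 2 <= lo <= hi")
        if self.n_sessions < 1:
            raise ValidationError("need at least one session")
        if self.shared_pool and len(set(self.n_individuals)) != 1:
            raise ValidationError("shared_pool requires equal population sizes")

    @property
    def session_order(self) -> list[str]:
        return [f"s{k + 1}" for k in range(self.n_sessions)]


def plant_labels(ids: Sequence[str], cfg: SyntheticConfig, rng: np.random.Generator) -> dict[str, str]:
    """Randomly plant goat/lamb labels on a population, remainder sheep."""
    n = len(ids)
    n_goat = round_half_up(cfg.goat_fraction * n)
    n_lamb = round_half_up(cfg.lamb_fraction * n)
    perm = [ids[i] for i in rng.permutation(n)]
    labels = {i: "sheep" for i in ids}
    labels.update({i: "goat" for i in perm[:n_goat]})
    labels.update({i: "lamb" for i in perm[n_goat:n_goat + n_lamb]})
    return labels


def generate_modality(
    cfg: SyntheticConfig,
    spec: ModalitySpec,
    planted: Mapping[str, str],
    seed: int | None = None,
) -> ModalityDataset:
    """Generate one modality's feature table for the given planted labels."""
    rng = np.random.default_rng(seed)
    d = spec.dimension
    records: list[SampleRecord] = []
    lo, hi = cfg.samples_per_session
    for ind in planted:  # mapping order fixes rng consumption order
        label = planted[ind]
        center = rng.normal(0.0, spec.sigma_between, size=d)
        if label == "lamb":
            center = center * cfg.lamb_shrink
        noise_scale = spec.sigma_within * (cfg.goat_multiplier if label == "goat" else 1.0)
        for sess in cfg.session_order:
            drift = rng.normal(0.0, spec.sigma_drift, size=d) if spec.sigma_drift > 0 else 0.0
            count = int(rng.integers(lo, hi + 1))
            noise = rng.normal(0.0, noise_scale, size=(count, d))
            for k in range(count):
                records.append(SampleRecord(ind, sess, k, center + drift + noise[k]))
    return ModalityDataset(
        modality_id=spec.modality_id,
        dimension=d,
        records=records,
        session_order=cfg.session_order,
    )


def generate_suite(
    cfg: SyntheticConfig = SyntheticConfig(), seed: int | None = None
) -> tuple[dict[str, ModalityDataset], dict[str, dict[str, str]]]:
    """Generate all modalities of a study.

    Independent mode (default) draws a separate individual pool per modality
    with its own planted labels; shared-pool mode reuses one id set and one
    planted labeling across modalities (same source population observed
    through different sensors).

    Returns (modality_id -> dataset, modality_id -> planted labels).
    """
    if len(cfg.modalities) < 2:
        raise ValidationError("a suite needs >= 2 modality specs")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(cfg.modalities) + 1)
    label_rng = np.random.default_rng(children[0])
    datasets: dict[str, ModalityDataset] = {}
    planted_all: dict[str, dict[str, str]] = {}
    shared_planted: dict[str, str] | None = None
    for m, (spec, n) in enumerate(zip(cfg.modalities, cfg.n_individuals)):
        if cfg.shared_pool:
            ids = [f"subj{j + 1:03d}" for j in range(n)]
            if shared_planted is None:
                shared_planted = plant_labels(ids, cfg, label_rng)
            planted = shared_planted
        else:
            ids = [f"{spec.modality_id}-{j + 1:03d}" for j in range(n)]
            planted = plant_labels(ids, cfg, label_rng)
        mod_seed = int(children[m + 1].generate_state(1)[0]) & 0x7FFFFFFF
        datasets[spec.modality_id] = generate_modality(cfg, spec, planted, mod_seed)
        planted_all[spec.modality_id] = dict(planted)
    return datasets, planted_all
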