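"""Assembly of chimeric (virtual) multimodal individuals.

A chimeric individual pairs one real individual per modality, all carrying
the same menagerie label. Per label, the number of chimeric individuals is
capped at the modality with the fewest individuals of that label; each real
individual is used by at most one chimeric individual (injective
assignment, "chosen only once"). Samples are paired sequentially within
each session — the k-th training sample of modality 1 with the k-th
training sample of modality 2, and so on — so the chimeric sample count is
the per-session minimum across sources. Pairing within sessions (rather
than across) keeps intra-session and inter-session evaluation scenarios
meaningful.

Every random draw is derived from a single master seed, and the resulting
:class:`~zoochimera.modality_store.BuildRecipe` replays the build exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InsufficientSamplesError, IntegrityError
from .modality_store import BuildRecipe, ModalityDataset
from .zoo_labeling import LABELS, ZooLabelMap


@dataclass(eq=True)
class ChimericIndividual:
    """A virtual subject: one source individual per modality, one label.

    ``samples[k]`` maps modality_id -> (session_id, sample_index) for the
    k-th chimeric sample; all refs of one chimeric sample share a session.
    """

    chimeric_id: str
    label: str
    sources: dict[str, str]
    samples: list[dict[str, tuple[str, int]]]

    def sample_session(self, k: int) -> str:
        return next(iter(self.samples[k].values()))[0]


@dataclass
class ChimericDataset:
    individuals: list[ChimericIndividual]
    recipe: BuildRecipe
    category_counts: dict[str, int] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChimericDataset):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.category_counts == other.category_counts
        )

    def __len__(self) -> int:
        return len(self.individuals)

    def session_samples(self, session_id: str) -> list[tuple[int, int]]:
        """(individual index, sample position) of every chimeric sample in
        a session, in deterministic order."""
        out = []
        for i, ind in enumerate(self.individuals):
            for k in range(len(ind.samples)):
                if ind.sample_session(k) == session_id:
                    out.append((i, k))
        return out


def cap_category_counts(
    counts_per_modality: Mapping[str, Mapping[str, int]],
) -> dict[str, int]:
    """Per label, the minimum count across modalities.

    E.g. one modality with 10 goats / 10 lambs / 80 sheep combined with one
    of 5 / 5 / 400 supports exactly 5 goats, 5 lambs, and 80 sheep.
    """
    if not counts_per_modality:
        raise IntegrityError("no modalities given")
    label_sets = [set(c) for c in counts_per_modality.values()]
    labels = label_sets[0]
    if any(ls != labels for ls in label_sets[1:]):
        raise IntegrityError("modalities declare different label sets")
    return {
        label: min(int(c[label]) for c in counts_per_modality.values())
        for label in sorted(labels)
    }


def assign_individuals(
    label_maps: Mapping[str, ZooLabelMap],
    caps: Mapping[str, int],
    seed: int | None = None,
) -> dict[str, tuple[str, dict[str, str]]]:
    """Pair same-label individuals across modalities, injectively.

    Per label, each modality's individuals of that label are permuted with
    the seeded generator and the first ``caps[label]`` are paired
    positionally. Returns chimeric_id -> (label, modality -> individual).
    """
    rng = np.random.default_rng(seed)
    assignments: dict[str, tuple[str, dict[str, str]]] = {}
    for label in LABELS:
        cap = int(caps.get(label, 0))
        selected: dict[str, list[str]] = {}
        for mod in label_maps:  # insertion order: deterministic rng consumption
            ids = label_maps[mod].ids_with(label)
            if cap > len(ids):
                raise IntegrityError(
                    f"cap {cap} for {label!r} exceeds the {len(ids)} available "
                    f"in modality {mod!r}"
                )
            perm = [ids[i] for i in rng.permutation(len(ids))]
            selected[mod] = perm[:cap]
        for k in range(cap):
            cid = f"{label}{k + 1:03d}"
            assignments[cid] = (label, {mod: selected[mod][k] for mod in label_maps})
    return assignments


def pair_samples(
    per_modality_sessions: Mapping[str, Mapping[str, Sequence[int]]],
    session_order: Sequence[str],
) -> list[dict[str, tuple[str, int]]]:
    """Sequentially pair source samples, session by session.

    ``per_modality_sessions[mod][session]`` is the ordered list of sample
    indices the source individual has in that session. The k-th chimeric
    sample of a session references the k-th sample of every modality; the
    per-session count is the minimum across modalities.
    """
    samples: list[dict[str, tuple[str, int]]] = []
    for sess in session_order:
        counts = {}
        for mod, sessions in per_modality_sessions.items():
            counts[mod] = len(sessions.get(sess, ()))
            if counts[mod] == 0:
                raise InsufficientSamplesError(
                    f"modality {mod!r} has no samples in required session {sess!r}"
                )
        for k in range(min(counts.values())):
            samples.append(
                {
                    mod: (sess, int(per_modality_sessions[mod][sess][k]))
                    for mod in per_modality_sessions
                }
            )
    return samples


def _source_sessions(
    dataset: ModalityDataset, individual_id: str
) -> dict[str, list[int]]:
    return {
        sess: [r.sample_index for r in dataset.samples_of(individual_id, sess)]
        for sess in dataset.session_order
    }


def build(
    modalities: Mapping[str, ModalityDataset],
    zoo_maps: Mapping[str, ZooLabelMap],
    seed: int = 0,
) -> ChimericDataset:
    """Cap categories, assign individuals, pair samples; fully seeded.

    All modalities must declare the same session order (chimeric samples
    are session-consistent across modalities).
    """
    if len(modalities) < 2:
        raise IntegrityError("chimeric construction needs >= 2 modalities")
    if set(zoo_maps) != set(modalities):
        raise IntegrityError("zoo maps and modalities cover different modality ids")
    session_orders = {tuple(ds.session_order) for ds in modalities.values()}
    if len(session_orders) != 1:
        raise IntegrityError("modalities declare different session orders")
    session_order = list(session_orders.pop())

    caps = cap_category_counts({mod: zoo_maps[mod].counts() for mod in modalities})
    assign_seed = int(np.random.SeedSequence(seed).generate_state(1)[0]) & 0x7FFFFFFF
    assignments = assign_individuals(zoo_maps, caps, assign_seed)

    individuals: list[ChimericIndividual] = []
    pairing: dict[str, list[dict[str, tuple[str, int]]]] = {}
    for cid in sorted(assignments):
        label, sources = assignments[cid]
        per_mod = {mod: _source_sessions(modalities[mod], ind) for mod, ind in sources.items()}
        samples = pair_samples(per_mod, session_order)
        individuals.append(
            ChimericIndividual(chimeric_id=cid, label=label, sources=dict(sources), samples=samples)
        )
        pairing[cid] = samples

    recipe = BuildRecipe(
        master_seed=seed,
        stage_seeds={"assign": assign_seed},
        individual_assignments={cid: dict(assignments[cid][1]) for cid in assignments},
        label_assignments={cid: assignments[cid][0] for cid in assignments},
        sample_pairing=pairing,
    )
    return ChimericDataset(individuals=individuals, recipe=recipe, category_counts=caps)


def replay(
    recipe: BuildRecipe, modalities: Mapping[str, ModalityDataset]
) -> ChimericDataset:
    """Reconstruct the chimeric dataset a recipe describes, verifying that
    every referenced source sample exists."""
    recipe.validate()
    individuals = []
    counts: dict[str, int] = {label: 0 for label in LABELS}
    for cid in sorted(recipe.individual_assignments):
        label = recipe.label_assignments[cid]
        sources = recipe.individual_assignments[cid]
        samples = []
        for samp in recipe.sample_pairing.get(cid, []):
            ref = {}
            for mod, (sess, idx) in samp.items():
                modalities[mod].lookup(sources[mod], sess, int(idx))  # existence check
                ref[mod] = (sess, int(idx))
            samples.append(ref)
        individuals.append(
            ChimericIndividual(chimeric_id=cid, label=label, sources=dict(sources), samples=samples)
        )
        counts[label] = counts.get(label, 0) + 1
    return ChimericDataset(individuals=individuals, recipe=recipe, category_counts=counts)
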