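"""Data model and I/O for per-modality feature tables and build recipes.

A *modality* is one biometric trait (e.g. ECG beats, periocular images,
faces) whose samples have already been reduced to fixed-length real feature
vectors. Tables are delimited text with a mandatory header::

    individual,session,sample,f1,...,fd

`individual` and `session` are opaque string labels; `sample` is a
non-negative integer index, dense per (individual, session). Session order
is declared explicitly (never sorted lexicographically) because acquisition
sessions are temporally ordered and labels like "10" would sort before "2".

A :class:`BuildRecipe` records every seed and assignment needed to replay a
chimeric-dataset build bit-for-bit; recipes serialize to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, EmptyInputError, IntegrityError

_META_COLUMNS = ("individual", "session", "sample")


@dataclass(eq=False)
class SampleRecord:
    """One feature-vector sample of one individual in one session."""

    individual_id: str
    session_id: str
    sample_index: int
    features: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 1:
            raise DimensionError("features must be a 1-D vector")
        if self.sample_index < 0:
            raise IntegrityError("sample_index must be non-negative")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.individual_id, self.session_id, self.sample_index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleRecord):
            return NotImplemented
        return self.key == other.key and np.array_equal(self.features, other.features)

    def __hash__(self) -> int:
        return hash(self.key)


@dataclass(eq=False)
class ModalityDataset:
    """All samples of one modality, with a declared session order.

    Records are stored in insertion order but every derived view (individual
    lists, per-individual sample lists) is deterministically ordered, so two
    datasets holding the same records in a different order behave
    identically downstream.
    """

    modality_id: str
    dimension: int
    records: list[SampleRecord]
    session_order: list[str]

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyInputError(f"modality {self.modality_id!r}: no records")
        seen: set[tuple[str, str, int]] = set()
        for rec in self.records:
            if rec.features.shape[0] != self.dimension:
                raise DimensionError(
                    f"modality {self.modality_id!r}: record {rec.key} has "
                    f"dimension {rec.features.shape[0]}, expected {self.dimension}"
                )
            if rec.key in seen:
                raise IntegrityError(
                    f"modality {self.modality_id!r}: duplicate sample key {rec.key}"
                )
            seen.add(rec.key)
            if rec.session_id not in self.session_order:
                raise IntegrityError(
                    f"modality {self.modality_id!r}: session {rec.session_id!r} "
                    f"not in declared session order {self.session_order}"
                )
        # deterministic lookup: (individual, session) -> records by sample_index
        self._index: dict[tuple[str, str], list[SampleRecord]] = {}
        for rec in sorted(self.records, key=lambda r: r.key):
            self._index.setdefault((rec.individual_id, rec.session_id), []).append(rec)

    # -- derived counts ---------------------------------------------------
    @property
    def individual_ids(self) -> list[str]:
        return sorted({rec.individual_id for rec in self.records})

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def samples_of(self, individual_id: str, session_id: str | None = None) -> list[SampleRecord]:
        """Records of one individual (optionally one session), ordered by
        (session position, sample_index)."""
        if session_id is not None:
            return list(self._index.get((individual_id, session_id), []))
        out: list[SampleRecord] = []
        for sess in self.session_order:
            out.extend(self._index.get((individual_id, sess), []))
        return out

    def sample_count(self, individual_id: str, session_id: str | None = None) -> int:
        return len(self.samples_of(individual_id, session_id))

    def features_of(self, individual_id: str, session_id: str | None = None) -> np.ndarray:
        recs = self.samples_of(individual_id, session_id)
        if not recs:
            return np.empty((0, self.dimension))
        return np.vstack([r.features for r in recs])

    def lookup(self, individual_id: str, session_id: str, sample_index: int) -> SampleRecord:
        for rec in self._index.get((individual_id, session_id), []):
            if rec.sample_index == sample_index:
                return rec
        raise IntegrityError(
            f"modality {self.modality_id!r}: no sample "
            f"({individual_id!r}, {session_id!r}, {sample_index})"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModalityDataset):
            return NotImplemented
        return (
            self.modality_id == other.modality_id
            and self.dimension == other.dimension
            and self.session_order == other.session_order
            and sorted(self.records, key=lambda r: r.key)
            == sorted(other.records, key=lambda r: r.key)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.records, key=lambda r: r.key)
        meta = pd.DataFrame(
            {
                "individual": [r.individual_id for r in rows],
                "session": [r.session_id for r in rows],
                "sample": [r.sample_index for r in rows],
            }
        )
        feats = pd.DataFrame(
            np.vstack([r.features for r in rows]),
            columns=[f"f{i + 1}" for i in range(self.dimension)],
        )
        return pd.concat([meta, feats], axis=1)


def _detect_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_feature_table(
    path: str | Path,
    modality_id: str,
    session_order: Sequence[str] | None = None,
    delimiter: str | None = None,
) -> ModalityDataset:
    """Read a delimited feature table into a :class:`ModalityDataset`.

    Parameters
    ----------
    session_order
        Explicit ordered session list. Defaults to order of first appearance
        in the file.
    delimiter
        ``","`` or ``"\\t"``; auto-detected from the header when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path} is empty")
    sep = delimiter or _detect_delimiter(path)
    df = pd.read_csv(
        path,
        sep=sep,
        dtype={"individual": str, "session": str},
        float_precision="round_trip",
    )
    if df.empty:
        raise EmptyInputError(f"{path} contains a header but no rows")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise IntegrityError(f"{path}: missing required columns {missing}")
    feat_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if not feat_cols:
        raise DimensionError(f"{path}: no feature columns")
    feats = df[feat_cols].to_numpy(dtype=float)
    if np.isnan(feats).any():
        bad = int(np.where(np.isnan(feats).any(axis=1))[0][0])
        raise DimensionError(f"{path}: ragged/short feature row at data line {bad + 1}")
    records = [
        SampleRecord(str(ind), str(sess), int(samp), feats[i])
        for i, (ind, sess, samp) in enumerate(
            zip(df["individual"], df["session"], df["sample"])
        )
    ]
    if session_order is None:
        session_order = list(dict.fromkeys(df["session"].astype(str)))
    return ModalityDataset(
        modality_id=modality_id,
        dimension=feats.shape[1],
        records=records,
        session_order=list(session_order),
    )


def write_feature_table(dataset: ModalityDataset, path: str | Path, delimiter: str = ",") -> None:
    # %.17g round-trips IEEE doubles exactly
    dataset.to_frame().to_csv(path, sep=delimiter, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Build recipes
# ---------------------------------------------------------------------------

@dataclass
class BuildRecipe:
    """Everything needed to replay a chimeric build exactly.

    ``sample_pairing`` maps each chimeric id to the ordered list of chimeric
    samples; each chimeric sample is a mapping modality_id -> [session_id,
    sample_index] pointing into the source modality tables.
    """

    master_seed: int
    stage_seeds: dict[str, int]
    individual_assignments: dict[str, dict[str, str]]
    label_assignments: dict[str, str]
    sample_pairing: dict[str, list[dict[str, list]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # JSON round-trips tuples as lists; normalise so equality is stable.
        self.sample_pairing = {
            cid: [
                {mod: [ref[0], int(ref[1])] for mod, ref in samp.items()}
                for samp in samples
            ]
            for cid, samples in self.sample_pairing.items()
        }
        self.validate()

    def validate(self) -> None:
        if not self.stage_seeds:
            raise IntegrityError("recipe has no stage seeds")
        for name, seed in self.stage_seeds.items():
            if not isinstance(seed, int):
                raise IntegrityError(f"stage seed {name!r} is not an integer")
        if not self.label_assignments:
            raise IntegrityError("recipe has no label assignments")
        if set(self.label_assignments) != set(self.individual_assignments):
            raise IntegrityError(
                "label assignments do not cover the same chimeric ids as "
                "individual assignments"
            )

    def to_dict(self) -> dict:
        return {
            "master_seed": self.master_seed,
            "stage_seeds": self.stage_seeds,
            "individual_assignments": self.individual_assignments,
            "label_assignments": self.label_assignments,
            "sample_pairing": self.sample_pairing,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "BuildRecipe":
        try:
            return cls(
                master_seed=int(data["master_seed"]),
                stage_seeds={k: int(v) for k, v in data["stage_seeds"].items()},
                individual_assignments={
                    cid: dict(srcs) for cid, srcs in data["individual_assignments"].items()
                },
                label_assignments=dict(data["label_assignments"]),
                sample_pairing=data.get("sample_pairing", {}),
            )
        except KeyError as exc:
            raise IntegrityError(f"recipe is missing field {exc}") from exc


def write_recipe(recipe: BuildRecipe, path: str | Path) -> None:
    recipe.validate()
    Path(path).write_text(json.dumps(recipe.to_dict(), indent=2, sort_keys=True) + "\n")


def read_recipe(path: str | Path) -> BuildRecipe:
    return BuildRecipe.from_dict(json.loads(Path(path).read_text()))
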