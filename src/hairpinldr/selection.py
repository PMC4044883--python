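"""Wrapper feature selection (beam search) and RBF parameter grid search.

The selection procedure scores feature subsets by cross-validated Gm:
every pair of features is evaluated and the best B (default 10) pairs are
kept; each survivor is then extended by every unused feature, the best B
triplets are kept, and so on up to a maximum subset size (default 12).
Width B interpolates between greedy forward search (B = 1) and
exhaustive search (B = infinity).

Every cross-validation result is cached in a single-file JSON store keyed
by a fingerprint of (subset, mapping parameters, CV configuration, data
hash), so re-running selection or reusing subsets during grid search
costs nothing.  The fold seed is frozen across all evaluations so scores
are comparable; with the default m = n + 15 rule, the mapped dimension is
recomputed from each subset's size.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import CVSummary, cross_validate
from .features import FeatureTable
from .pipeline import PipelineConfig

__all__ = [
    "SubsetScore",
    "BeamConfig",
    "GridResult",
    "ResultCache",
    "beam_search",
    "grid_search",
]


@dataclass(frozen=True)
class SubsetScore:
    """Cross-validated score of one feature subset."""

    features: tuple[int, ...]       # sorted column indices into the table
    mean_gm: float
    fold_gm: tuple[float, ...]
    fold_se: tuple[float, ...]
    fold_sp: tuple[float, ...]
    fingerprint: str

    def __post_init__(self) -> None:
        if tuple(sorted(set(self.features))) != self.features:
            raise ValueError("feature indices must be sorted and unique")

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "mean_gm": self.mean_gm,
            "fold_gm": list(self.fold_gm),
            "fold_se": list(self.fold_se),
            "fold_sp": list(self.fold_sp),
            "fingerprint": self.fingerprint,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubsetScore":
        return cls(
            features=tuple(d["features"]),
            mean_gm=d["mean_gm"],
            fold_gm=tuple(d["fold_gm"]),
            fold_se=tuple(d["fold_se"]),
            fold_sp=tuple(d["fold_sp"]),
            fingerprint=d["fingerprint"],
        )


@dataclass
class BeamConfig:
    """Beam-search settings wrapped around a pipeline/CV template."""

    beam_width: int = 10
    max_size: int = 12
    cv: PipelineConfig = field(default_factory=PipelineConfig)
    cache_path: str | Path | None = None
    min_improvement: float | None = None  # optional early stop on mean Gm

    def __post_init__(self) -> None:
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        if self.max_size < 2:
            raise ValueError("max_size must be >= 2")


class ResultCache:
    """Single-file JSON key-value store for subset evaluations.

    A corrupted file is discarded and rebuilt with a warning rather than
    aborting a long selection run.
    """

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self._store: dict[str, dict] = {}
        if self.path is not None and self.path.exists():
            try:
                self._store = json.loads(self.path.read_text())
            except (json.JSONDecodeError, OSError) as exc:
                warnings.warn(
                    f"cache file {self.path} unreadable ({exc}); rebuilding",
                    stacklevel=2,
                )
                self._store = {}

    def __len__(self) -> int:
        return len(self._store)

    def lookup(self, fingerprint: str) -> SubsetScore | None:
        rec = self._store.get(fingerprint)
        return SubsetScore.from_dict(rec) if rec is not None else None

    def store(self, score: SubsetScore) -> None:
        self._store[score.fingerprint] = score.to_dict()
        if self.path is not None:
            self.path.write_text(json.dumps(self._store))


def _fingerprint(
    subset: tuple[int, ...], config: PipelineConfig, data_hash: str
) -> str:
    payload = json.dumps(
        {"subset": list(subset), "config": config.to_dict(), "data": data_hash},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def _subset_config(
    base: PipelineConfig, names: list[str], subset: tuple[int, ...]
) -> PipelineConfig:
    # n_components=None keeps the m = n + 15 rule tracking the subset size
    return base.replace(features=tuple(names[j] for j in subset))


class _Evaluator:
    """Cache-aware subset scorer; counts actual (non-cached) CV runs."""

    def __init__(self, table: FeatureTable, base: PipelineConfig,
                 cache: ResultCache):
        self.table = table
        self.base = base
        self.cache = cache
        self.names = table.feature_names
        self.data_hash = table.data_hash()
        self.n_evaluations = 0

    def __call__(self, subset: tuple[int, ...]) -> SubsetScore:
        config = _subset_config(self.base, self.names, subset)
        fp = _fingerprint(subset, config, self.data_hash)
        hit = self.cache.lookup(fp)
        if hit is not None:
            return hit
        summary: CVSummary = cross_validate(self.table, config)
        self.n_evaluations += 1
        score = SubsetScore(
            features=subset,
            mean_gm=summary.mean_gm,
            fold_gm=tuple(summary.fold_gm),
            fold_se=tuple(summary.fold_se),
            fold_sp=tuple(summary.fold_sp),
            fingerprint=fp,
        )
        self.cache.store(score)
        return score


def _top_b(scores: list[SubsetScore], b: int) -> list[SubsetScore]:
    # ties break to the lexicographically smallest subset
    return sorted(scores, key=lambda s: (-s.mean_gm, s.features))[:b]


def beam_search(
    table: FeatureTable,
    config: BeamConfig,
    evaluator=None,
) -> dict[int, list[SubsetScore]]:
    """Beam-width-B floating forward selection scored by CV mean Gm.

    Returns, for each subset size from 2 up to ``max_size``, the top-B
    scored subsets.  ``evaluator`` may be injected for testing; by
    default a cache-backed cross-validation scorer is built.  The
    evaluator used is exposed on the returned dict as ``.evaluator``
    (for instrumentation) via a small dict subclass.
    """
    n = table.n_features
    if n < 2:
        raise ValueError("need at least 2 features for selection")
    max_size = config.max_size
    if max_size > n:
        warnings.warn(
            f"max_size {max_size} exceeds feature count {n}; truncating",
            stacklevel=2,
        )
        max_size = n

    if evaluator is None:
        evaluator = _Evaluator(table, config.cv, ResultCache(config.cache_path))

    results = _BeamResults()
    results.evaluator = evaluator

    pairs = [tuple(c) for c in combinations(range(n), 2)]
    beam = _top_b([evaluator(s) for s in pairs], config.beam_width)
    results[2] = beam

    for size in range(3, max_size + 1):
        candidates = {
            tuple(sorted(set(score.features) | {j}))
            for score in beam
            for j in range(n)
            if j not in score.features
        }
        scored = [evaluator(s) for s in sorted(candidates)]
        new_beam = _top_b(scored, config.beam_width)
        results[size] = new_beam
        if (
            config.min_improvement is not None
            and new_beam[0].mean_gm - beam[0].mean_gm < config.min_improvement
        ):
            break
        beam = new_beam
    return results


class _BeamResults(dict):
    """dict[size -> top-B SubsetScores] carrying its evaluator."""

    evaluator = None

    def best(self) -> SubsetScore:
        return max(
            (scores[0] for scores in self.values()),
            key=lambda s: (s.mean_gm, -len(s.features)),
        )

    def to_frame(self, feature_names: list[str] | None = None) -> pd.DataFrame:
        rows = []
        for size, scores in sorted(self.items()):
            for rank, s in enumerate(scores):
                names = (
                    ",".join(feature_names[j] for j in s.features)
                    if feature_names
                    else ",".join(map(str, s.features))
                )
                rows.append(
                    {"size": size, "rank": rank, "features": names,
                     "mean_gm": s.mean_gm}
                )
        return pd.DataFrame(rows)


@dataclass
class GridResult:
    """Gm matrix over a (gamma, m) grid for a fixed feature subset."""

    gammas: list[float]
    ms: list[int]
    gm_matrix: np.ndarray          # (len(gammas), len(ms)); NaN = failed cell
    best_cell: tuple[int, int]

    @property
    def best_gamma(self) -> float:
        return self.gammas[self.best_cell[0]]

    @property
    def best_m(self) -> int:
        return self.ms[self.best_cell[1]]

    @property
    def best_gm(self) -> float:
        return float(self.gm_matrix[self.best_cell])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.gm_matrix,
            index=pd.Index(self.gammas, name="gamma"),
            columns=pd.Index(self.ms, name="m"),
        )

    def write_matrix(self, path, sep: str = "\t") -> None:
        """Plain matrix file, ready for heatmap rendering."""
        self.to_frame().to_csv(path, sep=sep)


def grid_search(
    table: FeatureTable,
    subset: tuple[str, ...] | None,
    gammas: list[float],
    ms: list[int],
    cv_config: PipelineConfig | None = None,
) -> GridResult:
    """Cross-validate every (gamma, m) cell of the RBF map on one subset.

    The fold seed is frozen across cells so scores are comparable; a
    failing cell is recorded as NaN rather than aborting the grid.
    """
    if not gammas or not ms:
        raise ValueError("gamma and m grids must be non-empty")
    base = cv_config or PipelineConfig()
    if subset is not None:
        base = base.replace(features=tuple(subset))
    base = base.replace(mapping="rbf")

    gm = np.full((len(gammas), len(ms)), np.nan)
    for i, gamma in enumerate(gammas):
        for j, m in enumerate(ms):
            config = base.replace(gamma=float(gamma), n_components=int(m))
            try:
                gm[i, j] = cross_validate(table, config).mean_gm
            except Exception as exc:  # cell marked failed, grid continues
                warnings.warn(
                    f"grid cell (gamma={gamma}, m={m}) failed: {exc}",
                    stacklevel=2,
                )
    if np.all(np.isnan(gm)):
        raise RuntimeError("every grid cell failed")
    best = np.unravel_index(np.nanargmax(gm), gm.shape)
    return GridResult(
        gammas=[float(g) for g in gammas],
        ms=[int(m) for m in ms],
        gm_matrix=gm,
        best_cell=(int(best[0]), int(best[1])),
    )
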