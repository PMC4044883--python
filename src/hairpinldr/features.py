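"""Sequence composition features and the canonical feature table.

The classifier consumes a 48-column feature table per hairpin candidate:
17 sequence-composition features (16 overlapping dinucleotide frequencies
plus the G+C fraction) computed natively here from FASTA, and 31
folding/thermodynamic features (minimum-free-energy measures, structure
entropy/enthalpy, melting temperature, base-pair and stem statistics)
that require an RNA secondary-structure engine and are therefore accepted
as precomputed columns and merged by record id.

``FeatureTable`` is the interchange object between all pipeline stages: a
pandas DataFrame indexed by record id, named feature columns and a binary
``label`` column (1 = pre-microRNA, 0 = pseudo hairpin / other ncRNA).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "HairpinRecord",
    "FeatureTable",
    "read_fasta",
    "write_fasta",
    "dinucleotide_frequencies",
    "gc_ratio",
    "composition_features",
    "merge_external_features",
    "NUCLEOTIDES",
    "DINUCLEOTIDES",
    "COMPOSITION_FEATURES",
    "THERMODYNAMIC_FEATURES",
    "CANONICAL_FEATURES",
    "LABEL_COLUMN",
]

NUCLEOTIDES = ("A", "C", "G", "U")
DINUCLEOTIDES = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)

#: 17 composition features computed natively from sequence
COMPOSITION_FEATURES = tuple(f"freq_{p}" for p in DINUCLEOTIDES) + ("GC_ratio",)

#: 31 folding/thermodynamic/base-pair features accepted as external columns:
#: the classic folding measures and their z-scores, the MFE indices, the
#: ensemble/entropy/enthalpy/melting measures and per-stem statistics.
THERMODYNAMIC_FEATURES = (
    "dP", "dG", "dD", "dQ", "dF",
    "MFEI1", "MFEI2",
    "zP", "zG", "zD", "zQ", "zF",
    "MFEI3", "MFEI4",
    "NEFE", "Freq", "Diversity", "Diff",
    "dS", "dS_L", "dH", "dH_L", "Tm", "Tm_L",
    "AU_L", "GC_L", "GU_L",
    "avg_bp_stem", "AU_nstems", "GC_nstems", "GU_nstems",
)

#: the full 48-feature schema
CANONICAL_FEATURES = COMPOSITION_FEATURES + THERMODYNAMIC_FEATURES

LABEL_COLUMN = "label"

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class HairpinRecord:
    """A hairpin candidate sequence, normalized to uppercase RNA (T -> U)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - set(NUCLEOTIDES)
        if bad:
            raise ValueError(
                f"record {self.id!r} contains illegal residue(s) "
                f"{sorted(bad)} after normalization"
            )
        if len(seq) < 2:
            raise ValueError(f"record {self.id!r} is shorter than 2 nt")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "HairpinRecord":
        rc = "".join(_COMPLEMENT[b] for b in reversed(self.sequence))
        return HairpinRecord(id=self.id, sequence=rc)


def read_fasta(path) -> list[HairpinRecord]:
    """Read hairpin candidates from FASTA; ids are headers up to the first
    whitespace, sequences are normalized (uppercase, T -> U)."""
    records = [
        HairpinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[HairpinRecord], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        path,
        "fasta",
    )


def dinucleotide_frequencies(rec: HairpinRecord) -> dict[str, float]:
    """Overlapping dinucleotide counts divided by L - 1; sums to 1."""
    seq = rec.sequence
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    counts = dict.fromkeys(DINUCLEOTIDES, 0)
    for i in range(len(seq) - 1):
        counts[seq[i : i + 2]] += 1
    denom = len(seq) - 1
    return {f"freq_{p}": counts[p] / denom for p in DINUCLEOTIDES}


def gc_ratio(rec: HairpinRecord) -> float:
    """(#G + #C) / L."""
    seq = rec.sequence
    return (seq.count("G") + seq.count("C")) / len(seq)


def composition_features(records: list[HairpinRecord]) -> "FeatureTable":
    """The 17 composition features for each record (labels default to 0)."""
    rows = []
    for rec in records:
        row = dinucleotide_frequencies(rec)
        row["GC_ratio"] = gc_ratio(rec)
        rows.append(row)
    frame = pd.DataFrame(rows, index=pd.Index([r.id for r in records], name="id"))
    frame[LABEL_COLUMN] = 0
    return FeatureTable(frame)


class FeatureTable:
    """Named feature matrix with a binary label column, indexed by id."""

    def __init__(self, frame: pd.DataFrame):
        if LABEL_COLUMN not in frame.columns:
            raise ValueError(f"feature table needs a {LABEL_COLUMN!r} column")
        if frame.columns.duplicated().any():
            dupes = frame.columns[frame.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        labels = frame[LABEL_COLUMN]
        if not set(np.unique(labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0/1)")
        self.frame = frame.copy()
        self.frame[LABEL_COLUMN] = labels.astype(int)

    @property
    def ids(self) -> pd.Index:
        return self.frame.index

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c != LABEL_COLUMN]

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def __len__(self) -> int:
        return len(self.frame)

    def matrix(self, features: list[str] | None = None) -> np.ndarray:
        cols = features if features is not None else self.feature_names
        missing = [c for c in cols if c not in self.frame.columns]
        if missing:
            raise KeyError(f"unknown feature columns: {missing}")
        X = self.frame[cols].to_numpy(dtype=float)
        if np.isnan(X).any():
            bad = [c for c in cols if self.frame[c].isna().any()]
            raise ValueError(f"missing values in feature columns: {bad}")
        return X

    @property
    def labels(self) -> np.ndarray:
        return self.frame[LABEL_COLUMN].to_numpy(dtype=int)

    def write(self, path, sep: str = "\t") -> None:
        self.frame.to_csv(path, sep=sep, index_label="id")

    @classmethod
    def read(cls, path, sep: str = "\t") -> "FeatureTable":
        return cls(pd.read_csv(path, sep=sep, index_col="id"))

    def data_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(",".join(map(str, self.frame.columns)).encode())
        h.update(",".join(map(str, self.frame.index)).encode())
        h.update(np.ascontiguousarray(self.frame.to_numpy(dtype=float)).tobytes())
        return h.hexdigest()


def merge_external_features(base: FeatureTable, extra: pd.DataFrame) -> FeatureTable:
    """Join externally computed feature columns (e.g. the folding block)
    onto a base table, keyed by record id; row order follows ``base``.

    Unknown column names (outside the 48-feature registry) are accepted
    with a warning so project-specific extras remain usable.
    """
    if extra.empty and len(extra.columns) == 0:
        return FeatureTable(base.frame)
    collisions = set(base.frame.columns) & set(extra.columns)
    if collisions:
        raise ValueError(f"column name collisions: {sorted(collisions)}")
    missing = base.ids.difference(extra.index)
    if len(missing):
        raise ValueError(
            f"external table is missing ids: {list(missing[:10])}"
        )
    unknown = [
        c for c in extra.columns
        if c not in CANONICAL_FEATURES and c != LABEL_COLUMN
    ]
    if unknown:
        warnings.warn(
            f"columns not in the 48-feature registry: {unknown}", stacklevel=2
        )
    joined = base.frame.join(extra.reindex(base.ids), how="left")
    # keep label as the last column
    cols = [c for c in joined.columns if c != LABEL_COLUMN] + [LABEL_COLUMN]
    return FeatureTable(joined[cols])
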