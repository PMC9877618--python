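"""Dataset construction: FASTA I/O, redundancy removal, scaling, splitting.

Redundancy removal follows CD-HIT's documented greedy semantics at desk
scale: records are sorted longest-first; each record joins the first
existing representative whose global-alignment identity (exact matches
divided by the shorter sequence's length) reaches the threshold, otherwise
it founds a new cluster.  Scaling and the stratified splits mirror the
standard sklearn preprocessing stack (StandardScaler / MinMaxScaler /
StratifiedKFold) behind a thin, JSON-serializable surface.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler, StandardScaler

from .features import ProteinRecord

__all__ = [
    "FastaParseError",
    "LabeledDataset",
    "SplitSpec",
    "read_fasta",
    "write_fasta",
    "sequence_identity",
    "dedup_by_identity",
    "FeatureScaler",
    "fit_scaler",
    "transform",
    "stratified_split",
    "stratified_kfold",
]


class FastaParseError(ValueError):
    """Malformed FASTA input, with a 1-based line number where possible."""


@dataclass
class LabeledDataset:
    """Binary-labeled sequence set for one stress class.

    labels: 1 = stress-responsive (positive), 0 = negative.
    feature_matrix is attached after extraction (n x 46).
    """

    records: list[ProteinRecord]
    labels: np.ndarray
    stress_class: str = "synthetic"
    feature_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.records) != len(self.labels):
            raise ValueError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SplitSpec:
    """Train/test and nested validation fractions plus fold count and seed."""

    train_fraction: float = 0.8
    inner_validation_fraction: float = 0.2
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("train_fraction", "inner_validation_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")


def _validate_fasta_structure(path) -> None:
    saw_header = False
    header_line = 0
    seq_chars = 0
    header_id = ""
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if saw_header and seq_chars == 0:
                    raise FastaParseError(
                        f"line {header_line}: record {header_id!r} has an empty sequence"
                    )
                header_id = stripped[1:].split()[0] if len(stripped) > 1 else ""
                if not header_id:
                    raise FastaParseError(f"line {lineno}: header with no identifier")
                if header_id in seen:
                    raise FastaParseError(
                        f"line {lineno}: duplicate id {header_id!r} "
                        f"(first seen at line {seen[header_id]})"
                    )
                seen[header_id] = lineno
                saw_header = True
                header_line = lineno
                seq_chars = 0
            else:
                if not saw_header:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                seq_chars += len(stripped)
    if not saw_header:
        raise FastaParseError("line 1: no FASTA records found")
    if seq_chars == 0:
        raise FastaParseError(
            f"line {header_line}: record {header_id!r} has an empty sequence"
        )


def read_fasta(path) -> list[ProteinRecord]:
    """Parse a (possibly line-wrapped) multi-record FASTA file.

    Order is preserved; malformed structure raises :class:`FastaParseError`
    with a line number; duplicate ids are rejected.
    """
    _validate_fasta_structure(path)
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    """Write records as 60-column-wrapped FASTA."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


_ALIGNER: PairwiseAligner | None = None


def _aligner() -> PairwiseAligner:
    # unit match score, zero mismatch, simple affine gap penalty
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = PairwiseAligner(
            mode="global",
            match_score=1.0,
            mismatch_score=0.0,
            open_gap_score=-1.0,
            extend_gap_score=-0.5,
        )
    return _ALIGNER


def sequence_identity(a: str, b: str) -> float:
    """Exact matches in a global alignment divided by the shorter length."""
    if a == b:
        return 1.0
    aln = _aligner().align(a, b)[0]
    identities = aln.counts().identities
    return identities / min(len(a), len(b))


def dedup_by_identity(
    records: Sequence[ProteinRecord], threshold: float = 0.80
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Greedy longest-first clustering at an identity threshold.

    Returns (representatives, cluster_map) where cluster_map sends every
    record id to its representative's id.  No two surviving representatives
    share identity >= threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0,1], got {threshold}")
    order = sorted(
        range(len(records)), key=lambda i: (-len(records[i].sequence), i)
    )
    reps: list[ProteinRecord] = []
    cluster_map: dict[str, str] = {}
    for i in order:
        rec = records[i]
        for rep in reps:
            if sequence_identity(rec.sequence, rep.sequence) >= threshold:
                cluster_map[rec.id] = rep.id
                break
        else:
            reps.append(rec)
            cluster_map[rec.id] = rec.id
    return reps, cluster_map


class FeatureScaler(TransformerMixin, BaseEstimator):
    """Min-max or z-score scaler with constant-column flagging and JSON state.

    Fit on training rows only; test rows are transformed with the training
    parameters (min-max outputs may then exceed [0, 1]).  Constant training
    columns are flagged and mapped to 0.
    """

    def __init__(self, kind: Literal["minmax", "zscore"] = "zscore"):
        self.kind = kind

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.kind == "zscore":
            self._impl = StandardScaler()
        elif self.kind == "minmax":
            self._impl = MinMaxScaler()
        else:
            raise ValueError(f"unknown scaler kind {self.kind!r}")
        self._impl.fit(X)
        self.constant_mask_ = X.std(axis=0) == 0.0
        self.n_features_in_ = X.shape[1]
        self.fingerprint_ = hashlib.sha256(
            np.ascontiguousarray(X).tobytes()
        ).hexdigest()[:16]
        return self

    def transform(self, X):
        if not hasattr(self, "_impl"):
            raise RuntimeError("scaler not fitted; call fit on training rows first")
        X = np.asarray(X, dtype=float)
        out = self._impl.transform(X)
        out[:, self.constant_mask_] = 0.0
        return out

    def inverse_transform(self, X):
        if not hasattr(self, "_impl"):
            raise RuntimeError("scaler not fitted")
        X = np.asarray(X, dtype=float)
        out = self._impl.inverse_transform(X)
        if self.kind == "zscore":
            means = self._impl.mean_
        else:
            means = self._impl.data_min_
        out[:, self.constant_mask_] = np.broadcast_to(
            means[self.constant_mask_], out[:, self.constant_mask_].shape
        )
        return out

    def to_json(self) -> str:
        state = {
            "kind": self.kind,
            "constant_mask": self.constant_mask_.tolist(),
            "fingerprint": self.fingerprint_,
        }
        if self.kind == "zscore":
            state["mean"] = self._impl.mean_.tolist()
            state["scale"] = self._impl.scale_.tolist()
        else:
            state["data_min"] = self._impl.data_min_.tolist()
            state["data_max"] = self._impl.data_max_.tolist()
        return json.dumps(state, indent=2)

    @classmethod
    def from_json(cls, payload: str) -> "FeatureScaler":
        state = json.loads(payload)
        obj = cls(kind=state["kind"])
        n = len(state["constant_mask"])
        if state["kind"] == "zscore":
            impl = StandardScaler()
            impl.mean_ = np.asarray(state["mean"])
            impl.scale_ = np.asarray(state["scale"])
            impl.var_ = impl.scale_**2
            impl.n_features_in_ = n
        else:
            impl = MinMaxScaler()
            dmin = np.asarray(state["data_min"])
            dmax = np.asarray(state["data_max"])
            impl.data_min_, impl.data_max_ = dmin, dmax
            rng = np.where(dmax - dmin == 0, 1.0, dmax - dmin)
            impl.data_range_ = dmax - dmin
            impl.scale_ = 1.0 / rng
            impl.min_ = -dmin * impl.scale_
            impl.n_features_in_ = n
        obj._impl = impl
        obj.constant_mask_ = np.asarray(state["constant_mask"], dtype=bool)
        obj.fingerprint_ = state["fingerprint"]
        obj.n_features_in_ = n
        return obj


def fit_scaler(matrix, kind: str = "zscore") -> FeatureScaler:
    """Fit a :class:`FeatureScaler` on training rows."""
    return FeatureScaler(kind=kind).fit(np.asarray(matrix, dtype=float))


def transform(matrix, state: FeatureScaler):
    """Apply a fitted scaler to new rows."""
    return state.transform(matrix)


def stratified_split(
    labels, spec: SplitSpec = SplitSpec()
) -> dict[str, np.ndarray]:
    """Seeded stratified 80:20 split with a nested train-core/validation split.

    Per class, the test count is round(n_class * test_fraction); the nested
    validation carve-out applies the same rounding within the training
    indices.  Returns index arrays: train, test, train_core, validation.
    """
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(spec.seed)

    def carve(idx: np.ndarray, lab: np.ndarray, held_fraction: float):
        held, kept = [], []
        for cls in np.unique(lab):
            cls_idx = idx[lab == cls]
            if len(cls_idx) < 2:
                raise ValueError(
                    f"class {cls} has {len(cls_idx)} member(s); need >= 2 to split"
                )
            perm = rng.permutation(cls_idx)
            n_held = int(round(len(cls_idx) * held_fraction))
            held.append(perm[:n_held])
            kept.append(perm[n_held:])
        return np.sort(np.concatenate(kept)), np.sort(np.concatenate(held))

    all_idx = np.arange(len(labels))
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    train, test = carve(all_idx, labels, 1.0 - spec.train_fraction)
    train_core, validation = carve(
        train, labels[train], spec.inner_validation_fraction
    )
    return {
        "train": train,
        "test": test,
        "train_core": train_core,
        "validation": validation,
    }


def stratified_kfold(
    labels, n_folds: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold partition (disjoint, exhaustive, +/-1 balance)."""
    labels = np.asarray(labels, dtype=int)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; need >= {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [
        (train_idx, test_idx)
        for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels)
    ]
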