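"""46-feature numeric encoding of protein sequences.

The feature vector concatenates, in fixed order: the 20 residue-composition
fractions (A R N D C Q E G H I L K M F P T S W Y V), a coiled-coil heptad
score, 12 post-translational-modification motif counts (S-nitrosylation
A/B/C/total around C, nitrotyrosine A/B/C/total around Y, SUMOylation
I/II/III/total around K), sequence length, acidic and basic residue counts,
molecular weight, theoretical isoelectric point, C/H/N/O/S atom counts, the
Guruprasad instability index, the aliphatic index and the Kyte-Doolittle
GRAVY.

The PTM and coiled-coil counters are deterministic, documented stand-ins:
no published motif library is mandated for these columns, so the patterns
live in :class:`FeatureSchema` and can be substituted wholesale.  Molecular
weight, the dipeptide instability weights (DIWV) and the hydropathy scale
come from biopython (``Bio.SeqUtils``).
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, asdict
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight as _bio_mw
from Bio.SeqUtils import ProtParamData
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "AMINO_ACIDS",
    "FEATURE_NAMES",
    "ProteinRecord",
    "FeatureSchema",
    "DEFAULT_SCHEMA",
    "sanitize_sequence",
    "composition",
    "charge_counts",
    "molecular_weight",
    "atom_counts",
    "net_charge",
    "theoretical_pi",
    "instability_index",
    "aliphatic_index",
    "gravy",
    "ptm_motif_counts",
    "coiled_coil_score",
    "extract_features",
    "extract_feature_table",
    "ProteinFeaturizer",
]

# Table order: A R N D C Q E G H I L K M F P T S W Y V (note T before S).
AMINO_ACIDS = "ARNDCQEGHILKMFPTSWYV"
_AA_SET = frozenset(AMINO_ACIDS)

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"comp_{aa}" for aa in AMINO_ACIDS]
    + [
        "coiled_coil",
        "nitrosylation_a", "nitrosylation_b", "nitrosylation_c", "nitrosylation_total",
        "nitrotyrosine_a", "nitrotyrosine_b", "nitrotyrosine_c", "nitrotyrosine_total",
        "sumoylation_1", "sumoylation_2", "sumoylation_3", "sumoylation_total",
        "length", "n_negative", "n_positive",
        "molecular_weight", "theoretical_pi",
        "n_carbon", "n_hydrogen", "n_nitrogen", "n_oxygen", "n_sulphur",
        "instability_index", "aliphatic_index", "gravy",
    ]
)
assert len(FEATURE_NAMES) == 46

# Free amino-acid molecular formulas (C, H, N, O, S); a peptide of length L
# is the elementwise sum minus (L-1) waters (H2, O1).
_AA_FORMULA: dict[str, tuple[int, int, int, int, int]] = {
    "A": (3, 7, 1, 2, 0), "R": (6, 14, 4, 2, 0), "N": (4, 8, 2, 3, 0),
    "D": (4, 7, 1, 4, 0), "C": (3, 7, 1, 2, 1), "Q": (5, 10, 2, 3, 0),
    "E": (5, 9, 1, 4, 0), "G": (2, 5, 1, 2, 0), "H": (6, 9, 3, 2, 0),
    "I": (6, 13, 1, 2, 0), "L": (6, 13, 1, 2, 0), "K": (6, 14, 2, 2, 0),
    "M": (5, 11, 1, 2, 1), "F": (9, 11, 1, 2, 0), "P": (5, 9, 1, 2, 0),
    "T": (4, 9, 1, 3, 0), "S": (3, 7, 1, 3, 0), "W": (11, 12, 2, 2, 0),
    "Y": (9, 11, 1, 3, 0), "V": (5, 11, 1, 2, 0),
}

WATER_MASS = 18.0153  # average mass of H2O, Da

# EMBOSS pKa set: positive groups (N-terminus, K, R, H) and negative groups
# (C-terminus, D, E, C, Y).
EMBOSS_PKA = {
    "Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5,
    "Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}

_IMPUTE_MAP = {"B": "N", "Z": "Q", "U": "C", "J": "L", "O": "K"}
_GAP_CHARS = "-*. "


@dataclass(frozen=True)
class ProteinRecord:
    """One identifier + amino-acid sequence; the atomic input unit."""

    id: str
    sequence: str


@dataclass(frozen=True)
class PtmMotifConfig:
    """Deterministic PTM motif stand-ins, configurable per schema.

    SUMO patterns are overlap-counting regexes; nitrosylation and
    nitrotyrosine count each C (resp. Y) whose +/-``window`` flank contains
    at least one acidic (A-class), basic (B-class) or hydrophobic (C-class)
    residue.
    """

    sumo_patterns: tuple[str, str, str] = (
        r"(?=[AILMVF]K.E)",   # SUMO I:  psi-K-x-E
        r"(?=[AILMVF]K.D)",   # SUMO II: psi-K-x-D
        r"(?=[ED].K[AILMVF])",  # SUMO III: inverted E/D-x-K-psi
    )
    window: int = 3
    acidic: str = "DE"
    basic: str = "KRH"
    hydrophobic: str = "AILMFVW"


@dataclass(frozen=True)
class CoiledCoilConfig:
    """Windowed heptad-hydrophobicity counter (stand-in for a predictor)."""

    window: int = 28
    hydrophobic: str = "AILMFVW"
    min_fraction: float = 0.75  # fraction of a/d positions that must be hydrophobic


@dataclass(frozen=True)
class FeatureSchema:
    """Everything that pins down the 46-feature encoding for reproducibility."""

    feature_names: tuple[str, ...] = FEATURE_NAMES
    pka_set: str = "EMBOSS"
    pka: dict = field(default_factory=lambda: dict(EMBOSS_PKA))
    positive_residues: str = "KR"  # His excluded at physiological pH
    negative_residues: str = "DE"
    ptm: PtmMotifConfig = field(default_factory=PtmMotifConfig)
    coiled_coil: CoiledCoilConfig = field(default_factory=CoiledCoilConfig)
    mass_table: str = "biopython-average"
    hydropathy_table: str = "Kyte-Doolittle"
    diwv_table: str = "Guruprasad-ProtParam"

    def schema_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


DEFAULT_SCHEMA = FeatureSchema()


def sanitize_sequence(
    raw: str, policy: Literal["strict", "drop", "impute"] = "strict"
) -> str:
    """Uppercase a raw sequence and resolve non-standard letters.

    strict  -> error on anything outside the 20 standard letters;
    drop    -> remove non-standard letters and gaps;
    impute  -> map B->N, Z->Q, U->C, J->L, O->K; drop X and gaps.
    """
    if not raw:
        raise ValueError("empty sequence")
    seq = raw.upper().replace("\n", "").replace("\r", "")
    seq = "".join(c for c in seq if c not in _GAP_CHARS or policy == "strict")
    out = []
    for c in seq:
        if c in _AA_SET:
            out.append(c)
        elif policy == "strict":
            raise ValueError(f"non-standard residue {c!r} under strict policy")
        elif policy == "impute" and c in _IMPUTE_MAP:
            out.append(_IMPUTE_MAP[c])
        # drop policy, or impute with X/unknown: skip
    cleaned = "".join(out)
    if not cleaned:
        raise ValueError("sequence empty after sanitization")
    return cleaned


def _check(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - _AA_SET
    if bad:
        raise ValueError(f"unsanitized residues {sorted(bad)}; call sanitize_sequence")
    return seq


def composition(seq: str) -> np.ndarray:
    """Fractions of the 20 standard residues, in table order; sums to 1."""
    seq = _check(seq)
    n = len(seq)
    return np.array([seq.count(aa) / n for aa in AMINO_ACIDS])


def charge_counts(seq: str, schema: FeatureSchema = DEFAULT_SCHEMA) -> tuple[int, int]:
    """(n_negative, n_positive): D+E and K+R counts (His excluded)."""
    seq = _check(seq)
    neg = sum(seq.count(aa) for aa in schema.negative_residues)
    pos = sum(seq.count(aa) for aa in schema.positive_residues)
    return neg, pos


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Da (residue masses plus one water)."""
    return float(_bio_mw(_check(seq), seq_type="protein"))


def atom_counts(seq: str) -> tuple[int, int, int, int, int]:
    """(C, H, N, O, S) atom counts: free-residue formulas minus (L-1) waters."""
    seq = _check(seq)
    totals = np.zeros(5, dtype=int)
    for c in seq:
        totals += _AA_FORMULA[c]
    totals[1] -= 2 * (len(seq) - 1)  # H
    totals[3] -= len(seq) - 1  # O
    return tuple(int(v) for v in totals)


def net_charge(seq: str, ph: float, schema: FeatureSchema = DEFAULT_SCHEMA) -> float:
    """Henderson-Hasselbalch net charge at a given pH under the schema pKa set."""
    seq = _check(seq)
    pka = schema.pka
    pos = 1.0 / (1.0 + 10.0 ** (ph - pka["Nterm"]))
    for aa in "KRH":
        pos += seq.count(aa) / (1.0 + 10.0 ** (ph - pka[aa]))
    neg = 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - ph))
    for aa in "DECY":
        neg += seq.count(aa) / (1.0 + 10.0 ** (pka[aa] - ph))
    return pos - neg


def theoretical_pi(
    seq: str, schema: FeatureSchema = DEFAULT_SCHEMA, tol: float = 1e-4
) -> float:
    """pH at which the modeled net charge is zero, by bisection on (0, 14).

    Net charge is strictly decreasing in pH, positive near pH 0 (free
    N-terminus) and negative near pH 14, so the root is unique.
    """
    seq = _check(seq)
    lo, hi = 0.0, 14.0
    if net_charge(seq, lo, schema) < 0 or net_charge(seq, hi, schema) > 0:
        raise ValueError("net-charge function does not bracket zero on (0, 14)")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(seq, mid, schema)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def instability_index(seq: str) -> float:
    """Guruprasad instability index: (10/L) * sum of DIWV over adjacent pairs."""
    seq = _check(seq)
    if len(seq) < 2:
        raise ValueError("instability index needs length >= 2")
    diwv = ProtParamData.DIWV
    total = sum(diwv[a][b] for a, b in zip(seq, seq[1:]))
    return 10.0 / len(seq) * total


def aliphatic_index(seq: str) -> float:
    """X_Ala + 2.9*X_Val + 3.9*(X_Ile + X_Leu), X in mole percent."""
    seq = _check(seq)
    n = len(seq)
    x = {aa: 100.0 * seq.count(aa) / n for aa in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def gravy(seq: str) -> float:
    """Grand average of hydropathy (mean Kyte-Doolittle value)."""
    seq = _check(seq)
    kd = ProtParamData.kd
    return sum(kd[c] for c in seq) / len(seq)


def _context_counts(seq: str, center: str, cfg: PtmMotifConfig) -> tuple[int, int, int]:
    a = b = c = 0
    w = cfg.window
    for i, res in enumerate(seq):
        if res != center:
            continue
        flank = seq[max(0, i - w) : i] + seq[i + 1 : i + 1 + w]
        if any(ch in cfg.acidic for ch in flank):
            a += 1
        if any(ch in cfg.basic for ch in flank):
            b += 1
        if any(ch in cfg.hydrophobic for ch in flank):
            c += 1
    return a, b, c


def ptm_motif_counts(
    seq: str, schema: FeatureSchema = DEFAULT_SCHEMA
) -> dict[str, int]:
    """The 12 PTM motif counts (overlap-counting, deterministic stand-ins)."""
    seq = _check(seq)
    cfg = schema.ptm
    na, nb, nc = _context_counts(seq, "C", cfg)
    ya, yb, yc = _context_counts(seq, "Y", cfg)
    s1, s2, s3 = (len(re.findall(p, seq)) for p in cfg.sumo_patterns)
    return {
        "nitrosylation_a": na, "nitrosylation_b": nb, "nitrosylation_c": nc,
        "nitrosylation_total": na + nb + nc,
        "nitrotyrosine_a": ya, "nitrotyrosine_b": yb, "nitrotyrosine_c": yc,
        "nitrotyrosine_total": ya + yb + yc,
        "sumoylation_1": s1, "sumoylation_2": s2, "sumoylation_3": s3,
        "sumoylation_total": s1 + s2 + s3,
    }


def coiled_coil_score(seq: str, schema: FeatureSchema = DEFAULT_SCHEMA) -> int:
    """Count of length-28 windows with a hydrophobic heptad a/d pattern.

    For each window the seven heptad phases are tried; the window counts if,
    in the best phase, at least ``min_fraction`` of the a/d positions carry a
    hydrophobic residue.  Sequences shorter than the window score 0.
    """
    seq = _check(seq)
    cfg = schema.coiled_coil
    w = cfg.window
    if len(seq) < w:
        return 0
    hyd = frozenset(cfg.hydrophobic)
    score = 0
    for start in range(len(seq) - w + 1):
        win = seq[start : start + w]
        best = 0.0
        for phase in range(7):
            ad = [win[i] for i in range(w) if (i - phase) % 7 in (0, 3)]
            frac = sum(c in hyd for c in ad) / len(ad)
            best = max(best, frac)
        if best >= cfg.min_fraction:
            score += 1
    return score


def extract_features(
    record: ProteinRecord | str, schema: FeatureSchema = DEFAULT_SCHEMA
) -> np.ndarray:
    """The ordered 46-value encoding of one sanitized sequence."""
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    seq = _check(seq)
    comp = composition(seq)
    ptm = ptm_motif_counts(seq, schema)
    neg, pos = charge_counts(seq, schema)
    atoms = atom_counts(seq)
    values = np.concatenate(
        [
            comp,
            [float(coiled_coil_score(seq, schema))],
            [float(ptm[k]) for k in FEATURE_NAMES[21:33]],
            [
                float(len(seq)), float(neg), float(pos),
                molecular_weight(seq), theoretical_pi(seq, schema),
            ],
            [float(v) for v in atoms],
            [instability_index(seq), aliphatic_index(seq), gravy(seq)],
        ]
    )
    assert values.shape == (46,)
    return values


def extract_feature_table(
    records: Iterable[ProteinRecord], schema: FeatureSchema = DEFAULT_SCHEMA
) -> pd.DataFrame:
    """Feature table indexed by record id, columns in schema order."""
    records = list(records)
    data = np.vstack([extract_features(r, schema) for r in records])
    return pd.DataFrame(
        data, index=pd.Index([r.id for r in records], name="id"),
        columns=list(schema.feature_names),
    )


def write_feature_table(df: pd.DataFrame, path, schema: FeatureSchema = DEFAULT_SCHEMA) -> None:
    """Write a CSV plus a JSON sidecar recording the schema hash."""
    df.to_csv(path)
    sidecar = str(path) + ".schema.json"
    with open(sidecar, "w") as fh:
        json.dump(
            {"schema_hash": schema.schema_hash(), "feature_names": list(schema.feature_names)},
            fh, indent=2,
        )


class ProteinFeaturizer(TransformerMixin, BaseEstimator):
    """sklearn transformer: protein sequences -> n x 46 feature matrix.

    Parameters
    ----------
    policy : {"strict", "drop", "impute"}
        Non-standard-residue policy applied before encoding.
    schema : FeatureSchema
        Encoding schema (motif sets, pKa table, heptad config).
    """

    def __init__(self, policy: str = "impute", schema: FeatureSchema = DEFAULT_SCHEMA):
        self.policy = policy
        self.schema = schema

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        self.schema_hash_ = self.schema.schema_hash()
        return self

    def transform(self, X: Sequence[ProteinRecord | str]) -> np.ndarray:
        if not hasattr(self, "schema_hash_"):
            self.fit(X)
        rows = []
        for item in X:
            seq = item.sequence if isinstance(item, ProteinRecord) else str(item)
            rows.append(extract_features(sanitize_sequence(seq, self.policy), self.schema))
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.schema.feature_names, dtype=object)
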