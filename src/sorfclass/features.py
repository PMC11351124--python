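"""Coding-potential feature extraction.

Two feature families are combined into the 100-dimension coding-potential
(CP) vector:

* **TIS** — the 9-nt translation-initiation-site context at positions
  -7..+5 relative to the start codon, with the start codon itself
  (occupying +1..+3) excluded: 7 nt of upstream flank plus the 2 nt at
  +4/+5.  Each position is one-hot encoded with the maximal-Hamming-
  distance code A=0001, C=0010, T=0100, G=1000, giving 36 binary values.

* **CC** (coding composition) — the in-frame 3-mer frequency profile of a
  fixed-length window (54, 99 or 180 nt) of the ORF body, extracted at
  step 3 so codon structure is preserved, giving 64 non-negative values.
  The window may optionally start after the first 90 nt of the body to
  avoid compositionally atypical signal-peptide regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core_io import Rejection, SorfRecord

AUTO = "auto"
CC_WINDOW_SIZES = (54, 99, 180)
SIGNAL_PEPTIDE_SKIP_NT = 90

# one-hot codes, bit order (G, T, C, A) within each 4-bit group so the
# code table G=1000, T=0100, C=0010, A=0001 reads off left to right
TIS_CODE = {
    "A": (0.0, 0.0, 0.0, 1.0),
    "C": (0.0, 0.0, 1.0, 0.0),
    "T": (0.0, 1.0, 0.0, 0.0),
    "G": (1.0, 0.0, 0.0, 0.0),
}
TIS_BIT_ORDER = ("G", "T", "C", "A")

_BASES = "ACGT"
CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)
_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

# byte -> base index lookup (A=0, C=1, G=2, T=3), 255 marks invalid
_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE_LUT[ord(_b)] = _i


class FeatureError(ValueError):
    """A record cannot yield the requested features."""


@dataclass(frozen=True)
class FeatureConfig:
    """Controls which features are extracted and how.

    feature_set:
        "tis" (36 dims), "cc" (64 dims) or "cp" (100 dims, TIS ++ CC).
    cc_window:
        54, 99, 180 or "auto" (longest window that fits the record).
    skip_signal_peptide:
        Skip the first 90 nt of the ORF body before the CC window.
        Defaults off, matching the predictor; training pipelines enable
        it explicitly.
    """

    feature_set: str = "cp"
    cc_window: Union[int, str] = AUTO
    skip_signal_peptide: bool = False
    tis_upstream: int = 7
    tis_downstream: int = 2
    frequency_normalized: bool = True

    def __post_init__(self):
        if self.feature_set not in ("tis", "cc", "cp"):
            raise ValueError(f"unknown feature_set {self.feature_set!r}")
        if self.cc_window != AUTO and self.cc_window not in CC_WINDOW_SIZES:
            raise ValueError(f"cc_window must be one of {CC_WINDOW_SIZES} or 'auto'")
        if self.tis_upstream + self.tis_downstream != 9:
            raise ValueError("TIS window must span 9 nt (upstream + downstream)")

    @property
    def n_features(self) -> int:
        return {"tis": 36, "cc": 64, "cp": 100}[self.feature_set]


@dataclass(frozen=True)
class FeatureVector:
    """TIS one-hot part (36), CC frequency part (64), plus the routing
    metadata (which CC window was used, whether the signal-peptide skip
    applied)."""

    tis: np.ndarray
    cc: np.ndarray
    window_used: int
    skip_used: bool

    @property
    def cp(self) -> np.ndarray:
        return np.concatenate([self.tis, self.cc])

    def values(self, feature_set: str = "cp") -> np.ndarray:
        if feature_set == "tis":
            return self.tis
        if feature_set == "cc":
            return self.cc
        return self.cp


def extract_tis_window(record: SorfRecord, upstream: int = 7, downstream: int = 2) -> str:
    """The 9-nt TIS context: positions -7..-1 and +4..+5.

    The start codon occupies positions +1..+3 and is excluded so the
    feature is insensitive to start-codon usage.
    """
    if len(record.flank) < upstream:
        raise FeatureError(
            f"{record.id}: insufficient upstream context "
            f"({len(record.flank)} < {upstream} nt)"
        )
    if len(record.orf) < 3 + downstream:
        raise FeatureError(f"{record.id}: orf too short for TIS context")
    return record.flank[-upstream:] + record.orf[3 : 3 + downstream]


def encode_tis(window9: str) -> np.ndarray:
    """One-hot encode the 9-nt TIS window into 36 binary values."""
    if len(window9) != 9:
        raise FeatureError(f"TIS window must be 9 nt, got {len(window9)}")
    out = np.empty(36, dtype=np.float64)
    for i, base in enumerate(window9):
        try:
            out[4 * i : 4 * i + 4] = TIS_CODE[base]
        except KeyError:
            raise FeatureError(f"invalid base {base!r} in TIS window") from None
    return out


def select_cc_window(
    record: SorfRecord, config: FeatureConfig
) -> tuple[int, int]:
    """Choose the CC window size and its offset into the ORF.

    The usable body excludes the start codon, the stop codon, and — when
    the signal-peptide skip is on — the first 90 nt after the start.  In
    auto mode the longest of 180/99/54 nt that fits is taken.
    """
    skip = SIGNAL_PEPTIDE_SKIP_NT if config.skip_signal_peptide else 0
    available = len(record.orf) - 3 - _stop_reserve(record.orf) - skip
    offset = 3 + skip
    if config.cc_window == AUTO:
        for size in sorted(CC_WINDOW_SIZES, reverse=True):
            if size <= available:
                return size, offset
        raise FeatureError(
            f"{record.id}: sORF too short for smallest CC window "
            f"({available} nt available, 54 required)"
        )
    size = int(config.cc_window)
    if size > available:
        raise FeatureError(
            f"{record.id}: sORF too short for {size}-nt CC window "
            f"({available} nt available)"
        )
    return size, offset


def _stop_reserve(orf: str) -> int:
    """Reserve the terminal stop codon when present; prediction-only
    records lacking a stop use the sequence through its end."""
    from .core_io import STOP_CODONS

    return 3 if orf[-3:] in STOP_CODONS else 0


def extract_cc_window(record: SorfRecord, window_size: int, offset: int) -> str:
    """In-frame ORF substring for CC profiling; never overlaps the stop."""
    if offset % 3 != 0:
        raise AssertionError(f"CC window offset {offset} violates reading frame")
    if offset + window_size > len(record.orf) - _stop_reserve(record.orf):
        raise AssertionError(
            f"CC window [{offset}, {offset + window_size}) overlaps the stop codon"
        )
    return record.orf[offset : offset + window_size]


def codon_frequencies(window: str, normalized: bool = True) -> np.ndarray:
    """64-element in-frame 3-mer profile of ``window``.

    3-mers are read non-overlapping at step 3 (codon structure) and
    ordered lexicographically AAA, AAC, ..., TTT.  With ``normalized``
    the counts are divided by the number of 3-mers.
    """
    if len(window) == 0:
        raise FeatureError("empty CC window")
    if len(window) % 3 != 0:
        raise FeatureError(f"CC window length {len(window)} not a multiple of 3")
    idx = _BASE_LUT[np.frombuffer(window.encode("ascii"), dtype=np.uint8)]
    if idx.max() == 255:
        raise FeatureError("invalid base in CC window")
    codons = 16 * idx[0::3] + 4 * idx[1::3] + idx[2::3]
    counts = np.bincount(codons, minlength=64).astype(np.float64)
    if normalized:
        counts /= len(window) // 3
    return counts


def assemble_features(record: SorfRecord, config: FeatureConfig) -> FeatureVector:
    """Build the full feature vector (TIS ++ CC) for one record.

    Pure function: identical inputs yield identical vectors.  Feature
    errors propagate with the record id attached.
    """
    try:
        window_size, offset = select_cc_window(record, config)
        cc = codon_frequencies(
            extract_cc_window(record, window_size, offset),
            normalized=config.frequency_normalized,
        )
        tis = encode_tis(
            extract_tis_window(record, config.tis_upstream, config.tis_downstream)
        )
    except FeatureError as exc:
        if record.id not in str(exc):
            raise FeatureError(f"{record.id}: {exc}") from exc
        raise
    return FeatureVector(
        tis=tis, cc=cc, window_used=window_size,
        skip_used=config.skip_signal_peptide,
    )


def feature_matrix(
    records: Sequence[SorfRecord], config: FeatureConfig
) -> tuple[np.ndarray, list[str], list[Rejection]]:
    """Feature matrix for a record set.

    Returns (X, ids, exclusions); records failing feature extraction are
    excluded from X and reported once each.
    """
    rows, ids, exclusions = [], [], []
    for rec in records:
        try:
            fv = assemble_features(rec, config)
        except FeatureError as exc:
            exclusions.append(Rejection(rec.id, str(exc)))
            continue
        rows.append(fv.values(config.feature_set))
        ids.append(rec.id)
    X = np.vstack(rows) if rows else np.empty((0, config.n_features))
    return X, ids, exclusions


def feature_column_names(feature_set: str = "cp") -> list[str]:
    """Stable column headers: tis_p-7_G ... tis_p+5_A, cc_AAA ... cc_TTT."""
    positions = [f"-{p}" for p in range(7, 0, -1)] + ["+4", "+5"]
    tis_cols = [f"tis_p{pos}_{b}" for pos in positions for b in TIS_BIT_ORDER]
    cc_cols = [f"cc_{c}" for c in CODONS]
    if feature_set == "tis":
        return tis_cols
    if feature_set == "cc":
        return cc_cols
    return tis_cols + cc_cols


def feature_table(
    records: Sequence[SorfRecord], config: FeatureConfig
) -> tuple[pd.DataFrame, list[Rejection]]:
    """Feature matrix as a DataFrame (id, window_used, feature columns)."""
    X, ids, exclusions = feature_matrix(records, config)
    by_id = {r.id: r for r in records}
    windows = [select_cc_window(by_id[i], config)[0] for i in ids]
    df = pd.DataFrame(X, columns=feature_column_names(config.feature_set))
    df.insert(0, "window_used", windows)
    df.insert(0, "id", ids)
    return df, exclusions
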