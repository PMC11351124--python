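"""Training/evaluation dataset construction from a genome + annotation.

Positives come from annotated coding sequences (single-isoform genes for
training; longest isoform per multi-isoform gene for the simulated
evaluation set).  Negatives are pseudo-ORFs sampled from intergenic
space: the complement of gene intervals with a promoter mask removed,
partitioned by region size into a training pool (20-50 kb regions) and a
simulated-evaluation pool (>50 kb regions) so the two never overlap.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from math import floor
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    GeneInterval,
    GenomeAnnotation,
    Rejection,
    SorfRecord,
    STOP_CODONS,
)

Interval = tuple[str, int, int]  # contig, start, end — 0-based half-open


@dataclass(frozen=True)
class NegativeSamplingConfig:
    promoter_mask: int = 2000
    training_size_class: tuple[int, int] = (20_000, 50_000)  # closed interval
    n_train: int = 8100
    target_mean_length: int = 210
    # bounds on pseudo-ORF length (nt, ATG through stop codon inclusive);
    # chosen so unconstrained extension over near-random sequence lands
    # near the 210-nt target mean
    length_bounds: tuple[int, int] = (60, 450)
    flank_length: int = 100
    seed: int = 0


@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(
    base: list[tuple[int, int]], cut: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    cut = _merge(cut)
    out: list[tuple[int, int]] = []
    for s, e in base:
        cur = s
        for cs, ce in cut:
            if ce <= cur or cs >= e:
                continue
            if cs > cur:
                out.append((cur, cs))
            cur = max(cur, ce)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def compute_intergenic_regions(
    annotation: GenomeAnnotation, promoter_mask: int = 2000
) -> list[Interval]:
    """Intergenic complement with strand-aware promoter masking.

    Per contig: complement the union of gene intervals, then remove the
    ``promoter_mask`` nt immediately upstream of each gene (upstream in
    gene orientation: before the start for + genes, after the end for -
    genes) so promoter-like functional sequence never enters the
    negative pools.  Returns maximal disjoint intervals.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {c: [] for c in annotation.sequences}
    masks: dict[str, list[tuple[int, int]]] = {c: [] for c in annotation.sequences}
    for g in annotation.genes:
        by_contig.setdefault(g.contig, []).append((g.start, g.end))
        m = masks.setdefault(g.contig, [])
        if g.strand == "+":
            m.append((max(0, g.start - promoter_mask), g.start))
        else:
            m.append((g.end, g.end + promoter_mask))
    out: list[Interval] = []
    for contig, seq in annotation.sequences.items():
        length = len(seq)
        genes = _merge(by_contig.get(contig, []))
        if not genes:
            warnings.warn(f"contig {contig} has no gene annotation")
        complement = _subtract([(0, length)], genes)
        clipped_masks = [
            (max(0, s), min(length, e)) for s, e in masks.get(contig, []) if s < length
        ]
        for s, e in _subtract(complement, clipped_masks):
            out.append((contig, s, e))
    return out


def partition_by_size(
    intergenic: Sequence[Interval],
    config: NegativeSamplingConfig = NegativeSamplingConfig(),
) -> dict[str, list[Interval]]:
    """Split intergenic intervals into the training pool ([20 kb, 50 kb],
    closed) and the simulated-evaluation pool (> 50 kb); disjoint by
    construction."""
    lo, hi = config.training_size_class
    training = [iv for iv in intergenic if lo <= iv[2] - iv[1] <= hi]
    simulated = [iv for iv in intergenic if iv[2] - iv[1] > hi]
    if not training and not simulated:
        warnings.warn("no intergenic interval reaches the training size class")
    return {"training_pool": training, "simulated_pool": simulated}


def _scan_pseudo_orfs(
    seq: str, lo: int, hi: int
) -> list[tuple[int, int]]:
    """All ATG-anchored in-frame ORFs within ``seq`` whose total length
    (ATG through stop, inclusive) lies in [lo, hi]."""
    found: list[tuple[int, int]] = []
    for m in re.finditer("ATG", seq):
        start = m.start()
        limit = min(len(seq), start + hi)
        for p in range(start + 3, limit - 2, 3):
            if seq[p : p + 3] in STOP_CODONS:
                end = p + 3
                if lo <= end - start <= hi:
                    found.append((start, end))
                break
    return found


def sample_negative_orfs(
    pool: Sequence[Interval],
    genome: dict[str, str],
    n: int,
    config: NegativeSamplingConfig = NegativeSamplingConfig(),
    seed: Optional[int] = None,
) -> tuple[list[SorfRecord], dict]:
    """Sample pseudo-ORFs from intergenic pool intervals.

    Scans the + strand of each pooled interval for ATG occurrences,
    extends each to the first in-frame stop codon, keeps candidates
    whose length falls inside ``config.length_bounds``, and samples
    ``n`` without replacement.  The flank is the genomic sequence
    immediately upstream of the ATG, truncated at the interval boundary.
    Returns (records, report) where the report carries the candidate
    count and achieved mean length.
    """
    if not pool:
        raise ValueError("empty interval pool")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.length_bounds
    candidates: list[tuple[str, int, int, int]] = []  # contig, iv_start, start, end
    for contig, iv_start, iv_end in pool:
        seq = genome[contig][iv_start:iv_end]
        for s, e in _scan_pseudo_orfs(seq, lo, hi):
            candidates.append((contig, iv_start, iv_start + s, iv_start + e))
    if len(candidates) < n:
        warnings.warn(
            f"only {len(candidates)} pseudo-ORF candidates for requested {n}"
        )
        chosen = list(range(len(candidates)))
    else:
        chosen = sorted(rng.choice(len(candidates), size=n, replace=False))
    records = []
    for i in chosen:
        contig, iv_start, s, e = candidates[i]
        flank_start = max(iv_start, s - config.flank_length)
        records.append(
            SorfRecord(
                id=f"neg_{contig}_{s}_{e}",
                flank=genome[contig][flank_start:s],
                orf=genome[contig][s:e],
                label="noncoding",
            )
        )
    lengths = [len(r.orf) for r in records]
    report = {
        "n_candidates": len(candidates),
        "n_sampled": len(records),
        "achieved_mean_length": float(np.mean(lengths)) if lengths else float("nan"),
    }
    return records, report


def build_positive_records(
    records: Sequence[SorfRecord],
    metadata: pd.DataFrame,
    ) -> tuple[dict[str, list[SorfRecord]], list[Rejection]]:
    """Partition coding records into training and simulated-evaluation sets.

    ``metadata`` maps record_id -> (gene_id, isoform_count, cds_length).
    Genes with exactly one isoform feed the training set (avoiding
    alternative-start ambiguity); for multi-isoform genes only the
    longest isoform enters the simulated set (ties broken by
    lexicographically smallest record id).  The two sets are disjoint by
    gene id.
    """
    required = {"record_id", "gene_id", "isoform_count", "cds_length"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing column(s): {', '.join(sorted(missing))}")
    meta = metadata.set_index("record_id")
    excluded: list[Rejection] = []
    training: list[SorfRecord] = []
    by_gene: dict[str, list[tuple[int, str, SorfRecord]]] = {}
    for rec in records:
        if rec.id not in meta.index:
            excluded.append(Rejection(rec.id, "no isoform metadata"))
            continue
        row = meta.loc[rec.id]
        rec = SorfRecord(rec.id, rec.flank, rec.orf, label="coding")
        if int(row["isoform_count"]) == 1:
            training.append(rec)
        else:
            by_gene.setdefault(str(row["gene_id"]), []).append(
                (int(row["cds_length"]), rec.id, rec)
            )
    simulated = [
        max(isoforms, key=lambda t: (t[0], _NegId(t[1])))[2]
        for gene, isoforms in sorted(by_gene.items())
    ]
    return {"training_records": training, "simulated_records": simulated}, excluded


class _NegId(str):
    """Orders ids descending inside max(): smallest id wins length ties."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def split_dataset(
    records: Sequence[SorfRecord], spec: SplitSpec = SplitSpec()
) -> dict[str, list[SorfRecord]]:
    """Stratified train/validation/test split.

    Validation and test sizes are floor-allocated per label; remainders
    go to the training split, so 16,200 balanced examples at 60/20/20
    give 9,720/3,240/3,240 with class ratio preserved.  Reproducible for
    a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    groups: dict[Optional[str], list[SorfRecord]] = {}
    if spec.stratified:
        for rec in records:
            groups.setdefault(rec.label, []).append(rec)
    else:
        groups[None] = list(records)
    splits: dict[str, list[SorfRecord]] = {"train": [], "validation": [], "test": []}
    for label in sorted(groups, key=str):
        members = groups[label]
        if len(members) < 3:
            raise ValueError(
                f"class {label!r} has {len(members)} member(s); "
                "cannot stratify into three splits"
            )
        order = rng.permutation(len(members))
        n_val = floor(len(members) * spec.ratios[1])
        n_test = floor(len(members) * spec.ratios[2])
        n_train = len(members) - n_val - n_test
        for k, idx in enumerate(order):
            if k < n_train:
                splits["train"].append(members[idx])
            elif k < n_train + n_val:
                splits["validation"].append(members[idx])
            else:
                splits["test"].append(members[idx])
    return splits


def split_manifest(splits: dict[str, list[SorfRecord]]) -> pd.DataFrame:
    """Tabular manifest of a split (id, label, split), deterministic order."""
    rows = [
        {"id": r.id, "label": r.label, "split": name}
        for name in ("train", "validation", "test")
        for r in splits[name]
    ]
    return pd.DataFrame(rows, columns=["id", "label", "split"])
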