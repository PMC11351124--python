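"""Synthetic sequence generation with a controllable coding signal.

Emulates the statistical contrast that separates coding from non-coding
ORFs: coding records carry biased (human-like) codon usage in the ORF
body and a Kozak-like consensus around the start codon, while
non-coding records are ATG-anchored stretches of compositionally
near-uniform background extended to the first in-frame stop codon.

``signal_strength`` mixes the coding model (codon-usage table and Kozak
profile alike) with the background: at 1 the two classes are strongly
separable, at 0 coding and non-coding records are drawn from feature
distributions that are exchangeable, so any downstream classifier can do
no better than chance.  Mini-genomes arrange background intergenic
stretches around planted genes for testing interval logic end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import GeneInterval, SorfRecord, STOP_CODONS
from .features import CODONS

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SENSE_CODONS = tuple(c for c in CODONS if c not in STOP_CODONS)
STOP_LIST = tuple(sorted(STOP_CODONS))

# Human-like codon usage (relative frequency per thousand codons) used as
# the default coding bias.  Synthetic default for simulation — an
# approximate, order-of-magnitude-faithful table, not measured data.
_HUMAN_LIKE_USAGE = {
    "TTT": 17.6, "TTC": 20.3, "TTA": 7.7, "TTG": 12.9,
    "CTT": 13.2, "CTC": 19.6, "CTA": 7.2, "CTG": 39.6,
    "ATT": 16.0, "ATC": 20.8, "ATA": 7.5, "ATG": 22.0,
    "GTT": 11.0, "GTC": 14.5, "GTA": 7.1, "GTG": 28.1,
    "TCT": 15.2, "TCC": 17.7, "TCA": 12.2, "TCG": 4.4,
    "CCT": 17.5, "CCC": 19.8, "CCA": 16.9, "CCG": 6.9,
    "ACT": 13.1, "ACC": 18.9, "ACA": 15.1, "ACG": 6.1,
    "GCT": 18.4, "GCC": 27.7, "GCA": 15.8, "GCG": 7.4,
    "TAT": 12.2, "TAC": 15.3,
    "CAT": 10.9, "CAC": 15.1, "CAA": 12.3, "CAG": 34.2,
    "AAT": 17.0, "AAC": 19.1, "AAA": 24.4, "AAG": 31.9,
    "GAT": 21.8, "GAC": 25.1, "GAA": 29.0, "GAG": 39.6,
    "TGT": 10.6, "TGC": 12.6, "TGG": 13.2,
    "CGT": 4.5, "CGC": 10.4, "CGA": 6.2, "CGG": 11.4,
    "AGT": 12.1, "AGC": 19.5, "AGA": 12.2, "AGG": 12.0,
    "GGT": 10.8, "GGC": 22.2, "GGA": 16.5, "GGG": 16.5,
}


def human_like_codon_usage() -> np.ndarray:
    """Default 61-element codon-usage probability vector (sense codons in
    lexicographic order)."""
    p = np.array([_HUMAN_LIKE_USAGE[c] for c in SENSE_CODONS], dtype=np.float64)
    return p / p.sum()


def default_kozak_profile(consensus_weight: float = 0.6) -> np.ndarray:
    """Position-specific base distributions for the 9 TIS positions
    (-7..-1, +4, +5), concentrating the canonical Kozak consensus
    gccGCCACC|atg|GC: purine at -3, G at +4."""
    consensus = "GGCCACCGC"  # -7 -6 -5 -4 -3 -2 -1 +4 +5
    profile = np.full((9, 4), (1.0 - consensus_weight) / 3.0)
    for i, base in enumerate(consensus):
        profile[i, BASES.index(base)] = consensus_weight
    return profile


class GenerationError(RuntimeError):
    """The configured distributions cannot produce a valid record."""


@dataclass
class SyntheticConfig:
    """Generation parameters; probability vectors must each sum to 1.

    length_range_aa is the peptide length (codons including the initial
    Met, excluding the stop codon).  The default 61-99 aa keeps every
    record long enough for the largest (180 nt) composition window while
    staying under the 100-aa sORF bound.
    """

    codon_usage: np.ndarray = field(default_factory=human_like_codon_usage)
    kozak_profile: np.ndarray = field(default_factory=default_kozak_profile)
    background_composition: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    signal_strength: float = 1.0
    n_pos: int = 1000
    n_neg: int = 1000
    length_range_aa: tuple[int, int] = (61, 99)
    flank_length: int = 100
    seed: int = 0

    def __post_init__(self):
        self.codon_usage = np.asarray(self.codon_usage, dtype=np.float64)
        self.kozak_profile = np.asarray(self.kozak_profile, dtype=np.float64)
        self.background_composition = np.asarray(
            self.background_composition, dtype=np.float64
        )
        if self.codon_usage.shape != (len(SENSE_CODONS),):
            raise ValueError("codon_usage must have 61 elements (sense codons)")
        if self.kozak_profile.shape != (9, 4):
            raise ValueError("kozak_profile must be 9 position distributions")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in [0, 1]")
        for name, vec in [
            ("codon_usage", self.codon_usage),
            ("background_composition", self.background_composition),
            *[(f"kozak_profile[{i}]", row) for i, row in enumerate(self.kozak_profile)],
        ]:
            if abs(vec.sum() - 1.0) > 1e-9 or (vec < 0).any():
                raise ValueError(f"{name} is not a probability vector")


def _draw(rng: np.random.Generator, cum: np.ndarray, size) -> np.ndarray:
    """Sample category indices from a precomputed cumulative distribution."""
    return np.searchsorted(cum, rng.random(size), side="right")


def _background_codon_probs(background: np.ndarray) -> np.ndarray:
    """64-codon distribution implied by i.i.d. background base draws."""
    p = np.empty(64)
    for i, codon in enumerate(CODONS):
        p[i] = np.prod([background[BASES.index(b)] for b in codon])
    return p


def _bases_from_idx(idx: np.ndarray) -> str:
    return "".join(BASES[i] for i in idx)


def _mixture_sense_cum(config: SyntheticConfig) -> np.ndarray:
    s = config.signal_strength
    uniform = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    return np.cumsum(s * config.codon_usage + (1.0 - s) * uniform)


def _effective_kozak(config: SyntheticConfig) -> np.ndarray:
    """Kozak profile attenuated toward background by signal_strength."""
    s = config.signal_strength
    return s * config.kozak_profile + (1.0 - s) * config.background_composition


def generate_coding_record(
    config: SyntheticConfig, rng: np.random.Generator, index: int = 0
) -> SorfRecord:
    """One labeled coding record.

    Flank is background except its last 7 nt; those, and the 2 nt at
    +4/+5 (the first two bases of the first body codon), follow the
    Kozak profile.  Body codons are i.i.d. from the signal-strength
    mixture of the codon-usage table with the uniform sense-codon
    distribution; the terminal stop codon is uniform over the three.
    """
    bg_cum = np.cumsum(config.background_composition)
    kozak = _effective_kozak(config)
    sense_cum = _mixture_sense_cum(config)

    aa = int(rng.integers(config.length_range_aa[0], config.length_range_aa[1] + 1))
    flank_bg = _bases_from_idx(_draw(rng, bg_cum, config.flank_length - 7))
    flank_tis = "".join(
        BASES[_draw(rng, np.cumsum(kozak[i]), 1)[0]] for i in range(7)
    )
    post_atg = "".join(
        BASES[_draw(rng, np.cumsum(kozak[i]), 1)[0]] for i in (7, 8)
    )
    body_codons = [SENSE_CODONS[i] for i in _draw(rng, sense_cum, aa - 1)]
    if body_codons:
        # first body codon: bases +4/+5 come from the Kozak profile, its
        # third base from the codon mixture conditioned on that prefix
        # (stop completions excluded)
        mixture = np.zeros(4)
        for bi, b in enumerate(BASES):
            codon = post_atg + b
            if codon in STOP_CODONS:
                continue
            j = SENSE_CODONS.index(codon)
            mixture[bi] = sense_cum[j] - (sense_cum[j - 1] if j else 0.0)
        if mixture.sum() <= 0:
            mixture = np.array(
                [0.0 if post_atg + b in STOP_CODONS else 1.0 for b in BASES]
            )
        mixture /= mixture.sum()
        third = BASES[_draw(rng, np.cumsum(mixture), 1)[0]]
        body_codons[0] = post_atg + third
    stop = STOP_LIST[int(rng.integers(3))]
    return SorfRecord(
        id=f"pos_{index}",
        flank=flank_bg + flank_tis,
        orf="ATG" + "".join(body_codons) + stop,
        label="coding",
    )


def generate_noncoding_record(
    config: SyntheticConfig,
    rng: np.random.Generator,
    index: int = 0,
    max_batches: int = 10_000,
) -> SorfRecord:
    """One labeled non-coding record: ATG-anchored background sequence
    extended to the first in-frame stop codon, resampled until the
    peptide length lands inside length_range_aa.  Flank is pure
    background."""
    p64 = _background_codon_probs(config.background_composition)
    stop_idx = np.array([CODONS.index(s) for s in STOP_LIST])
    if p64[stop_idx].sum() <= 0.0:
        raise GenerationError("background composition admits no stop codon")
    cum64 = np.cumsum(p64)
    bg_cum = np.cumsum(config.background_composition)
    min_body, max_body = (a - 1 for a in config.length_range_aa)

    batch = 16
    for _ in range(max_batches):
        draws = _draw(rng, cum64, (batch, max_body + 1))
        is_stop = np.isin(draws, stop_idx)
        has_stop = is_stop.any(axis=1)
        first_stop = np.where(has_stop, is_stop.argmax(axis=1), -1)
        ok = has_stop & (first_stop >= min_body) & (first_stop <= max_body)
        hits = np.flatnonzero(ok)
        if hits.size:
            row = hits[0]
            k = first_stop[row]
            body = "".join(CODONS[c] for c in draws[row, :k])
            stop = CODONS[draws[row, k]]
            flank = _bases_from_idx(_draw(rng, bg_cum, config.flank_length))
            return SorfRecord(
                id=f"neg_{index}", flank=flank, orf="ATG" + body + stop,
                label="noncoding",
            )
    raise GenerationError(
        "could not draw a non-coding record in the length range "
        f"{config.length_range_aa} after {max_batches} batches"
    )


def generate_dataset(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[SorfRecord], list[SorfRecord]]:
    """Generate (coding, noncoding) record lists under one RNG stream."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pos = [generate_coding_record(config, rng, i) for i in range(config.n_pos)]
    neg = [generate_noncoding_record(config, rng, i) for i in range(config.n_neg)]
    return pos, neg


def _reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_minigenome(
    config: SyntheticConfig,
    n_genes: int,
    intergenic_lengths: Sequence[int],
    rng: Optional[np.random.Generator] = None,
    contig: str = "chr1",
    gene_length_range_aa: Optional[tuple[int, int]] = None,
) -> tuple[dict[str, str], list[GeneInterval], pd.DataFrame]:
    """Build a single-contig mini-genome of alternating background
    intergenic stretches and planted coding genes.

    ``intergenic_lengths`` supplies the stretch before each gene (plus an
    optional trailing stretch); gene strands alternate +/-.  Returns the
    sequence, the gene intervals, and a truth manifest of every planted
    feature for assertion in tests.
    """
    if len(intergenic_lengths) not in (n_genes, n_genes + 1):
        raise ValueError(
            "need one intergenic stretch per gene (plus optional trailing one)"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    bg_cum = np.cumsum(config.background_composition)
    if gene_length_range_aa is not None:
        import dataclasses

        config = dataclasses.replace(config, length_range_aa=gene_length_range_aa)

    parts: list[str] = []
    genes: list[GeneInterval] = []
    manifest_rows = []
    pos = 0
    for i in range(n_genes):
        stretch = _bases_from_idx(_draw(rng, bg_cum, int(intergenic_lengths[i])))
        manifest_rows.append(
            {"kind": "intergenic", "contig": contig, "start": pos,
             "end": pos + len(stretch), "strand": ".", "length": len(stretch)}
        )
        parts.append(stretch)
        pos += len(stretch)
        orf = generate_coding_record(config, rng, i).orf
        strand = "+" if i % 2 == 0 else "-"
        embedded = orf if strand == "+" else _reverse_complement(orf)
        genes.append(GeneInterval(contig, pos, pos + len(embedded), strand))
        manifest_rows.append(
            {"kind": "gene", "contig": contig, "start": pos,
             "end": pos + len(embedded), "strand": strand, "length": len(embedded)}
        )
        parts.append(embedded)
        pos += len(embedded)
    if len(intergenic_lengths) == n_genes + 1 or n_genes == 0:
        tail = int(intergenic_lengths[-1]) if intergenic_lengths else 0
        if tail:
            stretch = _bases_from_idx(_draw(rng, bg_cum, tail))
            manifest_rows.append(
                {"kind": "intergenic", "contig": contig, "start": pos,
                 "end": pos + tail, "strand": ".", "length": tail}
            )
            parts.append(stretch)
            pos += tail
    manifest = pd.DataFrame(
        manifest_rows, columns=["kind", "contig", "start", "end", "strand", "length"]
    )
    return {contig: "".join(parts)}, genes, manifest
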