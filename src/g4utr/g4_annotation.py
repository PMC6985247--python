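"""Canonical G-quadruplex (pG4) discovery and isoform-level classification.

A canonical pG4 is four runs of three or more guanines (G-tracts) separated by
three loops ("gaps") of 1-7 arbitrary nucleotides::

    GGG-N(1-7)-GGG-N(1-7)-GGG-N(1-7)-GGG

The scanner works on sense-strand UTR sequences. Because a text pattern of
this shape is ambiguous where G-runs are longer than three or candidate
matches overlap, the scanner commits to a single documented policy: G-runs are
always maximal, and matches are reported greedily left-to-right without
overlap (a reported motif consumes its four runs; the search resumes at the
next run). ``N`` never counts as a guanine and simply breaks runs.

Genomic projection maps motif offsets through the (possibly spliced) UTR block
structure of a transcript; on the minus strand transcript offset 0 maps to the
highest genomic coordinate. Motifs whose genomic footprint intersects any
annotated coding block are flagged and excluded from downstream gene-level
analyses.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .intervals import GenomeIntervals, Interval

logger = logging.getLogger(__name__)

_VALID_ALPHABET = frozenset("ACGTN")
_G_RUN = re.compile(r"G{3,}")

UTR_SIDES = ("5p", "3p")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GTract:
    """A maximal run of guanines inside a pG4 motif (offsets in UTR coords).

    Trinucleotide tracts carry positional labels mapping the 5' guanine, the
    central guanine and the 3' guanine to their sequence offsets; longer
    tracts are positionally ambiguous and carry none.
    """

    start: int
    end: int
    positional_labels: dict[str, int] | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self):
        if self.length < 3:
            raise ValueError("G-tract must span at least 3 guanines")
        if self.length == 3 and self.positional_labels is None:
            self.positional_labels = {
                "5'G": self.start,
                "central": self.start + 1,
                "3'G": self.start + 2,
            }
        if self.length != 3:
            self.positional_labels = None


@dataclass
class G4Motif:
    """One canonical pG4 occurrence within a UTR sequence."""

    start: int
    end: int
    sequence: str
    tracts: list[GTract]
    gaps: list[Interval]
    transcript_id: str = ""
    utr_side: str = ""
    genomic_blocks: list[Interval] = field(default_factory=list)
    rg4_supported: bool = False
    cds_overlap: bool = False

    @property
    def n_tracts(self) -> int:
        return len(self.tracts)

    def validate(self) -> None:
        if self.n_tracts < 4:
            raise ValueError("pG4 requires >=4 G-tracts")
        for g0, g1 in self.gaps:
            if not 1 <= g1 - g0 <= 7:
                raise ValueError("gap length outside [1, 7]")
        off = self.start
        pieces = sorted(
            [(t.start, t.end, True) for t in self.tracts]
            + [(s, e, False) for s, e in self.gaps]
        )
        for s, e, is_tract in pieces:
            if s != off:
                raise ValueError("tracts and gaps do not tile the motif")
            if is_tract and set(self.sequence[s - self.start : e - self.start]) != {"G"}:
                raise ValueError("tract contains a non-G base")
            off = e
        if off != self.end:
            raise ValueError("tracts and gaps do not tile the motif")


@dataclass
class TranscriptModel:
    """One protein-coding transcript with UTR/CDS block structure.

    Blocks are genomic, 0-based half-open, sorted and non-overlapping within
    each list; UTR sequences are given in transcript (sense) orientation.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    utr5_blocks: list[Interval] = field(default_factory=list)
    utr3_blocks: list[Interval] = field(default_factory=list)
    cds_blocks: list[Interval] = field(default_factory=list)
    utr5_seq: str = ""
    utr3_seq: str = ""
    loeuf: float | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for name in ("utr5", "utr3"):
            blocks = getattr(self, f"{name}_blocks")
            seq = getattr(self, f"{name}_seq")
            prev_end = None
            for s, e in blocks:
                if e <= s:
                    raise ValueError("empty block")
                if prev_end is not None and s < prev_end:
                    raise ValueError("blocks overlap or are unsorted")
                prev_end = e
            if blocks and sum(e - s for s, e in blocks) != len(seq):
                raise ValueError(f"{name} sequence length != total block length")
            if set(seq.upper()) - _VALID_ALPHABET:
                raise ValueError(f"{name} sequence has non-ACGTN characters")

    def utr_blocks(self, side: str) -> list[Interval]:
        return self.utr5_blocks if side == "5p" else self.utr3_blocks

    def utr_seq(self, side: str) -> str:
        return self.utr5_seq if side == "5p" else self.utr3_seq


@dataclass
class IsoformClassification:
    """Gene-level pG4 inclusion status on one UTR side."""

    gene_id: str
    utr_side: str
    status: str  # constitutive | alternative | non_pg4
    n_pg4_isoforms: int
    n_total_isoforms: int
    identical_pg4: bool


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------


def _maximal_g_runs(seq: str) -> list[Interval]:
    return [(m.start(), m.end()) for m in _G_RUN.finditer(seq)]


def scan_pg4(seq: str, transcript_id: str = "", utr_side: str = "") -> list[G4Motif]:
    """Scan a sense-strand UTR sequence for canonical pG4 motifs.

    Returns leftmost non-overlapping motifs built from consecutive maximal
    G-runs with every inter-run gap of length 1-7 (see module docstring for
    the disambiguation policy). Coordinates are relative to ``seq``.
    """
    if seq == "":
        return []
    s = seq.upper()
    bad = set(s) - _VALID_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    runs = _maximal_g_runs(s)
    motifs: list[G4Motif] = []
    i = 0
    while i + 3 < len(runs):
        gaps_ok = all(
            1 <= runs[j + 1][0] - runs[j][1] <= 7 for j in range(i, i + 3)
        )
        if gaps_ok:
            start, end = runs[i][0], runs[i + 3][1]
            m = G4Motif(
                start=start,
                end=end,
                sequence=s[start:end],
                tracts=[],
                gaps=[],
                transcript_id=transcript_id,
                utr_side=utr_side,
            )
            m.tracts, m.gaps = partition_tracts(m)
            m.validate()
            motifs.append(m)
            i += 4
        else:
            i += 1
    return motifs


def partition_tracts(m: G4Motif) -> tuple[list[GTract], list[Interval]]:
    """Partition a motif into maximal G-tracts and the intervening gaps.

    Trinucleotide tracts get 5'G/central/3'G positional labels; the tract and
    gap intervals tile ``[m.start, m.end)`` exactly.
    """
    runs = _maximal_g_runs(m.sequence)
    tracts = [GTract(m.start + s, m.start + e) for s, e in runs]
    gaps = [
        (tracts[k].end, tracts[k + 1].start) for k in range(len(tracts) - 1)
    ]
    return tracts, gaps


# ---------------------------------------------------------------------------
# genomic projection
# ---------------------------------------------------------------------------


def transcript_offsets_to_genome(
    offsets: tuple[int, int], blocks: Sequence[Interval], strand: str
) -> list[Interval]:
    """Map a half-open transcript-offset interval through spliced blocks.

    Blocks are genomic and sorted ascending; on the minus strand transcript
    offset 0 corresponds to the last block's highest coordinate.
    """
    a, b = offsets
    total = sum(e - s for s, e in blocks)
    if not 0 <= a < b <= total:
        raise ValueError(f"offset interval [{a},{b}) outside transcript [0,{total})")
    ordered = list(blocks) if strand == "+" else list(reversed(blocks))
    out: list[Interval] = []
    cum = 0
    for s, e in ordered:
        length = e - s
        lo, hi = max(a, cum), min(b, cum + length)
        if lo < hi:
            if strand == "+":
                out.append((s + (lo - cum), s + (hi - cum)))
            else:
                out.append((e - (hi - cum), e - (lo - cum)))
        cum += length
    return sorted(out)


def project_to_genome(
    m: G4Motif, t: TranscriptModel, cds: GenomeIntervals | None = None
) -> G4Motif:
    """Fill a motif's genomic blocks and CDS-overlap flag in place.

    ``cds`` is the union of coding blocks of the whole annotation set (all
    transcripts genome-wide); a motif overlapping any coding block is flagged
    and excluded from downstream gene/variant analyses.
    """
    blocks = t.utr_blocks(m.utr_side)
    m.genomic_blocks = transcript_offsets_to_genome((m.start, m.end), blocks, t.strand)
    if sum(e - s for s, e in m.genomic_blocks) != m.end - m.start:
        raise ValueError("projected blocks do not cover the motif")
    m.cds_overlap = bool(cds) and any(
        cds.overlaps(t.chrom, s, e) for s, e in m.genomic_blocks
    )
    return m


def scan_transcripts(
    transcripts: Iterable[TranscriptModel],
    cds: GenomeIntervals | None = None,
    rg4: GenomeIntervals | None = None,
) -> list[G4Motif]:
    """Scan every UTR of every transcript and project motifs to the genome.

    If ``cds`` is omitted it is built from the transcripts' own CDS blocks.
    ``rg4`` intervals (experimental rG4-seq support) set ``rg4_supported`` on
    any motif whose genomic footprint they intersect.
    """
    transcripts = list(transcripts)
    if cds is None:
        cds = GenomeIntervals(
            (t.chrom, s, e) for t in transcripts for s, e in t.cds_blocks
        )
    motifs: list[G4Motif] = []
    for t in transcripts:
        for side in UTR_SIDES:
            for m in scan_pg4(t.utr_seq(side), t.transcript_id, side):
                project_to_genome(m, t, cds)
                if rg4 is not None:
                    m.rg4_supported = any(
                        rg4.overlaps(t.chrom, s, e) for s, e in m.genomic_blocks
                    )
                motifs.append(m)
    return motifs


# ---------------------------------------------------------------------------
# gene-level classification
# ---------------------------------------------------------------------------


def classify_isoforms(
    transcripts: Sequence[TranscriptModel],
    motifs: Sequence[G4Motif],
    utr_side: str,
) -> IsoformClassification:
    """Classify one gene's pG4 inclusion on one UTR side.

    Constitutive: every protein-coding isoform carries >=1 non-CDS-overlapping
    motif on that side. Alternative: >=1 isoform carries one and >=1 lacks
    one. ``identical_pg4`` is true when all pG4-bearing isoforms carry the
    same set of genomic motif blocks.
    """
    if not transcripts:
        raise ValueError("gene has no isoforms")
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) != 1:
        raise ValueError(f"transcripts from multiple genes: {sorted(gene_ids)}")
    by_tx: dict[str, set[frozenset[Interval]]] = {t.transcript_id: set() for t in transcripts}
    for m in motifs:
        if m.utr_side == utr_side and not m.cds_overlap and m.transcript_id in by_tx:
            by_tx[m.transcript_id].add(frozenset(m.genomic_blocks))
    carrier_sets = [blocks for blocks in by_tx.values() if blocks]
    n_pg4 = len(carrier_sets)
    n_total = len(transcripts)
    if n_pg4 == 0:
        status = "non_pg4"
    elif n_pg4 == n_total:
        status = "constitutive"
    else:
        status = "alternative"
    identical = n_pg4 > 0 and all(s == carrier_sets[0] for s in carrier_sets)
    return IsoformClassification(
        gene_id=gene_ids.pop(),
        utr_side=utr_side,
        status=status,
        n_pg4_isoforms=n_pg4,
        n_total_isoforms=n_total,
        identical_pg4=identical,
    )


def classify_expression(
    transcripts: Sequence[TranscriptModel],
    pg4_transcript_ids: set[str],
    tpm: pd.DataFrame,
    threshold: float = 1.0,
) -> dict[str, str]:
    """Per-tissue expression label for a gene with alternative pG4 isoforms.

    ``tpm`` is indexed by transcript id with one column per tissue holding
    median TPM. Per tissue the highest-expressed pG4 isoform and the
    highest-expressed non-pG4 isoform are compared to a strict ``> threshold``
    rule (default 1 TPM); the label records which side(s) are expressed.
    """
    ids = [t.transcript_id for t in transcripts]
    missing = [i for i in ids if i not in tpm.index]
    if missing:
        raise KeyError(f"transcripts missing from TPM matrix: {missing}")
    pg4_ids = [i for i in ids if i in pg4_transcript_ids]
    non_ids = [i for i in ids if i not in pg4_transcript_ids]
    labels: dict[str, str] = {}
    for tissue in tpm.columns:
        pg4_max = tpm.loc[pg4_ids, tissue].max() if pg4_ids else -np.inf
        non_max = tpm.loc[non_ids, tissue].max() if non_ids else -np.inf
        pg4_on = pg4_max > threshold
        non_on = non_max > threshold
        if pg4_on and non_on:
            labels[tissue] = "both_expressed"
        elif pg4_on:
            labels[tissue] = "pg4_only"
        elif non_on:
            labels[tissue] = "non_pg4_only"
        else:
            labels[tissue] = "neither"
    return labels


def position_classes(t: TranscriptModel, motifs: Sequence[G4Motif], utr_side: str) -> pd.DataFrame:
    """Per-position variant-class labels for one UTR of one transcript.

    Labels every UTR offset as ``central_g`` / ``flank_g`` (5' or 3' guanine)
    for trinucleotide G-tracts, ``long_tract`` for guanines of tracts longer
    than three (positionally ambiguous, excluded from positional analyses),
    ``gap`` for loop positions, and ``background`` otherwise. Offsets without
    a full trinucleotide context (UTR ends) are dropped. Returns columns
    offset, class_label, tri_context, ref.
    """
    seq = t.utr_seq(utr_side).upper()
    labels = np.full(len(seq), "background", dtype=object)
    for m in motifs:
        if m.utr_side != utr_side or m.transcript_id != t.transcript_id or m.cds_overlap:
            continue
        for s, e in m.gaps:
            labels[s:e] = "gap"
        for tr in m.tracts:
            if tr.length == 3:
                labels[tr.start] = "flank_g"
                labels[tr.start + 1] = "central_g"
                labels[tr.start + 2] = "flank_g"
            else:
                labels[tr.start : tr.end] = "long_tract"
    rows = [
        {
            "transcript_id": t.transcript_id,
            "utr_side": utr_side,
            "offset": i,
            "class_label": labels[i],
            "tri_context": seq[i - 1 : i + 2],
            "ref": seq[i],
        }
        for i in range(1, len(seq) - 1)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# isoform-label permutation test
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    observed_ratio: float
    p_value: float
    n_iter: int
    null_ratios: np.ndarray


def _alt_const_ratio(k: np.ndarray, n: np.ndarray) -> float:
    """Alternative:constitutive gene ratio for per-gene pG4 counts ``k``."""
    n_const = int(np.sum(k == n))
    n_alt = int(np.sum((k >= 1) & (k < n)))
    if n_const == 0:
        return np.inf if n_alt > 0 else 0.0
    return n_alt / n_const


def _suffix_polynomials(n: np.ndarray, k_total: int) -> list[np.ndarray]:
    """Suffix products of (1+x)^{n_g} - 1, truncated at degree ``k_total``.

    ``S[g][m]`` is proportional to the number of ways of choosing ``m``
    pG4-labelled transcripts from genes ``g..G-1`` with every gene getting at
    least one; each suffix polynomial is max-normalized (only within-suffix
    ratios are ever used).
    """
    G = len(n)
    S = [np.zeros(k_total + 1) for _ in range(G + 1)]
    S[G][0] = 1.0
    for g in range(G - 1, -1, -1):
        j = np.arange(1, n[g] + 1)
        coef = np.exp(
            gammaln(n[g] + 1) - gammaln(j + 1) - gammaln(n[g] - j + 1)
        )  # C(n_g, j), j = 1..n_g
        poly = np.zeros(k_total + 1)
        for jj, c in zip(j, coef):
            if jj <= k_total:
                poly[jj:] += c * S[g + 1][: k_total + 1 - jj]
        m = poly.max()
        if m == 0:
            raise ValueError("pG4 transcript total infeasible for gene set")
        S[g] = poly / m
    return S


def sample_pg4_label_counts(
    n: np.ndarray, k_total: int, n_iter: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-gene pG4-isoform counts under the permutation null.

    Samples uniformly over all assignments of ``k_total`` pG4 labels to the
    pooled transcripts that give every gene at least one pG4 isoform, using an
    exact sequential scheme: gene ``g`` receives ``j`` labels with probability
    proportional to C(n_g, j) times the number of valid completions of the
    remaining genes (read off suffix generating polynomials). Returns an
    ``(n_iter, G)`` integer array.
    """
    n = np.asarray(n, dtype=np.int64)
    G = len(n)
    if not G:
        raise ValueError("no genes")
    if not G <= k_total <= int(n.sum()):
        raise ValueError("pG4 transcript total outside feasible range")
    S = _suffix_polynomials(n, k_total)
    counts = np.zeros((n_iter, G), dtype=np.int64)
    remaining = np.full(n_iter, k_total, dtype=np.int64)
    for g in range(G):
        j = np.arange(1, n[g] + 1)
        binom = np.exp(gammaln(n[g] + 1) - gammaln(j + 1) - gammaln(n[g] - j + 1))
        idx = remaining[:, None] - j[None, :]  # (n_iter, n_g)
        valid = idx >= 0
        idx_c = np.clip(idx, 0, k_total)
        w = binom[None, :] * S[g + 1][idx_c] * valid
        tot = w.sum(axis=1, keepdims=True)
        if np.any(tot == 0):
            raise RuntimeError("sampler reached an infeasible state")
        cdf = np.cumsum(w, axis=1) / tot
        u = rng.random((n_iter, 1))
        pick = (u > cdf).sum(axis=1)  # index into j
        counts[:, g] = j[pick]
        remaining -= counts[:, g]
    assert np.all(remaining == 0)
    return counts


def permute_isoform_labels(
    genes: Mapping[str, tuple[int, int]] | Sequence[tuple[int, int]],
    n_iter: int,
    seed: int,
) -> PermutationResult:
    """Permutation test for the observed alternative:constitutive gene ratio.

    ``genes`` maps gene id (or just lists) ``(n_total_isoforms,
    n_pg4_isoforms)`` per gene. Genes with zero pG4 isoforms are excluded
    with a warning (the null conditions on >=1 pG4 isoform per gene). The
    p-value is ``(1 + #{null ratio >= observed}) / (n_iter + 1)``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    pairs = list(genes.values()) if isinstance(genes, Mapping) else list(genes)
    kept = [(nt, npq) for nt, npq in pairs if npq >= 1]
    dropped = len(pairs) - len(kept)
    if dropped:
        logger.warning("excluding %d genes with zero pG4 transcripts", dropped)
    if not kept:
        raise ValueError("no genes with >=1 pG4 transcript")
    n = np.array([nt for nt, _ in kept], dtype=np.int64)
    k = np.array([npq for _, npq in kept], dtype=np.int64)
    if np.any(k > n):
        raise ValueError("gene with more pG4 isoforms than isoforms")
    observed = _alt_const_ratio(k, n)
    rng = np.random.default_rng(seed)
    null_counts = sample_pg4_label_counts(n, int(k.sum()), n_iter, rng)
    null_ratios = np.array(
        [_alt_const_ratio(null_counts[i], n) for i in range(n_iter)]
    )
    p = (1 + int(np.sum(null_ratios >= observed))) / (n_iter + 1)
    return PermutationResult(observed, p, n_iter, null_ratios)
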