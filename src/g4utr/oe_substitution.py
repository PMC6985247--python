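"""Observed vs expected polymorphic sites under a heptamer substitution model.

A local-context neutral model assigns each genomic position a probability of
being polymorphic from its 7-mer reference context (the sum of the three
per-alternative posterior substitution probabilities). For a region class the
expected number of polymorphic sites is the sum of these cumulative
probabilities; depletion of the observed/expected ratio below 1 indicates
purifying selection. Because the model carries no methylation adjustment,
every position inside a CpG dinucleotide (the C or the G, either strand) is
masked out of both observed and expected counts.

Confidence intervals come from bootstrap resampling of positions with
replacement; significance against a background comes from comparing the
target's bootstrap ratio distribution with that of windows drawn from
constraint-matched UTRs (small p = depletion relative to background).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HEPTAMER_K = 7
_CENTER = HEPTAMER_K // 2
N_HEPTAMERS = 4**HEPTAMER_K

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def encode_kmers(kmers: "pd.Series | np.ndarray | list[str]", k: int = HEPTAMER_K) -> np.ndarray:
    """Base-4 integer codes for k-mers; -1 for any k-mer containing non-ACGT."""
    arr = np.asarray(kmers, dtype=f"S{k}")
    flat = np.frombuffer(arr.tobytes(), dtype=np.uint8).reshape(-1, k)
    codes = _BASE_CODE[flat]
    bad = (codes < 0).any(axis=1)
    out = np.zeros(len(arr), dtype=np.int64)
    for j in range(k):
        out = out * 4 + np.where(codes[:, j] < 0, 0, codes[:, j])
    out[bad] = -1
    return out


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def is_cpg_heptamer(hept: str) -> bool:
    """Is the central base of the 7-mer part of a CG dinucleotide (either strand)?"""
    h = hept.upper()
    return h[_CENTER : _CENTER + 2] == "CG" or h[_CENTER - 1 : _CENTER + 1] == "CG"


class HeptamerSubstitutionTable:
    """Posterior substitution probabilities keyed by (7-mer, alt of center).

    ``probs`` is a dense (4**7, 4) array over alternative alleles (the
    reference center allele's column is zero); ``cumulative`` sums the three
    alternatives per 7-mer. On load the table is strand-symmetrized by
    default — each entry averaged with its reverse-complement entry — since
    the source model is strand-collapsed.
    """

    def __init__(self, probs: np.ndarray, symmetrize: bool = True):
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (N_HEPTAMERS, 4):
            raise ValueError(f"probs must have shape ({N_HEPTAMERS}, 4)")
        if (probs < 0).any():
            raise ValueError("negative substitution probability")
        if symmetrize:
            probs = 0.5 * (probs + self._reverse_complement_probs(probs))
        self.probs = probs
        self.cumulative = probs.sum(axis=1)
        if (self.cumulative > 1.0 + 1e-9).any():
            raise ValueError("cumulative substitution probability exceeds 1")

    @staticmethod
    def _reverse_complement_probs(probs: np.ndarray) -> np.ndarray:
        idx = np.arange(N_HEPTAMERS)
        digits = np.empty((N_HEPTAMERS, HEPTAMER_K), dtype=np.int64)
        rem = idx.copy()
        for j in range(HEPTAMER_K - 1, -1, -1):
            digits[:, j] = rem % 4
            rem //= 4
        comp = 3 - digits[:, ::-1]  # complement of reversed digits
        rc_idx = np.zeros(N_HEPTAMERS, dtype=np.int64)
        for j in range(HEPTAMER_K):
            rc_idx = rc_idx * 4 + comp[:, j]
        out = np.empty_like(probs)
        for alt in range(4):
            out[:, alt] = probs[rc_idx, 3 - alt]
        return out

    def cumulative_for(self, heptamers) -> np.ndarray:
        """Cumulative probability per 7-mer; NaN where the 7-mer contains N."""
        codes = encode_kmers(heptamers)
        out = np.full(len(codes), np.nan)
        ok = codes >= 0
        out[ok] = self.cumulative[codes[ok]]
        return out

    @classmethod
    def from_tsv(cls, path, symmetrize: bool = True) -> "HeptamerSubstitutionTable":
        df = pd.read_csv(path, sep="\t")
        probs = np.zeros((N_HEPTAMERS, 4))
        codes = encode_kmers(df["heptamer"])
        alt_codes = _BASE_CODE[np.frombuffer(np.asarray(df["alt"], dtype="S1").tobytes(), dtype=np.uint8)]
        probs[codes, alt_codes] = df["probability"].to_numpy()
        return cls(probs, symmetrize=symmetrize)


def positions_from_sequence(
    chrom: str, seq: str, start: int = 0, region_id: str = "", offsets=None
) -> pd.DataFrame:
    """Tabulate genomic positions with their reference 7-mer contexts.

    ``seq`` is the plus-strand reference beginning at genomic ``start``;
    ``offsets`` restricts the table to those sequence offsets (default: every
    position with a full 7-mer). Positions too close to the sequence ends for
    a full context are skipped.
    """
    s = seq.upper()
    if offsets is None:
        offsets = range(_CENTER, len(s) - _CENTER)
    rows = []
    for i in offsets:
        if i < _CENTER or i >= len(s) - _CENTER:
            continue
        rows.append(
            {
                "chrom": chrom,
                "pos": start + i,
                "heptamer": s[i - _CENTER : i + _CENTER + 1],
                "region_id": region_id or chrom,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "heptamer", "region_id"])


@dataclass
class RegionOEResult:
    """Observed/expected polymorphic-site ratio for one region class."""

    region_label: str
    n_positions: int
    observed: int
    expected: float
    ratio: float
    ci90: tuple[float, float] | None = None
    permutation_p: float | None = None
    n_dropped: int = 0


@dataclass
class PositionArrays:
    """Per-position model inputs after dropping N-context and CpG positions."""

    cum: np.ndarray  # cumulative substitution probability
    poly: np.ndarray  # bool: position intersects >=1 polymorphic site
    n_input: int
    n_dropped: int


def prepare_positions(
    positions: pd.DataFrame,
    table: HeptamerSubstitutionTable,
    polymorphic_sites: "set[tuple[str, int]] | pd.DataFrame",
) -> PositionArrays:
    """Resolve per-position cumulative rates and polymorphism indicators.

    ``positions`` needs columns chrom, pos, heptamer. Positions whose 7-mer
    contains N are dropped with a log message; CpG positions are masked.
    Polymorphic sites may be a set of (chrom, pos) or a DataFrame with those
    columns; a site counts once however many alternative alleles it has.
    """
    hept = positions["heptamer"].astype(str).str.upper()
    cum = table.cumulative_for(hept)
    has_n = np.isnan(cum)
    if has_n.any():
        logger.info("dropping %d positions with N in the 7-mer context", has_n.sum())
    cpg = hept.map(is_cpg_heptamer).to_numpy()
    keep = ~has_n & ~cpg
    if isinstance(polymorphic_sites, pd.DataFrame):
        site_set = set(zip(polymorphic_sites["chrom"], polymorphic_sites["pos"]))
    else:
        site_set = polymorphic_sites
    poly = np.fromiter(
        ((c, p) in site_set for c, p in zip(positions["chrom"], positions["pos"])),
        dtype=bool,
        count=len(positions),
    )
    return PositionArrays(
        cum=cum[keep],
        poly=poly[keep],
        n_input=len(positions),
        n_dropped=int((~keep).sum()),
    )


def expected_substitutions(
    positions: pd.DataFrame, table: HeptamerSubstitutionTable
) -> float:
    """Expected polymorphic-site count: sum of cumulative probabilities over
    non-CpG positions with a full ACGT 7-mer context."""
    pa = prepare_positions(positions, table, set())
    return float(pa.cum.sum())


def observed_substitutions(
    positions: pd.DataFrame,
    polymorphic_sites: "set[tuple[str, int]] | pd.DataFrame",
    table: HeptamerSubstitutionTable | None = None,
) -> int:
    """Count non-CpG positions intersecting at least one polymorphic site."""
    if table is None:
        hept = positions["heptamer"].astype(str).str.upper()
        cpg = hept.map(is_cpg_heptamer).to_numpy()
        has_n = ~hept.str.fullmatch("[ACGT]{7}").to_numpy()
        keep = ~cpg & ~has_n
        if isinstance(polymorphic_sites, pd.DataFrame):
            site_set = set(zip(polymorphic_sites["chrom"], polymorphic_sites["pos"]))
        else:
            site_set = polymorphic_sites
        return int(
            sum(
                (c, p) in site_set
                for c, p, k in zip(positions["chrom"], positions["pos"], keep)
                if k
            )
        )
    pa = prepare_positions(positions, table, polymorphic_sites)
    return int(pa.poly.sum())


def _bootstrap_ratios(
    pa: PositionArrays, n_iter: int, rng: np.random.Generator, chunk: int = 512
) -> np.ndarray:
    """Bootstrap O/E ratios by resampling positions with replacement.

    Iterations whose resampled expectation is zero are discarded (returned
    array may be shorter than ``n_iter``) and logged.
    """
    n = len(pa.cum)
    out = np.empty(n_iter)
    done = 0
    discarded = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        idx = rng.integers(0, n, size=(m, n))
        exp = pa.cum[idx].sum(axis=1)
        obs = pa.poly[idx].sum(axis=1)
        ok = exp > 0
        discarded += int((~ok).sum())
        k = int(ok.sum())
        out[done : done + k] = obs[ok] / exp[ok]
        done += k
    if discarded:
        logger.warning("discarded %d bootstrap iterations with zero expectation", discarded)
    return out[:done]


def oe_bootstrap(
    positions: pd.DataFrame,
    table: HeptamerSubstitutionTable,
    polymorphic_sites,
    n_iter: int = 10000,
    seed: int = 2020,
    region_label: str = "region",
) -> RegionOEResult:
    """O/E ratio with a bootstrap 90% confidence interval.

    Positions are resampled with replacement at the original region size each
    iteration; the CI is the empirical 5%/95% quantile of the resampled
    ratios.
    """
    pa = prepare_positions(positions, table, polymorphic_sites)
    if len(pa.cum) < 1:
        raise ValueError("no usable positions after N/CpG masking")
    expected = float(pa.cum.sum())
    observed = int(pa.poly.sum())
    ratio = observed / expected if expected > 0 else 0.0
    rng = np.random.default_rng(seed)
    boots = _bootstrap_ratios(pa, n_iter, rng)
    if observed == 0:
        ci = (0.0, 0.0)
    else:
        ci = tuple(float(q) for q in np.quantile(boots, [0.05, 0.95]))
    return RegionOEResult(
        region_label=region_label,
        n_positions=len(pa.cum),
        observed=observed,
        expected=expected,
        ratio=ratio,
        ci90=ci,
        n_dropped=pa.n_dropped,
    )


def sample_background_windows(
    utr_positions: pd.DataFrame,
    window_len: int = 25,
    n_windows: int = 5000,
    seed: int = 2020,
    region_col: str = "region_id",
) -> pd.DataFrame:
    """Sample fixed-length windows from a pool of background UTR positions.

    ``utr_positions`` holds consecutive positions grouped by ``region_col``
    (one UTR per region, rows in coordinate order). Windows of ``window_len``
    consecutive rows are drawn with replacement, uniformly over all valid
    window starts; regions shorter than the window are ignored.
    """
    rng = np.random.default_rng(seed)
    starts: list[tuple[int, int]] = []  # (absolute row offset, n valid starts)
    offset = 0
    for _, grp in utr_positions.groupby(region_col, sort=False):
        L = len(grp)
        if L >= window_len:
            starts.append((offset, L - window_len + 1))
        offset += L
    if not starts:
        raise ValueError("no background region is as long as the window")
    n_starts = np.array([s[1] for s in starts])
    region_pick = rng.choice(len(starts), size=n_windows, p=n_starts / n_starts.sum())
    rows = []
    base = utr_positions.reset_index(drop=True)
    for r in region_pick:
        off, nv = starts[r]
        w = off + rng.integers(0, nv)
        rows.append(base.iloc[w : w + window_len])
    return pd.concat(rows, ignore_index=True)


def empirical_null(
    target_positions: pd.DataFrame,
    background_utr_positions: pd.DataFrame,
    table: HeptamerSubstitutionTable,
    polymorphic_sites,
    window_len: int = 25,
    n_windows: int = 5000,
    n_iter: int = 10000,
    seed: int = 2020,
    region_label: str = "region",
) -> RegionOEResult:
    """Depletion test of a region's O/E ratio against matched UTR background.

    A background position pool is built from ``n_windows`` windows of
    ``window_len`` nt drawn from constraint-matched UTRs; both target and
    background are then bootstrap-resampled ``n_iter`` times and the one-
    sided depletion p-value is the proportion of paired draws in which the
    target's ratio is >= the background's (small p = target depleted).
    """
    rng = np.random.default_rng(seed)
    bg = sample_background_windows(
        background_utr_positions,
        window_len=window_len,
        n_windows=n_windows,
        seed=int(rng.integers(2**31)),
    )
    pa_t = prepare_positions(target_positions, table, polymorphic_sites)
    pa_b = prepare_positions(bg, table, polymorphic_sites)
    boots_t = _bootstrap_ratios(pa_t, n_iter, rng)
    boots_b = _bootstrap_ratios(pa_b, n_iter, rng)
    m = min(len(boots_t), len(boots_b))
    p = float(np.mean(boots_t[:m] >= boots_b[:m]))
    res = oe_bootstrap(
        target_positions, table, polymorphic_sites,
        n_iter=n_iter, seed=int(rng.integers(2**31)), region_label=region_label,
    )
    res.permutation_p = p
    return res
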