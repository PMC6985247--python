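"""Population-variant quality filtering and the allele-frequency depletion test.

Variant tables are pandas DataFrames with the columns

    chrom, pos, ref, alt, ac, an, rf_prob, segdup, lcr, decoy

(`pos` 0-based; `segdup`/`lcr`/`decoy` boolean region flags; `rf_prob` the
random-forest true-positive probability shipped with the callset). Optional
columns `tri_context` (reference 3-mer centred on the site) and `methylation`
are carried through untouched. A singleton is a variant with allele count 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FLAG_COLUMNS = ("segdup", "lcr", "decoy")

#: random-forest probability must strictly exceed this to pass
RF_THRESHOLD = 0.40
#: allele number must reach this fraction of the dataset maximum
AN_FRACTION = 0.80

_NUCS = frozenset("ACGT")


@dataclass
class VariantRecord:
    """A single biallelic SNV with callset evidence."""

    chrom: str
    pos: int
    ref: str
    alt: str
    ac: int
    an: int
    rf_prob: float
    segdup: bool = False
    lcr: bool = False
    decoy: bool = False
    tri_context: str | None = None
    methylation: float | None = None

    def __post_init__(self):
        if not 0 <= self.ac <= self.an:
            raise ValueError("need 0 <= AC <= AN")
        if self.an <= 0:
            raise ValueError("AN must be positive")
        if not 0.0 <= self.rf_prob <= 1.0:
            raise ValueError("rf_prob outside [0, 1]")

    @property
    def is_singleton(self) -> bool:
        return self.ac == 1

    @property
    def is_snv(self) -> bool:
        return self.ref in _NUCS and self.alt in _NUCS


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


@dataclass
class FrequencyComparison:
    """Aggregate allele-frequency comparison between two variant groups."""

    group_a: str
    group_b: str
    ac_a: int
    an_a: int
    ac_b: int
    an_b: int
    odds_ratio: float
    p_value: float
    continuity_flag: bool = False

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [[self.ac_a, self.an_a - self.ac_a], [self.ac_b, self.an_b - self.ac_b]]
        )


def _is_autosome(chrom: str) -> bool:
    c = chrom.removeprefix("chr")
    return c.isdigit()


def max_allele_numbers(variants: pd.DataFrame) -> dict[bool, int]:
    """Maximum observed AN per chromosome type (autosome vs not)."""
    auto = variants["chrom"].map(_is_autosome)
    out: dict[bool, int] = {}
    for flag in (True, False):
        sub = variants.loc[auto == flag, "an"]
        if len(sub):
            out[flag] = int(sub.max())
    return out


def filter_variants(
    variants: pd.DataFrame, max_an: int | dict[bool, int] | None = None
) -> pd.DataFrame:
    """Apply callset quality filters and keep biallelic SNVs.

    Keeps records with ``rf_prob > 0.40``, allele number at least 80% of the
    dataset maximum, no segdup/LCR/decoy flag, and single-nucleotide REF/ALT.
    ``max_an`` may be a scalar, a per-chromosome-type mapping (autosome bool
    -> AN), or omitted to compute the per-type maximum from the table itself.
    Filtering is idempotent.
    """
    if variants.empty:
        return variants.copy()
    auto = variants["chrom"].map(_is_autosome)
    if max_an is None:
        max_an = max_allele_numbers(variants)
    if isinstance(max_an, dict):
        cap = auto.map(max_an).astype(float)
    else:
        cap = pd.Series(float(max_an), index=variants.index)
    if (variants["an"] > cap).any():
        raise ValueError("variant AN exceeds the stated maximum allele number")
    is_snv = variants["ref"].isin(_NUCS) & variants["alt"].isin(_NUCS)
    clean = ~variants[list(FLAG_COLUMNS)].any(axis=1)
    keep = (
        (variants["rf_prob"] > RF_THRESHOLD)
        & (variants["an"] >= AN_FRACTION * cap)
        & clean
        & is_snv
    )
    return variants.loc[keep].copy()


def decompose_multiallelic(variants: pd.DataFrame) -> pd.DataFrame:
    """Split comma-separated ALT alleles into one biallelic row each.

    Per-allele AC values may be comma-separated in step with ALT; each ALT is
    judged independently downstream.
    """
    alt = variants["alt"].astype(str)
    multi = alt.str.contains(",")
    if not multi.any():
        return variants.copy()
    rows = []
    for _, row in variants.iterrows():
        alts = str(row["alt"]).split(",")
        acs = str(row["ac"]).split(",")
        if len(acs) == 1:
            acs = acs * len(alts)
        if len(acs) != len(alts):
            raise ValueError("AC list does not match ALT list")
        for a, c in zip(alts, acs):
            r = row.copy()
            r["alt"] = a
            r["ac"] = int(c)
            rows.append(r)
    return pd.DataFrame(rows).reset_index(drop=True)


def match_transcripts_by_loeuf(
    targets: pd.DataFrame,
    candidate_pool: pd.DataFrame,
    seed: int,
    bin_width: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Select a LOEUF-matched comparator transcript set.

    ``targets`` and ``candidate_pool`` need columns ``transcript_id`` and
    ``loeuf``. For each target one candidate is drawn without replacement
    from the same LOEUF bin (width ``bin_width``); an exhausted bin is
    widened to the nearest non-empty bin with a warning. Returns the matched
    subset of the pool and a per-bin QC table of target/matched LOEUF means.
    """
    for df, name in ((targets, "targets"), (candidate_pool, "candidate_pool")):
        if df["loeuf"].isna().any():
            raise ValueError(f"{name} contain missing LOEUF values")
    rng = np.random.default_rng(seed)
    pool = candidate_pool.reset_index(drop=True)
    pool_bins = np.floor(pool["loeuf"].to_numpy() / bin_width).astype(int)
    available: dict[int, list[int]] = {}
    for i, b in enumerate(pool_bins):
        available.setdefault(b, []).append(i)
    for idxs in available.values():
        rng.shuffle(idxs)
    chosen: list[int] = []
    target_bins = np.floor(targets["loeuf"].to_numpy() / bin_width).astype(int)
    # shuffled target order so bin exhaustion does not favour early targets
    order = rng.permutation(len(target_bins))
    for ti in order:
        b = target_bins[ti]
        if not available.get(b):
            occupied = [k for k, v in available.items() if v]
            if not occupied:
                raise ValueError("candidate pool exhausted")
            nearest = min(occupied, key=lambda k: (abs(k - b), k))
            logger.warning(
                "LOEUF bin %d empty; widened to nearest non-empty bin %d", b, nearest
            )
            b = nearest
        chosen.append(available[b].pop())
    matched = pool.iloc[sorted(chosen)].reset_index(drop=True)
    qc = (
        pd.DataFrame(
            {
                "bin": np.concatenate([target_bins, np.floor(matched["loeuf"] / bin_width).astype(int)]),
                "loeuf": np.concatenate([targets["loeuf"], matched["loeuf"]]),
                "set": ["target"] * len(targets) + ["matched"] * len(matched),
            }
        )
        .groupby(["bin", "set"])["loeuf"]
        .agg(["mean", "count"])
        .reset_index()
    )
    return matched, qc


def compare_allele_frequencies(
    variants_a: pd.DataFrame,
    variants_b: pd.DataFrame,
    label_a: str = "a",
    label_b: str = "b",
) -> FrequencyComparison:
    """Two-sided Fisher exact test on pooled allele counts vs allele numbers.

    Builds the 2x2 table ``[[sum AC_a, sum AN_a - sum AC_a], [sum AC_b,
    sum AN_b - sum AC_b]]`` — the fraction of observed alleles that carry a
    variant in each group — and reports the odds ratio and exact p-value.
    """
    if variants_a.empty or variants_b.empty:
        raise ValueError("both variant groups must be nonempty")
    ac_a, an_a = int(variants_a["ac"].sum()), int(variants_a["an"].sum())
    ac_b, an_b = int(variants_b["ac"].sum()), int(variants_b["an"].sum())
    table = np.array([[ac_a, an_a - ac_a], [ac_b, an_b - ac_b]])
    continuity = bool((table == 0).any())
    if continuity:
        logger.warning("zero marginal cell in frequency table; OR flagged")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    return FrequencyComparison(
        label_a, label_b, ac_a, an_a, ac_b, an_b, float(odds), float(p), continuity
    )
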