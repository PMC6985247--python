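"""Mutability-adjusted proportion of singletons (MAPS).

The proportion of singleton variants in a class measures the strength of
purifying selection, but raw proportions confound selection with mutability:
highly mutable contexts (CpG transitions above all) recur in the population
and are depleted of singletons for purely neutral reasons. MAPS removes this
confound by calibrating the expected singleton proportion against context
mutation rates on synonymous variants, assumed neutral:

    MAPS(class) = observed singleton proportion - mean predicted proportion

where the prediction is a count-weighted least-squares regression of per
context singleton proportion on context mutation rate, fit on synonymous
variants. Mutation rates are keyed by (trinucleotide context, alt,
methylation bin); methylation adjustment applies only at CpG dinucleotides,
binned into none/low (<0.2), intermediate (0.2-0.6), and high (>0.6) median
methylation.

Significance against a comparator class (e.g. position-matched non-pG4
GGG/CCC trinucleotide variants) comes from bootstrap resampling of both
classes: p is the proportion of paired resamples in which the class MAPS does
not exceed the comparator's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

METHYLATION_BINS = ("none_low", "intermediate", "high", "not_cpg")

_NUCS = "ACGT"


def assign_methylation_bin(level: float | None) -> str:
    """Bin a CpG median methylation level; missing / non-CpG -> ``not_cpg``.

    Bins follow the printed intervals: <0.2 none/low, 0.2-0.6 intermediate
    (both endpoints inclusive), >0.6 high.
    """
    if level is None or (isinstance(level, float) and np.isnan(level)):
        return "not_cpg"
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"methylation level {level} outside [0, 1]")
    if level < 0.2:
        return "none_low"
    if level <= 0.6:
        return "intermediate"
    return "high"


def is_cpg_context(tri_context: str) -> bool:
    """Does the 3-mer put its central base in a CpG dinucleotide (either strand)?"""
    c = tri_context.upper()
    return c[1:3] == "CG" or c[0:2] == "CG"


class MutationRateTable:
    """Per-context mutation rates keyed by (3-mer, alt, methylation bin).

    Every ACGT 3-mer x 3 alternative alleles must be covered for the
    ``not_cpg`` bin; CpG-containing contexts must additionally be covered for
    the three methylation bins.
    """

    def __init__(self, rates: dict[tuple[str, str, str], float]):
        for (ctx, alt, mbin), rate in rates.items():
            if rate <= 0:
                raise ValueError(f"non-positive rate for {(ctx, alt, mbin)}")
            if mbin not in METHYLATION_BINS:
                raise ValueError(f"unknown methylation bin {mbin!r}")
        self.rates = dict(rates)
        self._validate_coverage()

    def _validate_coverage(self) -> None:
        missing = []
        for a in _NUCS:
            for b in _NUCS:
                for c in _NUCS:
                    ctx = a + b + c
                    for alt in _NUCS:
                        if alt == b:
                            continue
                        if (ctx, alt, "not_cpg") not in self.rates:
                            missing.append((ctx, alt, "not_cpg"))
                        if is_cpg_context(ctx):
                            for mbin in METHYLATION_BINS[:3]:
                                if (ctx, alt, mbin) not in self.rates:
                                    missing.append((ctx, alt, mbin))
        if missing:
            raise ValueError(f"rate table missing {len(missing)} entries, e.g. {missing[:3]}")

    def rate(self, tri_context: str, alt: str, methylation_bin: str = "not_cpg") -> float:
        return self.rates[(tri_context, alt, methylation_bin)]

    def lookup(self, variants: pd.DataFrame) -> np.ndarray:
        """Vectorized rate lookup for a variant table.

        Requires ``tri_context`` and ``alt`` columns; an optional
        ``methylation_bin`` column defaults to ``not_cpg``. Raises with the
        offending keys if any context is uncovered.
        """
        if "methylation_bin" in variants.columns:
            mbin = variants["methylation_bin"]
        else:
            mbin = pd.Series("not_cpg", index=variants.index)
        keys = list(zip(variants["tri_context"], variants["alt"], mbin))
        out = np.empty(len(keys))
        bad = []
        for i, k in enumerate(keys):
            r = self.rates.get(k)
            if r is None:
                bad.append(k)
            else:
                out[i] = r
        if bad:
            raise KeyError(f"contexts not covered by the rate table: {sorted(set(bad))[:5]}")
        return out

    @classmethod
    def from_tsv(cls, path) -> "MutationRateTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            {
                (r.context, r.alt, r.methylation_bin): r.rate
                for r in df.itertuples(index=False)
            }
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [
                {"context": c, "alt": a, "methylation_bin": m, "rate": r}
                for (c, a, m), r in sorted(self.rates.items())
            ]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class MutabilityCalibration:
    """Singleton-proportion ~ mutation-rate regression fit on neutral variants."""

    intercept: float
    slope: float
    r_squared: float
    context_table: pd.DataFrame  # per-context rate, proportion, n
    clamped: int = 0

    def predict(self, rates: np.ndarray) -> np.ndarray:
        """Predicted singleton proportion per variant, clamped to [0, 1]."""
        raw = self.intercept + self.slope * np.asarray(rates, dtype=float)
        clipped = np.clip(raw, 0.0, 1.0)
        n_clamped = int(np.sum(raw != clipped))
        if n_clamped:
            object.__setattr__(self, "clamped", self.clamped + n_clamped)
            logger.warning("clamped %d predictions to [0, 1]", n_clamped)
        return clipped


@dataclass
class MAPSResult:
    class_label: str
    n_variants: int
    observed_singleton_prop: float
    expected_singleton_prop: float
    maps: float
    ci90: tuple[float, float] | None = None
    permutation_p: float | None = None
    comparator_label: str | None = None
    n_boot: int | None = None
    boot_maps: np.ndarray | None = field(default=None, repr=False)


def _require_columns(variants: pd.DataFrame) -> None:
    need = {"ac", "tri_context", "alt"}
    missing = need - set(variants.columns)
    if missing:
        raise ValueError(f"variant table lacks columns {sorted(missing)}")


def calibrate(
    synonymous_variants: pd.DataFrame,
    rates: MutationRateTable,
    weighted: bool = True,
) -> MutabilityCalibration:
    """Fit the singleton-proportion regression on synonymous variants.

    Variants are grouped by (context, alt, methylation bin); the per-group
    observed singleton proportion is regressed on the group mutation rate,
    weighted by group variant count (unweighted optional). At least two
    distinct rate values are required.
    """
    _require_columns(synonymous_variants)
    df = synonymous_variants.copy()
    if "methylation_bin" not in df.columns:
        df["methylation_bin"] = "not_cpg"
    df["_singleton"] = (df["ac"] == 1).astype(float)
    grouped = (
        df.groupby(["tri_context", "alt", "methylation_bin"], observed=True)["_singleton"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "singleton_prop", "count": "n"})
    )
    grouped["rate"] = rates.lookup(grouped)
    if grouped["rate"].nunique() < 2:
        raise ValueError("degenerate design: fewer than two distinct context rates")
    X = sm.add_constant(grouped["rate"].to_numpy())
    y = grouped["singleton_prop"].to_numpy()
    w = grouped["n"].to_numpy().astype(float) if weighted else np.ones(len(grouped))
    fit = sm.WLS(y, X, weights=w).fit()
    # constant proportions have zero total sum of squares; the flat fit is
    # then exact, so report R^2 = 1 rather than 0/0
    r2 = 1.0 if np.allclose(y, y[0]) else float(fit.rsquared)
    return MutabilityCalibration(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        r_squared=r2,
        context_table=grouped,
    )


def _maps_ingredients(
    variants: pd.DataFrame, calibration: MutabilityCalibration, rates: MutationRateTable
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant singleton indicators and predicted singleton probabilities."""
    _require_columns(variants)
    if variants.empty:
        raise ValueError("variant class is empty")
    singles = (variants["ac"] == 1).to_numpy(dtype=float)
    predicted = calibration.predict(rates.lookup(variants))
    return singles, predicted


def compute_maps(
    class_variants: pd.DataFrame,
    calibration: MutabilityCalibration,
    rates: MutationRateTable,
    class_label: str = "class",
) -> MAPSResult:
    """MAPS point estimate for one variant class.

    ``maps = (sum singleton indicator - sum predicted) / n``; positive values
    indicate an excess of singletons beyond mutability, i.e. purifying
    selection.
    """
    s, p = _maps_ingredients(class_variants, calibration, rates)
    n = len(s)
    return MAPSResult(
        class_label=class_label,
        n_variants=n,
        observed_singleton_prop=float(s.mean()),
        expected_singleton_prop=float(p.mean()),
        maps=float(s.mean() - p.mean()),
    )


def _bootstrap_maps(
    diff: np.ndarray, n_out: int, n_boot: int, rng: np.random.Generator,
    chunk: int = 256,
) -> np.ndarray:
    """Bootstrap means of per-variant (singleton - predicted) differences."""
    out = np.empty(n_boot)
    n = len(diff)
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(m, n_out))
        out[done : done + m] = diff[idx].mean(axis=1)
        done += m
    return out


def permute_maps(
    class_variants: pd.DataFrame,
    comparator_variants: pd.DataFrame,
    calibration: MutabilityCalibration,
    rates: MutationRateTable,
    n_boot: int = 10000,
    seed: int = 2020,
    class_label: str = "class",
    comparator_label: str = "comparator",
) -> MAPSResult:
    """Bootstrap significance of a class MAPS against a comparator class.

    Both classes are resampled with replacement ``n_boot`` times (the
    comparator resample sized to the class); ``p`` is the proportion of
    iterations in which the class MAPS is <= the comparator's, and the 5%/95%
    bootstrap quantiles of the class MAPS are attached.
    """
    if n_boot < 100:
        logger.warning("n_boot=%d is small; permutation p will be unstable", n_boot)
    s_c, p_c = _maps_ingredients(class_variants, calibration, rates)
    s_k, p_k = _maps_ingredients(comparator_variants, calibration, rates)
    rng = np.random.default_rng(seed)
    n = len(s_c)
    boot_class = _bootstrap_maps(s_c - p_c, n, n_boot, rng)
    boot_comp = _bootstrap_maps(s_k - p_k, n, n_boot, rng)
    p = float(np.mean(boot_class <= boot_comp))
    lo, hi = np.quantile(boot_class, [0.05, 0.95])
    base = compute_maps(class_variants, calibration, rates, class_label)
    base.ci90 = (float(lo), float(hi))
    base.permutation_p = p
    base.comparator_label = comparator_label
    base.n_boot = n_boot
    base.boot_maps = boot_class
    return base
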