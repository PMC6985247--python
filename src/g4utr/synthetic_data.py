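"""Synthetic fixtures with known truth for every pipeline stage.

The generator encodes the statistical structure each analysis assumes, so
recovery of the planted truth is a meaningful end-to-end check:

* a transcriptome whose UTR background sequence is rejection-sampled to
  contain no unplanted canonical pG4, with motifs planted at known
  coordinates and isoform structures that realise constitutive / alternative
  inclusion;
* variant tables whose singleton probability is linear in context mutation
  rate plus a per-class excess ``delta`` (so a class MAPS recovers delta);
* a random heptamer substitution table and polymorphic sites drawn
  Bernoulli from it (neutral O/E ratio 1), with optional thinning to plant
  depletion;
* eQTL / CLIP / knockdown / ClinVar layers with enrichment planted on the
  odds scale so the tests' odds ratios estimate the configured multiplier;
* beta-binomial allele-count tables at configured (rho, phi).

All randomness flows through ``numpy.random.default_rng`` (PCG64, recorded
in the truth metadata); a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .g4_annotation import TranscriptModel, position_classes, scan_pg4
from .maps_model import METHYLATION_BINS, MutationRateTable, is_cpg_context
from .oe_substitution import N_HEPTAMERS, HeptamerSubstitutionTable, revcomp

_NUCS = "ACGT"
#: background base weights; guanine lowered so canonical motifs are rare
#: enough for whole-sequence rejection sampling to be cheap
_BG_WEIGHTS = np.array([0.30, 0.25, 0.20, 0.25])
_NON_G = "ACT"


@dataclass
class SimulationConfig:
    """Desk-scale defaults: ~200 genes, <=5 isoforms, UTRs 100-2000 nt."""

    n_genes: int = 200
    max_isoforms: int = 5
    utr_len_min: int = 100
    utr_len_max: int = 2000
    cds_len: int = 300
    pg4_rate: float = 0.6  # per gene per UTR side
    alt_fraction: float = 0.6  # alternative (vs constitutive) among multi-isoform pG4 genes
    tract4_rate: float = 0.2  # chance a planted tract has 4 Gs
    max_rejections: int = 200
    # variant layer
    an_total: int = 30000
    variant_rate_scale: float = 0.5  # occurrence prob = scale * rate / max rate
    singleton_intercept: float = 0.30  # p(singleton) = a + b * rate + delta
    singleton_slope: float = 3.0
    deltas: dict = field(
        default_factory=lambda: {
            "central_g": 0.10,
            "flank_g": 0.04,
            "gap": 0.0,
            "background": 0.0,
        }
    )
    # functional layers
    eqtl_base_rate: float = 0.10
    eqtl_multiplier: float = 2.0
    n_tissues: int = 3
    tract_pos_prob: float = 0.64  # P(NES > 0) for tract eQTLs; gaps are 0.5
    clip_peak_width: int = 8
    clip_base_density: float = 1.0  # peaks per kb of non-pG4 UTR
    clip_multiplier: float = 6.0
    rbp_names: tuple = ("GRSF1", "FUS", "UPF1", "DDX6", "LARP4", "TAF15")
    rbp_pg4_biased: tuple = ("GRSF1", "FUS")
    kd_base_rate: float = 0.10
    kd_multiplier: float = 2.0
    clinvar_base_rate: float = 0.02  # variants per non-pG4 UTR base
    clinvar_multiplier: float = 1.5
    # ASE layer
    ase_rho: float = 0.8
    ase_dispersion: float = 0.05  # phi
    ase_n_samples: int = 84
    ase_depth_mean: float = 50.0
    ase_n_variants: int = 5


# ---------------------------------------------------------------------------
# transcriptome with planted motifs
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(_NUCS))[rng.choice(4, size=length, p=_BG_WEIGHTS)])


def random_motif(rng: np.random.Generator, tract4_rate: float = 0.2) -> str:
    """A random canonical pG4: 4 G-tracts (length 3-4), loops of 1-7 non-G."""
    parts = []
    for i in range(4):
        parts.append("G" * (4 if rng.random() < tract4_rate else 3))
        if i < 3:
            gap_len = int(rng.integers(1, 8))
            parts.append("".join(rng.choice(list(_NON_G), size=gap_len)))
    return "".join(parts)


def _motif_free_seq(rng: np.random.Generator, length: int, cap: int) -> str:
    for _ in range(cap):
        s = _random_seq(rng, length)
        if not scan_pg4(s):
            return s
    raise RuntimeError(
        "rejection sampling failed to produce a motif-free sequence; lower the GC content"
    )


def _plant_motif(
    rng: np.random.Generator, seq: str, lo: float, hi: float, cap: int
) -> tuple[str, int, int]:
    """Overwrite a slice of ``seq`` with a canonical motif.

    The motif start is drawn uniformly from the [lo, hi) fraction of the
    sequence; one non-G base is forced on each flank so the planted tracts
    stay maximal. Retries until a rescan finds exactly the planted motif.
    """
    for _ in range(cap):
        motif = random_motif(rng)
        left = max(1, int(len(seq) * lo))
        right = min(len(seq) - len(motif) - 1, int(len(seq) * hi))
        if right <= left:
            continue
        start = int(rng.integers(left, right))
        s = (
            seq[: start - 1]
            + rng.choice(list(_NON_G))
            + motif
            + rng.choice(list(_NON_G))
            + seq[start + len(motif) + 1 :]
        )
        found = scan_pg4(s)
        if len(found) == 1 and found[0].start == start and found[0].end == start + len(motif):
            return s, start, start + len(motif)
    raise RuntimeError("failed to plant a clean motif; lower the GC content")


@dataclass
class SyntheticTranscriptome:
    transcripts: list[TranscriptModel]
    genome: dict[str, str]  # plus-strand reference per chromosome
    truth_motifs: pd.DataFrame  # per isoform-side planted motif coordinates
    truth_genes: pd.DataFrame  # per gene-side inclusion status
    meta: dict


def make_transcriptome(cfg: SimulationConfig, seed: int) -> SyntheticTranscriptome:
    """Generate a transcriptome with planted pG4 motifs and truth tables.

    Each gene occupies its own locus; isoforms share the locus and differ by
    alternative transcription start (5' UTR) or polyadenylation (3' UTR)
    points, which is how non-pG4 isoforms of a pG4 gene exclude the motif.
    Background UTR sequence contains no unplanted canonical motif.
    """
    rng = np.random.default_rng(seed)
    transcripts: list[TranscriptModel] = []
    motif_rows: list[dict] = []
    gene_rows: list[dict] = []
    genome_parts: dict[str, list[str]] = {}
    cursors: dict[str, int] = {}
    n_chroms = 4
    for gi in range(cfg.n_genes):
        gene_id = f"G{gi:04d}"
        chrom = f"chr{gi % n_chroms + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_iso = int(rng.integers(1, cfg.max_isoforms + 1))
        lens = {
            "5p": int(rng.integers(cfg.utr_len_min, cfg.utr_len_max + 1)),
            "3p": int(rng.integers(cfg.utr_len_min, cfg.utr_len_max + 1)),
        }
        side_info: dict[str, dict] = {}
        for side in ("5p", "3p"):
            L = lens[side]
            seq = _motif_free_seq(rng, L, cfg.max_rejections)
            has_pg4 = rng.random() < cfg.pg4_rate
            info: dict = {"seq": seq, "motif": None, "carriers": list(range(n_iso))}
            if has_pg4:
                # plant early in the 5' UTR, late in the 3' UTR, so the
                # alternative isoform can exclude it by trimming
                lo, hi = (0.05, 0.35) if side == "5p" else (0.65, 0.90)
                seq, ms, me = _plant_motif(rng, seq, lo, hi, cfg.max_rejections)
                info["seq"] = seq
                info["motif"] = (ms, me)
                if n_iso > 1 and rng.random() < cfg.alt_fraction:
                    n_car = int(rng.integers(1, n_iso))  # proper subset
                    info["carriers"] = sorted(rng.choice(n_iso, size=n_car, replace=False).tolist())
            side_info[side] = info
            status = (
                "non_pg4"
                if info["motif"] is None
                else ("constitutive" if len(info["carriers"]) == n_iso else "alternative")
            )
            gene_rows.append(
                {
                    "gene_id": gene_id,
                    "utr_side": side,
                    "status": status,
                    "n_pg4_isoforms": 0 if info["motif"] is None else len(info["carriers"]),
                    "n_total_isoforms": n_iso,
                }
            )
        s5, s3 = side_info["5p"]["seq"], side_info["3p"]["seq"]
        locus_len = len(s5) + cfg.cds_len + len(s3)
        g0 = cursors.get(chrom, 0)
        cds_seq = _motif_free_seq(rng, cfg.cds_len, cfg.max_rejections)
        if strand == "+":
            plus = s5 + cds_seq + s3
            utr5_full = (g0, g0 + len(s5))
            cds = (g0 + len(s5), g0 + len(s5) + cfg.cds_len)
            utr3_full = (cds[1], g0 + locus_len)
        else:
            plus = revcomp(s3) + revcomp(cds_seq) + revcomp(s5)
            utr3_full = (g0, g0 + len(s3))
            cds = (g0 + len(s3), g0 + len(s3) + cfg.cds_len)
            utr5_full = (cds[1], g0 + locus_len)
        genome_parts.setdefault(chrom, []).append(plus)
        spacer = "".join(rng.choice(list(_NON_G), size=30))
        genome_parts[chrom].append(spacer)
        cursors[chrom] = g0 + locus_len + len(spacer)

        loeuf = float(np.round(rng.uniform(0.05, 1.95), 3))
        for iso in range(n_iso):
            tx_id = f"{gene_id}.{iso}"
            tx_utr: dict[str, tuple[str, tuple[int, int]]] = {}
            for side, full_block in (("5p", utr5_full), ("3p", utr3_full)):
                info = side_info[side]
                seq = info["seq"]
                trim = 0
                if info["motif"] is not None and iso not in info["carriers"]:
                    ms, me = info["motif"]
                    # exclude the motif (and its guard base) from this isoform
                    trim = me + 1 if side == "5p" else len(seq) - ms + 1
                if side == "5p":
                    sub_seq = seq[trim:]
                    if strand == "+":
                        block = (full_block[0] + trim, full_block[1])
                    else:
                        block = (full_block[0], full_block[1] - trim)
                else:
                    sub_seq = seq[: len(seq) - trim] if trim else seq
                    if strand == "+":
                        block = (full_block[0], full_block[1] - trim)
                    else:
                        block = (full_block[0] + trim, full_block[1])
                tx_utr[side] = (sub_seq, block)
                if info["motif"] is not None and iso in info["carriers"]:
                    ms, me = info["motif"]
                    motif_rows.append(
                        {
                            "gene_id": gene_id,
                            "transcript_id": tx_id,
                            "utr_side": side,
                            "start": ms,
                            "end": me,
                            "sequence": seq[ms:me],
                            "chrom": chrom,
                        }
                    )
            transcripts.append(
                TranscriptModel(
                    transcript_id=tx_id,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    utr5_blocks=[tx_utr["5p"][1]],
                    utr3_blocks=[tx_utr["3p"][1]],
                    cds_blocks=[cds],
                    utr5_seq=tx_utr["5p"][0],
                    utr3_seq=tx_utr["3p"][0],
                    loeuf=loeuf,
                )
            )
    genome = {c: "".join(parts) for c, parts in genome_parts.items()}
    return SyntheticTranscriptome(
        transcripts=transcripts,
        genome=genome,
        truth_motifs=pd.DataFrame(motif_rows),
        truth_genes=pd.DataFrame(gene_rows),
        meta={"rng": "numpy.random.default_rng/PCG64", "seed": seed, "config": vars(cfg)},
    )


# ---------------------------------------------------------------------------
# mutation-rate and heptamer tables
# ---------------------------------------------------------------------------


def random_rate_table(seed: int, rate_lo: float = 0.01, rate_hi: float = 0.10) -> MutationRateTable:
    """A seeded mutation-rate table covering every context/alt/bin key.

    Rates are uniform on [rate_lo, rate_hi] (arbitrary units: only the
    linear relation to singleton proportion matters); CpG contexts get an
    increasing rate across methylation bins.
    """
    rng = np.random.default_rng(seed)
    rates: dict[tuple[str, str, str], float] = {}
    for a in _NUCS:
        for b in _NUCS:
            for c in _NUCS:
                ctx = a + b + c
                for alt in _NUCS:
                    if alt == b:
                        continue
                    base = float(rng.uniform(rate_lo, rate_hi))
                    rates[(ctx, alt, "not_cpg")] = base
                    if is_cpg_context(ctx):
                        for k, mbin in enumerate(METHYLATION_BINS[:3]):
                            rates[(ctx, alt, mbin)] = base * (1.0 + 0.5 * k)
    return MutationRateTable(rates)


def random_heptamer_table(
    seed: int, mean_rate: float = 0.03, symmetrize: bool = True
) -> HeptamerSubstitutionTable:
    """A seeded heptamer substitution table with per-alt probabilities."""
    rng = np.random.default_rng(seed)
    probs = rng.uniform(mean_rate / 3 * 0.5, mean_rate / 3 * 1.5, size=(N_HEPTAMERS, 4))
    # zero out the reference (center base) column of each heptamer
    center = (np.arange(N_HEPTAMERS) // 4**3) % 4
    probs[np.arange(N_HEPTAMERS), center] = 0.0
    return HeptamerSubstitutionTable(probs, symmetrize=symmetrize)


# ---------------------------------------------------------------------------
# variants with controlled singleton excess
# ---------------------------------------------------------------------------


def simulate_class_variants(
    positions: pd.DataFrame,
    rates: MutationRateTable,
    cfg: SimulationConfig,
    seed: int,
) -> pd.DataFrame:
    """Draw variants at labelled positions with class-controlled constraint.

    ``positions`` needs class_label, tri_context (and optionally chrom/pos or
    transcript/offset bookkeeping columns, carried through). Per position a
    variant occurs Bernoulli with probability proportional to its context
    mutability; its singleton status is Bernoulli(a + b*rate + delta_class),
    clipped to [0, 1]. With delta = 0 the class is exactly calibrated
    (MAPS -> 0); positive delta plants purifying selection.
    """
    df = positions[positions["tri_context"].str.fullmatch("[ACGT]{3}")].copy()
    rng = np.random.default_rng(seed)
    alt_choices = []
    alt_rates = []
    for ctx in df["tri_context"]:
        alts = [a for a in _NUCS if a != ctx[1]]
        rs = np.array([rates.rate(ctx, a) for a in alts])
        k = rng.choice(3, p=rs / rs.sum())
        alt_choices.append(alts[k])
        alt_rates.append(rs[k])
    df["alt"] = alt_choices
    df["rate"] = alt_rates
    max_rate = max(df["rate"].max(), 1e-12)
    occur = rng.random(len(df)) < cfg.variant_rate_scale * df["rate"] / max_rate
    df = df[occur].copy()
    delta = df["class_label"].map(lambda c: cfg.deltas.get(c, 0.0)).to_numpy()
    p_single = np.clip(
        cfg.singleton_intercept + cfg.singleton_slope * df["rate"].to_numpy() + delta,
        0.0,
        1.0,
    )
    singleton = rng.random(len(df)) < p_single
    ac = np.where(singleton, 1, 2 + rng.geometric(0.05, size=len(df)))
    an = rng.integers(int(0.85 * cfg.an_total), cfg.an_total + 1, size=len(df))
    ac = np.minimum(ac, an)
    df["ac"] = ac
    df["an"] = an
    df["ref"] = df["tri_context"].str[1]
    df["rf_prob"] = rng.uniform(0.5, 1.0, size=len(df))
    for flag in ("segdup", "lcr", "decoy"):
        df[flag] = False
    df["true_delta"] = delta
    return df.reset_index(drop=True)


def simulate_calibration_variants(
    rates: MutationRateTable,
    cfg: SimulationConfig,
    seed: int,
    n_per_context: int = 200,
) -> pd.DataFrame:
    """Synonymous-proxy training variants: one pool per (context, alt) key,
    singleton status exactly linear in the context rate (delta = 0)."""
    rng = np.random.default_rng(seed)
    rows = []
    for a in _NUCS:
        for b in _NUCS:
            for c in _NUCS:
                ctx = a + b + c
                for alt in _NUCS:
                    if alt == b:
                        continue
                    r = rates.rate(ctx, alt)
                    p = np.clip(cfg.singleton_intercept + cfg.singleton_slope * r, 0, 1)
                    singles = rng.random(n_per_context) < p
                    rows.append(
                        pd.DataFrame(
                            {
                                "tri_context": ctx,
                                "alt": alt,
                                "ac": np.where(singles, 1, 5),
                                "an": cfg.an_total,
                            }
                        )
                    )
    return pd.concat(rows, ignore_index=True)


def simulate_polymorphic_sites(
    positions: pd.DataFrame,
    table: HeptamerSubstitutionTable,
    seed: int,
    thinning: float = 1.0,
) -> set[tuple[str, int]]:
    """Neutral polymorphic sites: Bernoulli(cumulative probability) per
    position, optionally thinned to plant depletion."""
    rng = np.random.default_rng(seed)
    cum = table.cumulative_for(positions["heptamer"])
    p = np.nan_to_num(cum) * thinning
    hit = rng.random(len(positions)) < p
    return set(
        (c, int(p_)) for c, p_, h in zip(positions["chrom"], positions["pos"], hit) if h
    )


# ---------------------------------------------------------------------------
# functional layers
# ---------------------------------------------------------------------------


def _odds_to_prob(base_p: float, multiplier: float) -> float:
    o = base_p / (1 - base_p) * multiplier
    return o / (1 + o)


def simulate_eqtls(
    utr_positions: pd.DataFrame,
    in_pg4: np.ndarray,
    cfg: SimulationConfig,
    seed: int,
    n_snps: int = 4000,
) -> pd.DataFrame:
    """Tested cis-eQTL SNPs with significance enriched in pG4 on the odds scale.

    ``utr_positions`` needs chrom, pos, gene_id; ``in_pg4`` flags each row.
    Significance probability is ``eqtl_base_rate`` outside pG4 and the
    odds-multiplied rate inside, so the enrichment test's OR estimates
    ``eqtl_multiplier``.
    """
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(utr_positions), size=min(n_snps, len(utr_positions)), replace=False)
    df = utr_positions.iloc[idx].reset_index(drop=True).copy()
    pg4 = np.asarray(in_pg4)[idx]
    p_sig = np.where(
        pg4, _odds_to_prob(cfg.eqtl_base_rate, cfg.eqtl_multiplier), cfg.eqtl_base_rate
    )
    rows = []
    for t in range(cfg.n_tissues):
        sig = rng.random(len(df)) < p_sig
        pv = np.where(sig, rng.uniform(1e-12, 1e-5, len(df)), rng.uniform(0.1, 1.0, len(df)))
        rows.append(
            pd.DataFrame(
                {
                    "chrom": df["chrom"],
                    "pos": df["pos"],
                    "gene_id": df["gene_id"],
                    "tissue": f"tissue_{t}",
                    "p_value": pv,
                    "significant": sig,
                    "causal_candidate": sig & (rng.random(len(df)) < 0.3),
                    "in_pg4": pg4,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_direction_effects(
    n_effects: int, frac_tract: float, cfg: SimulationConfig, seed: int
) -> pd.DataFrame:
    """Significant variant-tissue effects inside pG4 motifs with a planted
    direction bias for G-tract positions."""
    rng = np.random.default_rng(seed)
    in_tract = rng.random(n_effects) < frac_tract
    p_pos = np.where(in_tract, cfg.tract_pos_prob, 0.5)
    sign = np.where(rng.random(n_effects) < p_pos, 1, -1)
    return pd.DataFrame({"in_tract": in_tract, "nes_sign": sign})


def simulate_clip_peaks(
    pg4_blocks: list[tuple[str, int, int]],
    non_pg4_blocks: list[tuple[str, int, int]],
    cfg: SimulationConfig,
    seed: int,
) -> pd.DataFrame:
    """IDR-passing CLIP peaks with pG4 density planted at the multiplier.

    Peak counts per class are Poisson(density * kb); each peak is placed
    entirely inside one randomly chosen block of its class, so merged-peak
    density per kb recovers ``clip_multiplier``. Two RBPs
    (``rbp_pg4_biased``) take a disproportionate share of pG4 peaks.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def _place(blocks, density, in_pg4):
        # deduplicate: the same genomic motif may recur across isoforms
        usable = [b for b in sorted(set(blocks)) if b[2] - b[1] > cfg.clip_peak_width]
        if not usable:
            return
        total_kb = sum(e - s for _, s, e in usable) / 1000
        n = rng.poisson(density * total_kb)
        weights = np.array([e - s for _, s, e in usable], dtype=float)
        weights /= weights.sum()
        for _ in range(n):
            chrom, s, e = usable[rng.choice(len(usable), p=weights)]
            start = int(rng.integers(s, e - cfg.clip_peak_width))
            if in_pg4 and rng.random() < 0.5:
                rbp = str(rng.choice(list(cfg.rbp_pg4_biased)))
            else:
                rbp = str(rng.choice(list(cfg.rbp_names)))
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + cfg.clip_peak_width,
                    "rbp_name": rbp,
                    "cell_line": str(rng.choice(["K562", "HepG2"])),
                    "idr_pass": True,
                }
            )

    _place(non_pg4_blocks, cfg.clip_base_density, False)
    _place(pg4_blocks, cfg.clip_base_density * cfg.clip_multiplier, True)
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "rbp_name", "cell_line", "idr_pass"]
    )


def simulate_knockdown_tables(
    gene_ids: list[str],
    pg4_genes: set[str],
    cfg: SimulationConfig,
    seed: int,
    rbps: tuple | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-RBP knockdown differential-expression tables.

    DE probability is odds-multiplied for pG4 genes; pG4 log2 fold changes
    skew negative (knockdown decreases pG4 gene expression).
    """
    rng = np.random.default_rng(seed)
    rbps = rbps or cfg.rbp_names
    is_pg4 = np.array([g in pg4_genes for g in gene_ids])
    p_de = np.where(
        is_pg4, _odds_to_prob(cfg.kd_base_rate, cfg.kd_multiplier), cfg.kd_base_rate
    )
    tables = {}
    for rbp in rbps:
        de = rng.random(len(gene_ids)) < p_de
        padj = np.where(de, rng.uniform(0, 0.049, len(gene_ids)), rng.uniform(0.06, 1, len(gene_ids)))
        mean_fc = np.where(is_pg4, -0.3, 0.0)
        log2fc = rng.normal(mean_fc, 0.5)
        tables[rbp] = pd.DataFrame(
            {"gene_id": gene_ids, "log2fc": log2fc, "padj": padj}
        )
    return tables


def simulate_clinvar(
    utr_positions: pd.DataFrame,
    in_pg4: np.ndarray,
    cfg: SimulationConfig,
    seed: int,
) -> tuple[pd.DataFrame, set[str]]:
    """ClinVar-style variant table with pG4 per-base density multiplied.

    Every gene also gets one Pathogenic coding-proxy variant so the whole
    gene set qualifies as disease-associated; the UTR variants under test are
    Uncertain_significance single-nucleotide records.
    """
    rng = np.random.default_rng(seed)
    rate = np.where(
        np.asarray(in_pg4), cfg.clinvar_base_rate * cfg.clinvar_multiplier, cfg.clinvar_base_rate
    )
    hit = rng.random(len(utr_positions)) < rate
    df = utr_positions[hit].copy()
    df["span"] = 1
    df["clnsig"] = "Uncertain_significance"
    genes = sorted(set(utr_positions["gene_id"]))
    anchor = pd.DataFrame(
        {
            "chrom": "chr0",
            "pos": np.arange(len(genes)),
            "gene_id": genes,
            "span": 1,
            "clnsig": "Pathogenic",
        }
    )
    out = pd.concat([df[["chrom", "pos", "gene_id", "span", "clnsig"]], anchor], ignore_index=True)
    return out, set(genes)


def simulate_ase_counts(
    cfg: SimulationConfig, seed: int, rho: float | None = None
) -> list:
    """Beta-binomial allele-count tables at the configured (rho, phi)."""
    from .allelic_imbalance import AlleleCountTable

    rng = np.random.default_rng(seed)
    rho = cfg.ase_rho if rho is None else rho
    phi = cfg.ase_dispersion
    tables = []
    for v in range(cfg.ase_n_variants):
        depth = np.maximum(1, rng.poisson(cfg.ase_depth_mean, size=cfg.ase_n_samples))
        if phi > 0:
            a = rho * (1 - phi) / phi
            b = (1 - rho) * (1 - phi) / phi
            p = rng.beta(a, b, size=cfg.ase_n_samples)
        else:
            p = np.full(cfg.ase_n_samples, rho)
        ref = rng.binomial(depth, p)
        tables.append(AlleleCountTable(f"var_{v}", ref, depth - ref))
    return tables
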