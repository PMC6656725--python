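"""Config-driven generator of a complete synthetic chromatin study.

Everything the pipeline consumes can be emitted here with planted ground
truth: a gene annotation (TSS table), replicate peak landscapes whose
histone marks respect the promoter/enhancer geometry the annotation module
expects, Poisson region counts with planted log2 effects, the three-way
conventional-/innate-memory differential structure behind the concordance
clusters, transcription-factor peaks with a pioneer factor pre-positioned
in the naive state, sequences with embedded motifs, expression tables and
bivariate cell intensities with a target Kendall tau.

Scale presets: the default (small) preset shrinks the study's printed
region counts roughly tenfold so the full pipeline runs in seconds; a
``paper_scale`` preset restores the printed magnitudes (9,814 promoters,
20,103 enhancers, 29,414 activity regions, 4,306 EOMES peaks) for realism
runs. Generation is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import TssRecord
from .cobinding import Pwm
from .diff import CountMatrix
from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "SimConfig",
    "GroundTruth",
    "Landscape",
    "default_test_pwm",
    "simulate_annotation",
    "simulate_peak_landscape",
    "simulate_counts",
    "simulate_comparison_counts",
    "simulate_sequences",
    "simulate_expression",
    "simulate_cells",
    "simulate_study",
]

COMPARISONS = ("lcmv", "listeria", "tim")

# which clusters carry a planted effect in each comparison (sign of beta)
_CLUSTER_EFFECTS: Dict[str, Dict[str, int]] = {
    "lcmv": {"C1": 1, "C2": 1, "C4": -1, "C5": -1},
    "listeria": {"C1": 1, "C2": 1, "C4": -1, "C5": -1},
    "tim": {"C2": 1, "C3": 1, "C5": -1, "C6": -1},
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Cluster compositions default to the printed gain-side 55/34/11 and
    loss-side 57/36/7 percentage splits; the naive-prebound pioneer-factor
    fraction defaults to 0.43 and the any-state co-binding fraction to
    0.65. Region counts default to roughly a tenth of the printed study
    scale.
    """

    seed: int = 0
    # annotation geometry
    n_genes: int = 400
    gene_spacing: int = 20_000
    chrom_names: Tuple[str, ...] = ("chr1", "chr2", "chr3")
    # landscape scale
    n_promoters: int = 300
    n_enhancers: int = 800
    h3k27ac_promoter_fraction: float = 0.9
    h3k27ac_enhancer_fraction: float = 0.9
    replicates: int = 2
    peak_jitter: int = 50  # per-sample boundary jitter (bp)
    promoter_peak_len: Tuple[int, int] = (600, 1500)
    enhancer_peak_len: Tuple[int, int] = (400, 1200)
    enhancer_tss_margin: int = 7000  # keeps enhancers clear of promoter space
    # differential structure
    effect_fraction: float = 0.10
    effect_log2fc: float = 2.0
    mu_range: Tuple[float, float] = (20.0, 500.0)
    library_size_base: int = 1_000_000
    library_size_jitter: float = 0.2
    overdispersion: float = 0.0  # gamma-Poisson shape 1/od when > 0
    # concordance clusters
    diff_enhancer_fraction: float = 0.4  # fraction of activity enhancers clustered
    cluster_composition_more: Tuple[float, float, float] = (0.55, 0.34, 0.11)
    cluster_composition_less: Tuple[float, float, float] = (0.57, 0.36, 0.07)
    # transcription factors
    eomes_peak_len: int = 200
    runx3_peak_len: int = 200
    runx3_offset: Tuple[int, int] = (20, 60)
    cobound_runx3_fraction: float = 0.65
    prebound_runx3_fraction: float = 0.43
    eomes_background_fraction: float = 0.10  # EOMES in non-C2/C3 enhancers
    # sequences
    seq_gc: float = 0.5
    motif_offset_sd: float = 20.0
    # expression
    expression_effect: float = 2.0
    expression_effect_sd: float = 0.5
    expression_min_abs_lfc: float = 1.25  # truncation keeps groups separable
    static_lfc_sd: float = 0.3
    static_max_abs_lfc: float = 0.95
    # cells
    n_cells: int = 1000
    tau_targets: Dict[str, float] = field(
        default_factory=lambda: {"control": 0.6, "deficient": 0.2}
    )
    cell_markers: Tuple[str, str] = ("EOMES", "CXCR3")

    def __post_init__(self) -> None:
        if not (0 < self.effect_fraction < 1):
            raise ValueError("effect_fraction must lie in (0, 1)")
        for comp in (self.cluster_composition_more, self.cluster_composition_less):
            if abs(sum(comp) - 1.0) > 1e-9:
                raise ValueError("cluster composition per side must sum to 1")
        if self.n_promoters > self.n_genes:
            raise ValueError("n_promoters cannot exceed n_genes")

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "SimConfig":
        """Preset matching the printed study magnitudes (slow)."""
        return cls(
            seed=seed,
            n_genes=11_000,
            n_promoters=9_814,
            n_enhancers=20_103,
            chrom_names=tuple(f"chr{i}" for i in range(1, 20)),
        )


def _rng(cfg_or_seed) -> np.random.Generator:
    seed = cfg_or_seed.seed if isinstance(cfg_or_seed, SimConfig) else cfg_or_seed
    return np.random.default_rng(seed)


@dataclass
class GroundTruth:
    """Planted truth: everything needed to score the pipeline.

    regions: per activity region — reg_class, cluster, per-comparison
    differential label, TF-bound and prebound flags. genes: per gene —
    expression group and true-target flag. sequences: planted motif offset
    and strand. cells: target tau per group.
    """

    regions: pd.DataFrame = field(default_factory=pd.DataFrame)
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    sequences: pd.DataFrame = field(default_factory=pd.DataFrame)
    cell_taus: Dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "regions": self.regions.to_dict(orient="list"),
            "genes": self.genes.to_dict(orient="list"),
            "sequences": self.sequences.to_dict(orient="list"),
            "cell_taus": self.cell_taus,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            regions=pd.DataFrame(payload["regions"]),
            genes=pd.DataFrame(payload["genes"]),
            sequences=pd.DataFrame(payload["sequences"]),
            cell_taus=payload["cell_taus"],
        )


@dataclass
class Landscape:
    """Synthetic peak landscape plus per-element planted classification."""

    tss: List[TssRecord]
    chrom_sizes: Dict[str, int]
    sample_sets: Dict[str, IntervalSet]  # "{mark}.{condition}.rep{k}" -> peaks
    elements: pd.DataFrame  # planted elements with reg_class/cluster/TF flags
    truth: GroundTruth


def default_test_pwm(length: int = 12, dominant: float = 0.97, seed: int = 7) -> Pwm:
    """A sharp synthetic PWM for plant-and-recover experiments.

    High information content (one base at ``dominant`` probability per
    position) so a planted consensus is essentially always the best hit.
    Synthetic stand-in for a curated database motif; not a biological PWM.
    """
    rng = np.random.default_rng(seed)
    consensus = rng.integers(0, 4, size=length)
    m = np.full((length, 4), (1 - dominant) / 3)
    m[np.arange(length), consensus] = dominant
    return Pwm(motif_id="synthetic_test_motif", matrix=m)


# ---------------------------------------------------------------------------
# annotation

def simulate_annotation(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> Tuple[List[TssRecord], Dict[str, int]]:
    """TSS positions uniform with minimum spacing, strands Bernoulli(1/2).

    Genes are distributed round-robin over the configured chromosomes;
    each chromosome is sized to hold its genes at twice the minimum
    spacing plus flanks. Packing infeasibility raises.
    """
    rng = rng if rng is not None else _rng(cfg)
    n_chrom = len(cfg.chrom_names)
    per_chrom = [
        cfg.n_genes // n_chrom + (1 if i < cfg.n_genes % n_chrom else 0)
        for i in range(n_chrom)
    ]
    flank = 2 * cfg.gene_spacing
    chrom_sizes = {
        ch: 2 * flank + 2 * cfg.gene_spacing * max(1, k)
        for ch, k in zip(cfg.chrom_names, per_chrom)
    }
    tss: List[TssRecord] = []
    gid = 0
    for ch, k in zip(cfg.chrom_names, per_chrom):
        if k == 0:
            continue
        usable = chrom_sizes[ch] - 2 * flank - (k - 1) * cfg.gene_spacing
        if usable < 0:
            raise ValueError(
                f"chromosome {ch} too small for {k} genes at spacing "
                f"{cfg.gene_spacing}"
            )
        offsets = np.sort(rng.uniform(0, usable, size=k))
        positions = flank + offsets + np.arange(k) * cfg.gene_spacing
        strands = rng.random(k) < 0.5
        for pos, plus in zip(positions, strands):
            tss.append(
                TssRecord(
                    gene_id=f"gene_{gid:05d}",
                    chrom=ch,
                    position=int(pos),
                    strand="+" if plus else "-",
                )
            )
            gid += 1
    return tss, chrom_sizes


def write_tss_table(tss: Sequence[TssRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in tss],
            "chrom": [t.chrom for t in tss],
            "position": [t.position for t in tss],
            "strand": [t.strand for t in tss],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# peak landscape

def _exact_counts(n: int, proportions: Sequence[float]) -> List[int]:
    """Largest-remainder apportionment: integer counts summing to n."""
    raw = [p * n for p in proportions]
    base = [int(np.floor(r)) for r in raw]
    short = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])  # largest remainder first
    for i in order[:short]:
        base[i] += 1
    return base


def _assign_clusters(
    n_enhancers: int, cfg: SimConfig, rng: np.random.Generator
) -> List[str]:
    """Deterministic cluster counts from the configured compositions.

    The differential fraction is split evenly between the gain and loss
    sides; within a side the composition is hit exactly (largest
    remainder), emulating a printed percentage split.
    """
    n_diff = int(round(cfg.diff_enhancer_fraction * n_enhancers))
    n_more = n_diff // 2
    n_less = n_diff - n_more
    labels = ["none"] * n_enhancers
    chosen = rng.choice(n_enhancers, size=n_diff, replace=False)
    more_idx, less_idx = chosen[:n_more], chosen[n_more:]
    for side_idx, comp, clusters in (
        (more_idx, cfg.cluster_composition_more, ("C1", "C2", "C3")),
        (less_idx, cfg.cluster_composition_less, ("C4", "C5", "C6")),
    ):
        counts = _exact_counts(len(side_idx), comp)
        pos = 0
        for c, k in zip(clusters, counts):
            for j in side_idx[pos : pos + k]:
                labels[j] = c
            pos += k
    return labels


def simulate_peak_landscape(
    cfg: SimConfig,
    tss: Sequence[TssRecord] | None = None,
    chrom_sizes: Dict[str, int] | None = None,
    rng: np.random.Generator | None = None,
) -> Landscape:
    """Plant promoters, enhancers, activity regions and TF peaks.

    H3K4me3 peaks sit inside strand-aware promoter windows of selected
    genes; H3K4me1 peaks sit in intergenic stretches at least
    ``enhancer_tss_margin`` bp from every TSS (comfortably beyond the 2 kb
    exclusion even after replicate jitter); H3K27ac peaks are overlaid
    inside a configured fraction of each element class. EOMES peaks go to
    cluster C2/C3 enhancers (plus a small background fraction elsewhere);
    RUNX3 peaks are co-placed at a 20-60 bp offset for the co-bound
    fraction in the memory state, and pre-placed in the naive state for the
    prebound fraction. Each replicate sample re-jitters peak boundaries by
    ±``peak_jitter`` bp.
    """
    rng = rng if rng is not None else _rng(cfg)
    if tss is None:
        tss, chrom_sizes = simulate_annotation(cfg, rng)
    assert chrom_sizes is not None

    # --- promoter elements (H3K4me3 inside the -5/+2 kb window)
    gene_idx = rng.choice(len(tss), size=cfg.n_promoters, replace=False)
    promoter_rows = []
    for i in sorted(gene_idx):
        t = tss[i]
        length = int(rng.integers(*cfg.promoter_peak_len))
        if t.strand == "+":
            lo, hi = t.position - 5000, t.position + 2000
        else:
            lo, hi = t.position - 2000, t.position + 5000
        pad = cfg.peak_jitter + 10  # jittered replicates must stay in-window
        lo, hi = max(0, lo) + pad, hi - pad
        start = int(rng.integers(lo, max(lo + 1, hi - length)))
        promoter_rows.append(
            {
                "element_id": f"prom_{len(promoter_rows):05d}",
                "reg_class": "promoter",
                "chrom": t.chrom,
                "start": start,
                "end": start + length,
                "gene_id": t.gene_id,
            }
        )

    # --- enhancer elements in inter-TSS gaps, clear of promoter space
    pos_by_chrom: Dict[str, List[int]] = {}
    for t in tss:
        pos_by_chrom.setdefault(t.chrom, []).append(t.position)
    gaps = []  # (chrom, lo, hi) usable stretches
    for ch, positions in pos_by_chrom.items():
        positions = sorted(positions)
        bounds = [0] + positions + [chrom_sizes[ch]]
        for a, b in zip(bounds[:-1], bounds[1:]):
            lo = a + cfg.enhancer_tss_margin
            hi = b - cfg.enhancer_tss_margin
            if hi - lo >= cfg.enhancer_peak_len[1] + 2 * cfg.peak_jitter + 200:
                gaps.append((ch, lo, hi))
    if not gaps:
        raise ValueError("no intergenic stretch can host an enhancer")
    per_gap = int(np.ceil(cfg.n_enhancers / len(gaps)))
    enhancer_rows = []
    for ch, lo, hi in gaps:
        if len(enhancer_rows) >= cfg.n_enhancers:
            break
        # evenly spaced slots inside the stretch, lightly jittered, so
        # enhancers never merge with one another after replicate jitter
        slot_w = (hi - lo) / per_gap
        if slot_w < cfg.enhancer_peak_len[1] + 4 * cfg.peak_jitter + 100:
            usable_slots = max(1, int((hi - lo) // (cfg.enhancer_peak_len[1] + 4 * cfg.peak_jitter + 100)))
        else:
            usable_slots = per_gap
        slot_w = (hi - lo) / usable_slots
        for s in range(usable_slots):
            if len(enhancer_rows) >= cfg.n_enhancers:
                break
            length = int(rng.integers(*cfg.enhancer_peak_len))
            margin = 2 * cfg.peak_jitter + 10
            s_lo = int(lo + s * slot_w) + margin
            s_hi = int(lo + (s + 1) * slot_w) - margin - length
            if s_hi <= s_lo:
                continue
            start = int(rng.integers(s_lo, s_hi))
            enhancer_rows.append(
                {
                    "element_id": f"enh_{len(enhancer_rows):05d}",
                    "reg_class": "enhancer",
                    "chrom": ch,
                    "start": start,
                    "end": start + length,
                    "gene_id": None,
                }
            )
    if len(enhancer_rows) < cfg.n_enhancers:
        raise ValueError(
            f"could only place {len(enhancer_rows)} of {cfg.n_enhancers} "
            "enhancers; enlarge chromosomes or lower n_enhancers"
        )

    elements = pd.DataFrame(promoter_rows + enhancer_rows)

    # --- H3K27ac activity overlay + concordance clusters on enhancers
    has_ac = np.zeros(len(elements), dtype=bool)
    is_prom = (elements["reg_class"] == "promoter").to_numpy()
    for mask, frac in (
        (is_prom, cfg.h3k27ac_promoter_fraction),
        (~is_prom, cfg.h3k27ac_enhancer_fraction),
    ):
        idx = np.flatnonzero(mask)
        take = rng.choice(idx, size=int(round(frac * len(idx))), replace=False)
        has_ac[take] = True
    elements["h3k27ac"] = has_ac

    ac_enh_idx = np.flatnonzero(has_ac & ~is_prom)
    cluster_labels = _assign_clusters(len(ac_enh_idx), cfg, rng)
    elements["cluster"] = "none"
    elements.loc[ac_enh_idx, "cluster"] = cluster_labels

    # --- transcription-factor peaks
    cluster_col = elements["cluster"].to_numpy()
    c23 = np.flatnonzero(np.isin(cluster_col, ("C2", "C3")))
    other_enh = np.flatnonzero(~is_prom & ~np.isin(cluster_col, ("C2", "C3")))
    n_bg = int(round(cfg.eomes_background_fraction * len(other_enh)))
    eomes_idx = np.concatenate(
        [c23, rng.choice(other_enh, size=n_bg, replace=False)]
    ) if len(other_enh) and n_bg else c23
    eomes_idx = np.sort(eomes_idx)
    elements["eomes"] = False
    elements.loc[eomes_idx, "eomes"] = True

    n_eomes = len(eomes_idx)
    n_cobound = int(round(cfg.cobound_runx3_fraction * n_eomes))
    n_prebound = int(round(cfg.prebound_runx3_fraction * n_eomes))
    if n_prebound > n_cobound:
        raise ValueError("prebound fraction cannot exceed co-bound fraction")
    perm = rng.permutation(n_eomes)
    cobound = eomes_idx[perm[:n_cobound]]
    prebound = eomes_idx[perm[:n_prebound]]  # prebound subset of co-bound
    elements["runx3_tim"] = False
    elements.loc[cobound, "runx3_tim"] = True
    elements["runx3_naive"] = False
    elements.loc[prebound, "runx3_naive"] = True

    # --- emit per-sample replicate peak sets
    def jittered(row, length_shrink: int = 0) -> GenomicInterval:
        j1 = int(rng.integers(-cfg.peak_jitter, cfg.peak_jitter + 1))
        j2 = int(rng.integers(-cfg.peak_jitter, cfg.peak_jitter + 1))
        start = max(0, int(row.start) + length_shrink + j1)
        end = int(row.end) - length_shrink + j2
        return GenomicInterval(row.chrom, start, max(start + 50, end))

    sample_sets: Dict[str, IntervalSet] = {}
    conditions = ("naive", "tim")
    prom_rows = elements[is_prom]
    enh_rows = elements[~is_prom]
    ac_rows = elements[elements["h3k27ac"]]
    for cond in conditions:
        for rep in range(1, cfg.replicates + 1):
            tag = f"{cond}.rep{rep}"
            sample_sets[f"H3K4me3.{tag}"] = IntervalSet(
                f"H3K4me3.{tag}", [jittered(r) for r in prom_rows.itertuples()]
            )
            sample_sets[f"H3K4me1.{tag}"] = IntervalSet(
                f"H3K4me1.{tag}", [jittered(r) for r in enh_rows.itertuples()]
            )
            sample_sets[f"H3K27ac.{tag}"] = IntervalSet(
                f"H3K27ac.{tag}", [jittered(r, length_shrink=60) for r in ac_rows.itertuples()]
            )

    def tf_peaks(idx: np.ndarray, offset: bool) -> List[GenomicInterval]:
        out = []
        for i in idx:
            row = elements.iloc[int(i)]
            center = (int(row.start) + int(row.end)) // 2
            if offset:
                shift = int(rng.integers(*cfg.runx3_offset)) * (
                    1 if rng.random() < 0.5 else -1
                )
                center += shift
                half = cfg.runx3_peak_len // 2
            else:
                half = cfg.eomes_peak_len // 2
            out.append(GenomicInterval(row.chrom, max(0, center - half), center + half))
        return out

    sample_sets["EOMES.tim"] = IntervalSet("EOMES.tim", tf_peaks(eomes_idx, offset=False))
    sample_sets["RUNX3.tim"] = IntervalSet("RUNX3.tim", tf_peaks(cobound, offset=True))
    sample_sets["RUNX3.naive"] = IntervalSet(
        "RUNX3.naive", tf_peaks(prebound, offset=True)
    )

    region_truth = elements.rename(columns={"element_id": "region_id"}).copy()
    for comp in COMPARISONS:
        effects = _CLUSTER_EFFECTS[comp]
        region_truth[f"label_{comp}"] = [
            {1: "up", -1: "down"}.get(effects.get(c, 0), "null")
            for c in region_truth["cluster"]
        ]
    truth = GroundTruth(regions=region_truth)
    return Landscape(
        tss=list(tss),
        chrom_sizes=dict(chrom_sizes),
        sample_sets=sample_sets,
        elements=elements,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# counts

def simulate_counts(
    n_regions: int,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    betas: np.ndarray | None = None,
    condition_names: Tuple[str, str] = ("memory", "naive"),
) -> Tuple[CountMatrix, np.ndarray]:
    """Poisson region counts with planted log2 effects.

    count(r, s) ~ Poisson(N_s / N_ref * mu_r * 2^(beta_r * x_s)) with x_s
    the treatment indicator, N_ref the smallest library size and mu_r
    log-uniform over ``mu_range``. When ``betas`` is omitted a fraction
    ``effect_fraction`` of regions gets ±``effect_log2fc``, signs split
    evenly. Returns the count matrix (treatment condition first) and the
    planted beta vector. ``overdispersion`` > 0 switches to gamma-Poisson
    mixing with that squared coefficient of variation.
    """
    rng = rng if rng is not None else _rng(cfg)
    if betas is None:
        betas = np.zeros(n_regions)
        n_eff = int(round(cfg.effect_fraction * n_regions))
        idx = rng.choice(n_regions, size=n_eff, replace=False)
        signs = np.where(np.arange(n_eff) % 2 == 0, 1.0, -1.0)
        betas[idx] = signs * cfg.effect_log2fc
    betas = np.asarray(betas, dtype=float)
    if len(betas) != n_regions:
        raise ValueError("betas length must equal n_regions")
    mu = np.exp(
        rng.uniform(np.log(cfg.mu_range[0]), np.log(cfg.mu_range[1]), size=n_regions)
    )
    samples = []
    conds = {}
    libs = []
    for cond, x in ((condition_names[0], 1.0), (condition_names[1], 0.0)):
        for rep in range(1, cfg.replicates + 1):
            sid = f"{cond}_rep{rep}"
            samples.append((sid, x))
            conds[sid] = cond
            libs.append(
                int(
                    cfg.library_size_base
                    * (1 + cfg.library_size_jitter * (2 * rng.random() - 1))
                )
            )
    libs = np.array(libs)
    n_ref = libs.min()
    counts = np.empty((n_regions, len(samples)), dtype=np.int64)
    for j, ((sid, x), N) in enumerate(zip(samples, libs)):
        lam = (N / n_ref) * mu * np.power(2.0, betas * x)
        if cfg.overdispersion > 0:
            shape = 1.0 / cfg.overdispersion
            lam = lam * rng.gamma(shape, 1.0 / shape, size=n_regions)
        counts[:, j] = rng.poisson(lam)
    m = CountMatrix(
        region_ids=[f"region_{i:05d}" for i in range(n_regions)],
        sample_ids=[s for s, _ in samples],
        counts=counts,
        library_sizes=libs,
        condition=conds,
    )
    return m, betas


def simulate_comparison_counts(
    truth: GroundTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> Dict[str, CountMatrix]:
    """One count matrix per memory comparison over the clustered enhancers.

    Effects follow the planted cluster labels: gain clusters are up in the
    comparisons where they apply, loss clusters down (see the concordance
    rule table). Region ids are the enhancer element ids.
    """
    rng = rng if rng is not None else _rng(cfg)
    regions = truth.regions[truth.regions["reg_class"] == "enhancer"]
    regions = regions[regions["h3k27ac"]]
    out = {}
    for comp in COMPARISONS:
        sign = regions[f"label_{comp}"].map({"up": 1.0, "down": -1.0}).fillna(0.0)
        betas = sign.to_numpy() * cfg.effect_log2fc
        m, _ = simulate_counts(
            len(regions),
            cfg,
            rng=rng,
            betas=betas,
            condition_names=("memory", "naive"),
        )
        m.region_ids = list(regions["region_id"])
        out[comp] = m
    return out


# ---------------------------------------------------------------------------
# sequences / expression / cells

_BASES = np.array(list("ACGT"))


def simulate_sequences(
    pwm: Pwm,
    n: int,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    length: int | None = None,
    plant: bool = True,
) -> Tuple[Dict[str, str], pd.DataFrame]:
    """IID background sequences with the motif consensus embedded.

    Offsets are Normal(center, motif_offset_sd) clipped to valid range;
    the reverse complement is planted with probability 1/2. ``plant=False``
    emits pure background for flatness controls.
    """
    rng = rng if rng is not None else _rng(cfg)
    L = len(pwm)
    length = length if length is not None else 2 * 250 + L - 1
    gc = cfg.seq_gc
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    consensus = pwm.consensus
    rc = consensus.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    seqs: Dict[str, str] = {}
    rows = []
    center_offset = (length - L) / 2.0
    for i in range(n):
        arr = _BASES[rng.choice(4, size=length, p=probs)]
        if plant:
            off = int(np.clip(round(rng.normal(center_offset, cfg.motif_offset_sd)), 0, length - L))
            minus = rng.random() < 0.5
            arr[off : off + L] = list(rc if minus else consensus)
            rows.append(
                {"seq_id": f"seq_{i:05d}", "offset": off, "strand": "-" if minus else "+"}
            )
        else:
            rows.append({"seq_id": f"seq_{i:05d}", "offset": -1, "strand": "."})
        seqs[f"seq_{i:05d}"] = "".join(arr)
    return seqs, pd.DataFrame(rows)


def simulate_expression(
    gene_ids: Sequence[str],
    target_up: Sequence[str],
    target_down: Sequence[str],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Gene LFC/q table: targets get |lfc| ~ truncated Normal(2, 0.5)
    (|lfc| >= 1.25) with q ~ U(0, 0.01); static genes Normal(0, 0.3)
    truncated to |lfc| <= 0.95 with q ~ U(0.2, 1), so thresholding at
    q < 0.05, |lfc| > 1 recovers the groups exactly."""
    rng = rng if rng is not None else _rng(cfg)
    up, down = set(target_up), set(target_down)
    rows = []
    for g in gene_ids:
        if g in up or g in down:
            mag = 0.0
            while mag < cfg.expression_min_abs_lfc:
                mag = abs(rng.normal(cfg.expression_effect, cfg.expression_effect_sd))
            lfc = mag if g in up else -mag
            q = rng.uniform(0, 0.01)
            group = "up" if g in up else "down"
        else:
            lfc = cfg.static_max_abs_lfc + 1
            while abs(lfc) > cfg.static_max_abs_lfc:
                lfc = rng.normal(0, cfg.static_lfc_sd)
            q = rng.uniform(0.2, 1.0)
            group = "static"
        rows.append({"gene_id": g, "log2fc": lfc, "q": q, "group": group})
    return pd.DataFrame(rows)


def simulate_cells(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Bivariate cell intensities per group with a target Kendall tau.

    Gaussian copula with rho = sin(pi * tau / 2), lognormal marginals.
    """
    rng = rng if rng is not None else _rng(cfg)
    rows = []
    m1, m2 = cfg.cell_markers
    for group, tau in cfg.tau_targets.items():
        if not (-1 < tau < 1):
            raise ValueError("target tau must lie in (-1, 1)")
        rho = np.sin(np.pi * tau / 2.0)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        z = rng.multivariate_normal([0, 0], cov, size=cfg.n_cells)
        intensities = np.exp(1.0 + 0.5 * z) * 100.0
        for i in range(cfg.n_cells):
            rows.append(
                {
                    "cell_id": f"{group}_{i:05d}",
                    "group": group,
                    m1: intensities[i, 0],
                    m2: intensities[i, 1],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full study

def simulate_study(cfg: SimConfig, outdir: str | Path) -> GroundTruth:
    """Generate and write the complete synthetic study under ``outdir``.

    Emits: TSS TSV, per-sample BED peak files, per-comparison counts +
    samples TSVs, motif FASTA, expression TSVs, cells TSV, the ground-truth
    manifest JSON and the config as YAML.
    """
    import yaml

    from .intervals import write_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(cfg)
    tss, chrom_sizes = simulate_annotation(cfg, rng)
    write_tss_table(tss, outdir / "tss.tsv")
    land = simulate_peak_landscape(cfg, tss, chrom_sizes, rng)
    (outdir / "peaks").mkdir(exist_ok=True)
    for name, s in land.sample_sets.items():
        write_bed(s, outdir / "peaks" / f"{name}.bed")

    counts = simulate_comparison_counts(land.truth, cfg, rng)
    (outdir / "counts").mkdir(exist_ok=True)
    for comp, m in counts.items():
        df = pd.DataFrame(m.counts, columns=m.sample_ids)
        df.insert(0, "region_id", m.region_ids)
        df.to_csv(outdir / "counts" / f"{comp}.counts.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "sample_id": m.sample_ids,
                "condition": [m.condition[s] for s in m.sample_ids],
                "library_size": m.library_sizes,
            }
        ).to_csv(outdir / "counts" / f"{comp}.samples.tsv", sep="\t", index=False)

    pwm = default_test_pwm()
    seqs, seq_truth = simulate_sequences(pwm, n=500, cfg=cfg, rng=rng)
    with open(outdir / "sequences.fasta", "w") as fh:
        for sid, s in seqs.items():
            fh.write(f">{sid}\n{s}\n")

    # expression: genes nearest to EOMES-bound gain enhancers are up targets
    el = land.elements
    eomes_gain = el[(el["eomes"]) & (el["cluster"].isin(["C2", "C3"]))]
    pos_by_gene = {t.gene_id: (t.chrom, t.position) for t in tss}
    target_up: List[str] = []
    for r in eomes_gain.itertuples():
        center = (r.start + r.end) / 2
        best = None
        for g, (ch, p) in pos_by_gene.items():
            if ch != r.chrom:
                continue
            d = abs(p - center)
            if best is None or (d, g) < best:
                best = (d, g)
        if best:
            target_up.append(best[1])
    target_up = sorted(set(target_up))
    remaining = [t.gene_id for t in tss if t.gene_id not in set(target_up)]
    target_down = remaining[: max(10, len(target_up) // 2)]
    expr = simulate_expression(
        [t.gene_id for t in tss], target_up, target_down, cfg, rng
    )
    expr[["gene_id", "log2fc", "q"]].to_csv(
        outdir / "expression.tim.tsv", sep="\t", index=False
    )

    cells = simulate_cells(cfg, rng)
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)

    truth = land.truth
    truth.genes = expr[["gene_id", "group"]].assign(
        true_target=expr["gene_id"].isin(set(target_up) | set(target_down))
    )
    truth.sequences = seq_truth
    truth.cell_taus = dict(cfg.tau_targets)
    truth.to_json(outdir / "ground_truth.json")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {k: _yamlable(v) for k, v in dataclasses.asdict(cfg).items()}, fh
        )
    return truth


def _yamlable(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, dict):
        return {k: _yamlable(x) for k, x in v.items()}
    return v
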