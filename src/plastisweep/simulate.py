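"""Synthetic data generators with full ground truth.

Two generators back the whole pipeline:

* :func:`simulate_counts` draws negative-binomial miRNA/mRNA count
  matrices over the reciprocal-transplant design, planting environment-,
  breed- and interaction-driven features whose identities and effect
  directions are recorded in a :class:`SyntheticTruth`.
* :func:`simulate_genotypes` draws two diverged diploid populations of
  independent biallelic SNPs on one synthetic chromosome, planting
  high-differentiation windows with a controlled allele-frequency gap.

Both are fully deterministic given their seed, and every dataset can be
round-tripped through the module's own writers and readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignError, GROUPS, make_design, validate_design

FEATURE_CLASSES = ("NULL", "EN", "BR", "INT")


@dataclass
class CountSimParams:
    """Parameters of the NB count simulator.

    The negative binomial is parameterized by mean and dispersion phi,
    with variance mu + phi * mu**2 (phi = 0 recovers Poisson). Baseline
    per-feature means are drawn log-uniformly (log2 scale) at a reference
    library size; per-sample means scale with the planted library size.
    """

    n_features: int = 2000
    n_reps: int = 3
    baseline_log2_mean_range: tuple[float, float] = (4.0, 10.0)
    dispersion: float = 0.05
    frac_en: float = 0.1
    frac_br: float = 0.1
    frac_int: float = 0.05
    effect_log2fc: float = 2.0
    lib_size_range: tuple[int, int] = (800_000, 1_200_000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_features < 1 or self.n_reps < 1:
            raise ValueError("n_features and n_reps must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name in ("frac_en", "frac_br", "frac_int"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_en + self.frac_br + self.frac_int > 1.0 + 1e-12:
            raise ValueError("frac_en + frac_br + frac_int must be <= 1")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")
        lo, hi = self.lib_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("lib_size_range must be a positive interval")


@dataclass
class GenotypeSimParams:
    """Parameters of the two-population genotype simulator.

    Neutral sites share one allele frequency drawn from Beta(beta_a,
    beta_b) (clipped away from fixation) for both populations; sites
    inside planted diverged windows have the populations' frequencies
    pushed apart symmetrically by ``diverged_delta`` (p +/- delta/2,
    clipped to [0.02, 0.98] so both stay polymorphic). Genotypes are
    unphased diploid Binomial(2, p) draws per individual; sites are
    unlinked.
    """

    n_pop1: int = 10
    n_pop2: int = 10
    chrom_length: int = 2_000_000
    snp_density: float = 0.01
    n_diverged_windows: int = 5
    diverged_window_span: int = 40_000
    beta_a: float = 0.8
    beta_b: float = 0.8
    diverged_delta: float = 0.6
    missing_rate: float = 0.0
    chrom: str = "chr1"
    pop1: str = "TIB"
    pop2: str = "PX"
    seed: int = 0

    def validate(self) -> None:
        if self.n_pop1 < 1 or self.n_pop2 < 1:
            raise ValueError("population sizes must be positive")
        if self.chrom_length < 1:
            raise ValueError("chrom_length must be positive")
        if self.snp_density * self.chrom_length < 1:
            raise ValueError("snp_density * chrom_length must be >= 1 (no sites)")
        if not 0.0 <= self.diverged_delta <= 0.96:
            raise ValueError("diverged_delta must be in [0, 0.96]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        span_total = self.n_diverged_windows * self.diverged_window_span
        if span_total > self.chrom_length:
            raise ValueError("planted windows do not fit on the chromosome")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the simulators.

    ``feature_class`` maps feature -> {NULL, EN, BR, INT};
    ``effect_direction`` maps feature -> +1/-1 (sign of the high-altitude
    or Tibetan-breed effect; 0 for NULL features); ``lib_sizes`` records
    the planted per-sample library scale. ``diverged_windows`` holds the
    planted (start, end) intervals (1-based inclusive) for the genotype
    simulator; everything outside them is NEUTRAL.
    """

    feature_class: pd.Series | None = None
    effect_direction: pd.Series | None = None
    lib_sizes: pd.Series | None = None
    diverged_windows: pd.DataFrame | None = None

    def window_class(self, start: int, end: int) -> str:
        """Classify a query window (1-based inclusive) by overlap with planted spans."""
        if self.diverged_windows is None or self.diverged_windows.empty:
            return "NEUTRAL"
        dw = self.diverged_windows
        hit = (dw["start"] <= end) & (dw["end"] >= start)
        return "DIVERGED" if bool(hit.any()) else "NEUTRAL"

    def window_overlap_class(self, start: int, end: int) -> str:
        """Three-way window classification for recovery scoring.

        DIVERGED when the window lies entirely inside one planted span,
        NEUTRAL when it overlaps none, PARTIAL otherwise (mixed content;
        ambiguous for recovery/false-call scoring).
        """
        if self.diverged_windows is None or self.diverged_windows.empty:
            return "NEUTRAL"
        dw = self.diverged_windows
        inside = (dw["start"] <= start) & (dw["end"] >= end)
        if bool(inside.any()):
            return "DIVERGED"
        hit = (dw["start"] <= end) & (dw["end"] >= start)
        return "PARTIAL" if bool(hit.any()) else "NEUTRAL"


@dataclass
class CountMatrix:
    """Integer feature x sample count table with its design metadata."""

    counts: pd.DataFrame  # features x samples, non-negative ints
    design: pd.DataFrame  # one row per sample (design.DESIGN_COLUMNS)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.counts.columns) != list(self.design["sample_id"]):
            raise ValueError("count matrix columns must match design sample_ids in order")
        if self.counts.index.duplicated().any():
            raise ValueError("feature ids must be unique")

    def subset_tissue(self, tissue: str) -> "CountMatrix":
        sub = self.design[self.design["tissue"] == tissue].reset_index(drop=True)
        if sub.empty:
            raise DesignError(f"no samples for tissue {tissue!r}")
        return CountMatrix(self.counts[list(sub["sample_id"])], sub)

    def samples_of_group(self, group: str) -> list[str]:
        return list(self.design.loc[self.design["group"] == group, "sample_id"])


def _assign_classes(rng: np.random.Generator, params: CountSimParams) -> tuple[np.ndarray, np.ndarray]:
    n = params.n_features
    n_en = int(round(params.frac_en * n))
    n_br = int(round(params.frac_br * n))
    n_int = int(round(params.frac_int * n))
    classes = np.array(["NULL"] * n, dtype=object)
    order = rng.permutation(n)
    classes[order[:n_en]] = "EN"
    classes[order[n_en : n_en + n_br]] = "BR"
    classes[order[n_en + n_br : n_en + n_br + n_int]] = "INT"
    direction = np.where(classes == "NULL", 0, rng.choice([-1, 1], size=n))
    return classes, direction


def simulate_counts(
    params: CountSimParams, design: pd.DataFrame | None = None
) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw an NB count matrix over a factorial design, with planted effects.

    EN-class features shift their mean by ``effect_log2fc`` log2 units in
    HIGH vs LOW samples regardless of breed; BR-class between breeds
    regardless of environment; INT-class only in the (TIB, HIGH) cell.
    A positive direction means higher expression at high altitude (EN,
    INT) or in the Tibetan breed (BR).
    """
    params.validate()
    if design is None:
        design = make_design(n_reps=params.n_reps)
    validate_design(design, min_reps=2)

    rng = np.random.default_rng(params.seed)
    n = params.n_features
    lo, hi = params.baseline_log2_mean_range
    base_mean = 2.0 ** rng.uniform(lo, hi, size=n)
    classes, direction = _assign_classes(rng, params)

    lib_lo, lib_hi = params.lib_size_range
    lib_sizes = rng.integers(lib_lo, lib_hi + 1, size=len(design)).astype(float)
    ref_lib = 0.5 * (lib_lo + lib_hi)

    fc = 2.0 ** (direction * params.effect_log2fc)
    is_en = classes == "EN"
    is_br = classes == "BR"
    is_int = classes == "INT"

    features = [f"feat{i:05d}" for i in range(n)]
    counts = np.empty((n, len(design)), dtype=np.int64)
    for j, (_, row) in enumerate(design.iterrows()):
        mult = np.ones(n)
        if row["env"] == "HIGH":
            mult = np.where(is_en, fc, mult)
        if row["breed"] == "TIB":
            mult = np.where(is_br, fc, mult)
        if row["breed"] == "TIB" and row["env"] == "HIGH":
            mult = np.where(is_int, fc, mult)
        mu = base_mean * mult * (lib_sizes[j] / ref_lib)
        if params.dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / params.dispersion
            p = r / (r + mu)
            counts[:, j] = rng.negative_binomial(r, p)

    cm = CountMatrix(
        pd.DataFrame(counts, index=features, columns=list(design["sample_id"])),
        design.reset_index(drop=True),
    )
    truth = SyntheticTruth(
        feature_class=pd.Series(classes, index=features, name="class"),
        effect_direction=pd.Series(direction, index=features, name="direction"),
        lib_sizes=pd.Series(lib_sizes, index=list(design["sample_id"]), name="lib_size"),
    )
    return cm, truth


@dataclass
class VariantTable:
    """Biallelic diploid genotypes for one or more chromosomes.

    ``gt`` holds alt-allele dosage per site x sample (0, 1, 2; -1 for
    missing). Positions are 1-based and strictly increasing within a
    chromosome.
    """

    chrom: np.ndarray  # str per site
    pos: np.ndarray  # int per site
    gt: np.ndarray  # (n_sites, n_samples) int8
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")


def simulate_genotypes(params: GenotypeSimParams) -> tuple[VariantTable, SyntheticTruth, dict[str, str]]:
    """Draw two populations of unlinked biallelic SNPs with planted divergence.

    Returns the variant table, the truth (planted diverged windows), and
    the sample -> population map.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    n_sites = int(params.snp_density * params.chrom_length)
    pos = np.sort(rng.choice(params.chrom_length, size=n_sites, replace=False)) + 1

    # planted windows on a grid of span-width slots => non-overlapping
    span = params.diverged_window_span
    n_slots = params.chrom_length // span
    if params.n_diverged_windows > 0:
        slots = np.sort(rng.choice(n_slots, size=params.n_diverged_windows, replace=False))
        starts = slots * span + 1
        dw = pd.DataFrame({"start": starts, "end": starts + span - 1})
    else:
        dw = pd.DataFrame(columns=["start", "end"], dtype=int)

    p_shared = np.clip(rng.beta(params.beta_a, params.beta_b, size=n_sites), 0.05, 0.95)
    p1 = p_shared.copy()
    p2 = p_shared.copy()
    if params.diverged_delta > 0 and not dw.empty:
        in_dw = np.zeros(n_sites, dtype=bool)
        for _, w in dw.iterrows():
            in_dw |= (pos >= w["start"]) & (pos <= w["end"])
        half = params.diverged_delta / 2.0
        p1[in_dw] = np.clip(p_shared[in_dw] + half, 0.02, 0.98)
        p2[in_dw] = np.clip(p_shared[in_dw] - half, 0.02, 0.98)
    if params.diverged_delta == 0:
        dw = pd.DataFrame(columns=["start", "end"], dtype=int)

    g1 = rng.binomial(2, p1[:, None], size=(n_sites, params.n_pop1))
    g2 = rng.binomial(2, p2[:, None], size=(n_sites, params.n_pop2))
    gt = np.concatenate([g1, g2], axis=1).astype(np.int8)
    if params.missing_rate > 0:
        mask = rng.random(gt.shape) < params.missing_rate
        gt[mask] = -1

    samples = [f"{params.pop1}_{i + 1}" for i in range(params.n_pop1)] + [
        f"{params.pop2}_{i + 1}" for i in range(params.n_pop2)
    ]
    popmap = {s: params.pop1 for s in samples[: params.n_pop1]}
    popmap.update({s: params.pop2 for s in samples[params.n_pop1 :]})

    vt = VariantTable(
        chrom=np.array([params.chrom] * n_sites, dtype=object),
        pos=pos.astype(np.int64),
        gt=gt,
        samples=samples,
    )
    truth = SyntheticTruth(diverged_windows=dw.reset_index(drop=True))
    return vt, truth, popmap


# ---------------------------------------------------------------------------
# writers / readers

def write_counts(cm: CountMatrix, counts_path, design_path) -> None:
    df = cm.counts.copy()
    df.index.name = "feature"
    df.to_csv(counts_path, sep="\t")
    cm.design.to_csv(design_path, sep="\t", index=False)


def read_counts(counts_path, design_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    design = pd.read_csv(design_path, sep="\t", comment="#", dtype={"sample_id": str})
    return CountMatrix(counts, design)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(vt: VariantTable, path, contig_length: int | None = None) -> None:
    """Write a minimal uncompressed VCF 4.2 (GT only)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(pd.Series(vt.chrom)):
            if contig_length is not None:
                fh.write(f"##contig=<ID={c},length={contig_length}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(vt.samples) + "\n")
        for i in range(len(vt.pos)):
            gts = "\t".join(_GT_STR[int(g)] for g in vt.gt[i])
            fh.write(f"{vt.chrom[i]}\t{vt.pos[i]}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def write_popmap(popmap: dict[str, str], path) -> None:
    with Path(path).open("w") as fh:
        for sample, pop in popmap.items():
            fh.write(f"{sample}\t{pop}\n")


def simulate_gene_annotation(
    chrom: str,
    chrom_length: int,
    gene_length: int = 20_000,
    gene_spacing: int = 50_000,
) -> pd.DataFrame:
    """Regularly spaced synthetic gene intervals (1-based inclusive)."""
    rows = []
    start = 1 + gene_spacing // 2
    i = 0
    while start + gene_length - 1 <= chrom_length:
        rows.append(
            {"chrom": chrom, "start": start, "end": start + gene_length - 1, "gene_id": f"gene{i:04d}"}
        )
        start += gene_spacing
        i += 1
    return pd.DataFrame(rows)


def write_bed(genes: pd.DataFrame, path) -> None:
    """Write gene intervals as BED (0-based half-open)."""
    with Path(path).open("w") as fh:
        for _, g in genes.iterrows():
            fh.write(f"{g['chrom']}\t{g['start'] - 1}\t{g['end']}\t{g['gene_id']}\n")
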