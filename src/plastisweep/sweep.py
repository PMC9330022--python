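"""Two-population windowed selective-sweep scan.

Per-site Weir & Cockerham (1984) variance components are aggregated over
40-kb sliding windows (20-kb step) as a ratio of sums, giving a window
Fst; per-population nucleotide diversity pi uses the unbiased per-site
heterozygosity 2p(1-p) * 2n/(2n-1) divided by the window span, and the
pi ratio (pop2 over pop1, with pop1 the putatively selected population)
localizes diversity loss. Windows at Fst >= 0.3 are merged into
candidate sweep regions and annotated with overlapping gene intervals.

A Hudson-style estimator is available as an alternative; the Weir &
Cockerham form is the default. Negative window Fst is clamped to 0 for
thresholding while the raw value is retained in the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .simulate import VariantTable

DEFAULT_WINDOW = 40_000
DEFAULT_STEP = 20_000
DEFAULT_FST_MIN = 0.3


# ---------------------------------------------------------------------------
# input readers


def read_vcf(path) -> VariantTable:
    """Read a biallelic-SNP VCF into alt-allele dosages (cyvcf2 backend)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, positions, rows = [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            continue  # biallelic only
        chroms.append(v.CHROM)
        positions.append(v.POS)
        g = v.gt_types.astype(np.int8)  # gts012: 0,1,2 dosage; 3 unknown
        g[g == 3] = -1
        rows.append(g)
    if not rows:
        return VariantTable(np.array([], dtype=object), np.array([], dtype=np.int64),
                            np.zeros((0, len(samples)), dtype=np.int8), samples)
    return VariantTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        gt=np.vstack(rows),
        samples=samples,
    )


def read_popmap(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], comment="#")
    return dict(zip(df["sample"].astype(str), df["population"].astype(str)))


def read_bed(path) -> pd.DataFrame:
    """Gene intervals from BED (0-based half-open -> 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError("BED needs >= 3 columns")
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": df[1].astype(int) + 1,
            "end": df[2].astype(int),
        }
    )
    out["gene_id"] = (
        df[3].astype(str) if df.shape[1] > 3 else [f"interval{i}" for i in range(len(df))]
    )
    return out


def read_gff(path) -> pd.DataFrame:
    """Gene intervals from GFF3 (1-based inclusive), feature type 'gene'."""
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError("malformed GFF line (need 9 columns)")
            if f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
            rows.append(
                {"chrom": f[0], "start": int(f[3]), "end": int(f[4]), "gene_id": gid}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def read_annotation(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return read_bed(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return read_gff(path)
    raise ValueError(f"unknown annotation format: {path.suffix!r} (use .bed or .gff/.gff3)")


# ---------------------------------------------------------------------------
# per-site statistics


def _pop_site_stats(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n called diploids, alt frequency, het proportion) per site for one pop."""
    called = gt >= 0
    n = called.sum(axis=1).astype(float)
    het = np.where(called, gt == 1, False).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(called, gt, 0).sum(axis=1) / (2 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def site_fst_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) two-population variance components per site.

    Returns (a, a + b + c) arrays; sites monomorphic across both
    populations, or with < 1 called diploid in either population, give
    (0, 0) and are thereby skipped by the ratio-of-sums aggregation.
    """
    n1 = np.asarray(n1, float); n2 = np.asarray(n2, float)
    p1 = np.asarray(p1, float); p2 = np.asarray(p2, float)
    h1 = np.asarray(h1, float); h2 = np.asarray(h2, float)
    r = 2.0
    valid = (n1 >= 1) & (n2 >= 1)
    pbar_all = np.where(valid, (n1 * p1 + n2 * p2) / np.maximum(n1 + n2, 1), 0.0)
    poly = valid & (pbar_all > 0) & (pbar_all < 1)

    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        denom = a + b + c
    a = np.where(poly, a, 0.0)
    denom = np.where(poly, denom, 0.0)
    return np.nan_to_num(a), np.nan_to_num(denom)


def hudson_fst_components(
    n1: np.ndarray, p1: np.ndarray, n2: np.ndarray, p2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hudson-style numerator/denominator per site (allele counts 2n)."""
    n1 = np.asarray(n1, float) * 2
    n2 = np.asarray(n2, float) * 2
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    valid = (n1 >= 2) & (n2 >= 2)
    pbar = np.where(valid, (n1 * p1 + n2 * p2) / np.maximum(n1 + n2, 1), 0.0)
    poly = valid & (pbar > 0) & (pbar < 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    return np.nan_to_num(np.where(poly, num, 0.0)), np.nan_to_num(np.where(poly, den, 0.0))


def site_pi_terms(n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity 2p(1-p) * 2n/(2n-1); NaN where n < 1."""
    n = np.asarray(n, float)
    p = np.asarray(p, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        term = 2 * p * (1 - p) * (2 * n / (2 * n - 1))
    return np.where(n >= 1, term, np.nan)


# ---------------------------------------------------------------------------
# windows


def make_windows(
    chrom_lengths: dict[str, int],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> pd.DataFrame:
    """Sliding windows starting at 1, 1+step, ...; the final partial
    window is retained and flagged."""
    if not (window >= step > 0):
        raise ValueError("need window >= step > 0")
    rows = []
    for chrom, length in chrom_lengths.items():
        start = 1
        while start <= length:
            end = start + window - 1
            rows.append(
                {"chrom": chrom, "start": start, "end": end, "partial": end > length}
            )
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])


def window_fst(num: np.ndarray, den: np.ndarray) -> tuple[float, float]:
    """Ratio-of-sums window Fst; (raw, clamped to [0, 1]); NaN when no
    polymorphic site contributes."""
    s_num, s_den = float(np.sum(num)), float(np.sum(den))
    if s_den == 0:
        return np.nan, np.nan
    raw = s_num / s_den
    return raw, float(np.clip(raw, 0.0, 1.0))


def scan_windows(
    vt: VariantTable,
    popmap: dict[str, str],
    pop1: str,
    pop2: str,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    chrom_lengths: dict[str, int] | None = None,
    estimator: str = "wc",
) -> pd.DataFrame:
    """Windowed Fst / pi scan over all chromosomes in the variant table.

    pop1 is the putatively selected population; pi_ratio = pi_pop2 /
    pi_pop1 (NaN where the denominator is 0). ``estimator`` is "wc"
    (Weir & Cockerham, default) or "hudson".
    """
    if estimator not in ("wc", "hudson"):
        raise ValueError(f"unknown Fst estimator {estimator!r}")
    idx1 = [i for i, s in enumerate(vt.samples) if popmap.get(s) == pop1]
    idx2 = [i for i, s in enumerate(vt.samples) if popmap.get(s) == pop2]
    if not idx1 or not idx2:
        raise ValueError(f"populations {pop1!r}/{pop2!r} not found in popmap")

    if chrom_lengths is None:
        chrom_lengths = {
            str(c): int(vt.pos[vt.chrom == c].max()) if (vt.chrom == c).any() else 0
            for c in pd.unique(pd.Series(vt.chrom))
        }
    windows = make_windows(chrom_lengths, window, step)

    n1, p1, h1 = _pop_site_stats(vt.gt[:, idx1]) if len(vt.pos) else (None, None, None)
    n2, p2, h2 = _pop_site_stats(vt.gt[:, idx2]) if len(vt.pos) else (None, None, None)
    if len(vt.pos):
        if estimator == "wc":
            num, den = site_fst_components(n1, p1, h1, n2, p2, h2)
        else:
            num, den = hudson_fst_components(n1, p1, n2, p2)
        pi1_terms = site_pi_terms(n1, p1)
        pi2_terms = site_pi_terms(n2, p2)

    out = []
    for _, w in windows.iterrows():
        span = w["end"] - w["start"] + 1
        if len(vt.pos):
            in_w = (vt.chrom == w["chrom"]) & (vt.pos >= w["start"]) & (vt.pos <= w["end"])
        else:
            in_w = np.zeros(0, dtype=bool)
        n_sites = int(in_w.sum())
        if n_sites:
            raw, clamped = window_fst(num[in_w], den[in_w])
            pi_1 = float(np.nansum(pi1_terms[in_w])) / span
            pi_2 = float(np.nansum(pi2_terms[in_w])) / span
        else:
            raw = clamped = np.nan
            pi_1 = pi_2 = 0.0
        pi_ratio = pi_2 / pi_1 if pi_1 > 0 else np.nan
        out.append(
            {
                "chrom": w["chrom"],
                "start": int(w["start"]),
                "end": int(w["end"]),
                "partial": bool(w["partial"]),
                "n_sites": n_sites,
                "fst_raw": raw,
                "fst": clamped,
                "pi_pop1": pi_1,
                "pi_pop2": pi_2,
                "pi_ratio": pi_ratio,
            }
        )
    return pd.DataFrame(out)


def call_regions(
    windows: pd.DataFrame,
    fst_threshold: float = DEFAULT_FST_MIN,
    include_partial: bool = False,
) -> pd.DataFrame:
    """Merge qualifying windows (Fst >= threshold) into sweep regions.

    Overlapping or book-ended windows on the same chromosome merge;
    region span is the union of member windows. Partial terminal windows
    are excluded by default.
    """
    q = windows[windows["fst"].notna() & (windows["fst"] >= fst_threshold)]
    if not include_partial:
        q = q[~q["partial"]]
    regions = []
    for chrom, sub in q.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur = None
        for _, w in sub.iterrows():
            if cur is not None and w["start"] <= cur["end"] + 1:
                cur["end"] = max(cur["end"], int(w["end"]))
                cur["n_windows"] += 1
                cur["peak_fst"] = max(cur["peak_fst"], float(w["fst"]))
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": int(w["start"]),
                    "end": int(w["end"]),
                    "n_windows": 1,
                    "peak_fst": float(w["fst"]),
                }
        if cur is not None:
            regions.append(cur)
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "n_windows", "peak_fst"])


def annotate_regions(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Attach gene ids overlapping each region by >= 1 bp.

    ``genes`` must use 1-based inclusive coordinates (see
    :func:`read_bed` / :func:`read_gff`). A gene spanning several
    regions is attached to each; unique-gene totals deduplicate.
    """
    trees: dict[str, IntervalTree] = {}
    for _, g in genes.iterrows():
        # interval tree is half-open; end + 1 makes the inclusive end queryable
        trees.setdefault(str(g["chrom"]), IntervalTree()).addi(
            int(g["start"]), int(g["end"]) + 1, str(g["gene_id"])
        )
    gene_lists = []
    for _, r in regions.iterrows():
        tree = trees.get(str(r["chrom"]))
        if tree is None:
            gene_lists.append([])
            continue
        hits = tree.overlap(int(r["start"]), int(r["end"]) + 1)
        gene_lists.append(sorted({iv.data for iv in hits}))
    out = regions.copy()
    out["genes"] = gene_lists
    return out


def unique_genes(annotated: pd.DataFrame) -> list[str]:
    return sorted({g for gl in annotated["genes"] for g in gl})
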