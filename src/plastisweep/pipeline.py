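"""End-to-end orchestration with a validated config file.

``run_transcriptome`` composes normalization -> exact-test DE -> the
effective/ineffective intersection screen -> two-way ANOVA per tissue,
writing every intermediate (normalization factors, per-comparison
tables, the UpSet-style membership table, candidates, ANOVA). A
membership-injection mode accepts per-tissue signed membership tables
directly and bypasses the DE stage, so reported screen structures can be
replayed without the original sequencing data. ``run_sweep`` composes
the windowed Fst / pi scan, region calling and gene annotation.

Every output TSV carries a header comment with the tool version, a
config hash, and the seed. All stages are deterministic given their
inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .anova import classify_candidates, two_way_anova
from .de import (
    DEThresholds,
    call_dems,
    cpm,
    estimate_common_dispersion,
    nb_exact_test,
    qc_correlation,
    qc_pca,
    tmm_factors,
)
from .design import DesignError, validate_design
from .screen import (
    build_screen_design,
    de_sets_from_membership,
    membership_table,
    screen_enm,
)
from .simulate import read_counts
from .sweep import (
    annotate_regions,
    call_regions,
    read_annotation,
    read_popmap,
    read_vcf,
    scan_windows,
    unique_genes,
)

log = logging.getLogger("plastisweep")


class ConfigError(ValueError):
    """Raised for malformed or unknown configuration."""


_DE_KEYS = {"min_abs_log2fc", "min_log2cpm", "max_fdr"}
_TRANSCRIPTOME_KEYS = {"counts", "design", "out_dir", "membership_dir", "de", "anova_alpha"}
_SWEEP_KEYS = {
    "vcf", "popmap", "annotation", "out_dir",
    "window", "step", "fst_min", "pop1", "pop2", "estimator",
}
_TOP_KEYS = {"seed", "transcriptome", "sweep"}


def _reject_unknown(d: dict, allowed: set, context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown {context} keys: {sorted(unknown)}")


def load_config(path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    _reject_unknown(cfg, _TOP_KEYS, "top-level")
    if "transcriptome" in cfg:
        t = cfg["transcriptome"]
        _reject_unknown(t, _TRANSCRIPTOME_KEYS, "transcriptome")
        if "de" in t:
            _reject_unknown(t["de"], _DE_KEYS, "transcriptome.de")
        if t.get("membership_dir") is None and ("counts" not in t or "design" not in t):
            raise ConfigError("transcriptome needs counts+design or membership_dir")
    if "sweep" in cfg:
        s = cfg["sweep"]
        _reject_unknown(s, _SWEEP_KEYS, "sweep")
        for key in ("vcf", "popmap"):
            if key not in s:
                raise ConfigError(f"sweep.{key} is required")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _header(cfg: dict) -> str:
    seed = cfg.get("seed", 0)
    return f"# plastisweep {__version__} | config={config_hash(cfg)} | seed={seed}\n"


def write_tsv(df: pd.DataFrame, path, cfg: dict, index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def dry_run(cfg: dict) -> list[str]:
    """Validate config and input formats without running any stage."""
    validate_config(cfg)
    checked = []
    t = cfg.get("transcriptome")
    if t:
        if t.get("membership_dir"):
            p = Path(t["membership_dir"])
            if not p.is_dir():
                raise FileNotFoundError(f"membership_dir {p} does not exist")
            checked.append(str(p))
        else:
            cm = read_counts(t["counts"], t["design"])
            validate_design(cm.design)
            checked += [t["counts"], t["design"]]
    s = cfg.get("sweep")
    if s:
        for key in ("vcf", "popmap"):
            if not Path(s[key]).exists():
                raise FileNotFoundError(f"sweep.{key} {s[key]} does not exist")
            checked.append(s[key])
        if s.get("annotation"):
            read_annotation(s["annotation"])
            checked.append(s["annotation"])
    return checked


# ---------------------------------------------------------------------------


def _screen_from_membership(cfg: dict, t: dict, out: Path) -> dict:
    sdesign = build_screen_design()
    summary: dict = {"tissues": {}}
    mdir = Path(t["membership_dir"])
    for mfile in sorted(mdir.glob("*_membership.tsv")):
        tissue = mfile.name.rsplit("_membership.tsv", 1)[0]
        table = pd.read_csv(mfile, sep="\t", index_col=0, comment="#")
        de_sets = de_sets_from_membership(table)
        candidates = screen_enm(de_sets, sdesign, tissue=tissue)
        cand_df = pd.DataFrame(
            [
                {
                    "tissue": c.tissue,
                    "feature": c.feature,
                    "altitude_preference": c.altitude_preference,
                    "support": ";".join(f"{k}:{v:+d}" for k, v in sorted(c.support.items())),
                }
                for c in candidates
            ],
            columns=["tissue", "feature", "altitude_preference", "support"],
        )
        write_tsv(cand_df, out / f"{tissue}_candidates.tsv", cfg, index=False)
        summary["tissues"][tissue] = {
            "candidates": [c.feature for c in candidates],
            "n_candidates": len(candidates),
        }
    summary["total_candidates"] = sum(
        v["n_candidates"] for v in summary["tissues"].values()
    )
    return summary


def run_transcriptome(cfg: dict) -> dict:
    """Run the full transcriptome half; returns a per-tissue summary dict."""
    validate_config(cfg)
    t = cfg.get("transcriptome")
    if t is None:
        raise ConfigError("config has no transcriptome section")
    out = Path(t.get("out_dir", "transcriptome_out"))
    out.mkdir(parents=True, exist_ok=True)

    if t.get("membership_dir"):
        return _screen_from_membership(cfg, t, out)

    cm = read_counts(t["counts"], t["design"])
    validate_design(cm.design)
    thresholds = DEThresholds(**(t.get("de") or {}))
    alpha = float(t.get("anova_alpha", 0.05))
    sdesign = build_screen_design(cm.design)

    summary: dict = {"tissues": {}}
    for tissue in sorted(cm.design["tissue"].unique()):
        sub = cm.subset_tissue(tissue)
        factors = tmm_factors(sub)
        write_tsv(factors.to_frame(), out / f"{tissue}_norm_factors.tsv", cfg)
        logcpm = cpm(sub, factors, log=True)
        write_tsv(qc_correlation(logcpm), out / f"{tissue}_qc_correlation.tsv", cfg)
        scores, varfrac = qc_pca(logcpm, n_components=min(3, sub.counts.shape[1] - 1))
        write_tsv(scores, out / f"{tissue}_qc_pca.tsv", cfg)

        phi = estimate_common_dispersion(sub, sub.design.set_index("sample_id")["group"], factors)
        de_sets = {}
        for comp in sdesign.comparisons:
            res = nb_exact_test(sub, comp.a, comp.b, phi, factors, label=comp.label)
            res = call_dems(res, thresholds)
            write_tsv(res.table, out / f"{tissue}_{comp.label}_de.tsv", cfg)
            de_sets[comp.label] = res.de_set()
        write_tsv(membership_table(de_sets, sdesign), out / f"{tissue}_membership.tsv", cfg)

        candidates = screen_enm(de_sets, sdesign, tissue=tissue)
        anova_table = two_way_anova(logcpm, sub.design)
        write_tsv(anova_table, out / f"{tissue}_anova.tsv", cfg)
        classified = classify_candidates(candidates, anova_table, alpha=alpha)
        write_tsv(classified, out / f"{tissue}_candidates.tsv", cfg, index=False)

        enms = list(classified.loc[classified["enm"], "feature"]) if len(classified) else []
        summary["tissues"][tissue] = {
            "dispersion": phi,
            "candidates": [c.feature for c in candidates],
            "n_candidates": len(candidates),
            "enms": enms,
            "n_enms": len(enms),
        }
        log.info(
            "tissue %s: %d candidates, %d final ENMs",
            tissue, len(candidates), len(enms),
        )
    summary["total_candidates"] = sum(v["n_candidates"] for v in summary["tissues"].values())
    summary["total_enms"] = sum(v["n_enms"] for v in summary["tissues"].values())
    return summary


def run_sweep(cfg: dict) -> dict:
    """Run the sweep scan; returns a summary dict and writes windows/regions."""
    validate_config(cfg)
    s = cfg.get("sweep")
    if s is None:
        raise ConfigError("config has no sweep section")
    out = Path(s.get("out_dir", "sweep_out"))
    out.mkdir(parents=True, exist_ok=True)

    vt = read_vcf(s["vcf"])
    popmap = read_popmap(s["popmap"])
    pops = sorted(set(popmap.values()))
    pop1 = s.get("pop1") or (pops[0] if pops else None)
    pop2 = s.get("pop2") or (pops[1] if len(pops) > 1 else None)
    if pop1 is None or pop2 is None:
        raise ConfigError("population map must define two populations")

    windows = scan_windows(
        vt, popmap, pop1, pop2,
        window=int(s.get("window", 40_000)),
        step=int(s.get("step", 20_000)),
        estimator=s.get("estimator", "wc"),
    )
    write_tsv(windows, out / "windows.tsv", cfg, index=False)

    fst_min = float(s.get("fst_min", 0.3))
    regions = call_regions(windows, fst_threshold=fst_min)
    genes: list[str] = []
    if s.get("annotation"):
        ann = read_annotation(s["annotation"])
        regions = annotate_regions(regions, ann)
        genes = unique_genes(regions)
        regions = regions.assign(genes=[",".join(g) for g in regions["genes"]])
    write_tsv(regions, out / "regions.tsv", cfg, index=False)

    n_qual = int((windows["fst"].notna() & (windows["fst"] >= fst_min)).sum())
    summary = {
        "n_windows": int(len(windows)),
        "n_windows_with_sites": int((windows["n_sites"] > 0).sum()),
        "n_qualifying": n_qual,
        "n_regions": int(len(regions)),
        "n_genes": len(genes),
    }
    log.info(
        "sweep: %(n_windows)d windows, %(n_qualifying)d qualifying, "
        "%(n_regions)d regions, %(n_genes)d genes", summary,
    )
    return summary
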