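"""Two-way breed x environment ANOVA and the final ENM call.

Candidates surviving the set-logic screen are confirmed with a balanced
two-way factorial ANOVA on log2-CPM expression: the final ENM call
requires a significant environment main effect together with a
non-significant breed main effect. The interaction term is computed and
reported but does not enter the call, which keys on main effects only.

Only balanced complete 2x2 designs are accepted; with balance, the
type-I sums of squares used here coincide with type-III, so there is no
ordering ambiguity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .design import BREEDS, DesignError, ENVS


def _check_balanced(design: pd.DataFrame) -> int:
    """Return replicates per cell; raise on unbalanced/incomplete designs."""
    sizes = design.groupby(["breed", "env"]).size()
    cells = [(b, e) for b in BREEDS for e in ENVS]
    missing = [c for c in cells if c not in sizes.index]
    if missing:
        raise DesignError(f"incomplete 2x2 design: missing cell {missing[0]}")
    if sizes.nunique() != 1:
        raise DesignError(f"unbalanced design: cell sizes {dict(sizes)}")
    n = int(sizes.iloc[0])
    if n < 2:
        raise DesignError("need >= 2 replicates per cell")
    return n


def two_way_anova(expr: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Balanced two-way ANOVA per feature (rows of ``expr``).

    ``expr`` columns must match ``design['sample_id']``. Returns a table
    with F and p per effect (breed, env, interaction), the four cell
    means, and the residual SS. Constant responses give F = 0, p = 1.
    """
    if list(expr.columns) != list(design["sample_id"]):
        expr = expr[list(design["sample_id"])]
    n = _check_balanced(design)
    y = expr.values.astype(float)  # features x samples

    cell_idx = {
        (b, e): np.flatnonzero((design["breed"] == b) & (design["env"] == e)).astype(int)
        for b in BREEDS
        for e in ENVS
    }
    cell_means = {be: y[:, idx].mean(axis=1) for be, idx in cell_idx.items()}
    grand = y.mean(axis=1)
    breed_means = {b: (cell_means[(b, "HIGH")] + cell_means[(b, "LOW")]) / 2 for b in BREEDS}
    env_means = {e: (cell_means[("TIB", e)] + cell_means[("PX", e)]) / 2 for e in ENVS}

    # balanced 2x2: each factor level covers 2n observations, each cell n
    ss_breed = 2 * n * sum((breed_means[b] - grand) ** 2 for b in BREEDS)
    ss_env = 2 * n * sum((env_means[e] - grand) ** 2 for e in ENVS)
    ss_int = n * sum(
        (cell_means[(b, e)] - breed_means[b] - env_means[e] + grand) ** 2
        for b in BREEDS
        for e in ENVS
    )
    ss_resid = np.zeros(y.shape[0])
    for be, idx in cell_idx.items():
        ss_resid += ((y[:, idx] - cell_means[be][:, None]) ** 2).sum(axis=1)

    df_resid = 4 * (n - 1)
    ms_resid = ss_resid / df_resid

    out = {}
    for name, ss in (("breed", ss_breed), ("env", ss_env), ("int", ss_int)):
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(ms_resid > 0, ss / ms_resid, 0.0)
            # zero residual variance: any nonzero effect SS is infinitely
            # significant; a fully constant response gives F = 0, p = 1
            f = np.where((ms_resid == 0) & (ss > 1e-12), np.inf, f)
        p = stats.f.sf(f, 1, df_resid)
        p = np.where(f == 0, 1.0, p)
        out[f"F_{name}"] = f
        out[f"p_{name}"] = p

    table = pd.DataFrame(out, index=expr.index)
    for (b, e), m in cell_means.items():
        table[f"mean_{b}_{e}"] = m
    table["ss_resid"] = ss_resid
    return table


def anova_ss_decomposition(expr: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Sums of squares per feature (breed, env, interaction, residual, total)."""
    if list(expr.columns) != list(design["sample_id"]):
        expr = expr[list(design["sample_id"])]
    table = two_way_anova(expr, design)
    n = _check_balanced(design)
    df_resid = 4 * (n - 1)
    y = expr.values.astype(float)
    ss_total = ((y - y.mean(axis=1)[:, None]) ** 2).sum(axis=1)
    ms_resid = table["ss_resid"] / df_resid
    return pd.DataFrame(
        {
            "ss_breed": table["F_breed"] * ms_resid,
            "ss_env": table["F_env"] * ms_resid,
            "ss_int": table["F_int"] * ms_resid,
            "ss_resid": table["ss_resid"],
            "ss_total": ss_total,
        },
        index=expr.index,
    )


def classify_candidates(
    candidates, anova_table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Final ENM call per screen candidate.

    ENM iff p_env <= alpha AND p_breed > alpha; interaction significance
    is reported alongside but not used for the call.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rows = []
    for cand in candidates:
        feature = cand.feature if hasattr(cand, "feature") else str(cand)
        if feature not in anova_table.index:
            raise KeyError(f"candidate {feature!r} has no ANOVA row")
        r = anova_table.loc[feature]
        rows.append(
            {
                "feature": feature,
                "tissue": getattr(cand, "tissue", None),
                "altitude_preference": getattr(cand, "altitude_preference", None),
                "p_breed": r["p_breed"],
                "p_env": r["p_env"],
                "p_int": r["p_int"],
                "int_significant": bool(r["p_int"] <= alpha),
                "enm": bool(r["p_env"] <= alpha and r["p_breed"] > alpha),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature",
            "tissue",
            "altitude_preference",
            "p_breed",
            "p_env",
            "p_int",
            "int_significant",
            "enm",
        ],
    )
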