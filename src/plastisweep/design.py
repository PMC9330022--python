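"""Sample design for the 2x2 reciprocal-transplant layout.

Two chicken breeds -- Tibetan (``TIB``, native to high altitude) and
Peng'xian yellow (``PX``, native to low altitude) -- are each raised in
both a high-altitude and a low-altitude environment, giving four groups:

========  =======  ======
group     breed    env
========  =======  ======
TC        TIB      HIGH
LTC       TIB      LOW
HLC       PX       HIGH
LC        PX       LOW
========  =======  ======

Each group is sampled in up to four tissues (heart, liver, lung, brain)
with replicate individuals. The design table is the single source of
sample metadata for every downstream stage.
"""

from __future__ import annotations

import itertools

import pandas as pd

BREEDS = ("TIB", "PX")
ENVS = ("HIGH", "LOW")
TISSUES = ("heart", "liver", "lung", "brain")

GROUP_OF = {
    ("TIB", "HIGH"): "TC",
    ("TIB", "LOW"): "LTC",
    ("PX", "HIGH"): "HLC",
    ("PX", "LOW"): "LC",
}
GROUPS = ("TC", "LTC", "HLC", "LC")
GROUP_BREED_ENV = {g: be for be, g in GROUP_OF.items()}

DESIGN_COLUMNS = ["sample_id", "breed", "env", "tissue", "replicate", "group"]


class DesignError(ValueError):
    """Raised when a design table is malformed or incomplete."""


def group_label(breed: str, env: str) -> str:
    """Group label derived from (breed, env); never assigned independently."""
    try:
        return GROUP_OF[(breed, env)]
    except KeyError:
        raise DesignError(f"unknown (breed, env) combination: ({breed!r}, {env!r})")


def make_design(tissues=TISSUES, n_reps: int = 3) -> pd.DataFrame:
    """Build the full factorial design table (2 breeds x 2 envs x tissues x reps)."""
    if n_reps < 1:
        raise DesignError("n_reps must be >= 1")
    rows = []
    for breed, env, tissue, rep in itertools.product(BREEDS, ENVS, tissues, range(1, n_reps + 1)):
        grp = group_label(breed, env)
        rows.append(
            {
                "sample_id": f"{grp}_{tissue}_{rep}",
                "breed": breed,
                "env": env,
                "tissue": tissue,
                "replicate": rep,
                "group": grp,
            }
        )
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def validate_design(design: pd.DataFrame, min_reps: int = 2) -> None:
    """Check uniqueness, derived group labels, and factorial completeness.

    Every tissue present must have all four (group) cells with at least
    ``min_reps`` replicates; raises :class:`DesignError` naming the first
    missing or under-replicated cell.
    """
    missing_cols = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing_cols:
        raise DesignError(f"design table missing columns: {missing_cols}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DesignError(f"duplicate sample_id: {dup!r}")
    for _, row in design.iterrows():
        expected = group_label(row["breed"], row["env"])
        if row["group"] != expected:
            raise DesignError(
                f"sample {row['sample_id']!r}: group {row['group']!r} "
                f"inconsistent with (breed, env) -> {expected!r}"
            )
    for tissue, sub in design.groupby("tissue"):
        counts = sub.groupby("group").size()
        for grp in GROUPS:
            n = int(counts.get(grp, 0))
            if n < min_reps:
                raise DesignError(
                    f"tissue {tissue!r}: cell {grp!r} has {n} replicates "
                    f"(need >= {min_reps})"
                )


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    return df[DESIGN_COLUMNS]


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)
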