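"""Predicted phenotypic performance (PMAI) and family-representation trimming."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .animal_model import ModelFit
from .pedigree import Pedigree


def mai_from_height(height, age):
    """Mean annual increment: height divided by stand age (cm/year)."""
    height = np.asarray(height, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise ValueError("stand age must be positive")
    if np.any(height < 0):
        raise ValueError("height must be non-negative")
    out = height / age
    return float(out) if out.ndim == 0 else out


def pmai(overall_mean, site_effect, bv):
    """Predicted performance: overall mean + site effect + breeding value."""
    return np.asarray(overall_mean, float) + np.asarray(site_effect, float) + np.asarray(bv, float)


def performance_table(
    fit: ModelFit,
    phenotypes: pd.DataFrame,
    pedigree: Pedigree,
    trait: str = "mai",
    mean_weighting: str = "site",
) -> pd.DataFrame:
    """Per-individual performance table for the growth trait.

    ``family`` is the maternal half-sib family (the dam), which every offspring
    has since seed is collected on orchard mothers.  The overall mean is the
    unweighted mean of the site cell means by default (``mean_weighting="site"``);
    ``"record"`` weights cells by their record counts instead.  The site effect
    is the cell mean minus that overall mean, so ``pmai = mean + effect + bv``
    holds exactly.
    """
    cell_means = fit.mme.site_effects(trait)
    if mean_weighting == "site":
        overall = float(cell_means.mean())
    elif mean_weighting == "record":
        counts = phenotypes["site"].value_counts()
        w = counts.reindex(cell_means.index).fillna(0)
        overall = float((cell_means * w).sum() / w.sum())
    else:
        raise ValueError("mean_weighting must be 'site' or 'record'")
    site_effect = cell_means - overall

    bv_col = f"bv_{trait}"
    bv = fit.mme.breeding_values.set_index("individual")[bv_col]
    dam_of = {ind: d for ind, _, d in pedigree.records}

    df = phenotypes.copy()
    if "mai" not in df.columns:
        df["mai"] = mai_from_height(df["height"], df["age"])
    out = pd.DataFrame(
        {
            "individual": df["individual"],
            "family": df["individual"].map(dam_of),
            "site": df["site"],
            "mai": df["mai"],
            "bv": df["individual"].map(bv),
            "site_effect": df["site"].map(site_effect),
        }
    )
    out["pmai"] = pmai(overall, out["site_effect"], out["bv"])
    out.attrs["overall_mean"] = overall
    return out


def trim_families(perf: pd.DataFrame, min_sites: int = 6) -> pd.DataFrame:
    """Keep only half-sib families represented in at least ``min_sites`` sites."""
    for col in ("family", "site"):
        if col not in perf.columns:
            raise ValueError(f"performance table lacks column {col!r}")
    n_sites = perf.groupby("family")["site"].nunique()
    keep = n_sites[n_sites >= min_sites].index
    out = perf[perf["family"].isin(keep)].reset_index(drop=True)
    if out.empty:
        raise ValueError(
            f"trimming at min_sites={min_sites} removed every family"
        )
    dropped = len(n_sites) - len(keep)
    if dropped:
        warnings.warn(f"trimmed {dropped} families below {min_sites} sites")
    out.attrs.update(perf.attrs)
    return out
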