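"""Quantitative genetics of state-duration phenotypes.

For a panel of inbred lines measured in both sexes, partitions phenotypic
variance into among-line (sigma2_L), line-by-sex (sigma2_SL) and residual
(sigma2_E) components and computes broad-sense heritability

    combined sexes:  H2 = (sigma2_L + sigma2_SL) / (sigma2_L + sigma2_SL + sigma2_E)
    single sex:      H2 = sigma2_L / (sigma2_L + sigma2_E)

and the genetic correlation between two traits

    r_G = cov_ab / sqrt(sigma2_La * sigma2_Lb)

with cov_ab the covariance of line means.  Components are estimated by
the expected-mean-squares method of moments on a (near-)balanced
line x sex x replicate layout: with s sexes and r flies per line-sex
cell,

    sigma2_E  = MS_error
    sigma2_SL = (MS_line_x_sex - MS_error) / r
    sigma2_L  = (MS_line - MS_line_x_sex) / (s * r)

Negative moment estimates are truncated at zero (logged).  Block and
replicate terms of the full experimental design are absorbed into the
residual, which can only shrink H2 (conservative).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("somnostate")

__all__ = [
    "PhenotypeRecord",
    "VarianceComponents",
    "variance_components",
    "broad_sense_heritability",
    "genetic_correlation",
    "line_means",
]


@dataclass(frozen=True)
class PhenotypeRecord:
    """One fly's value for one trait, with its design labels."""

    fly_id: str
    genotype: str
    sex: str
    block: str
    replicate: str
    value: float


@dataclass
class VarianceComponents:
    sigma2_L: float
    sigma2_SL: float
    sigma2_E: float
    design: str  # "combined" or "per_sex"


def _records_frame(records: Sequence[PhenotypeRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "line": [r.genotype for r in records],
            "sex": [r.sex for r in records],
            "value": [float(r.value) for r in records],
        }
    )
    if not np.all(np.isfinite(df["value"])):
        raise ValueError("non-finite phenotype value")
    return df


def _truncate(name: str, value: float) -> float:
    if value < 0:
        logger.info("negative %s estimate (%.4g) truncated to 0", name, value)
        return 0.0
    return float(value)


def variance_components(
    records: Sequence[PhenotypeRecord], design: str = "combined"
) -> VarianceComponents:
    """Method-of-moments variance components from a balanced panel.

    combined: two-way random-effects ANOVA (line, sex, line x sex) with
    the expected-mean-squares identities above.  per_sex: one-way
    among-line ANOVA; sigma2_SL is reported as 0.  Cell sizes may differ
    slightly (the harmonic-mean cell size is used), but layouts missing
    more than 20% of line-sex cells are refused.
    """
    if design not in ("combined", "per_sex"):
        raise ValueError("design must be 'combined' or 'per_sex'")
    df = _records_frame(records)
    n_lines = df["line"].nunique()
    if n_lines < 2:
        raise ValueError("need at least 2 lines")

    if design == "combined":
        sexes = df["sex"].unique()
        s = len(sexes)
        cells = df.groupby(["line", "sex"])["value"]
        sizes = cells.size()
        n_expected = n_lines * s
        if len(sizes) < 0.8 * n_expected:
            raise ValueError(
                f"severe imbalance: only {len(sizes)}/{n_expected} line-sex "
                "cells present; fill in the design or analyze per sex"
            )
        # harmonic-mean cell size accommodates mild imbalance
        r = len(sizes) / float((1.0 / sizes).sum())
        grand = df["value"].mean()
        cell_means = cells.mean()
        line_mean = df.groupby("line")["value"].mean()
        sex_mean = df.groupby("sex")["value"].mean()

        ss_line = (s * r) * float(((line_mean - grand) ** 2).sum())
        ss_sex = (n_lines * r) * float(((sex_mean - grand) ** 2).sum())
        inter = (
            cell_means
            - line_mean.reindex(cell_means.index.get_level_values(0)).to_numpy()
            - sex_mean.reindex(cell_means.index.get_level_values(1)).to_numpy()
            + grand
        )
        ss_inter = r * float((inter ** 2).sum())
        resid = df["value"].to_numpy() - cells.transform("mean").to_numpy()
        ss_err = float((resid ** 2).sum())

        df_line = n_lines - 1
        df_inter = (n_lines - 1) * (s - 1)
        df_err = len(df) - len(sizes)
        if df_err < 1 or df_inter < 1:
            raise ValueError("not enough replication to separate components")
        ms_line = ss_line / df_line
        ms_inter = ss_inter / df_inter
        ms_err = ss_err / df_err
        sigma2_E = _truncate("sigma2_E", ms_err)
        sigma2_SL = _truncate("sigma2_SL", (ms_inter - ms_err) / r)
        sigma2_L = _truncate("sigma2_L", (ms_line - ms_inter) / (s * r))
        return VarianceComponents(sigma2_L, sigma2_SL, sigma2_E, "combined")

    # per_sex: one-way among-line ANOVA on a single sex's records
    if df["sex"].nunique() > 1:
        raise ValueError("per_sex design expects records from a single sex")
    groups = df.groupby("line")["value"]
    sizes = groups.size()
    if (sizes < 1).any() or len(sizes) < 2:
        raise ValueError("need >= 2 lines with data")
    r = len(sizes) / float((1.0 / sizes).sum())
    grand = df["value"].mean()
    ss_line = float((sizes * (groups.mean() - grand) ** 2).sum())
    resid = df["value"].to_numpy() - groups.transform("mean").to_numpy()
    ss_err = float((resid ** 2).sum())
    df_line = len(sizes) - 1
    df_err = len(df) - len(sizes)
    if df_err < 1:
        raise ValueError("need within-line replication")
    ms_line = ss_line / df_line
    ms_err = ss_err / df_err
    sigma2_E = _truncate("sigma2_E", ms_err)
    sigma2_L = _truncate("sigma2_L", (ms_line - ms_err) / r)
    return VarianceComponents(sigma2_L, 0.0, sigma2_E, "per_sex")


def broad_sense_heritability(vc: VarianceComponents):
    """Design-appropriate broad-sense heritability ratio; None when all
    components vanish (undefined)."""
    if vc.design == "combined":
        num = vc.sigma2_L + vc.sigma2_SL
        den = vc.sigma2_L + vc.sigma2_SL + vc.sigma2_E
    else:
        num = vc.sigma2_L
        den = vc.sigma2_L + vc.sigma2_E
    if den <= 0:
        logger.warning("all variance components are zero; H2 undefined")
        return None
    return num / den


def line_means(records: Sequence[PhenotypeRecord]) -> pd.Series:
    """Per-line mean phenotype, indexed by line, sorted by line id."""
    df = _records_frame(records)
    return df.groupby("line")["value"].mean().sort_index()


def genetic_correlation(
    line_means_a, line_means_b, sigma2_La: float, sigma2_Lb: float
):
    """r_G = cov_ab / sqrt(sigma2_La * sigma2_Lb), clamped to [-1, 1].

    ``line_means_a``/``b`` are per-line means of the two traits over the
    same line set (aligned by index when pandas Series are given).
    Returns None when either among-line variance is zero.
    """
    a = pd.Series(line_means_a)
    b = pd.Series(line_means_b)
    if isinstance(line_means_a, pd.Series) and isinstance(line_means_b, pd.Series):
        common = a.index.intersection(b.index)
        if len(common) != len(a) or len(common) != len(b):
            raise ValueError("traits must cover the same line set")
        a, b = a.loc[common], b.loc[common]
    if len(a) != len(b):
        raise ValueError("traits must cover the same line set")
    if len(a) < 3:
        raise ValueError("need at least 3 lines")
    if sigma2_La <= 0 or sigma2_Lb <= 0:
        logger.warning("zero among-line variance; r_G undefined")
        return None
    cov_ab = float(np.cov(a.to_numpy(), b.to_numpy(), ddof=1)[0, 1])
    r = cov_ab / math.sqrt(sigma2_La * sigma2_Lb)
    if abs(r) > 1.0:
        logger.info("r_G = %.4f clamped to [-1, 1]", r)
        r = math.copysign(1.0, r)
    return r
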