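"""Relative expression quantification by the ΔΔCt method.

Technical replicates are averaged per biological replicate; the target Ct is
normalised by the arithmetic mean Ct of one or more reference genes (ΔCt),
then by the mean ΔCt of a designated control group (ΔΔCt).  With
amplification factor F (2.0 for perfect doubling per cycle, or estimated
from a dilution titration), the fold change is F**(-ΔΔCt) and
log2FC = -ΔΔCt·log2(F).  Group comparisons aggregate to biological-replicate
means and apply a one-way fixed-effects analysis with Tukey's
honest-significant-difference adjustment; for balanced designs this matches
a mixed model with a random biological-replicate intercept.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats


REQUIRED_CT_COLUMNS = ("strain", "gene", "bio_rep", "tech_rep", "ct")


class TitrationError(ValueError):
    """A dilution series is insufficient to estimate PCR efficiency."""


class EfficiencyFit(NamedTuple):
    slope: float  # Ct per log10 dilution
    factor: float  # per-cycle amplification factor, 10**(-1/slope)


def efficiency(log10_dilution: Sequence[float], ct: Sequence[float]) -> EfficiencyFit:
    """Estimate amplification efficiency from a cDNA dilution titration.

    Requires at least three points spanning at least two logs.  The slope of
    Ct on log10(input) gives the amplification factor 10**(-1/slope);
    a perfectly efficient reaction has slope -log2(10) ~ -3.32 and factor 2.
    """
    x = np.asarray(log10_dilution, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.size != y.size:
        raise TitrationError("dilution and Ct vectors differ in length")
    if x.size < 3:
        raise TitrationError(f"titration needs >= 3 points, got {x.size}")
    if x.max() - x.min() < 2.0:
        raise TitrationError("titration must span at least two logs of input")
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise TitrationError(f"non-negative titration slope ({res.slope:.3f})")
    return EfficiencyFit(slope=float(res.slope), factor=float(10.0 ** (-1.0 / res.slope)))


def _validate_ct(ct_table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_CT_COLUMNS if c not in ct_table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns {missing}")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycle numbers")
    return ct_table


def delta_ct(
    ct_table: pd.DataFrame,
    reference_genes: Sequence[str],
    target_genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-biological-replicate ΔCt: target mean Ct minus mean reference Ct.

    Technical replicates are averaged first.  Reference Cts are combined by
    arithmetic mean (the geometric mean of the linear quantities); a single
    reference gene is fully supported.  An optional ``run`` column is carried
    through so ΔΔCt can be computed within runs.
    """
    ct_table = _validate_ct(ct_table)
    reference_genes = list(reference_genes)
    if not reference_genes:
        raise ValueError("at least one reference gene is required")
    keys = ["strain", "bio_rep"]
    if "run" in ct_table.columns:
        keys = ["run"] + keys
    tech_mean = (
        ct_table.groupby(keys + ["gene"], as_index=False)["ct"].mean()
    )
    refs = tech_mean[tech_mean["gene"].isin(reference_genes)]
    if refs.empty:
        raise ValueError(f"no Ct rows for reference genes {reference_genes}")
    ref_mean = refs.groupby(keys, as_index=False)["ct"].mean().rename(columns={"ct": "ref_ct"})
    targets = tech_mean[~tech_mean["gene"].isin(reference_genes)]
    if target_genes is not None:
        targets = targets[targets["gene"].isin(list(target_genes))]
    merged = targets.merge(ref_mean, on=keys, how="left")
    if merged["ref_ct"].isna().any():
        bad = merged[merged["ref_ct"].isna()][keys].drop_duplicates()
        raise ValueError(f"samples without reference-gene measurements: {bad.to_dict('records')}")
    merged["delta_ct"] = merged["ct"] - merged["ref_ct"]
    return merged[keys + ["gene", "ct", "ref_ct", "delta_ct"]]


def ddct_log2fc(
    dct: pd.DataFrame,
    control: str,
    amplification_factor: float = 2.0,
) -> pd.DataFrame:
    """ΔΔCt against the control group's mean ΔCt, and the log2 fold change.

    When a ``run`` column is present, the control mean is taken within each
    run (runs with different primer sets are normalised independently and
    combined afterwards).
    """
    if amplification_factor <= 1.0:
        raise ValueError("amplification factor must exceed 1")
    dct = dct.copy()
    keys = ["gene"] + (["run"] if "run" in dct.columns else [])
    controls = dct[dct["strain"] == control]
    if controls.empty:
        raise ValueError(f"control group {control!r} absent from ΔCt table")
    ctrl_mean = (
        controls.groupby(keys, as_index=False)["delta_ct"]
        .mean()
        .rename(columns={"delta_ct": "control_delta_ct"})
    )
    out = dct.merge(ctrl_mean, on=keys, how="left")
    if out["control_delta_ct"].isna().any():
        raise ValueError("some genes/runs lack control-group measurements")
    out["ddct"] = out["delta_ct"] - out["control_delta_ct"]
    out["log2fc"] = -out["ddct"] * np.log2(amplification_factor)
    return out


def relative_expression(
    ct_table: pd.DataFrame,
    control: str,
    reference_genes: Sequence[str],
    target_genes: Sequence[str] | None = None,
    amplification_factor: float = 2.0,
) -> pd.DataFrame:
    """Full ΔΔCt chain: technical averaging, ΔCt, ΔΔCt, log2 fold change."""
    return ddct_log2fc(
        delta_ct(ct_table, reference_genes, target_genes),
        control=control,
        amplification_factor=amplification_factor,
    )


def compare_expression(log2fc: pd.DataFrame, gene: str | None = None) -> pd.DataFrame:
    """Pairwise Tukey-HSD comparisons of log2 fold change between groups.

    Input rows are per biological replicate (technical replicates already
    averaged); when several runs are present their per-run ΔΔCt values enter
    as repeated measures of the biological replicate and are averaged.
    Returns one row per (gene, group pair) with the mean difference and the
    Tukey-adjusted p-value.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = log2fc
    if gene is not None:
        df = df[df["gene"] == gene]
    if df.empty:
        raise ValueError("no rows to compare")
    rows = []
    for g, sub in df.groupby("gene"):
        per_bio = sub.groupby(["strain", "bio_rep"], as_index=False)["log2fc"].mean()
        groups = per_bio["strain"].to_numpy()
        values = per_bio["log2fc"].to_numpy(dtype=float)
        uniq = sorted(set(groups))
        if len(uniq) < 2:
            continue
        # degenerate zero-variance data (noise-free simulations) short-circuits
        resid_var = per_bio.groupby("strain")["log2fc"].var(ddof=1).fillna(0.0).max()
        if resid_var < 1e-24:
            for i, a in enumerate(uniq):
                for b in uniq[i + 1 :]:
                    diff = float(
                        values[groups == b].mean() - values[groups == a].mean()
                    )
                    rows.append(
                        {
                            "gene": g,
                            "group_a": a,
                            "group_b": b,
                            "meandiff": diff,
                            "p_adj": 1.0 if abs(diff) < 1e-12 else 0.0,
                            "reject": abs(diff) >= 1e-12,
                        }
                    )
            continue
        res = pairwise_tukeyhsd(values, groups)
        table = res.summary().data[1:]
        for line in table:
            rows.append(
                {
                    "gene": g,
                    "group_a": str(line[0]),
                    "group_b": str(line[1]),
                    "meandiff": float(line[2]),
                    "p_adj": float(line[3]),
                    "reject": bool(line[6]),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "group_a", "group_b", "meandiff", "p_adj", "reject"])


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return _validate_ct(df)
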