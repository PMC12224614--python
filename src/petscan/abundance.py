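"""Metagenomic gene abundance: FPKM, recA normalization, depth summaries,
and PETase/MHETase co-occurrence.

Per-sample gene abundance is expressed as FPKM (fragments per kilobase of
gene per million mapped fragments).  To compare the PETase gene content of
communities of different size, the summed FPKM of the functional (M5-tier)
PETase variants in a sample is divided by the FPKM of the single-copy
housekeeping marker recA; the resulting dimensionless ratio approximates
"PETase gene copies per genome".  The same ratio machinery applies unchanged
to metatranscriptome units (length-normalized insert counts), since the
marker ratio cancels the unit.

Detection is defined strictly as a normalized value > 0.  Depth summaries
use six half-open layers: [0,100), [100,500), [500,1000), [1000,2000),
[2000,3000), [3000, inf) meters.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger("petscan")

#: half-open depth layer edges in meters
DEPTH_EDGES = (0.0, 100.0, 500.0, 1000.0, 2000.0, 3000.0, np.inf)

COUNT_COLUMNS = (
    "sample_id", "gene_id", "fragments", "gene_length", "total_mapped_fragments",
)


class AbundanceInputError(ValueError):
    pass


def depth_layer_labels(edges=DEPTH_EDGES) -> list[str]:
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if np.isinf(hi):
            labels.append(f">{lo:g} m")
        else:
            labels.append(f"{lo:g}-{hi:g} m")
    return labels


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------

def compute_fpkm(fragments, gene_length, total_mapped_fragments):
    """FPKM = fragments / ((gene_length/1e3) * (total_mapped/1e6)).

    Accepts scalars or aligned arrays; gene length is in bp.  Zero or
    negative lengths/totals are input errors.
    """
    fragments = np.asarray(fragments, dtype=float)
    gene_length = np.asarray(gene_length, dtype=float)
    total = np.asarray(total_mapped_fragments, dtype=float)
    if np.any(gene_length <= 0):
        raise AbundanceInputError("gene_length must be > 0")
    if np.any(total <= 0):
        raise AbundanceInputError("total_mapped_fragments must be > 0")
    if np.any(fragments < 0):
        raise AbundanceInputError("fragments must be >= 0")
    fpkm = fragments / ((gene_length / 1e3) * (total / 1e6))
    return float(fpkm) if fpkm.ndim == 0 else fpkm


def fpkm_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Add an ``fpkm`` column to a per-sample per-gene count table."""
    missing = set(COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise AbundanceInputError(f"count table missing columns {sorted(missing)}")
    out = counts.copy()
    out["fpkm"] = compute_fpkm(
        out["fragments"], out["gene_length"], out["total_mapped_fragments"]
    )
    return out


# ---------------------------------------------------------------------------
# marker normalization
# ---------------------------------------------------------------------------

def normalize_by_marker(fpkm: pd.DataFrame, variant_ids, marker_ids) -> pd.DataFrame:
    """Per-sample Σ FPKM(variants) / Σ FPKM(markers).

    Multiple marker (recA) copies in a sample are summed.  Samples with zero
    or absent marker FPKM get a missing value and a warning.  Returns a table
    with columns ``sample_id, value, detected``.
    """
    variant_ids = set(variant_ids)
    marker_ids = set(marker_ids)
    if "fpkm" not in fpkm.columns:
        fpkm = fpkm_table(fpkm)
    samples = pd.unique(fpkm["sample_id"])
    v = (
        fpkm[fpkm["gene_id"].isin(variant_ids)]
        .groupby("sample_id")["fpkm"].sum()
    )
    m = (
        fpkm[fpkm["gene_id"].isin(marker_ids)]
        .groupby("sample_id")["fpkm"].sum()
    )
    rows = []
    for s in samples:
        marker = m.get(s, 0.0)
        if marker <= 0:
            warnings.warn(f"sample {s!r}: no marker FPKM; normalized value missing")
            value = np.nan
        else:
            value = v.get(s, 0.0) / marker
        rows.append(
            {"sample_id": s, "value": value,
             "detected": bool(value > 0) if np.isfinite(value) else False}
        )
    return pd.DataFrame(rows, columns=["sample_id", "value", "detected"])


# ---------------------------------------------------------------------------
# depth layers
# ---------------------------------------------------------------------------

def assign_depth_layer(depths, edges=DEPTH_EDGES) -> pd.Categorical:
    """Map each depth (m, >= 0) to its half-open layer."""
    depths = np.asarray(depths, dtype=float)
    if np.any(depths < 0):
        raise AbundanceInputError("depths must be >= 0")
    labels = depth_layer_labels(edges)
    idx = np.digitize(depths, edges[1:-1], right=False)
    return pd.Categorical.from_codes(idx, categories=labels, ordered=True)


def depth_layer_summary(
    normalized: pd.DataFrame, depths, edges=DEPTH_EDGES
) -> pd.DataFrame:
    """Per-layer detection fraction and mean ± SE over detected samples.

    ``normalized`` needs ``value``/``detected`` columns (one row per sample);
    ``depths`` is an aligned sequence of sample depths in meters.  Means and
    SE are computed only over detected samples; an empty layer reports
    fraction 0 and missing mean.  SE = sd / sqrt(n) with ddof=1.
    """
    df = normalized.copy()
    df["layer"] = assign_depth_layer(depths, edges)
    rows = []
    for layer in depth_layer_labels(edges):
        sub = df[df["layer"] == layer]
        n_total = len(sub)
        det = sub[sub["detected"]]
        n_det = len(det)
        fraction = n_det / n_total if n_total else 0.0
        if n_det:
            mean = float(det["value"].mean())
            se = float(det["value"].std(ddof=1) / np.sqrt(n_det)) if n_det > 1 else np.nan
        else:
            mean, se = np.nan, np.nan
        rows.append(
            {"layer": layer, "n_samples": n_total, "n_detected": n_det,
             "detection_fraction": fraction, "mean": mean, "se": se}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# depth trend
# ---------------------------------------------------------------------------

def depth_trend(
    normalized: pd.DataFrame, transform=None
) -> dict:
    """Depth effect on normalized abundance with station-level grouping.

    Fits ``value ~ depth`` with a per-station random intercept (linear
    mixed model, restricted maximum likelihood) and returns the depth slope,
    its standard error, 95% CI, and two-sided p-value.  ``normalized`` needs
    ``value``, ``depth`` and ``station`` columns; ``transform`` (e.g.
    ``np.log10``) is applied to ``value`` first when given.  With a single
    station the model is degenerate and an ordinary least-squares fit is
    used instead, with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = normalized.dropna(subset=["value", "depth", "station"]).copy()
    if transform is not None:
        df["value"] = transform(df["value"])
    if df["depth"].nunique() < 2:
        raise AbundanceInputError("need >= 2 distinct depths for a depth trend")
    n_station = df["station"].nunique()
    if n_station < 2:
        warnings.warn("single station: falling back to ordinary regression")
        X = sm.add_constant(df["depth"].to_numpy())
        fit = sm.OLS(df["value"].to_numpy(), X).fit()
        slope, se = fit.params[1], fit.bse[1]
        p = fit.pvalues[1]
        ci = fit.conf_int()[1]
        model = "ols"
    else:
        md = smf.mixedlm("value ~ depth", df, groups=df["station"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = md.fit(reml=True)
        slope = fit.params["depth"]
        se = fit.bse["depth"]
        p = fit.pvalues["depth"]
        ci = fit.conf_int().loc["depth"].to_numpy()
        model = "mixed_random_intercept"
    return {
        "slope": float(slope),
        "se": float(se),
        "p_value": float(p),
        "ci95": (float(ci[0]), float(ci[1])),
        "n_obs": int(len(df)),
        "n_stations": int(n_station),
        "model": model,
    }


# ---------------------------------------------------------------------------
# co-occurrence
# ---------------------------------------------------------------------------

def cooccurrence(table: pd.DataFrame) -> dict:
    """Counts of samples with both, either, or neither gene family.

    ``table`` is boolean per sample with ``has_petase``/``has_mhetase``
    columns; the four counts sum to the number of samples.
    """
    p = table["has_petase"].astype(bool)
    m = table["has_mhetase"].astype(bool)
    return {
        "both": int((p & m).sum()),
        "petase_only": int((p & ~m).sum()),
        "mhetase_only": int((~p & m).sum()),
        "neither": int((~p & ~m).sum()),
    }
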