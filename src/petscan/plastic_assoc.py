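"""Association between surface plastic concentration and PETase abundance.

Ocean-surface plastic survey records (g/km²) are matched to sequencing
samples by proximity: for each plastic record, the nearest eligible sample
location within a 5° radius (~556 km great-circle) is selected, and every
sample collected at that location joins the association; plastic records
with no in-radius sample are discarded.  Only samples from <= 10 m depth are
eligible, since the plastic data are surface tows.  On the matched records,
a two-sided Mann-Whitney U test contrasts normalized PETase abundance
between plastic-present and plastic-free records, and an ordinary
least-squares fit quantifies the linear concentration-abundance relation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("petscan")

EARTH_RADIUS_KM = 6371.0
#: 5 degrees of arc along a great circle
DEFAULT_RADIUS_DEG = 5.0
DEFAULT_MAX_DEPTH_M = 10.0
#: coordinate rounding that defines "same location"
LOCATION_DECIMALS = 4
#: exact Mann-Whitney enumeration up to this many pairs (and no ties)
EXACT_PAIR_LIMIT = 400


class AssociationError(ValueError):
    pass


@dataclass(frozen=True)
class MatchConfig:
    radius_deg: float = DEFAULT_RADIUS_DEG
    max_sample_depth: float = DEFAULT_MAX_DEPTH_M
    metric: str = "great_circle"  # or "degrees" (flat lat/lon distance)

    def __post_init__(self):
        if self.radius_deg <= 0:
            raise AssociationError("radius must be > 0")
        if self.metric not in ("great_circle", "degrees"):
            raise AssociationError(f"unknown metric {self.metric!r}")

    @property
    def radius_km(self) -> float:
        return math.radians(self.radius_deg) * EARTH_RADIUS_KM


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km; accepts scalars or arrays (degrees)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def _check_coords(df, what):
    if np.any(np.abs(df["latitude"]) > 90) or np.any(np.abs(df["longitude"]) > 180):
        raise AssociationError(f"{what}: coordinates out of range")


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def match_records(
    plastic: pd.DataFrame,
    samples: pd.DataFrame,
    config: MatchConfig | None = None,
) -> pd.DataFrame:
    """Match plastic records to their nearest in-radius sample location.

    ``plastic`` needs ``record_id, latitude, longitude, concentration``;
    ``samples`` needs ``sample_id, latitude, longitude, depth`` (plus any
    abundance columns, carried through).  Samples deeper than the configured
    maximum are excluded first.  For each plastic record the nearest eligible
    sample defines the matched *location* (coordinates rounded to 4
    decimals); every sample at that location yields one association record.
    One sample may serve many plastic records.  The result is sorted by
    ``record_id`` then ``sample_id`` and is therefore stable under
    permutation of the input rows.
    """
    if config is None:
        config = MatchConfig()
    _check_coords(plastic, "plastic")
    _check_coords(samples, "samples")
    if np.any(plastic["concentration"] < 0):
        raise AssociationError("plastic concentration must be >= 0")

    eligible = samples[samples["depth"] <= config.max_sample_depth].reset_index(drop=True)
    if eligible.empty:
        return _empty_assoc(samples)

    s_lat = eligible["latitude"].to_numpy(float)
    s_lon = eligible["longitude"].to_numpy(float)
    loc_key = list(
        zip(np.round(s_lat, LOCATION_DECIMALS), np.round(s_lon, LOCATION_DECIMALS))
    )

    rows = []
    for rec in plastic.itertuples(index=False):
        if config.metric == "great_circle":
            d = haversine_km(rec.latitude, rec.longitude, s_lat, s_lon)
            radius = config.radius_km
        else:
            d = np.hypot(s_lat - rec.latitude, s_lon - rec.longitude)
            radius = config.radius_deg
        best = int(np.argmin(d))
        if d[best] > radius:
            continue  # no sample within the radius: record discarded
        best_loc = loc_key[best]
        for i in np.flatnonzero([k == best_loc for k in loc_key]):
            row = {
                "record_id": rec.record_id,
                "sample_id": eligible.at[int(i), "sample_id"],
                "distance_km": float(
                    haversine_km(rec.latitude, rec.longitude, s_lat[i], s_lon[i])
                ),
                "concentration": rec.concentration,
            }
            for col in eligible.columns:
                if col not in ("sample_id", "latitude", "longitude"):
                    row[col] = eligible.at[int(i), col]
            rows.append(row)
    if not rows:
        return _empty_assoc(samples)
    out = pd.DataFrame(rows)
    return out.sort_values(["record_id", "sample_id"], kind="mergesort").reset_index(
        drop=True
    )


def _empty_assoc(samples) -> pd.DataFrame:
    extra = [c for c in samples.columns if c not in ("sample_id", "latitude", "longitude")]
    return pd.DataFrame(
        columns=["record_id", "sample_id", "distance_km", "concentration"] + extra
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def presence_absence_test(
    associations: pd.DataFrame, abundance_col: str = "normalized_abundance"
) -> dict:
    """Two-sided Mann-Whitney U contrasting abundance by plastic presence.

    Presence is concentration > 0.  U is computed exactly (full enumeration)
    when n1*n2 <= 400 and there are no ties, and by the tie-corrected normal
    approximation otherwise.  Reports U for each group, p, and group means
    with standard errors.
    """
    presence = associations[associations["concentration"] > 0][abundance_col]
    absence = associations[associations["concentration"] <= 0][abundance_col]
    return mann_whitney(presence.to_numpy(float), absence.to_numpy(float))


def mann_whitney(x, y) -> dict:
    """Two-sided Mann-Whitney U for two non-empty samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise AssociationError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    method = "exact" if (n1 * n2 <= EXACT_PAIR_LIMIT and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    return {
        "U1": u1,
        "U2": n1 * n2 - u1,
        "p_two_sided": float(res.pvalue),
        "method": method,
        "n1": n1,
        "n2": n2,
        "mean1": float(np.mean(x)),
        "se1": float(np.std(x, ddof=1) / np.sqrt(n1)) if n1 > 1 else float("nan"),
        "mean2": float(np.mean(y)),
        "se2": float(np.std(y, ddof=1) / np.sqrt(n2)) if n2 > 1 else float("nan"),
    }


def linear_fit(concentration, abundance) -> dict:
    """Ordinary least squares of abundance on concentration (untransformed).

    Returns slope, intercept, R², the two-sided slope p-value and n.  Zero
    variance in the predictor is an explicit error.
    """
    x = np.asarray(concentration, dtype=float)
    y = np.asarray(abundance, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise AssociationError("need n >= 3 for a linear fit")
    if np.ptp(x) == 0:
        raise AssociationError("zero variance in concentration")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue) ** 2,
        "p_value": float(res.pvalue),
        "n": int(len(x)),
    }


def association_stats(
    associations: pd.DataFrame, abundance_col: str = "normalized_abundance"
) -> dict:
    """Presence/absence contrast and linear relation on matched records."""
    mw = presence_absence_test(associations, abundance_col)
    lin = linear_fit(associations["concentration"], associations[abundance_col])
    return {"mann_whitney": mw, "linear": lin, "n_records": int(len(associations))}
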