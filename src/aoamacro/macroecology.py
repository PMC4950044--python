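"""Macroecological statistics on transect community tables.

Implements the four pattern analyses of the pipeline:

* distance-decay: Bray-Curtis similarity of every sample of a depth layer to
  the southernmost (or northernmost) reference station, regressed as
  ln(similarity) on great-circle distance per 1000 km, split at the equator;
* Rapoport ranges: per-OTU latitudinal (or temperature) occurrence ranges
  and per-sample Stevens mean ranges, regressed on absolute latitude;
* shared-OTU biogeography: pairwise proportions of OTUs shared between
  provinces or depth layers;
* the latitudinal diversity gradient with a two-hemisphere ANCOVA
  (slope-homogeneity F-test and adjusted means).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .beta import bray_curtis, haversine_km
from .tables import OtuTable, align_samples

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionFit",
    "reference_similarity_profile",
    "decay_segments",
    "fit_decay",
    "otu_ranges",
    "range_vs_latitude",
    "abundance_class_ranges",
    "shared_otus",
    "diversity_gradient_ancova",
]


@dataclass
class RegressionFit:
    """Ordinary least-squares fit summary."""

    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float
    n: int
    x_units: str = ""
    y_units: str = ""

    @property
    def significant(self) -> bool:
        """False (NS) when p >= 0.05."""
        return bool(self.p_value < 0.05)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n": self.n,
            "significant": self.significant,
            "x_units": self.x_units,
            "y_units": self.y_units,
        }


def _ols(x, y, x_units="", y_units="") -> RegressionFit:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 3:
        raise ValueError(f"need >= 3 points for a regression, got {x.size}")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
        x_units=x_units,
        y_units=y_units,
    )


def reference_similarity_profile(
    table: OtuTable,
    meta: pd.DataFrame,
    layer: str,
    reference: str = "southernmost",
):
    """Similarity of each sample of a depth layer to a polar reference.

    Returns ``(profile, trends)``: ``profile`` has one row per non-reference
    sample of the layer (distance_km to the reference, Bray-Curtis
    similarity, latitude), and ``trends`` reports Pearson r both for
    similarity against distance (linear) and against a quadratic in
    latitude (the U-shape of a bipolar transect), labelled explicitly.
    """
    if reference not in ("southernmost", "northernmost"):
        raise ValueError(f"unknown reference {reference!r}")
    sub, msub = align_samples(table, meta)
    keep = msub["layer"] == layer
    if keep.sum() < 2:
        raise ValueError(f"layer {layer!r} has {int(keep.sum())} samples; need >= 2")
    sub = sub.subset_samples(list(msub.loc[keep, "sample_id"]))
    msub = msub.loc[keep].reset_index(drop=True)

    lat = msub["latitude"].to_numpy()
    ref_i = int(np.argmin(lat)) if reference == "southernmost" else int(np.argmax(lat))
    sim = bray_curtis(sub).to_similarity().values[ref_i]

    rows = []
    for i in range(len(msub)):
        if i == ref_i:
            continue
        rows.append(
            {
                "sample_id": msub["sample_id"].iloc[i],
                "distance_km": haversine_km(
                    lat[ref_i], msub["longitude"].iloc[ref_i],
                    lat[i], msub["longitude"].iloc[i],
                ),
                "similarity": float(sim[i]),
                "latitude": float(lat[i]),
            }
        )
    profile = pd.DataFrame(rows)

    trends = {}
    if len(profile) >= 3 and profile["similarity"].std() > 0:
        r_lin = stats.pearsonr(profile["distance_km"], profile["similarity"])
        trends["similarity_vs_distance_linear"] = {
            "r": float(r_lin.statistic), "p_value": float(r_lin.pvalue)
        }
        # quadratic-in-latitude trend: r between observed and fitted values
        coef = np.polyfit(profile["latitude"], profile["similarity"], 2)
        fitted = np.polyval(coef, profile["latitude"])
        r_quad = stats.pearsonr(fitted, profile["similarity"])
        trends["similarity_vs_latitude_quadratic"] = {
            "r": float(r_quad.statistic), "p_value": float(r_quad.pvalue)
        }
    return profile, trends


def fit_decay(profile: pd.DataFrame) -> RegressionFit:
    """OLS of ln(similarity) on distance/1000 km; zero similarities dropped."""
    usable = profile[profile["similarity"] > 0]
    dropped = len(profile) - len(usable)
    if dropped:
        logger.info("fit_decay: dropped %d zero-similarity points", dropped)
    if len(usable) < 3:
        raise ValueError(
            f"decay segment has {len(usable)} usable points (similarity > 0); need >= 3"
        )
    return _ols(
        usable["distance_km"] / 1000.0,
        np.log(usable["similarity"]),
        x_units="1000 km",
        y_units="ln(similarity)",
    )


def decay_segments(south_profile: pd.DataFrame, north_profile: pd.DataFrame) -> dict:
    """Four distance-decay fits split at the equator.

    From the southern reference: towards the equator (targets at latitude
    <= 0) and beyond it (>= 0); likewise from the northern reference.
    Equator samples belong to whichever segment is being fit (the equator is
    the joint endpoint).  Slopes are in ln(similarity) per 1000 km; fits
    with p >= 0.05 are flagged non-significant via ``RegressionFit.significant``.
    """
    return {
        "south_to_equator": fit_decay(south_profile[south_profile["latitude"] <= 0]),
        "south_beyond_equator": fit_decay(south_profile[south_profile["latitude"] >= 0]),
        "north_to_equator": fit_decay(north_profile[north_profile["latitude"] >= 0]),
        "north_beyond_equator": fit_decay(north_profile[north_profile["latitude"] <= 0]),
    }


def otu_ranges(
    table: OtuTable,
    meta: pd.DataFrame,
    axis: str = "latitude",
    presence_threshold: float = 0.0,
):
    """Per-OTU occurrence ranges and per-sample Stevens mean ranges.

    An OTU is present in a sample when its abundance exceeds
    ``presence_threshold``.  Its range on ``axis`` (latitude or temperature)
    is max - min of the axis value over occupied samples (0 for single
    occurrences).  The Stevens mean of a sample is the unweighted mean range
    of the OTUs present in it.  Returns ``(per_otu, per_sample)`` frames;
    OTUs absent everywhere are excluded with a log record.
    """
    col = {"latitude": "latitude", "temperature": "temperature_c"}.get(axis)
    if col is None:
        raise ValueError(f"unknown axis {axis!r}")
    sub, msub = align_samples(table, meta)
    axis_vals = msub[col].to_numpy(float)
    present = sub.values > presence_threshold

    otu_rows, ranges = [], {}
    absent = []
    rel = sub.values / np.maximum(sub.values.sum(axis=1, keepdims=True), 1e-300)
    for j, otu in enumerate(sub.otu_ids):
        occ = present[:, j]
        if not occ.any():
            absent.append(otu)
            continue
        vals = axis_vals[occ]
        rng = float(vals.max() - vals.min())
        ranges[j] = rng
        otu_rows.append(
            {
                "otu_id": otu,
                "axis": axis,
                "min": float(vals.min()),
                "max": float(vals.max()),
                "range": rng,
                "n_occurrences": int(occ.sum()),
                "mean_relative_abundance": float(rel[occ, j].mean()),
            }
        )
    if absent:
        logger.info("otu_ranges: %d OTUs absent everywhere, excluded", len(absent))

    sample_rows = []
    for i, sid in enumerate(sub.sample_ids):
        idx = [j for j in np.flatnonzero(present[i]) if j in ranges]
        if not idx:
            continue
        sample_rows.append(
            {
                "sample_id": sid,
                "stevens_mean_range": float(np.mean([ranges[j] for j in idx])),
                "n_otus_present": len(idx),
            }
        )
    return pd.DataFrame(otu_rows), pd.DataFrame(sample_rows)


def range_vs_latitude(
    per_sample: pd.DataFrame,
    meta: pd.DataFrame,
    hemisphere: str = None,
    layer: str = None,
) -> RegressionFit:
    """OLS of per-sample Stevens mean range on absolute latitude.

    ``hemisphere`` "N"/"S" restricts to latitude >= 0 / <= 0 (the equator
    belongs to both); ``layer`` restricts to one depth layer.  A positive
    significant slope is Rapoport-consistent.
    """
    merged = per_sample.merge(
        meta[["sample_id", "latitude", "layer"]], on="sample_id", how="inner"
    )
    if hemisphere == "N":
        merged = merged[merged["latitude"] >= 0]
    elif hemisphere == "S":
        merged = merged[merged["latitude"] <= 0]
    elif hemisphere is not None:
        raise ValueError(f"hemisphere must be 'N', 'S' or None, got {hemisphere!r}")
    if layer is not None:
        merged = merged[merged["layer"] == layer]
    if len(merged) < 3:
        raise ValueError(
            f"hemisphere={hemisphere!r} layer={layer!r} has {len(merged)} samples; need >= 3"
        )
    return _ols(
        merged["latitude"].abs(),
        merged["stevens_mean_range"],
        x_units="degrees |latitude|",
        y_units="degrees range",
    )


def abundance_class_ranges(
    table: OtuTable,
    meta: pd.DataFrame,
    low_cut: float = 0.005,
    high_cut: float = 0.05,
    layer: str = None,
) -> pd.DataFrame:
    """Mean latitudinal range of low- vs high-abundance OTUs.

    Classes follow maximum relative abundance: HA if it exceeds ``high_cut``,
    LA if it exceeds ``low_cut`` — so HA is nested inside LA.  Both the
    inclusive LA class (every detected OTU above ``low_cut``) and the
    exclusive one (LA without HA members) are reported.  Empty classes are
    reported with NaN mean, not an error.
    """
    if table.mode != "relative":
        raise ValueError("abundance classes are defined on relative-mode tables")
    sub, msub = align_samples(table, meta)
    if layer is not None:
        keep = list(msub.loc[msub["layer"] == layer, "sample_id"])
        sub = sub.subset_samples(keep)
        msub = msub[msub["layer"] == layer]
    per_otu, _ = otu_ranges(sub, msub, axis="latitude")
    max_ab = pd.Series(sub.values.max(axis=0), index=sub.otu_ids)
    per_otu = per_otu.assign(max_abundance=per_otu["otu_id"].map(max_ab))

    ha = per_otu[per_otu["max_abundance"] > high_cut]
    la_incl = per_otu[per_otu["max_abundance"] > low_cut]
    la_excl = la_incl[la_incl["max_abundance"] <= high_cut]
    rows = []
    for name, df in (("HA", ha), ("LA_inclusive", la_incl), ("LA_exclusive", la_excl)):
        rows.append(
            {
                "abundance_class": name,
                "layer": layer if layer is not None else "all",
                "n_otus": len(df),
                "mean_range": float(df["range"].mean()) if len(df) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def shared_otus(
    table: OtuTable,
    meta: pd.DataFrame,
    group_by: str = "province",
    within_layer: str = None,
) -> pd.DataFrame:
    """Pairwise shared-OTU counts and proportions between groups.

    An OTU belongs to a group when its abundance exceeds zero in any of that
    group's samples.  The proportion divides the shared count by the *focal*
    group's richness, so the record (focal, other) is asymmetric in
    proportion but symmetric in ``n_shared``.  Groups without samples are
    excluded with a log record.
    """
    if group_by not in ("province", "layer"):
        raise ValueError(f"group_by must be 'province' or 'layer', got {group_by!r}")
    sub, msub = align_samples(table, meta)
    if within_layer is not None:
        keep = list(msub.loc[msub["layer"] == within_layer, "sample_id"])
        if not keep:
            raise ValueError(f"no samples in layer {within_layer!r}")
        sub = sub.subset_samples(keep)
        msub = msub[msub["layer"] == within_layer].reset_index(drop=True)

    groups = {}
    for g in pd.unique(msub[group_by]):
        ids = list(msub.loc[msub[group_by] == g, "sample_id"])
        idx = [sub.sample_ids.index(s) for s in ids]
        present = set(np.flatnonzero((sub.values[idx] > 0).any(axis=0)))
        if not present:
            logger.info("shared_otus: group %r has no detected OTUs, excluded", g)
            continue
        groups[g] = present
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")

    rows = []
    for focal, fs in groups.items():
        for other, os_ in groups.items():
            if focal == other:
                continue
            shared = len(fs & os_)
            rows.append(
                {
                    "focal_group": focal,
                    "other_group": other,
                    "layer": within_layer if within_layer is not None else "all",
                    "n_shared": shared,
                    "n_focal": len(fs),
                    "n_other": len(os_),
                    "proportion": shared / len(fs),
                }
            )
    return pd.DataFrame(rows)


def diversity_gradient_ancova(
    diversity: pd.DataFrame, meta: pd.DataFrame, layer: str = None
) -> dict:
    """Hemisphere ANCOVA of Shannon diversity against absolute latitude.

    Fits H' ~ |lat| * hemisphere by least squares; the slope-homogeneity
    test is the F-test of the interaction term (full vs additive model).
    Adjusted means are additive-model predictions per hemisphere at the
    grand-mean |lat|.  Requires >= 3 samples per hemisphere.
    """
    merged = diversity.merge(
        meta[["sample_id", "latitude", "layer"]], on="sample_id", how="inner"
    )
    if layer is not None:
        merged = merged[merged["layer"] == layer]
    merged = merged.dropna(subset=["shannon_h"]).copy()
    merged["abs_lat"] = merged["latitude"].abs()
    merged["hemi"] = np.where(merged["latitude"] >= 0, "N", "S")
    counts = merged["hemi"].value_counts()
    if counts.get("N", 0) < 3 or counts.get("S", 0) < 3:
        raise ValueError(
            f"need >= 3 samples per hemisphere, got N={counts.get('N', 0)}, "
            f"S={counts.get('S', 0)}"
        )

    south = (merged["hemi"] == "S").astype(float).to_numpy()
    x = merged["abs_lat"].to_numpy()
    y = merged["shannon_h"].to_numpy()
    x_full = sm.add_constant(np.column_stack([x, south, x * south]))
    x_add = sm.add_constant(np.column_stack([x, south]))
    full = sm.OLS(y, x_full).fit()
    add = sm.OLS(y, x_add).fit()
    ftest = full.compare_f_test(add)  # (F, p, df_diff)

    grand = float(np.mean(x))
    adj_n = float(add.predict([1.0, grand, 0.0])[0])
    adj_s = float(add.predict([1.0, grand, 1.0])[0])
    return {
        "slope_N": float(full.params[1]),
        "slope_S": float(full.params[1] + full.params[3]),
        "adjusted_means": {"N": adj_n, "S": adj_s},
        "interaction_F": float(ftest[0]),
        "interaction_p": float(ftest[1]),
        "n": int(len(merged)),
    }
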