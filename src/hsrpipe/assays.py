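"""Fold-change quantification for bench assays.

Covers three measurement types with shared conventions:

* qRT-PCR relative expression by the efficiency^-ddCt method, combining
  two housekeeping genes (arithmetic mean of their Ct values, which is
  the geometric mean on the quantity scale) and anchoring a reference
  cell line at 1 within each condition;
* western-blot densitometry normalized to a loading control and a
  reference lane;
* kinetic plate-reader viability traces rescaled to percent of the t=0
  signal after subtracting the detergent-killed negative-control floor.

Technical replicates are averaged before any statistics; biological
lines are the statistical unit for group means, s.e.m. and tests.
"""
from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DegenerateInputError, InputError
from .rankstats import pooled_ttest

log = logging.getLogger(__name__)

#: Multiple-comparison corrections accepted by :func:`group_test`.
CORRECTIONS = {"holm-sidak": "holm-sidak", "bonferroni": "bonferroni",
               "fdr_bh": "fdr_bh", "none": None}


def relative_expression(ct: pd.DataFrame, housekeeping,
                        reference_line: str | None,
                        efficiency: float = 2.0,
                        hk_combine: str = "mean_ct") -> pd.DataFrame:
    """Relative transcript quantities from a long-format Ct table.

    ``ct`` columns: ``line, condition, gene, ct`` (one row per technical
    replicate; replicates are averaged first). Per (line, condition,
    gene): quantity = efficiency^-(Ct_gene - mean Ct of housekeeping
    genes), then divided by the reference line's quantity in the same
    condition, so the reference line reads 1 everywhere.
    ``reference_line=None`` skips the cross-line anchor and returns the
    housekeeping-normalized quantities themselves — the ddCt input for
    :func:`fold_over_baseline`, where each line is compared with its own
    baseline condition (a condition effect shared by every line would
    cancel out of the reference-anchored values).

    ``hk_combine`` may be ``"mean_ct"`` or ``"geometric"``; at a single
    fixed efficiency the arithmetic mean of Ct values equals the
    geometric mean of per-gene quantities, so both names select the same
    computation.

    Returns ``line, condition, gene, relative_expression`` for the
    non-housekeeping genes.
    """
    _require_columns(ct, ("line", "condition", "gene", "ct"), "Ct table")
    if hk_combine not in ("mean_ct", "geometric"):
        raise ConfigError(f"unknown hk_combine: {hk_combine!r}")
    if efficiency <= 0:
        raise ConfigError("amplification efficiency must be positive")
    if efficiency == 1.0:
        warnings.warn("efficiency=1 makes all relative expressions 1.0",
                      stacklevel=2)
    hk = list(housekeeping)
    if not hk:
        raise ConfigError("at least one housekeeping gene is required")
    mean_ct = (ct.groupby(["line", "condition", "gene"], sort=False)["ct"]
                 .mean().reset_index())
    lines = mean_ct["line"].unique().tolist()
    if reference_line is not None and reference_line not in lines:
        raise InputError(f"reference line {reference_line!r} not in table")
    wide = mean_ct.pivot_table(index=["line", "condition"], columns="gene",
                               values="ct", sort=False)
    missing_hk = [g for g in hk if g not in wide.columns]
    if missing_hk:
        raise InputError(f"housekeeping gene(s) missing entirely: {missing_hk}")
    hk_na = wide[hk].isna().any(axis=1)
    if hk_na.any():
        line, cond = wide.index[hk_na][0]
        raise InputError(
            f"missing housekeeping measurement for line {line!r}, "
            f"condition {cond!r}")
    hk_ct = wide[hk].mean(axis=1)
    targets = [g for g in wide.columns if g not in hk]
    rows = []
    for gene in targets:
        dct = wide[gene] - hk_ct
        qty = efficiency ** (-dct)
        for cond in dict.fromkeys(wide.index.get_level_values("condition")):
            if reference_line is None:
                ref = 1.0
            else:
                try:
                    ref = qty.loc[(reference_line, cond)]
                except KeyError:
                    raise InputError(
                        f"reference line {reference_line!r} lacks condition "
                        f"{cond!r}") from None
            if np.isnan(ref):
                continue
            for line in lines:
                if (line, cond) in qty.index and not np.isnan(
                        qty.loc[(line, cond)]):
                    rows.append({
                        "line": line, "condition": cond, "gene": gene,
                        "relative_expression":
                            float(qty.loc[(line, cond)] / ref),
                    })
    return pd.DataFrame(rows)


def fold_over_baseline(fc: pd.DataFrame, baseline_condition: str,
                       value_col: str = "relative_expression") -> pd.DataFrame:
    """Divide each line's values by its own baseline condition, per gene.

    Adds a ``fold_over_baseline`` column; baseline rows read exactly 1.
    """
    _require_columns(fc, ("line", "condition", "gene", value_col),
                     "fold-change table")
    out = fc.copy()
    base = fc.loc[fc["condition"] == baseline_condition]
    if base.empty:
        raise InputError(
            f"baseline condition {baseline_condition!r} absent from table")
    base_map = base.set_index(["line", "gene"])[value_col]
    keys = pd.MultiIndex.from_frame(out[["line", "gene"]])
    missing = ~keys.isin(base_map.index)
    if missing.any():
        line, gene = keys[missing][0]
        raise InputError(
            f"line {line!r} lacks baseline {baseline_condition!r} "
            f"for gene {gene!r}")
    out["fold_over_baseline"] = (
        out[value_col].to_numpy() / base_map.loc[keys].to_numpy())
    return out


def pool_group_stats(values: pd.DataFrame, groups: dict,
                     value_col: str = "fold_over_baseline") -> pd.DataFrame:
    """Mean and s.e.m. over biological lines, per group.

    ``values`` must carry one row per line (technical replicates already
    averaged) with columns ``line`` and ``value_col``; ``groups`` maps
    line -> group label. s.e.m. = s / sqrt(n) over lines; a single-line
    group gets mean with NaN s.e.m. and is flagged.
    """
    _require_columns(values, ("line", value_col), "pooled table")
    unassigned = set(values["line"]) - set(groups)
    if unassigned:
        raise InputError(f"lines without group assignment: {sorted(unassigned)}")
    df = values.copy()
    df["group"] = df["line"].map(groups)
    rows = []
    for group, sub in df.groupby("group", sort=False):
        per_line = sub.groupby("line", sort=False)[value_col].mean()
        n = per_line.size
        mean = float(per_line.mean())
        sem = float(per_line.std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
        if n < 2:
            log.warning("group %r has a single line; s.e.m. undefined", group)
        rows.append({"group": group, "n_lines": n, "mean": mean,
                     "sem": sem, "sem_defined": n >= 2})
    return pd.DataFrame(rows)


def group_test(groups: dict, design: str = "t_test",
               correction: str = "holm-sidak") -> dict:
    """Significance testing over biological groups.

    ``groups`` maps group label -> array of per-line values. ``design``
    is ``"t_test"`` (exactly two groups, two-tailed pooled-variance
    Student's t) or ``"one_way_anova"`` (>= 2 groups; the omnibus F is
    followed by all pairwise t comparisons corrected by ``correction``).

    Returns a dict with ``design, statistic, df, p_value`` and, for the
    ANOVA path, a ``pairwise`` DataFrame with raw and corrected p values.
    """
    if correction not in CORRECTIONS:
        raise ConfigError(f"unknown correction {correction!r}; "
                          f"choose from {sorted(CORRECTIONS)}")
    labels = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(labels) < 2:
        raise InputError("need at least two groups")
    for k, arr in arrays.items():
        if arr.size < 2:
            raise InputError(f"group {k!r} needs at least two values")
    if all(np.ptp(arr) == 0 for arr in arrays.values()) and len(
            {arr.mean() for arr in arrays.values()}) > 1:
        raise DegenerateInputError("zero within-group variance with "
                                   "unequal group means")
    if design == "t_test":
        if len(labels) != 2:
            raise ConfigError("t_test design requires exactly two groups")
        t, df, p = pooled_ttest(arrays[labels[0]], arrays[labels[1]])
        return {"design": design, "statistic": t, "df": df, "p_value": p}
    if design != "one_way_anova":
        raise ConfigError(f"unknown design: {design!r}")
    f_stat, p = _sps.f_oneway(*arrays.values())
    pairs, raw = [], []
    for a, b in combinations(labels, 2):
        t, df, pt = pooled_ttest(arrays[a], arrays[b])
        pairs.append({"group_a": a, "group_b": b, "t_statistic": t,
                      "df": df, "p_raw": pt})
        raw.append(pt)
    method = CORRECTIONS[correction]
    adj = (multipletests(raw, method=method)[1] if method is not None
           else np.asarray(raw))
    pairwise = pd.DataFrame(pairs)
    pairwise["p_adjusted"] = adj
    log.info("one-way ANOVA F=%.4g p=%.4g; %d pairwise comparisons, "
             "%s correction", f_stat, p, len(pairs), correction)
    k = len(labels)
    n_total = sum(arr.size for arr in arrays.values())
    return {"design": design, "statistic": float(f_stat),
            "df": (k - 1, n_total - k), "p_value": float(p),
            "pairwise": pairwise}


def viability_percent(trace: pd.DataFrame,
                      subtract_floor: bool = True) -> pd.DataFrame:
    """Percent-viable time series from raw kinetic fluorescence traces.

    ``trace`` columns: ``well, line, time_h, signal,
    negative_control`` (boolean; detergent-killed wells). With the
    default floor subtraction,

        percent(t) = 100 * (S(t) - mean S_neg(t)) / (S(0) - mean S_neg(0))

    per well; ``subtract_floor=False`` rescales to the t=0 signal only.
    Returns per-well percentages plus per-line mean and s.d. over
    replicate wells (columns ``well, line, time_h, percent, line_mean,
    line_sd``).
    """
    _require_columns(trace, ("well", "line", "time_h", "signal",
                             "negative_control"), "viability trace")
    neg = trace.loc[trace["negative_control"]]
    if subtract_floor and neg.empty:
        raise InputError("no negative-control wells on the plate")
    floor = (neg.groupby("time_h")["signal"].mean()
             if subtract_floor else None)
    rows = []
    for well, sub in trace.loc[~trace["negative_control"]].groupby(
            "well", sort=False):
        sub = sub.sort_values("time_h")
        t = sub["time_h"].to_numpy(dtype=float)
        if t.size == 0 or t[0] != 0:
            raise InputError(f"well {well!r} lacks a t=0 baseline")
        if np.any(np.diff(t) <= 0):
            raise InputError(f"timepoints not strictly increasing in {well!r}")
        s = sub["signal"].to_numpy(dtype=float)
        if subtract_floor:
            f = floor.reindex(t).to_numpy(dtype=float)
            if np.isnan(f).any():
                raise InputError(
                    f"negative-control signal missing at some timepoints "
                    f"of well {well!r}")
            denom = s[0] - f[0]
            if denom <= 0:
                raise DegenerateInputError(
                    f"baseline signal does not exceed the negative-control "
                    f"floor in well {well!r}")
            pct = 100.0 * (s - f) / denom
        else:
            if s[0] <= 0:
                raise DegenerateInputError(f"non-positive baseline in {well!r}")
            pct = 100.0 * s / s[0]
        line = sub["line"].iloc[0]
        for ti, pi in zip(t, pct):
            rows.append({"well": well, "line": line, "time_h": float(ti),
                         "percent": float(pi)})
    out = pd.DataFrame(rows)
    summary = out.groupby(["line", "time_h"])["percent"].agg(
        line_mean="mean", line_sd=lambda v: v.std(ddof=1))
    return out.join(summary, on=["line", "time_h"])


def densitometry_normalize(d: pd.DataFrame, reference_lane: str) -> pd.DataFrame:
    """Band / loading-control ratios, rescaled to a reference lane.

    ``d`` columns: ``lane, band_intensity, loading_control_intensity``.
    Adds ``normalized_ratio`` (band over loading control) and
    ``relative_to_reference`` (ratio over the reference lane's ratio, so
    the reference lane reads exactly 1).
    """
    _require_columns(d, ("lane", "band_intensity",
                         "loading_control_intensity"), "densitometry table")
    if d["lane"].duplicated().any():
        raise InputError("duplicate lanes in densitometry table")
    out = d.copy()
    loading = out["loading_control_intensity"].to_numpy(dtype=float)
    if (loading <= 0).any():
        bad = out.loc[loading <= 0, "lane"].iloc[0]
        raise InputError(f"non-positive loading-control intensity in lane "
                         f"{bad!r}")
    if (out["band_intensity"].to_numpy(dtype=float) < 0).any():
        raise InputError("band intensities must be non-negative")
    out["normalized_ratio"] = out["band_intensity"] / loading
    ref = out.loc[out["lane"] == reference_lane, "normalized_ratio"]
    if ref.empty:
        raise InputError(f"reference lane {reference_lane!r} not present")
    if ref.iloc[0] == 0:
        raise DegenerateInputError("reference lane has zero band signal")
    out["relative_to_reference"] = out["normalized_ratio"] / ref.iloc[0]
    return out


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"{what} lacks required column(s): {missing}")
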