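"""Downstream analysis of a label-free quantification (LFQ) protein table.

Mirrors the standard Perseus-style workflow applied to a MaxQuant
proteinGroups export: remove contaminant / reverse / only-identified-by-
site entries, log10-transform the LFQ intensities, run per-protein
two-sample Student's t-tests between the two biological groups (volcano
at -log10 p > 1.30, i.e. p < 0.05), collect group-exclusive proteins by
a presence/absence rule, and feed either list into a hypergeometric
over-representation analysis against user-supplied gene sets.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, InputError
from .rankstats import pooled_ttest

log = logging.getLogger(__name__)

#: Quality-flag columns recognized on a protein table.
FLAG_COLUMNS = ("contaminant", "reverse", "only_identified_by_site")

#: Volcano significance threshold on the p scale.
ALPHA = 0.05


def neglog10(p) -> np.ndarray | float:
    """The -log10 transform used on every p value the stage reports."""
    return -np.log10(p)


@dataclass
class ProteinTable:
    """Protein x sample LFQ intensities with quality flags and a design.

    ``intensities`` holds positive values where quantified and NaN where
    absent (zeros are coerced to NaN with a warning, matching MaxQuant's
    use of 0 for "not quantified"). ``flags`` is a boolean frame over
    :data:`FLAG_COLUMNS`; ``groups`` maps each sample to one of exactly
    two group labels and ``group_order`` fixes which label plays the
    role of "A" (differences are reported as A minus B).
    """

    intensities: pd.DataFrame
    flags: pd.DataFrame
    groups: pd.Series
    group_order: tuple[str, str] = field(default=None)  # type: ignore[assignment]
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            raise InputError("duplicate protein ids")
        if not self.log_scale:
            zero = self.intensities == 0
            if zero.any().any():
                warnings.warn(
                    f"{int(zero.sum().sum())} zero intensities coerced to "
                    f"missing", stacklevel=2)
                self.intensities = self.intensities.mask(zero)
            if (self.intensities.to_numpy(dtype=float) < 0).any():
                raise InputError("raw intensities must be positive")
        missing_flags = [c for c in FLAG_COLUMNS if c not in self.flags.columns]
        if missing_flags:
            warnings.warn(
                f"flag columns absent, treated as all-false: {missing_flags}",
                stacklevel=2)
            for c in missing_flags:
                self.flags[c] = False
        self.flags = self.flags.reindex(self.intensities.index,
                                        fill_value=False).astype(bool)
        extra = set(self.intensities.columns) - set(self.groups.index)
        if extra:
            raise InputError(f"samples without group assignment: {sorted(extra)}")
        self.groups = self.groups.loc[self.intensities.columns]
        labels = list(dict.fromkeys(self.groups))
        if len(labels) != 2:
            raise InputError(
                f"design must contain exactly two groups, got {labels}")
        if self.group_order is None:
            self.group_order = (labels[0], labels[1])
        elif set(self.group_order) != set(labels):
            raise InputError("group_order does not match the design labels")

    @property
    def protein_ids(self) -> list:
        return self.intensities.index.tolist()

    def group_columns(self, label: str) -> list:
        return self.groups.index[self.groups == label].tolist()

    def _replace(self, intensities: pd.DataFrame, log_scale=None) -> "ProteinTable":
        return ProteinTable(intensities,
                            self.flags.loc[intensities.index].copy(),
                            self.groups.copy(),
                            self.group_order,
                            self.log_scale if log_scale is None else log_scale)


@dataclass
class ExclusiveSets:
    """Group-exclusive protein ids (detected in >= min_present samples of
    one group and in none of the other)."""

    exclusive_a: list
    exclusive_b: list
    group_a: str
    group_b: str
    min_present: int


def filter_flags(table: ProteinTable) -> ProteinTable:
    """Drop every row carrying any quality flag; log counts per flag."""
    flagged = table.flags[list(FLAG_COLUMNS)].any(axis=1)
    for c in FLAG_COLUMNS:
        log.info("flag filter: %d rows flagged %s", int(table.flags[c].sum()), c)
    log.info("flag filter: removed %d of %d rows",
             int(flagged.sum()), len(flagged))
    kept = table.intensities.loc[~flagged]
    if kept.empty:
        warnings.warn("flag filtering removed every protein", stacklevel=2)
    return table._replace(kept)


def log10_transform(table: ProteinTable) -> ProteinTable:
    """Replace present intensities by their base-10 log; keep NaN absent."""
    if table.log_scale:
        raise InputError("table is already log-transformed")
    vals = table.intensities
    bad = vals.le(0)
    if bad.any().any():
        prot = bad.any(axis=1)
        pid = prot.index[prot][0]
        sample = bad.columns[bad.loc[pid]][0]
        raise InputError(
            f"non-positive intensity for protein {pid!r}, sample {sample!r}")
    return table._replace(np.log10(vals), log_scale=True)


def two_sample_ttest(table: ProteinTable, min_valid_per_group: int = 2,
                     equal_var: bool = True,
                     alpha: float = ALPHA) -> pd.DataFrame:
    """Per-protein two-tailed t-test between the two groups.

    Only proteins with at least ``min_valid_per_group`` quantified values
    in each group are testable; the rest are excluded (and remain
    candidates for the exclusivity rule). Returns one row per tested
    protein: ``mean_log10_A/B, t_diff, t_statistic, df, p_value,
    neglog10_p, significant, direction, q_value``. ``significant`` uses
    the strict volcano rule ``neglog10_p > -log10(alpha)`` (p < alpha);
    ``q_value`` is a Benjamini-Hochberg annotation, not the volcano rule.
    """
    if min_valid_per_group < 2:
        raise ConfigError("min_valid_per_group must be >= 2 "
                          "(variance needs two values)")
    if not table.log_scale:
        raise InputError("run log10_transform before testing")
    ga, gb = table.group_order
    a = table.intensities[table.group_columns(ga)].to_numpy(dtype=float)
    b = table.intensities[table.group_columns(gb)].to_numpy(dtype=float)
    na = (~np.isnan(a)).sum(axis=1)
    nb = (~np.isnan(b)).sum(axis=1)
    testable = (na >= min_valid_per_group) & (nb >= min_valid_per_group)
    log.info("t-test: %d of %d proteins testable (>=%d valid per group)",
             int(testable.sum()), testable.size, min_valid_per_group)
    rows = []
    ids = table.intensities.index
    for i in np.flatnonzero(testable):
        xa = a[i][~np.isnan(a[i])]
        xb = b[i][~np.isnan(b[i])]
        t, df, p = pooled_ttest(xa, xb, equal_var=equal_var)
        diff = float(xa.mean() - xb.mean())
        rows.append({
            "protein_id": ids[i],
            f"mean_log10_{ga}": float(xa.mean()),
            f"mean_log10_{gb}": float(xb.mean()),
            "t_diff": diff,
            "t_statistic": t,
            "df": df,
            "p_value": p,
            "neglog10_p": float(neglog10(p)),
            "direction": (f"up_in_{ga}" if diff > 0
                          else f"up_in_{gb}" if diff < 0 else "none"),
        })
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    res["significant"] = res["neglog10_p"] > float(neglog10(alpha))
    res["q_value"] = multipletests(res["p_value"].to_numpy(),
                                   method="fdr_bh")[1]
    return res.set_index("protein_id")


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot coordinates: t_diff vs -log10 p plus the calls."""
    if results.empty:
        return pd.DataFrame(
            columns=["t_diff", "neglog10_p", "significant", "direction"])
    return results[["t_diff", "neglog10_p", "significant", "direction"]].copy()


def exclusivity_sets(table: ProteinTable, min_present: int = 2) -> ExclusiveSets:
    """Presence/absence rule: detected in >= ``min_present`` samples of
    one group and in no sample of the other group."""
    ga, gb = table.group_order
    a = table.intensities[table.group_columns(ga)].notna().sum(axis=1)
    b = table.intensities[table.group_columns(gb)].notna().sum(axis=1)
    excl_a = table.intensities.index[(a >= min_present) & (b == 0)].tolist()
    excl_b = table.intensities.index[(b >= min_present) & (a == 0)].tolist()
    log.info("exclusivity: %d proteins only in %s, %d only in %s",
             len(excl_a), ga, len(excl_b), gb)
    return ExclusiveSets(excl_a, excl_b, ga, gb, min_present)


def ora_hypergeometric(selected, universe, gene_sets: dict,
                       min_set_size: int = 5) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` within ``universe``.

    For each gene set with at least ``min_set_size`` members inside the
    universe: hits k among the selection, upper-tail p
    ``P(X >= k | N, K, n)`` and enrichment ratio ``(k/n) / (K/N)``.
    Sets below the membership floor are dropped. Rows are ordered by
    ascending p.
    """
    sel = set(selected)
    uni = set(universe)
    stray = sorted(sel - uni)
    if stray:
        raise InputError(f"selected ids outside the universe: {stray[:10]}")
    if not sel:
        raise InputError("empty selection")
    n_universe, n_sel = len(uni), len(sel)
    rows = []
    for name, members in gene_sets.items():
        in_uni = set(members) & uni
        big_k = len(in_uni)
        if big_k < min_set_size:
            continue
        k = len(in_uni & sel)
        expected = n_sel * big_k / n_universe
        p = float(_sps.hypergeom.sf(k - 1, n_universe, big_k, n_sel))
        rows.append({
            "set_name": name,
            "set_size_in_universe": big_k,
            "hits": k,
            "expected": expected,
            "enrichment_ratio": (k / n_sel) / (big_k / n_universe),
            "p_value": min(1.0, p),
        })
    out = pd.DataFrame(rows, columns=["set_name", "set_size_in_universe",
                                      "hits", "expected", "enrichment_ratio",
                                      "p_value"])
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
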