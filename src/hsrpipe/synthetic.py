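"""Seeded synthetic fixtures with known ground truth.

The generators emulate the inputs of the three analysis stages:

* a developmental brain atlas — samples annotated by region category
  (neocortex, subcortex, ganglionic eminence, cerebellum) crossed with
  developmental stage (postconception weeks up to one year), each
  (region, stage) cell carrying a disjoint planted gene signature on a
  log-normal expression baseline — plus query profiles drawn from one
  chosen cell;
* a 3-vs-3 label-free proteomics intensity matrix with log-normal
  intensities, detection dropout, group-exclusive proteins, planted
  differential proteins and flagged (contaminant/reverse/only-by-site)
  rows;
* qRT-PCR Ct tables with two housekeeping genes, and kinetic viability
  traces with a detergent-killed negative-control floor.

Every generator is a pure function of its spec including the seed.
The defaults model the study conditions the pipeline is meant for:
roughly stage-resolved atlases with a handful of biological replicates
per cell, moderate planted effects (two log2 units over unit log2
noise), and small 3-per-group LFQ designs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, InvalidSpecError
from .matrix import ExpressionMatrix
from .proteomics import FLAG_COLUMNS, ProteinTable

#: Default region categories of the reference atlas.
DEFAULT_REGIONS = ("neocortex", "subcortex", "ganglionic_eminence",
                   "cerebellum")

#: Default developmental stages, chronologically ordered (postconception
#: weeks, then months, then years).
DEFAULT_STAGES = ("pcw8", "pcw9", "pcw12", "pcw13", "pcw16", "pcw17",
                  "pcw21", "pcw24", "pcw35", "pcw37", "mo4", "yr1")

#: Baseline log2 expression distribution (mean, s.d.) shared by all
#: samples of an atlas; rank-based downstream stages are invariant to
#: this choice.
BASELINE_LOG2 = (6.0, 2.0)


@dataclass
class AtlasSpec:
    """Parameters of a synthetic reference atlas.

    ``effect`` is the log2 up-shift applied to a cell's signature genes
    in samples of that cell; ``noise_sd`` the log2-scale residual s.d.
    With ``effect=0`` all sample labels are exchangeable.
    """

    n_genes: int = 2400
    regions: tuple = DEFAULT_REGIONS
    stages: tuple = DEFAULT_STAGES
    replicates_per_cell: int = 3
    signature_size: int = 50
    effect: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.replicates_per_cell <= 0:
            raise InvalidSpecError("counts must be positive")
        if self.signature_size <= 0:
            raise InvalidSpecError("signature_size must be positive")
        if self.effect < 0 or self.noise_sd < 0:
            raise InvalidSpecError("effect and noise_sd must be >= 0")
        if not self.regions or not self.stages:
            raise InvalidSpecError("need at least one region and one stage")
        budget = self.signature_size * len(self.regions) * len(self.stages)
        if budget > self.n_genes:
            raise InvalidSpecError(
                f"signature budget {budget} exceeds n_genes {self.n_genes}")


@dataclass
class AtlasTruth:
    """Ground truth of a generated atlas: the spec, the shared baseline
    log2 means, and the disjoint signature gene sets per (region, stage)."""

    spec: AtlasSpec
    genes: list
    baseline_log2: np.ndarray
    signatures: dict = field(repr=False)

    def signature_of(self, category: tuple) -> list:
        if category not in self.signatures:
            raise InputError(
                f"unknown atlas category {category!r}; known categories are "
                f"(region, stage) pairs such as {next(iter(self.signatures))!r}")
        return self.signatures[category]


def generate_atlas(spec: AtlasSpec) -> tuple[ExpressionMatrix, AtlasTruth]:
    """Generate an annotated atlas matrix and its ground truth.

    The matrix has ``n_genes`` rows and |regions| x |stages| x
    replicates columns; sample metadata carries region and stage. Linear
    expression values are ``2 ** (baseline + effect * signature + noise)``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    baseline = rng.normal(*BASELINE_LOG2, size=spec.n_genes)
    cells = [(r, s) for r in spec.regions for s in spec.stages]
    perm = rng.permutation(spec.n_genes)
    signatures = {}
    for i, cell in enumerate(cells):
        idx = perm[i * spec.signature_size:(i + 1) * spec.signature_size]
        signatures[cell] = sorted(genes[j] for j in idx)
    gene_pos = {g: i for i, g in enumerate(genes)}
    sig_rows = {cell: np.asarray(
        [gene_pos[g] for g in sig]) for cell, sig in signatures.items()}

    columns, meta_rows = [], []
    data = np.empty((spec.n_genes, len(cells) * spec.replicates_per_cell))
    col = 0
    for region, stage in cells:
        for rep in range(1, spec.replicates_per_cell + 1):
            log2 = baseline + rng.normal(0.0, spec.noise_sd, spec.n_genes)
            log2[sig_rows[(region, stage)]] += spec.effect
            data[:, col] = log2
            columns.append(f"{region}_{stage}_r{rep}")
            meta_rows.append({"sample": f"{region}_{stage}_r{rep}",
                              "region": region, "stage": stage})
            col += 1
    values = pd.DataFrame(2.0 ** data, index=genes, columns=columns)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    truth = AtlasTruth(spec, genes, baseline, signatures)
    return ExpressionMatrix(values, meta), truth


def generate_queries(truth: AtlasTruth, category: tuple, n_queries: int,
                     effect_scale: float = 1.0, seed: int = 0,
                     ) -> ExpressionMatrix:
    """Query profiles carrying ``category``'s signature at a scaled effect.

    ``effect_scale=0`` yields pure-noise queries sharing only the atlas
    baseline. Queries use the same noise s.d. as the atlas.
    """
    if n_queries <= 0:
        raise InvalidSpecError("n_queries must be positive")
    sig = truth.signature_of(tuple(category))
    spec = truth.spec
    rng = np.random.default_rng(seed)
    gene_pos = {g: i for i, g in enumerate(truth.genes)}
    rows = np.asarray([gene_pos[g] for g in sig])
    data = np.empty((spec.n_genes, n_queries))
    for j in range(n_queries):
        log2 = truth.baseline_log2 + rng.normal(0.0, spec.noise_sd,
                                                spec.n_genes)
        log2[rows] += spec.effect * effect_scale
        data[:, j] = log2
    cols = [f"query{j + 1}" for j in range(n_queries)]
    return ExpressionMatrix(
        pd.DataFrame(2.0 ** data, index=truth.genes, columns=cols))


@dataclass
class LfqSpec:
    """Parameters of a synthetic label-free proteomics experiment.

    Groups are named A (controls) and B (patients), three samples each
    by default. ``diff_effect`` is the planted mean log10 shift of the
    ``n_diff`` differential proteins (up in A); exclusive proteins are
    fully detected in their group and never in the other; flagged rows
    are disjoint from every truth set.
    """

    n_proteins: int = 2000
    n_per_group: int = 3
    n_diff: int = 50
    diff_effect: float = 0.6
    n_exclusive_a: int = 20
    n_exclusive_b: int = 20
    dropout_rate: float = 0.1
    noise_sd: float = 0.25
    n_flagged_per_kind: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise InvalidSpecError(
                "n_per_group must be >= 2 (t-test impossible otherwise)")
        for name in ("n_proteins", "n_diff", "n_exclusive_a",
                     "n_exclusive_b", "n_flagged_per_kind"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be non-negative")
        if not 0 <= self.dropout_rate < 1:
            raise InvalidSpecError("dropout_rate must be in [0, 1)")
        reserved = (self.n_diff + self.n_exclusive_a + self.n_exclusive_b
                    + 3 * self.n_flagged_per_kind)
        if reserved > self.n_proteins:
            raise InvalidSpecError(
                f"planted rows ({reserved}) exceed n_proteins "
                f"({self.n_proteins})")


@dataclass
class LfqTruth:
    """Ground-truth row labels of a generated LFQ matrix."""

    differential: list
    exclusive_a: list
    exclusive_b: list
    flagged: dict


def generate_lfq(spec: LfqSpec) -> tuple[ProteinTable, LfqTruth]:
    """Generate a protein table plus ground-truth labels.

    Intensities are log10-normal (means N(7, 0.8), residual s.d.
    ``noise_sd``); missing detections are NaN. Group A samples are named
    ``A1..`` and group B ``B1..``; the planted differential shift is up
    in A.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    ids = [f"P{i:05d}" for i in range(n)]
    perm = rng.permutation(n)
    cursor = 0

    def take(k):
        nonlocal cursor
        out = np.sort(perm[cursor:cursor + k])
        cursor += k
        return out

    diff_idx = take(spec.n_diff)
    excl_a_idx = take(spec.n_exclusive_a)
    excl_b_idx = take(spec.n_exclusive_b)
    flag_idx = {c: take(spec.n_flagged_per_kind) for c in FLAG_COLUMNS}

    samples = ([f"A{i + 1}" for i in range(spec.n_per_group)]
               + [f"B{i + 1}" for i in range(spec.n_per_group)])
    in_a = np.array([s.startswith("A") for s in samples])
    mean_log10 = rng.normal(7.0, 0.8, size=n)
    log10 = (mean_log10[:, None]
             + rng.normal(0.0, spec.noise_sd, size=(n, len(samples))))
    log10[np.ix_(diff_idx, np.flatnonzero(in_a))] += spec.diff_effect

    missing = rng.random(size=(n, len(samples))) < spec.dropout_rate
    # keep truth labels unambiguous: a non-planted row must never satisfy
    # the exclusivity rule by chance, so each group retains at least one
    # detection (the group's first sample is restored if dropout removed
    # them all)
    for cols in (np.flatnonzero(in_a), np.flatnonzero(~in_a)):
        lost = missing[:, cols].all(axis=1)
        missing[np.flatnonzero(lost), cols[0]] = False
    # exclusive rows override dropout: fully detected in their group,
    # absent in the other
    missing[excl_a_idx, :] = ~in_a[None, :]
    missing[excl_b_idx, :] = in_a[None, :]

    vals = 10.0 ** log10
    vals[missing] = np.nan
    intensities = pd.DataFrame(vals, index=ids, columns=samples)
    flags = pd.DataFrame(False, index=ids, columns=list(FLAG_COLUMNS))
    for c, idx in flag_idx.items():
        flags.iloc[idx, flags.columns.get_loc(c)] = True
    groups = pd.Series({s: ("A" if a else "B")
                        for s, a in zip(samples, in_a)})
    table = ProteinTable(intensities, flags, groups, group_order=("A", "B"))
    truth = LfqTruth(
        differential=[ids[i] for i in diff_idx],
        exclusive_a=[ids[i] for i in excl_a_idx],
        exclusive_b=[ids[i] for i in excl_b_idx],
        flagged={c: [ids[i] for i in idx] for c, idx in flag_idx.items()},
    )
    return table, truth


#: Housekeeping genes included in every generated Ct table.
HOUSEKEEPING_GENES = ("GAPDH", "TBP")


def generate_ct_table(n_lines: int, conditions, true_folds: dict,
                      seed: int = 0, noise_sd: float = 0.0,
                      replicates: int = 3,
                      line_folds: dict | None = None) -> pd.DataFrame:
    """Long-format Ct table with two housekeeping genes.

    ``true_folds`` maps gene -> {condition: fold over the first
    condition}; folds apply to every line. ``line_folds`` optionally
    maps gene -> {line: multiplier} for line-to-line differences (the
    first line, ``line1``, is the natural reference). Ct values follow
    ``base_ct - log2(fold)`` plus Gaussian noise; housekeeping genes
    have fold 1 everywhere.

    Returns columns ``line, condition, gene, replicate, ct``.
    """
    if n_lines <= 0 or replicates <= 0:
        raise InvalidSpecError("n_lines and replicates must be positive")
    conditions = list(conditions)
    if not conditions:
        raise InvalidSpecError("need at least one condition")
    for gene, per_cond in true_folds.items():
        for cond, fold in per_cond.items():
            if not fold > 0:
                raise InvalidSpecError(
                    f"non-positive fold for {gene!r} in {cond!r}")
    line_folds = line_folds or {}
    for gene, per_line in line_folds.items():
        for line, fold in per_line.items():
            if not fold > 0:
                raise InvalidSpecError(
                    f"non-positive line fold for {gene!r}, {line!r}")
    rng = np.random.default_rng(seed)
    lines = [f"line{i + 1}" for i in range(n_lines)]
    target_genes = list(true_folds)
    genes = target_genes + list(HOUSEKEEPING_GENES)
    base_ct = {g: c for g, c in zip(
        genes, rng.uniform(18.0, 28.0, size=len(genes)))}
    rows = []
    for line in lines:
        for cond in conditions:
            for gene in genes:
                fold = 1.0
                if gene in true_folds:
                    fold = true_folds[gene].get(cond, 1.0)
                    fold *= line_folds.get(gene, {}).get(line, 1.0)
                ct0 = base_ct[gene] - np.log2(fold)
                for rep in range(1, replicates + 1):
                    ct = ct0 + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
                    rows.append({"line": line, "condition": cond,
                                 "gene": gene, "replicate": rep,
                                 "ct": float(ct)})
    return pd.DataFrame(rows)


def generate_viability(n_lines: int = 3, timepoints=(0, 1, 2, 3, 4, 5, 6),
                       half_life_h: float = 2.0, n_replicates: int = 3,
                       signal0: float = 1000.0, floor: float = 50.0,
                       noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Kinetic plate-reader traces with exponential viability decay.

    Live wells read ``floor + (signal0 - floor) * 2^(-t / half_life_h)``
    plus optional Gaussian noise; negative-control (detergent-killed)
    wells sit at the floor. With zero noise, percent viability recovers
    ``100 * 2^(-t / half_life_h)`` exactly.

    Returns columns ``well, line, time_h, signal, negative_control``.
    """
    if half_life_h <= 0 or signal0 <= floor:
        raise InvalidSpecError(
            "half-life must be positive and signal0 must exceed the floor")
    rng = np.random.default_rng(seed)
    t = np.asarray(sorted(timepoints), dtype=float)
    if t[0] != 0:
        raise InvalidSpecError("timepoints must include t=0")
    rows = []
    for i in range(n_lines):
        line = f"line{i + 1}"
        for rep in range(1, n_replicates + 1):
            well = f"{line}_w{rep}"
            sig = floor + (signal0 - floor) * 2.0 ** (-t / half_life_h)
            if noise_sd:
                sig = sig + rng.normal(0.0, noise_sd, size=t.size)
            for ti, si in zip(t, sig):
                rows.append({"well": well, "line": line, "time_h": float(ti),
                             "signal": float(si), "negative_control": False})
    for rep in range(1, n_replicates + 1):
        well = f"triton_w{rep}"
        sig = np.full(t.size, floor)
        if noise_sd:
            sig = sig + rng.normal(0.0, noise_sd, size=t.size)
        for ti, si in zip(t, sig):
            rows.append({"well": well, "line": "triton", "time_h": float(ti),
                         "signal": float(si), "negative_control": True})
    return pd.DataFrame(rows)
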