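"""Per-gene randomized-complete-block ANOVA with pairwise cell-mean
contrasts and the triple significance filter.

The additive block-treatment model (no block x treatment interaction) is
fitted on log2 intensities; the fold-change and absolute-difference
filters operate on the linear scale, as per-subject statistics whose
median over blocks is then taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONDITIONS, ExpressionStudy, ValidationError

#: The six unordered treatment pairs, ordered (treatment, reference).
CONTRAST_PAIRS: tuple[tuple[str, str], ...] = (
    ("IgG", "medium"),
    ("IL12", "medium"),
    ("IgG_IL12", "medium"),
    ("IL12", "IgG"),
    ("IgG_IL12", "IgG"),
    ("IgG_IL12", "IL12"),
)

#: The three primary vs-medium comparisons.
PRIMARY_PAIRS: tuple[tuple[str, str], ...] = CONTRAST_PAIRS[:3]


def contrast_name(pair: tuple[str, str]) -> str:
    return f"{pair[0]}_vs_{pair[1]}"


@dataclass
class DEThresholds:
    """Cutoffs of the triple significance filter (strict inequalities)."""

    alpha_per_contrast: float = 0.008
    fc_threshold: float = 2.0
    diff_threshold: float = 150.0
    m_contrasts: int = 6
    family_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("alpha_per_contrast", "fc_threshold", "diff_threshold", "family_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.alpha_per_contrast > self.family_alpha:
            raise ValueError("alpha_per_contrast must not exceed family_alpha")


def bonferroni_threshold(family_alpha: float, m: int) -> float:
    """Exact per-test cutoff ``family_alpha / m``.

    The pipeline default of 0.008 is this value at (0.05, 6) rounded to
    three decimals.
    """
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return family_alpha / m


@dataclass
class BlockAnovaFit:
    """Vectorized per-gene fit of the additive block-treatment model."""

    genes: list[str]
    conditions: list[str]
    blocks: list[str]
    cell_means: np.ndarray  # (n_genes, k) treatment means
    block_means: np.ndarray  # (n_genes, b)
    grand_mean: np.ndarray  # (n_genes,)
    mse: np.ndarray  # (n_genes,)
    df_error: int = field(init=False)

    def __post_init__(self) -> None:
        b, k = len(self.blocks), len(self.conditions)
        self.df_error = (b - 1) * (k - 1)
        if self.df_error < 1:
            raise ValidationError("need b >= 2 blocks and k >= 2 treatments")

    @property
    def b(self) -> int:
        return len(self.blocks)

    @property
    def k(self) -> int:
        return len(self.conditions)


def _cell_array(study: ExpressionStudy) -> tuple[np.ndarray, list[str], list[str]]:
    """Arrange a collapsed complete study as (genes, blocks, conditions)."""
    donors = study.donors
    conditions = study.conditions
    missing = [
        (d, c)
        for d in donors
        for c in conditions
        if not study.sample_ids(d, c)
    ]
    if missing:
        raise ValidationError(f"incomplete design; missing cells: {missing}")
    y = np.empty((len(study.genes), len(donors), len(conditions)))
    for i, d in enumerate(donors):
        for j, c in enumerate(conditions):
            ids = study.sample_ids(d, c)
            if len(ids) != 1:
                raise ValidationError(
                    f"cell ({d}, {c}) has {len(ids)} samples; collapse replicates first"
                )
            y[:, i, j] = study.column(ids[0])
    return y, donors, conditions


def fit_block_anova(study: ExpressionStudy, log2: bool = True) -> BlockAnovaFit:
    """Fit the additive two-way decomposition per gene.

    SS_total = SS_block + SS_treatment + SS_error with
    MSE = SS_error / ((b-1)(k-1)).  ``log2=True`` (default) fits on log2
    intensities; the study must be floored positive in that case.
    """
    y, donors, conditions = _cell_array(study)
    if len(donors) < 2 or len(conditions) < 2:
        raise ValidationError("need at least 2 blocks and 2 treatments")
    if log2:
        if np.any(y <= 0):
            raise ValidationError("non-positive intensities; floor the study before log2 fit")
        y = np.log2(y)
    grand = y.mean(axis=(1, 2))
    block_means = y.mean(axis=2)  # (g, b)
    cell_means = y.mean(axis=1)  # (g, k)
    resid = (
        y
        - block_means[:, :, None]
        - cell_means[:, None, :]
        + grand[:, None, None]
    )
    b, k = len(donors), len(conditions)
    ss_error = np.sum(resid**2, axis=(1, 2))
    mse = ss_error / ((b - 1) * (k - 1))
    return BlockAnovaFit(
        genes=list(study.genes),
        conditions=conditions,
        blocks=donors,
        cell_means=cell_means,
        block_means=block_means,
        grand_mean=grand,
        mse=mse,
    )


def contrast_test(
    fit: BlockAnovaFit, pair: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cell-mean contrast between two treatments.

    Returns per-gene (estimate, t, two-sided p).  With MSE = 0 the
    degenerate convention applies: t = +/-inf and p = 0 when the
    estimate is nonzero, t = 0 and p = 1 when it is zero.
    """
    for cond in pair:
        if cond not in fit.conditions:
            raise ValidationError(f"condition {cond!r} not in fit {fit.conditions}")
    j = fit.conditions.index(pair[0])
    jr = fit.conditions.index(pair[1])
    estimate = fit.cell_means[:, j] - fit.cell_means[:, jr]
    # treat MSE that is pure accumulation roundoff as exactly zero so the
    # degenerate convention fires on noiseless fixtures
    scale = np.maximum(np.abs(fit.grand_mean), 1.0)
    mse = np.where(fit.mse <= (1e-12 * scale) ** 2, 0.0, fit.mse)
    se = np.sqrt(2.0 * mse / fit.b)
    t = np.where(se > 0, estimate / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=fit.df_error)
    zero_mse = se == 0
    nonzero_est = estimate != 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero_mse & nonzero_est, np.sign(estimate) * np.inf, t)
    p = np.where(zero_mse, np.where(nonzero_est, 0.0, 1.0), p)
    return estimate, t, p


def fold_change_stats(
    study: ExpressionStudy, pair: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Median over blocks of per-block fold change and |intensity difference|.

    Per block d: fc_d = y[d, treatment] / y[d, reference] and
    diff_d = |y[d, treatment] - y[d, reference]|, both on the linear
    scale; the even-b median is the mean of the two central order
    statistics (numpy convention).
    """
    y, donors, conditions = _cell_array(study)
    for cond in pair:
        if cond not in conditions:
            raise ValidationError(f"condition {cond!r} missing from study")
    j = conditions.index(pair[0])
    jr = conditions.index(pair[1])
    treat = y[:, :, j]
    ref = y[:, :, jr]
    if np.any(ref <= 0):
        raise ValidationError("non-positive reference intensities; floor the study first")
    median_fc = np.median(treat / ref, axis=1)
    median_abs_diff = np.median(np.abs(treat - ref), axis=1)
    return median_fc, median_abs_diff


def call_differential_genes(
    study: ExpressionStudy,
    thresholds: DEThresholds | None = None,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Apply the triple filter to every gene and all six contrasts.

    A gene is significant for a contrast iff p < alpha AND
    (median_fc > fc OR median_fc < 1/fc) AND median_abs_diff > diff,
    all strict.  Direction is ``up`` when median_fc > fc, ``down`` when
    median_fc < 1/fc, else ``none``.  Returns a long-format table with
    one row per gene x contrast; the three vs-medium contrasts carry
    ``primary = True``.
    """
    thresholds = thresholds or DEThresholds()
    floored = study.floor(floor)
    fit = fit_block_anova(floored, log2=True)
    frames = []
    for pair in CONTRAST_PAIRS:
        estimate, t, p = contrast_test(fit, pair)
        median_fc, median_abs_diff = fold_change_stats(floored, pair)
        pass_p = p < thresholds.alpha_per_contrast
        up = median_fc > thresholds.fc_threshold
        down = median_fc < 1.0 / thresholds.fc_threshold
        pass_fc = up | down
        pass_diff = median_abs_diff > thresholds.diff_threshold
        significant = pass_p & pass_fc & pass_diff
        direction = np.where(up, "up", np.where(down, "down", "none"))
        frames.append(
            pd.DataFrame(
                {
                    "gene": fit.genes,
                    "contrast": contrast_name(pair),
                    "primary": pair in PRIMARY_PAIRS,
                    "estimate": estimate,
                    "t": t,
                    "p": p,
                    "median_fc": median_fc,
                    "median_abs_diff": median_abs_diff,
                    "pass_p": pass_p,
                    "pass_fc": pass_fc,
                    "pass_diff": pass_diff,
                    "significant": significant,
                    "direction": direction,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def significant_sets(table: pd.DataFrame) -> dict[tuple[str, str], set[str]]:
    """Map (contrast, direction) -> set of significant genes.

    Only rows with ``significant`` contribute; direction is ``up`` or
    ``down``.
    """
    out: dict[tuple[str, str], set[str]] = {}
    for pair in CONTRAST_PAIRS:
        name = contrast_name(pair)
        for direction in ("up", "down"):
            mask = (
                (table["contrast"] == name)
                & table["significant"]
                & (table["direction"] == direction)
            )
            out[(name, direction)] = set(table.loc[mask, "gene"])
    return out
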