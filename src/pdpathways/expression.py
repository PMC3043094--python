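"""Within-individual adjacent-Braak-region differential expression.

The design: for every subject, subtract each region's log2 expression from
the next region's in Braak order (later minus earlier), giving one delta per
consecutive region pair.  Controls are treated as replicates; their average
delta is subtracted from each case's delta so that normal region-to-region
baseline variation cancels.  Each adjusted case delta is then tested against
the control replicate delta distribution with a z statistic

    z = adjusted_delta / (sd_control * sqrt(1 + 1/n_controls)),

where the sqrt term accounts for the sampling error of the control mean.
A t-test or ANOVA is not applicable here: each individual and region pair is
unique, so the control replicates are the only source of a null spread.
Calls additionally require the adjusted delta to clear a linear fold-change
threshold (|delta| >= log2(threshold)); BH correction is applied across
genes within each (subject, region-pair) stratum, mirroring the
one-subtraction-at-a-time workflow.

Genes whose control deltas have zero variance are uncallable (p set to 1)
rather than infinitely significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import ExpressionPanel, PipelineConfig

log = logging.getLogger(__name__)

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NONE = "none"

SUBTRACTION_COLUMNS = [
    "gene", "subject", "pair", "raw_delta", "adjusted_delta", "p_value",
    "q_value", "call",
]


@dataclass
class DifferentialGeneLists:
    up: set[str]
    down: set[str]

    @property
    def merged(self) -> set[str]:
        return self.up | self.down


def adjacent_deltas(panel: ExpressionPanel, subject: str) -> pd.DataFrame:
    """Per-gene deltas between consecutive Braak regions for one subject.

    Row index is gene id; columns are the region pairs "earlier->later";
    each entry is value(later) - value(earlier) in log2 units.
    """
    j = panel.subject_index(subject)
    vals = panel.values[:, j, :]
    deltas = vals[:, 1:] - vals[:, :-1]
    return pd.DataFrame(deltas, index=panel.genes, columns=panel.pair_labels)


def _delta_cube(panel: ExpressionPanel) -> np.ndarray:
    """(genes, subjects, pairs) array of raw adjacent-region deltas."""
    return panel.values[:, :, 1:] - panel.values[:, :, :-1]


def control_average_deltas(panel: ExpressionPanel) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean and sample sd (ddof=1) of raw deltas across control replicates."""
    controls = panel.control_subjects
    if len(controls) < 2:
        raise ValueError("need >= 2 controls to estimate delta variance")
    idx = [panel.subject_index(s) for s in controls]
    cube = _delta_cube(panel)[:, idx, :]
    mean = cube.mean(axis=1)
    sd = cube.std(axis=1, ddof=1)
    n_zero = int((sd == 0).sum())
    if n_zero:
        log.warning("%d (gene, pair) control sds are exactly zero", n_zero)
    cols = panel.pair_labels
    return (
        pd.DataFrame(mean, index=panel.genes, columns=cols),
        pd.DataFrame(sd, index=panel.genes, columns=cols),
    )


def adjust_case_deltas(
    case_deltas: pd.DataFrame, control_means: pd.DataFrame
) -> pd.DataFrame:
    """Subtract the control mean delta from one case's raw deltas."""
    if not case_deltas.index.equals(control_means.index) or list(
        case_deltas.columns
    ) != list(control_means.columns):
        raise ValueError("case and control delta tables are not aligned")
    return case_deltas - control_means


def adjusted_delta_pvalues(adjusted, control_sds, n_controls: int):
    """Two-sided normal p for adjusted deltas against the control spread.

    z = adjusted / (sd * sqrt(1 + 1/n_controls)); entries with sd == 0 are
    uncallable and get p = 1 (z = 0).  Returns (z, p) arrays broadcast over
    the inputs.
    """
    adjusted = np.asarray(adjusted, dtype=float)
    sd = np.asarray(control_sds, dtype=float)
    if n_controls < 2:
        raise ValueError("need >= 2 controls")
    scale = sd * np.sqrt(1.0 + 1.0 / n_controls)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(scale > 0, adjusted / np.where(scale > 0, scale, 1.0), 0.0)
    p = np.where(scale > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return z, p


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (q-values), in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(panel: ExpressionPanel, config: PipelineConfig) -> pd.DataFrame:
    """Full subtraction table: one row per (gene, case subject, region pair).

    Columns: gene, subject, pair, raw_delta, adjusted_delta, p_value,
    q_value, call.  BH is applied across genes separately within each
    (subject, pair) stratum.
    """
    cases = panel.case_subjects
    controls = panel.control_subjects
    n_c = len(controls)
    cube = _delta_cube(panel)
    ctrl_idx = [panel.subject_index(s) for s in controls]
    case_idx = [panel.subject_index(s) for s in cases]
    ctrl = cube[:, ctrl_idx, :]
    ctrl_mean = ctrl.mean(axis=1)
    ctrl_sd = ctrl.std(axis=1, ddof=1)

    raw = cube[:, case_idx, :]                      # (genes, cases, pairs)
    adjusted = raw - ctrl_mean[:, None, :]

    n_zero = int((ctrl_sd == 0).sum())
    if n_zero:
        log.warning("%d (gene, pair) strata uncallable (zero control sd)", n_zero)
    _, p = adjusted_delta_pvalues(adjusted, ctrl_sd[:, None, :], n_c)

    q = np.empty_like(p)
    for j in range(p.shape[1]):
        for k in range(p.shape[2]):
            q[:, j, k] = benjamini_hochberg(p[:, j, k])

    thr = config.log2_fold_threshold
    sig = q < config.q_threshold
    call = np.full(p.shape, CALL_NONE, dtype=object)
    call[sig & (adjusted >= thr)] = CALL_UP
    call[sig & (adjusted <= -thr)] = CALL_DOWN

    n_genes, n_cases, n_pairs = raw.shape
    gene_col = np.repeat(panel.genes, n_cases * n_pairs)
    subj_col = np.tile(np.repeat(cases, n_pairs), n_genes)
    pair_col = np.tile(panel.pair_labels, n_genes * n_cases)
    return pd.DataFrame(
        {
            "gene": gene_col,
            "subject": subj_col,
            "pair": pair_col,
            "raw_delta": raw.ravel(),
            "adjusted_delta": adjusted.ravel(),
            "p_value": p.ravel(),
            "q_value": q.ravel(),
            "call": call.ravel(),
        }
    )


def collect_gene_lists(sub_table: pd.DataFrame) -> DifferentialGeneLists:
    """Up/down/merged gene lists: a gene is listed if called in any stratum.

    A gene up in one subject and down in another appears in both lists; the
    merged list counts it once.
    """
    up = set(sub_table.loc[sub_table["call"] == CALL_UP, "gene"])
    down = set(sub_table.loc[sub_table["call"] == CALL_DOWN, "gene"])
    return DifferentialGeneLists(up=up, down=down)


def differential_analysis(
    panel: ExpressionPanel, config: PipelineConfig
) -> tuple[pd.DataFrame, DifferentialGeneLists]:
    table = call_differential(panel, config)
    return table, collect_gene_lists(table)
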