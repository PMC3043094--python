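"""Fisher's combined-probability meta-analysis of the two pathway studies.

For each pathway tested in both the GWAS and the expression analysis the
two p-values are combined as chi2_stat = -2(ln p_gwas + ln p_expr), which
under independent nulls follows a chi-square with 4 degrees of freedom
(2 tests x 2 df each); the combined p is its survival function, equal in
closed form to p1*p2*(1 - ln(p1*p2)).  Combined p-values are
Bonferroni-corrected by M = the number of pathways actually combined, and
ranked ascending (ties broken by pathway id).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import EnrichmentResult
from .models import GeneSetCollection

log = logging.getLogger(__name__)

FISHER_DF = 4  # two independent tests, 2 df each

META_COLUMNS = [
    "pathway_id", "name", "p_gwas", "p_expr", "chi2_stat", "p_meta",
    "p_corrected", "rank",
]


@dataclass(frozen=True)
class OverlapReport:
    n_gwas_sig: int
    n_expr_sig: int
    n_common: int
    common_ids: frozenset[str]


def _check_p(p: float, label: str) -> float:
    if p <= 0:
        raise ValueError(f"{label} must be > 0 (log undefined), got {p}")
    if p > 1:
        if p > 1 + 1e-9:
            raise ValueError(f"{label} must be <= 1, got {p}")
        log.warning("%s = %.17g slightly above 1; clamped", label, p)
        return 1.0
    return float(p)


def fisher_combine(p_gwas: float, p_expr: float) -> tuple[float, float]:
    """Return (chi2_stat, combined p) for two independent p-values."""
    p1 = _check_p(p_gwas, "p_gwas")
    p2 = _check_p(p_expr, "p_expr")
    stat = -2.0 * (math.log(p1) + math.log(p2))
    p_meta = float(stats.chi2.sf(stat, FISHER_DF))
    return stat, p_meta


def bonferroni_correct(p_meta: float, M: int) -> float:
    """min(1, M * p), the Bonferroni-corrected p over M performed tests."""
    if M < 1:
        raise ValueError("M must be >= 1")
    return min(1.0, M * p_meta)


def infer_bonferroni_multiplier(
    pairs: Iterable[tuple[float, float]], tol: float = 0.02
) -> int:
    """Recover the integer test count M from (raw p, corrected p) pairs.

    Each uncapped pair fixes corrected/raw = M up to the rounding of the
    printed values; the median ratio is rounded to the nearest integer and
    every pair is required to agree with it within ``tol`` relative.
    """
    ratios = [c / p for p, c in pairs if c < 1]
    if not ratios:
        raise ValueError("no uncapped (p, corrected) pairs to infer from")
    M = int(round(float(np.median(ratios))))
    off = [r for r in ratios if abs(r - M) > tol * M]
    if off:
        raise ValueError(f"ratios inconsistent with a single multiplier {M}: {off}")
    return M


def meta_analysis(
    gwas_results: Sequence[EnrichmentResult],
    expr_results: Sequence[EnrichmentResult],
) -> tuple[pd.DataFrame, list[str]]:
    """Combine per-pathway p-values from the two studies.

    Only pathways tested in BOTH analyses are combined; M (the Bonferroni
    multiplier) is their count.  Returns the ranked table plus the ids of
    pathways tested in only one study.
    """
    gwas = {r.pathway_id: r for r in gwas_results}
    expr = {r.pathway_id: r for r in expr_results}
    shared = sorted(set(gwas) & set(expr))
    uncombined = sorted(set(gwas) ^ set(expr))
    if not shared:
        raise ValueError("no pathway was tested in both analyses; nothing to combine")
    M = len(shared)
    rows = []
    for pid in shared:
        p1, p2 = gwas[pid].p_value, expr[pid].p_value
        stat, p_meta = fisher_combine(p1, p2)
        rows.append((pid, gwas[pid].name, p1, p2, stat, p_meta,
                     bonferroni_correct(p_meta, M)))
    df = pd.DataFrame(rows, columns=META_COLUMNS[:-1])
    df = df.sort_values(["p_meta", "pathway_id"]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df, uncombined


def overlap_report(gwas_sig: set[str], expr_sig: set[str]) -> OverlapReport:
    """Venn counts of the per-study significant pathway sets."""
    common = frozenset(gwas_sig & expr_sig)
    return OverlapReport(
        n_gwas_sig=len(gwas_sig),
        n_expr_sig=len(expr_sig),
        n_common=len(common),
        common_ids=common,
    )


def pathway_gene_provenance(
    pathway_id: str,
    gwas_query: set[str],
    expr_query: set[str],
    pathways: GeneSetCollection,
) -> pd.DataFrame:
    """Label each pathway member by which study's query list contains it."""
    if pathway_id not in pathways:
        raise KeyError(f"unknown pathway {pathway_id!r}")
    rows = []
    for gene in sorted(pathways.members(pathway_id)):
        in_g, in_e = gene in gwas_query, gene in expr_query
        label = (
            "both" if in_g and in_e
            else "gwas_only" if in_g
            else "expr_only" if in_e
            else "neither"
        )
        rows.append((gene, label))
    return pd.DataFrame(rows, columns=["gene", "label"])


def format_overlap(report: OverlapReport) -> str:
    lines = [
        f"GWAS-significant pathways:       {report.n_gwas_sig}",
        f"Expression-significant pathways: {report.n_expr_sig}",
        f"Common to both:                  {report.n_common}",
    ]
    if report.common_ids:
        lines.append("Common ids: " + ", ".join(sorted(report.common_ids)))
    return "\n".join(lines) + "\n"
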