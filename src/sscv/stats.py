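"""Evaluation statistics for splice-site creating variants.

Covers the novel-junction usage ratio, the per-tissue one-sided Wilcoxon
rank-sum comparison of carriers vs non-carriers, Fisher's method for
combining per-tissue p-values, the genomic (DNA-level) validation rule,
and the germline/somatic origin triage from tumour and matched-normal
pileups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

GERMLINE = "Germline"
SOMATIC = "Somatic"
SOMATIC_OR_GERMLINE = "Somatic_or_germline"
AMBIGUOUS = "Ambiguous"
FALSE_POSITIVE = "False_positive"

ORIGIN_CATEGORIES = (GERMLINE, SOMATIC, SOMATIC_OR_GERMLINE, AMBIGUOUS, FALSE_POSITIVE)


@dataclass(frozen=True)
class RatioObservation:
    """Per-sample usage of the novel junction relative to the hijacked one."""

    sample_id: str
    tissue: str
    carrier: bool
    n_novel: int
    n_hijacked: int

    @property
    def ratio(self) -> float:
        return novel_junction_ratio(self.n_novel, self.n_hijacked)

    @property
    def undefined(self) -> bool:
        return self.n_novel == 0 and self.n_hijacked == 0


def novel_junction_ratio(n_novel: int, n_hijacked: int) -> float:
    """#novel / (#novel + #hijacked); 0.0 when both counts are zero."""
    if n_novel < 0 or n_hijacked < 0:
        raise ValueError("junction read counts must be non-negative")
    total = n_novel + n_hijacked
    if total == 0:
        return 0.0
    return n_novel / total


def wilcoxon_one_sided(
    carrier_ratios: Sequence[float], noncarrier_ratios: Sequence[float]
) -> Optional[float]:
    """One-sided rank-sum p-value for carriers having greater ratios.

    Exact enumeration when the smaller group has <= 8 observations and the
    data are tie-free; normal approximation with tie correction otherwise.
    Returns None when either group is empty (the tissue is skipped).
    """
    x = np.asarray(carrier_ratios, dtype=float)
    y = np.asarray(noncarrier_ratios, dtype=float)
    if x.size == 0 or y.size == 0:
        return None
    tie_free = len(set(x.tolist()) | set(y.tolist())) == x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.pvalue)


def fisher_combine(p_values: Sequence[float], clamp: float = 1e-300) -> Optional[float]:
    """Fisher's method: X^2 = -2 sum(ln p) against chi-square with 2k df."""
    ps = [p for p in p_values if p is not None]
    if not ps:
        return None
    if any(p < 0 or p > 1 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    x2 = -2.0 * sum(math.log(max(p, clamp)) for p in ps)
    return float(sps.chi2.sf(x2, df=2 * len(ps)))


def combine_tissue_pvalues(observations: Sequence[RatioObservation]) -> Optional[float]:
    """Per-tissue one-sided rank tests combined across tissues."""
    tissues = sorted({o.tissue for o in observations})
    ps = []
    for tissue in tissues:
        carriers = [o.ratio for o in observations if o.tissue == tissue and o.carrier]
        others = [o.ratio for o in observations if o.tissue == tissue and not o.carrier]
        p = wilcoxon_one_sided(carriers, others)
        if p is not None:
            ps.append(p)
    return fisher_combine(ps)


def validate_genomic(depth: int, alt_reads: int) -> bool:
    """DNA-level confirmation: > 2 supporting reads and > 5% of coverage."""
    if alt_reads < 0 or depth < alt_reads:
        raise ValueError("need depth >= alt_reads >= 0")
    if depth == 0:
        return False
    return alt_reads > 2 and alt_reads / depth > 0.05


@dataclass(frozen=True)
class OriginThresholds:
    """Decision-tree thresholds for origin triage (documented defaults)."""

    min_normal_depth: int = 8
    germline_vaf: float = 0.25


@dataclass(frozen=True)
class OriginCall:
    category: str
    tumor_depth: int
    tumor_alt: int
    normal_depth: int
    normal_alt: int
    thresholds: OriginThresholds


def classify_origin(
    tumor: tuple[int, int],
    normal: tuple[int, int],
    thresholds: OriginThresholds = OriginThresholds(),
) -> OriginCall:
    """Germline/somatic triage from tumour and matched-normal pileups.

    Order: insufficient normal coverage -> Ambiguous; tumour failing the
    DNA-level validation rule -> False_positive; normal VAF at or above the
    germline threshold -> Germline; no normal support -> Somatic; residual
    low-level normal support -> Somatic_or_germline.
    """
    t_depth, t_alt = tumor
    n_depth, n_alt = normal
    if n_depth < thresholds.min_normal_depth:
        category = AMBIGUOUS
    elif not validate_genomic(t_depth, t_alt):
        category = FALSE_POSITIVE
    elif n_depth > 0 and n_alt / n_depth >= thresholds.germline_vaf:
        category = GERMLINE
    elif n_alt == 0:
        category = SOMATIC
    else:
        category = SOMATIC_OR_GERMLINE
    return OriginCall(category, t_depth, t_alt, n_depth, n_alt, thresholds)
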