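"""Independent validation statistics.

Allelic-imbalance testing: within one treatment condition, the natural
log ratio of the two allele quantities (numerator fixed to the allele
associated with increased expression) is quantile-normalized and the
mean of heterozygotes is compared against homozygotes — which carry no
true imbalance and serve as the empirical null — by a one-tailed Welch
t-test.  Set-overlap significance uses the upper-tail hypergeometric
probability.
"""

from __future__ import annotations

from collections.abc import Collection

import numpy as np
from scipy import stats

from .preprocess import quantile_normalize_to_normal


def ase_test(
    log_ratios: np.ndarray, genotype_class: np.ndarray
) -> tuple[float, float]:
    """Allelic-imbalance test for one gene within one treatment.

    ``genotype_class`` holds "het"/"hom" per measurement.  Log ratios are
    quantile-normalized across all measurements in the treatment, then a
    one-tailed Welch t-test asks whether heterozygote means exceed
    homozygote means (the direction fixed by the numerator convention).
    Returns (mean normalized het log-ratio, one-tailed p).
    """
    lr = np.asarray(log_ratios, dtype=float)
    cls = np.asarray(genotype_class)
    bad = set(np.unique(cls)) - {"het", "hom"}
    if bad:
        raise ValueError(f"unknown genotype classes: {sorted(bad)}")
    n_het = int((cls == "het").sum())
    n_hom = int((cls == "hom").sum())
    if n_het < 2:
        raise ValueError(f"heterozygote group too small (n={n_het} < 2)")
    if n_hom < 2:
        raise ValueError(f"homozygote group too small (n={n_hom} < 2)")
    norm = quantile_normalize_to_normal(lr)
    het = norm[cls == "het"]
    hom = norm[cls == "hom"]
    res = stats.ttest_ind(het, hom, equal_var=False, alternative="greater")
    return float(het.mean()), float(res.pvalue)


def overlap_test(
    set_a: Collection, set_b: Collection, universe_size: int
) -> tuple[int, float]:
    """Upper-tail hypergeometric p for the overlap of two gene sets.

    Returns (observed overlap, P[overlap >= observed] when |set_a| genes
    are drawn without replacement from a universe containing |set_b|
    marked genes).  Symmetric in the two sets.
    """
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than the universe")
    k = len(a & b)
    if k > min(len(a), len(b)):  # unreachable for true sets; guards count input
        raise ValueError("overlap exceeds smaller set")
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(b), len(a)))
    return k, min(p, 1.0)
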