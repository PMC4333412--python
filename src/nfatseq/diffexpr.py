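"""Two-group differential-expression testing, threshold filtering, and gene-set algebra.

The expression matrix is on the log2 scale (rows = genes, columns = samples).
For a contrast A vs B, log2 fold change is mean(A) - mean(B); p-values come
from a Welch two-sample t-test per gene and are Benjamini-Hochberg adjusted
across all tested genes.  A gene passes as up-regulated when adj_p <
``adj_p_cutoff`` and its fold change is >= ``fc_cutoff`` (inclusive);
down-regulation mirrors this on the reciprocal fold change.

Degenerate genes whose replicates are constant in both groups are assigned
p = 0 when the group means differ (perfect separation) and p = 1 when they
are equal, with a warning — the t statistic is undefined there.

The NFAT-dependent sets come from the curdlan+FK506 vs curdlan contrast:
genes *reduced* by calcineurin inhibition (down in that contrast) required
NFAT for their curdlan-driven up-regulation, and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import RunConfig, ValidationError, log


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    contrast: str
    log2fc: float
    p_value: float
    adj_p: float


def two_group_test(expr: pd.DataFrame, samples: pd.Series,
                   contrast: tuple[str, str]) -> pd.DataFrame:
    """Welch t + BH for ``contrast = (condition_A, condition_B)``.

    Returns a frame indexed by gene with columns log2fc, p_value, adj_p
    and a ``contrast`` label ``A_vs_B``.  Each group needs >= 2 replicates.
    """
    cond_a, cond_b = contrast
    cols_a = [s for s in expr.columns if samples.get(s) == cond_a]
    cols_b = [s for s in expr.columns if samples.get(s) == cond_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError(
            f"contrast {cond_a} vs {cond_b}: each group needs >= 2 replicates "
            f"(got {len(cols_a)}, {len(cols_b)})")
    a = expr[cols_a].to_numpy(dtype=float)
    b = expr[cols_b].to_numpy(dtype=float)
    l2fc = a.mean(axis=1) - b.mean(axis=1)

    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    import warnings
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-identical replicates trip scipy's catastrophic-cancellation
        # warning; the degenerate branch below handles those genes
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    if degenerate.any():
        log.warning("two_group_test: %d genes with zero variance in both groups",
                    int(degenerate.sum()))
        p = np.where(degenerate, np.where(l2fc == 0.0, 1.0, 0.0), p)
    p = np.nan_to_num(p, nan=1.0)
    adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"contrast": f"{cond_a}_vs_{cond_b}", "log2fc": l2fc, "p_value": p, "adj_p": adj},
        index=expr.index.rename("gene_id"),
    )


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (thin wrapper, exposed for clarity)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def de_filter(results: pd.DataFrame, config: RunConfig) -> tuple[set[str], set[str]]:
    """Split a tested contrast into (up, down) gene-id sets.

    Inclusive fold-change threshold: fc >= fc_cutoff passes.  Comparison is
    done on the log2 scale (log2fc >= log2(fc_cutoff)), which is exact for
    effects planted in log2 units.  The two sets are disjoint by construction.
    """
    if results.empty:
        return set(), set()
    sig = results["adj_p"] < config.adj_p_cutoff
    thr = np.log2(config.fc_cutoff)
    up = set(results.index[sig & (results["log2fc"] >= thr)])
    down = set(results.index[sig & (-results["log2fc"] >= thr)])
    return up, down


def _pct(numer: int, denom: int) -> float:
    """Percentage rounded half-up to one decimal (0.0 when denom == 0)."""
    if denom == 0:
        return 0.0
    frac = Decimal(100) * Decimal(numer) / Decimal(denom)
    return float(frac.quantize(Decimal("0.1"), ROUND_HALF_UP))


def venn_summary(dectin_up: set[str], dectin_down: set[str],
                 nfat_up: set[str], nfat_down: set[str]) -> pd.DataFrame:
    """Cardinalities and overlaps of the dectin-1- and NFAT-modulated sets.

    Reports |dectin_up|, |dectin_down|, |nfat_up|, |nfat_down|, the up-set
    and down-set overlaps, and the up-overlap expressed as a percentage of
    each parent set (one decimal, half-up rounding).
    """
    common_up = dectin_up & nfat_up
    common_down = dectin_down & nfat_down
    return pd.DataFrame([{
        "n_dectin_up": len(dectin_up),
        "n_dectin_down": len(dectin_down),
        "n_nfat_up": len(nfat_up),
        "n_nfat_down": len(nfat_down),
        "n_common_up": len(common_up),
        "n_common_down": len(common_down),
        "pct_common_of_dectin_up": _pct(len(common_up), len(dectin_up)),
        "pct_common_of_nfat_up": _pct(len(common_up), len(nfat_up)),
    }])


def nfat_dependent_sets(expr: pd.DataFrame, samples: pd.Series, config: RunConfig,
                        stim: str = "curdlan", inhib: str = "curdlan_fk506",
                        baseline: str = "untreated"):
    """Run both contrasts and derive the four Venn sets.

    dectin_up/down come from stim vs baseline; nfat_up is the *down* set of
    inhib vs stim (expression lost when calcineurin/NFAT is blocked) and
    nfat_down its up set.
    """
    de_stim = two_group_test(expr, samples, (stim, baseline))
    de_inhib = two_group_test(expr, samples, (inhib, stim))
    dectin_up, dectin_down = de_filter(de_stim, config)
    fk_up, fk_down = de_filter(de_inhib, config)
    return {
        "dectin_up": dectin_up, "dectin_down": dectin_down,
        "nfat_up": fk_down, "nfat_down": fk_up,
        "de_stim": de_stim, "de_inhib": de_inhib,
    }
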