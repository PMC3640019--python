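"""Drug-to-oncogene sensitivity associations and their recapitulation.

For every (drug, genomic feature) pair with enough altered and wild-type cell
lines, the log10 IC50 values of the two groups are compared with a two-sample
t-test (Welch by default).  The *effect* is mean(altered) - mean(wildtype):
a negative effect means the alteration sensitizes cell lines to the drug
(lower IC50), a positive one marks resistance; its sign is the *tendency*.
P-values are adjusted across the whole pair family with the
Benjamini-Hochberg step-up procedure and flagged significant at q <= FDR
(0.2 by default).

Recapitulation asks how well associations discovered from *predicted* IC50s
(test-set predictions only) reproduce those discovered from experimental
values: the fraction of experimentally significant pairs whose predicted
tendency matches, and the fraction that is also significant on the predicted
side with matching tendency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "RecapitulationReport",
    "test_association",
    "bh_adjust",
    "discover_associations",
    "compare_association_sets",
]

DEFAULT_FDR = 0.2
DEFAULT_MIN_GROUP = 3


@dataclass(frozen=True)
class AssociationResult:
    drug_id: str
    feature_id: str
    n_altered: int
    n_wildtype: int
    effect: float  # mean log10 IC50 (altered) - mean log10 IC50 (wildtype)
    tendency: int  # sign of effect: -1 sensitizing, +1 resistance
    p_value: float
    q_value: float = float("nan")
    significant: bool = False


@dataclass(frozen=True)
class RecapitulationReport:
    n_experimental_associations: int
    n_same_tendency: int
    n_predicted_significant_overlap: int

    @property
    def fraction_same_tendency(self) -> float:
        return self.n_same_tendency / self.n_experimental_associations

    @property
    def fraction_recovered_significant(self) -> float:
        return self.n_predicted_significant_overlap / self.n_experimental_associations


def test_association(
    log_ic50_altered,
    log_ic50_wildtype,
    min_group: int = DEFAULT_MIN_GROUP,
    equal_var: bool = False,
):
    """Two-sample t-test of log10 IC50, altered vs wild type.

    Returns ``(effect, tendency, p_value)`` or ``None`` when either group is
    below ``min_group`` (the pair is flagged untested, not an error).  Welch's
    unequal-variance test by default; ``equal_var=True`` gives Student's.
    """
    a = np.asarray(log_ic50_altered, dtype=float)
    w = np.asarray(log_ic50_wildtype, dtype=float)
    if len(a) < min_group or len(w) < min_group:
        return None
    effect = float(a.mean() - w.mean())
    tendency = int(np.sign(effect))
    if np.ptp(a) == 0 and np.ptp(w) == 0 and effect == 0:
        return effect, 0, 1.0  # identical constant groups: no evidence at all
    res = stats.ttest_ind(a, w, equal_var=equal_var)
    p = float(res.pvalue)
    if np.isnan(p):
        p = 1.0
    return effect, tendency, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def discover_associations(
    log_ic50: pd.DataFrame,
    genomic: pd.DataFrame,
    fdr: float = DEFAULT_FDR,
    min_group: int = DEFAULT_MIN_GROUP,
    equal_var: bool = False,
) -> list[AssociationResult]:
    """Test every (drug, genomic feature) pair on that drug's observed entries.

    ``log_ic50`` is a cell-line x drug matrix of log10 IC50 values (NaN =
    unobserved); ``genomic`` the encoded {-1, 0, 1} feature matrix.  A cell
    line counts as *altered* for a feature when its value is non-zero (either
    copy-number direction, a sequence variant, or microsatellite instability).
    BH adjustment runs jointly across all tested pairs; pairs with a group
    below ``min_group`` are skipped.
    """
    cells = [c for c in log_ic50.index if c in set(genomic.index)]
    if not cells:
        raise ValueError("no shared cell lines between response and genomic tables")
    resp = log_ic50.loc[cells]
    geno = genomic.loc[cells]
    results: list[AssociationResult] = []
    for drug in resp.columns:
        y = resp[drug]
        observed = y.notna()
        for feat in geno.columns:
            altered = geno[feat] != 0
            ya = y[observed & altered]
            yw = y[observed & ~altered]
            out = test_association(ya, yw, min_group=min_group, equal_var=equal_var)
            if out is None:
                continue
            effect, tendency, p = out
            results.append(
                AssociationResult(
                    drug_id=str(drug), feature_id=str(feat),
                    n_altered=len(ya), n_wildtype=len(yw),
                    effect=effect, tendency=tendency, p_value=p,
                )
            )
    if not results:
        raise ValueError("no testable (drug, feature) pairs")
    q = bh_adjust([r.p_value for r in results])
    return [
        AssociationResult(
            r.drug_id, r.feature_id, r.n_altered, r.n_wildtype, r.effect,
            r.tendency, r.p_value, float(qi), bool(qi <= fdr),
        )
        for r, qi in zip(results, q)
    ]


def associations_frame(results) -> pd.DataFrame:
    """Tabular view of an association set."""
    return pd.DataFrame(
        [
            {
                "drug": r.drug_id, "feature": r.feature_id,
                "n_altered": r.n_altered, "n_wildtype": r.n_wildtype,
                "effect": r.effect, "tendency": r.tendency,
                "p_value": r.p_value, "q_value": r.q_value,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def compare_association_sets(
    experimental, predicted
) -> RecapitulationReport:
    """Score predicted-side recapitulation of experimentally significant pairs.

    Over the experimentally significant (drug, feature) pairs: the fraction
    whose predicted-side tendency matches, and the fraction that is also
    significant in the predicted set with the same tendency.  Pairs untested
    on the predicted side count as unrecovered.
    """
    exp_sig = [r for r in experimental if r.significant]
    if not exp_sig:
        raise ValueError("experimental association set has no significant pairs")
    pred_by_pair = {(r.drug_id, r.feature_id): r for r in predicted}
    same = overlap = 0
    for r in exp_sig:
        p = pred_by_pair.get((r.drug_id, r.feature_id))
        if p is None:
            continue
        if p.tendency == r.tendency:
            same += 1
            if p.significant:
                overlap += 1
    return RecapitulationReport(
        n_experimental_associations=len(exp_sig),
        n_same_tendency=same,
        n_predicted_significant_overlap=overlap,
    )


def predictions_to_matrix(predictions: pd.DataFrame) -> pd.DataFrame:
    """Pivot test-set predictions into a cell-line x drug log10 IC50 matrix."""
    return predictions.pivot_table(
        index="cell_line", columns="drug", values="log10_ic50", aggfunc="mean"
    )
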